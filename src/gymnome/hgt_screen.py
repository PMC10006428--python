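"""Average-bitscore (ABV) screening for horizontally transferred genes.

Each query protein is searched against three database partitions — an
out-group (archaea + bacteria + fungi), a mid-group (non-gymnosperm plants)
and an in-group (gymnosperms). After keeping at most one (the best) hit per
species and at most ``cap`` hits per database, the mean bitscore (ABV) per
database is compared: a query whose out-group ABV exceeds its mid-group ABV
is a transfer candidate, to be confirmed by phylogeny downstream (outside
this package's scope — candidates are emitted with their kept hit tables).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import pandas as pd

from .errors import ValidationError
from .io_formats import BlastHitRow


@dataclass(frozen=True)
class AbvRecord:
    """Per-query mean bitscores per database partition and the screen verdict."""

    query_id: str
    abv_out: float | None
    abv_mid: float | None
    abv_in: float | None
    n_out: int
    n_mid: int
    n_in: int
    is_candidate: bool
    mid_absent: bool = False
    no_signal: bool = False


def _hit_order(h: BlastHitRow) -> tuple:
    # best first: high bitscore, then low evalue, then lexicographic subject id
    return (-h.bitscore, h.evalue, h.subject_id)


def best_hit_per_species(hits: list[BlastHitRow]) -> list[BlastHitRow]:
    """Keep the single best hit per species (ties: lower evalue, then subject id)."""
    best: dict[str, BlastHitRow] = {}
    for h in hits:
        cur = best.get(h.species)
        if cur is None or _hit_order(h) < _hit_order(cur):
            best[h.species] = h
    return sorted(best.values(), key=_hit_order)


def truncate_top_hits(hits: list[BlastHitRow], cap: int = 100) -> list[BlastHitRow]:
    """Keep the top ``cap`` hits by bitscore (deterministic tie order)."""
    return sorted(hits, key=_hit_order)[:cap]


def compute_abv(hits: list[BlastHitRow]) -> float | None:
    """Arithmetic mean bitscore of the kept hits; None (missing) when empty."""
    if not hits:
        return None
    return sum(h.bitscore for h in hits) / len(hits)


def kept_hits(hits: list[BlastHitRow], cap: int = 100) -> list[BlastHitRow]:
    """The filter pipeline for one query x one database: one hit per species,
    then the top ``cap`` by bitscore."""
    return truncate_top_hits(best_hit_per_species(hits), cap)


def screen_candidates(
    tables: dict[str, list[BlastHitRow]],
    min_out_hits: int = 5,
    cap: int = 100,
) -> list[AbvRecord]:
    """Run the ABV screen over pre-filtered hit tables keyed by db class.

    A query is a candidate iff its out-group ABV is present on at least
    ``min_out_hits`` kept hits and either exceeds the mid-group ABV or the
    mid-group is hit-free (then flagged ``mid_absent`` for scrutiny —
    classic transfer signature but also contamination-prone). Queries with
    only in-group hits are reported ``no_signal``.
    """
    for db in tables:
        if db not in ("out", "mid", "in"):
            raise ValidationError(f"unknown db class {db!r}")
    per_query: dict[str, dict[str, list[BlastHitRow]]] = defaultdict(
        lambda: {"out": [], "mid": [], "in": []}
    )
    for db, hits in tables.items():
        for h in hits:
            if h.db_class != db:
                raise ValidationError(
                    f"hit {h.query_id}->{h.subject_id} labelled {h.db_class!r} "
                    f"in {db!r} table"
                )
            per_query[h.query_id][db].append(h)
    records = []
    for query_id in sorted(per_query):
        kept = {db: kept_hits(per_query[query_id][db], cap) for db in ("out", "mid", "in")}
        abv = {db: compute_abv(kept[db]) for db in kept}
        n = {db: len(kept[db]) for db in kept}
        mid_absent = abv["out"] is not None and abv["mid"] is None
        no_signal = abv["out"] is None and abv["mid"] is None and abv["in"] is not None
        is_candidate = (
            abv["out"] is not None
            and n["out"] >= min_out_hits
            and (abv["mid"] is None or abv["out"] > abv["mid"])
        )
        records.append(
            AbvRecord(
                query_id, abv["out"], abv["mid"], abv["in"],
                n["out"], n["mid"], n["in"],
                is_candidate, mid_absent and is_candidate, no_signal,
            )
        )
    return records


def summarize_candidates(
    records: list[AbvRecord],
    truth: dict[str, bool] | pd.DataFrame | None = None,
) -> dict:
    """Candidate counts, plus confusion-matrix metrics when truth is given."""
    out = {
        "n_queries": len(records),
        "n_candidates": sum(r.is_candidate for r in records),
    }
    if truth is None:
        return out
    if isinstance(truth, pd.DataFrame):
        truth = dict(zip(truth["query_id"], truth["is_transferred"]))
    tp = sum(r.is_candidate and truth.get(r.query_id, False) for r in records)
    fp = sum(r.is_candidate and not truth.get(r.query_id, False) for r in records)
    fn = sum((not r.is_candidate) and truth.get(r.query_id, False) for r in records)
    out.update(
        tp=tp, fp=fp, fn=fn,
        precision=tp / (tp + fp) if tp + fp else float("nan"),
        recall=tp / (tp + fn) if tp + fn else float("nan"),
    )
    return out


def records_to_frame(records: list[AbvRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])
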