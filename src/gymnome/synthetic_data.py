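"""Seeded generators producing every input the pipeline consumes, with truth tables.

Each generator emulates one feature of a large gymnosperm seed genome:

* divergent 5'/3' LTR pairs of known insertion age, evolved site-by-site so the
  multiple-hit correction of the K2P estimator is genuinely exercised;
* per-cytosine methylation count tracks (CG/CHG/CHH) with planted
  demethylation valleys and an unmethylated lambda-phage spike-in whose
  apparent methylation estimates the bisulfite non-conversion rate;
* three-database (out/mid/in-group) BLAST bitscore structures with planted
  horizontal transfers;
* Ks mixtures carrying an ancient whole-genome-duplication component;
* chromosome sequences with telomeric TTTAGGG arrays and a tandem 101-bp
  centromeric monomer.

All randomness flows through one ``numpy.random.default_rng(seed)`` per call,
so identical parameters give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_formats import (
    BlastHitRow,
    CytosineRecord,
    GenomeSequence,
    Interval,
    KsRecord,
)
from .ltr_dynamics import LtrPairAlignment, classify_substitution

BASES = np.array(list("ACGT"))
TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}
TELOMERE_MOTIF = "TTTAGGG"


def _revcomp(seq: str) -> str:
    comp = str.maketrans("ACGTN", "TGCAN")
    return seq.translate(comp)[::-1]


# ---------------------------------------------------------------------------
# LTR pairs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LtrSimParams:
    """Forward model for LTR divergence: both LTRs are identical at insertion
    and accumulate substitutions independently at ``subst_rate`` per site per
    year for ``true_age`` years (expected pairwise divergence ~ 2 r T before
    multiple-hit saturation)."""

    n_elements: int = 200
    ltr_length: int = 2000
    true_age: float = 1.0e7
    subst_rate: float = 2.2e-9
    transition_fraction: float = 2.0 / 3.0
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.transition_fraction <= 1.0):
            raise ValidationError("transition_fraction must be in [0, 1]")
        if self.true_age < 0:
            raise ValidationError("true_age must be >= 0")
        if self.subst_rate <= 0:
            raise ValidationError("subst_rate must be > 0")
        if self.n_elements < 1 or self.ltr_length < 1:
            raise ValidationError("n_elements and ltr_length must be >= 1")


def _evolve(seq: np.ndarray, expected_hits: float, transition_fraction: float,
            rng: np.random.Generator) -> np.ndarray:
    """Apply an independent per-site Poisson number of substitutions."""
    out = seq.copy()
    hits = rng.poisson(expected_hits, size=len(seq))
    for i in np.nonzero(hits)[0]:
        base = out[i]
        for _ in range(hits[i]):
            if rng.random() < transition_fraction:
                base = TRANSITION[base]
            else:
                base = TRANSVERSIONS[base][rng.integers(2)]
        out[i] = base
    return out


def simulate_ltr_pairs(params: LtrSimParams) -> tuple[list[LtrPairAlignment], pd.DataFrame]:
    """Simulate intact-element LTR pairs of known age; returns (alignments, truth)."""
    rng = np.random.default_rng(params.seed)
    per_branch = params.subst_rate * params.true_age
    alignments: list[LtrPairAlignment] = []
    truth_rows = []
    for i in range(params.n_elements):
        ancestral = rng.choice(BASES, size=params.ltr_length)
        five = _evolve(ancestral, per_branch, params.transition_fraction, rng)
        three = _evolve(ancestral, per_branch, params.transition_fraction, rng)
        s5, s3 = "".join(five), "".join(three)
        n_ts = n_tv = 0
        for a, b in zip(s5, s3):
            kind = classify_substitution(a, b)
            if kind == "transition":
                n_ts += 1
            elif kind == "transversion":
                n_tv += 1
        element_id = f"LTR{i + 1:04d}"
        alignments.append(
            LtrPairAlignment(element_id, s5, s3, params.ltr_length, n_ts, n_tv)
        )
        truth_rows.append({"element_id": element_id, "true_age": params.true_age})
    return alignments, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# methylome
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MethylomeSimParams:
    """Per-cytosine sampling model: read depth ~ Poisson(mean_depth) and
    methylated count ~ Binomial(depth, level + (1 - level) * non_conversion).
    ``true_levels`` defaults to the global CG/CHG/CHH levels typical of a
    heavily methylated gymnosperm seed genome (0.83 / 0.69 / 0.04)."""

    n_sites_per_context: dict = field(
        default_factory=lambda: {"CG": 4000, "CHG": 4000, "CHH": 8000}
    )
    true_levels: dict = field(
        default_factory=lambda: {"CG": 0.83, "CHG": 0.69, "CHH": 0.04}
    )
    mean_depth: float = 20.0
    non_conversion: float = 0.005
    planted_dmvs: tuple = ()
    lambda_sites: int = 5000
    chrom: str = "chr1"
    chrom_length: int | None = None
    seed: int = 0

    def __post_init__(self):
        for ctx, lv in self.true_levels.items():
            if not (0.0 <= lv <= 1.0):
                raise ValidationError(f"level for {ctx} outside [0, 1]")
        if not (0.0 <= self.non_conversion <= 1.0):
            raise ValidationError("non_conversion must be in [0, 1]")
        if self.mean_depth < 0:
            raise ValidationError("mean_depth must be >= 0")

    @property
    def total_sites(self) -> int:
        return sum(self.n_sites_per_context.values())

    @property
    def span(self) -> int:
        # ~50 bp mean inter-cytosine spacing unless stated
        return self.chrom_length or self.total_sites * 50


def simulate_methylome(
    params: MethylomeSimParams,
) -> tuple[list[CytosineRecord], list[CytosineRecord], dict]:
    """Simulate genomic + lambda CX tracks; returns (records, lambda_records, truth).

    ``truth`` is a dict with a per-site table (``sites``) and the planted DMV
    intervals (``dmvs``).
    """
    rng = np.random.default_rng(params.seed)
    span = params.span
    for dmv in params.planted_dmvs:
        if dmv.chrom != params.chrom or dmv.end > span:
            raise ValidationError(
                f"planted DMV {dmv.chrom}:{dmv.start}-{dmv.end} outside "
                f"simulated chromosome {params.chrom} (span {span})"
            )

    total = params.total_sites
    positions = np.sort(rng.choice(span, size=total, replace=False)) + 1  # 1-based
    contexts = np.concatenate(
        [np.repeat(ctx, n) for ctx, n in sorted(params.n_sites_per_context.items())]
    )
    rng.shuffle(contexts)
    strands = rng.choice(np.array(["+", "-"]), size=total)

    levels = np.array([params.true_levels[c] for c in contexts])
    in_dmv = np.zeros(total, dtype=bool)
    for dmv in params.planted_dmvs:
        in_dmv |= (positions - 1 >= dmv.start) & (positions - 1 < dmv.end)
    levels = np.where(in_dmv, 0.0, levels)

    depth = rng.poisson(params.mean_depth, size=total)
    p_obs = levels + (1.0 - levels) * params.non_conversion
    count_m = rng.binomial(depth, p_obs)

    records = [
        CytosineRecord(params.chrom, int(p), s, c, int(m), int(t))
        for p, s, c, m, t in zip(positions, strands, contexts, count_m, depth)
    ]

    lam_positions = np.arange(1, params.lambda_sites + 1) * 10
    lam_depth = rng.poisson(params.mean_depth, size=params.lambda_sites)
    lam_m = rng.binomial(lam_depth, params.non_conversion)
    lam_ctx = np.tile(np.array(["CG", "CHG", "CHH"]), params.lambda_sites // 3 + 1)
    lambda_records = [
        CytosineRecord("lambda", int(p), "+", c, int(m), int(t))
        for p, c, m, t in zip(lam_positions, lam_ctx, lam_m, lam_depth)
    ]

    truth = {
        "sites": pd.DataFrame(
            {
                "chrom": params.chrom,
                "pos": positions,
                "context": contexts,
                "true_level": levels,
                "in_dmv": in_dmv,
            }
        ),
        "dmvs": list(params.planted_dmvs),
    }
    return records, lambda_records, truth


# ---------------------------------------------------------------------------
# HGT bitscore tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HgtSimParams:
    """Bitscore structure of the three-database screen: native queries score
    highest against close relatives (in > mid > out), transferred queries
    against the out-group (prokaryote/fungal) database."""

    n_queries: int = 30
    n_transferred: int = 5
    species_per_db: int = 20
    bitscore_means: dict = field(
        default_factory=lambda: {
            "native": {"out": 80.0, "mid": 160.0, "in": 260.0},
            "transferred": {"out": 260.0, "mid": 90.0, "in": 220.0},
        }
    )
    bitscore_sd: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if self.n_transferred > self.n_queries:
            raise ValidationError("n_transferred must be <= n_queries")
        if self.bitscore_sd <= 0:
            raise ValidationError("bitscore_sd must be > 0")
        if self.species_per_db < 1:
            raise ValidationError("species_per_db must be >= 1")


def simulate_hgt_tables(
    params: HgtSimParams,
) -> tuple[dict[str, list[BlastHitRow]], dict[str, str], pd.DataFrame]:
    """Simulate hits against out/mid/in databases; returns (tables, species_map, truth)."""
    rng = np.random.default_rng(params.seed)
    transferred = set(
        rng.choice(params.n_queries, size=params.n_transferred, replace=False)
    )
    tables: dict[str, list[BlastHitRow]] = {"out": [], "mid": [], "in": []}
    species_map: dict[str, str] = {}
    truth_rows = []
    for q in range(params.n_queries):
        query_id = f"q{q + 1:04d}"
        kind = "transferred" if q in transferred else "native"
        truth_rows.append({"query_id": query_id, "is_transferred": kind == "transferred"})
        for db in ("out", "mid", "in"):
            mean = params.bitscore_means[kind][db]
            scores = np.maximum(
                1.0, rng.normal(mean, params.bitscore_sd, size=params.species_per_db)
            )
            for s in range(params.species_per_db):
                species = f"{db}_sp{s + 1:03d}"
                subject = f"{species}_p1"
                species_map[subject] = species
                tables[db].append(
                    BlastHitRow(query_id, subject, species, db, float(scores[s]), 1e-50)
                )
    return tables, species_map, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# Ks mixtures
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KsSimParams:
    """Gaussian mixture over paralog Ks, truncated at 0. The default plants a
    recent-duplicate component at 0.3 and an ancient-WGD component at 1.4."""

    component_weights: tuple = (0.5, 0.5)
    component_means: tuple = (0.3, 1.4)
    component_sds: tuple = (0.1, 0.25)
    n_pairs: int = 2000
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.component_weights) - 1.0) > 1e-9:
            raise ValidationError("component_weights must sum to 1")
        if any(m <= 0 for m in self.component_means):
            raise ValidationError("component_means must be > 0")
        if any(s < 0 for s in self.component_sds):
            raise ValidationError("component_sds must be >= 0")
        if not (len(self.component_weights) == len(self.component_means)
                == len(self.component_sds)):
            raise ValidationError("mixture spec lengths differ")


def simulate_ks(params: KsSimParams) -> list[KsRecord]:
    """Draw n_pairs Ks values from the mixture (negatives redrawn)."""
    rng = np.random.default_rng(params.seed)
    comp = rng.choice(len(params.component_weights), size=params.n_pairs,
                      p=np.asarray(params.component_weights))
    means = np.asarray(params.component_means)[comp]
    sds = np.asarray(params.component_sds)[comp]
    vals = rng.normal(means, sds)
    bad = vals < 0
    while bad.any():
        vals[bad] = rng.normal(means[bad], sds[bad])
        bad = vals < 0
    return [KsRecord(f"pair{i + 1:05d}", float(v)) for i, v in enumerate(vals)]


# ---------------------------------------------------------------------------
# feature genome (telomeres + centromeric monomer)
# ---------------------------------------------------------------------------


def simulate_feature_genome(
    n_chroms: int = 2,
    chrom_length: int = 50_000,
    telomere_copies: int = 100,
    centromere_monomer_length: int = 101,
    centromere_copies: int = 100,
    seed: int = 0,
    ends: str = "both",
) -> tuple[list[GenomeSequence], pd.DataFrame]:
    """Random chromosomes with planted telomere arrays and a centromeric
    tandem array; returns (sequences, truth table of placements).

    ``ends`` selects which chromosome ends receive telomere arrays:
    "both", "5", "3" or "none". The 5' array is the reverse complement of
    the 3' TTTAGGG array, as on a real chromosome.
    """
    if ends not in ("both", "5", "3", "none"):
        raise ValidationError(f"invalid ends {ends!r}")
    rng = np.random.default_rng(seed)
    telo = TELOMERE_MOTIF * telomere_copies
    telo_len = len(telo)
    cen_len = centromere_monomer_length * centromere_copies
    need = cen_len + 2 * telo_len
    if need > chrom_length:
        raise ValidationError(
            f"planted features ({need} bp) exceed chrom_length ({chrom_length} bp)"
        )
    seqs: list[GenomeSequence] = []
    truth_rows = []
    for c in range(n_chroms):
        chrom = f"chr{c + 1}"
        arr = rng.choice(BASES, size=chrom_length)
        seq = "".join(arr)
        if centromere_copies > 0:
            monomer = "".join(rng.choice(BASES, size=centromere_monomer_length))
            cen_start = (chrom_length - cen_len) // 2
            seq = seq[:cen_start] + monomer * centromere_copies + seq[cen_start + cen_len:]
            truth_rows.append({
                "chrom": chrom, "feature": "centromere", "start": cen_start,
                "end": cen_start + cen_len, "period": centromere_monomer_length,
                "copies": centromere_copies,
            })
        if telomere_copies > 0 and ends in ("both", "5"):
            seq = _revcomp(telo) + seq[telo_len:]
            truth_rows.append({
                "chrom": chrom, "feature": "telomere_5prime", "start": 0,
                "end": telo_len, "period": len(TELOMERE_MOTIF),
                "copies": telomere_copies,
            })
        if telomere_copies > 0 and ends in ("both", "3"):
            seq = seq[:-telo_len] + telo
            truth_rows.append({
                "chrom": chrom, "feature": "telomere_3prime",
                "start": chrom_length - telo_len, "end": chrom_length,
                "period": len(TELOMERE_MOTIF), "copies": telomere_copies,
            })
        seqs.append(GenomeSequence(chrom, seq))
    return seqs, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# dataset writers (formats io_formats reads, plus TSV truth tables)
# ---------------------------------------------------------------------------


def write_methylome_dataset(params: MethylomeSimParams, out_dir: str | Path) -> None:
    from .io_formats import write_cx_report

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records, lam, truth = simulate_methylome(params)
    write_cx_report(records, out_dir / "genome.cx.tsv")
    write_cx_report(lam, out_dir / "lambda.cx.tsv")
    truth["sites"].to_csv(out_dir / "truth_sites.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"chrom": d.chrom, "start": d.start, "end": d.end} for d in truth["dmvs"]]
    ).to_csv(out_dir / "truth_dmvs.tsv", sep="\t", index=False)


def write_hgt_dataset(params: HgtSimParams, out_dir: str | Path) -> None:
    from .io_formats import write_blast_tab

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tables, species_map, truth = simulate_hgt_tables(params)
    for db, rows in tables.items():
        write_blast_tab(rows, out_dir / f"{db}.blast.tsv")
    with open(out_dir / "species_map.tsv", "w") as fh:
        for subject, species in sorted(species_map.items()):
            fh.write(f"{subject}\t{species}\n")
    truth.to_csv(out_dir / "truth_transfers.tsv", sep="\t", index=False)


def write_ltr_dataset(params: LtrSimParams, out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    alignments, truth = simulate_ltr_pairs(params)
    with open(out_dir / "ltr_pairs.tsv", "w") as fh:
        fh.write("element_id\tltr5\tltr3\n")
        for a in alignments:
            fh.write(f"{a.element_id}\t{a.aligned_5prime}\t{a.aligned_3prime}\n")
    truth.to_csv(out_dir / "truth_ages.tsv", sep="\t", index=False)


def write_ks_dataset(params: KsSimParams, out_dir: str | Path) -> None:
    from .io_formats import write_ks_table

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_ks_table(simulate_ks(params), out_dir / "ks.tsv")
    pd.DataFrame(
        {
            "weight": params.component_weights,
            "mean": params.component_means,
            "sd": params.component_sds,
        }
    ).to_csv(out_dir / "truth_mixture.tsv", sep="\t", index=False)


def write_feature_genome_dataset(out_dir: str | Path, **kwargs) -> None:
    from .io_formats import write_fasta

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seqs, truth = simulate_feature_genome(**kwargs)
    write_fasta(seqs, out_dir / "genome.fasta")
    truth.to_csv(out_dir / "truth_features.tsv", sep="\t", index=False)
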