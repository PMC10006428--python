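"""Whole-genome bisulfite methylome statistics.

The statistical chain:

1. the bisulfite conversion rate is estimated from an unmethylated
   lambda-phage spike-in as converted / total read observations;
2. each covered cytosine is tested for methylation with a one-sided
   upper-tail binomial test of its methylated count against the null
   success probability (1 - conversion rate), i.e. failure-to-convert
   noise, with Benjamini-Hochberg FDR control per context class (CG, CHG,
   CHH have very different null burdens) and calls at q < 0.05;
3. every methylation *level* is count-pooled: sum(mC) / sum(mC + umC),
   never a mean of per-site ratios — so the global level is exactly the
   coverage-weighted mean of window levels;
4. demethylation valleys (DMVs) are maximal runs of covered cytosines with
   per-site level below 5%, chained while the gap between successive
   qualifying sites stays within ``max_gap``, then filtered on span, site
   count and re-checked pooled per-context level;
5. common DMVs across samples are the base-pair intersection of each
   sample's merged DMV intervals.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .io_formats import (
    CONTEXTS,
    CytosineRecord,
    ExpressionRecord,
    GeneModel,
    Interval,
)

# ---------------------------------------------------------------------------
# conversion rate and site calling
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConversionEstimate:
    """Bisulfite conversion rate from the lambda spike-in (fully unmethylated,
    so any methylated-looking read is a conversion failure)."""

    converted: int
    total: int

    def __post_init__(self):
        if self.total <= 0:
            raise ValidationError("conversion estimate needs total > 0")
        if not (0 <= self.converted <= self.total):
            raise ValidationError("invalid converted/total counts")

    @property
    def rate(self) -> float:
        return self.converted / self.total


@dataclass(frozen=True)
class MethylationCall:
    site: CytosineRecord
    p_value: float
    q_value: float
    is_methylated: bool


@dataclass(frozen=True)
class DmvRegion:
    """A merged low-methylation interval with per-context pooled levels."""

    interval: Interval
    n_sites: int
    level_cg: float | None
    level_chg: float | None
    level_chh: float | None


@dataclass(frozen=True)
class MetaProfile:
    """Ordered feature bins (upstream / exon / intron / downstream) with
    pooled methylation levels per context per bin."""

    feature_bins: tuple
    levels: pd.DataFrame  # index = feature_bins, columns = contexts


def estimate_conversion_rate(lambda_records: list[CytosineRecord]) -> ConversionEstimate:
    """rate = sum(count_total - count_m) / sum(count_total) over lambda cytosines."""
    total = sum(r.count_total for r in lambda_records)
    if total == 0:
        raise ValidationError("zero total coverage on lambda spike-in")
    m = sum(r.count_m for r in lambda_records)
    return ConversionEstimate(total - m, total)


def call_methylated_sites(
    records: list[CytosineRecord],
    conversion: ConversionEstimate,
    alpha: float = 0.05,
    min_coverage: int = 4,
) -> list[MethylationCall]:
    """Binomial test of each covered site against conversion-failure noise.

    One-sided upper tail: p = P(X >= count_m | n = count_total,
    p0 = 1 - conversion rate). BH adjustment is applied within each context
    class; a site is called methylated iff q < alpha.
    """
    from statsmodels.stats.multitest import multipletests

    if not (0.0 < alpha < 1.0):
        raise ValidationError("alpha must be in (0, 1)")
    p0 = 1.0 - conversion.rate
    kept = [r for r in records if r.count_total >= min_coverage]
    calls: list[MethylationCall | None] = [None] * len(kept)
    by_context: dict[str, list[int]] = defaultdict(list)
    for i, r in enumerate(kept):
        by_context[r.context].append(i)
    for context, idx in by_context.items():
        m = np.array([kept[i].count_m for i in idx])
        n = np.array([kept[i].count_total for i in idx])
        # P(X >= m) = sf(m - 1); exact at p0 = 0 (point mass at zero)
        pvals = stats.binom.sf(m - 1, n, p0)
        _, qvals, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
        for j, i in enumerate(idx):
            calls[i] = MethylationCall(
                kept[i], float(pvals[j]), float(qvals[j]), bool(qvals[j] < alpha)
            )
    return [c for c in calls if c is not None]


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone step-up)."""
    from statsmodels.stats.multitest import multipletests

    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals
    return multipletests(pvals, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# levels
# ---------------------------------------------------------------------------


def methylation_level(records: list[CytosineRecord]) -> float | None:
    """Count-pooled level sum(mC)/sum(mC+umC); None when nothing is covered."""
    total = sum(r.count_total for r in records)
    if total == 0:
        return None
    return sum(r.count_m for r in records) / total


def binned_levels(
    records: list[CytosineRecord],
    chrom_sizes: dict[str, int],
    bin_size: int = 10_000,
    contexts: tuple = CONTEXTS,
) -> pd.DataFrame:
    """Count-pooled level per context per non-overlapping genomic bin.

    Bins with no covered site get NaN (missing, not zero). The last partial
    bin of each chromosome is retained.
    """
    if bin_size <= 0:
        raise ValidationError("bin size must be > 0")
    acc: dict[tuple, list[int]] = defaultdict(lambda: [0, 0])
    for r in records:
        if r.context not in contexts or r.chrom not in chrom_sizes:
            continue
        b = (r.pos - 1) // bin_size
        key = (r.chrom, b, r.context)
        acc[key][0] += r.count_m
        acc[key][1] += r.count_total
    rows = []
    for chrom, size in chrom_sizes.items():
        n_bins = (size + bin_size - 1) // bin_size
        for b in range(n_bins):
            start = b * bin_size
            end = min(size, start + bin_size)
            for ctx in contexts:
                m, t = acc.get((chrom, b, ctx), (0, 0))
                rows.append({
                    "chrom": chrom, "bin_start": start, "bin_end": end,
                    "context": ctx,
                    "level": (m / t) if t > 0 else np.nan,
                    "count_m": m, "count_total": t,
                })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# gene metaprofiles and gene-body methylation
# ---------------------------------------------------------------------------


def _index_records(records):
    by_chrom: dict[str, list[CytosineRecord]] = defaultdict(list)
    for r in records:
        by_chrom[r.chrom].append(r)
    out = {}
    for chrom, recs in by_chrom.items():
        recs.sort(key=lambda r: r.pos)
        pos = np.array([r.pos - 1 for r in recs])  # 0-based
        m = np.array([r.count_m for r in recs])
        t = np.array([r.count_total for r in recs])
        ctx = np.array([r.context for r in recs])
        out[chrom] = (pos, m, t, ctx)
    return out


def _accumulate_segment(index, chrom, start, end, n_bins, reverse,
                        add):
    """Distribute cytosines in [start, end) into n_bins by fractional position."""
    if chrom not in index or end <= start:
        return
    pos, m, t, ctx = index[chrom]
    lo = np.searchsorted(pos, start, side="left")
    hi = np.searchsorted(pos, end, side="left")
    if hi <= lo:
        return
    frac = (pos[lo:hi] - start) / (end - start)
    if reverse:
        frac = 1.0 - frac - 1e-12
    bins = np.minimum((frac * n_bins).astype(int), n_bins - 1)
    for b, mm, tt, cc in zip(bins, m[lo:hi], t[lo:hi], ctx[lo:hi]):
        add(int(b), cc, int(mm), int(tt))


def _accumulate_spliced(index, chrom, segments, n_bins, reverse, add):
    """Like _accumulate_segment, over a chain of segments with a concatenated axis."""
    total = sum(e - s for s, e in segments)
    if total == 0 or chrom not in index:
        return
    pos, m, t, ctx = index[chrom]
    offset = 0
    for s, e in segments:
        lo = np.searchsorted(pos, s, side="left")
        hi = np.searchsorted(pos, e, side="left")
        if hi > lo:
            frac = (pos[lo:hi] - s + offset) / total
            if reverse:
                frac = 1.0 - frac - 1e-12
            bins = np.minimum((frac * n_bins).astype(int), n_bins - 1)
            for b, mm, tt, cc in zip(bins, m[lo:hi], t[lo:hi], ctx[lo:hi]):
                add(int(b), cc, int(mm), int(tt))
        offset += e - s


def gene_metaprofile(
    records: list[CytosineRecord],
    genes: list[GeneModel],
    flank: int = 2000,
    n_body_bins: int = 20,
    n_flank_bins: int = 10,
) -> MetaProfile:
    """Pooled methylation metaprofile over upstream flank, exons, introns and
    downstream flank, strand-aware (upstream = 5' of the gene).

    Exonic (and intronic) cytosines are placed on a concatenated
    spliced axis scaled to ``n_body_bins``. Genes on chromosomes absent
    from ``records`` are skipped (counted in the returned profile's
    ``levels.attrs['n_skipped']``).
    """
    if not genes:
        raise ValidationError("no genes given")
    index = _index_records(records)
    labels = (
        [f"upstream_{i + 1}" for i in range(n_flank_bins)]
        + [f"exon_{i + 1}" for i in range(n_body_bins)]
        + [f"intron_{i + 1}" for i in range(n_body_bins)]
        + [f"downstream_{i + 1}" for i in range(n_flank_bins)]
    )
    acc = {(lab, ctx): [0, 0] for lab in labels for ctx in CONTEXTS}

    def adder(prefix):
        def add(b, ctx, m, t):
            cell = acc[(f"{prefix}_{b + 1}", ctx)]
            cell[0] += m
            cell[1] += t
        return add

    n_skipped = 0
    for g in genes:
        chrom = g.interval.chrom
        if chrom not in index:
            n_skipped += 1
            continue
        minus = g.interval.strand == "-"
        if minus:
            up = (g.interval.end, g.interval.end + flank)
            down = (max(0, g.interval.start - flank), g.interval.start)
        else:
            up = (max(0, g.interval.start - flank), g.interval.start)
            down = (g.interval.end, g.interval.end + flank)
        _accumulate_segment(index, chrom, up[0], up[1], n_flank_bins, minus,
                            adder("upstream"))
        _accumulate_segment(index, chrom, down[0], down[1], n_flank_bins, minus,
                            adder("downstream"))
        exon_segs = [(e.start, e.end) for e in g.exons]
        _accumulate_spliced(index, chrom, exon_segs, n_body_bins, minus,
                            adder("exon"))
        intron_segs = [(iv.start, iv.end) for iv in g.introns]
        if intron_segs:
            _accumulate_spliced(index, chrom, intron_segs, n_body_bins, minus,
                                adder("intron"))

    data = {
        ctx: [
            (acc[(lab, ctx)][0] / acc[(lab, ctx)][1])
            if acc[(lab, ctx)][1] > 0 else np.nan
            for lab in labels
        ]
        for ctx in CONTEXTS
    }
    levels = pd.DataFrame(data, index=labels)
    levels.attrs["n_skipped"] = n_skipped
    return MetaProfile(tuple(labels), levels)


def expression_ventile_gbm(
    records: list[CytosineRecord],
    genes: list[GeneModel],
    expression: list[ExpressionRecord],
    n_groups: int = 20,
) -> pd.DataFrame:
    """Gene-body methylation vs expression: genes ranked by TPM, split into
    ``n_groups`` groups; per group the median TPM and the pooled exonic
    methylation level per context.

    TPM is averaged across samples per gene; ties are ordered stably by
    gene id. Group sizes differ by at most one when n_genes is not a
    multiple of n_groups.
    """
    if n_groups > len(genes):
        raise ValidationError("n_groups exceeds number of genes")
    tpm_acc: dict[str, list[float]] = defaultdict(list)
    for e in expression:
        tpm_acc[e.gene_id].append(e.tpm)
    missing = [g.gene_id for g in genes if g.gene_id not in tpm_acc]
    if missing:
        raise ValidationError(
            f"expression table lacks {len(missing)} gene(s), e.g. {missing[0]!r}"
        )
    gene_tpm = {gid: float(np.mean(v)) for gid, v in tpm_acc.items()}
    ordered = sorted(genes, key=lambda g: (gene_tpm[g.gene_id], g.gene_id))
    groups = np.array_split(np.arange(len(ordered)), n_groups)
    index = _index_records(records)
    rows = []
    for gi, idxs in enumerate(groups):
        members = [ordered[i] for i in idxs]
        ctx_counts = {ctx: [0, 0] for ctx in CONTEXTS}
        for g in members:
            chrom = g.interval.chrom
            if chrom not in index:
                continue
            pos, m, t, ctx = index[chrom]
            for ex in g.exons:
                lo = np.searchsorted(pos, ex.start, side="left")
                hi = np.searchsorted(pos, ex.end, side="left")
                for j in range(lo, hi):
                    ctx_counts[ctx[j]][0] += int(m[j])
                    ctx_counts[ctx[j]][1] += int(t[j])
        row = {
            "group": gi + 1,
            "median_tpm": float(np.median([gene_tpm[g.gene_id] for g in members])),
            "n_genes": len(members),
        }
        for c in CONTEXTS:
            mm, tt = ctx_counts[c]
            row[f"level_{c}"] = (mm / tt) if tt > 0 else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# demethylation valleys
# ---------------------------------------------------------------------------


def detect_dmv(
    records: list[CytosineRecord],
    threshold: float = 0.05,
    min_length: int = 1000,
    min_sites: int = 10,
    max_gap: int = 2000,
    min_coverage: int = 4,
    mode: str = "all",
) -> list[DmvRegion]:
    """Merge runs of low-methylation cytosines into demethylation valleys.

    A covered site (count_total >= min_coverage) qualifies when its per-site
    level < ``threshold``. Successive qualifying sites are chained while
    their genomic gap is <= ``max_gap`` AND the chain, taken over all
    covered sites it spans, keeps every pooled per-context level below the
    threshold (mode "all", the default; mode "any" demands only one
    context) — the low-methylation condition is enforced on the growing
    region itself, so a valley cannot leak into high-methylation
    background through isolated noisy sites. A closed chain is kept when
    its span >= ``min_length`` and it holds >= ``min_sites`` covered
    sites.
    """
    if not (0.0 < threshold < 1.0):
        raise ValidationError("threshold must be inside (0, 1)")
    if mode not in ("all", "any"):
        raise ValidationError(f"invalid mode {mode!r}")
    by_chrom: dict[str, list[CytosineRecord]] = defaultdict(list)
    for r in records:
        if r.count_total >= min_coverage:
            by_chrom[r.chrom].append(r)
    regions: list[DmvRegion] = []
    for chrom in sorted(by_chrom):
        recs = sorted(by_chrom[chrom], key=lambda r: r.pos)
        pos = np.array([r.pos for r in recs])
        # per-context cumulative counts: window sums in O(1)
        cum_m = {}
        cum_t = {}
        for ctx in CONTEXTS:
            sel = np.array([r.context == ctx for r in recs])
            cum_m[ctx] = np.concatenate(
                [[0], np.cumsum(np.where(sel, [r.count_m for r in recs], 0))]
            )
            cum_t[ctx] = np.concatenate(
                [[0], np.cumsum(np.where(sel, [r.count_total for r in recs], 0))]
            )

        def pooled_ok(i: int, j: int) -> bool:
            """Pooled-level condition over covered sites i..j inclusive."""
            oks = []
            for ctx in CONTEXTS:
                t = cum_t[ctx][j + 1] - cum_t[ctx][i]
                if t == 0:
                    continue
                m = cum_m[ctx][j + 1] - cum_m[ctx][i]
                oks.append(m / t < threshold)
            if not oks:
                return False
            return all(oks) if mode == "all" else any(oks)

        qual_idx = [i for i, r in enumerate(recs) if r.level < threshold]
        if not qual_idx:
            continue

        def close(first: int, last: int):
            start, end = int(pos[first]) - 1, int(pos[last])  # 0-based half-open
            n_inside = last - first + 1
            if end - start < min_length or n_inside < min_sites:
                return
            levels = {}
            for ctx in CONTEXTS:
                t = cum_t[ctx][last + 1] - cum_t[ctx][first]
                m = cum_m[ctx][last + 1] - cum_m[ctx][first]
                levels[ctx] = (m / t) if t > 0 else None
            regions.append(
                DmvRegion(Interval(chrom, start, end), n_inside,
                          levels["CG"], levels["CHG"], levels["CHH"])
            )

        first = last = qual_idx[0]
        for i in qual_idx[1:]:
            if pos[i] - pos[last] <= max_gap and pooled_ok(first, i):
                last = i
            else:
                close(first, last)
                first = last = i
        close(first, last)
    return regions


def _merge_intervals(intervals: list[Interval]) -> dict[str, list[tuple[int, int]]]:
    by_chrom: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for iv in intervals:
        by_chrom[iv.chrom].append((iv.start, iv.end))
    merged = {}
    for chrom, spans in by_chrom.items():
        spans.sort()
        out = [list(spans[0])]
        for s, e in spans[1:]:
            if s <= out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        merged[chrom] = [(s, e) for s, e in out]
    return merged


def _intersect(a: dict, b: dict) -> dict[str, list[tuple[int, int]]]:
    out: dict[str, list[tuple[int, int]]] = {}
    for chrom in set(a) & set(b):
        pieces = []
        ai = bi = 0
        sa, sb = a[chrom], b[chrom]
        while ai < len(sa) and bi < len(sb):
            s = max(sa[ai][0], sb[bi][0])
            e = min(sa[ai][1], sb[bi][1])
            if s < e:
                pieces.append((s, e))
            if sa[ai][1] < sb[bi][1]:
                ai += 1
            else:
                bi += 1
        if pieces:
            out[chrom] = pieces
    return out


def common_dmvs(
    dmv_sets: list[list[DmvRegion]] | list[list[Interval]],
    min_length: int = 1000,
) -> list[Interval]:
    """Base-pair intersection of the merged DMV intervals of >= 2 samples.

    Intersected pieces shorter than ``min_length`` are dropped.
    """
    if len(dmv_sets) < 2:
        raise ValidationError("need at least two DMV sets")
    merged_sets = []
    for regions in dmv_sets:
        ivs = [r.interval if isinstance(r, DmvRegion) else r for r in regions]
        merged_sets.append(_merge_intervals(ivs))
    common = merged_sets[0]
    for other in merged_sets[1:]:
        common = _intersect(common, other)
    out = []
    for chrom in sorted(common):
        for s, e in common[chrom]:
            if e - s >= min_length:
                out.append(Interval(chrom, s, e))
    return out


def annotate_dmv_genes(
    dmvs: list[DmvRegion] | list[Interval],
    genes: list[GeneModel],
) -> pd.DataFrame:
    """Flag genes overlapping any DMV by >= 1 bp (half-open arithmetic)."""
    ivs = [d.interval if isinstance(d, DmvRegion) else d for d in dmvs]
    merged = _merge_intervals(ivs)
    rows = []
    for g in genes:
        spans = merged.get(g.interval.chrom, [])
        hit = any(s < g.interval.end and g.interval.start < e for s, e in spans)
        rows.append({"gene_id": g.gene_id, "in_dmv": hit})
    return pd.DataFrame(rows)


def enrichment_chi2(
    in_class_in_dmv: int,
    in_class_out: int,
    out_class_in_dmv: int,
    out_class_out: int,
) -> tuple[float, int, float]:
    """Pearson chi-squared (df=1, no continuity correction) on a 2x2 table."""
    table = np.array(
        [[in_class_in_dmv, in_class_out], [out_class_in_dmv, out_class_out]],
        dtype=float,
    )
    if (table < 0).any():
        raise ValidationError("cell counts must be >= 0")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValidationError("zero marginal in the 2x2 table")
    chi2, p, dof, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), int(dof), float(p)
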