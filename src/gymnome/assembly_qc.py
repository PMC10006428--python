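"""Assembly-descriptive arithmetic: N50, coverage folds, Phred-QV accuracy,
anchoring/repeat fractions, k-mer genome-size estimation, telomere and
centromere-monomer detection.

Printed-precision rounding is half-up (one decimal for folds/percentages,
three for base accuracy), matching how reported assembly statistics are
conventionally quoted.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_formats import GenomeSequence


def round_half_up(x: float, ndigits: int) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(str(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class AssemblyStats:
    total_length: int
    n_contigs: int
    n50: int
    anchored_length: int
    anchoring_rate: float
    repeat_length: int
    repeat_fraction: float

    def __post_init__(self):
        if not (0.0 <= self.anchoring_rate <= 1.0 and 0.0 <= self.repeat_fraction <= 1.0):
            raise ValidationError("rates must be fractions in [0, 1]")
        if self.anchored_length > self.total_length:
            raise ValidationError("anchored length exceeds total length")


@dataclass(frozen=True)
class TelomereReport:
    chrom: str
    has_5prime: bool
    has_3prime: bool
    copies_5prime: int
    copies_3prime: int


def contig_n50(lengths: list[int]) -> int:
    """Largest L such that contigs of length >= L sum to >= half the total."""
    if not lengths:
        raise ValidationError("empty length list")
    if any(x <= 0 for x in lengths):
        raise ValidationError("contig lengths must be positive")
    ordered = sorted(lengths, reverse=True)
    half = sum(ordered) / 2.0
    acc = 0
    for x in ordered:
        acc += x
        if acc >= half:
            return x
    raise AssertionError("unreachable")


def coverage_fold(total_bases: float, genome_size: float) -> float:
    """Sequencing depth total_bases / genome_size, half-up to one decimal."""
    if genome_size <= 0:
        raise ValidationError("genome_size must be > 0")
    if total_bases < 0:
        raise ValidationError("total_bases must be >= 0")
    return round_half_up(total_bases / genome_size, 1)


def qv_to_accuracy(qv: float) -> float:
    """Phred consensus quality -> percent base accuracy (1 - 10^(-QV/10)) * 100."""
    if qv < 0:
        raise ValidationError("QV must be >= 0")
    return round_half_up((1.0 - 10.0 ** (-qv / 10.0)) * 100.0, 3)


def fraction_of_assembly(part_bases: float, total_bases: float) -> float:
    """part / total as a percent, half-up to one decimal."""
    if total_bases <= 0:
        raise ValidationError("total must be > 0")
    if not (0 <= part_bases <= total_bases):
        raise ValidationError("part must satisfy 0 <= part <= total")
    return round_half_up(part_bases / total_bases * 100.0, 1)


def genome_size_from_kmer_histogram(
    histogram: dict[int, int] | pd.DataFrame,
    k: int | None = None,
    error_cutoff: int | None = None,
) -> float:
    """Estimate genome size as (k-mers above the error cutoff) / homozygous-peak depth.

    The error cutoff defaults to the histogram's first local minimum (the
    trough between the low-depth sequencing-error spike and the coverage
    peak). ``k`` is carried as metadata only; the estimator itself is
    k-free. Raises when no coverage mode exists above the cutoff.
    """
    if isinstance(histogram, pd.DataFrame):
        histogram = dict(zip(histogram.iloc[:, 0].astype(int),
                             histogram.iloc[:, 1].astype(int)))
    if not histogram:
        raise ValidationError("empty histogram")
    depths = np.array(sorted(histogram))
    counts = np.array([histogram[d] for d in depths], dtype=float)
    if (depths <= 0).any() or (counts < 0).any():
        raise ValidationError("depths must be positive and counts >= 0")

    if error_cutoff is None:
        # first depth from which counts rise again; no rise => no mode
        rise = np.nonzero(counts[1:] > counts[:-1])[0]
        if rise.size == 0:
            raise ValidationError("no coverage mode above the error region")
        error_cutoff = int(depths[rise[0]])

    keep = depths > error_cutoff
    if not keep.any():
        raise ValidationError("no coverage mode above the error cutoff")
    peak_depth = int(depths[keep][np.argmax(counts[keep])])
    total_kmers = float(np.sum(depths[keep] * counts[keep]))
    return total_kmers / peak_depth


_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def telomere_scan(
    seq: GenomeSequence,
    motif: str = "TTTAGGG",
    window: int = 10_000,
    min_copies: int = 10,
) -> TelomereReport:
    """Count non-overlapping telomere motif copies in the terminal windows.

    The 3' window is scanned for the motif itself and the 5' window for its
    reverse complement (telomere arrays read outward on opposite strands).
    An end is flagged when its copy count reaches ``min_copies``.
    """
    if not motif:
        raise ValidationError("empty motif")
    if window > len(seq):
        raise ValidationError("window exceeds sequence length")
    head = seq.residues[:window]
    tail = seq.residues[-window:]
    copies5 = head.count(_revcomp(motif))
    copies3 = tail.count(motif)
    return TelomereReport(
        seq.id,
        copies5 >= min_copies,
        copies3 >= min_copies,
        copies5,
        copies3,
    )


def centromere_monomer_summary(
    tandem_annotations: pd.DataFrame,
    copy_threshold: int = 100,
) -> dict:
    """Aggregate tandem-repeat annotations by monomer period.

    ``tandem_annotations`` needs columns chrom, start, end, period, copies.
    Returns per-period genome-wide copy totals, the modal period(s) (ties
    flagged), and the chromosomes carrying arrays of the modal period with
    at least ``copy_threshold`` copies.
    """
    if tandem_annotations.empty:
        return {"per_period": {}, "modal_periods": [], "tie": False,
                "chromosomes_with_modal": []}
    df = tandem_annotations
    if (df["period"] <= 0).any():
        raise ValidationError("periods must be > 0")
    totals = df.groupby("period")["copies"].sum()
    top = totals.max()
    modal = sorted(int(p) for p in totals[totals == top].index)
    modal_arrays = df[(df["period"].isin(modal)) & (df["copies"] >= copy_threshold)]
    chroms = sorted(modal_arrays["chrom"].unique())
    return {
        "per_period": {int(p): int(c) for p, c in totals.items()},
        "modal_periods": modal,
        "tie": len(modal) > 1,
        "chromosomes_with_modal": chroms,
    }
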