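"""LTR retrotransposon dating and turnover statistics.

At insertion the two LTRs of an intact element are identical; they then
diverge neutrally. The element's age is estimated from the Kimura
two-parameter (K2P) distance K between the aligned 5' and 3' LTRs,

    K = -1/2 * ln[(1 - 2P - Q) * sqrt(1 - 2Q)]

with P and Q the transition and transversion proportions over compared
columns, and the molecular-clock conversion

    T = K / (2 r)

where r is the per-site per-year substitution rate (default 2.2e-9, the
value commonly applied to gymnosperms). Gap and ambiguity columns are
excluded by pairwise deletion; saturated distances raise
:class:`~gymnome.errors.SaturationError` rather than returning NaN.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import SaturationError, ValidationError

log = logging.getLogger(__name__)

GYMNOSPERM_RATE = 2.2e-9  # substitutions / site / year

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


def classify_substitution(a: str, b: str) -> str | None:
    """Return 'transition', 'transversion', or None for an identical pair.

    Columns containing a gap or an ambiguity code must be excluded by the
    caller (pairwise deletion); this helper only sees A/C/G/T.
    """
    if a == b:
        return None
    pair = {a, b}
    if pair <= _PURINES or pair <= _PYRIMIDINES:
        return "transition"
    return "transversion"


@dataclass(frozen=True)
class LtrPairAlignment:
    """Aligned 5'/3' LTR sequences of one intact element with substitution counts."""

    element_id: str
    aligned_5prime: str
    aligned_3prime: str
    n_sites: int
    n_transitions: int
    n_transversions: int

    def __post_init__(self):
        if len(self.aligned_5prime) != len(self.aligned_3prime):
            raise ValidationError(
                f"{self.element_id}: aligned sequences differ in length"
            )
        if self.n_transitions + self.n_transversions > self.n_sites:
            raise ValidationError(f"{self.element_id}: substitutions exceed sites")

    @property
    def P(self) -> float:
        return self.n_transitions / self.n_sites

    @property
    def Q(self) -> float:
        return self.n_transversions / self.n_sites


@dataclass(frozen=True)
class K2PDistance:
    P: float
    Q: float
    K: float


@dataclass(frozen=True)
class LtrAge:
    element_id: str
    K: float
    r: float
    T: float  # years


def align_ltr_pair(
    seq5: str,
    seq3: str,
    element_id: str = "element",
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
) -> LtrPairAlignment:
    """Globally align two LTR sequences (linear gap cost) and count substitutions.

    Columns where either row carries a gap or an N are excluded from
    ``n_sites`` (pairwise deletion).
    """
    from Bio import Align

    for name, s in (("seq5", seq5), ("seq3", seq3)):
        if not s:
            raise ValidationError(f"{name} is empty")
        bad = set(s.upper()) - set("ACGTN")
        if bad:
            raise ValidationError(f"{name} contains non-DNA characters: {sorted(bad)}")
    seq5, seq3 = seq5.upper(), seq3.upper()

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    aln = aligner.align(seq5, seq3)[0]
    row5, row3 = str(aln[0]), str(aln[1])

    n_sites = n_ts = n_tv = 0
    for a, b in zip(row5, row3):
        if a in "-N" or b in "-N":
            continue
        n_sites += 1
        kind = classify_substitution(a, b)
        if kind == "transition":
            n_ts += 1
        elif kind == "transversion":
            n_tv += 1
    return LtrPairAlignment(element_id, row5, row3, n_sites, n_ts, n_tv)


def kimura2p(P: float, Q: float) -> float:
    """Kimura two-parameter distance K = -1/2 ln[(1-2P-Q) sqrt(1-2Q)]."""
    if P < 0 or Q < 0 or P + Q > 1:
        raise ValidationError(f"invalid proportions P={P}, Q={Q}")
    a = 1.0 - 2.0 * P - Q
    b = 1.0 - 2.0 * Q
    if a <= 0 or b <= 0:
        raise SaturationError(
            f"K2P distance undefined at P={P:.4f}, Q={Q:.4f} (saturated)"
        )
    return -0.5 * math.log(a * math.sqrt(b))


def k2p_distance(alignment: LtrPairAlignment) -> K2PDistance:
    if alignment.n_sites == 0:
        raise ValidationError(f"{alignment.element_id}: no compared sites")
    P, Q = alignment.P, alignment.Q
    return K2PDistance(P, Q, kimura2p(P, Q))


def insertion_time(K: float, r: float = GYMNOSPERM_RATE) -> float:
    """Molecular-clock insertion age T = K / (2 r) in years."""
    if r <= 0:
        raise ValidationError("substitution rate r must be > 0")
    if K < 0:
        raise ValidationError("distance K must be >= 0")
    return K / (2.0 * r)


def date_elements(
    alignments: list[LtrPairAlignment], r: float = GYMNOSPERM_RATE
) -> tuple[list[LtrAge], list[str]]:
    """Estimate ages for a set of elements; saturated elements are reported
    separately (T undefined) rather than clamped."""
    ages: list[LtrAge] = []
    saturated: list[str] = []
    for aln in alignments:
        try:
            d = k2p_distance(aln)
        except SaturationError:
            saturated.append(aln.element_id)
            continue
        ages.append(LtrAge(aln.element_id, d.K, r, insertion_time(d.K, r)))
    if saturated:
        log.warning("%d element(s) saturated, age undefined: %s",
                    len(saturated), ", ".join(saturated[:5]))
    return ages, saturated


def age_distribution(
    ages: list[LtrAge],
    bin_width_years: float,
    family_labels: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Histogram of insertion ages, overall and per family when labels given.

    Returns a table with columns bin_start, bin_end, family, count
    (family 'all' for the pooled histogram).
    """
    if bin_width_years <= 0:
        raise ValidationError("bin width must be > 0")
    if not ages:
        return pd.DataFrame(columns=["bin_start", "bin_end", "family", "count"])
    t = np.array([a.T for a in ages])
    if (t < 0).any():
        raise ValidationError("negative ages")
    n_bins = int(t.max() // bin_width_years) + 1
    edges = np.arange(n_bins + 1) * bin_width_years
    rows = []

    def _hist(values, family):
        counts, _ = np.histogram(values, bins=edges)
        for i, c in enumerate(counts):
            rows.append({"bin_start": edges[i], "bin_end": edges[i + 1],
                         "family": family, "count": int(c)})

    _hist(t, "all")
    if family_labels:
        fams = sorted({family_labels.get(a.element_id, "unknown") for a in ages})
        for fam in fams:
            vals = [a.T for a in ages if family_labels.get(a.element_id, "unknown") == fam]
            _hist(np.array(vals), fam)
    return pd.DataFrame(rows)


def solo_intact_ratio(n_solo: int, n_intact: int) -> float:
    """Solo:intact LTR ratio (element-removal index), two decimals."""
    if n_intact <= 0:
        raise ValidationError("ratio undefined with zero intact elements")
    if n_solo < 0:
        raise ValidationError("n_solo must be >= 0")
    from .assembly_qc import round_half_up

    return round_half_up(n_solo / n_intact, 2)
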