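"""Small expression-side computations: 2^(-ddCt) relative expression,
descriptive fold changes, and small-RNA length spectra."""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

from .errors import ValidationError


@dataclass(frozen=True)
class QpcrMeasurement:
    """Cycle thresholds of a target gene and the reference normalizer
    (an actin gene, conventionally) in one sample."""

    sample_id: str
    ct_target: float
    ct_reference: float

    def __post_init__(self):
        for v in (self.ct_target, self.ct_reference):
            if not math.isfinite(v) or v <= 0:
                raise ValidationError("Ct values must be positive and finite")

    @property
    def delta_ct(self) -> float:
        return self.ct_target - self.ct_reference


def ddct_relative_expression(test: QpcrMeasurement, calibrator: QpcrMeasurement) -> float:
    """Relative expression 2^(-ddCt) of test vs calibrator sample."""
    ddct = test.delta_ct - calibrator.delta_ct
    return 2.0 ** (-ddct)


def fold_change(group_a: list[float], group_b: list[float], pseudocount: float = 0.0) -> float:
    """Descriptive ratio (mean_a + pc) / (mean_b + pc); not a DE test."""
    if not group_a or not group_b:
        raise ValidationError("groups must be non-empty")
    mean_a = sum(group_a) / len(group_a)
    mean_b = sum(group_b) / len(group_b)
    denom = mean_b + pseudocount
    if denom == 0:
        raise ValidationError("zero denominator; use a pseudocount")
    return (mean_a + pseudocount) / denom


def srna_length_spectrum(read_lengths: list[int]) -> tuple[dict[int, int], list[int]]:
    """Histogram over small-RNA read lengths and the modal length(s).

    Returns (counts per length, sorted list of modal lengths — more than
    one entry on a tie).
    """
    if not read_lengths:
        raise ValidationError("empty length list")
    if any(x <= 0 for x in read_lengths):
        raise ValidationError("lengths must be positive")
    counts = Counter(read_lengths)
    top = max(counts.values())
    modes = sorted(length for length, c in counts.items() if c == top)
    return dict(sorted(counts.items())), modes
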