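"""Binary fear mapping from PAD self-reports.

Fear occupies the low-valence, high-arousal, low-dominance octant of the
PAD (pleasure/valence, arousal, dominance) space.  The 1-9 SAM scales are
split at the midpoint: with ``midpoint=5`` a report maps to the positive
(fear) class iff ``valence <= 5 and arousal > 5 and dominance <= 5``.
The boundary rating 5 counts as "low" for valence and dominance and as
"not high" for arousal; this is a declared convention — the split itself
is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .io import SelfReport, ValidationError


@dataclass(frozen=True)
class FearLabel:
    """Binary class: 1 = fear (positive), 0 = anything else."""

    value: int

    def __post_init__(self) -> None:
        if self.value not in (0, 1):
            raise ValidationError(f"fear label must be 0 or 1, got {self.value!r}")


def binarize_pad(report: SelfReport, midpoint: int = 5) -> FearLabel:
    """Map a PAD self-report to the binary fear label.

    Pure and total over valid reports; lowering valence or dominance, or
    raising arousal, never flips a positive label negative.
    """
    if not (1 <= midpoint <= 9):
        raise ValidationError(f"midpoint must be within the 1-9 scale, got {midpoint}")
    positive = (
        report.valence <= midpoint
        and report.arousal > midpoint
        and report.dominance <= midpoint
    )
    return FearLabel(1 if positive else 0)


def class_distribution(labels_by_subject: Mapping[str, Iterable[int]]) -> pd.Series:
    """Fraction of positive (fear) labels per subject, for imbalance reporting."""
    if not labels_by_subject:
        raise ValidationError("no subjects given")
    out = {}
    for subject, labels in labels_by_subject.items():
        labels = list(labels)
        if not labels:
            raise ValidationError(f"subject {subject!r} has no labels")
        out[subject] = sum(labels) / len(labels)
    return pd.Series(out, name="fear_fraction")
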