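"""Enzyme-activity measurement types and arithmetic.

A variant construct's activity is expressed as a percentage of the wild-type
expression construct assayed in the same run (4MU released per hour per mg of
lysate protein, normalized after subtracting the mock-transfection
background).  Replicate plates are averaged; activity below the detection
limit of the fluorometric assay is carried as a flag and compared as 0% for
every threshold decision.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from statistics import fmean
from typing import Mapping, Optional, Sequence

__all__ = [
    "VariantId",
    "ActivityMeasurement",
    "AssayRun",
    "percent_of_wildtype",
    "average_replicates",
    "round_half_away",
    "InvalidAssayError",
]


class InvalidAssayError(ValueError):
    """Raised when an assay run or measurement violates its preconditions."""


# Minimal HGVS c. grammar: substitutions (c.316C>T), deletions (c.525delT,
# c.1589del), duplications/insertions, and intronic-offset positions
# (c.-32-13T>G).  Position ranges (c.10_12del) are accepted.
_POS = r"-?\d+(?:[+-]\d+)?"
_HGVS_C_RE = re.compile(
    rf"^c\.{_POS}(?:_{_POS})?"
    r"(?:[ACGT]>[ACGT]|del[ACGT]*|dup[ACGT]*|ins[ACGT]+)$"
)

DEFAULT_TRANSCRIPT = "NM_000152.5"


@dataclass(frozen=True, order=True)
class VariantId:
    """A variant named at the cDNA level on a fixed reference transcript."""

    cdna: str
    protein: str = ""
    transcript: str = DEFAULT_TRANSCRIPT

    def __post_init__(self) -> None:
        if not self.cdna:
            raise ValueError("cdna name must be non-empty")
        if not _HGVS_C_RE.match(self.cdna):
            raise ValueError(f"not a recognized HGVS c. name: {self.cdna!r}")

    def __str__(self) -> str:
        return f"{self.cdna} ({self.protein})" if self.protein else self.cdna


def percent_of_wildtype(
    variant_raw: float, wildtype_raw: float, mock_raw: float = 0.0
) -> float:
    """Normalize a raw activity to percent of wild type.

    The mock-transfection background is subtracted from both numerator and
    denominator; sub-background signal is clipped to zero, so the result is
    never negative.

    Raises
    ------
    InvalidAssayError
        If the wild-type positive control does not exceed the mock negative
        control (the run carries no dynamic range).
    """
    if mock_raw < 0:
        raise InvalidAssayError(f"mock activity must be >= 0, got {mock_raw}")
    if wildtype_raw <= mock_raw:
        raise InvalidAssayError(
            f"wild-type activity ({wildtype_raw}) must exceed mock ({mock_raw})"
        )
    if variant_raw < 0:
        raise InvalidAssayError(f"variant activity must be >= 0, got {variant_raw}")
    return 100.0 * max(variant_raw - mock_raw, 0.0) / (wildtype_raw - mock_raw)


def average_replicates(values: Sequence[float]) -> float:
    """Arithmetic mean of replicate percent-of-wild-type values.

    Returns the unrounded mean; use :func:`round_half_away` for the one-decimal
    reporting convention.  Threshold comparisons must always use the unrounded
    mean so that a display convention can never change a classification.
    """
    if len(values) == 0:
        raise InvalidAssayError("no replicate values given")
    if any(v < 0 for v in values):
        raise InvalidAssayError("replicate activities must be >= 0")
    return fmean(values)


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round with ties going away from zero, on the printed decimal value.

    Operates on ``repr(x)`` (the shortest round-tripping decimal) so that a
    mean whose decimal form ends in 5 — e.g. 17.45 or 11.65, which binary
    floats store just below the tie — still rounds up as a bench scientist
    would report it.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ActivityMeasurement:
    """Replicate activities and/or a percent-of-wild-type summary.

    Parameters
    ----------
    replicates
        Per-plate percent-of-wild-type values (possibly empty when only a
        summary value is known).
    below_detection
        True when no activity was measurable; the measurement then compares
        as 0% against every threshold and ``percent_wt`` is undefined.
    percent_wt
        Unrounded percent of wild type.  Derived from the replicate mean when
        replicates are given.
    """

    replicates: list[float] = field(default_factory=list)
    below_detection: bool = False
    percent_wt: Optional[float] = None

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.replicates):
            raise InvalidAssayError("replicate activities must be >= 0")
        if self.below_detection:
            self.percent_wt = None
            return
        if self.replicates:
            mean = average_replicates(self.replicates)
            if self.percent_wt is not None and self.percent_wt != mean:
                raise InvalidAssayError(
                    "percent_wt inconsistent with replicate mean "
                    f"({self.percent_wt} vs {mean})"
                )
            self.percent_wt = mean
        if self.percent_wt is None:
            raise InvalidAssayError(
                "a measurement needs replicates, percent_wt, or below_detection"
            )
        if self.percent_wt < 0:
            raise InvalidAssayError("percent_wt must be >= 0")

    @classmethod
    def from_percent(cls, percent_wt: float) -> "ActivityMeasurement":
        return cls(percent_wt=percent_wt)

    @classmethod
    def not_detectable(cls) -> "ActivityMeasurement":
        return cls(below_detection=True)

    @property
    def value(self) -> float:
        """The percent used for all threshold comparisons (0 when not detectable)."""
        return 0.0 if self.below_detection else float(self.percent_wt)

    @property
    def display(self) -> str:
        """One-decimal reporting form, or 'Not detectable'."""
        if self.below_detection:
            return "Not detectable"
        return f"{round_half_away(self.value, 1):.1f}"


@dataclass
class AssayRun:
    """One expression-assay run: wild-type and mock controls plus variant wells."""

    wildtype_activity: float
    mock_activity: float
    measurements: dict[VariantId, ActivityMeasurement] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.mock_activity >= 0:
            raise InvalidAssayError("mock activity must be >= 0")
        if not self.wildtype_activity > self.mock_activity:
            raise InvalidAssayError("wild-type activity must exceed mock activity")

    def normalize(self, raw_replicates: Mapping[VariantId, Sequence[float]]) -> None:
        """Convert raw replicate activities to percent wild type and store them."""
        for vid, raws in raw_replicates.items():
            pct = [
                percent_of_wildtype(r, self.wildtype_activity, self.mock_activity)
                for r in raws
            ]
            self.measurements[vid] = ActivityMeasurement(replicates=pct)
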