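"""Calibration of the activity assay against controls of known classification.

The pathogenic zone is bounded above by the highest residual activity seen in
a known-pathogenic control, the benign zone below by the lowest activity in a
known-benign control; activities in between are indeterminate and carry no
functional evidence.  The number of validated controls sets the strength at
which PS3/BS3 may be applied, following ClinGen SVI guidance: a balanced mix
of at least 11 pathogenic and benign controls permits moderate strength,
fewer permits supporting.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence, Union

from .assay import ActivityMeasurement, VariantId

__all__ = [
    "KnownClass",
    "ControlVariant",
    "CalibrationResult",
    "ActivityZone",
    "Policy",
    "Strength",
    "CalibrationError",
    "calibrate",
    "determine_strength",
    "classify_activity",
]

# Minimum control count for moderate-strength functional evidence under the
# ClinGen SVI recommendation ("a balanced mix of at least 11 well-established,
# known pathogenic and benign controls").
SVI_MODERATE_MIN_CONTROLS = 11


class CalibrationError(ValueError):
    """The control panel cannot validate the assay (overlap or missing class)."""


class CalibrationWarning(UserWarning):
    """Non-fatal panel problem, e.g. a pseudodeficiency sentinel out of place."""


class KnownClass(str, enum.Enum):
    PATHOGENIC = "pathogenic"
    LIKELY_PATHOGENIC = "likely_pathogenic"
    BENIGN = "benign"
    LIKELY_BENIGN = "likely_benign"
    PSEUDODEFICIENCY = "pseudodeficiency"


_PATHOGENIC_SIDE = {KnownClass.PATHOGENIC, KnownClass.LIKELY_PATHOGENIC}
_BENIGN_SIDE = {KnownClass.BENIGN, KnownClass.LIKELY_BENIGN}


class Strength(str, enum.Enum):
    """ACMG/AMP evidence strength scale."""

    STAND_ALONE = "stand_alone"
    VERY_STRONG = "very_strong"
    STRONG = "strong"
    MODERATE = "moderate"
    SUPPORTING = "supporting"


class Policy(str, enum.Enum):
    """How control counts translate into PS3/BS3 strength.

    ``svi`` applies the SVI count rule literally (>= 11 controls with both
    classes represented -> moderate).  ``conservative`` caps both strengths at
    supporting regardless of count — appropriate when the indeterminate zone
    is wide and sparsely sampled by controls.
    """

    SVI = "svi"
    CONSERVATIVE = "conservative"


class ActivityZone(str, enum.Enum):
    PATHOGENIC_RANGE = "pathogenic_range"
    INDETERMINATE = "indeterminate"
    BENIGN_RANGE = "benign_range"


@dataclass
class ControlVariant:
    """A known-classification variant with its measured residual activity."""

    id: VariantId
    known_class: KnownClass
    activity: ActivityMeasurement

    def __post_init__(self) -> None:
        self.known_class = KnownClass(self.known_class)


@dataclass
class CalibrationResult:
    """Activity-zone boundaries plus the permitted PS3/BS3 strengths."""

    pathogenic_max: float
    benign_min: float
    n_pathogenic_controls: int
    n_benign_controls: int
    ps3_strength: Strength
    bs3_strength: Strength
    warnings: list[str] = field(default_factory=list)

    @property
    def ps3_applicable(self) -> bool:
        return self.n_pathogenic_controls >= 1

    @property
    def bs3_applicable(self) -> bool:
        return self.n_benign_controls >= 1

    def to_dict(self) -> dict:
        return {
            "pathogenic_max": self.pathogenic_max,
            "benign_min": self.benign_min,
            "n_pathogenic_controls": self.n_pathogenic_controls,
            "n_benign_controls": self.n_benign_controls,
            "ps3_strength": self.ps3_strength.value,
            "bs3_strength": self.bs3_strength.value,
            "ps3_applicable": self.ps3_applicable,
            "bs3_applicable": self.bs3_applicable,
            "warnings": list(self.warnings),
        }


def determine_strength(
    n_pathogenic: int, n_benign: int, policy: Policy = Policy.CONSERVATIVE
) -> tuple[Strength, Strength]:
    """Evidence strength at which PS3 and BS3 may be applied.

    Under ``svi``, both strengths are moderate when the panel totals at least
    11 controls with each class represented; otherwise supporting.  Under
    ``conservative`` both are supporting regardless of count.
    """
    if n_pathogenic < 0 or n_benign < 0:
        raise ValueError("control counts must be >= 0")
    policy = Policy(policy)
    if (
        policy is Policy.SVI
        and n_pathogenic + n_benign >= SVI_MODERATE_MIN_CONTROLS
        and n_pathogenic >= 1
        and n_benign >= 1
    ):
        return Strength.MODERATE, Strength.MODERATE
    return Strength.SUPPORTING, Strength.SUPPORTING


def calibrate(
    controls: Iterable[ControlVariant], policy: Policy = Policy.CONSERVATIVE
) -> CalibrationResult:
    """Derive activity-zone boundaries from a control panel.

    ``pathogenic_max`` is the maximum activity over pathogenic/likely-pathogenic
    controls (below-detection counts as 0); ``benign_min`` the minimum over
    benign/likely-benign controls.  A benign control at or below a pathogenic
    one means the assay does not separate the classes and calibration fails.
    Pseudodeficiency controls never move a boundary; each must fall strictly
    inside the indeterminate gap, else a validation warning is recorded.
    """
    path_vals: list[float] = []
    benign_vals: list[float] = []
    pseudo: list[ControlVariant] = []
    for c in controls:
        if c.known_class in _PATHOGENIC_SIDE:
            path_vals.append(c.activity.value)
        elif c.known_class in _BENIGN_SIDE:
            benign_vals.append(c.activity.value)
        elif c.known_class is KnownClass.PSEUDODEFICIENCY:
            pseudo.append(c)
        else:  # pragma: no cover - KnownClass is closed
            raise CalibrationError(f"unknown control class: {c.known_class}")
    if not path_vals:
        raise CalibrationError("panel has no pathogenic control")
    if not benign_vals:
        raise CalibrationError("panel has no benign/likely-benign control")

    pathogenic_max = max(path_vals)
    benign_min = min(benign_vals)
    if benign_min <= pathogenic_max:
        raise CalibrationError(
            "control classes overlap: lowest benign activity "
            f"({benign_min}%) does not exceed highest pathogenic ({pathogenic_max}%)"
        )

    notes: list[str] = []
    for c in pseudo:
        v = c.activity.value
        if not (pathogenic_max < v < benign_min):
            msg = (
                f"pseudodeficiency control {c.id} at {v}% lies outside the "
                f"indeterminate gap ({pathogenic_max}%, {benign_min}%)"
            )
            notes.append(msg)
            warnings.warn(msg, CalibrationWarning, stacklevel=2)

    ps3, bs3 = determine_strength(len(path_vals), len(benign_vals), policy)
    return CalibrationResult(
        pathogenic_max=pathogenic_max,
        benign_min=benign_min,
        n_pathogenic_controls=len(path_vals),
        n_benign_controls=len(benign_vals),
        ps3_strength=ps3,
        bs3_strength=bs3,
        warnings=notes,
    )


def classify_activity(
    activity: Union[float, ActivityMeasurement], cal: CalibrationResult
) -> ActivityZone:
    """Place an activity in the pathogenic, indeterminate, or benign zone.

    The pathogenic zone is strictly below ``pathogenic_max`` (a variant at
    exactly the boundary is indeterminate); the benign zone starts at
    ``benign_min`` inclusive.  Not-detectable activity is pathogenic-range.
    """
    if isinstance(activity, ActivityMeasurement):
        if activity.below_detection:
            return ActivityZone.PATHOGENIC_RANGE
        percent = activity.value
    else:
        percent = float(activity)
    if percent < cal.pathogenic_max:
        return ActivityZone.PATHOGENIC_RANGE
    if percent >= cal.benign_min:
        return ActivityZone.BENIGN_RANGE
    return ActivityZone.INDETERMINATE
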