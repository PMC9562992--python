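"""Mapping per-variant observations to ACMG/AMP evidence codes.

Thresholds follow the ClinGen GAA variant-curation expert panel (VCEP)
specification: PM2_supporting below an allele frequency of 0.001 in every
continental population (or absence from gnomAD), BS1 above 0.005 in any
population, PP3 for REVEL > 0.7, BP4 for REVEL < 0.5, PP4 at moderate
strength when the clinical phenotype shows deficient GAA activity with
pseudodeficiency alleles excluded.  PS3/BS3 come from the calibrated
functional assay at the strength the calibration permits.
"""

from __future__ import annotations

import enum
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Union

from .assay import ActivityMeasurement, InvalidAssayError, VariantId
from .calibration import ActivityZone, CalibrationResult, Strength, classify_activity

__all__ = [
    "EvidenceCategory",
    "EvidenceItem",
    "VCEPProfile",
    "ProteinBands",
    "VariantObservations",
    "assign_ps3_bs3",
    "assign_pm2_bs1",
    "assign_pm3",
    "assign_pm5",
    "assign_pp3_bp4",
    "assign_pp4",
    "build_profile",
]


class EvidenceCategory(str, enum.Enum):
    PATHOGENIC = "pathogenic"
    BENIGN = "benign"


def category_for_code(code: str) -> EvidenceCategory:
    """Infer the evidence category from a standard ACMG/AMP code."""
    if re.match(r"^(PVS|PS|PM|PP)\d", code):
        return EvidenceCategory.PATHOGENIC
    if re.match(r"^(BA|BS|BP)\d", code):
        return EvidenceCategory.BENIGN
    raise ValueError(f"cannot infer category for evidence code {code!r}")


_BASE_STRENGTH = {
    "PVS": Strength.VERY_STRONG,
    "PS": Strength.STRONG,
    "PM": Strength.MODERATE,
    "PP": Strength.SUPPORTING,
    "BA": Strength.STAND_ALONE,
    "BS": Strength.STRONG,
    "BP": Strength.SUPPORTING,
}


def base_strength_for_code(code: str) -> Strength:
    m = re.match(r"^(PVS|PS|PM|PP|BA|BS|BP)\d", code)
    if not m:
        raise ValueError(f"cannot infer base strength for evidence code {code!r}")
    return _BASE_STRENGTH[m.group(1)]


@dataclass(frozen=True)
class EvidenceItem:
    """One applied ACMG/AMP criterion, possibly at a VCEP-modified strength."""

    code: str
    category: EvidenceCategory
    base_strength: Strength
    applied_strength: Strength
    justification: str = ""

    @classmethod
    def applied(
        cls,
        code: str,
        strength: Optional[Strength] = None,
        justification: str = "",
    ) -> "EvidenceItem":
        """Build an item for a standard code, modifying strength if given."""
        base = base_strength_for_code(code)
        return cls(
            code=code,
            category=category_for_code(code),
            base_strength=base,
            applied_strength=strength or base,
            justification=justification,
        )

    @property
    def label(self) -> str:
        """Report label, e.g. ``PS3_supporting`` when strength was modified."""
        if self.applied_strength is self.base_strength:
            return self.code
        return f"{self.code}_{self.applied_strength.value}"


@dataclass
class VCEPProfile:
    """Numeric thresholds and strength modifications of the VCEP specification."""

    pm2_af_max: float = 0.001
    bs1_af_min: float = 0.005
    pp3_revel_min: float = 0.7
    bp4_revel_max: float = 0.5
    pm2_strength: Strength = Strength.SUPPORTING
    pp4_strength: Strength = Strength.MODERATE
    pm3_strength: Strength = Strength.MODERATE
    pm5_strength: Strength = Strength.MODERATE

    def __post_init__(self) -> None:
        for name in ("pm2_strength", "pp4_strength", "pm3_strength", "pm5_strength"):
            setattr(self, name, Strength(getattr(self, name)))
        for f in (self.pm2_af_max, self.bs1_af_min):
            if not 0.0 <= f <= 1.0:
                raise ValueError("allele-frequency thresholds must be in [0, 1]")
        for s in (self.pp3_revel_min, self.bp4_revel_max):
            if not 0.0 <= s <= 1.0:
                raise ValueError("REVEL thresholds must be in [0, 1]")
        if not self.bp4_revel_max < self.pp3_revel_min:
            raise ValueError("bp4_revel_max must be below pp3_revel_min")
        if not self.pm2_af_max < self.bs1_af_min:
            raise ValueError("pm2_af_max must be below bs1_af_min")

    def to_dict(self) -> dict:
        return {
            "pm2_af_max": self.pm2_af_max,
            "bs1_af_min": self.bs1_af_min,
            "pp3_revel_min": self.pp3_revel_min,
            "bp4_revel_max": self.bp4_revel_max,
            "pm2_strength": self.pm2_strength.value,
            "pp4_strength": self.pp4_strength.value,
            "pm3_strength": self.pm3_strength.value,
            "pm5_strength": self.pm5_strength.value,
        }

    def write_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "VCEPProfile":
        return cls(**json.loads(Path(path).read_text()))


class ProteinBands(str, enum.Enum):
    """Western-blot annotation (110 kDa precursor / 76 kDa mature forms).

    Carried into reports for the curator's benefit; never consulted by any
    evidence assigner.
    """

    PRECURSOR_AND_MATURE = "precursor_and_mature"
    PRECURSOR_ONLY = "precursor_only"
    NONE_OBSERVED = "none_observed"
    NOT_ASSAYED = "not_assayed"


# p.Arg375Leu style: one three-letter residue, a position, another residue —
# excludes Ter/frameshift/synonymous forms, which can never support PM5.
_MISSENSE_P_RE = re.compile(r"^p\.[A-Z][a-z]{2}\d+(?!Ter$)[A-Z][a-z]{2}$")


def _is_missense_protein(p_name: str) -> bool:
    return bool(_MISSENSE_P_RE.match(p_name))


@dataclass
class VariantObservations:
    """Everything observed about one tested variant, as assigner inputs."""

    id: VariantId
    activity: Optional[ActivityMeasurement] = None
    af_by_population: dict[str, float] = field(default_factory=dict)
    in_trans_pathogenic: bool = False
    trans_partner: str = ""
    same_codon_pathogenic: bool = False
    same_codon_variant_cdna: str = ""
    same_codon_variant_protein: str = ""
    revel: Optional[float] = None
    phenotype_consistent: bool = False
    pseudodeficiency_excluded: bool = False
    protein_bands: ProteinBands = ProteinBands.NOT_ASSAYED

    def __post_init__(self) -> None:
        self.protein_bands = ProteinBands(self.protein_bands)
        for pop, f in self.af_by_population.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"allele frequency for {pop} out of [0, 1]: {f}")
        if self.revel is not None and not 0.0 <= self.revel <= 1.0:
            raise ValueError(f"REVEL score out of [0, 1]: {self.revel}")


def assign_ps3_bs3(
    activity: ActivityMeasurement, cal: CalibrationResult
) -> Optional[EvidenceItem]:
    """Functional evidence from the calibrated assay.

    Activity in the pathogenic range yields PS3, in the benign range BS3, each
    at the strength the calibration permits; the indeterminate zone yields no
    functional code at any strength.
    """
    if activity is None:
        raise InvalidAssayError("no activity measurement supplied")
    zone = classify_activity(activity, cal)
    if zone is ActivityZone.PATHOGENIC_RANGE and cal.ps3_applicable:
        return EvidenceItem.applied(
            "PS3",
            cal.ps3_strength,
            f"residual activity {activity.display} in pathogenic range "
            f"(<{cal.pathogenic_max:g}%)",
        )
    if zone is ActivityZone.BENIGN_RANGE and cal.bs3_applicable:
        return EvidenceItem.applied(
            "BS3",
            cal.bs3_strength,
            f"residual activity {activity.display} in benign range "
            f"(>={cal.benign_min:g}%)",
        )
    return None


def assign_pm2_bs1(
    af_by_population: Mapping[str, float], profile: VCEPProfile
) -> Optional[EvidenceItem]:
    """Population-frequency evidence.

    BS1 when any single population exceeds the BS1 floor; PM2 (at the VCEP's
    supporting strength) when every reported population is below the PM2
    ceiling or the variant is absent from gnomAD (empty map).  Comparisons are
    strict on both sides; frequencies between the thresholds yield no code.
    """
    over = [(p, f) for p, f in af_by_population.items() if f > profile.bs1_af_min]
    if over:
        pop, f = max(over, key=lambda x: x[1])
        return EvidenceItem.applied(
            "BS1", justification=f"allele frequency {f:g} ({pop}) > {profile.bs1_af_min:g}"
        )
    if all(f < profile.pm2_af_max for f in af_by_population.values()):
        detail = (
            "absent from gnomAD"
            if not af_by_population
            else f"< {profile.pm2_af_max:g} in all continental populations"
        )
        return EvidenceItem.applied("PM2", profile.pm2_strength, detail)
    return None


def assign_pm3(
    in_trans_pathogenic: bool,
    profile: VCEPProfile,
    partner: str = "",
) -> Optional[EvidenceItem]:
    """In trans with a pathogenic variant, phase confirmed (parental or equivalent)."""
    if not in_trans_pathogenic:
        return None
    just = f"in trans with pathogenic variant {partner}" if partner else "in trans with a pathogenic variant"
    return EvidenceItem.applied("PM3", profile.pm3_strength, just)


def assign_pm5(
    same_codon_pathogenic_missense: bool,
    profile: VCEPProfile,
    other_cdna: str = "",
    other_protein: str = "",
) -> Optional[EvidenceItem]:
    """A different missense change at the same codon is established pathogenic.

    When the cited variant's protein name is supplied it must itself be
    missense — a nonsense, frameshift or synonymous change at the codon can
    never support PM5.
    """
    if not same_codon_pathogenic_missense:
        return None
    if other_protein and not _is_missense_protein(other_protein):
        raise ValueError(
            f"PM5 requires a missense change at the codon; {other_protein!r} is not"
        )
    cited = " ".join(x for x in (other_cdna, other_protein) if x)
    return EvidenceItem.applied(
        "PM5",
        profile.pm5_strength,
        f"pathogenic missense at same codon: {cited}" if cited else "pathogenic missense at same codon",
    )


def assign_pp3_bp4(
    revel: Optional[float], profile: VCEPProfile
) -> Optional[EvidenceItem]:
    """Computational evidence from the REVEL ensemble score, strict thresholds."""
    if revel is None:
        return None
    if not 0.0 <= revel <= 1.0:
        raise ValueError(f"REVEL score out of [0, 1]: {revel}")
    if revel > profile.pp3_revel_min:
        return EvidenceItem.applied(
            "PP3", justification=f"REVEL {revel:g} > {profile.pp3_revel_min:g}"
        )
    if revel < profile.bp4_revel_max:
        return EvidenceItem.applied(
            "BP4", justification=f"REVEL {revel:g} < {profile.bp4_revel_max:g}"
        )
    return None


def assign_pp4(
    phenotype_consistent: bool,
    pseudodeficiency_excluded: bool,
    profile: VCEPProfile,
) -> Optional[EvidenceItem]:
    """Phenotype evidence: deficient GAA activity in blood with a
    Pompe-consistent presentation, valid only once pseudodeficiency alleles
    are excluded (they suppress measured activity without causing disease)."""
    if phenotype_consistent and pseudodeficiency_excluded:
        return EvidenceItem.applied(
            "PP4",
            profile.pp4_strength,
            "GAA deficiency with consistent phenotype; pseudodeficiency excluded",
        )
    return None


def build_profile(
    obs: VariantObservations,
    cal: CalibrationResult,
    profile: VCEPProfile,
) -> "EvidenceProfile":
    """Run every assigner on one variant's observations.

    Items appear in a fixed column order (functional, frequency, PM3, PM5,
    computational, phenotype); each code at most once by construction.
    """
    from .engine import EvidenceProfile  # local import to avoid a cycle

    items = [
        assign_ps3_bs3(obs.activity, cal),
        assign_pm2_bs1(obs.af_by_population, profile),
        assign_pm3(obs.in_trans_pathogenic, profile, obs.trans_partner),
        assign_pm5(
            obs.same_codon_pathogenic,
            profile,
            obs.same_codon_variant_cdna,
            obs.same_codon_variant_protein,
        ),
        assign_pp3_bp4(obs.revel, profile),
        assign_pp4(obs.phenotype_consistent, obs.pseudodeficiency_excluded, profile),
    ]
    return EvidenceProfile([i for i in items if i is not None])
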