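"""End-to-end orchestration: calibrate, assign evidence, combine, report.

The report mirrors a curation table: one row per tested variant with the
displayed and raw activity, the calibrated zone, every evidence-code decision
(not just the final tier), the five-tier classification with its rationale
and matched combining rule, and a counterfactual column showing the tier
without the functional PS3/BS3 evidence — the quantity that tells a curator
what the assay contributed.
"""

from __future__ import annotations

import datetime
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from . import __version__
from .assay import round_half_away
from .calibration import (
    CalibrationResult,
    ControlVariant,
    Policy,
    calibrate,
    classify_activity,
)
from .engine import Classification, EvidenceProfile, combine
from .evidence import VariantObservations, VCEPProfile, build_profile
from . import io as gio

__all__ = ["ReportRow", "ClassificationReport", "run_pipeline", "classify_observations"]

logger = logging.getLogger("gaavar")

_EVIDENCE_COLUMNS = ["PS3/BS3", "PM2/BS1", "PM3", "PM5", "PP3/BP4", "PP4"]
_COLUMN_CODES = {
    "PS3/BS3": ("PS3", "BS3"),
    "PM2/BS1": ("PM2", "BS1"),
    "PM3": ("PM3",),
    "PM5": ("PM5",),
    "PP3/BP4": ("PP3", "BP4"),
    "PP4": ("PP4",),
}


@dataclass
class ReportRow:
    variant_cdna: str
    variant_protein: str
    activity_display: str
    percent_wt_raw: Optional[float]
    below_detection: bool
    zone: str
    evidence: dict[str, Optional[str]]
    evidence_labels: list[str]
    tier: str
    rationale: str
    matched_rule: Optional[str]
    tier_without_functional: Optional[str]
    protein_bands: str
    notes: str = ""

    def to_dict(self) -> dict:
        d = {
            "variant_cdna": self.variant_cdna,
            "variant_protein": self.variant_protein,
            "activity_display": self.activity_display,
            "percent_wt_raw": self.percent_wt_raw,
            "below_detection": self.below_detection,
            "zone": self.zone,
        }
        for col in _EVIDENCE_COLUMNS:
            d[col] = self.evidence.get(col)
        d.update(
            {
                "tier": self.tier,
                "rationale": self.rationale,
                "matched_rule": self.matched_rule,
                "tier_without_functional": self.tier_without_functional,
                "protein_bands": self.protein_bands,
                "notes": self.notes,
            }
        )
        return d


@dataclass
class ClassificationReport:
    calibration: CalibrationResult
    vcep_profile: VCEPProfile
    policy: Policy
    rows: list[ReportRow] = field(default_factory=list)
    version: str = __version__
    timestamp: Optional[str] = None

    def to_dataframe(self) -> pd.DataFrame:
        cols = list(ReportRow.__dataclass_fields__)
        cols.remove("evidence")
        cols.remove("evidence_labels")
        frame_cols = cols[:6] + _EVIDENCE_COLUMNS + cols[6:]
        return pd.DataFrame([r.to_dict() for r in self.rows], columns=frame_cols)

    def tier_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for r in self.rows:
            counts[r.tier] = counts.get(r.tier, 0) + 1
        return counts

    def write_tsv(self, path: Union[str, Path]) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False, na_rep="NA")

    def to_dict(self) -> dict:
        return {
            "metadata": {
                "version": self.version,
                "timestamp": self.timestamp,
                "policy": self.policy.value,
                "calibration": self.calibration.to_dict(),
                "vcep_profile": self.vcep_profile.to_dict(),
            },
            "rows": [r.to_dict() for r in self.rows],
        }

    def write_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def _evidence_columns(profile: EvidenceProfile) -> dict[str, Optional[str]]:
    by_code = {i.code: i.label for i in profile}
    out: dict[str, Optional[str]] = {}
    for col, codes in _COLUMN_CODES.items():
        out[col] = next((by_code[c] for c in codes if c in by_code), None)
    return out


def classify_observations(
    controls: Sequence[ControlVariant],
    observations: Sequence[VariantObservations],
    vcep: Optional[VCEPProfile] = None,
    policy: Policy = Policy.CONSERVATIVE,
    include_ablation: bool = True,
) -> ClassificationReport:
    """Calibrate on the controls, then classify each observation.

    The in-memory core of :func:`run_pipeline`; rows keep input order and
    every intermediate decision is recorded and logged.
    """
    vcep = vcep or VCEPProfile()
    policy = Policy(policy)
    cal = calibrate(controls, policy)
    logger.info(
        "calibration: pathogenic_max=%.4g benign_min=%.4g (n=%d+%d, PS3 %s / BS3 %s)",
        cal.pathogenic_max, cal.benign_min,
        cal.n_pathogenic_controls, cal.n_benign_controls,
        cal.ps3_strength.value, cal.bs3_strength.value,
    )
    report = ClassificationReport(
        calibration=cal,
        vcep_profile=vcep,
        policy=policy,
        timestamp=datetime.datetime.now(datetime.timezone.utc).isoformat(),
    )
    for obs in observations:
        profile = build_profile(obs, cal, vcep)
        for item in profile:
            logger.info(
                "%s: %s (%s)", obs.id.cdna, item.label, item.justification
            )
        result = combine(profile)
        zone = classify_activity(obs.activity, cal)
        ablated: Optional[Classification] = None
        if include_ablation:
            ablated = combine(profile.without("PS3").without("BS3"))
        notes = ""
        if zone.value == "indeterminate":
            notes = (
                "activity in indeterminate zone "
                f"({cal.pathogenic_max:g}%-{cal.benign_min:g}%); "
                "no functional code applied at any strength"
            )
        logger.info(
            "%s: %s (%s)%s", obs.id.cdna, result.tier.value, result.rationale.value,
            f" [without PS3/BS3: {ablated.tier.value}]" if ablated else "",
        )
        report.rows.append(
            ReportRow(
                variant_cdna=obs.id.cdna,
                variant_protein=obs.id.protein,
                activity_display=obs.activity.display,
                percent_wt_raw=None if obs.activity.below_detection else obs.activity.percent_wt,
                below_detection=obs.activity.below_detection,
                zone=zone.value,
                evidence=_evidence_columns(profile),
                evidence_labels=profile.labels(),
                tier=result.tier.value,
                rationale=result.rationale.value,
                matched_rule=result.matched_rule,
                tier_without_functional=ablated.tier.value if ablated else None,
                protein_bands=obs.protein_bands.value,
                notes=notes,
            )
        )
    return report


def run_pipeline(
    controls_path: Union[str, Path],
    variants_path: Union[str, Path],
    profile_path: Optional[Union[str, Path]] = None,
    policy: Policy = Policy.CONSERVATIVE,
    include_ablation: bool = True,
) -> ClassificationReport:
    """Read the control and variant tables (and optional VCEP-threshold JSON),
    calibrate, and classify.  Calibration failure aborts before any variant is
    classified; parse failures name the file, line, and column."""
    controls = gio.read_controls_tsv(controls_path)
    observations = gio.read_observations_tsv(variants_path)
    vcep = VCEPProfile.from_json(profile_path) if profile_path else VCEPProfile()
    return classify_observations(
        controls, observations, vcep, policy, include_ablation
    )
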