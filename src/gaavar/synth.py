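"""Seeded synthetic control panels, observations, and the published fixtures.

The generator emulates the statistical structure the calibration assumes:
pathogenic control activities fall below a true pathogenic boundary, benign
controls above a true benign boundary, an optional pseudodeficiency sentinel
strictly between, and replicate plates scatter around the construct's true
activity with additive Gaussian noise clipped at zero (two replicates of the
real assay differ by at most ~1.7 percentage points, so the default noise
scale is 1.0%).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .assay import ActivityMeasurement, VariantId
from .calibration import CalibrationResult, ControlVariant, KnownClass
from .evidence import ProteinBands, VariantObservations, VCEPProfile
from . import io as gio
from . import tables

__all__ = ["PanelSpec", "generate_panel", "generate_observations", "write_published_fixtures"]


@dataclass
class PanelSpec:
    """Parameters of a synthetic control panel.

    Defaults mirror the real validation panel: 7 pathogenic and 4 benign
    controls, one pseudodeficiency sentinel, true boundaries at 11% and 54%,
    two replicate plates per construct.
    """

    n_pathogenic: int = 7
    n_benign: int = 4
    include_pseudodeficiency: bool = True
    true_pathogenic_max: float = 11.0
    true_benign_min: float = 54.0
    replicate_sd: float = 1.0
    n_replicates: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.true_pathogenic_max < self.true_benign_min <= 100.0:
            raise ValueError(
                "need 0 <= true_pathogenic_max < true_benign_min <= 100, got "
                f"({self.true_pathogenic_max}, {self.true_benign_min})"
            )
        if self.replicate_sd < 0:
            raise ValueError("replicate_sd must be >= 0")
        if self.n_pathogenic < 0 or self.n_benign < 0:
            raise ValueError("control counts must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")


def _synthetic_id(index: int, prefix: str) -> VariantId:
    # Distinct single-nucleotide substitutions at increasing positions.
    return VariantId(f"c.{100 + index}A>G", f"p.{prefix}{index}")


def generate_panel(spec: PanelSpec) -> list[ControlVariant]:
    """Draw a reproducible synthetic control panel.

    True activities are uniform on [0, pathogenic_max] for pathogenic
    controls, [benign_min, 100] for benign, and strictly inside the gap for
    the pseudodeficiency sentinel; each expands to ``n_replicates`` noisy
    replicates clipped at zero.
    """
    rng = np.random.default_rng(spec.seed)
    panel: list[ControlVariant] = []

    def add(true_activity: float, cls: KnownClass, index: int, prefix: str) -> None:
        reps = true_activity + rng.normal(0.0, spec.replicate_sd, spec.n_replicates)
        reps = np.clip(reps, 0.0, None)
        panel.append(
            ControlVariant(
                _synthetic_id(index, prefix),
                cls,
                ActivityMeasurement(replicates=[float(r) for r in reps]),
            )
        )

    idx = 0
    for _ in range(spec.n_pathogenic):
        add(float(rng.uniform(0.0, spec.true_pathogenic_max)), KnownClass.PATHOGENIC, idx, "Path")
        idx += 1
    for _ in range(spec.n_benign):
        add(float(rng.uniform(spec.true_benign_min, 100.0)), KnownClass.BENIGN, idx, "Ben")
        idx += 1
    if spec.include_pseudodeficiency:
        lo, hi = spec.true_pathogenic_max, spec.true_benign_min
        if not lo < hi:  # guarded already by PanelSpec, kept for clarity
            raise ValueError("no indeterminate gap for a pseudodeficiency control")
        add(float(rng.uniform(np.nextafter(lo, hi), hi)), KnownClass.PSEUDODEFICIENCY, idx, "Psd")
    return panel


def generate_observations(
    n: int,
    seed: int,
    cal: CalibrationResult,
    profile: VCEPProfile,
    with_strata: bool = False,
):
    """Draw ``n`` random variant observations spanning all evidence strata.

    Activities are stratified over the three calibrated zones (with some
    not-detectable measurements inside the pathogenic stratum), allele
    frequencies over the PM2 / neither / BS1 strata, REVEL scores over the
    BP4 / neither / PP3 strata, and the PM3/PM5/PP4 booleans are fair coins.
    With ``with_strata`` the intended stratum labels are returned alongside,
    for generator self-consistency checks.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    observations: list[VariantObservations] = []
    strata: list[dict[str, str]] = []
    for i in range(n):
        zone = rng.choice(["pathogenic", "indeterminate", "benign"])
        if zone == "pathogenic":
            if rng.random() < 0.25:
                activity = ActivityMeasurement.not_detectable()
            else:
                activity = ActivityMeasurement.from_percent(
                    float(rng.uniform(0.0, cal.pathogenic_max))
                )
        elif zone == "indeterminate":
            activity = ActivityMeasurement.from_percent(
                float(rng.uniform(cal.pathogenic_max, np.nextafter(cal.benign_min, 0)))
            )
        else:
            activity = ActivityMeasurement.from_percent(
                float(rng.uniform(cal.benign_min, 120.0))
            )

        af_stratum = rng.choice(["pm2", "between", "bs1"])
        if af_stratum == "pm2":
            af = (
                {}
                if rng.random() < 0.5
                else {"global": float(rng.uniform(0.0, np.nextafter(profile.pm2_af_max, 0)))}
            )
        elif af_stratum == "between":
            af = {"global": float(rng.uniform(profile.pm2_af_max, profile.bs1_af_min))}
        else:
            af = {
                "global": float(rng.uniform(0.0, profile.pm2_af_max / 2)),
                "south_asian": float(
                    rng.uniform(np.nextafter(profile.bs1_af_min, 1), min(1.0, profile.bs1_af_min * 10))
                ),
            }

        revel_stratum = rng.choice(["bp4", "between", "pp3"])
        if revel_stratum == "bp4":
            revel = float(rng.uniform(0.0, np.nextafter(profile.bp4_revel_max, 0)))
        elif revel_stratum == "between":
            revel = float(rng.uniform(profile.bp4_revel_max, profile.pp3_revel_min))
        else:
            revel = float(rng.uniform(np.nextafter(profile.pp3_revel_min, 1), 1.0))

        in_trans = bool(rng.random() < 0.5)
        same_codon = bool(rng.random() < 0.5)
        observations.append(
            VariantObservations(
                id=_synthetic_id(i, "Obs"),
                activity=activity,
                af_by_population=af,
                in_trans_pathogenic=in_trans,
                trans_partner="c.-32-13T>G" if in_trans else "",
                same_codon_pathogenic=same_codon,
                same_codon_variant_cdna=f"c.{101 + i}A>T" if same_codon else "",
                same_codon_variant_protein=f"p.Gly{i + 1}Arg" if same_codon else "",
                revel=revel,
                phenotype_consistent=bool(rng.random() < 0.5),
                pseudodeficiency_excluded=bool(rng.random() < 0.9),
                protein_bands=ProteinBands(
                    rng.choice([b.value for b in ProteinBands])
                ),
            )
        )
        strata.append({"zone": str(zone), "af": str(af_stratum), "revel": str(revel_stratum)})
    if with_strata:
        return observations, strata
    return observations


def write_published_fixtures(directory: Union[str, Path]) -> dict[str, Path]:
    """Write the published control panel, replicate activities, and tested-
    variant observation table (plus default VCEP thresholds) as TSV/JSON.

    Output is byte-stable across runs.  Returns the paths written, keyed by
    role (``controls``, ``activities``, ``variants``, ``vcep_profile``).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "controls": directory / "controls.tsv",
        "activities": directory / "activities.tsv",
        "variants": directory / "variants.tsv",
        "vcep_profile": directory / "vcep_profile.json",
    }
    observations = tables.tested_observations()
    gio.write_controls_tsv(tables.control_panel(), paths["controls"])
    gio.write_measurements_tsv(
        {o.id: o.activity for o in observations}, paths["activities"]
    )
    gio.write_observations_tsv(observations, paths["variants"])
    VCEPProfile().write_json(paths["vcep_profile"])
    return paths
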