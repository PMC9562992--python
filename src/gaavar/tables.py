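"""Published GAA control-panel and tested-variant values.

These are the curated inputs of the validated HEK293 expression assay: the
12-variant control panel with known ClinVar classifications and measured
residual activities, the replicate activities of the eight variants tested
after newborn-screening ascertainment, and the per-variant curation
observations (gnomAD frequencies, phase, same-codon variants, REVEL scores,
phenotype flags, western-blot bands) used for ACMG/AMP classification.
"""

from __future__ import annotations

from .assay import ActivityMeasurement, VariantId
from .calibration import ControlVariant, KnownClass
from .evidence import ProteinBands, VariantObservations

__all__ = ["control_panel", "tested_observations", "TESTED_VARIANT_ORDER"]


# (cdna, protein, known class, percent activity or None when not detectable)
_CONTROLS = [
    ("c.2560C>T", "p.Arg854*", KnownClass.PATHOGENIC, None),
    ("c.525delT", "p.Glu176Argfs*45", KnownClass.PATHOGENIC, None),
    ("c.1933G>A", "p.Asp645Asn", KnownClass.PATHOGENIC, None),
    ("c.655G>A", "p.Gly219Arg", KnownClass.PATHOGENIC, 11.0),
    ("c.670C>T", "p.Arg224Trp", KnownClass.PATHOGENIC, 6.4),
    ("c.925G>A", "p.Gly309Arg", KnownClass.PATHOGENIC, 1.3),
    ("c.1655T>C", "p.Leu552Pro", KnownClass.PATHOGENIC, 7.8),
    ("c.2338G>A", "p.Val780Ile", KnownClass.BENIGN, 100.0),
    ("c.668G>A", "p.Arg223His", KnownClass.BENIGN, 100.0),
    ("c.1935C>T", "p.Asp645=", KnownClass.LIKELY_BENIGN, 100.0),
    ("c.596A>G", "p.His199Arg", KnownClass.BENIGN, 54.0),
    ("c.1726G>A", "p.Gly576Ser", KnownClass.PSEUDODEFICIENCY, 17.0),
]


def control_panel() -> list[ControlVariant]:
    """The 12-control validation panel (7 pathogenic, 4 benign/likely benign,
    1 pseudodeficiency)."""
    panel = []
    for cdna, protein, cls, pct in _CONTROLS:
        meas = (
            ActivityMeasurement.not_detectable()
            if pct is None
            else ActivityMeasurement.from_percent(pct)
        )
        panel.append(ControlVariant(VariantId(cdna, protein), cls, meas))
    return panel


# One record per tested variant, in patient order (patient 4 carries two).
# replicates=None encodes "not detectable" in both experiments.
_TESTED = [
    dict(
        patient=1,
        cdna="c.316C>T",
        protein="p.Arg106Cys",
        replicates=[11.05, 10.35],
        # below 0.001 in every continental population; gnomAD prints no
        # single figure, so a representative sub-threshold value is carried
        af={"all_continental": 0.0005},
        in_trans=True,
        trans_partner="c.-32-13T>G",
        same_codon=False,
        same_codon_cdna="",
        same_codon_protein="",
        revel=0.566,
        bands=ProteinBands.PRECURSOR_AND_MATURE,
    ),
    dict(
        patient=2,
        cdna="c.1103G>A",
        protein="p.Gly368Asp",
        replicates=[2.6, 2.9],
        af={},
        in_trans=True,
        trans_partner="c.-32-13T>G",
        same_codon=False,
        same_codon_cdna="",
        same_codon_protein="",
        revel=0.647,
        bands=ProteinBands.PRECURSOR_AND_MATURE,
    ),
    dict(
        patient=3,
        cdna="c.1721T>C",
        protein="p.Leu574Pro",
        replicates=None,
        af={},
        in_trans=True,
        trans_partner="c.-32-13T>G",
        same_codon=False,
        same_codon_cdna="",
        same_codon_protein="",
        revel=0.958,
        bands=ProteinBands.PRECURSOR_ONLY,
    ),
    dict(
        patient=4,
        cdna="c.664G>A",
        protein="p.Val222Met",
        replicates=[11.4, 12.1],
        # above the 0.005 BS1 floor in South Asians
        af={"south_asian": 0.006},
        in_trans=False,
        trans_partner="",
        same_codon=False,
        same_codon_cdna="",
        same_codon_protein="",
        revel=0.446,
        bands=ProteinBands.PRECURSOR_AND_MATURE,
    ),
    dict(
        patient=4,
        cdna="c.2450A>G",
        protein="p.His817Arg",
        replicates=None,
        af={},
        in_trans=False,
        trans_partner="",
        same_codon=False,
        same_codon_cdna="",
        same_codon_protein="",
        revel=0.926,
        bands=ProteinBands.PRECURSOR_ONLY,
    ),
    dict(
        patient=5,
        cdna="c.1048G>A",
        protein="p.Val350Met",
        replicates=[1.8, 1.2],
        af={"global": 0.00022},
        in_trans=True,
        trans_partner="c.1589del",
        same_codon=False,
        same_codon_cdna="",
        same_codon_protein="",
        revel=0.878,
        bands=ProteinBands.PRECURSOR_AND_MATURE,
    ),
    dict(
        patient=6,
        cdna="c.1378G>A",
        protein="p.Glu460Lys",
        replicates=[18.9, 16.0],
        af={"global": 0.00002},
        in_trans=True,
        trans_partner="c.-32-13T>G",
        same_codon=False,
        same_codon_cdna="",
        same_codon_protein="",
        revel=0.546,
        bands=ProteinBands.PRECURSOR_AND_MATURE,
    ),
    dict(
        patient=7,
        cdna="c.1123C>T",
        protein="p.Arg375Cys",
        replicates=[10.8, 12.5],
        af={"global": 0.00004},
        in_trans=True,
        trans_partner="c.-32-13T>G",
        same_codon=True,
        same_codon_cdna="c.1124G>T",
        same_codon_protein="p.Arg375Leu",
        revel=0.9539,
        bands=ProteinBands.PRECURSOR_AND_MATURE,
    ),
]

TESTED_VARIANT_ORDER = [rec["cdna"] for rec in _TESTED]


def tested_observations() -> list[VariantObservations]:
    """Curation observations for the eight tested variants, in patient order.

    Every patient had a Pompe-consistent phenotype with deficient blood GAA
    activity and no known pseudodeficiency allele, so the two PP4 booleans are
    true for all rows.
    """
    obs = []
    for rec in _TESTED:
        activity = (
            ActivityMeasurement.not_detectable()
            if rec["replicates"] is None
            else ActivityMeasurement(replicates=list(rec["replicates"]))
        )
        obs.append(
            VariantObservations(
                id=VariantId(rec["cdna"], rec["protein"]),
                activity=activity,
                af_by_population=dict(rec["af"]),
                in_trans_pathogenic=rec["in_trans"],
                trans_partner=rec["trans_partner"],
                same_codon_pathogenic=rec["same_codon"],
                same_codon_variant_cdna=rec["same_codon_cdna"],
                same_codon_variant_protein=rec["same_codon_protein"],
                revel=rec["revel"],
                phenotype_consistent=True,
                pseudodeficiency_excluded=True,
                protein_bands=rec["bands"],
            )
        )
    return obs
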