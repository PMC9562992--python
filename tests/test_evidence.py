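import dataclasses

import pytest
from hypothesis import given, strategies as st

from gaavar import (
    ActivityMeasurement,
    ProteinBands,
    Strength,
    VCEPProfile,
    VariantId,
    VariantObservations,
    assign_pm2_bs1,
    assign_pm3,
    assign_pm5,
    assign_pp3_bp4,
    assign_pp4,
    assign_ps3_bs3,
    build_profile,
    combine,
)
from gaavar.assay import InvalidAssayError


class TestAssignPs3Bs3:
    @pytest.mark.parametrize(
        "measurement,label",
        [
            (ActivityMeasurement.from_percent(10.7), "PS3_supporting"),
            (ActivityMeasurement.from_percent(11.7), None),
            (ActivityMeasurement.not_detectable(), "PS3_supporting"),
            (ActivityMeasurement.from_percent(60.0), "BS3_supporting"),
        ],
    )
    def test_zone_to_code(self, measurement, label, cal):
        item = assign_ps3_bs3(measurement, cal)
        assert (item.label if item else None) == label

    def test_missing_activity_is_incomplete_input(self, cal):
        with pytest.raises(InvalidAssayError):
            assign_ps3_bs3(None, cal)


class TestAssignPm2Bs1:
    @pytest.mark.parametrize(
        "af,label",
        [
            ({}, "PM2_supporting"),  # absent from gnomAD
            ({"south_asian": 0.006}, "BS1"),
            ({"european": 0.002}, None),  # between the thresholds
            ({"global": 0.00022}, "PM2_supporting"),
            ({"global": 0.0005, "european": 0.002}, None),  # one pop not rare
            ({"global": 0.001}, None),  # PM2 comparison is strict
            ({"global": 0.005}, None),  # BS1 comparison is strict
        ],
    )
    def test_frequency_thresholds(self, af, label, vcep):
        item = assign_pm2_bs1(af, vcep)
        assert (item.label if item else None) == label

    @given(
        af=st.dictionaries(
            st.sampled_from(["afr", "eas", "nfe", "sas"]),
            st.floats(0, 0.1),
            max_size=4,
        ),
        bump=st.floats(0, 0.5),
    )
    def test_raising_a_frequency_never_removes_bs1(self, af, bump):
        vcep = VCEPProfile()
        before = assign_pm2_bs1(af, vcep)
        if before is not None and before.code == "BS1":
            raised = dict(af)
            pop = max(raised, key=raised.get)
            raised[pop] = min(1.0, raised[pop] + bump)
            after = assign_pm2_bs1(raised, vcep)
            assert after is not None and after.code == "BS1"


class TestAssignPm3Pm5:
    def test_pm3_on_confirmed_trans_phase(self, vcep):
        item = assign_pm3(True, vcep, partner="c.-32-13T>G")
        assert item.label == "PM3"
        assert item.applied_strength is Strength.MODERATE
        assert "c.-32-13T>G" in item.justification
        assert assign_pm3(False, vcep) is None

    def test_pm5_cites_missense_at_same_codon(self, vcep):
        item = assign_pm5(True, vcep, "c.1124G>T", "p.Arg375Leu")
        assert item.label == "PM5"
        assert assign_pm5(False, vcep) is None

    @pytest.mark.parametrize("protein", ["p.Arg854*", "p.Glu530Glyfs*48", "p.Asp645="])
    def test_pm5_rejects_non_missense_citation(self, protein, vcep):
        with pytest.raises(ValueError):
            assign_pm5(True, vcep, "c.1G>A", protein)


class TestAssignPp3Bp4:
    @pytest.mark.parametrize(
        "revel,label",
        [
            (0.958, "PP3"),
            (0.446, "BP4"),
            (0.566, None),
            (0.7, None),  # thresholds are strict
            (0.5, None),
            (None, None),  # missing score
        ],
    )
    def test_revel_thresholds(self, revel, label, vcep):
        item = assign_pp3_bp4(revel, vcep)
        assert (item.label if item else None) == label

    @given(revel=st.floats(0.701, 1.0), bump=st.floats(0, 0.3))
    def test_raising_revel_never_removes_pp3(self, revel, bump):
        vcep = VCEPProfile()
        assert assign_pp3_bp4(revel, vcep).code == "PP3"
        assert assign_pp3_bp4(min(1.0, revel + bump), vcep).code == "PP3"

    def test_out_of_range_score_rejected(self, vcep):
        with pytest.raises(ValueError):
            assign_pp3_bp4(1.2, vcep)


class TestAssignPp4:
    def test_requires_both_flags(self, vcep):
        assert assign_pp4(True, True, vcep).label == "PP4_moderate"
        assert assign_pp4(True, False, vcep) is None
        assert assign_pp4(False, True, vcep) is None


class TestVCEPProfile:
    def test_defaults_are_the_published_thresholds(self, vcep):
        assert vcep.pm2_af_max == 0.001
        assert vcep.bs1_af_min == 0.005
        assert vcep.pp3_revel_min == 0.7
        assert vcep.bp4_revel_max == 0.5

    def test_json_round_trip(self, tmp_path, vcep):
        path = tmp_path / "vcep.json"
        vcep.write_json(path)
        assert VCEPProfile.from_json(path) == vcep

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"bp4_revel_max": 0.8},  # crosses pp3_revel_min
            {"pm2_af_max": 0.01},  # crosses bs1_af_min
            {"pp3_revel_min": 1.5},
        ],
    )
    def test_invalid_thresholds_rejected(self, kwargs):
        with pytest.raises(ValueError):
            VCEPProfile(**kwargs)


def _obs(**kwargs):
    defaults = dict(
        id=VariantId("c.316C>T", "p.Arg106Cys"),
        activity=ActivityMeasurement.from_percent(10.7),
        af_by_population={},
        in_trans_pathogenic=True,
        trans_partner="c.-32-13T>G",
        revel=0.566,
        phenotype_consistent=True,
        pseudodeficiency_excluded=True,
    )
    defaults.update(kwargs)
    return VariantObservations(**defaults)


class TestBuildProfile:
    def test_first_curated_variant_profile(self, cal, vcep):
        profile = build_profile(_obs(), cal, vcep)
        assert sorted(profile.labels()) == [
            "PM2_supporting", "PM3", "PP4_moderate", "PS3_supporting",
        ]

    def test_indeterminate_activity_and_midrange_revel_yield_neither(self, cal, vcep):
        profile = build_profile(
            _obs(activity=ActivityMeasurement.from_percent(17.5), revel=0.546),
            cal, vcep,
        )
        assert sorted(profile.labels()) == ["PM2_supporting", "PM3", "PP4_moderate"]

    def test_featureless_observation_gives_empty_profile(self, cal, vcep):
        obs = _obs(
            activity=ActivityMeasurement.from_percent(20.0),
            af_by_population={"global": 0.002},
            in_trans_pathogenic=False,
            trans_partner="",
            revel=0.6,
            phenotype_consistent=False,
            pseudodeficiency_excluded=False,
        )
        assert len(build_profile(obs, cal, vcep)) == 0

    def test_mutually_exclusive_codes_never_cooccur(self, cal, vcep):
        # sweep activity/frequency/REVEL strata jointly
        for pct in (None, 1.0, 20.0, 80.0):
            for af in ({}, {"g": 0.0005}, {"g": 0.002}, {"g": 0.02}):
                for revel in (None, 0.2, 0.6, 0.9):
                    activity = (
                        ActivityMeasurement.not_detectable()
                        if pct is None
                        else ActivityMeasurement.from_percent(pct)
                    )
                    labels = build_profile(
                        _obs(activity=activity, af_by_population=af, revel=revel),
                        cal, vcep,
                    ).labels()
                    codes = {l.split("_")[0] for l in labels}
                    assert not {"PM2", "BS1"} <= codes
                    assert not {"PP3", "BP4"} <= codes
                    assert not {"PS3", "BS3"} <= codes

    def test_protein_bands_never_influence_evidence(self, cal, vcep, observations):
        for obs in observations:
            baseline = None
            for bands in ProteinBands:
                toggled = dataclasses.replace(obs, protein_bands=bands)
                profile = build_profile(toggled, cal, vcep)
                outcome = (profile.labels(), combine(profile))
                if baseline is None:
                    baseline = outcome
                assert outcome == baseline
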