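import itertools

import pytest
from hypothesis import given, strategies as st

from gaavar import (
    EvidenceItem,
    EvidenceProfile,
    Rationale,
    Strength,
    Tier,
    ablate,
    combine,
)
from gaavar.evidence import EvidenceCategory

P, B = EvidenceCategory.PATHOGENIC, EvidenceCategory.BENIGN


def _item(k, category, strength):
    return EvidenceItem(
        code=f"E{k}", category=category, base_strength=strength,
        applied_strength=strength,
    )


def profile_from_counts(vs=0, s=0, m=0, p=0, sa=0, bs=0, bp=0):
    """Build a profile holding exactly the given strength counts."""
    spec = [
        (vs, P, Strength.VERY_STRONG),
        (s, P, Strength.STRONG),
        (m, P, Strength.MODERATE),
        (p, P, Strength.SUPPORTING),
        (sa, B, Strength.STAND_ALONE),
        (bs, B, Strength.STRONG),
        (bp, B, Strength.SUPPORTING),
    ]
    items, k = [], 0
    for count, cat, strength in spec:
        for _ in range(count):
            items.append(_item(k, cat, strength))
            k += 1
    return EvidenceProfile(items)


def oracle(vs, s, m, p, sa, bs, bp):
    """Independent transcription of the ACMG/AMP combining table."""
    pathogenic = (
        (vs >= 1 and (s >= 1 or m >= 2 or (m == 1 and p == 1) or p >= 2))
        or s >= 2
        or (s == 1 and (m >= 3 or (m == 2 and p >= 2) or (m == 1 and p >= 4)))
    )
    likely_pathogenic = (
        (vs == 1 and m == 1)
        or (s == 1 and 1 <= m <= 2)
        or (s == 1 and p >= 2)
        or m >= 3
        or (m == 2 and p >= 2)
        or (m == 1 and p >= 4)
    )
    benign = sa >= 1 or bs >= 2
    likely_benign = (bs == 1 and bp >= 1) or bp >= 2

    path_side = pathogenic or likely_pathogenic
    benign_side = benign or likely_benign
    has_path = vs + s + m + p > 0
    has_benign = sa + bs + bp > 0
    if has_path and has_benign and (path_side or benign_side):
        return Tier.UNCERTAIN_SIGNIFICANCE, Rationale.EVIDENCE_IN_CONFLICT
    if pathogenic:
        return Tier.PATHOGENIC, Rationale.NO_CONFLICT
    if likely_pathogenic:
        return Tier.LIKELY_PATHOGENIC, Rationale.NO_CONFLICT
    if benign:
        return Tier.BENIGN, Rationale.NO_CONFLICT
    if likely_benign:
        return Tier.LIKELY_BENIGN, Rationale.NO_CONFLICT
    return Tier.UNCERTAIN_SIGNIFICANCE, Rationale.INSUFFICIENT_EVIDENCE


def test_combine_matches_oracle_exhaustively():
    """Exhaustive agreement with an independent rule transcription over all
    strength-count vectors with every count <= 4 (5^7 cases)."""
    for counts in itertools.product(range(5), repeat=7):
        result = combine(profile_from_counts(*counts))
        assert (result.tier, result.rationale) == oracle(*counts), counts


class TestCombineExamples:
    def _curated(self, labels):
        strengths = {
            "PS3_supporting": ("PS3", P, Strength.SUPPORTING),
            "PM2_supporting": ("PM2", P, Strength.SUPPORTING),
            "PM3": ("PM3", P, Strength.MODERATE),
            "PM5": ("PM5", P, Strength.MODERATE),
            "PP3": ("PP3", P, Strength.SUPPORTING),
            "PP4_moderate": ("PP4", P, Strength.MODERATE),
            "BS1": ("BS1", B, Strength.STRONG),
            "BP4": ("BP4", B, Strength.SUPPORTING),
        }
        items = []
        for label in labels:
            code, cat, strength = strengths[label]
            items.append(
                EvidenceItem(code=code, category=cat,
                             base_strength=strength, applied_strength=strength)
            )
        return EvidenceProfile(items)

    @pytest.mark.parametrize(
        "labels,tier,rationale",
        [
            # modified strengths count at their applied strength: PS3_supporting
            # is a supporting item, PP4_moderate a moderate one
            (["PS3_supporting", "PM2_supporting", "PM3", "PP4_moderate"],
             Tier.LIKELY_PATHOGENIC, Rationale.NO_CONFLICT),
            (["PS3_supporting", "PM2_supporting", "PP3", "PP4_moderate"],
             Tier.UNCERTAIN_SIGNIFICANCE, Rationale.INSUFFICIENT_EVIDENCE),
            (["BS1", "BP4", "PP4_moderate"],
             Tier.UNCERTAIN_SIGNIFICANCE, Rationale.EVIDENCE_IN_CONFLICT),
            (["PM2_supporting", "PM3", "PM5", "PP3", "PP4_moderate"],
             Tier.LIKELY_PATHOGENIC, Rationale.NO_CONFLICT),
            ([], Tier.UNCERTAIN_SIGNIFICANCE, Rationale.INSUFFICIENT_EVIDENCE),
        ],
    )
    def test_curated_profiles(self, labels, tier, rationale):
        result = combine(self._curated(labels))
        assert result.tier is tier
        assert result.rationale is rationale

    def test_likely_benign_without_pathogenic_items(self):
        result = combine(self._curated(["BS1", "BP4"]))
        assert result.tier is Tier.LIKELY_BENIGN

    def test_duplicate_codes_forbidden(self):
        item = _item(0, P, Strength.MODERATE)
        with pytest.raises(ValueError):
            EvidenceProfile([item, item])

    def test_vus_always_carries_a_vus_rationale(self):
        result = combine(self._curated(["PM2_supporting"]))
        assert result.tier is Tier.UNCERTAIN_SIGNIFICANCE
        assert result.rationale in (
            Rationale.INSUFFICIENT_EVIDENCE, Rationale.EVIDENCE_IN_CONFLICT
        )
        assert result.matched_rule is None


class TestAblate:
    def _patient_profile(self, with_pp3):
        labels = ["PS3_supporting", "PM2_supporting", "PM3", "PP4_moderate"]
        if with_pp3:
            labels.append("PP3")
        return TestCombineExamples()._curated(labels)

    def test_removing_functional_evidence_can_flip_to_vus(self):
        profile = self._patient_profile(with_pp3=False)
        assert combine(profile).tier is Tier.LIKELY_PATHOGENIC
        assert ablate(profile, "PS3").tier is Tier.UNCERTAIN_SIGNIFICANCE

    def test_other_evidence_can_carry_the_classification(self):
        profile = self._patient_profile(with_pp3=True)
        assert ablate(profile, "PS3").tier is Tier.LIKELY_PATHOGENIC

    def test_removing_absent_code_is_noop(self):
        profile = self._patient_profile(with_pp3=True)
        assert ablate(profile, "BS3") == combine(profile)


_TIER_ORDER = [Tier.BENIGN, Tier.LIKELY_BENIGN, Tier.UNCERTAIN_SIGNIFICANCE,
               Tier.LIKELY_PATHOGENIC, Tier.PATHOGENIC]


@given(
    vs=st.integers(0, 1),
    counts=st.tuples(*[st.integers(0, 3) for _ in range(3)]),
    which=st.integers(0, 2),
)
def test_adding_pathogenic_evidence_is_monotone_without_benign_items(vs, counts, which):
    # scoped to the strengths the assigners emit (strong and below, at most
    # one very-strong): the frozen combining table is monotone there
    s, m, p = counts
    before = combine(profile_from_counts(vs, s, m, p))
    bumped = list(counts)
    bumped[which] += 1
    after = combine(profile_from_counts(vs, *bumped))
    assert _TIER_ORDER.index(after.tier) >= _TIER_ORDER.index(before.tier)


def test_frozen_table_quirk_two_very_strong_items_match_no_rule():
    """The 2015 combining table as frozen here has no rule for two
    very-strong items with one moderate: adding a second PVS-level item to a
    likely-pathogenic profile falls back to VUS.  Pinned so any future rule
    revision is a deliberate change."""
    assert combine(profile_from_counts(vs=1, m=1)).tier is Tier.LIKELY_PATHOGENIC
    assert (
        combine(profile_from_counts(vs=2, m=1)).tier is Tier.UNCERTAIN_SIGNIFICANCE
    )


@given(counts=st.tuples(*[st.integers(0, 3) for _ in range(3)]), which=st.integers(0, 2))
def test_adding_benign_evidence_is_monotone_without_pathogenic_items(counts, which):
    sa, bs, bp = counts
    before = combine(profile_from_counts(sa=sa, bs=bs, bp=bp))
    bumped = list(counts)
    bumped[which] += 1
    after = combine(profile_from_counts(sa=bumped[0], bs=bumped[1], bp=bumped[2]))
    assert _TIER_ORDER.index(after.tier) <= _TIER_ORDER.index(before.tier)


def test_combine_is_deterministic():
    profile = profile_from_counts(m=2, p=2)
    results = {combine(profile) for _ in range(10)}
    assert len(results) == 1


def test_json_profile_round_trip():
    profile = profile_from_counts(vs=1, m=1, bp=1)
    back = EvidenceProfile.from_dicts(profile.to_dicts())
    assert combine(back) == combine(profile)
    assert [i.code for i in back] == [i.code for i in profile]
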