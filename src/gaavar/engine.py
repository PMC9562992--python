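"""Combining ACMG/AMP evidence into a five-tier classification.

The 2015 ACMG/AMP combining rules are evaluated over counts of evidence items
by category and *applied* strength, so VCEP strength modifications take
effect naturally (PS3 applied at supporting counts as one supporting item,
PP4 at moderate as one moderate).  Mixed-category profiles where either side
alone would reach a non-VUS tier resolve to uncertain significance with an
evidence-in-conflict rationale.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .calibration import Strength
from .evidence import EvidenceCategory, EvidenceItem

__all__ = [
    "EvidenceProfile",
    "Classification",
    "Tier",
    "Rationale",
    "combine",
    "ablate",
]


class Tier(str, enum.Enum):
    PATHOGENIC = "pathogenic"
    LIKELY_PATHOGENIC = "likely_pathogenic"
    UNCERTAIN_SIGNIFICANCE = "uncertain_significance"
    LIKELY_BENIGN = "likely_benign"
    BENIGN = "benign"


class Rationale(str, enum.Enum):
    NO_CONFLICT = "no_conflict"
    INSUFFICIENT_EVIDENCE = "insufficient_evidence"
    EVIDENCE_IN_CONFLICT = "evidence_in_conflict"


class EvidenceProfile:
    """An ordered set of evidence items with unique codes."""

    def __init__(self, items: Iterable[EvidenceItem] = ()):
        self.items: list[EvidenceItem] = list(items)
        codes = [i.code for i in self.items]
        if len(codes) != len(set(codes)):
            dupes = sorted({c for c in codes if codes.count(c) > 1})
            raise ValueError(f"duplicate evidence codes in profile: {dupes}")

    def __iter__(self):
        return iter(self.items)

    def __len__(self) -> int:
        return len(self.items)

    def __contains__(self, code: str) -> bool:
        return any(i.code == code for i in self.items)

    def __eq__(self, other) -> bool:
        return isinstance(other, EvidenceProfile) and self.items == other.items

    def __repr__(self) -> str:
        return f"EvidenceProfile([{', '.join(i.label for i in self.items)}])"

    def without(self, code: str) -> "EvidenceProfile":
        return EvidenceProfile([i for i in self.items if i.code != code])

    def counts(self) -> dict[tuple[EvidenceCategory, Strength], int]:
        return dict(Counter((i.category, i.applied_strength) for i in self.items))

    def labels(self) -> list[str]:
        return [i.label for i in self.items]

    def to_dicts(self) -> list[dict]:
        return [
            {
                "code": i.code,
                "category": i.category.value,
                "strength": i.applied_strength.value,
                "justification": i.justification,
            }
            for i in self.items
        ]

    @classmethod
    def from_dicts(cls, records: Sequence[dict]) -> "EvidenceProfile":
        items = []
        for r in records:
            strength = Strength(r["strength"])
            items.append(
                EvidenceItem(
                    code=r["code"],
                    category=EvidenceCategory(r["category"]),
                    base_strength=Strength(r.get("base_strength", strength.value)),
                    applied_strength=strength,
                    justification=r.get("justification", ""),
                )
            )
        return cls(items)


@dataclass(frozen=True)
class Classification:
    tier: Tier
    rationale: Rationale
    matched_rule: Optional[str] = None

    def __post_init__(self) -> None:
        is_vus = self.tier is Tier.UNCERTAIN_SIGNIFICANCE
        vus_rationale = self.rationale in (
            Rationale.INSUFFICIENT_EVIDENCE,
            Rationale.EVIDENCE_IN_CONFLICT,
        )
        if is_vus != vus_rationale:
            raise ValueError(
                f"inconsistent classification: {self.tier.value} / {self.rationale.value}"
            )


def _strength_counts(profile: EvidenceProfile) -> tuple[int, int, int, int, int, int, int]:
    """Counts (VS, S, M, P) pathogenic and (SA, BS, BP) benign by applied strength.

    Strengths without a slot in the 2015 combining table are folded toward the
    nearest defined slot: a pathogenic stand-alone counts as very strong, a
    benign very-strong as strong, and a benign moderate as supporting.
    """
    vs = s = m = p = sa = bs = bp = 0
    for item in profile:
        st = item.applied_strength
        if item.category is EvidenceCategory.PATHOGENIC:
            if st in (Strength.STAND_ALONE, Strength.VERY_STRONG):
                vs += 1
            elif st is Strength.STRONG:
                s += 1
            elif st is Strength.MODERATE:
                m += 1
            else:
                p += 1
        else:
            if st is Strength.STAND_ALONE:
                sa += 1
            elif st in (Strength.VERY_STRONG, Strength.STRONG):
                bs += 1
            else:
                bp += 1
    return vs, s, m, p, sa, bs, bp


# Rule list frozen from the 2015 ACMG/AMP combining table; each entry is
# (rule id, predicate over the strength counts).
_PATHOGENIC_RULES = [
    ("P1", lambda vs, s, m, p: vs >= 1 and (s >= 1 or m >= 2 or (m == 1 and p == 1) or p >= 2)),
    ("P2", lambda vs, s, m, p: s >= 2),
    ("P3", lambda vs, s, m, p: s == 1 and (m >= 3 or (m == 2 and p >= 2) or (m == 1 and p >= 4))),
]
_LIKELY_PATHOGENIC_RULES = [
    ("LP1", lambda vs, s, m, p: vs == 1 and m == 1),
    ("LP2", lambda vs, s, m, p: s == 1 and 1 <= m <= 2),
    ("LP3", lambda vs, s, m, p: s == 1 and p >= 2),
    ("LP4", lambda vs, s, m, p: m >= 3),
    ("LP5", lambda vs, s, m, p: m == 2 and p >= 2),
    ("LP6", lambda vs, s, m, p: m == 1 and p >= 4),
]
_BENIGN_RULES = [
    ("B1", lambda sa, bs, bp: sa >= 1),
    ("B2", lambda sa, bs, bp: bs >= 2),
]
_LIKELY_BENIGN_RULES = [
    ("LB1", lambda sa, bs, bp: bs == 1 and bp >= 1),
    ("LB2", lambda sa, bs, bp: bp >= 2),
]


def _pathogenic_side(vs: int, s: int, m: int, p: int) -> tuple[Optional[Tier], Optional[str]]:
    for rule_id, pred in _PATHOGENIC_RULES:
        if pred(vs, s, m, p):
            return Tier.PATHOGENIC, rule_id
    for rule_id, pred in _LIKELY_PATHOGENIC_RULES:
        if pred(vs, s, m, p):
            return Tier.LIKELY_PATHOGENIC, rule_id
    return None, None


def _benign_side(sa: int, bs: int, bp: int) -> tuple[Optional[Tier], Optional[str]]:
    for rule_id, pred in _BENIGN_RULES:
        if pred(sa, bs, bp):
            return Tier.BENIGN, rule_id
    for rule_id, pred in _LIKELY_BENIGN_RULES:
        if pred(sa, bs, bp):
            return Tier.LIKELY_BENIGN, rule_id
    return None, None


def combine(profile: EvidenceProfile) -> Classification:
    """Evaluate the combining rules over one evidence profile.

    A pure, total function: any valid profile yields exactly one of the five
    tiers, and a VUS always carries a rationale (insufficient evidence, or
    evidence in conflict when both categories are present and at least one
    side alone would reach a non-VUS tier).
    """
    vs, s, m, p, sa, bs, bp = _strength_counts(profile)
    path_tier, path_rule = _pathogenic_side(vs, s, m, p)
    benign_tier, benign_rule = _benign_side(sa, bs, bp)

    has_path = vs + s + m + p > 0
    has_benign = sa + bs + bp > 0
    if has_path and has_benign and (path_tier is not None or benign_tier is not None):
        return Classification(
            Tier.UNCERTAIN_SIGNIFICANCE, Rationale.EVIDENCE_IN_CONFLICT, None
        )
    if path_tier is not None:
        return Classification(path_tier, Rationale.NO_CONFLICT, path_rule)
    if benign_tier is not None:
        return Classification(benign_tier, Rationale.NO_CONFLICT, benign_rule)
    return Classification(
        Tier.UNCERTAIN_SIGNIFICANCE, Rationale.INSUFFICIENT_EVIDENCE, None
    )


def ablate(profile: EvidenceProfile, code: str) -> Classification:
    """Counterfactual classification with one code removed.

    Removing a code that is not present is a no-op; used to report what each
    evidence line (typically the functional PS3/BS3 data) contributed.
    """
    return combine(profile.without(code))
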