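"""Ego-relative kinship canonicalization.

Every person in a household network is described relative to the *index adult*
(the focal young-adult respondent).  Co-surveyed family members describe the
people in their own networks relative to *themselves*, so fusing several
reporters' networks requires composing "the reporter's relation to the index"
with "the alter's relation to the reporter": a participating mother's
"husband" is the index adult's father; a participating grandmother's "son" is
either the father or an uncle, and stays ambiguous until another reporter's
data (or a manual override) resolves it.

The canonical vocabulary is closed.  Kin terms carry a generation offset
relative to the index adult: grandparents +2; parents, aunts/uncles,
godparents and parents-in-law +1; the index, siblings, cousins, spouses and
siblings-in-law 0; children, nieces/nephews and children-in-law -1;
grandchildren -2.  Collateral kin outside the named slots (grand-aunts,
parents' cousins, ...) map to the named term of their generation class, so a
granduncle is carried as ``grandparent`` -- what matters downstream is the
generation offset, not the exact pedigree path.  Friends and unresolvable
relations carry no offset.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field, replace
from importlib import resources as _importlib_resources
from typing import Iterable, Mapping, Optional

__all__ = [
    "CanonicalRelation",
    "CandidateSet",
    "KinshipError",
    "parse_relation_label",
    "compose_relations",
    "resolve_candidates",
    "inverse_relation",
    "GENERATION_OFFSETS",
    "CANONICAL_TERMS",
]


class KinshipError(ValueError):
    """Raised for invalid labels or conflicting manual overrides."""


#: generation offset of each canonical kin term relative to the index adult
GENERATION_OFFSETS: Mapping[str, int] = {
    "ego": 0,
    "father": 1,
    "mother": 1,
    "sibling": 0,
    "grandparent": 2,
    "aunt_uncle": 1,
    "godparent": 1,
    "godchild": -1,
    "cousin": 0,
    "child": -1,
    "niece_nephew": -1,
    "grandchild": -2,
    "spouse_partner": 0,
    "parent_in_law": 1,
    "sibling_in_law": 0,
    "child_in_law": -1,
}

CANONICAL_TERMS = tuple(GENERATION_OFFSETS) + ("friend", "other")

_SPOUSE_LABELS = {"spouse_partner"}
_NON_FAMILY = {"friend", "other"}


@dataclass(frozen=True)
class CanonicalRelation:
    """A canonical ego-relative (or reporter-relative) kinship term.

    ``generation_offset`` is ``None`` for friends and unresolved relations
    (the sentinel for "undefined").  ``sex`` is the implied or reported sex of
    the person ('m', 'f' or None when unknown); it is metadata used for
    composition filtering and node matching, not part of relation identity.
    """

    label: str
    generation_offset: Optional[int]
    is_family: bool
    is_spouse_partner: bool
    sex: Optional[str] = field(default=None, compare=False)

    @classmethod
    def from_label(cls, label: str, sex: Optional[str] = None) -> "CanonicalRelation":
        if label in _NON_FAMILY:
            return cls(label, None, False, False, sex)
        if label not in GENERATION_OFFSETS:
            raise KinshipError(f"unknown canonical term: {label!r}")
        return cls(
            label,
            GENERATION_OFFSETS[label],
            True,
            label in _SPOUSE_LABELS,
            sex,
        )


FRIEND = CanonicalRelation.from_label("friend")
OTHER = CanonicalRelation.from_label("other")
EGO = CanonicalRelation.from_label("ego")


@dataclass(frozen=True)
class CandidateSet:
    """Outcome of composing two relations: one or more consistent readings.

    ``ambiguous`` is true when more than one candidate existed before
    resolution.  ``resolution_source`` records how (or whether) the ambiguity
    was settled: 'unique', 'cross_reporter_match', 'manual_override' or
    'unresolved'.
    """

    candidates: frozenset[CanonicalRelation]
    ambiguous: bool
    resolution_source: str = "unique"

    def __post_init__(self):
        if not self.candidates:
            raise KinshipError("CandidateSet must be non-empty")


# ---------------------------------------------------------------------------
# label parsing

_TERM_MAP = {
    "father": ("father", "m"), "dad": ("father", "m"), "daddy": ("father", "m"),
    "papa": ("father", "m"), "pa": ("father", "m"),
    "mother": ("mother", "f"), "mum": ("mother", "f"), "mom": ("mother", "f"),
    "mummy": ("mother", "f"), "mommy": ("mother", "f"), "mama": ("mother", "f"),
    "ma": ("mother", "f"),
    "parent": ("father", None),  # sex decides father/mother; handled below
    "brother": ("sibling", "m"), "bro": ("sibling", "m"),
    "sister": ("sibling", "f"), "sis": ("sibling", "f"),
    "sibling": ("sibling", None),
    "grandfather": ("grandparent", "m"), "grandpa": ("grandparent", "m"),
    "granddad": ("grandparent", "m"), "gramps": ("grandparent", "m"),
    "grandmother": ("grandparent", "f"), "grandma": ("grandparent", "f"),
    "granny": ("grandparent", "f"), "nana": ("grandparent", "f"),
    "grandparent": ("grandparent", None),
    "granduncle": ("grandparent", "m"), "grandaunt": ("grandparent", "f"),
    "uncle": ("aunt_uncle", "m"),
    "aunt": ("aunt_uncle", "f"), "auntie": ("aunt_uncle", "f"),
    "aunty": ("aunt_uncle", "f"),
    "godfather": ("godparent", "m"), "godmother": ("godparent", "f"),
    "godparent": ("godparent", None),
    "godson": ("godchild", "m"), "goddaughter": ("godchild", "f"),
    "godchild": ("godchild", None),
    "cousin": ("cousin", None),
    "son": ("child", "m"), "daughter": ("child", "f"), "child": ("child", None),
    "nephew": ("niece_nephew", "m"), "niece": ("niece_nephew", "f"),
    "grandson": ("grandchild", "m"), "granddaughter": ("grandchild", "f"),
    "grandchild": ("grandchild", None),
    "husband": ("spouse_partner", "m"), "wife": ("spouse_partner", "f"),
    "spouse": ("spouse_partner", None), "partner": ("spouse_partner", None),
    "boyfriend": ("spouse_partner", "m"), "girlfriend": ("spouse_partner", "f"),
    "fiance": ("spouse_partner", "m"), "fiancee": ("spouse_partner", "f"),
    "father-in-law": ("parent_in_law", "m"), "mother-in-law": ("parent_in_law", "f"),
    "parent-in-law": ("parent_in_law", None),
    "brother-in-law": ("sibling_in_law", "m"),
    "sister-in-law": ("sibling_in_law", "f"),
    "son-in-law": ("child_in_law", "m"), "daughter-in-law": ("child_in_law", "f"),
    "ego": ("ego", None), "self": ("ego", None),
}

#: qualifiers that refine but do not change the kin type
_QUALIFIERS = {
    "oldest", "eldest", "older", "elder", "youngest", "younger", "young",
    "big", "little", "second", "third", "first", "twin", "half", "step",
    "maternal", "paternal", "my", "the", "1st", "2nd", "3rd",
}


def _normalize(raw: str) -> list[str]:
    # "Mother in law" -> "mother-in-law"; drop initials/pseudonym suffixes
    s = re.sub(r"\s+in[\s-]+law\b", "-in-law", raw.strip(), flags=re.I)
    tokens = []
    for tok in s.replace("_", " ").split():
        if tok.isupper() and len(tok) <= 3:
            continue  # initials like "AZ" in "auntie AZ"
        tokens.append(tok.lower().strip(".,"))
    return [t for t in tokens if t not in _QUALIFIERS]


def parse_relation_label(
    raw_label: str, relation_class: str = "family", sex: Optional[str] = None
) -> CanonicalRelation:
    """Map a free-text relation label to a canonical relation.

    Qualifiers ("oldest brother", "maternal grandmother") and pseudonym
    initials ("auntie AZ") are ignored for kin typing.  Labels with no kin
    term fall back to ``friend`` or ``other`` according to the reporter's
    ``relation_class`` field; an unknown label classed as family becomes
    ``other`` (it cannot be placed in a generation).
    """
    if not raw_label or not raw_label.strip():
        raise KinshipError("empty relation label")
    tokens = _normalize(raw_label)
    hit = None
    for tok in tokens:
        if tok in _TERM_MAP:
            hit = _TERM_MAP[tok]
            break
    if hit is None:
        joined = " ".join(tokens)
        if joined in _TERM_MAP:
            hit = _TERM_MAP[joined]
    if hit is None:
        if relation_class == "friend":
            return replace(FRIEND, sex=sex)
        return replace(OTHER, sex=sex)
    label, implied_sex = hit
    sex = sex or implied_sex
    if label == "father" and implied_sex is None and sex == "f":
        label = "mother"  # generic "parent" with known female sex
    return CanonicalRelation.from_label(label, sex=sex or implied_sex)


# ---------------------------------------------------------------------------
# composition

def _load_composition() -> dict[tuple[str, str], list[tuple[str, str]]]:
    table: dict[tuple[str, str], list[tuple[str, str]]] = {}
    ref = _importlib_resources.files("kinnet.resources").joinpath("composition.csv")
    with ref.open("r", newline="") as fh:
        for row in csv.DictReader(fh):
            key = (row["reporter"], row["reported"])
            table.setdefault(key, []).append((row["candidate"], row["sex"]))
    return table


_COMPOSITION: Optional[dict] = None


def _composition_table():
    global _COMPOSITION
    if _COMPOSITION is None:
        _COMPOSITION = _load_composition()
    return _COMPOSITION


def compose_relations(
    reporter_rel: CanonicalRelation, reported: CanonicalRelation
) -> CandidateSet:
    """All index-relative relations consistent with reporter∘reported.

    ``reporter_rel`` is the reporter's canonical relation to the index adult;
    ``reported`` is the alter's relation to the reporter.  The identity
    reporter (the index adult) maps every reported relation to itself.
    Friends and "other" compose to themselves regardless of reporter.
    Compositions outside the shipped table yield ``{other}`` marked
    unresolved, never an exception.
    """
    if reported.label in _NON_FAMILY:
        return CandidateSet(frozenset({replace(reported)}), False, "unique")
    if reporter_rel.label == "ego":
        return CandidateSet(frozenset({reported}), False, "unique")
    cands = _composition_table().get((reporter_rel.label, reported.label))
    if not cands:
        return CandidateSet(
            frozenset({replace(OTHER, sex=reported.sex)}), False, "unresolved"
        )
    kept = []
    for label, sex_req in cands:
        if sex_req != "any" and reported.sex is not None and reported.sex != sex_req:
            continue
        kept.append(CanonicalRelation.from_label(label, sex=reported.sex))
    if not kept:
        kept = [replace(OTHER, sex=reported.sex)]
    ambiguous = len(set(kept)) > 1
    return CandidateSet(
        frozenset(kept), ambiguous, "unresolved" if ambiguous else "unique"
    )


_INVERSE = {
    "father": "child", "mother": "child", "child": "father",
    "sibling": "sibling", "grandparent": "grandchild", "grandchild": "grandparent",
    "aunt_uncle": "niece_nephew", "niece_nephew": "aunt_uncle",
    "godparent": "godchild", "godchild": "godparent",
    "cousin": "cousin", "spouse_partner": "spouse_partner",
    "parent_in_law": "child_in_law", "child_in_law": "parent_in_law",
    "sibling_in_law": "sibling_in_law", "ego": "ego",
    "friend": "friend", "other": "other",
}


def inverse_relation(rel: CanonicalRelation, subject_sex: Optional[str] = None) -> CanonicalRelation:
    """The relation of B to A given A's relation ``rel`` to B.

    ``subject_sex`` is the sex of the person whose relation is being derived
    (used to pick father vs mother when inverting 'child').
    """
    label = _INVERSE[rel.label]
    if label == "father" and subject_sex == "f":
        label = "mother"
    return CanonicalRelation.from_label(label, sex=subject_sex)


# ---------------------------------------------------------------------------
# ambiguity resolution

@dataclass(frozen=True)
class ResolvedNodeContext:
    """A uniquely-resolved node from another reporter, used for matching."""

    relation: CanonicalRelation
    sex: Optional[str]
    age: Optional[float]


def resolve_candidates(
    cands: CandidateSet,
    alter_sex: Optional[str],
    alter_age: Optional[float],
    registry_context: Iterable[ResolvedNodeContext] = (),
    overrides: Optional[Mapping[str, str]] = None,
    override_key: Optional[str] = None,
    age_tolerance: float = 5.0,
    log: Optional[list] = None,
) -> tuple[CanonicalRelation, str]:
    """Settle a candidate set to a single relation.

    Resolution order: (1) a manual override row, standing in for the study
    team contacting participants; (2) a cross-reporter match -- a candidate
    that coincides with another reporter's uniquely-resolved node of
    compatible sex and age within ``age_tolerance`` years; (3) otherwise the
    node stays unresolved and its relation falls to ``other``, excluding it
    from generational classification.

    Returns ``(relation, resolution_source)``.
    """
    overrides = overrides or {}
    if override_key is not None and override_key in overrides:
        label = overrides[override_key]
        rel = CanonicalRelation.from_label(label, sex=alter_sex)
        if log is not None:
            log.append((override_key, label, "manual_override"))
        return rel, "manual_override"

    ordered = sorted(cands.candidates, key=lambda r: r.label)
    if len(ordered) == 1:
        only = ordered[0]
        src = "unique" if cands.resolution_source != "unresolved" else "unresolved"
        return only, src

    matches = []
    for cand in ordered:
        for node in registry_context:
            if node.relation.label != cand.label:
                continue
            if node.sex is not None and alter_sex is not None and node.sex != alter_sex:
                continue
            if (
                node.age is not None
                and alter_age is not None
                and abs(node.age - alter_age) > age_tolerance
            ):
                continue
            matches.append(cand)
            break
    if len(set(m.label for m in matches)) == 1 and matches:
        rel = replace(matches[0], sex=alter_sex or matches[0].sex)
        if log is not None:
            log.append((override_key, rel.label, "cross_reporter_match"))
        return rel, "cross_reporter_match"

    if log is not None:
        log.append((override_key, "other", "unresolved"))
    return replace(OTHER, sex=alter_sex), "unresolved"
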