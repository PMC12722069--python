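"""Fuse multi-reporter egocentric surveys into one household network.

Each surveyed household member reports their own egocentric network; the
same person (the index adult's father, say) can appear as "father" in one
report, "husband" in another and "son" in a third.  Fusion canonicalizes
every reported relation to an index-relative kinship term
(:mod:`kinnet.kinship`), merges nodes that occupy the same kin slot,
averages dyadic ratings reported by several reporters, and classifies every
consolidated tie as intergenerational, intragenerational, spouse/partner,
friend or other.

Merge rules
-----------
* Singleton kin slots (father, mother, the index adult, the index's
  spouse/partner) always merge.
* Multi-instance slots (siblings, grandparents, aunts/uncles, cousins, ...)
  merge only when sex is compatible and ages agree within a tolerance, so
  two brothers stay distinct nodes.
* Friend (and unresolved "other") nodes merge across reporters only on an
  exact label match after case/whitespace normalization: nothing else ties
  two reporters' friends together.
* Surveyed participants' self-reported attributes take precedence over other
  reporters' perceptions of them; perceived attributes of merged alters are
  averaged across reporters.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from . import kinship
from .kinship import (
    CanonicalRelation,
    CandidateSet,
    ResolvedNodeContext,
    compose_relations,
    parse_relation_label,
    resolve_candidates,
)
from .survey_io import BAND_MIDPOINTS, HouseholdSurvey, band_age

__all__ = [
    "Node",
    "NodeRegistry",
    "FusedEdge",
    "HouseholdNetwork",
    "IntegrityError",
    "CATEGORIES",
    "fuse_household",
    "fuse_cohort",
    "deduplicate_nodes",
    "consolidate_edges",
    "classify_edge",
    "is_spousal_pair",
    "build_directed_records",
]


class IntegrityError(ValueError):
    """Two surveyed participants occupy the same singleton kin slot."""


CATEGORIES = (
    "intergenerational",
    "intragenerational",
    "spouse_partner",
    "friend",
    "other",
)

#: kin slots that can hold at most one person per household
_SINGLETON_SLOTS = {"ego", "father", "mother"}

#: unordered label pairs classified as a spousal tie (couple slots)
_SPOUSAL_PAIRS = {
    frozenset({"ego", "spouse_partner"}),
    frozenset({"father", "mother"}),
    frozenset({"sibling", "sibling_in_law"}),
    frozenset({"child", "child_in_law"}),
}
#: same-label pairs spousal when the two nodes are of opposite sex
_SPOUSAL_SAME_LABEL = {"grandparent", "parent_in_law"}


@dataclass
class Node:
    node_id: str
    relation: CanonicalRelation
    surveyed: bool
    participant_id: Optional[str]
    sex: Optional[str]
    age: Optional[float]
    self_health: Optional[float] = None
    self_effort: Optional[float] = None
    perceived_health_vals: list = field(default_factory=list)
    perceived_effort_vals: list = field(default_factory=list)
    age_vals: list = field(default_factory=list)
    reporters: set = field(default_factory=set)
    resolution_source: str = "unique"

    @property
    def reporter_count(self) -> int:
        return len(self.reporters)

    @property
    def perceived_health(self) -> Optional[float]:
        return float(np.mean(self.perceived_health_vals)) if self.perceived_health_vals else None

    @property
    def perceived_effort(self) -> Optional[float]:
        return float(np.mean(self.perceived_effort_vals)) if self.perceived_effort_vals else None

    @property
    def health(self) -> Optional[float]:
        """Best available health rating: self-report beats perception."""
        return self.self_health if self.surveyed else self.perceived_health

    @property
    def effort(self) -> Optional[float]:
        return self.self_effort if self.surveyed else self.perceived_effort

    @property
    def age_years(self) -> Optional[float]:
        """Age in years: surveyed age, else mean reported age, else band midpoint."""
        if self.age is not None:
            return self.age
        if self.age_vals:
            return float(np.mean(self.age_vals))
        return None


@dataclass
class NodeRegistry:
    household_id: str
    nodes: dict[str, Node] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for n in self.nodes.values():
            rows.append(
                dict(
                    household_id=self.household_id,
                    node_id=n.node_id,
                    relation=n.relation.label,
                    generation_offset=n.relation.generation_offset,
                    is_family=n.relation.is_family,
                    surveyed=n.surveyed,
                    participant_id=n.participant_id,
                    sex=n.sex,
                    age=n.age_years,
                    health=n.health,
                    effort=n.effort,
                    perceived_health=n.perceived_health,
                    perceived_effort=n.perceived_effort,
                    reporter_count=n.reporter_count,
                    resolution_source=n.resolution_source,
                )
            )
        return pd.DataFrame(rows)


@dataclass
class FusedEdge:
    a: str
    b: str
    interact_freq: float
    closeness: float
    eat_freq: float
    importance_ab: float  # a (source) -> b (target)
    importance_ba: float
    reporter_count: int
    category: str = "other"
    direction_subtype: str = "same"  # for a->b view: older_to_younger / younger_to_older / same


@dataclass
class HouseholdNetwork:
    registry: NodeRegistry
    edges: list[FusedEdge] = field(default_factory=list)

    @property
    def household_id(self) -> str:
        return self.registry.household_id

    def edge_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                dict(
                    household_id=self.household_id,
                    a=e.a, b=e.b, category=e.category,
                    direction_subtype=e.direction_subtype,
                    interact_freq=e.interact_freq, closeness=e.closeness,
                    eat_freq=e.eat_freq, importance_ab=e.importance_ab,
                    importance_ba=e.importance_ba, reporter_count=e.reporter_count,
                )
                for e in self.edges
            ]
        )

    def to_networkx(self) -> nx.Graph:
        G = nx.Graph()
        for nid, n in self.registry.nodes.items():
            G.add_node(
                nid, relation=n.relation.label, surveyed=n.surveyed,
                sex=n.sex or "", age=n.age_years if n.age_years is not None else "",
                health=n.health if n.health is not None else "",
                effort=n.effort if n.effort is not None else "",
            )
        for e in self.edges:
            G.add_edge(
                e.a, e.b, category=e.category, interact_freq=e.interact_freq,
                closeness=e.closeness, eat_freq=e.eat_freq,
                importance_ab=e.importance_ab, importance_ba=e.importance_ba,
                importance=(e.importance_ab + e.importance_ba) / 2.0,
                reporter_count=e.reporter_count,
            )
        return G

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.to_networkx(), path)


# ---------------------------------------------------------------------------
# node fusion

def _sex_compatible(a: Optional[str], b: Optional[str]) -> bool:
    return a is None or b is None or a == b


def _age_compatible(a: Optional[float], b: Optional[float], tol: float) -> bool:
    return a is None or b is None or abs(a - b) <= tol


def _normalize_label(label: str) -> str:
    return " ".join(label.lower().split())


def _overrides_map(survey: HouseholdSurvey) -> dict[str, str]:
    if survey.overrides is None or len(survey.overrides) == 0:
        return {}
    out: dict[str, str] = {}
    for _, row in survey.overrides.iterrows():
        key = f"{row['reporter_id']}::{row['alter_label']}"
        if key in out and out[key] != row["resolved_label"]:
            raise kinship.KinshipError(
                f"conflicting overrides for {key!r}: "
                f"{out[key]!r} vs {row['resolved_label']!r}"
            )
        out[key] = row["resolved_label"]
    return out


def deduplicate_nodes(
    survey: HouseholdSurvey, age_tolerance: float = 5.0
) -> tuple[NodeRegistry, dict]:
    """Build the fused node registry for one household.

    Returns ``(registry, ref_map)`` where ``ref_map`` maps
    ``(reporter_id, person_ref)`` -- a participant_id or one of the
    reporter's alter labels -- to the fused node_id, for edge consolidation.
    """
    hh = survey.household_id
    registry = NodeRegistry(household_id=hh)
    overrides = _overrides_map(survey)
    ref_map: dict[tuple[str, str], str] = {}
    counters: dict[str, int] = {}

    def new_node_id(label: str, friend_label: Optional[str] = None) -> str:
        if friend_label is not None:
            return f"{hh}:{label}:{friend_label}"
        counters[label] = counters.get(label, 0) + 1
        k = counters[label]
        return f"{hh}:{label}" if k == 1 else f"{hh}:{label}#{k}"

    # --- surveyed participants become nodes first
    reporter_rel: dict[str, CanonicalRelation] = {}
    for p in sorted(survey.participants, key=lambda q: q.participant_id):
        if p.is_index:
            rel = CanonicalRelation.from_label("ego", sex=p.sex)
        else:
            rel = parse_relation_label(p.relation_to_index, "family", sex=p.sex)
        if rel.label in _SINGLETON_SLOTS | {"spouse_partner"}:
            clash = [
                n for n in registry.nodes.values()
                if n.surveyed and n.relation.label == rel.label
            ]
            if clash:
                raise IntegrityError(
                    f"household {hh!r}: participants {clash[0].participant_id!r} and "
                    f"{p.participant_id!r} both resolve to kin slot {rel.label!r}"
                )
        age = p.age if p.age is not None else BAND_MIDPOINTS.get(p.age_band)
        node = Node(
            node_id=new_node_id(rel.label),
            relation=rel,
            surveyed=True,
            participant_id=p.participant_id,
            sex=p.sex,
            age=age,
            self_health=float(p.self_health),
            self_effort=float(p.self_effort),
        )
        registry.nodes[node.node_id] = node
        reporter_rel[p.participant_id] = rel
    pid_to_node = {
        n.participant_id: n.node_id for n in registry.nodes.values() if n.surveyed
    }
    for rid in reporter_rel:
        for pid, nid in pid_to_node.items():
            ref_map[(rid, pid)] = nid

    # --- canonicalize every alter: two passes so unique resolutions can
    #     anchor cross-reporter matching of ambiguous ones
    alters = sorted(survey.alters, key=lambda a: (a.reporter_id, a.alter_label))
    parsed = []
    for a in alters:
        rep_rel = reporter_rel.get(a.reporter_id)
        if rep_rel is None:
            raise kinship.KinshipError(f"unknown reporter {a.reporter_id!r}")
        reported = parse_relation_label(a.alter_label, a.relation_class, sex=a.sex)
        cands = compose_relations(rep_rel, reported)
        parsed.append((a, cands))

    context = [
        ResolvedNodeContext(relation=n.relation, sex=n.sex, age=n.age)
        for n in registry.nodes.values()
    ]
    for a, cands in parsed:
        if not cands.ambiguous:
            rel = next(iter(cands.candidates))
            if rel.is_family:
                context.append(
                    ResolvedNodeContext(relation=rel, sex=a.sex, age=a.age_approx)
                )

    resolved: list[tuple] = []
    for a, cands in parsed:
        key = f"{a.reporter_id}::{a.alter_label}"
        rel, source = resolve_candidates(
            cands,
            alter_sex=a.sex,
            alter_age=a.age_approx,
            registry_context=context,
            overrides=overrides,
            override_key=key,
            age_tolerance=age_tolerance,
        )
        if source == "unresolved" and cands.ambiguous:
            registry.warnings.append(
                f"unresolved ambiguous relation for {key!r}: "
                f"{sorted(c.label for c in cands.candidates)} -> other"
            )
        resolved.append((a, rel, source))

    # --- merge alters into nodes
    for a, rel, source in resolved:
        label = rel.label
        target: Optional[Node] = None
        if label == "ego":
            target = registry.nodes[pid_to_node[survey.index_participant.participant_id]]
        elif label in ("friend", "other"):
            norm = _normalize_label(a.alter_label)
            for n in registry.nodes.values():
                if n.relation.label == label and n.node_id.endswith(f":{norm}"):
                    target = n
                    break
            if target is None:
                target = Node(
                    node_id=new_node_id(label, friend_label=norm),
                    relation=rel, surveyed=False, participant_id=None,
                    sex=a.sex, age=None, resolution_source=source,
                )
                registry.nodes[target.node_id] = target
        else:
            candidates = [
                n for n in registry.nodes.values() if n.relation.label == label
            ]
            if label in _SINGLETON_SLOTS:
                target = candidates[0] if candidates else None
            else:
                for n in candidates:
                    if _sex_compatible(n.sex, a.sex) and _age_compatible(
                        n.age_years, a.age_approx, age_tolerance
                    ):
                        target = n
                        break
            if target is None:
                target = Node(
                    node_id=new_node_id(label),
                    relation=rel, surveyed=False, participant_id=None,
                    sex=a.sex, age=None, resolution_source=source,
                )
                registry.nodes[target.node_id] = target

        target.reporters.add(a.reporter_id)
        if not target.surveyed:
            if a.perceived_health is not None:
                target.perceived_health_vals.append(a.perceived_health)
            if a.perceived_effort is not None:
                target.perceived_effort_vals.append(a.perceived_effort)
            if a.age_approx is not None:
                target.age_vals.append(a.age_approx)
            if target.sex is None:
                target.sex = a.sex
        else:
            if a.perceived_health is not None:
                target.perceived_health_vals.append(a.perceived_health)
            if a.perceived_effort is not None:
                target.perceived_effort_vals.append(a.perceived_effort)
        ref_map[(a.reporter_id, a.alter_label)] = target.node_id

    # reporters implicitly report themselves
    for p in survey.participants:
        nid = pid_to_node[p.participant_id]
        registry.nodes[nid].reporters.add(p.participant_id)

    return registry, ref_map


# ---------------------------------------------------------------------------
# edge consolidation

def consolidate_edges(
    survey: HouseholdSurvey, registry: NodeRegistry, ref_map: dict
) -> list[FusedEdge]:
    """Average all reporters' ratings for each unordered node pair.

    Symmetric ratings (interaction, closeness, eating) are averaged
    directly; the two directed importance ratings are oriented to the
    canonical (a, b) node ordering before averaging, so "a's importance in
    b's health" is always pooled with itself across reporters.
    """
    acc: dict[tuple[str, str], dict] = {}
    for r in survey.ratings:
        key_a = (r.reporter_id, r.person_a)
        key_b = (r.reporter_id, r.person_b)
        if key_a not in ref_map or key_b not in ref_map:
            missing = r.person_a if key_a not in ref_map else r.person_b
            raise kinship.KinshipError(
                f"rating references unknown person {missing!r} "
                f"for reporter {r.reporter_id!r}"
            )
        na, nb = ref_map[key_a], ref_map[key_b]
        if na == nb:
            # two refs fused to one person (e.g. rating with a duplicate); skip
            registry.warnings.append(
                f"self-loop after fusion for reporter {r.reporter_id!r}: "
                f"{r.person_a!r} ~ {r.person_b!r}"
            )
            continue
        a, b = (na, nb) if na <= nb else (nb, na)
        imp_ab, imp_ba = (
            (r.importance_a_in_b, r.importance_b_in_a)
            if (na, nb) == (a, b)
            else (r.importance_b_in_a, r.importance_a_in_b)
        )
        slot = acc.setdefault(
            (a, b),
            dict(interact=[], close=[], eat=[], iab=[], iba=[], reporters=set()),
        )
        slot["interact"].append(r.interact_freq)
        slot["close"].append(r.closeness)
        slot["eat"].append(r.eat_freq)
        slot["iab"].append(imp_ab)
        slot["iba"].append(imp_ba)
        slot["reporters"].add(r.reporter_id)

    edges = []
    for (a, b), s in sorted(acc.items()):
        edges.append(
            FusedEdge(
                a=a, b=b,
                interact_freq=float(np.mean(s["interact"])),
                closeness=float(np.mean(s["close"])),
                eat_freq=float(np.mean(s["eat"])),
                importance_ab=float(np.mean(s["iab"])),
                importance_ba=float(np.mean(s["iba"])),
                reporter_count=len(s["reporters"]),
            )
        )
    return edges


# ---------------------------------------------------------------------------
# tie classification

def is_spousal_pair(na: Node, nb: Node) -> bool:
    """Whether two nodes occupy a couple slot (label-driven spouse detection)."""
    pair = frozenset({na.relation.label, nb.relation.label})
    return pair in _SPOUSAL_PAIRS or (
        na.relation.label == nb.relation.label
        and na.relation.label in _SPOUSAL_SAME_LABEL
        and na.sex is not None
        and nb.sex is not None
        and na.sex != nb.sex
    )


def classify_edge(edge: FusedEdge, registry: NodeRegistry) -> tuple[str, str]:
    """Classify a fused tie; precedence spouse/partner > friend > generational.

    Any non-family endpoint makes the tie a friend tie; unresolved ("other")
    endpoints make it "other" (kept, never silently dropped).  Family ties
    crossing at least one generation are intergenerational, with a direction
    subtype for the stored a->b view; same-generation family ties are
    intragenerational.
    """
    na, nb = registry.nodes[edge.a], registry.nodes[edge.b]
    ra, rb = na.relation, nb.relation

    if is_spousal_pair(na, nb):
        return "spouse_partner", "same"
    if "friend" in (ra.label, rb.label):
        return "friend", "same"
    if ra.generation_offset is None or rb.generation_offset is None:
        return "other", "same"
    delta = ra.generation_offset - rb.generation_offset
    if delta == 0:
        return "intragenerational", "same"
    return "intergenerational", ("older_to_younger" if delta > 0 else "younger_to_older")


# ---------------------------------------------------------------------------
# orchestration

def fuse_household(
    survey: HouseholdSurvey, age_tolerance: float = 5.0
) -> HouseholdNetwork:
    registry, ref_map = deduplicate_nodes(survey, age_tolerance=age_tolerance)
    edges = consolidate_edges(survey, registry, ref_map)
    for e in edges:
        e.category, e.direction_subtype = classify_edge(e, registry)
    net = HouseholdNetwork(registry=registry, edges=edges)
    if registry.warnings:
        _warnings.warn(
            f"household {survey.household_id}: {len(registry.warnings)} fusion warning(s)"
        )
    return net


def fuse_cohort(
    surveys: Sequence[HouseholdSurvey], age_tolerance: float = 5.0
) -> list[HouseholdNetwork]:
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        return [fuse_household(s, age_tolerance=age_tolerance) for s in surveys]


# ---------------------------------------------------------------------------
# directed expansion for dyadic modelling

def _node_covs(n: Node, prefix: str) -> dict:
    return {
        f"{prefix}_node": n.node_id,
        f"{prefix}_age": n.age_years,
        f"{prefix}_age_band": band_age(n.age_years) if n.age_years is not None else None,
        f"{prefix}_sex": n.sex,
        f"{prefix}_health": n.health,
        f"{prefix}_effort": n.effort,
        f"{prefix}_surveyed": n.surveyed,
        f"{prefix}_participant_id": n.participant_id,
    }


def build_directed_records(network: HouseholdNetwork) -> pd.DataFrame:
    """Expand each fused tie into its two directed source->target records.

    The outcome of a record is the source node's rated importance in the
    target node's health.  Intergenerational direction is re-oriented per
    record: ``category_directed`` distinguishes ties whose target is in an
    older vs a younger generation than the source.  Records with missing
    covariates are kept; models apply listwise deletion themselves.
    """
    rows = []
    reg = network.registry
    for e in network.edges:
        na, nb = reg.nodes[e.a], reg.nodes[e.b]
        for src, tgt, outcome in ((na, nb, e.importance_ab), (nb, na, e.importance_ba)):
            if e.category == "intergenerational":
                delta = src.relation.generation_offset - tgt.relation.generation_offset
                cat_dir = (
                    "intergenerational_target_younger"
                    if delta > 0
                    else "intergenerational_target_older"
                )
            else:
                cat_dir = e.category
            row = dict(
                household_id=network.household_id,
                edge=(e.a, e.b),
                outcome=outcome,
                interact_freq=e.interact_freq,
                closeness=e.closeness,
                eat_freq=e.eat_freq,
                category=e.category,
                category_directed=cat_dir,
                reporter_count=e.reporter_count,
            )
            row.update(_node_covs(src, "source"))
            row.update(_node_covs(tgt, "target"))
            rows.append(row)
    df = pd.DataFrame(rows)
    if len(df):
        df["both_surveyed"] = df["source_surveyed"] & df["target_surveyed"]
    return df
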