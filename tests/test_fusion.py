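"""Node fusion, edge consolidation, tie classification, directed expansion."""

import numpy as np
import pandas as pd
import pytest

from kinnet import fusion
from kinnet.fusion import (
    CATEGORIES,
    FusedEdge,
    Node,
    NodeRegistry,
    build_directed_records,
    classify_edge,
    fuse_cohort,
    fuse_household,
)
from kinnet.kinship import CanonicalRelation
from kinnet.survey_io import (
    AlterRecord,
    DyadRatingRow,
    HouseholdSurvey,
    ParticipantRecord,
)
from kinnet.synthetic import _REL_LABEL, GeneratorConfig, generate_cohort


def make_participant(pid, hh, relation="ego", sex="m", age=30, **kw):
    defaults = dict(
        participant_id=pid, household_id=hh, is_index=relation == "ego",
        relation_to_index=relation, age=float(age), sex=sex,
        age_band="19-39" if age < 40 else ("40-59" if age < 60 else "60+"),
        race="chinese", income="4k_8k", housing="hdb_4room", bmi=22.0,
        marital_status="single", self_health=7, self_effort=6,
        hi_items=(7, 7, 7, 7), vc_items=(7, 7, 7, 7),
        diet_freq={"vegetables": 3, "fruits": 3, "snacks": 2, "fast_food": 1},
    )
    defaults.update(kw)
    return ParticipantRecord(**defaults)


def make_alter(reporter, label, cls="family", sex="m", age=55.0, health=7, effort=6):
    return AlterRecord(reporter, label, cls, sex, age, health, effort)


def rate(reporter, a, b, **kw):
    vals = dict(interact_freq=5, closeness=5, eat_freq=5,
                importance_a_in_b=5, importance_b_in_a=5)
    vals.update(kw)
    return DyadRatingRow(reporter, a, b, **vals)


@pytest.fixture
def triple_reporter_survey():
    """Index + mother + paternal grandmother; father named three ways."""
    participants = [
        make_participant("P0", "H", "ego", sex="m", age=28),
        make_participant("P1", "H", "mother", sex="f", age=53),
        make_participant("P2", "H", "grandmother", sex="f", age=80),
    ]
    alters = [
        make_alter("P0", "father", sex="m", age=58.0, health=6),
        make_alter("P1", "husband", sex="m", age=58.0, health=8),
        make_alter("P2", "son", sex="m", age=58.0, health=7),
        make_alter("P0", "mother", sex="f", age=53.0),
        make_alter("P1", "mother-in-law", sex="f", age=80.0),
        make_alter("P2", "daughter-in-law", sex="f", age=53.0),
    ]
    ratings = [
        rate("P0", "P0", "father", eat_freq=6),
        rate("P1", "P1", "husband", eat_freq=8),
        rate("P0", "father", "mother", closeness=7),
        rate("P2", "son", "daughter-in-law", closeness=9),
    ]
    return HouseholdSurvey("H", participants, alters, ratings)


class TestNodeFusion:
    def test_father_husband_son_fuse_to_one_node(self, triple_reporter_survey):
        net = fuse_household(triple_reporter_survey)
        fathers = [
            n for n in net.registry.nodes.values() if n.relation.label == "father"
        ]
        assert len(fathers) == 1
        assert fathers[0].reporter_count == 3
        assert not fathers[0].surveyed
        # perceived health {6, 8, 7} averages to 7
        assert fathers[0].perceived_health == pytest.approx(7.0)

    def test_no_overlap_single_reporter(self):
        participants = [
            make_participant("P0", "H", "ego"),
            make_participant("P1", "H", "mother", sex="f", age=55),
        ]
        alters = [
            make_alter("P0", "uncle", age=50.0),
            make_alter("P0", "cousin", sex="f", age=25.0),
            make_alter("P0", "pal Z", cls="friend", sex="m", age=29.0),
            make_alter("P1", "sister", sex="f", age=50.0),
            make_alter("P1", "colleague Q", cls="friend", sex="f", age=52.0),
        ]
        survey = HouseholdSurvey("H", participants, alters, [
            rate("P0", "P0", "uncle"), rate("P1", "P1", "sister"),
        ])
        net = fuse_household(survey)
        # 2 surveyed + 5 distinct alters
        assert len(net.registry.nodes) == 7

    def test_surveyed_attributes_take_precedence(self, triple_reporter_survey):
        net = fuse_household(triple_reporter_survey)
        mothers = [
            n for n in net.registry.nodes.values() if n.relation.label == "mother"
        ]
        assert len(mothers) == 1
        assert mothers[0].surveyed
        assert mothers[0].health == 7  # self-report, not the perceptions
        assert mothers[0].reporter_count == 3

    def test_same_slot_integrity_error(self):
        participants = [
            make_participant("P0", "H", "ego"),
            make_participant("P1", "H", "mother", sex="f", age=53),
            make_participant("P2", "H", "mum", sex="f", age=50),
        ]
        with pytest.raises(fusion.IntegrityError):
            fuse_household(HouseholdSurvey("H", participants, [
                make_alter("P0", "mother", sex="f", age=53.0),
                make_alter("P0", "father", sex="m", age=56.0),
                make_alter("P1", "husband", sex="m", age=56.0),
                make_alter("P2", "husband", sex="m", age=56.0),
            ], []))

    def test_distinct_siblings_stay_distinct(self):
        participants = [
            make_participant("P0", "H", "ego"),
            make_participant("P1", "H", "mother", sex="f", age=53),
        ]
        alters = [
            make_alter("P0", "older brother", sex="m", age=36.0),
            make_alter("P0", "younger brother", sex="m", age=22.0),
            make_alter("P1", "husband", sex="m", age=56.0),
        ]
        net = fuse_household(HouseholdSurvey("H", participants, alters, []))
        sibs = [n for n in net.registry.nodes.values() if n.relation.label == "sibling"]
        assert len(sibs) == 2

    def test_friends_merge_only_on_exact_label(self):
        participants = [
            make_participant("P0", "H", "ego"),
            make_participant("P1", "H", "sister", sex="f", age=34),
        ]
        alters = [
            make_alter("P0", "Jane W", cls="friend", sex="f", age=29.0),
            make_alter("P0", "father", sex="m", age=60.0),
            make_alter("P1", "jane  w", cls="friend", sex="f", age=29.0),
            make_alter("P1", "Janet", cls="friend", sex="f", age=30.0),
        ]
        net = fuse_household(HouseholdSurvey("H", participants, alters, []))
        friends = [n for n in net.registry.nodes.values() if n.relation.label == "friend"]
        assert len(friends) == 2  # "jane w" merged across reporters; "Janet" separate


class TestEdges:
    def test_multi_reporter_average(self, triple_reporter_survey):
        net = fuse_household(triple_reporter_survey)
        reg = net.registry.nodes
        fid = next(k for k, n in reg.items() if n.relation.label == "father")
        mid = next(k for k, n in reg.items() if n.relation.label == "mother")
        e = next(e for e in net.edges if {e.a, e.b} == {fid, mid})
        # the spousal tie is rated by the wife herself (5), the index (7)
        # and the grandmother (9): component-wise mean
        assert e.closeness == pytest.approx(7.0)
        assert e.reporter_count == 3

    def test_single_reporter_passthrough(self):
        participants = [
            make_participant("P0", "H", "ego"),
            make_participant("P1", "H", "mother", sex="f", age=53),
        ]
        alters = [
            make_alter("P0", "uncle", age=50.0),
            make_alter("P0", "cousin", sex="f", age=25.0),
            make_alter("P1", "brother-in-law", sex="m", age=50.0),
        ]
        survey = HouseholdSurvey("H", participants, alters, [
            rate("P0", "P0", "uncle", eat_freq=3, importance_a_in_b=2, importance_b_in_a=8),
        ])
        net = fuse_household(survey)
        assert len(net.edges) == 1
        e = net.edges[0]
        assert e.eat_freq == 3 and e.reporter_count == 1
        assert {e.importance_ab, e.importance_ba} == {2, 8}

    def test_importance_orientation_preserved(self):
        """Directed importance pools source->target consistently across
        reporters who listed the pair in opposite orders."""
        participants = [
            make_participant("P0", "H", "ego", sex="m", age=28),
            make_participant("P1", "H", "grandmother", sex="f", age=80),
        ]
        alters = [
            make_alter("P0", "father", sex="m", age=58.0),
            make_alter("P0", "mother", sex="f", age=53.0),
            make_alter("P1", "son", sex="m", age=58.0),
            make_alter("P1", "daughter-in-law", sex="f", age=53.0),
        ]
        ratings = [
            rate("P0", "father", "mother", importance_a_in_b=9, importance_b_in_a=1),
            rate("P1", "daughter-in-law", "son", importance_a_in_b=1, importance_b_in_a=9),
        ]
        net = fuse_household(HouseholdSurvey("H", participants, alters, ratings))
        reg = net.registry.nodes
        fid = next(k for k, n in reg.items() if n.relation.label == "father")
        mid = next(k for k, n in reg.items() if n.relation.label == "mother")
        e = next(e for e in net.edges if {e.a, e.b} == {fid, mid})
        f_to_m = e.importance_ab if e.a == fid else e.importance_ba
        m_to_f = e.importance_ba if e.a == fid else e.importance_ab
        assert f_to_m == pytest.approx(9.0)
        assert m_to_f == pytest.approx(1.0)

    def test_edge_count_equals_distinct_rated_pairs(self, study_cohort, study_networks):
        """Set-cardinality oracle via the generator's true person roster."""
        truth = study_cohort.truth["households"]
        p = study_cohort.participants.set_index("participant_id")
        for net in study_networks:
            hh = net.household_id
            roles = truth[hh]["roles"]
            # rebuild each reporter's label->role map independently
            pid_role = {}
            for role, info in roles.items():
                if info["surveyed"]:
                    match = p[(p.household_id == hh) & (p.age == info["age"]) & (p.sex == info["sex"])]
                    for pid in match.index:
                        if pid not in pid_role.values():
                            pid_role[pid] = role
                            break
            pairs = set()
            ratings = study_cohort.ratings
            for _, row in ratings[ratings.reporter_id.isin(pid_role)].iterrows():
                rep_role = pid_role[row.reporter_id]
                label_role = {}
                for role, info in roles.items():
                    if role.startswith("friend"):
                        continue
                    if role != rep_role and role in _REL_LABEL.get(rep_role, {}):
                        label_role[_REL_LABEL[rep_role][role](info["sex"])] = role

                def to_role(ref):
                    if ref in pid_role:
                        return pid_role[ref]
                    if ref in label_role:
                        return label_role[ref]
                    return f"friendlabel:{ref}"

                pairs.add(frozenset({to_role(row.person_a), to_role(row.person_b)}))
            assert len(net.edges) == len(pairs)


class TestClassification:
    def _net(self):
        reg = NodeRegistry("H")

        def add(label, sex, nid=None):
            rel = CanonicalRelation.from_label(label, sex=sex)
            nid = nid or f"H:{label}"
            reg.nodes[nid] = Node(nid, rel, False, None, sex, 40.0)
            return nid

        return reg, add

    @pytest.mark.parametrize(
        "la,sa,lb,sb,expected",
        [
            ("father", "m", "ego", "m", "intergenerational"),
            ("sibling", "m", "sibling", "f", "intragenerational"),
            ("mother", "f", "father", "m", "spouse_partner"),
            ("ego", "m", "spouse_partner", "f", "spouse_partner"),
            ("grandparent", "f", "grandparent", "m", "spouse_partner"),
            ("grandparent", "f", "grandparent", "f", "intragenerational"),
            ("friend", "m", "father", "m", "friend"),
            ("other", "m", "father", "m", "other"),
            ("grandparent", "f", "child", "m", "intergenerational"),
            ("sibling", "m", "sibling_in_law", "f", "spouse_partner"),
        ],
    )
    def test_categories(self, la, sa, lb, sb, expected):
        reg, add = self._net()
        a = add(la, sa, "H:a")
        b = add(lb, sb, "H:b")
        e = FusedEdge(a, b, 5, 5, 5, 5, 5, 1)
        cat, _ = classify_edge(e, reg)
        assert cat == expected

    def test_direction_subtype(self):
        reg, add = self._net()
        a = add("grandparent", "f", "H:a")
        b = add("ego", "m", "H:b")
        e = FusedEdge(a, b, 5, 5, 5, 5, 5, 1)
        cat, sub = classify_edge(e, reg)
        assert cat == "intergenerational" and sub == "older_to_younger"


class TestDirectedExpansion:
    def test_two_records_per_edge(self, study_networks):
        for net in study_networks:
            records = build_directed_records(net)
            assert len(records) == 2 * len(net.edges)

    def test_swapped_source_target(self, triple_reporter_survey):
        net = fuse_household(triple_reporter_survey)
        records = build_directed_records(net)
        for (a, b), grp in records.groupby("edge"):
            assert set(grp["source_node"]) == {a, b}
            assert set(grp["target_node"]) == {a, b}
            assert (grp["source_node"] != grp["target_node"]).all()

    def test_missing_covariates_kept(self):
        participants = [
            make_participant("P0", "H", "ego"),
            make_participant("P1", "H", "mother", sex="f", age=53),
        ]
        alters = [
            make_alter("P0", "uncle", age=50.0, health=None, effort=None),
            make_alter("P0", "cousin", age=25.0),
            make_alter("P1", "husband", sex="m", age=56.0),
        ]
        survey = HouseholdSurvey("H", participants, alters, [
            rate("P0", "P0", "uncle"),
        ])
        records = build_directed_records(fuse_household(survey))
        assert len(records) == 2
        assert records["source_health"].isna().sum() == 1


class TestInvariants:
    def test_category_partition(self, study_networks):
        for net in study_networks:
            counts = {c: 0 for c in CATEGORIES}
            for e in net.edges:
                counts[e.category] += 1
            assert sum(counts.values()) == len(net.edges)

    def test_node_counts_match_generator_truth(self, study_cohort, study_networks):
        truth = study_cohort.truth["households"]
        for net in study_networks:
            assert len(net.registry.nodes) == truth[net.household_id]["n_unique_persons"]

    def test_merge_commutativity(self, small_cohort):
        """Row order of the input tables does not change the fusion result."""
        surveys = small_cohort.surveys()
        base = fuse_cohort(surveys)
        rng = np.random.default_rng(4)
        p = small_cohort.participants.sample(frac=1, random_state=1).reset_index(drop=True)
        a = small_cohort.alters.sample(frac=1, random_state=2).reset_index(drop=True)
        r = small_cohort.ratings.sample(frac=1, random_state=3).reset_index(drop=True)
        from kinnet.survey_io import frames_to_surveys

        shuffled = fuse_cohort(frames_to_surveys(p, a, r))
        for n1, n2 in zip(base, shuffled):
            f1 = n1.registry.to_frame().sort_values("node_id").reset_index(drop=True)
            f2 = n2.registry.to_frame().sort_values("node_id").reset_index(drop=True)
            pd.testing.assert_frame_equal(f1, f2)
            e1 = n1.edge_frame().sort_values(["a", "b"]).reset_index(drop=True)
            e2 = n2.edge_frame().sort_values(["a", "b"]).reset_index(drop=True)
            pd.testing.assert_frame_equal(e1, e2)
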