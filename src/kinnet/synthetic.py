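"""Synthetic multi-reporter household survey generator with known truth.

Emulates the survey tables the pipeline ingests: households anchored on a
21-35-year-old index adult with 1-3 co-surveyed family members, each
reporter naming 2-10 important people (overlapping across reporters, so
fusion is genuinely exercised -- including the classic pattern where the
index adult's "father" is the mother's "husband" and the paternal
grandmother's "son"), dyadic 0-9 ratings drawn per relationship category,
directed health-importance generated from a linear model with node and
household random intercepts, and diet outcomes drawn from a logistic model
on each participant's network averages.

Every stochastic choice derives from the seed in :class:`GeneratorConfig`;
the emitted tables always pass :mod:`kinnet.survey_io` validation, and a
truth record preserves the generating parameters and the per-household
person roster so tests can check fusion against ground truth.

Ratings are discretized truncated normals on the 0-9 scale with
category-specific means (spouse/partner highest, intergenerational next,
friends lowest).  An opposite-sex bonus on eating-together induces the
negative sex assortativity the cohort analyses look for.

Besides the full cohort generator, two direct simulators
(:func:`simulate_dyad_records`, :func:`simulate_diet_data`) produce
model-ready tables straight from the truth models; parameter-recovery
simulations use these so that hundreds of replicates stay cheap.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .survey_io import DIET_ITEMS, band_age, frames_to_surveys

__all__ = [
    "GeneratorConfig",
    "SimulatedCohort",
    "generate_cohort",
    "inject_ambiguity",
    "example_household",
    "simulate_dyad_records",
    "simulate_diet_data",
]


def _default_category_means():
    # interaction/closeness/eating means by tie category, 0-9 scale
    return {
        "spouse_partner": 7.2,
        "intergenerational": 5.3,
        "intragenerational": 4.5,
        "friend": 2.0,
        "other": 3.0,
    }


def _default_dyad_coefs():
    # truth coefficients for the directed importance model
    return {
        "intercept": 1.0,
        "interact_freq": 0.05,
        "closeness": 0.38,
        "eat_freq": 0.43,
        "spouse_partner": 0.89,
        "intergenerational_target_younger": 0.62,
        "intergenerational_target_older": 0.36,
        "intragenerational": 0.30,
        "source_effort": 0.10,
    }


def _default_diet_coefs():
    # truth log-odds per 1-point increase in a (centered) network average
    return {
        "snacks_low": {"family_avg_health": -1.166, "family_avg_effort": 0.693},
        "fastfood_none": {"family_avg_effort": 0.891, "friends_avg_eat": 0.693},
        "veg_meets": {},
        "fruit_meets": {},
    }


def _default_diet_base_rates():
    return {
        "veg_meets": 0.28,
        "fruit_meets": 0.25,
        "fastfood_none": 0.33,
        "snacks_low": 0.22,
    }


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic cohort, with study-scale defaults."""

    n_households: int = 36
    seed: int = 0
    female_share: float = 0.57
    index_age_range: tuple[int, int] = (21, 35)
    #: probability of 1, 2 or 3 co-surveyed family members
    co_survey_weights: dict = field(default_factory=lambda: {1: 0.3, 2: 0.4, 3: 0.3})
    #: inclusion probabilities of roster kin beyond the parents
    roster_probs: dict = field(
        default_factory=lambda: {
            "sib": 0.6, "gp": 0.5, "aunt": 0.45, "uncle": 0.35,
            "cousin": 0.35, "spouse": 0.5,
        }
    )
    friends_per_reporter: tuple[int, int] = (1, 2)
    #: chance a reporter rates a friend x family pair (self-friend and
    #: own friend-friend pairs are always rated; family pairs always rated)
    friend_family_rating_prob: float = 0.3
    category_rating_means: dict = field(default_factory=_default_category_means)
    rating_sd: float = 1.5
    reporter_noise_sd: float = 0.8
    cross_sex_eat_bonus: float = 1.0
    dyad_coefs: dict = field(default_factory=_default_dyad_coefs)
    node_re_sd: float = 0.5
    household_re_sd: float = 0.3
    dyad_resid_sd: float = 1.5
    diet_coefs: dict = field(default_factory=_default_diet_coefs)
    diet_base_rates: dict = field(default_factory=_default_diet_base_rates)
    diet_household_re_sd: float = 0.3
    missing_perception_rate: float = 0.02
    health_mean: float = 7.1
    health_sd: float = 1.6
    effort_mean: float = 6.6
    effort_sd: float = 1.95
    #: scale items share a per-person latent trait so the four items are
    #: internally consistent (alpha ~0.8) and score medians land near 28
    scale_item_mean: float = 6.9
    scale_latent_sd: float = 1.3
    scale_item_noise_sd: float = 1.1

    def validate(self) -> None:
        for cat, m in self.category_rating_means.items():
            if not 0 <= m <= 9:
                raise ValueError(f"rating mean for {cat!r} out of [0,9]: {m}")
        for p in list(self.roster_probs.values()) + [
            self.female_share, self.missing_perception_rate
        ]:
            if not 0 <= p <= 1:
                raise ValueError(f"probability out of [0,1]: {p}")
        if not abs(sum(self.co_survey_weights.values()) - 1) < 1e-9:
            raise ValueError("co_survey_weights must sum to 1")
        if min(self.co_survey_weights) < 1 or max(self.co_survey_weights) > 3:
            raise ValueError("co-surveyed members per household must be 1-3")


# ---------------------------------------------------------------------------
# person roster and relative labels

#: generation offset of each internal role, relative to the index adult
_ROLE_GEN = {
    "ego": 0, "father": 1, "mother": 1, "sib": 0, "gp": 2,
    "aunt": 1, "uncle": 1, "cousin": 0, "spouse": 0,
}
#: canonical ego-relative relation each role should resolve to after fusion
ROLE_CANONICAL = {
    "ego": "ego", "father": "father", "mother": "mother", "sib": "sibling",
    "gp": "grandparent", "aunt": "aunt_uncle", "uncle": "aunt_uncle",
    "cousin": "cousin", "spouse": "spouse_partner",
}

_SPOUSAL_ROLE_PAIRS = {frozenset({"father", "mother"}), frozenset({"ego", "spouse"})}


def _sexed(m_label: str, f_label: str):
    return lambda sex: m_label if sex == "m" else f_label


# label a reporter of role R gives to a person of role P (None: not listed).
# The roster is fixed-pedigree: gp is the paternal grandmother, aunt is the
# mother's younger sister, uncle the father's younger brother, cousin the
# aunt's child.
_REL_LABEL = {
    "ego": {
        "father": lambda s: "father", "mother": lambda s: "mother",
        "sib": _sexed("brother", "sister"), "gp": lambda s: "grandmother",
        "aunt": lambda s: "auntie", "uncle": lambda s: "uncle",
        "cousin": lambda s: "cousin", "spouse": _sexed("husband", "wife"),
    },
    "mother": {
        "ego": _sexed("son", "daughter"), "sib": _sexed("older son", "older daughter"),
        "father": lambda s: "husband", "gp": lambda s: "mother-in-law",
        "aunt": lambda s: "sister", "uncle": lambda s: "brother-in-law",
        "cousin": _sexed("nephew", "niece"),
        "spouse": _sexed("son-in-law", "daughter-in-law"),
    },
    "father": {
        "ego": _sexed("son", "daughter"), "sib": _sexed("older son", "older daughter"),
        "mother": lambda s: "wife", "gp": lambda s: "mother",
        "aunt": lambda s: "sister-in-law", "uncle": lambda s: "brother",
        "cousin": _sexed("nephew", "niece"),
        "spouse": _sexed("son-in-law", "daughter-in-law"),
    },
    "sib": {
        "father": lambda s: "father", "mother": lambda s: "mother",
        "ego": _sexed("brother", "sister"), "gp": lambda s: "grandmother",
        "aunt": lambda s: "auntie", "uncle": lambda s: "uncle",
        "cousin": lambda s: "cousin",
        "spouse": _sexed("brother-in-law", "sister-in-law"),
    },
    "gp": {
        "father": lambda s: "son", "uncle": lambda s: "younger son",
        "mother": lambda s: "daughter-in-law",
        "ego": _sexed("grandson", "granddaughter"),
        "sib": _sexed("older grandson", "older granddaughter"),
    },
    "spouse": {
        "ego": _sexed("husband", "wife"),
        "father": lambda s: "father-in-law", "mother": lambda s: "mother-in-law",
        "sib": _sexed("brother-in-law", "sister-in-law"),
    },
}


@dataclass
class _Person:
    role: str           # internal pedigree role, or "friend_<reporter>_<k>"
    sex: str
    age: float
    health: int
    effort: int
    surveyed: bool = False
    participant_id: Optional[str] = None
    owner: Optional[str] = None   # reporter role owning a friend node
    label: Optional[str] = None   # friend pseudonym


def _draw_int(rng, mean, sd, lo, hi) -> int:
    return int(np.clip(np.round(rng.normal(mean, sd)), lo, hi))


def _household_roster(cfg: GeneratorConfig, rng, hh_idx: int):
    """Draw one household's people, surveyed set, and reporters' friends."""
    a = float(rng.integers(cfg.index_age_range[0], cfg.index_age_range[1] + 1))
    sex_of = lambda: "f" if rng.random() < cfg.female_share else "m"

    ego_sex = sex_of()
    people = {"ego": _Person("ego", ego_sex, a, 0, 0)}
    father_age = a + 28.0 + float(rng.integers(0, 5))
    people["father"] = _Person("father", "m", father_age, 0, 0)
    people["mother"] = _Person("mother", "f", father_age - 7.0, 0, 0)
    rp = cfg.roster_probs
    if rng.random() < rp["sib"]:
        people["sib"] = _Person("sib", sex_of(), a + 6.0, 0, 0)
    if rng.random() < rp["gp"]:
        people["gp"] = _Person("gp", "f", father_age + 26.0, 0, 0)
    if rng.random() < rp["aunt"]:
        people["aunt"] = _Person("aunt", "f", father_age - 15.0, 0, 0)
    if rng.random() < rp["uncle"]:
        people["uncle"] = _Person("uncle", "m", father_age - 8.0, 0, 0)
    if "aunt" in people and rng.random() < rp["cousin"]:
        people["cousin"] = _Person("cousin", sex_of(), a - 11.0, 0, 0)
    if rng.random() < rp["spouse"]:
        people["spouse"] = _Person(
            "spouse", "m" if ego_sex == "f" else "f", a + 2.0, 0, 0
        )

    for p in people.values():
        p.health = _draw_int(rng, cfg.health_mean, cfg.health_sd, 1, 10)
        p.effort = _draw_int(rng, cfg.effort_mean, cfg.effort_sd, 1, 10)

    # surveyed set: index plus 1-3 adult family members
    ks, ws = zip(*sorted(cfg.co_survey_weights.items()))
    n_co = int(rng.choice(ks, p=np.asarray(ws) / sum(ws)))
    pool, weights = [], []
    for role, w in (
        ("mother", 0.9), ("father", 0.55), ("sib", 0.5), ("gp", 0.35), ("spouse", 0.5)
    ):
        if role in people and role in _REL_LABEL:
            pool.append(role)
            weights.append(w)
    n_co = min(n_co, len(pool))
    probs = np.asarray(weights) / sum(weights)
    co_roles = list(rng.choice(pool, size=n_co, replace=False, p=probs))
    people["ego"].surveyed = True
    for r in co_roles:
        people[r].surveyed = True

    # friends are private to each reporter
    reporters = ["ego"] + sorted(co_roles)
    lo, hi = cfg.friends_per_reporter
    for rep in reporters:
        kin_count = sum(
            1 for role in people
            if role != rep and not role.startswith("friend") and role in _REL_LABEL[rep]
        )
        nf = min(int(rng.integers(lo, hi + 1)), 10 - kin_count)
        for k in range(nf):
            fsex = sex_of()
            name = f"friend {rep[:2]}{hh_idx:02d}{k}"
            key = f"friend_{rep}_{k}"
            people[key] = _Person(
                role=key, sex=fsex,
                age=people[rep].age + float(rng.integers(-5, 6)),
                health=_draw_int(rng, cfg.health_mean, cfg.health_sd, 1, 10),
                effort=_draw_int(rng, cfg.effort_mean, cfg.effort_sd, 1, 10),
                owner=rep, label=name,
            )
    return people, reporters


def _true_category(pa: _Person, pb: _Person) -> str:
    ra, rb = pa.role, pb.role
    if ra.startswith("friend") or rb.startswith("friend"):
        return "friend"
    if frozenset({ra, rb}) in _SPOUSAL_ROLE_PAIRS:
        return "spouse_partner"
    return (
        "intergenerational"
        if _ROLE_GEN[ra] != _ROLE_GEN[rb]
        else "intragenerational"
    )


def _alter_list(reporter: str, people: dict) -> list[str]:
    """Roles the reporter names as important people (excluding self)."""
    out = []
    table = _REL_LABEL[reporter]
    for role, p in people.items():
        if role == reporter:
            continue
        if role.startswith("friend"):
            if p.owner == reporter:
                out.append(role)
        elif role in table:
            out.append(role)
    return out


# ---------------------------------------------------------------------------
# cohort generation

@dataclass
class SimulatedCohort:
    participants: pd.DataFrame
    alters: pd.DataFrame
    ratings: pd.DataFrame
    truth: dict

    def surveys(self):
        """Validated HouseholdSurvey bundles (runs full io validation)."""
        return frames_to_surveys(self.participants, self.alters, self.ratings)

    def write(self, out_dir) -> dict:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name in ("participants", "alters", "ratings"):
            paths[name] = out_dir / f"{name}.csv"
            getattr(self, name).to_csv(paths[name], index=False)
        paths["truth"] = out_dir / "truth.json"
        with open(paths["truth"], "w") as fh:
            json.dump(self.truth, fh, indent=1, sort_keys=True, default=str)
        return paths


_RACES = (("chinese", 0.767), ("malay", 0.1), ("indian", 0.09), ("other", 0.043))
_INCOMES = ("under_4k", "4k_8k", "8k_12k", "over_12k")
_HOUSING = ("hdb_3room", "hdb_4room", "hdb_5room", "private")


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


def generate_cohort(config: Optional[GeneratorConfig] = None, out_dir=None) -> SimulatedCohort:
    """Generate the three survey tables plus the generating truth.

    Deterministic in ``config.seed``.  If ``out_dir`` is given the tables and
    ``truth.json`` are written there as well.
    """
    cfg = config or GeneratorConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    prows, arows, rrows = [], [], []
    truth_households = {}

    for h in range(cfg.n_households):
        hh = f"H{h:03d}"
        people, reporters = _household_roster(cfg, rng, h)

        # assign participant ids to surveyed people
        for i, rep in enumerate(reporters):
            people[rep].participant_id = f"{hh}P{i}"

        # --- true symmetric rating values per within-household pair
        roles = sorted(people)
        true_edge: dict[tuple[str, str], dict] = {}

        def eat_mean(pa, pb, cat):
            m = cfg.category_rating_means[cat]
            bonus = cfg.cross_sex_eat_bonus
            return m + (0.5 * bonus if pa.sex != pb.sex else -0.5 * bonus)

        for i, ra in enumerate(roles):
            for rb in roles[i + 1:]:
                pa, pb = people[ra], people[rb]
                cat = _true_category(pa, pb)
                m = cfg.category_rating_means[cat]
                sd = cfg.rating_sd
                true_edge[(ra, rb)] = dict(
                    category=cat,
                    interact=float(np.clip(rng.normal(m, sd), 0, 9)),
                    close=float(np.clip(rng.normal(m, sd), 0, 9)),
                    eat=float(np.clip(rng.normal(eat_mean(pa, pb, cat), sd), 0, 9)),
                )

        # --- true directed importance: linear model + random intercepts
        u = {r: rng.normal(0, cfg.node_re_sd) for r in roles}
        w_hh = rng.normal(0, cfg.household_re_sd)
        coefs = cfg.dyad_coefs
        means = cfg.category_rating_means

        def importance(src_role, tgt_role, e):
            cat = e["category"]
            if cat == "intergenerational":
                cat_key = (
                    "intergenerational_target_younger"
                    if _ROLE_GEN[src_role] > _ROLE_GEN[tgt_role]
                    else "intergenerational_target_older"
                )
            else:
                cat_key = cat
            # ratings centered at the scale midpoint (not per category) so
            # the adjusted category coefficients equal the configured truth
            lp = (
                coefs.get("intercept", 0.0)
                + coefs.get("interact_freq", 0.0) * (e["interact"] - 4.5)
                + coefs.get("closeness", 0.0) * (e["close"] - 4.5)
                + coefs.get("eat_freq", 0.0) * (e["eat"] - 4.5)
                + coefs.get(cat_key, 0.0)
                + coefs.get("source_effort", 0.0) * (people[src_role].effort - 5.0)
                + 3.0  # anchor keeping the linear predictor mid-scale
                + u[src_role] + u[tgt_role] + w_hh
                + rng.normal(0, cfg.dyad_resid_sd)
            )
            return float(np.clip(lp, 0, 9))

        for (ra, rb), e in true_edge.items():
            e["imp_ab"] = importance(ra, rb, e)
            e["imp_ba"] = importance(rb, ra, e)

        # --- per-reporter survey rows
        def ref_of(reporter, role):
            p = people[role]
            if role == reporter:
                return p.participant_id
            if role.startswith("friend"):
                return p.label
            return _REL_LABEL[reporter][role](p.sex)

        for rep in reporters:
            rep_p = people[rep]
            alters = _alter_list(rep, people)
            for role in alters:
                p = people[role]
                missing = rng.random(2) < cfg.missing_perception_rate
                arows.append(
                    dict(
                        reporter_id=rep_p.participant_id,
                        alter_label=ref_of(rep, role),
                        relation_class="friend" if role.startswith("friend") else "family",
                        sex=p.sex,
                        age_approx=p.age,
                        perceived_health=(
                            np.nan if missing[0]
                            else _draw_int(rng, p.health, cfg.reporter_noise_sd, 1, 10)
                        ),
                        perceived_effort=(
                            np.nan if missing[1]
                            else _draw_int(rng, p.effort, cfg.reporter_noise_sd, 1, 10)
                        ),
                    )
                )
            # ratings: all family pairs, all self-friend and own friend-friend
            # pairs, and a fraction of friend x family pairs
            circle = [rep] + alters
            for i, ra in enumerate(circle):
                for rb in circle[i + 1:]:
                    fa, fb = ra.startswith("friend"), rb.startswith("friend")
                    if (fa != fb) and rep not in (ra, rb):
                        if rng.random() >= cfg.friend_family_rating_prob:
                            continue
                    key = (ra, rb) if (ra, rb) in true_edge else (rb, ra)
                    e = true_edge[key]
                    flip = key != (ra, rb)
                    iab = e["imp_ba"] if flip else e["imp_ab"]
                    iba = e["imp_ab"] if flip else e["imp_ba"]
                    noise = cfg.reporter_noise_sd
                    rrows.append(
                        dict(
                            reporter_id=rep_p.participant_id,
                            person_a=ref_of(rep, ra),
                            person_b=ref_of(rep, rb),
                            interact_freq=_draw_int(rng, e["interact"], noise, 0, 9),
                            closeness=_draw_int(rng, e["close"], noise, 0, 9),
                            eat_freq=_draw_int(rng, e["eat"], noise, 0, 9),
                            importance_a_in_b=_draw_int(rng, iab, noise, 0, 9),
                            importance_b_in_a=_draw_int(rng, iba, noise, 0, 9),
                        )
                    )

        # --- participant rows: demographics, scales, diet
        races, race_p = zip(*_RACES)
        diet_hh_re = rng.normal(0, cfg.diet_household_re_sd)
        for i, rep in enumerate(reporters):
            p = people[rep]
            # network averages over the reporter's own circle, by true scope
            alters = [people[r] for r in _alter_list(rep, people)]
            scopes = {
                "full": alters,
                "family": [
                    q for q in alters
                    if not q.role.startswith("friend")
                    and frozenset({rep, q.role}) not in _SPOUSAL_ROLE_PAIRS
                ],
                "friends": [q for q in alters if q.role.startswith("friend")],
            }
            avg = {}
            for sc, mem in scopes.items():
                avg[f"{sc}_avg_health"] = (
                    float(np.mean([q.health for q in mem])) if mem else np.nan
                )
                avg[f"{sc}_avg_effort"] = (
                    float(np.mean([q.effort for q in mem])) if mem else np.nan
                )
                eats = []
                for q in mem:
                    key = (rep, q.role) if (rep, q.role) in true_edge else (q.role, rep)
                    eats.append(true_edge[key]["eat"])
                avg[f"{sc}_avg_eat"] = float(np.mean(eats)) if eats else np.nan

            flags = {}
            for outcome, terms in cfg.diet_coefs.items():
                base = cfg.diet_base_rates[outcome]
                lp = np.log(base / (1 - base)) + diet_hh_re
                for term, beta in terms.items():
                    x = avg.get(term)
                    if x is None or np.isnan(x):
                        continue
                    center = (
                        cfg.effort_mean if "effort" in term
                        else cfg.health_mean if "health" in term
                        else 4.5
                    )
                    lp += beta * (x - center)
                flags[outcome] = bool(rng.random() < _logistic(lp))

            diet_levels = {
                "vegetables": int(rng.integers(4, 7) if flags["veg_meets"] else rng.integers(0, 4)),
                "fruits": int(rng.integers(3, 7) if flags["fruit_meets"] else rng.integers(0, 3)),
                "fast_food": int(0 if flags["fastfood_none"] else rng.integers(1, 4)),
                "snacks": int(rng.integers(0, 2) if flags["snacks_low"] else rng.integers(2, 6)),
            }
            row = dict(
                participant_id=p.participant_id,
                household_id=hh,
                is_index=rep == "ego",
                relation_to_index=(
                    "ego" if rep == "ego"
                    else _REL_LABEL["ego"][rep](p.sex)
                ),
                age=p.age,
                age_band=band_age(p.age),
                sex=p.sex,
                race=str(rng.choice(races, p=race_p)),
                income=str(rng.choice(_INCOMES)),
                housing=str(rng.choice(_HOUSING)),
                bmi=float(np.round(rng.normal(22.5, 3.5), 1)),
                marital_status="married" if rep in ("mother", "father", "gp") else "single",
                self_health=p.health,
                self_effort=p.effort,
            )
            hi_latent = rng.normal(cfg.scale_item_mean, cfg.scale_latent_sd)
            vc_latent = rng.normal(cfg.scale_item_mean, cfg.scale_latent_sd)
            for k in range(1, 5):
                row[f"hi_{k}"] = _draw_int(rng, hi_latent, cfg.scale_item_noise_sd, 1, 9)
                row[f"vc_{k}"] = _draw_int(rng, vc_latent, cfg.scale_item_noise_sd, 1, 9)
            for item in DIET_ITEMS:
                row[f"diet_{item}"] = diet_levels[item]
            prows.append(row)

        truth_households[hh] = {
            "n_unique_persons": len(people),
            "reporters": [people[r].participant_id for r in reporters],
            "roles": {
                r: dict(
                    sex=p.sex, age=p.age, surveyed=p.surveyed,
                    health=p.health, effort=p.effort,
                    canonical=ROLE_CANONICAL.get(r, "friend"),
                )
                for r, p in people.items()
            },
        }

    cohort = SimulatedCohort(
        participants=pd.DataFrame(prows),
        alters=pd.DataFrame(arows),
        ratings=pd.DataFrame(rrows),
        truth={
            "config": dataclasses.asdict(cfg),
            "households": truth_households,
        },
    )
    if out_dir is not None:
        cohort.write(out_dir)
    return cohort


# ---------------------------------------------------------------------------
# ambiguity injection

#: label degradations that widen the candidate set (truth preserved in key)
_AMBIGUOUS_FORMS = {"husband": "spouse", "wife": "spouse"}


def inject_ambiguity(cohort: SimulatedCohort, rate: float, seed: int = 0):
    """Replace a fraction of eligible alter labels with ambiguous forms.

    Eligible labels are spouse terms whose sex qualifier pins the candidate
    ("husband" -> "spouse" with the sex field cleared widens {father} to
    {father, mother}).  Returns ``(new_cohort, key)`` where ``key`` lists,
    per degraded row, the reporter, the old and new label, and the expected
    resolved canonical relation, for testing the resolution machinery.
    """
    if not 0 <= rate <= 1:
        raise ValueError("rate must be in [0,1]")
    rng = np.random.default_rng(seed)
    alters = cohort.alters.copy()
    ratings = cohort.ratings.copy()
    key = []
    pid_hh = cohort.participants.set_index("participant_id")["household_id"].to_dict()
    for i in alters.index:
        lab = alters.at[i, "alter_label"]
        if lab in _AMBIGUOUS_FORMS and rng.random() < rate:
            new = _AMBIGUOUS_FORMS[lab]
            rep = alters.at[i, "reporter_id"]
            old_sex = alters.at[i, "sex"]
            alters.at[i, "alter_label"] = new
            alters.at[i, "sex"] = np.nan
            m = (ratings["reporter_id"] == rep)
            ratings.loc[m & (ratings["person_a"] == lab), "person_a"] = new
            ratings.loc[m & (ratings["person_b"] == lab), "person_b"] = new
            key.append(
                dict(
                    household_id=pid_hh[rep], reporter_id=rep,
                    old_label=lab, new_label=new, sex=old_sex,
                    expected="father" if old_sex == "m" else "mother",
                )
            )
    return (
        SimulatedCohort(cohort.participants.copy(), alters, ratings, cohort.truth),
        pd.DataFrame(key),
    )


# ---------------------------------------------------------------------------
# hand-built worked example

def example_household() -> SimulatedCohort:
    """The canonical three-reporter fusion fixture.

    The index adult names his "father"; his surveyed mother names her
    "husband"; his surveyed paternal grandmother names her "son".  All
    three rows describe the same man and must fuse to a single father node
    reported by three reporters.
    """
    cfg = GeneratorConfig(
        n_households=1, seed=7,
        co_survey_weights={2: 1.0},
        roster_probs={"sib": 0.0, "gp": 1.0, "aunt": 0.0, "uncle": 0.0,
                      "cousin": 0.0, "spouse": 0.0},
    )
    # resample seeds until exactly mother+grandmother are co-surveyed,
    # leaving the father a three-times-reported alter
    for seed in range(200):
        cfg.seed = seed
        cohort = generate_cohort(cfg)
        roles = cohort.truth["households"]["H000"]["roles"]
        surveyed = {
            r for r, v in roles.items() if v["surveyed"] and not r.startswith("friend")
        }
        if surveyed == {"ego", "mother", "gp"}:
            return cohort
    raise RuntimeError("could not draw the example household")


# ---------------------------------------------------------------------------
# direct simulators for parameter-recovery studies

def simulate_dyad_records(
    n_households: int,
    coefs: Optional[dict] = None,
    rng: Optional[np.random.Generator] = None,
    node_re_sd: float = 0.5,
    household_re_sd: float = 0.3,
    resid_sd: float = 1.5,
    nodes_per_household: int = 8,
    edge_prob: float = 0.55,
    discretize: bool = True,
    category_rating_means: Optional[dict] = None,
    interact_eat_corr: float = 0.0,
) -> pd.DataFrame:
    """Directed dyad records straight from the truth model (no survey layer).

    Households get ``nodes_per_household`` nodes with ages spanning three
    generations, random ties, category-specific ratings, and importance
    outcomes from the linear model with crossed node and household random
    intercepts.  Columns match :func:`kinnet.fusion.build_directed_records`.
    """
    rng = rng or np.random.default_rng(0)
    coefs = coefs if coefs is not None else _default_dyad_coefs()
    means = category_rating_means or _default_category_means()
    gens = [0, 0, 0, 1, 1, 2, None, None]  # None: friend
    rows = []
    for h in range(n_households):
        hh = f"S{h:04d}"
        n = nodes_per_household
        node_gen = [gens[i % len(gens)] for i in range(n)]
        sex = rng.choice(["m", "f"], size=n)
        age = np.where(
            [g == 0 or g is None for g in node_gen],
            rng.integers(21, 36, n),
            np.where([g == 1 for g in node_gen], rng.integers(45, 62, n),
                     rng.integers(65, 85, n)),
        ).astype(float)
        health = np.clip(np.round(rng.normal(7.1, 1.6, n)), 1, 10)
        effort = np.clip(np.round(rng.normal(6.6, 1.95, n)), 1, 10)
        u = rng.normal(0, node_re_sd, n)
        w_hh = rng.normal(0, household_re_sd)
        spouse_pair = (0, 3)  # a generation-0 and generation-1 node form a couple
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() > edge_prob:
                    continue
                gi, gj = node_gen[i], node_gen[j]
                if (i, j) == spouse_pair:
                    cat = "spouse_partner"
                elif gi is None or gj is None:
                    cat = "friend"
                elif gi != gj:
                    cat = "intergenerational"
                else:
                    cat = "intragenerational"
                m = means[cat]
                close = float(np.clip(rng.normal(m, 1.5), 0, 9))
                eat = float(np.clip(rng.normal(m, 1.5), 0, 9))
                # optional mediation structure: interaction tracks eating
                rho = interact_eat_corr
                interact = float(
                    np.clip(
                        m + rho * (eat - m)
                        + np.sqrt(max(0.0, 1 - rho**2)) * rng.normal(0, 1.5),
                        0, 9,
                    )
                )
                for src, tgt in ((i, j), (j, i)):
                    gs, gt = node_gen[src], node_gen[tgt]
                    if cat == "intergenerational":
                        cat_dir = (
                            "intergenerational_target_younger"
                            if gs > gt
                            else "intergenerational_target_older"
                        )
                    else:
                        cat_dir = cat
                    # ratings centered on their category mean: keeps the
                    # linear predictor mid-scale (rare clipping) while the
                    # category dummies absorb the resulting shifts
                    lp = (
                        coefs.get("intercept", 0.0)
                        + coefs.get("interact_freq", 0.0) * (interact - m)
                        + coefs.get("closeness", 0.0) * (close - m)
                        + coefs.get("eat_freq", 0.0) * (eat - m)
                        + coefs.get(cat_dir, 0.0)
                        + coefs.get("source_effort", 0.0) * (effort[src] - 5.0)
                        + 4.5  # mid-scale anchor: keeps 0/9 truncation rare
                        + u[src] + u[tgt] + w_hh
                        + rng.normal(0, resid_sd)
                    )
                    outcome = (
                        float(np.clip(np.round(lp), 0, 9)) if discretize else float(lp)
                    )
                    rows.append(
                        dict(
                            household_id=hh,
                            outcome=outcome,
                            interact_freq=interact,
                            closeness=close,
                            eat_freq=eat,
                            category=cat,
                            category_directed=cat_dir,
                            source_node=f"{hh}:n{src}",
                            source_age=age[src],
                            source_age_band=band_age(age[src]),
                            source_sex=sex[src],
                            source_health=health[src],
                            source_effort=effort[src],
                            source_surveyed=True,
                            source_participant_id=f"{hh}:n{src}",
                            target_node=f"{hh}:n{tgt}",
                            target_age=age[tgt],
                            target_age_band=band_age(age[tgt]),
                            target_sex=sex[tgt],
                            target_health=health[tgt],
                            target_effort=effort[tgt],
                            target_surveyed=True,
                            target_participant_id=f"{hh}:n{tgt}",
                        )
                    )
    df = pd.DataFrame(rows)
    df["both_surveyed"] = True
    return df


def simulate_diet_data(
    n_households: int,
    coefs: Optional[dict] = None,
    rng: Optional[np.random.Generator] = None,
    outcome: str = "snacks_low",
    base_rate: float = 0.3,
    participants_per_household: int = 3,
    household_re_sd: float = 0.3,
) -> pd.DataFrame:
    """Participant table with network averages and one diet flag from truth.

    ``coefs`` maps average columns (e.g. ``family_avg_effort``) to true
    log-odds per unit; averages are drawn around realistic means so the
    intercept keeps the configured base rate.  Adjustment covariates are
    generated with zero true effect.  Output feeds
    :class:`kinnet.models.DietNetworkModel` directly.
    """
    rng = rng or np.random.default_rng(0)
    coefs = coefs or {}
    rows = []
    centers = {"avg_health": 7.1, "avg_effort": 6.6, "avg_eat": 4.5}
    for h in range(n_households):
        hh = f"D{h:04d}"
        w = rng.normal(0, household_re_sd)
        for k in range(participants_per_household):
            row = dict(
                participant_id=f"{hh}P{k}",
                household_id=hh,
                age_band=str(rng.choice(["19-39", "40-59", "60+"], p=[0.6, 0.3, 0.1])),
                sex=str(rng.choice(["m", "f"])),
                race=str(rng.choice(["chinese", "malay", "indian", "other"],
                                    p=[0.767, 0.1, 0.09, 0.043])),
                income=str(rng.choice(_INCOMES)),
                bmi=float(rng.normal(22.5, 3.5)),
                self_health=int(np.clip(np.round(rng.normal(7.1, 1.6)), 1, 10)),
                self_effort=int(np.clip(np.round(rng.normal(6.6, 1.95)), 1, 10)),
            )
            lp = np.log(base_rate / (1 - base_rate)) + w
            for scope in ("full", "family", "friends"):
                for stat, c in centers.items():
                    col = f"{scope}_{stat}"
                    x = float(rng.normal(c, 1.2))
                    row[col] = x
                    lp += coefs.get(col, 0.0) * (x - c)
            row[outcome] = bool(rng.random() < _logistic(lp))
            rows.append(row)
    df = pd.DataFrame(rows)
    for oc in ("veg_meets", "fruit_meets", "fastfood_none", "snacks_low"):
        if oc not in df.columns:
            df[oc] = False
    df = df.rename(columns={"full_avg_eat_freq": "full_avg_eat"})
    return df
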