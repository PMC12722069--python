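"""Survey data model and CSV ingestion for household network surveys.

Three tables describe a multi-reporter household survey:

``participants.csv``
    One row per surveyed person: demographics, self-rated health and effort
    (1-10), four-item horizontal-individualism and vertical-collectivism
    scales (items 1-9), and four diet-frequency items on a seven-level
    ordinal scale (0 = none ... 6 = 4+ times/day).  Exactly one participant
    per household is the *index adult* (the 21-35-year-old around whom the
    household was recruited); 1-3 co-surveyed family members accompany them.
    ``relation_to_index`` carries the raw relation label of each co-surveyed
    member to the index adult ("ego" for the index).

``alters.csv``
    One row per important person named by a reporter (2-10 per reporter):
    free-text relation label or pseudonym, family/friend/other class, sex,
    approximate age, and the reporter's perception of that person's health
    and effort (1-10, may be missing).

``ratings.csv``
    One row per unordered pair of persons rated by a reporter: five 0-9
    agreement ratings.  Interaction frequency, emotional closeness and
    eating-together are symmetric; the two health-importance ratings are
    directed (a's importance in b's health and vice versa).  Person
    references are either a participant_id or one of that reporter's alter
    labels.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ParticipantRecord",
    "AlterRecord",
    "DyadRatingRow",
    "HouseholdSurvey",
    "SchemaError",
    "ValidationError",
    "ReferentialError",
    "DIET_LEVEL_LABELS",
    "DIET_ITEMS",
    "band_age",
    "read_household_surveys",
    "write_cohort",
    "surveys_to_frames",
    "frames_to_surveys",
    "summarize_cohort",
]


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class ValidationError(ValueError):
    """A cell violates its documented range or type; names the row."""


class ReferentialError(ValueError):
    """An id refers to a row that does not exist."""


#: seven ordinal diet-frequency levels; thresholds below are defined on them
DIET_LEVEL_LABELS = (
    "none",
    "1-3/week",
    "4-6/week",
    "1/day",
    "2/day",
    "3/day",
    "4+/day",
)

DIET_ITEMS = ("vegetables", "fruits", "snacks", "fast_food")

AGE_BANDS = ("<19", "19-39", "40-59", "60+")


def band_age(age_years: float) -> str:
    """Band an age in years into the reporting strata used throughout."""
    if pd.isna(age_years):
        return np.nan
    if age_years < 19:
        return "<19"
    if age_years < 40:
        return "19-39"
    if age_years < 60:
        return "40-59"
    return "60+"


BAND_MIDPOINTS = {"<19": 10.0, "19-39": 29.0, "40-59": 49.5, "60+": 67.0}


@dataclass
class ParticipantRecord:
    participant_id: str
    household_id: str
    is_index: bool
    relation_to_index: str
    age: Optional[float]
    age_band: str
    sex: str
    race: str
    income: str
    housing: str
    bmi: Optional[float]
    marital_status: str
    self_health: int
    self_effort: int
    hi_items: tuple[int, int, int, int]
    vc_items: tuple[int, int, int, int]
    diet_freq: dict[str, int]


@dataclass
class AlterRecord:
    reporter_id: str
    alter_label: str
    relation_class: str
    sex: Optional[str]
    age_approx: Optional[float]
    perceived_health: Optional[int]
    perceived_effort: Optional[int]


@dataclass
class DyadRatingRow:
    reporter_id: str
    person_a: str
    person_b: str
    interact_freq: int
    closeness: int
    eat_freq: int
    importance_a_in_b: int
    importance_b_in_a: int


@dataclass
class HouseholdSurvey:
    household_id: str
    participants: list[ParticipantRecord] = field(default_factory=list)
    alters: list[AlterRecord] = field(default_factory=list)
    ratings: list[DyadRatingRow] = field(default_factory=list)
    overrides: Optional[pd.DataFrame] = None

    @property
    def index_participant(self) -> ParticipantRecord:
        return next(p for p in self.participants if p.is_index)


# ---------------------------------------------------------------------------
# column dictionaries

PARTICIPANT_COLUMNS = [
    "participant_id", "household_id", "is_index", "relation_to_index",
    "age", "age_band", "sex", "race", "income", "housing", "bmi",
    "marital_status", "self_health", "self_effort",
    "hi_1", "hi_2", "hi_3", "hi_4", "vc_1", "vc_2", "vc_3", "vc_4",
    "diet_vegetables", "diet_fruits", "diet_snacks", "diet_fast_food",
]
ALTER_COLUMNS = [
    "reporter_id", "alter_label", "relation_class", "sex", "age_approx",
    "perceived_health", "perceived_effort",
]
RATING_COLUMNS = [
    "reporter_id", "person_a", "person_b", "interact_freq", "closeness",
    "eat_freq", "importance_a_in_b", "importance_b_in_a",
]
OVERRIDE_COLUMNS = ["household_id", "reporter_id", "alter_label", "resolved_label"]


def _require_columns(df: pd.DataFrame, cols: Sequence[str], name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{name}: missing column(s) {missing}")


def _check_range(df, col, lo, hi, name, allow_missing=False):
    vals = pd.to_numeric(df[col], errors="coerce")
    bad_nan = df[col].notna() & vals.isna()
    if bad_nan.any():
        raise ValidationError(
            f"{name}: non-numeric {col} at row {int(bad_nan.idxmax())}"
        )
    if not allow_missing and vals.isna().any():
        raise ValidationError(f"{name}: missing {col} at row {int(vals.isna().idxmax())}")
    out = (vals < lo) | (vals > hi)
    if out.any():
        i = out.idxmax()
        raise ValidationError(
            f"{name}: {col}={df.loc[i, col]} out of [{lo},{hi}] at row {i}"
        )
    return vals


# ---------------------------------------------------------------------------
# reading

def _validate_participants(df: pd.DataFrame) -> pd.DataFrame:
    _require_columns(df, PARTICIPANT_COLUMNS, "participants")
    df = df.copy()
    df["is_index"] = df["is_index"].astype(bool)
    _check_range(df, "self_health", 1, 10, "participants")
    _check_range(df, "self_effort", 1, 10, "participants")
    for c in ["hi_1", "hi_2", "hi_3", "hi_4", "vc_1", "vc_2", "vc_3", "vc_4"]:
        _check_range(df, c, 1, 9, "participants")
    for item in DIET_ITEMS:
        _check_range(df, f"diet_{item}", 0, 6, "participants")
    if df["participant_id"].duplicated().any():
        dup = df["participant_id"][df["participant_id"].duplicated()].iloc[0]
        raise ValidationError(f"participants: duplicate participant_id {dup!r}")
    for hh, grp in df.groupby("household_id"):
        n_index = int(grp["is_index"].sum())
        if n_index != 1:
            raise ValidationError(
                f"participants: household {hh!r} has {n_index} index adults (need 1)"
            )
        n_co = len(grp) - 1
        if not 1 <= n_co <= 3:
            raise ValidationError(
                f"participants: household {hh!r} has {n_co} co-surveyed members (need 1-3)"
            )
    return df


def _validate_alters(df: pd.DataFrame, participant_ids: set) -> pd.DataFrame:
    _require_columns(df, ALTER_COLUMNS, "alters")
    df = df.copy()
    _check_range(df, "perceived_health", 1, 10, "alters", allow_missing=True)
    _check_range(df, "perceived_effort", 1, 10, "alters", allow_missing=True)
    orphan = ~df["reporter_id"].isin(participant_ids)
    if orphan.any():
        raise ReferentialError(
            f"alters: reporter_id {df['reporter_id'][orphan].iloc[0]!r} not in participants"
        )
    counts = df.groupby("reporter_id").size()
    bad = counts[(counts < 2) | (counts > 10)]
    if len(bad):
        raise ValidationError(
            f"alters: reporter {bad.index[0]!r} names {int(bad.iloc[0])} alters (need 2-10)"
        )
    dup = df.duplicated(subset=["reporter_id", "alter_label"])
    if dup.any():
        raise ValidationError(
            f"alters: duplicate label for reporter at row {int(dup.idxmax())}"
        )
    return df


def _validate_ratings(df: pd.DataFrame, alters: pd.DataFrame, participant_ids: set) -> pd.DataFrame:
    _require_columns(df, RATING_COLUMNS, "ratings")
    df = df.copy()
    for c in ["interact_freq", "closeness", "eat_freq", "importance_a_in_b", "importance_b_in_a"]:
        _check_range(df, c, 0, 9, "ratings")
    orphan = ~df["reporter_id"].isin(participant_ids)
    if orphan.any():
        raise ReferentialError(
            f"ratings: reporter_id {df['reporter_id'][orphan].iloc[0]!r} not in participants"
        )
    same = df["person_a"] == df["person_b"]
    if same.any():
        raise ValidationError(f"ratings: person_a == person_b at row {int(same.idxmax())}")
    labels_by_reporter = alters.groupby("reporter_id")["alter_label"].agg(set).to_dict()
    for i, row in df.iterrows():
        known = labels_by_reporter.get(row["reporter_id"], set()) | participant_ids
        for col in ("person_a", "person_b"):
            if row[col] not in known:
                raise ReferentialError(
                    f"ratings: {col}={row[col]!r} at row {i} is neither a participant "
                    f"nor an alter of reporter {row['reporter_id']!r}"
                )
    return df


def _participant_from_row(row: pd.Series) -> ParticipantRecord:
    return ParticipantRecord(
        participant_id=str(row["participant_id"]),
        household_id=str(row["household_id"]),
        is_index=bool(row["is_index"]),
        relation_to_index=str(row["relation_to_index"]),
        age=None if pd.isna(row["age"]) else float(row["age"]),
        age_band=str(row["age_band"]),
        sex=str(row["sex"]),
        race=str(row["race"]),
        income=str(row["income"]),
        housing=str(row["housing"]),
        bmi=None if pd.isna(row["bmi"]) else float(row["bmi"]),
        marital_status=str(row["marital_status"]),
        self_health=int(row["self_health"]),
        self_effort=int(row["self_effort"]),
        hi_items=tuple(int(row[f"hi_{i}"]) for i in range(1, 5)),
        vc_items=tuple(int(row[f"vc_{i}"]) for i in range(1, 5)),
        diet_freq={item: int(row[f"diet_{item}"]) for item in DIET_ITEMS},
    )


def read_household_surveys(
    participants_path,
    alters_path,
    ratings_path,
    overrides_path=None,
) -> list[HouseholdSurvey]:
    """Read and validate the three survey tables into per-household bundles.

    All schema, range and referential invariants are enforced; any violation
    raises with the offending column and row.  Returns one
    :class:`HouseholdSurvey` per household, ordered by household_id.
    """
    participants = pd.read_csv(participants_path, dtype={"participant_id": str, "household_id": str})
    alters = pd.read_csv(alters_path, dtype={"reporter_id": str, "alter_label": str})
    ratings = pd.read_csv(
        ratings_path, dtype={"reporter_id": str, "person_a": str, "person_b": str}
    )
    overrides = None
    if overrides_path is not None:
        overrides = pd.read_csv(overrides_path, dtype=str)
        _require_columns(overrides, OVERRIDE_COLUMNS, "overrides")
    return frames_to_surveys(participants, alters, ratings, overrides)


def frames_to_surveys(
    participants: pd.DataFrame,
    alters: pd.DataFrame,
    ratings: pd.DataFrame,
    overrides: Optional[pd.DataFrame] = None,
) -> list[HouseholdSurvey]:
    participants = _validate_participants(participants)
    pids = set(participants["participant_id"])
    alters = _validate_alters(alters, pids)
    ratings = _validate_ratings(ratings, alters, pids)

    hh_of = participants.set_index("participant_id")["household_id"].to_dict()
    surveys = []
    for hh, pgrp in participants.groupby("household_id", sort=True):
        hh_pids = set(pgrp["participant_id"])
        a = alters[alters["reporter_id"].isin(hh_pids)]
        r = ratings[ratings["reporter_id"].isin(hh_pids)]
        ov = None
        if overrides is not None:
            ov = overrides[overrides["household_id"] == hh].reset_index(drop=True)
        surveys.append(
            HouseholdSurvey(
                household_id=str(hh),
                participants=[_participant_from_row(row) for _, row in pgrp.iterrows()],
                alters=[
                    AlterRecord(
                        reporter_id=str(row["reporter_id"]),
                        alter_label=str(row["alter_label"]),
                        relation_class=str(row["relation_class"]),
                        sex=None if pd.isna(row["sex"]) else str(row["sex"]),
                        age_approx=None if pd.isna(row["age_approx"]) else float(row["age_approx"]),
                        perceived_health=None if pd.isna(row["perceived_health"]) else int(row["perceived_health"]),
                        perceived_effort=None if pd.isna(row["perceived_effort"]) else int(row["perceived_effort"]),
                    )
                    for _, row in a.iterrows()
                ],
                ratings=[
                    DyadRatingRow(
                        reporter_id=str(row["reporter_id"]),
                        person_a=str(row["person_a"]),
                        person_b=str(row["person_b"]),
                        interact_freq=int(row["interact_freq"]),
                        closeness=int(row["closeness"]),
                        eat_freq=int(row["eat_freq"]),
                        importance_a_in_b=int(row["importance_a_in_b"]),
                        importance_b_in_a=int(row["importance_b_in_a"]),
                    )
                    for _, row in r.iterrows()
                ],
                overrides=ov,
            )
        )
    # cross-household referential check: every reporter's household must exist
    for rid in set(alters["reporter_id"]):
        if rid not in hh_of:
            raise ReferentialError(f"alters: reporter {rid!r} has no household")
    return surveys


# ---------------------------------------------------------------------------
# writing

def surveys_to_frames(surveys: Sequence[HouseholdSurvey]):
    """Flatten survey bundles back into the three canonical DataFrames."""
    prows, arows, rrows = [], [], []
    for s in surveys:
        for p in s.participants:
            row = {
                "participant_id": p.participant_id,
                "household_id": p.household_id,
                "is_index": p.is_index,
                "relation_to_index": p.relation_to_index,
                "age": p.age,
                "age_band": p.age_band,
                "sex": p.sex,
                "race": p.race,
                "income": p.income,
                "housing": p.housing,
                "bmi": p.bmi,
                "marital_status": p.marital_status,
                "self_health": p.self_health,
                "self_effort": p.self_effort,
            }
            for i in range(4):
                row[f"hi_{i+1}"] = p.hi_items[i]
                row[f"vc_{i+1}"] = p.vc_items[i]
            for item in DIET_ITEMS:
                row[f"diet_{item}"] = p.diet_freq[item]
            prows.append(row)
        arows.extend(dataclasses.asdict(a) for a in s.alters)
        rrows.extend(dataclasses.asdict(r) for r in s.ratings)
    return (
        pd.DataFrame(prows, columns=PARTICIPANT_COLUMNS),
        pd.DataFrame(arows, columns=ALTER_COLUMNS),
        pd.DataFrame(rrows, columns=RATING_COLUMNS),
    )


def write_cohort(surveys: Sequence[HouseholdSurvey], out_dir) -> dict[str, Path]:
    """Write participants/alters/ratings CSVs; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    p, a, r = surveys_to_frames(surveys)
    paths = {
        "participants": out_dir / "participants.csv",
        "alters": out_dir / "alters.csv",
        "ratings": out_dir / "ratings.csv",
    }
    p.to_csv(paths["participants"], index=False)
    a.to_csv(paths["alters"], index=False)
    r.to_csv(paths["ratings"], index=False)
    return paths


# ---------------------------------------------------------------------------
# cohort summary

def summarize_cohort(surveys: Sequence[HouseholdSurvey]) -> pd.DataFrame:
    """Tidy cohort characteristics table: surveyed participants vs alters.

    Categorical variables (age band, sex, race) are reported as counts and
    percentages; 1-10 self-ratings and the two 4-36 cultural-orientation
    scores as mean and sd.  Alters contribute perceived ratings and their
    banded approximate ages.  Empty strata report count 0.
    """
    p, a, _ = surveys_to_frames(surveys)
    rows = []

    def cat_rows(series, group, variable, levels=None):
        series = series.dropna()
        counts = series.value_counts()
        levels = levels if levels is not None else sorted(counts.index)
        total = len(series)
        for lev in levels:
            n = int(counts.get(lev, 0))
            rows.append(
                dict(group=group, variable=variable, level=str(lev),
                     n=n, pct=100.0 * n / total if total else 0.0,
                     mean=np.nan, sd=np.nan)
            )

    def num_rows(series, group, variable):
        series = pd.to_numeric(series, errors="coerce").dropna()
        rows.append(
            dict(group=group, variable=variable, level="",
                 n=int(series.size), pct=np.nan,
                 mean=float(series.mean()) if series.size else np.nan,
                 sd=float(series.std(ddof=1)) if series.size > 1 else np.nan)
        )

    bands = [b for b in AGE_BANDS]
    cat_rows(p["age_band"], "participants", "age_band", bands)
    cat_rows(p["sex"], "participants", "sex")
    cat_rows(p["race"], "participants", "race")
    num_rows(p["self_health"], "participants", "self_health")
    num_rows(p["self_effort"], "participants", "self_effort")
    num_rows(p[[f"hi_{i}" for i in range(1, 5)]].sum(axis=1), "participants", "hi_score")
    num_rows(p[[f"vc_{i}" for i in range(1, 5)]].sum(axis=1), "participants", "vc_score")

    alter_bands = a["age_approx"].map(band_age)
    cat_rows(alter_bands, "alters", "age_band", bands)
    cat_rows(a["sex"], "alters", "sex")
    num_rows(a["perceived_health"], "alters", "perceived_health")
    num_rows(a["perceived_effort"], "alters", "perceived_effort")
    return pd.DataFrame(rows)
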