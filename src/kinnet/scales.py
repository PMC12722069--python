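"""Cultural-orientation scale scoring and diet dichotomization.

Horizontal individualism (HI) and vertical collectivism (VC) are each the sum
of four 1-9 items, giving scores from 4 to 36 that are median-split into
high/low for modelling.  The four diet-frequency items (seven ordinal levels,
none .. 4+ times/day) are dichotomized against dietary-guideline thresholds:
vegetables >= 2/day, fruit >= 1/day, fast food none vs any, snacks <= 3/week
vs more.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .survey_io import DIET_ITEMS, HouseholdSurvey, surveys_to_frames

__all__ = [
    "ScaleScore",
    "DietFlags",
    "score_scale",
    "median_split",
    "dichotomize_diet",
    "cronbach_alpha",
    "code_participants",
]

# indices into the 7-level ordinal diet scale
# 0 none | 1 1-3/wk | 2 4-6/wk | 3 1/day | 4 2/day | 5 3/day | 6 4+/day
_LEVEL_2_PER_DAY = 4
_LEVEL_1_PER_DAY = 3
_LEVEL_3_PER_WEEK = 1


@dataclass(frozen=True)
class ScaleScore:
    hi_score: int
    vc_score: int
    hi_high: bool
    vc_high: bool


@dataclass(frozen=True)
class DietFlags:
    veg_meets: bool      # >= 2 times per day
    fruit_meets: bool    # >= 1 time per day
    fastfood_none: bool  # none vs any
    snacks_low: bool     # <= 3 times per week


def score_scale(items: Sequence[int]) -> int:
    """Sum a 4-item, 9-point scale into a 4-36 score."""
    if len(items) != 4:
        raise ValueError(f"expected 4 items, got {len(items)}")
    items = [int(x) for x in items]
    if any(x < 1 or x > 9 for x in items):
        raise ValueError(f"scale items must be in [1,9]: {items}")
    return int(sum(items))


def median_split(scores: Sequence[float], tie_to_high: bool = False):
    """Split scores at the sample median; returns (flags, median).

    A score is "high" iff strictly above the median (ties go low unless
    ``tie_to_high``); the attained sample median is returned so it can be
    reported alongside the flags.
    """
    arr = np.asarray(list(scores), dtype=float)
    if arr.size < 2:
        raise ValueError("median split needs at least 2 scores")
    med = float(np.median(arr))
    flags = arr >= med if tie_to_high else arr > med
    if np.all(arr == arr[0]):
        warnings.warn("all scores identical; median split yields one empty group")
    return flags, med


def dichotomize_diet(diet_freq: Mapping[str, int]) -> DietFlags:
    """Apply the four guideline thresholds to ordinal diet levels."""
    lv = {item: int(diet_freq[item]) for item in DIET_ITEMS}
    for item, v in lv.items():
        if not 0 <= v <= 6:
            raise ValueError(f"diet level for {item} out of [0,6]: {v}")
    return DietFlags(
        veg_meets=lv["vegetables"] >= _LEVEL_2_PER_DAY,
        fruit_meets=lv["fruits"] >= _LEVEL_1_PER_DAY,
        fastfood_none=lv["fast_food"] == 0,
        snacks_low=lv["snacks"] <= _LEVEL_3_PER_WEEK,
    )


def cronbach_alpha(item_matrix: np.ndarray) -> float:
    """Cronbach's alpha for an (n_subjects, k_items) matrix.

    Reported as an internal-consistency diagnostic for the HI/VC scales.
    """
    X = np.asarray(item_matrix, dtype=float)
    k = X.shape[1]
    item_var = X.var(axis=0, ddof=1).sum()
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var == 0:
        return np.nan
    return k / (k - 1) * (1 - item_var / total_var)


def code_participants(surveys: Sequence[HouseholdSurvey]) -> pd.DataFrame:
    """Per-participant coded table: scores, median-split flags, diet flags.

    The HI/VC medians are computed on the full analysis sample (all surveyed
    participants across households), matching a single cohort-wide split.
    """
    p, _, _ = surveys_to_frames(surveys)
    out = p[["participant_id", "household_id", "is_index", "age", "age_band",
             "sex", "race", "income", "housing", "bmi",
             "self_health", "self_effort"]].copy()
    out["hi_score"] = p[[f"hi_{i}" for i in range(1, 5)]].sum(axis=1)
    out["vc_score"] = p[[f"vc_{i}" for i in range(1, 5)]].sum(axis=1)
    hi_flags, hi_med = median_split(out["hi_score"])
    vc_flags, vc_med = median_split(out["vc_score"])
    out["hi_high"] = hi_flags
    out["vc_high"] = vc_flags
    out.attrs["hi_median"] = hi_med
    out.attrs["vc_median"] = vc_med
    out.attrs["hi_alpha"] = cronbach_alpha(p[[f"hi_{i}" for i in range(1, 5)]].to_numpy())
    out.attrs["vc_alpha"] = cronbach_alpha(p[[f"vc_{i}" for i in range(1, 5)]].to_numpy())
    flags = [
        dichotomize_diet({item: p.loc[i, f"diet_{item}"] for item in DIET_ITEMS})
        for i in p.index
    ]
    out["veg_meets"] = [f.veg_meets for f in flags]
    out["fruit_meets"] = [f.fruit_meets for f in flags]
    out["fastfood_none"] = [f.fastfood_none for f in flags]
    out["snacks_low"] = [f.snacks_low for f in flags]
    return out
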