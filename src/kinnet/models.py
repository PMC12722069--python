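"""Dyadic mixed models and network-average diet models.

Two model families, presented as statsmodels-style Model/Results pairs:

:class:`DyadImportanceModel`
    A linear mixed model of the 0-9 "importance of the source in the target
    node's health" rating over directed dyads.  Because the same person
    appears in many dyads (as source and as target) and dyads nest within
    households, the model carries *cross-classified* random intercepts:
    one per source node, one per target node, and one per household.
    Fixed effects come in three nested specifications: interaction
    frequency and emotional closeness plus node demographics (spec 1);
    adding frequency of eating together (spec 2); restricting to surveyed
    source nodes and adding the individualism/collectivism median-split
    flags (spec 3).  A sensitivity switch restricts to dyads where both
    endpoints were surveyed.

:class:`DietNetworkModel`
    A marginal logistic model of a dichotomized diet behaviour on the
    participant's network averages (perceived health, health effort, eating
    together) over a chosen sub-network scope (full network, family
    excluding spouses/partners, or friends only), adjusted for participant
    demographics.  Estimated by generalised estimating equations with
    households as clusters, an exchangeable working correlation by default,
    and robust standard errors; estimates are reported as odds ratios per
    1-point increase in the network average.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import patsy
import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLM, VCSpec

from .fusion import HouseholdNetwork, build_directed_records, is_spousal_pair

__all__ = [
    "DyadImportanceModel",
    "DyadImportanceResults",
    "DietNetworkModel",
    "DietNetworkResults",
    "SampleSizeError",
    "compute_network_averages",
    "build_diet_data",
    "fit_dyad_mixed",
    "fit_diet_gee",
    "DIET_OUTCOMES",
    "SCOPES",
]

DIET_OUTCOMES = ("veg_meets", "fruit_meets", "fastfood_none", "snacks_low")
SCOPES = ("full", "family", "friends")


class SampleSizeError(ValueError):
    """Too few usable records (or a degenerate outcome) to fit the model."""


# ---------------------------------------------------------------------------
# shared results machinery

@dataclass
class _BaseResults:
    params: pd.Series
    bse: pd.Series
    conf_low: pd.Series
    conf_high: pd.Series
    n_used: int
    n_dropped: int
    converged: bool
    model_id: str
    sm_results: object

    def conf_int(self) -> pd.DataFrame:
        return pd.DataFrame({"lower": self.conf_low, "upper": self.conf_high})

    def tidy(self, or_scale: bool = False) -> pd.DataFrame:
        est, lo, hi = self.params, self.conf_low, self.conf_high
        if or_scale:
            est, lo, hi = np.exp(est), np.exp(lo), np.exp(hi)
        return pd.DataFrame(
            dict(
                term=self.params.index,
                estimate=est.values,
                se=self.bse.values,
                ci_low=lo.values,
                ci_high=hi.values,
                or_scale=or_scale,
                model_id=self.model_id,
                n=self.n_used,
            )
        )

    def summary(self):
        return self.sm_results.summary()


class DyadImportanceResults(_BaseResults):
    """Estimates, their uncertainty, and diagnostics for a dyadic fit."""

    vc_estimates: Optional[pd.Series] = None


class DietNetworkResults(_BaseResults):
    """GEE logistic results; ``odds_ratios`` are per 1-unit increase."""

    @property
    def odds_ratios(self) -> pd.Series:
        return np.exp(self.params)


def _treatment(col: str, ref) -> str:
    return f"C({col}, Treatment({ref!r}))"


def _modal(series: pd.Series):
    return series.mode().iloc[0]


# ---------------------------------------------------------------------------
# dyadic cross-classified mixed model

class DyadImportanceModel:
    """Linear mixed model for directed health-importance ratings.

    Parameters
    ----------
    records : DataFrame
        Directed dyad records from :func:`kinnet.fusion.build_directed_records`
        (concatenated across households).
    model_spec : {1, 2, 3}
        1: interaction frequency + closeness + tie category + node
        demographics; 2: adds eating frequency; 3: spec 2 restricted to
        surveyed source nodes with the HI/VC median-split flags added.
    surveyed_only : bool
        Restrict to dyads where both endpoints were surveyed (sensitivity
        analysis).
    node_effect_mode : {"crossed", "shared"}
        "crossed" fits separate source-node and target-node random
        intercepts; "shared" fits a single per-node intercept applied
        whichever role the node plays.
    coded : DataFrame, optional
        Coded participant table (from :func:`kinnet.scales.code_participants`)
        supplying hi_high/vc_high for spec 3.
    """

    #: tie-category dummies use friends as the reference group
    CATEGORY_REF = "friend"

    def __init__(
        self,
        records: pd.DataFrame,
        model_spec: int = 1,
        surveyed_only: bool = False,
        node_effect_mode: str = "crossed",
        coded: Optional[pd.DataFrame] = None,
        boundary_tol: float = 0.05,
    ):
        if model_spec not in (1, 2, 3):
            raise ValueError("model_spec must be 1, 2 or 3")
        if node_effect_mode not in ("crossed", "shared"):
            raise ValueError("node_effect_mode must be 'crossed' or 'shared'")
        self.model_spec = model_spec
        self.surveyed_only = surveyed_only
        self.node_effect_mode = node_effect_mode
        self.boundary_tol = boundary_tol

        df = records.copy()
        if model_spec == 3:
            df = df[df["source_surveyed"].astype(bool)]
            if coded is not None:
                df = df.merge(
                    coded[["participant_id", "hi_high", "vc_high"]],
                    left_on="source_participant_id",
                    right_on="participant_id",
                    how="left",
                ).drop(columns=["participant_id"])
            if "hi_high" not in df.columns:
                raise ValueError("spec 3 requires coded hi_high/vc_high (pass coded=)")
        if surveyed_only:
            df = df[df["both_surveyed"].astype(bool)]
        self._raw = df.reset_index(drop=True)

    @classmethod
    def from_networks(
        cls, networks: Sequence[HouseholdNetwork], **kwargs
    ) -> "DyadImportanceModel":
        records = pd.concat(
            [build_directed_records(n) for n in networks], ignore_index=True
        )
        return cls(records, **kwargs)

    def _formula(self, df: pd.DataFrame) -> tuple[str, list[str]]:
        terms = ["interact_freq", "closeness"]
        if self.model_spec >= 2:
            terms.append("eat_freq")
        cat_ref = (
            self.CATEGORY_REF
            if (df["category_directed"] == self.CATEGORY_REF).any()
            else _modal(df["category_directed"])
        )
        terms.append(_treatment("category_directed", cat_ref))
        for side in ("source", "target"):
            terms.append(_treatment(f"{side}_age_band", _modal(df[f"{side}_age_band"])))
            terms.append(_treatment(f"{side}_sex", _modal(df[f"{side}_sex"])))
            terms.append(f"{side}_health")
            terms.append(f"{side}_effort")
        if self.model_spec == 3:
            terms += ["hi_high", "vc_high"]
        required = [
            "outcome", "interact_freq", "closeness", "category_directed",
            "source_age_band", "source_sex", "source_health", "source_effort",
            "target_age_band", "target_sex", "target_health", "target_effort",
            "household_id", "source_node", "target_node",
        ]
        if self.model_spec >= 2:
            required.append("eat_freq")
        if self.model_spec == 3:
            required += ["hi_high", "vc_high"]
        return "outcome ~ " + " + ".join(terms), required

    def _roles(self) -> list[tuple[Optional[str], str]]:
        if self.node_effect_mode == "crossed":
            return [("source_node", "source"), ("target_node", "target")]
        return [(None, "node")]

    def _vcspec(self, df: pd.DataFrame, group_labels: list, roles) -> Optional[VCSpec]:
        if not roles:
            return None
        names, colnames, mats = [], [], []
        for col, name in roles:
            names.append(name)
            cn, mt = [], []
            for g in group_labels:
                sub = df[df["household_id"] == g]
                if col is not None:
                    nodes = sorted(sub[col].unique())
                    mat = np.column_stack(
                        [(sub[col] == nd).to_numpy(float) for nd in nodes]
                    )
                else:
                    nodes = sorted(
                        set(sub["source_node"]) | set(sub["target_node"])
                    )
                    mat = np.column_stack(
                        [
                            (sub["source_node"] == nd).to_numpy(float)
                            + (sub["target_node"] == nd).to_numpy(float)
                            for nd in nodes
                        ]
                    )
                cn.append(list(nodes))
                mt.append(mat)
            colnames.append(cn)
            mats.append(mt)
        return VCSpec(names, colnames, mats)

    def fit(self, reml: bool = True, maxiter: int = 200) -> DyadImportanceResults:
        formula, required = self._formula(self._raw)
        df = self._raw.dropna(subset=[c for c in required if c in self._raw.columns])
        df = df.reset_index(drop=True)
        n_dropped = len(self._raw) - len(df)
        if len(df) < 30:
            raise SampleSizeError(f"only {len(df)} complete dyad records")

        df = df.sort_values("household_id", kind="stable").reset_index(drop=True)
        y, X = patsy.dmatrices(formula, df, return_type="dataframe")
        yv = np.asarray(y).ravel()
        Xv = np.asarray(X)
        groups = df["household_id"].to_numpy()
        group_labels = list(pd.unique(groups))
        model_id = f"dyad_spec{self.model_spec}" + (
            "_surveyed" if self.surveyed_only else ""
        )

        # The REML surface is flat where a variance component sits at the
        # zero boundary: the optimizer either stalls or stops at a spurious
        # small value.  Components estimated below boundary_tol x residual
        # variance (or belonging to a non-converged fit) are treated as
        # boundary zeros and removed; with every random term gone the model
        # is exactly ordinary least squares.
        roles = list(self._roles())
        res = None
        converged = False
        dropped_terms: list[str] = []
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            while roles:
                vcspec = self._vcspec(df, group_labels, roles)
                model = MixedLM(
                    yv, Xv, groups=groups,
                    exog_re=np.ones((len(df), 1)),
                    exog_vc=vcspec,
                )
                try:
                    res = model.fit(reml=reml, maxiter=maxiter, method="lbfgs")
                except Exception:
                    res = model.fit(reml=reml, maxiter=maxiter)
                converged = bool(getattr(res, "converged", True))
                vc_only = dict(
                    zip(vcspec.names, map(float, np.atleast_1d(res.vcomp)))
                )
                at_zero = [
                    k for k, v in vc_only.items()
                    if v < self.boundary_tol * float(res.scale)
                ]
                if not at_zero:
                    # nothing at the boundary: accept (flagged if the
                    # optimizer did not report convergence)
                    break
                roles = [r for r in roles if r[1] not in at_zero]
                dropped_terms.extend(at_zero)
                res = None
            if res is None:
                # household-intercept-only refit; at the zero-variance
                # boundary this is exactly ordinary least squares
                model = MixedLM(
                    yv, Xv, groups=groups, exog_re=np.ones((len(df), 1))
                )
                res = model.fit(reml=reml, maxiter=maxiter)
                converged = bool(getattr(res, "converged", True))
                hh_var = float(np.asarray(res.cov_re)[0, 0])
                if not converged or hh_var < self.boundary_tol * float(res.scale):
                    res = None
                    dropped_terms.append("household")

        if res is None:  # full collapse: ordinary least squares
            ols = sm.OLS(yv, Xv).fit()
            params = pd.Series(ols.params, index=X.columns)
            bse = pd.Series(ols.bse, index=X.columns)
            ci = np.asarray(ols.conf_int())
            out = DyadImportanceResults(
                params=params, bse=bse,
                conf_low=pd.Series(ci[:, 0], index=X.columns),
                conf_high=pd.Series(ci[:, 1], index=X.columns),
                n_used=len(df), n_dropped=n_dropped,
                converged=True, model_id=model_id, sm_results=ols,
            )
            out.vc_estimates = pd.Series(dict(household_var=0.0))
            return out

        k = X.shape[1]
        params = pd.Series(res.params[:k], index=X.columns)
        bse = pd.Series(res.bse[:k], index=X.columns)
        ci = res.conf_int()[:k]
        out = DyadImportanceResults(
            params=params,
            bse=bse,
            conf_low=pd.Series(np.asarray(ci)[:, 0], index=X.columns),
            conf_high=pd.Series(np.asarray(ci)[:, 1], index=X.columns),
            n_used=len(df),
            n_dropped=n_dropped,
            converged=converged,
            model_id=model_id,
            sm_results=res,
        )
        vcs = dict(household_var=float(np.asarray(res.cov_re)[0, 0]))
        if roles:
            for name, v in zip([r[1] for r in roles], np.atleast_1d(res.vcomp)):
                vcs[name] = float(v)
        out.vc_estimates = pd.Series(vcs)
        return out


def fit_dyad_mixed(
    records: pd.DataFrame,
    model_spec: int = 1,
    surveyed_only: bool = False,
    **kwargs,
) -> DyadImportanceResults:
    """Functional wrapper: build and fit a :class:`DyadImportanceModel`."""
    return DyadImportanceModel(
        records, model_spec=model_spec, surveyed_only=surveyed_only, **kwargs
    ).fit()


# ---------------------------------------------------------------------------
# network averages

def compute_network_averages(
    network: HouseholdNetwork, participant_id: Optional[str] = None
) -> pd.DataFrame:
    """Per-participant network averages over full/family/friends scopes.

    For each surveyed participant (or just ``participant_id``), averages the
    members' health and effort ratings (self-reports for surveyed members,
    mean perceptions otherwise) and the participant's eating-together
    ratings with those members.  The family scope excludes the participant's
    spouse/partner; scopes with zero members yield no row.
    """
    reg = network.registry
    surveyed = {
        n.participant_id: n for n in reg.nodes.values() if n.surveyed
    }
    if participant_id is not None:
        if participant_id not in surveyed:
            raise ValueError(
                f"participant {participant_id!r} absent from network "
                f"{network.household_id!r}"
            )
        targets = {participant_id: surveyed[participant_id]}
    else:
        targets = surveyed

    eat_by_pair = {}
    for e in network.edges:
        eat_by_pair[(e.a, e.b)] = e.eat_freq
        eat_by_pair[(e.b, e.a)] = e.eat_freq

    rows = []
    for pid, me in targets.items():
        members = [n for n in reg.nodes.values() if n.node_id != me.node_id]
        scopes = {
            "full": members,
            "family": [
                n
                for n in members
                if n.relation.is_family and not is_spousal_pair(me, n)
            ],
            "friends": [n for n in members if n.relation.label == "friend"],
        }
        for scope, mem in scopes.items():
            if not mem:
                continue
            health = [n.health for n in mem if n.health is not None]
            effort = [n.effort for n in mem if n.effort is not None]
            eats = [
                eat_by_pair[(me.node_id, n.node_id)]
                for n in mem
                if (me.node_id, n.node_id) in eat_by_pair
            ]
            rows.append(
                dict(
                    participant_id=pid,
                    household_id=network.household_id,
                    scope=scope,
                    avg_health=float(np.mean(health)) if health else np.nan,
                    avg_effort=float(np.mean(effort)) if effort else np.nan,
                    avg_eat_freq=float(np.mean(eats)) if eats else np.nan,
                    n_members=len(mem),
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "participant_id", "household_id", "scope",
            "avg_health", "avg_effort", "avg_eat_freq", "n_members",
        ],
    )


def build_diet_data(
    networks: Sequence[HouseholdNetwork], coded: pd.DataFrame
) -> pd.DataFrame:
    """Join coded participants with their per-scope network averages (wide).

    Produces one row per participant with ``{scope}_avg_health``,
    ``{scope}_avg_effort`` and ``{scope}_avg_eat`` columns; scopes the
    participant lacks (e.g. no friends named) are NaN and drop out of that
    scope's model by listwise deletion.
    """
    avgs = pd.concat(
        [compute_network_averages(n) for n in networks], ignore_index=True
    )
    wide = coded.copy()
    for scope in SCOPES:
        sub = avgs[avgs["scope"] == scope].set_index("participant_id")
        wide = wide.merge(
            sub[["avg_health", "avg_effort", "avg_eat_freq"]].rename(
                columns={
                    "avg_health": f"{scope}_avg_health",
                    "avg_effort": f"{scope}_avg_effort",
                    "avg_eat_freq": f"{scope}_avg_eat",
                }
            ),
            left_on="participant_id",
            right_index=True,
            how="left",
        )
    return wide


# ---------------------------------------------------------------------------
# diet GEE

class DietNetworkModel:
    """GEE logistic model of a diet flag on network averages.

    ``data`` is the wide table from :func:`build_diet_data`.  The fit
    regresses the chosen flag on the three averages of one scope, adjusted
    for participant age band, sex, race, income, BMI, self-rated health and
    effort, clustering on household.  Standard errors use the Mancl-DeRouen
    bias-reduced sandwich covariance: with few clusters (the study design
    has only a few dozen households) the plain robust covariance is known
    to be anti-conservative.
    """

    ADJUSTMENT = ["age_band", "sex", "race", "income"]

    def __init__(
        self,
        data: pd.DataFrame,
        outcome: str,
        scope: str = "full",
        cov_struct: str = "exchangeable",
    ):
        if outcome not in DIET_OUTCOMES:
            raise ValueError(f"outcome must be one of {DIET_OUTCOMES}")
        if scope not in SCOPES:
            raise ValueError(f"scope must be one of {SCOPES}")
        self.outcome = outcome
        self.scope = scope
        self.cov_struct = cov_struct
        self._raw = data.copy()

    def _formula(self, df: pd.DataFrame) -> tuple[str, list[str]]:
        s = self.scope
        terms = [f"{s}_avg_health", f"{s}_avg_effort", f"{s}_avg_eat"]
        for col in self.ADJUSTMENT:
            if df[col].nunique() > 1:
                terms.append(_treatment(col, _modal(df[col])))
        terms += ["bmi", "self_health", "self_effort"]
        required = [
            self.outcome, f"{s}_avg_health", f"{s}_avg_effort", f"{s}_avg_eat",
            "bmi", "self_health", "self_effort", "household_id",
        ] + self.ADJUSTMENT
        return "_y ~ " + " + ".join(terms), required

    def fit(self, maxiter: int = 100) -> DietNetworkResults:
        formula, required = self._formula(self._raw)
        df = self._raw.dropna(subset=required).reset_index(drop=True)
        n_dropped = len(self._raw) - len(df)
        if df["household_id"].nunique() < 2:
            raise SampleSizeError("need at least 2 households")
        df["_y"] = df[self.outcome].astype(int)
        if df["_y"].nunique() < 2:
            raise SampleSizeError(f"outcome {self.outcome!r} has a single value")

        cov = (
            sm.cov_struct.Exchangeable()
            if self.cov_struct == "exchangeable"
            else sm.cov_struct.Independence()
        )
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            model = sm.GEE.from_formula(
                formula,
                groups="household_id",
                data=df,
                family=sm.families.Binomial(),
                cov_struct=cov,
            )
            res = model.fit(maxiter=maxiter, cov_type="bias_reduced")
            ci = res.conf_int()
            # (quasi-)separation or a degenerate robust covariance shows up
            # as absurd or undefined standard errors
            separated = bool((res.bse > 50).any() or res.bse.isna().any())
        return DietNetworkResults(
            params=res.params,
            bse=res.bse,
            conf_low=ci.iloc[:, 0],
            conf_high=ci.iloc[:, 1],
            n_used=len(df),
            n_dropped=n_dropped,
            converged=bool(getattr(res, "converged", True)) and not separated,
            model_id=f"diet_{self.outcome}_{self.scope}",
            sm_results=res,
        )


def fit_diet_gee(
    data: pd.DataFrame, outcome: str, scope: str = "full", **kwargs
) -> DietNetworkResults:
    """Functional wrapper: build and fit a :class:`DietNetworkModel`."""
    return DietNetworkModel(data, outcome, scope=scope, **kwargs).fit()
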