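"""Network descriptives and weighted assortativity.

Assortativity here is attribute mixing over the fused household network:
do people who eat together often (or rate each other as important to their
health) resemble each other in age, sex, health or effort?  Numeric
attributes use the weighted Pearson correlation of endpoint values over the
symmetrized edge list (each undirected edge contributes both orderings);
categorical attributes use the Newman mixing-matrix coefficient
r = (sum_i e_ii - sum_i a_i b_i) / (1 - sum_i a_i b_i) on the
weight-normalized symmetric mixing matrix.  Both reduce to the classical
unweighted coefficients when all weights are equal.

A tie's weight is the chosen rating: frequency of eating together, or
health importance (the mean of the two directed importance ratings).
Zero-weight ties contribute nothing; a network with zero total weight or no
attribute variance has an undefined (NaN) coefficient and is dropped from
cohort means with a logged count.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .fusion import CATEGORIES, FusedEdge, HouseholdNetwork, build_directed_records

__all__ = [
    "summarize_networks",
    "category_means",
    "assortativity_numeric",
    "assortativity_categorical",
    "cohort_assortativity",
    "plot_network",
    "NUMERIC_ATTRIBUTES",
    "CATEGORICAL_ATTRIBUTES",
    "ASSORT_WEIGHTS",
]

NUMERIC_ATTRIBUTES = ("age", "health", "effort")
CATEGORICAL_ATTRIBUTES = ("sex",)
ASSORT_WEIGHTS = ("eat_freq", "importance")


def _node_attr(network: HouseholdNetwork, node_id: str, attribute: str):
    n = network.registry.nodes[node_id]
    if attribute == "age":
        return n.age_years
    if attribute == "sex":
        return n.sex
    if attribute == "health":
        return n.health
    if attribute == "effort":
        return n.effort
    raise ValueError(f"unknown attribute {attribute!r}")


def _edge_weight(e: FusedEdge, weight: str) -> float:
    if weight == "eat_freq":
        return e.eat_freq
    if weight == "importance":
        return (e.importance_ab + e.importance_ba) / 2.0
    raise ValueError(f"unknown weight {weight!r}")


def _weighted_pairs(network, attribute, weight):
    """(x, y, w) arrays over ordered endpoint pairs with known attributes."""
    xs, ys, ws = [], [], []
    for e in network.edges:
        va = _node_attr(network, e.a, attribute)
        vb = _node_attr(network, e.b, attribute)
        if va is None or vb is None:
            continue
        w = _edge_weight(e, weight)
        if w <= 0:
            continue
        xs.extend([va, vb])
        ys.extend([vb, va])
        ws.extend([w, w])
    return xs, ys, ws


def assortativity_numeric(
    network: HouseholdNetwork, attribute: str, weight: str = "eat_freq"
) -> float:
    """Weighted numeric assortativity coefficient in [-1, 1], or NaN.

    Weighted Pearson correlation of the endpoint attribute values over the
    symmetrized edge list.  NaN when the total weight is zero or the
    attribute has no variance across tied endpoints.
    """
    xs, ys, ws = _weighted_pairs(network, attribute, weight)
    if not ws:
        return float("nan")
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    w = np.asarray(ws, dtype=float)
    wsum = w.sum()
    mx = (w * x).sum() / wsum
    my = (w * y).sum() / wsum
    cov = (w * (x - mx) * (y - my)).sum() / wsum
    vx = (w * (x - mx) ** 2).sum() / wsum
    vy = (w * (y - my) ** 2).sum() / wsum
    if vx <= 0 or vy <= 0:
        return float("nan")
    return float(cov / np.sqrt(vx * vy))


def assortativity_categorical(
    network: HouseholdNetwork, attribute: str = "sex", weight: str = "eat_freq"
) -> float:
    """Weighted mixing-matrix assortativity in [-1, 1], or NaN.

    Builds the symmetric, weight-normalized mixing matrix e over attribute
    categories and returns (tr e - sum a_i b_i) / (1 - sum a_i b_i).  NaN
    when only one category is present among tied nodes or the total weight
    is zero.
    """
    xs, ys, ws = _weighted_pairs(network, attribute, weight)
    if not ws:
        return float("nan")
    cats = sorted(set(xs) | set(ys))
    if len(cats) < 2:
        return float("nan")
    idx = {c: i for i, c in enumerate(cats)}
    e = np.zeros((len(cats), len(cats)))
    for xv, yv, wv in zip(xs, ys, ws):
        e[idx[xv], idx[yv]] += wv
    e /= e.sum()
    a = e.sum(axis=1)
    b = e.sum(axis=0)
    ab = float(a @ b)
    if np.isclose(1.0, ab):
        return float("nan")
    return float((np.trace(e) - ab) / (1.0 - ab))


def cohort_assortativity(
    networks: Sequence[HouseholdNetwork],
    attributes: Iterable[str] = NUMERIC_ATTRIBUTES + CATEGORICAL_ATTRIBUTES,
    weights: Iterable[str] = ASSORT_WEIGHTS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-network coefficients and cohort mean/sd over defined networks.

    Returns ``(per_network, summary)``; ``summary`` records how many
    networks were dropped for each attribute/weight because the coefficient
    was undefined.
    """
    rows = []
    for net in networks:
        for attr in attributes:
            fn = (
                assortativity_categorical
                if attr in CATEGORICAL_ATTRIBUTES
                else assortativity_numeric
            )
            for w in weights:
                rows.append(
                    dict(
                        household_id=net.household_id,
                        attribute=attr,
                        weight=w,
                        coefficient=fn(net, attr, w),
                    )
                )
    per_network = pd.DataFrame(rows)
    summary_rows = []
    for (attr, w), grp in per_network.groupby(["attribute", "weight"]):
        vals = grp["coefficient"].dropna()
        summary_rows.append(
            dict(
                attribute=attr,
                weight=w,
                mean=float(vals.mean()) if len(vals) else np.nan,
                sd=float(vals.std(ddof=1)) if len(vals) > 1 else np.nan,
                n_defined=int(len(vals)),
                n_dropped=int(len(grp) - len(vals)),
            )
        )
    return per_network, pd.DataFrame(summary_rows)


# ---------------------------------------------------------------------------
# size statistics and category-wise means

def summarize_networks(networks: Sequence[HouseholdNetwork]) -> pd.DataFrame:
    """Per-network size/count rows plus a cohort mean/sd row.

    Cohort sd uses the n-1 denominator; with a single network the sd cells
    are NaN.
    """
    rows = []
    for net in networks:
        counts = {c: 0 for c in CATEGORIES}
        for e in net.edges:
            counts[e.category] += 1
        rows.append(
            dict(
                household_id=net.household_id,
                n_nodes=len(net.registry.nodes),
                n_edges=len(net.edges),
                **{f"n_{c}": counts[c] for c in CATEGORIES},
            )
        )
    df = pd.DataFrame(rows)
    num = df.drop(columns=["household_id"])
    mean_row = dict(household_id="cohort_mean", **num.mean().to_dict())
    sd_row = dict(
        household_id="cohort_sd",
        **(num.std(ddof=1).to_dict() if len(df) > 1 else {c: np.nan for c in num}),
    )
    return pd.concat([df, pd.DataFrame([mean_row, sd_row])], ignore_index=True)


def category_means(networks: Sequence[HouseholdNetwork]) -> pd.DataFrame:
    """Mean ratings by tie category, pooled over directed records.

    Symmetric measures (interaction, closeness, eating) are grouped by
    category; health importance is additionally split by intergenerational
    direction (target in an older vs younger generation than the source).
    Categories absent from every network yield no row (missing, not zero).
    """
    records = pd.concat(
        [build_directed_records(n) for n in networks], ignore_index=True
    )
    if records.empty:
        return pd.DataFrame(columns=["category", "measure", "mean", "n"])
    rows = []
    for measure in ("interact_freq", "closeness", "eat_freq"):
        g = records.groupby("category")[measure].agg(["mean", "count"])
        for cat, r in g.iterrows():
            rows.append(
                dict(category=cat, measure=measure, mean=float(r["mean"]), n=int(r["count"]))
            )
    g = records.groupby("category_directed")["outcome"].agg(["mean", "count"])
    for cat, r in g.iterrows():
        rows.append(
            dict(category=cat, measure="importance", mean=float(r["mean"]), n=int(r["count"]))
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# plotting

def plot_network(
    network: HouseholdNetwork,
    weight: str = "eat_freq",
    threshold: float = 5.0,
    path: Optional[str] = None,
    seed: int = 0,
):
    """Draw the fused graph with edge thickness proportional to a rating.

    Only edges with the chosen rating >= ``threshold`` are drawn, keeping
    the display to the strong ties.  Returns the matplotlib figure.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import networkx as nx

    G = network.to_networkx()
    strong = [
        (e.a, e.b) for e in network.edges if _edge_weight(e, weight) >= threshold
    ]
    widths = [
        _edge_weight(e, weight) / 2.0
        for e in network.edges
        if _edge_weight(e, weight) >= threshold
    ]
    pos = nx.spring_layout(G, seed=seed)
    fig, ax = plt.subplots(figsize=(7, 6))
    nx.draw_networkx_nodes(
        G, pos, ax=ax, node_size=320,
        node_color=["tab:orange" if G.nodes[n]["surveyed"] else "tab:blue" for n in G],
    )
    nx.draw_networkx_edges(G, pos, edgelist=strong, width=widths, ax=ax, alpha=0.6)
    nx.draw_networkx_labels(
        G, pos, labels={n: G.nodes[n]["relation"] for n in G}, font_size=7, ax=ax
    )
    ax.set_title(f"{network.household_id}: ties with {weight} >= {threshold}")
    ax.axis("off")
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
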