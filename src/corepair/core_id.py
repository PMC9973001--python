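"""Two-step identification of core species pairs.

Step one scores every network node's *functional keystoneness*: a weighted
betweenness centrality in which each pair of functional endpoints (k, l)
contributes w_k * w_l times the fraction of k-l shortest paths passing
through the node. The per-species weight w_s combines the direct Pearson
correlation of the species' abundance with the emission metric (r_s) and
the group-pair interaction effects of the groups it belongs to:

    w_s = r_s + r_s * sum over group pairs (m != n) containing s of T_mn

Keystoneness is min-max standardized to B' in [0, 1].

Step two scores every linked pair (i, j) from the binary network adjacency:
with node degrees R_i, R_j, shared-neighbor count S_ij and network size N_I,

    C_ij = (R_i - S_ij)(R_j - S_ij)          checkerboard (independent)
    T_ij = S_ij (N_I + S_ij - R_i - R_j)     togetherness (cooperative)

(which satisfy C_ij - T_ij = R_i R_j - N_I S_ij exactly), and the core
reinforcement indices R_ij = B'_i B'_j C_ij and B'_i B'_j T_ij rank pairs.
The core microbiome is the union of the top between-group (15) and
within-group (10) pairs.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .data_io import OtuTable
from .network import FieldNetwork

logger = logging.getLogger("corepair")


def group_interaction_effects(connectances: pd.DataFrame,
                              metric: pd.Series) -> dict[tuple[str, str],
                                                         float]:
    """T_mn: Pearson correlation of each between-group interaction strength
    (per-field connectance) with the per-field emission metric.

    ``connectances`` columns are "groupA|groupB" labels; only m != n pairs
    are used. Undefined correlations (constant strength) count as 0.
    """
    common = connectances.index.intersection(metric.index)
    effects: dict[tuple[str, str], float] = {}
    y = metric.loc[common].to_numpy(dtype=float)
    for col in connectances.columns:
        a, b = col.split("|")
        if a == b:
            continue
        x = connectances.loc[common, col].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(y) == 0 or np.isnan(x).any():
            effects[(a, b)] = 0.0
            continue
        effects[(a, b)] = float(stats.pearsonr(x, y)[0])
    return effects


def function_weights(table: OtuTable, metric: pd.Series,
                     group_effects: Mapping[tuple[str, str], float]
                     ) -> pd.DataFrame:
    """Per-OTU function weight w_s and its direct correlation r_s.

    r_s is the Pearson correlation between the OTU's relative abundance and
    the emission metric across samples; w_s amplifies r_s by the summed
    between-group effects T_mn of every group pair containing the OTU's
    group. OTUs with constant abundance get w = 0 with a warning.
    """
    common = table.abundance.index.intersection(metric.index)
    ab = table.abundance.loc[common]
    y = metric.loc[common].to_numpy(dtype=float)
    group_sum = {}
    for (m, n), t_mn in group_effects.items():
        if m == n:
            continue
        group_sum[m] = group_sum.get(m, 0.0) + t_mn
        group_sum[n] = group_sum.get(n, 0.0) + t_mn
    rows = []
    n_constant = 0
    for otu in ab.columns:
        x = ab[otu].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            r_s, w_s = np.nan, 0.0
            n_constant += 1
        else:
            r_s = float(stats.pearsonr(x, y)[0])
            w_s = r_s + r_s * group_sum.get(table.taxonomy[otu], 0.0)
        rows.append({"otu_id": otu, "group": table.taxonomy[otu],
                     "r": r_s, "w": w_s})
    if n_constant:
        logger.warning("%d OTU(s) with constant abundance: w set to 0",
                       n_constant)
    return pd.DataFrame(rows).set_index("otu_id")


def _weighted_betweenness(graph: nx.Graph, w: Mapping[str, float],
                          functional_set: set[str]) -> dict[str, float]:
    """Brandes accumulation with endpoint weights.

    F_i = sum over unordered pairs {k, l} in the functional set (k, l != i)
    of w_k * w_l * sigma_kl(i) / sigma_kl, with disconnected pairs
    contributing zero.
    """
    F = dict.fromkeys(graph, 0.0)
    for s in functional_set:
        if w.get(s, 0.0) == 0.0:
            continue
        stack: list = []
        pred: dict = {v: [] for v in graph}
        sigma = dict.fromkeys(graph, 0.0)
        sigma[s] = 1.0
        dist = dict.fromkeys(graph, -1)
        dist[s] = 0
        queue = deque([s])
        while queue:
            v = queue.popleft()
            stack.append(v)
            for nb in graph[v]:
                if dist[nb] < 0:
                    dist[nb] = dist[v] + 1
                    queue.append(nb)
                if dist[nb] == dist[v] + 1:
                    sigma[nb] += sigma[v]
                    pred[nb].append(v)
        delta = dict.fromkeys(graph, 0.0)
        while stack:
            t = stack.pop()
            endpoint = w.get(t, 0.0) if (t in functional_set and t != s) \
                else 0.0
            coeff = endpoint + delta[t]
            for v in pred[t]:
                delta[v] += sigma[v] / sigma[t] * coeff
            if t != s:
                F[t] += w[s] * delta[t]
    # ordered (s, t) double-counts each unordered pair
    return {v: val / 2.0 for v, val in F.items()}


def keystoneness(net: FieldNetwork, weights: pd.DataFrame | Mapping[str,
                                                                    float],
                 functional_set: Iterable[str] | None = None
                 ) -> pd.DataFrame:
    """Functional keystoneness F and its min-max standardization B'.

    ``functional_set`` restricts the endpoint pairs (default: every network
    node). Isolated nodes have F = 0. When F is constant across the network
    all B' are defined as 0 with a warning.
    """
    if isinstance(weights, pd.DataFrame):
        w = weights["w"].to_dict()
    else:
        w = dict(weights)
    nodes = list(net.graph.nodes)
    missing = [v for v in nodes if v not in w]
    if missing:
        raise ValueError(f"no weight for network node {missing[0]!r}")
    mf = set(nodes) if functional_set is None else \
        set(functional_set) & set(nodes)
    F = _weighted_betweenness(net.graph, w, mf)
    f_vals = np.array([F[v] for v in nodes], dtype=float)
    f_min, f_max = (f_vals.min(), f_vals.max()) if len(f_vals) else (0.0,
                                                                     0.0)
    if f_max > f_min:
        b_std = (f_vals - f_min) / (f_max - f_min)
    else:
        logger.warning("keystoneness constant across network; all B' = 0")
        b_std = np.zeros_like(f_vals)
    groups = net.node_groups()
    return pd.DataFrame({
        "otu_id": nodes,
        "group": [groups[v] for v in nodes],
        "w": [w[v] for v in nodes],
        "F": f_vals,
        "B_std": b_std,
        "functional_set_member": [v in mf for v in nodes],
    }).set_index("otu_id")


@dataclass
class AdjacencyProjection:
    """Binary adjacency of the thresholded network with degree (R),
    shared-neighbor (S) counts and network size N_I."""

    otus: list[str]
    adjacency: np.ndarray      # int8, symmetric, zero diagonal
    degrees: np.ndarray        # R_i, int64
    shared: np.ndarray         # S_ij, int64
    n_nodes: int               # N_I


def project_adjacency(net: FieldNetwork) -> AdjacencyProjection:
    """Project the network into its binary adjacency matrix.

    R_i is node i's degree (row sum); S_ij counts neighbors shared by i and
    j; N_I is the number of nodes in the projected network (all candidate
    OTUs, isolated included).
    """
    otus = list(net.graph.nodes)
    a = nx.to_numpy_array(net.graph, nodelist=otus, dtype=np.int64,
                          weight=None)
    degrees = a.sum(axis=1).astype(np.int64)
    shared = (a @ a).astype(np.int64)
    return AdjacencyProjection(otus, a.astype(np.int8), degrees, shared,
                               len(otus))


def pair_scores(net: FieldNetwork, keystones: pd.DataFrame,
                projection: AdjacencyProjection | None = None
                ) -> pd.DataFrame:
    """Checkerboard/togetherness scores and reinforcement indices for every
    linked pair.

    The exact identity C - T = R_i R_j - N_I S_ij is asserted for every
    pair; a violation indicates an internal bug.
    """
    proj = projection if projection is not None else project_adjacency(net)
    idx = {o: k for k, o in enumerate(proj.otus)}
    groups = net.node_groups()
    b_std = keystones["B_std"]
    rows = []
    for oi, oj in net.graph.edges:
        i, j = idx[oi], idx[oj]
        r_i = int(proj.degrees[i])
        r_j = int(proj.degrees[j])
        s_ij = int(proj.shared[i, j])
        c = (r_i - s_ij) * (r_j - s_ij)
        t = s_ij * (proj.n_nodes + s_ij - r_i - r_j)
        if c - t != r_i * r_j - proj.n_nodes * s_ij:
            raise AssertionError(
                f"checkerboard/togetherness identity violated for pair "
                f"({oi}, {oj}): C-T={c - t}, "
                f"RiRj-N*S={r_i * r_j - proj.n_nodes * s_ij}")
        gi, gj = groups[oi], groups[oj]
        ga, gb = sorted((gi, gj))
        bi = float(b_std[oi])
        bj = float(b_std[oj])
        rows.append({
            "otu_i": oi, "otu_j": oj, "group_i": gi, "group_j": gj,
            "group_pair": f"{ga}|{gb}",
            "interaction_type": "within" if gi == gj else "between",
            "R_i": r_i, "R_j": r_j, "S_ij": s_ij, "N_I": proj.n_nodes,
            "C": c, "T": t,
            "B_i": bi, "B_j": bj,
            "R_checker": bi * bj * c,
            "R_together": bi * bj * t,
        })
    return pd.DataFrame(rows)


_VARIANT_COLS = {"checker": ("R_checker", "C"),
                 "together": ("R_together", "T")}


@dataclass
class CoreMicrobiome:
    """Top-ranked core pairs per variant plus a group-pair summary."""

    top_pairs: dict[tuple[str, str], pd.DataFrame]  # (variant, type) ->
    members: list[str]
    summary: pd.DataFrame
    k_between: int
    k_within: int

    def member_degrees(self) -> pd.Series:
        degree: dict[str, int] = {}
        for frame in self.top_pairs.values():
            for _, row in frame.iterrows():
                degree[row["otu_i"]] = degree.get(row["otu_i"], 0) + 1
                degree[row["otu_j"]] = degree.get(row["otu_j"], 0) + 1
        return pd.Series(degree, name="degree").sort_index()


def _select_top(pairs: pd.DataFrame, variant: str, interaction: str,
                k: int) -> pd.DataFrame:
    index_col, score_col = _VARIANT_COLS[variant]
    sub = pairs.loc[pairs["interaction_type"] == interaction].copy()
    if len(sub) < k:
        logger.warning("only %d %s-group pairs available (requested %d)",
                       len(sub), interaction, k)
    sub = sub.sort_values(
        by=[index_col, score_col, "otu_i", "otu_j"],
        ascending=[False, False, True, True], kind="mergesort")
    return sub.head(k).reset_index(drop=True)


def rank_core(pairs: pd.DataFrame, k_between: int = 15,
              k_within: int = 10) -> CoreMicrobiome:
    """Rank pairs by reinforcement index and nominate the core microbiome.

    Ties on the index break by the raw C (or T) score, then lexicographic
    OTU ids, so output is deterministic. The summary follows the
    group-pair layout: the sum of each index over all linked pairs of the
    group pair, and its mean over the selected core pairs (NaN where the
    group pair contributes no core pair; ``absent`` where it has no linked
    pairs at all).
    """
    if pairs.empty:
        raise ValueError("no scored pairs to rank")
    top: dict[tuple[str, str], pd.DataFrame] = {}
    for variant in ("checker", "together"):
        for interaction, k in (("between", k_between), ("within", k_within)):
            top[(variant, interaction)] = _select_top(pairs, variant,
                                                      interaction, k)
    members = sorted({o for frame in top.values()
                      for o in pd.concat([frame["otu_i"],
                                          frame["otu_j"]])})
    rows = []
    for group_pair, sub in pairs.groupby("group_pair"):
        interaction = sub["interaction_type"].iloc[0]
        row = {"group_pair": group_pair, "interaction_type": interaction,
               "n_pairs": len(sub)}
        for variant in ("checker", "together"):
            index_col = _VARIANT_COLS[variant][0]
            row[f"sum_{variant}"] = float(sub[index_col].sum())
            core = top[(variant, interaction)]
            core_sub = core.loc[core["group_pair"] == group_pair]
            row[f"core_mean_{variant}"] = (
                float(core_sub[index_col].mean()) if len(core_sub)
                else np.nan)
            row[f"n_core_{variant}"] = len(core_sub)
        rows.append(row)
    summary = pd.DataFrame(rows).sort_values(
        ["interaction_type", "group_pair"]).reset_index(drop=True)
    return CoreMicrobiome(top, members, summary, k_between, k_within)


def core_abundance(table: OtuTable, core: CoreMicrobiome) -> pd.DataFrame:
    """Relative abundances restricted to core-microbiome members."""
    present = [o for o in core.members if o in table.abundance.columns]
    return table.abundance[present]
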