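"""Co-occurrence network construction and connectance.

Networks are built per field (11 samples in the default design) or globally
across all samples: Spearman rank correlations between every pair of
candidate OTUs, with edges retained where rho exceeds a threshold (0.8 by
default, positive correlations only). Connectance — the percentage of strong
correlations among all candidate pairs — is the group-level interaction
strength used throughout the analysis.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .data_io import MAIN_GROUPS, OtuTable

logger = logging.getLogger("corepair")


@dataclass
class FieldNetwork:
    """Thresholded Spearman co-occurrence graph for one scope.

    ``graph`` holds every candidate OTU as a node (group label attached),
    including isolated ones; edges carry ``rho`` and ``p``.
    ``candidate_pairs`` is the connectance denominator: the number of OTU
    pairs for which a correlation was actually computed.
    """

    scope: str
    graph: nx.Graph
    threshold: float
    candidate_pairs: int
    edges: pd.DataFrame = dc_field(repr=False, default=None)

    @property
    def candidate_otus(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def node_groups(self) -> dict[str, str]:
        return nx.get_node_attributes(self.graph, "group")

    def connectance_pct(self) -> float:
        """Whole-network connectance: 100 x strong edges / candidate pairs."""
        if self.candidate_pairs == 0:
            return float("nan")
        return 100.0 * self.n_edges / self.candidate_pairs


def spearman_matrix(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs Spearman rho and two-sided p for columns of ``values``.

    Average ranks for ties; p from the t approximation on n - 2 degrees of
    freedom (the convention of scipy.stats.spearmanr).
    """
    n = values.shape[0]
    ranks = np.apply_along_axis(stats.rankdata, 0, values)
    rho = np.corrcoef(ranks, rowvar=False)
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isnan(t), np.where(np.isnan(rho), np.nan, 0.0), p)
    return rho, p


def _candidate_mask(values: np.ndarray, min_count: int) -> np.ndarray:
    prevalent = (values > 0).sum(axis=0) >= min_count
    non_constant = values.std(axis=0) > 0
    return prevalent & non_constant


def _build(table: OtuTable, scope: str, min_count: int, threshold: float,
           absolute: bool, fdr_q: float | None) -> FieldNetwork:
    values = table.abundance.to_numpy(dtype=float)
    n_samples = values.shape[0]
    if n_samples < 4:
        raise ValueError(
            f"scope {scope!r} has {n_samples} samples; rank correlation "
            "needs at least 4")
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    mask = _candidate_mask(values, min_count)
    otus = [o for o, keep in zip(table.otu_ids, mask) if keep]
    groups = table.taxonomy
    graph = nx.Graph()
    for o in otus:
        graph.add_node(o, group=groups[o])
    k = len(otus)
    candidate_pairs = k * (k - 1) // 2
    if k == 0:
        logger.warning("scope %s: zero candidate OTUs after filtering",
                       scope)
        return FieldNetwork(scope, graph, threshold, 0,
                            pd.DataFrame(columns=["otu_i", "otu_j",
                                                  "rho", "p"]))
    rho, p = spearman_matrix(values[:, mask])
    iu, ju = np.triu_indices(k, 1)
    rho_u, p_u = rho[iu, ju], p[iu, ju]
    strength = np.abs(rho_u) if absolute else rho_u
    keep = strength > threshold
    if fdr_q is not None:
        from statsmodels.stats.multitest import multipletests
        reject, *_ = multipletests(p_u, alpha=fdr_q, method="fdr_bh")
        keep &= reject
    edge_rows = []
    for a, b, r_val, p_val in zip(iu[keep], ju[keep], rho_u[keep],
                                  p_u[keep]):
        oi, oj = otus[a], otus[b]
        graph.add_edge(oi, oj, rho=float(r_val), p=float(p_val))
        edge_rows.append((oi, oj, float(r_val), float(p_val)))
    edges = pd.DataFrame(edge_rows, columns=["otu_i", "otu_j", "rho", "p"])
    return FieldNetwork(scope, graph, threshold, candidate_pairs, edges)


def build_field_network(table: OtuTable, field_id: str = "field",
                        min_prevalence: float = 0.5,
                        threshold: float = 0.8,
                        absolute: bool = False,
                        fdr_q: float | None = None) -> FieldNetwork:
    """Network for one field's samples.

    Candidate OTUs are those detected (abundance > 0) in at least
    ``min_prevalence`` of the field's samples and non-constant across them.
    """
    n = table.abundance.shape[0]
    min_count = math.ceil(min_prevalence * n)
    return _build(table, field_id, min_count, threshold, absolute, fdr_q)


def build_global_network(table: OtuTable, min_samples: int | None = None,
                         threshold: float = 0.8, absolute: bool = False,
                         fdr_q: float | None = None) -> FieldNetwork:
    """Network across all samples; prevalence filter is an absolute count.

    The default keeps OTUs detected in at least half the samples (ceil(n/2),
    e.g. 215 of 429).
    """
    n = table.abundance.shape[0]
    if min_samples is None:
        min_samples = math.ceil(n / 2)
    return _build(table, "global", min_samples, threshold, absolute, fdr_q)


def group_connectance(net: FieldNetwork) -> pd.DataFrame:
    """Connectance per group pair (including same-group pairs).

    possible = n_m * n_n for distinct groups m, n with n_m, n_n candidate
    OTUs; k(k-1)/2 within a group with k candidates. Group pairs with zero
    possible pairs are flagged absent (the "/" entries of the interaction
    maps).
    """
    node_groups = net.node_groups()
    counts = {g: 0 for g in MAIN_GROUPS}
    for g in node_groups.values():
        counts[g] = counts.get(g, 0) + 1
    strong = {}
    for u, v in net.graph.edges:
        key = tuple(sorted((node_groups[u], node_groups[v])))
        strong[key] = strong.get(key, 0) + 1
    rows = []
    present_groups = [g for g in MAIN_GROUPS if counts.get(g, 0) >= 0]
    for a, b in itertools.combinations_with_replacement(present_groups, 2):
        key = tuple(sorted((a, b)))
        if a == b:
            possible = counts[a] * (counts[a] - 1) // 2
        else:
            possible = counts[a] * counts[b]
        s = strong.get(key, 0)
        rows.append({
            "group_i": key[0], "group_j": key[1],
            "interaction_type": "within" if a == b else "between",
            "strong_count": s, "possible_count": possible,
            "connectance_pct": (100.0 * s / possible if possible else
                                float("nan")),
            "absent": possible == 0})
    return pd.DataFrame(rows)


def zone_summary(nets: dict[str, FieldNetwork], metadata: pd.DataFrame,
                 tukey: bool = True) -> pd.DataFrame:
    """Per-zone mean and sample SD of strong counts, candidate pairs and
    whole-network connectance over the zone's field networks.

    With Tukey letters (zones sharing a letter do not differ at alpha=0.05)
    attached when at least two zones have replicate fields.
    """
    field_zone = (metadata.drop_duplicates("field_id")
                  .set_index("field_id")["zone"])
    rows = []
    for fid, net in nets.items():
        rows.append({"field_id": fid, "zone": field_zone[fid],
                     "strong": net.n_edges,
                     "possible": net.candidate_pairs,
                     "connectance_pct": net.connectance_pct()})
    per_field = pd.DataFrame(rows)
    summary = per_field.groupby("zone").agg(
        n_fields=("field_id", "size"),
        strong_mean=("strong", "mean"), strong_sd=("strong", "std"),
        possible_mean=("possible", "mean"), possible_sd=("possible", "std"),
        connectance_mean=("connectance_pct", "mean"),
        connectance_sd=("connectance_pct", "std")).reset_index()
    if tukey and per_field["zone"].nunique() >= 2 and \
            (per_field.groupby("zone").size() >= 2).any():
        from .association import anova_tukey
        try:
            result = anova_tukey(per_field["connectance_pct"].to_numpy(),
                                 per_field["zone"].to_numpy())
            summary["letters"] = summary["zone"].map(result.letters)
        except ValueError:
            summary["letters"] = ""
    return summary


def write_edge_list(net: FieldNetwork, path: str | Path) -> None:
    net.edges.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_graphml(net: FieldNetwork, path: str | Path) -> None:
    nx.write_graphml(net.graph, str(path))


def read_edge_list(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"otu_i": str, "otu_j": str})
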