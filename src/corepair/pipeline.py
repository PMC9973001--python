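"""End-to-end convenience pipeline.

Wires the stages together for a complete study: per-field networks and
connectance, emission profiles, function weights, keystoneness, pair
scoring and core ranking. Each stage is importable on its own; this module
just sequences them with consistent defaults.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .contribution import (connectance_features, contribution_by_scope,
                           ContributionResult)
from .core_id import (CoreMicrobiome, function_weights, group_interaction_effects,
                      keystoneness, pair_scores, rank_core)
from .data_io import OtuTable
from .emission import field_means, profiles_from_fluxes
from .network import (FieldNetwork, build_field_network,
                      build_global_network)


@dataclass
class StudyResult:
    field_networks: dict[str, FieldNetwork]
    global_network: FieldNetwork
    connectances: pd.DataFrame          # fields x group-pair strengths
    profiles: pd.DataFrame              # per-sample emission profiles
    field_profiles: pd.DataFrame        # per-field means
    keystones: pd.DataFrame
    pairs: pd.DataFrame
    core: CoreMicrobiome
    contributions: dict[str, ContributionResult]


def field_networks(table: OtuTable, metadata: pd.DataFrame,
                   min_prevalence: float = 0.5, threshold: float = 0.8,
                   absolute: bool = False) -> dict[str, FieldNetwork]:
    """One thresholded co-occurrence network per field."""
    nets = {}
    meta = metadata.set_index("sample_id") \
        if metadata.index.name != "sample_id" else metadata
    for fid, sub in meta.groupby("field_id", sort=True):
        field_table = table.restrict_samples(list(sub.index))
        nets[fid] = build_field_network(field_table, field_id=str(fid),
                                        min_prevalence=min_prevalence,
                                        threshold=threshold,
                                        absolute=absolute)
    return nets


def run_study(table: OtuTable, metadata: pd.DataFrame, fluxes: pd.DataFrame,
              metric: str = "potential", threshold: float = 0.8,
              min_prevalence: float = 0.5, k_between: int = 15,
              k_within: int = 10, q10_method: str = "loglinear",
              n_trees: int = 1000, seed: int = 0) -> StudyResult:
    """Run the full analysis for one emission metric.

    ``metric`` selects the response: "potential" (rate at 25 C) or
    "temp_sensitivity_cv".
    """
    nets = field_networks(table, metadata, min_prevalence, threshold)
    global_net = build_global_network(table, threshold=threshold)
    connectances = connectance_features(nets)
    profiles = profiles_from_fluxes(fluxes, q10_method=q10_method)
    per_field = field_means(profiles, metadata)
    field_metric = per_field[metric]
    effects = group_interaction_effects(connectances, field_metric)
    sample_metric = profiles[metric]
    weights = function_weights(table, sample_metric, effects)
    keystones = keystoneness(global_net, weights)
    pairs = pair_scores(global_net, keystones)
    core = rank_core(pairs, k_between=k_between, k_within=k_within)
    contributions = contribution_by_scope(connectances, field_metric,
                                          n_trees=n_trees, seed=seed)
    return StudyResult(nets, global_net, connectances, profiles, per_field,
                       keystones, pairs, core, contributions)
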