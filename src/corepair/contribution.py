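"""Within- vs between-group contribution to emission variation.

Random-forest regressions of a per-field emission metric on the per-field
group-pair interaction strengths, reporting the percent variance explained
(PVE) from out-of-bag predictions: 100 x (1 - MSE_oob / Var(response)).
Within-group and between-group feature sets are disjoint by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .network import FieldNetwork, group_connectance

logger = logging.getLogger("corepair")


@dataclass
class ContributionResult:
    feature_set: str            # "within" or "between"
    percent_variance_explained: float
    n_features: int
    n_observations: int
    seed: int
    mode: str = "oob"           # "oob" or "training"
    importances: pd.Series | None = None


def connectance_features(nets: dict[str, FieldNetwork]) -> pd.DataFrame:
    """Per-field group-pair interaction strengths, wide layout.

    Rows = fields, columns = "groupA|groupB" connectance percentages.
    Group pairs absent in a field (zero possible pairs) are imputed 0 and
    recorded in ``frame.attrs['imputed']``.
    """
    rows = {}
    imputed: list[tuple[str, str]] = []
    for fid, net in nets.items():
        conn = group_connectance(net)
        vals = {}
        for _, r in conn.iterrows():
            key = f"{r['group_i']}|{r['group_j']}"
            if r["absent"]:
                vals[key] = 0.0
                imputed.append((fid, key))
            else:
                vals[key] = float(r["connectance_pct"])
        rows[fid] = vals
    frame = pd.DataFrame.from_dict(rows, orient="index").fillna(0.0)
    frame.index.name = "field_id"
    frame.attrs["imputed"] = imputed
    if imputed:
        logger.info("imputed 0 for %d absent field x group-pair "
                    "combinations", len(imputed))
    return frame


def build_feature_matrix(connectances: pd.DataFrame,
                         scope: str) -> pd.DataFrame:
    """Restrict the wide connectance table to within- or between-group
    columns (disjoint feature sets)."""
    if scope not in ("within", "between"):
        raise ValueError("scope must be 'within' or 'between'")
    if len(connectances) < 5:
        raise ValueError("need at least 5 fields")
    cols = []
    for col in connectances.columns:
        a, b = col.split("|")
        if (a == b) == (scope == "within"):
            cols.append(col)
    features = connectances[cols]
    if features.empty or not features.to_numpy().any():
        raise ValueError(f"the {scope}-group feature set is all zero")
    return features


def percent_variance_explained(features: pd.DataFrame,
                               response: pd.Series | np.ndarray,
                               n_trees: int = 1000,
                               seed: int = 0,
                               feature_set: str = "",
                               mode: str = "oob") -> ContributionResult:
    """Random-forest PVE of the response from the feature matrix.

    ``oob`` (default) reports 100 x the out-of-bag R-squared, which can be
    negative when the model predicts worse than the response mean;
    ``training`` reports the in-sample fit instead.
    """
    x = np.asarray(features, dtype=float)
    if isinstance(response, pd.Series):
        response = response.loc[features.index] \
            if isinstance(features, pd.DataFrame) else response
        y = response.to_numpy(dtype=float)
    else:
        y = np.asarray(response, dtype=float)
    if len(y) != len(x):
        raise ValueError("features and response are misaligned")
    if np.std(y) == 0:
        raise ValueError("constant response; explained variance undefined")
    max_features = max(1, x.shape[1] // 3)
    forest = RandomForestRegressor(
        n_estimators=n_trees, max_features=max_features,
        oob_score=(mode == "oob"), bootstrap=True, random_state=seed,
        n_jobs=1)
    forest.fit(x, y)
    if mode == "oob":
        pve = 100.0 * float(forest.oob_score_)
    elif mode == "training":
        pve = 100.0 * float(forest.score(x, y))
    else:
        raise ValueError("mode must be 'oob' or 'training'")
    names = (list(features.columns)
             if isinstance(features, pd.DataFrame)
             else [f"f{k}" for k in range(x.shape[1])])
    importances = pd.Series(forest.feature_importances_, index=names,
                            name="importance")
    return ContributionResult(feature_set or "features", pve, x.shape[1],
                              len(y), seed, mode, importances)


def contribution_by_scope(connectances: pd.DataFrame,
                          response: pd.Series, n_trees: int = 1000,
                          seed: int = 0, mode: str = "oob"
                          ) -> dict[str, ContributionResult]:
    """PVE for the within- and between-group feature sets."""
    out = {}
    for scope in ("between", "within"):
        features = build_feature_matrix(connectances, scope)
        out[scope] = percent_variance_explained(
            features, response, n_trees=n_trees, seed=seed,
            feature_set=scope, mode=mode)
    return out
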