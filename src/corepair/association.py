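"""Statistical linkage of network structure to emission metrics.

Spearman correlations between group-pair interaction strengths and emission
metrics, rank-based partial correlations controlling for climate and soil
covariates, one-way ANOVA with Tukey HSD compact letter displays for zone
comparisons, and the Mantel permutation test linking core-microbiome
dissimilarity to nitrogen-cycle gene profiles.
"""

from __future__ import annotations

import itertools
import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform


@dataclass
class AssociationResult:
    predictor: str
    response: str
    r: float
    p: float
    method: str
    controls: list[str] = field(default_factory=list)
    n: int = 0


def correlate_strengths(connectances: pd.DataFrame,
                        emissions: pd.DataFrame,
                        alpha: float = 0.05,
                        bh: bool = False) -> pd.DataFrame:
    """Spearman r and two-sided p per group-pair x emission metric.

    ``connectances``: rows = fields, columns = group-pair strengths.
    ``emissions``: rows = fields (same index), columns = metrics.
    Constant predictors are flagged undefined rather than dropped.
    """
    common = connectances.index.intersection(emissions.index)
    if len(common) < 5:
        raise ValueError("need at least 5 fields with both values")
    conn = connectances.loc[common]
    emis = emissions.loc[common]
    rows = []
    for pair_name in conn.columns:
        x = conn[pair_name].to_numpy(dtype=float)
        for metric in emis.columns:
            y = emis[metric].to_numpy(dtype=float)
            if np.std(x) == 0 or np.std(y) == 0:
                rows.append({"predictor": pair_name, "response": metric,
                             "r": np.nan, "p": np.nan, "n": len(common),
                             "undefined": True, "significant": False})
                continue
            r, p = stats.spearmanr(x, y)
            rows.append({"predictor": pair_name, "response": metric,
                         "r": float(r), "p": float(p), "n": len(common),
                         "undefined": False, "significant": False})
    out = pd.DataFrame(rows)
    defined = ~out["undefined"]
    if bh and defined.any():
        from statsmodels.stats.multitest import multipletests
        reject, q, *_ = multipletests(out.loc[defined, "p"], alpha=alpha,
                                      method="fdr_bh")
        out.loc[defined, "significant"] = reject
        out.loc[defined, "q"] = q
    else:
        out.loc[defined, "significant"] = out.loc[defined, "p"] < alpha
    return out


def partial_spearman(x, y, controls=None,
                     names: tuple[str, str] = ("x", "y"),
                     control_names: list[str] | None = None
                     ) -> AssociationResult:
    """Rank-based partial correlation of x and y given controls.

    All variables are rank-transformed (average ranks for ties); the x and
    y ranks are residualized on the control ranks (with intercept) by least
    squares, and the Pearson correlation of the residuals is returned with
    a t-distributed p-value on n - k - 2 degrees of freedom. With no
    controls this reduces exactly to the Spearman correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if controls is None:
        z = np.empty((len(x), 0))
    else:
        z = np.asarray(controls, dtype=float)
        if z.ndim == 1:
            z = z[:, None]
    k = z.shape[1]
    n = len(x)
    if n < k + 4:
        raise ValueError(f"need at least {k + 4} observations for "
                         f"{k} control(s)")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    design = np.column_stack([np.ones(n)] +
                             [stats.rankdata(z[:, j]) for j in range(k)])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("control variables are collinear (rank-deficient "
                         "design)")
    beta_x, *_ = np.linalg.lstsq(design, rx, rcond=None)
    beta_y, *_ = np.linalg.lstsq(design, ry, rcond=None)
    ex = rx - design @ beta_x
    ey = ry - design @ beta_y
    denom = np.sqrt(np.sum(ex ** 2) * np.sum(ey ** 2))
    if denom == 0:
        raise ValueError("residuals are constant; correlation undefined")
    r = float(np.sum(ex * ey) / denom)
    r = max(-1.0, min(1.0, r))
    df = n - k - 2
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r ** 2))
        p = float(2.0 * stats.t.sf(abs(t), df=df))
    ctrl = control_names if control_names is not None else \
        [f"z{j + 1}" for j in range(k)]
    return AssociationResult(names[0], names[1], r, p,
                             "partial_spearman" if k else "spearman",
                             ctrl, n)


def _compact_letter_display(groups: list[str],
                            significant_pairs: set[tuple[str, str]]
                            ) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Groups sharing a letter are not significantly different. Deterministic
    in the sorted group order, so letters are invariant to input ordering.
    """
    order = sorted(groups)
    sets: list[set[str]] = [set(order)]
    for a, b in sorted(significant_pairs):
        new_sets: list[set[str]] = []
        for s in sets:
            if a in s and b in s:
                new_sets.append(s - {a})
                new_sets.append(s - {b})
            else:
                new_sets.append(s)
        # absorb duplicates and subsets
        pruned: list[set[str]] = []
        for s in new_sets:
            if any(s <= t for t in pruned) or \
                    any(s < t for t in new_sets):
                continue
            if s and s not in pruned:
                pruned.append(s)
        sets = pruned
    sets.sort(key=lambda s: min(order.index(g) for g in s))
    letters = {g: "" for g in order}
    for letter, s in zip(string.ascii_lowercase, sets):
        for g in sorted(s):
            letters[g] += letter
    return letters


@dataclass
class TukeyResult:
    f_statistic: float
    p_value: float
    pairwise: pd.DataFrame
    letters: dict[str, str]


def anova_tukey(values, groups, alpha: float = 0.05) -> TukeyResult:
    """One-way ANOVA plus Tukey HSD with a compact letter display."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups, dtype=object)
    labels = sorted(set(groups))
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    by_group = [values[groups == g] for g in labels]
    if all(len(v) < 2 for v in by_group):
        raise ValueError("all groups are singletons; no within-group "
                         "variance")
    f_stat, p_val = stats.f_oneway(*by_group)
    from statsmodels.stats.multicomp import pairwise_tukeyhsd
    tukey = pairwise_tukeyhsd(values, groups, alpha=alpha)
    frame = pd.DataFrame(tukey.summary().data[1:],
                         columns=tukey.summary().data[0])
    significant = {tuple(sorted((str(r["group1"]), str(r["group2"]))))
                   for _, r in frame.iterrows() if bool(r["reject"])}
    letters = _compact_letter_display(labels, significant)
    return TukeyResult(float(f_stat), float(p_val), frame, letters)


def _check_square(d: np.ndarray, name: str) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError(f"{name} must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError(f"{name} must be symmetric")
    return d


def mantel(core_dissim, gene_dist, n_perm: int = 999,
           seed: int | None = None,
           rng: np.random.Generator | None = None) -> AssociationResult:
    """Mantel test between two distance matrices.

    Statistic: Pearson correlation of the lower triangles. p-value: add-one
    permutation estimate under joint row/column permutation of the second
    matrix, one-sided for positive association.

    DataFrames with ids are checked for matching index/columns.
    """
    ids1 = ids2 = None
    if isinstance(core_dissim, pd.DataFrame):
        ids1 = list(core_dissim.index)
        core_dissim = core_dissim.to_numpy()
    if isinstance(gene_dist, pd.DataFrame):
        ids2 = list(gene_dist.index)
        gene_dist = gene_dist.to_numpy()
    if ids1 is not None and ids2 is not None and ids1 != ids2:
        raise ValueError("distance matrices have mismatched sample ids")
    d1 = _check_square(core_dissim, "core_dissim")
    d2 = _check_square(gene_dist, "gene_dist")
    if d1.shape != d2.shape:
        raise ValueError("distance matrices differ in size")
    n = d1.shape[0]
    il = np.tril_indices(n, -1)
    v1 = d1[il]
    if rng is None:
        rng = np.random.default_rng(seed)

    def _corr(v2: np.ndarray) -> float:
        if v1.std() == 0 or v2.std() == 0:
            return np.nan
        return float(np.corrcoef(v1, v2)[0, 1])

    observed = _corr(d2[il])
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        permuted = d2[np.ix_(perm, perm)]
        if _corr(permuted[il]) >= observed:
            count += 1
    p = (1.0 + count) / (1.0 + n_perm)
    return AssociationResult("core_dissim", "gene_dist", observed, p,
                             "mantel", [], n)


def bray_curtis(abundance: pd.DataFrame) -> pd.DataFrame:
    """Bray-Curtis dissimilarity between samples (rows)."""
    d = squareform(pdist(abundance.to_numpy(dtype=float),
                         metric="braycurtis"))
    return pd.DataFrame(d, index=abundance.index, columns=abundance.index)


def euclidean(matrix: pd.DataFrame) -> pd.DataFrame:
    """Euclidean distance between samples (rows)."""
    d = squareform(pdist(matrix.to_numpy(dtype=float), metric="euclidean"))
    return pd.DataFrame(d, index=matrix.index, columns=matrix.index)


def gene_profile_matrix(genes: pd.DataFrame) -> pd.DataFrame:
    """Pivot a long gene-signal table to samples x probes."""
    return genes.pivot_table(index="sample_id", columns="probe_id",
                             values="intensity", aggfunc="mean")
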