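"""Synthetic multi-trophic study generator.

Emulates a nested paddy-field survey: four climatic zones spanning a mean
annual temperature (MAT) gradient, several fields per zone, 11 composite
samples per field, and OTUs from five main groups (archaea, bacteria,
fungi, algae, microfauna). Abundances come from a latent Gaussian copula
with log-normal marginals closed to relative abundance, so planted latent
correlations survive as Spearman correlations (monotone-invariant) up to
compositional closure. Ground truth — core pairs, function loadings, the
per-zone Q10 — is returned alongside the data so recovery can be tested.

N2O fluxes follow an exponential temperature response around the 25 C
incubation optimum with multiplicative log-normal noise; the baseline is an
affine function of the function-loaded OTU abundances plus a zone effect
that rises exponentially with MAT.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_io import (GENES, INCUBATION_TEMPS, MAIN_GROUPS, ZONES, OtuTable,
                      validate_metadata)

_GROUP_PREFIX = {"archaea": "arc", "bacteria": "bac", "fungi": "fun",
                 "algae": "alg", "microfauna": "fau"}

#: Per-zone Q10 defaults on the midtemperate-to-tropical gradient.
DEFAULT_Q10_BY_ZONE = {"midtemperate": 1.67, "warm-temperate": 2.14,
                       "subtropical": 2.85, "tropical": 2.45}


@dataclass
class StudyDesign:
    """Shape of the synthetic survey."""

    n_zones: int = 4
    fields_per_zone: int = 3
    samples_per_field: int = 11
    otus_per_group: Mapping[str, int] = field(default_factory=lambda: {
        "archaea": 35, "bacteria": 65, "fungi": 35, "algae": 32,
        "microfauna": 33})
    mat_range: tuple[float, float] = (1.5, 23.8)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_zones < 1 or self.n_zones > len(ZONES):
            raise ValueError(f"n_zones must be in [1, {len(ZONES)}]")
        if self.fields_per_zone < 1 or self.samples_per_field < 1:
            raise ValueError("field and sample counts must be >= 1")
        if any(c < 1 for c in self.otus_per_group.values()):
            raise ValueError("every group needs >= 1 OTU")
        if not self.mat_range[0] < self.mat_range[1]:
            raise ValueError("MAT range must be increasing")

    @property
    def n_fields(self) -> int:
        return self.n_zones * self.fields_per_zone

    @property
    def n_samples(self) -> int:
        return self.n_fields * self.samples_per_field

    @property
    def n_otus(self) -> int:
        return sum(self.otus_per_group.values())

    def zones(self) -> tuple[str, ...]:
        return ZONES[:self.n_zones]


@dataclass
class PlantedStructure:
    """Ground truth planted into a synthetic study.

    ``core_pairs`` are function-linked OTU pairs: each pair gets a high
    latent correlation (default 0.93) plus a module of shared neighbors
    (latent correlation ``intensity`` with both members) and a few private
    neighbors per member, so the pair is a genuine network hub pair.
    ``function_loadings`` tie member abundances to the emission baseline.
    """

    core_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    function_loadings: dict[str, float] = field(default_factory=dict)
    block_correlations: dict[tuple[str, str], float] | None = None
    q10_true: Mapping[str, float] | float = field(
        default_factory=lambda: dict(DEFAULT_Q10_BY_ZONE))
    noise_cv: float = 0.10
    pair_rho: float = 0.90
    private_rho: float = 0.84
    private_cross_rho: float = 0.62
    n_shared_neighbors: int = 5
    n_private_neighbors: int = 3
    background_zone_gradient: tuple[float, float] = (0.6, 1.4)
    module_zone_shift: float = 0.5
    loaded_mu_offset: float = -0.8
    emission_base: float = 2.0
    mat_slope: float = 0.08
    loading_scale: float = 60.0
    gene_linkage: float = 5.0
    modules: dict[tuple[str, str], dict[str, list[str]]] = field(
        default_factory=dict)

    def __post_init__(self) -> None:
        q10s = (self.q10_true.values()
                if isinstance(self.q10_true, Mapping) else [self.q10_true])
        if any(q <= 0 for q in q10s):
            raise ValueError("q10_true must be positive")
        if self.block_correlations is not None and \
                any(abs(r) > 1 for r in self.block_correlations.values()):
            raise ValueError("|target rho| must be <= 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if not 0 < self.pair_rho < 1:
            raise ValueError("pair_rho must be in (0, 1)")

    def resolved_block_correlations(self) -> dict[tuple[str, str], float]:
        """Background group-block latent correlations (before the zone
        multiplier). ``None`` means the defaults; pass an explicit map
        (possibly empty) to override."""
        if self.block_correlations is not None:
            return dict(self.block_correlations)
        out: dict[tuple[str, str], float] = {}
        for a in MAIN_GROUPS:
            for b in MAIN_GROUPS:
                out[(a, b)] = 0.55 if a == b else 0.50
        return out

    def q10_for_zone(self, zone: str) -> float:
        if isinstance(self.q10_true, Mapping):
            return float(self.q10_true[zone])
        return float(self.q10_true)


def _otu_ids(design: StudyDesign) -> tuple[list[str], dict[str, str]]:
    ids, taxonomy = [], {}
    for group in MAIN_GROUPS:
        count = design.otus_per_group.get(group, 0)
        for i in range(count):
            oid = f"{_GROUP_PREFIX[group]}_{i + 1:03d}"
            ids.append(oid)
            taxonomy[oid] = group
    return ids, taxonomy


def default_structure(design: StudyDesign, n_core_pairs: int = 10,
                      group_pairs: Sequence[tuple[str, str]] | None = None,
                      **overrides) -> PlantedStructure:
    """Plant ``n_core_pairs`` between-group core pairs with modules.

    Pairs cycle round-robin over the distinct between-group combinations
    (or the supplied ``group_pairs``) so no single group's OTU pool is
    exhausted. Members, shared neighbors and private neighbors are
    allocated from the front of each group's pool deterministically, so the
    same design always yields the same ground truth. Neighbor OTUs are
    drawn from the two member groups alternately so member-neighbor edges
    mix within- and between-group links.
    """
    import itertools as _it

    structure = PlantedStructure(**overrides)
    ids, taxonomy = _otu_ids(design)
    by_group = {g: [o for o in ids if taxonomy[o] == g] for g in MAIN_GROUPS}
    if group_pairs is None:
        group_pairs = [pair for pair in _it.combinations(MAIN_GROUPS, 2)]
    cursor = {g: 0 for g in MAIN_GROUPS}

    def take(group: str) -> str:
        pool = by_group[group]
        if cursor[group] >= len(pool):
            raise ValueError(
                f"group {group!r} has too few OTUs for the requested "
                f"planted structure")
        otu = pool[cursor[group]]
        cursor[group] += 1
        return otu

    for pair_index in range(n_core_pairs):
        ga, gb = group_pairs[pair_index % len(group_pairs)]
        i, j = take(ga), take(gb)
        shared = [take(ga if k % 2 else gb)
                  for k in range(structure.n_shared_neighbors)]
        priv_i = [take(ga) for _ in range(structure.n_private_neighbors)]
        priv_j = [take(gb) for _ in range(structure.n_private_neighbors)]
        structure.core_pairs.append((i, j, 0.88))
        structure.modules[(i, j)] = {
            "shared": shared, "private_i": priv_i, "private_j": priv_j}
        # the whole module is function-linked: every module OTU tracks the
        # module factor, so emission carries a coherent module signal
        structure.function_loadings[i] = 1.0
        structure.function_loadings[j] = 1.0
        for o in shared + priv_i + priv_j:
            structure.function_loadings[o] = 0.8
    return structure


def _nearest_positive_definite(corr: np.ndarray, eps: float = 1e-8,
                               max_shift: float = 0.15) -> np.ndarray:
    """Eigenvalue-clipped nearest correlation matrix.

    Raises if the repair moves any planted entry by more than ``max_shift``
    (the target correlations are then jointly infeasible).
    """
    sym = (corr + corr.T) / 2.0
    vals, vecs = np.linalg.eigh(sym)
    if vals.min() >= eps:
        return sym
    clipped = (vecs * np.maximum(vals, eps)) @ vecs.T
    d = np.sqrt(np.diag(clipped))
    repaired = clipped / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    shift = np.abs(repaired - sym).max()
    if shift > max_shift:
        raise ValueError(
            f"correlation targets are jointly infeasible (max repair shift "
            f"{shift:.3f}); lower the target rho values")
    return repaired


def _module_entries(structure: PlantedStructure, intensity: float
                    ) -> dict[str, float]:
    """Latent correlations implied by the module factor model.

    Members load on a pair factor g (loading sqrt(pair_rho)) plus a
    member-specific factor; shared neighbors load on g only; private
    neighbors load on g and their member's factor. All implied entries are
    therefore jointly positive semi-definite by construction.
    """
    a = structure.pair_rho
    sa = np.sqrt(a)
    lam = intensity / sa
    if lam > 1:
        raise ValueError(
            f"shared-neighbor intensity {intensity} exceeds sqrt(pair_rho)="
            f"{sa:.3f}; lower it or raise pair_rho")
    alpha = structure.private_cross_rho / sa
    beta = (structure.private_rho - structure.private_cross_rho) / \
        np.sqrt(1.0 - a)
    if alpha ** 2 + beta ** 2 > 1.0:
        raise ValueError(
            "private_rho/private_cross_rho targets are infeasible for "
            f"pair_rho={a}; lower private_rho or raise private_cross_rho")
    return {
        "pair": a,
        "member_shared": intensity,
        "shared_shared": lam ** 2,
        "member_private": structure.private_rho,
        "cross_private": structure.private_cross_rho,
        "private_private": alpha ** 2 + beta ** 2,
        "private_opposite": alpha ** 2,
        "shared_private": lam * alpha,
    }


def _latent_correlation(design: StudyDesign,
                        structure: PlantedStructure,
                        taxonomy: dict[str, str],
                        ids: list[str],
                        background_scale: float = 1.0) -> np.ndarray:
    n = len(ids)
    idx = {o: k for k, o in enumerate(ids)}
    corr = np.zeros((n, n))
    groups = np.array([taxonomy[o] for o in ids])
    # planted-module OTUs are tight guilds decoupled from the diffuse
    # background, so the matrix stays block positive-definite
    module_otus = {o for pair in structure.core_pairs for o in pair[:2]}
    for module in structure.modules.values():
        for members in module.values():
            module_otus.update(members)
    in_background = np.array([o not in module_otus for o in ids])
    background = structure.resolved_block_correlations()
    for a in MAIN_GROUPS:
        for b in MAIN_GROUPS:
            rho = background.get((a, b), background.get((b, a), 0.0))
            rho *= background_scale
            if rho:
                mask = np.outer((groups == a) & in_background,
                                (groups == b) & in_background)
                corr[mask] = rho
                corr[mask.T] = rho
    missing = [p for p, _, _ in structure.core_pairs if p not in idx] + \
              [q for _, q, _ in structure.core_pairs if q not in idx]
    if missing:
        raise ValueError(f"core pair OTU(s) not in design: {missing[:3]}")

    def put(a: str, b: str, rho: float) -> None:
        corr[idx[a], idx[b]] = corr[idx[b], idx[a]] = rho

    for (i, j, intensity) in structure.core_pairs:
        module = structure.modules.get((i, j))
        put(i, j, structure.pair_rho)
        if module is None:
            continue
        entries = _module_entries(structure, intensity)
        shared = module["shared"]
        priv_i = module["private_i"]
        priv_j = module["private_j"]
        for s in shared:
            put(i, s, entries["member_shared"])
            put(j, s, entries["member_shared"])
        for s_a in range(len(shared)):
            for s_b in range(s_a + 1, len(shared)):
                put(shared[s_a], shared[s_b], entries["shared_shared"])
        for member, own, other in ((i, priv_i, priv_j),
                                   (j, priv_j, priv_i)):
            for p in own:
                put(member, p, entries["member_private"])
                put(j if member == i else i, p, entries["cross_private"])
                for s in shared:
                    put(s, p, entries["shared_private"])
            for p_a in range(len(own)):
                for p_b in range(p_a + 1, len(own)):
                    put(own[p_a], own[p_b], entries["private_private"])
        for p in priv_i:
            for q in priv_j:
                put(p, q, entries["private_opposite"])
    np.fill_diagonal(corr, 1.0)
    return _nearest_positive_definite(corr)


def generate_metadata(design: StudyDesign,
                      rng: np.random.Generator) -> pd.DataFrame:
    """Field/sample metadata with an increasing MAT gradient over zones."""
    zones = design.zones()
    lo, hi = design.mat_range
    field_mats = np.linspace(lo, hi, design.n_fields)
    rows = []
    for f in range(design.n_fields):
        zone = zones[f // design.fields_per_zone]
        field_id = f"F{f + 1:02d}"
        region_id = f"R{f // design.fields_per_zone + 1:02d}"
        mat = field_mats[f] + rng.normal(0, 0.2)
        ph = 6.8 - 0.05 * mat + rng.normal(0, 0.15)
        doc = 120.0 + 3.0 * mat + rng.normal(0, 10.0)
        cec = 18.0 - 0.2 * mat + rng.normal(0, 1.0)
        for s in range(design.samples_per_field):
            rows.append({
                "sample_id": f"{field_id}_S{s + 1:02d}",
                "field_id": field_id, "region_id": region_id, "zone": zone,
                "mat": mat, "ph": ph, "doc": doc, "cec": cec})
    return validate_metadata(pd.DataFrame(rows))


def generate_abundances(design: StudyDesign, structure: PlantedStructure,
                        rng: np.random.Generator | None = None
                        ) -> tuple[OtuTable, pd.DataFrame]:
    """Draw the sample x OTU relative-abundance table plus metadata.

    Latent multivariate normals (block correlation matrix, positive-definite
    repaired) are pushed through per-OTU log-normal marginals and closed to
    sum 1 per sample. Spearman correlations between OTUs approximate the
    latent targets; closure perturbs them slightly.
    """
    if rng is None:
        rng = np.random.default_rng(design.seed)
    ids, taxonomy = _otu_ids(design)
    meta = generate_metadata(design, rng)
    zones = design.zones()
    lo, hi = structure.background_zone_gradient
    scales = (np.linspace(lo, hi, len(zones)) if len(zones) > 1
              else np.array([(lo + hi) / 2.0]))
    # one latent correlation per zone: the background tightens toward the
    # warm end of the gradient while planted modules stay fixed
    chol_by_zone = {}
    for zone, scale in zip(zones, scales):
        corr = _latent_correlation(design, structure, taxonomy, ids,
                                   background_scale=float(scale))
        chol_by_zone[zone] = np.linalg.cholesky(corr)
    # heterogeneous log-normal marginals: spread in mean abundance
    mu = rng.normal(0.0, 1.0, size=len(ids))
    sigma = 1.0
    # function-linked OTUs sit lower in mean abundance (so their summed
    # mass stays a modest share of the community and is not cancelled by
    # compositional closure) and rise toward the warm end of the gradient
    loading_vec = np.array([structure.function_loadings.get(o, 0.0)
                            for o in ids])
    mu = mu + structure.loaded_mu_offset * (loading_vec > 0)
    zone_shift = {z: s for z, s in zip(
        zones, np.linspace(-structure.module_zone_shift,
                           structure.module_zone_shift, len(zones)))}
    rel = np.empty((design.n_samples, len(ids)))
    zone_of_sample = meta["zone"].to_numpy()
    for start in range(0, design.n_samples, design.samples_per_field):
        stop = start + design.samples_per_field
        zone = zone_of_sample[start]
        z = rng.standard_normal((stop - start, len(ids))) \
            @ chol_by_zone[zone].T
        raw = np.exp(mu + loading_vec * zone_shift[zone] + sigma * z)
        rel[start:stop] = raw / raw.sum(axis=1, keepdims=True)
    frame = pd.DataFrame(rel, index=meta["sample_id"].tolist(), columns=ids)
    table = OtuTable(frame, taxonomy, is_relative=True)
    return table, meta


def generate_emissions(metadata: pd.DataFrame, table: OtuTable,
                       structure: PlantedStructure,
                       rng: np.random.Generator | None = None,
                       seed: int | None = None) -> pd.DataFrame:
    """Per-sample N2O rates at the five incubation temperatures.

    rate(sample, T) = baseline(sample) * q10^((T - 25)/10) * noise, with
    log-normal noise of coefficient of variation ``noise_cv`` (median 1, so
    log-scale fits are unbiased) and
    baseline = zone effect + loading-weighted abundance of planted OTUs.
    The zone effect rises exponentially with field MAT, emulating warmer
    zones emitting more.
    """
    if rng is None:
        rng = np.random.default_rng(0 if seed is None else seed)
    ab = table.abundance
    loadings = pd.Series(0.0, index=ab.columns)
    for otu, w in structure.function_loadings.items():
        if otu in loadings.index:
            loadings[otu] = w
    baseline = (structure.emission_base
                * np.exp(structure.mat_slope
                         * metadata.loc[ab.index, "mat"].to_numpy())
                + structure.loading_scale * (ab.to_numpy() @
                                             loadings.to_numpy()))
    zones = metadata.loc[ab.index, "zone"].to_numpy()
    q10 = np.array([structure.q10_for_zone(z) for z in zones])
    sigma = (np.sqrt(np.log1p(structure.noise_cv ** 2))
             if structure.noise_cv > 0 else 0.0)
    rows = []
    for t in INCUBATION_TEMPS:
        factor = q10 ** ((t - 25.0) / 10.0)
        noise = (np.exp(sigma * rng.standard_normal(len(baseline)))
                 if sigma > 0 else 1.0)
        rate = baseline * factor * noise
        rows.append(pd.DataFrame({
            "sample_id": ab.index, "temperature_C": t, "rate": rate}))
    return pd.concat(rows, ignore_index=True)


def generate_gene_signals(table: OtuTable, structure: PlantedStructure,
                          rng: np.random.Generator | None = None,
                          probes_per_gene: int = 4,
                          seed: int | None = None) -> pd.DataFrame:
    """Probe x sample intensities for the nitrogen-cycle genes.

    Denitrification genes (nirK, nirS, nosZ) get intensities that are an
    affine function of the summed core-pair member abundances (slope
    ``gene_linkage``) plus noise; the remaining genes are independent noise.
    """
    if rng is None:
        rng = np.random.default_rng(0 if seed is None else seed)
    ab = table.abundance
    members = [o for pair in structure.core_pairs for o in pair[:2]
               if o in ab.columns]
    core_signal = (ab[members].sum(axis=1).to_numpy()
                   if members else np.zeros(len(ab)))
    linked = {"nirK", "nirS", "nosZ"}
    rows = []
    for gene in GENES:
        for p in range(probes_per_gene):
            probe = f"{gene}_p{p + 1}"
            base = np.abs(rng.normal(1.0, 0.3, size=len(ab)))
            if gene in linked and structure.gene_linkage != 0:
                intensity = (0.5 + structure.gene_linkage * core_signal
                             + 0.1 * base)
            else:
                intensity = base
            rows.append(pd.DataFrame({
                "probe_id": probe, "gene": gene,
                "sample_id": ab.index, "intensity": np.abs(intensity)}))
    return pd.concat(rows, ignore_index=True)


def generate_study(design: StudyDesign | None = None,
                   structure: PlantedStructure | None = None,
                   n_core_pairs: int = 10,
                   seed: int | None = None) -> dict:
    """Generate a complete study bundle with ground truth.

    Returns a dict with keys ``table``, ``metadata``, ``fluxes``, ``genes``,
    ``structure`` and ``truth`` (planted pairs and parameters in plain
    types, for serialization).
    """
    if design is None:
        design = StudyDesign(seed=0 if seed is None else seed)
    elif seed is not None:
        design = StudyDesign(
            n_zones=design.n_zones, fields_per_zone=design.fields_per_zone,
            samples_per_field=design.samples_per_field,
            otus_per_group=design.otus_per_group,
            mat_range=design.mat_range, seed=seed)
    if structure is None:
        structure = default_structure(design, n_core_pairs=n_core_pairs)
    rng = np.random.default_rng(design.seed)
    table, meta = generate_abundances(design, structure, rng)
    fluxes = generate_emissions(meta, table, structure, rng)
    genes = generate_gene_signals(table, structure, rng)
    truth = {
        "core_pairs": [[i, j] for i, j, _ in structure.core_pairs],
        "q10_true": (dict(structure.q10_true)
                     if isinstance(structure.q10_true, Mapping)
                     else structure.q10_true),
        "noise_cv": structure.noise_cv,
        "function_loadings": dict(structure.function_loadings),
        "seed": design.seed,
    }
    return {"table": table, "metadata": meta, "fluxes": fluxes,
            "genes": genes, "design": design, "structure": structure,
            "truth": truth}
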