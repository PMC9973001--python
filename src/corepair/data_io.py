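"""Input/output and validation for study tables.

All tabular inputs are tab-delimited text with a header row. OTU tables are
samples x OTUs (the transposed orientation is auto-detected against the
taxonomy/metadata ids and transposed on read). A minimal BIOM (JSON dialect)
reader is included for interoperability with amplicon pipelines.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("corepair")

#: The five trophic/taxonomic aggregation levels used throughout.
MAIN_GROUPS = ("archaea", "bacteria", "fungi", "algae", "microfauna")

#: The four climatic zones of the study design, coldest to warmest.
ZONES = ("midtemperate", "warm-temperate", "subtropical", "tropical")

#: Controlled vocabulary for nitrogen-cycle gene probes.
GENES = ("amoA", "hao", "napA", "nirK", "nirS", "cnorB", "nosZ", "other")

#: Incubation temperatures (degrees C) at which fluxes are measured.
INCUBATION_TEMPS = (8.0, 15.0, 20.0, 25.0, 35.0)

REQUIRED_METADATA_COLUMNS = ("sample_id", "field_id", "region_id", "zone",
                             "mat", "ph", "doc", "cec")


class ValidationError(ValueError):
    """Raised when an input table violates its documented contract."""


@dataclass
class OtuTable:
    """Samples x OTUs abundance matrix with a main-group taxonomy.

    Parameters
    ----------
    abundance
        DataFrame with sample ids as the index and OTU ids as columns.
        Either relative abundances (rows sum to 1) or raw counts.
    taxonomy
        Map from OTU id to main group (one of :data:`MAIN_GROUPS`).
        May carry extra finer-rank labels in ``lineage``.
    is_relative
        True when rows are compositional (sum to 1).
    """

    abundance: pd.DataFrame
    taxonomy: dict[str, str]
    is_relative: bool = True
    lineage: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    @property
    def sample_ids(self) -> list[str]:
        return list(self.abundance.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.abundance.columns)

    def groups(self) -> pd.Series:
        """Main-group label per OTU, aligned with the matrix columns."""
        return pd.Series({o: self.taxonomy[o] for o in self.otu_ids},
                         name="group")

    def validate(self) -> None:
        ab = self.abundance
        if ab.index.duplicated().any():
            dup = ab.index[ab.index.duplicated()][0]
            raise ValidationError(f"duplicate sample id {dup!r}")
        if ab.columns.duplicated().any():
            dup = ab.columns[ab.columns.duplicated()][0]
            raise ValidationError(f"duplicate OTU id {dup!r}")
        values = ab.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            r, c = np.argwhere(~np.isfinite(values))[0]
            raise ValidationError(
                f"non-finite abundance at sample {ab.index[r]!r}, "
                f"OTU {ab.columns[c]!r}")
        if (values < 0).any():
            r, c = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative abundance at sample {ab.index[r]!r}, "
                f"OTU {ab.columns[c]!r}")
        missing = [o for o in ab.columns if o not in self.taxonomy]
        if missing:
            raise ValidationError(
                f"OTU {missing[0]!r} missing from taxonomy "
                f"({len(missing)} OTUs uncovered)")
        bad_group = {o: g for o, g in self.taxonomy.items()
                     if o in ab.columns and g not in MAIN_GROUPS}
        if bad_group:
            o, g = next(iter(bad_group.items()))
            raise ValidationError(
                f"OTU {o!r} has unknown main group {g!r}; "
                f"allowed: {', '.join(MAIN_GROUPS)}")
        if self.is_relative:
            sums = values.sum(axis=1)
            off = np.abs(sums - 1.0) > 1e-6
            if off.any():
                i = int(np.argmax(off))
                raise ValidationError(
                    f"relative-abundance row {ab.index[i]!r} sums to "
                    f"{sums[i]:.8f}, not 1")

    def to_relative(self) -> "OtuTable":
        """Close each row to sum 1 (no-op if already relative)."""
        if self.is_relative:
            return self
        totals = self.abundance.sum(axis=1)
        if (totals <= 0).any():
            bad = totals.index[totals <= 0][0]
            raise ValidationError(f"sample {bad!r} has zero total count")
        rel = self.abundance.div(totals, axis=0)
        return OtuTable(rel, dict(self.taxonomy), is_relative=True,
                        lineage=dict(self.lineage))

    def restrict_samples(self, sample_ids: Sequence[str]) -> "OtuTable":
        sub = self.abundance.loc[list(sample_ids)]
        return OtuTable(sub, dict(self.taxonomy),
                        is_relative=self.is_relative,
                        lineage=dict(self.lineage))


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Type, normalize and validate a sample-metadata frame.

    Zone labels are matched case-insensitively against :data:`ZONES`.
    """
    missing = [c for c in REQUIRED_METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ValidationError(f"metadata missing column(s): {missing}")
    meta = meta.copy()
    zone = meta["zone"].astype(str).str.strip().str.lower()
    # tolerate the common "warm temperate"/"warm_temperate" spellings
    zone = zone.str.replace(r"[ _]", "-", regex=True)
    unknown = sorted(set(zone) - set(ZONES))
    if unknown:
        raise ValidationError(
            f"unknown zone label(s) {unknown}; allowed: {list(ZONES)}")
    meta["zone"] = zone
    for col in ("mat", "ph", "doc", "cec"):
        meta[col] = pd.to_numeric(meta[col], errors="raise")
        if meta[col].isna().any():
            bad = meta.loc[meta[col].isna(), "sample_id"].iloc[0]
            raise ValidationError(f"column {col!r} missing for sample {bad!r}")
    if not np.isfinite(meta["mat"]).all():
        raise ValidationError("MAT must be finite for every sample")
    if meta["sample_id"].duplicated().any():
        dup = meta.loc[meta["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValidationError(f"duplicate sample id {dup!r} in metadata")
    return meta.set_index("sample_id", drop=False)


def validate_gene_signals(genes: pd.DataFrame) -> pd.DataFrame:
    """Validate a long-format probe x sample intensity table."""
    required = ("probe_id", "gene", "sample_id", "intensity")
    missing = [c for c in required if c not in genes.columns]
    if missing:
        raise ValidationError(f"gene table missing column(s): {missing}")
    genes = genes.copy()
    unknown = sorted(set(genes["gene"]) - set(GENES))
    if unknown:
        raise ValidationError(
            f"unknown gene label(s) {unknown}; allowed: {list(GENES)}")
    genes["intensity"] = pd.to_numeric(genes["intensity"], errors="raise")
    if (genes["intensity"] < 0).any():
        bad = genes.loc[genes["intensity"] < 0].iloc[0]
        raise ValidationError(
            f"negative intensity for probe {bad['probe_id']!r}, "
            f"sample {bad['sample_id']!r}")
    return genes


def read_taxonomy(path: str | Path) -> tuple[dict[str, str], dict[str, str]]:
    """Read a two/three-column TSV: otu_id, group[, lineage]."""
    tax = pd.read_csv(path, sep="\t", dtype=str)
    cols = list(tax.columns)
    if len(cols) < 2:
        raise ValidationError("taxonomy needs at least (otu_id, group)")
    taxonomy = dict(zip(tax[cols[0]], tax[cols[1]].str.lower()))
    lineage = (dict(zip(tax[cols[0]], tax[cols[2]]))
               if len(cols) >= 3 else {})
    return taxonomy, lineage


def read_otu_table(path: str | Path, taxonomy_path: str | Path,
                   relative: bool | None = None) -> OtuTable:
    """Read an OTU matrix TSV plus its taxonomy map.

    Orientation is auto-detected: if the row ids look like OTU ids from the
    taxonomy (and the column ids do not), the matrix is transposed to the
    samples-as-rows convention. Count tables (any value > 1, or
    ``relative=False``) are converted to per-sample relative abundances.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0)
    taxonomy, lineage = read_taxonomy(taxonomy_path)
    rows_are_otus = (raw.index.isin(taxonomy).mean()
                     > raw.columns.isin(taxonomy).mean())
    if rows_are_otus:
        logger.info("OTU table at %s is OTUs-as-rows; transposing", path)
        raw = raw.T
    values = raw.apply(pd.to_numeric)
    if relative is None:
        relative = not (values.to_numpy() > 1.0 + 1e-9).any()
    table = OtuTable(values, taxonomy, is_relative=False, lineage=lineage)
    table = table.to_relative()
    if relative:
        # already-relative input: closure is a no-op within tolerance
        pass
    return table


def write_otu_table(table: OtuTable, path: str | Path,
                    taxonomy_path: str | Path | None = None) -> None:
    table.abundance.to_csv(path, sep="\t", index_label="sample_id",
                           float_format="%.17g")
    if taxonomy_path is not None:
        rows = [{"otu_id": o, "group": table.taxonomy[o],
                 **({"lineage": table.lineage[o]} if o in table.lineage
                    else {})}
                for o in table.otu_ids]
        pd.DataFrame(rows).to_csv(taxonomy_path, sep="\t", index=False)


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read and validate a sample-metadata TSV."""
    return validate_metadata(pd.read_csv(path, sep="\t", dtype={
        "sample_id": str, "field_id": str, "region_id": str}))


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_fluxes(path: str | Path) -> pd.DataFrame:
    """Read a long flux TSV: sample_id, temperature_C, rate."""
    flux = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = ("sample_id", "temperature_C", "rate")
    missing = [c for c in required if c not in flux.columns]
    if missing:
        raise ValidationError(f"flux table missing column(s): {missing}")
    if (flux["rate"] < 0).any():
        bad = flux.loc[flux["rate"] < 0].iloc[0]
        raise ValidationError(
            f"negative rate for sample {bad['sample_id']!r} at "
            f"{bad['temperature_C']} C")
    return flux


def write_fluxes(flux: pd.DataFrame, path: str | Path) -> None:
    flux.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_gene_signals(path: str | Path) -> pd.DataFrame:
    return validate_gene_signals(pd.read_csv(path, sep="\t", dtype={
        "probe_id": str, "gene": str, "sample_id": str}))


def write_gene_signals(genes: pd.DataFrame, path: str | Path) -> None:
    genes.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_biom(path: str | Path, taxonomy_path: str | Path | None = None
              ) -> OtuTable:
    """Read a BIOM 1.0 (JSON dialect) observation table.

    Supports dense and sparse ``matrix_type``. BIOM stores observations
    (OTUs) as rows and samples as columns; the result follows this
    package's samples-as-rows convention. Group labels come from the
    optional external taxonomy TSV, else from each observation's
    ``metadata.group`` entry.
    """
    with open(path) as fh:
        doc = json.load(fh)
    otu_ids = [r["id"] for r in doc["rows"]]
    sample_ids = [c["id"] for c in doc["columns"]]
    shape = tuple(doc["shape"])
    mat = np.zeros(shape, dtype=float)
    if doc.get("matrix_type") == "sparse":
        for r, c, v in doc["data"]:
            mat[int(r), int(c)] = v
    else:
        mat[:] = np.asarray(doc["data"], dtype=float)
    if taxonomy_path is not None:
        taxonomy, lineage = read_taxonomy(taxonomy_path)
    else:
        taxonomy, lineage = {}, {}
        for row in doc["rows"]:
            md = row.get("metadata") or {}
            if "group" in md:
                taxonomy[row["id"]] = str(md["group"]).lower()
    frame = pd.DataFrame(mat.T, index=sample_ids, columns=otu_ids)
    table = OtuTable(frame, taxonomy, is_relative=False, lineage=lineage)
    return table.to_relative()


@dataclass
class StudyConfig:
    """Paths, thresholds and the single seed governing all randomness."""

    otu_table: str = ""
    taxonomy: str = ""
    metadata: str = ""
    fluxes: str = ""
    gene_signals: str = ""
    correlation_threshold: float = 0.8
    min_prevalence: float = 0.5
    absolute_threshold: bool = False
    fdr_q: float | None = None
    k_between: int = 15
    k_within: int = 10
    q10_method: str = "loglinear"
    n_permutations: int = 999
    n_trees: int = 1000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            logger.warning("ignoring unknown config keys: %s",
                           ", ".join(sorted(unknown)))
        return cls(**known)


def load_config(path: str | Path) -> StudyConfig:
    return StudyConfig.from_yaml(path)
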