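"""Cohort I/O: expression matrices, gene-module catalogs, and preprocessing.

Expression tables are plain TSV (genes in rows, samples in columns, or the
transpose); module catalogs use the GMT format. Standardization converts
each gene to cohort z-scores, optionally against externally supplied
reference statistics so that held-out samples can be scored with
training-cohort means and SDs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ModuleCategory",
    "GeneModule",
    "ModuleCatalog",
    "ExpressionMatrix",
    "read_expression",
    "standardize",
    "filter_low_expression",
    "read_gmt",
    "write_gmt",
]


class ModuleCategory(str, Enum):
    pathway = "pathway"
    ontology = "ontology"
    regulator = "regulator"
    dna_motif = "dna_motif"
    rna_motif_linear = "rna_motif_linear"
    rna_motif_structural = "rna_motif_structural"
    oncogenic_signature = "oncogenic_signature"
    other = "other"


@dataclass
class GeneModule:
    """A named gene set with a category label (pathway, regulon, motif...)."""

    name: str
    genes: frozenset[str]
    category: ModuleCategory = ModuleCategory.other
    source: str = ""

    def __post_init__(self) -> None:
        self.genes = frozenset(self.genes)
        if not self.genes:
            raise ValueError(f"module {self.name!r} has no genes")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class ModuleCatalog:
    """A collection of uniquely named gene modules, optionally with a universe."""

    modules: list[GeneModule]
    universe: Optional[frozenset[str]] = None

    def __post_init__(self) -> None:
        names = [m.name for m in self.modules]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValueError(f"duplicate module names: {sorted(dupes)}")
        if self.universe is not None:
            self.universe = frozenset(self.universe)

    def __iter__(self):
        return iter(self.modules)

    def __len__(self) -> int:
        return len(self.modules)

    def __getitem__(self, name: str) -> GeneModule:
        for m in self.modules:
            if m.name == name:
                return m
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [m.name for m in self.modules]


@dataclass
class ExpressionMatrix:
    """A genes × samples expression matrix.

    ``values`` is a pandas DataFrame indexed by gene id with sample-id
    columns. ``standardized`` records whether rows are cohort z-scores.
    Missing measurements stay as NaN until standardization, which maps them
    to 0 (so they are uninformative for binning and correlation).
    """

    values: pd.DataFrame
    standardized: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dupes = sorted(set(self.values.index[self.values.index.duplicated()]))
            raise ValueError(f"duplicate gene ids: {dupes}")
        if self.values.columns.duplicated().any():
            dupes = sorted(set(self.values.columns[self.values.columns.duplicated()]))
            raise ValueError(f"duplicate sample ids: {dupes}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().sum().sum())

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.loc[:, list(sample_ids)], self.standardized, dict(self.meta)
        )


def read_expression(path, transpose: bool = False) -> ExpressionMatrix:
    """Read a TSV expression table (first column gene ids, header sample ids).

    With ``transpose=True`` the file is sample × gene and is transposed on
    read. Duplicate ids raise; ragged rows raise with the parser's line
    diagnostic preserved.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.ParserError as exc:  # ragged rows: keep the line number
        raise ValueError(f"malformed expression table {path}: {exc}") from exc
    if transpose:
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(df.astype(float))


def write_expression(x: ExpressionMatrix, path) -> None:
    x.values.to_csv(path, sep="\t")


def standardize(
    x: ExpressionMatrix,
    ref_means: Optional[np.ndarray] = None,
    ref_sds: Optional[np.ndarray] = None,
) -> ExpressionMatrix:
    """Z-score each gene row: (x − mean) / SD, sample SD (ddof=1).

    With ``ref_means``/``ref_sds`` the supplied per-gene statistics are used
    instead of cohort statistics (the cross-validation path: test folds are
    standardized with training-fold statistics). Zero-SD genes become
    all-zero rows, and NaNs produced by z-scoring are set to 0.
    """
    vals = x.values.to_numpy(dtype=float)
    if ref_means is not None or ref_sds is not None:
        if ref_means is None or ref_sds is None:
            raise ValueError("supply both ref_means and ref_sds or neither")
        ref_means = np.asarray(ref_means, dtype=float)
        ref_sds = np.asarray(ref_sds, dtype=float)
        if ref_means.shape != (vals.shape[0],) or ref_sds.shape != (vals.shape[0],):
            raise ValueError(
                f"reference statistics have wrong length "
                f"(expected {vals.shape[0]}, got {ref_means.shape[0]}/{ref_sds.shape[0]})"
            )
        means, sds = ref_means, ref_sds
    else:
        means = np.nanmean(vals, axis=1)
        sds = np.nanstd(vals, axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (vals - means[:, None]) / sds[:, None]
    z[~np.isfinite(z)] = 0.0
    out = pd.DataFrame(z, index=x.values.index, columns=x.values.columns)
    meta = dict(x.meta)
    meta["sd_convention"] = "sample (ddof=1)"
    return ExpressionMatrix(out, standardized=True, meta=meta)


def gene_statistics(x: ExpressionMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene mean and sample SD, as used by :func:`standardize`."""
    vals = x.values.to_numpy(dtype=float)
    return np.nanmean(vals, axis=1), np.nanstd(vals, axis=1, ddof=1)


def filter_low_expression(
    x: ExpressionMatrix,
    n_draws: int = 100_000,
    percentile: float = 0.10,
    seed: int = 0,
) -> ExpressionMatrix:
    """Drop genes whose mean expression is at or below a sampled percentile.

    The threshold is the given percentile of ``n_draws`` values sampled
    uniformly with replacement from all (non-missing) matrix entries.
    ``percentile=0`` is vacuous and keeps everything.
    """
    if not (0 <= percentile < 1):
        raise ValueError(f"percentile must lie in [0, 1), got {percentile}")
    if x.standardized:
        raise ValueError("filter_low_expression expects unstandardized values")
    rng = np.random.default_rng(seed)
    flat = x.values.to_numpy(dtype=float).ravel()
    flat = flat[~np.isnan(flat)]
    draws = rng.choice(flat, size=n_draws, replace=True)
    cut = np.quantile(draws, percentile)
    keep = np.nanmean(x.values.to_numpy(dtype=float), axis=1) > cut
    return ExpressionMatrix(x.values.loc[keep], x.standardized, dict(x.meta))


def read_gmt(path, category: ModuleCategory = ModuleCategory.other) -> ModuleCatalog:
    """Read a GMT file (name, description, tab-separated genes per line)."""
    modules: list[GeneModule] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno} has fewer than 3 fields")
            name, source = fields[0], fields[1]
            genes = [g for g in fields[2:] if g]
            if not genes:
                raise ValueError(f"{path}: line {lineno} ({name!r}) lists no genes")
            if len(set(genes)) < len(genes):
                logger.info(
                    "GMT %s line %d (%s): %d duplicate gene entries collapsed",
                    path, lineno, name, len(genes) - len(set(genes)),
                )
            modules.append(GeneModule(name, frozenset(genes), category, source))
    return ModuleCatalog(modules)


def write_gmt(catalog: ModuleCatalog, path) -> None:
    with open(path, "w") as fh:
        for m in catalog:
            fh.write("\t".join([m.name, m.source or "na", *sorted(m.genes)]) + "\n")
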