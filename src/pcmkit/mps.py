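"""Module perturbation scores (MPS).

For one module and one sample, the per-gene z-scores of the sample are cut
into ``Ne`` equally populated expression bins and the mutual information
I(membership; bin) is computed from the 2 × Ne joint-counts table. I is
z-scored against a permutation null (random memberships of the same size),
gated at the null's top 1%, and signed by the Pearson correlation between
the membership vector and the z-scores:

    MPS = sgn(r) · max(0, (I − μ)/σ) · 1[I > 99th null percentile]

Positive MPS means the module's genes sit coherently high in the sample
(activation); negative means coherent repression. The magnitude is the
gated z by default; a pure step-function variant is available.

Because the bins are equally populated, the null bin counts of a random
m-gene membership follow a multivariate hypergeometric law over the bin
populations, which is how null draws are generated (exactly equivalent to
permuting the expression vector, but O(Ne) per draw instead of O(genes)).
Nulls are cached per (sample, module size).
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
import pandas as pd
from scipy.special import xlogy

from pcmkit.io import ExpressionMatrix, ModuleCatalog

__all__ = [
    "quantize_sample",
    "mutual_information",
    "NullModel",
    "null_model",
    "ModulePerturbation",
    "mps",
    "PerturbationMatrix",
    "score_cohort",
    "cohort_specific_modules",
    "tissue_specific_modules",
]

Magnitude = Literal["gated_z", "heaviside"]


def quantize_sample(z_values: np.ndarray, Ne: int) -> np.ndarray:
    """Assign each gene to one of ``Ne`` equally populated, rank-contiguous bins.

    Ties are broken by stable input order; when the gene count is not a
    multiple of ``Ne`` the extra genes go to the lowest-index (lowest
    expression) bins, so bin sizes differ by at most one.
    """
    z = np.asarray(z_values, dtype=float)
    n = z.size
    if Ne < 2:
        raise ValueError(f"Ne must be ≥ 2, got {Ne}")
    if Ne > n:
        raise ValueError(f"Ne={Ne} exceeds number of genes ({n})")
    order = np.argsort(z, kind="stable")
    sizes = _bin_sizes(n, Ne)
    labels = np.repeat(np.arange(Ne), sizes)
    bins = np.empty(n, dtype=np.int64)
    bins[order] = labels
    return bins


def _bin_sizes(n: int, Ne: int) -> np.ndarray:
    base, rem = divmod(n, Ne)
    sizes = np.full(Ne, base, dtype=np.int64)
    sizes[:rem] += 1
    return sizes


def mutual_information(table: np.ndarray) -> float:
    """I(membership; bin) in nats from a 2 × Ne joint-counts table.

    0·log 0 terms contribute nothing; natural log (downstream z-scores are
    base-invariant).
    """
    c = np.asarray(table, dtype=float)
    if (c < 0).any():
        raise ValueError("joint-counts table has negative entries")
    n = c.sum()
    if n <= 0:
        raise ValueError("empty joint-counts table")
    p = c / n
    pi = p.sum(axis=1, keepdims=True)
    pj = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * np.log(p / (pi * pj))
    return float(np.nansum(terms))


def _mi_from_member_counts(c1: np.ndarray, col_totals: np.ndarray, n: int) -> np.ndarray:
    """Vectorized MI for a batch of member-row counts against fixed bin totals.

    ``c1`` is (B, Ne): genes in the module per bin for each of B tables;
    ``col_totals`` the per-bin gene counts (shared margin). Returns B MIs.

    Uses the entropy decomposition
    N·I = Σ_ij c·ln c − Σ_i r·ln r − Σ_j s·ln s + N·ln N
    (row sums r, column sums s); xlogy handles the 0·ln 0 cells.
    """
    c1 = np.atleast_2d(np.asarray(c1, dtype=float))
    c0 = col_totals[None, :] - c1
    m = c1.sum(axis=1)
    cell_term = xlogy(c1, c1).sum(axis=1) + xlogy(c0, c0).sum(axis=1)
    row_term = xlogy(m, m) + xlogy(n - m, n - m)
    col_term = xlogy(col_totals, col_totals).sum()
    return (cell_term - row_term - col_term) / n + np.log(n)


@dataclass
class NullModel:
    """Summary of the permutation null for one (sample, module size)."""

    n_randomizations: int
    mu: float
    sigma: float
    top_quantile_cut: float  # 99th-percentile MI of the null; ties fail the gate
    seed: int

    def z(self, mi_value: float) -> float:
        if self.sigma <= 0:
            return 0.0
        return max(0.0, (mi_value - self.mu) / self.sigma)

    def significant(self, mi_value: float) -> bool:
        return mi_value > self.top_quantile_cut


def _null_mis(
    col_totals: np.ndarray, m: int, n: int, n_rand: int, rng: np.random.Generator
) -> np.ndarray:
    draws = rng.multivariate_hypergeometric(
        col_totals.astype(np.int64), m, size=n_rand, method="count")
    return _mi_from_member_counts(draws, col_totals, n)


def null_model(
    membership: np.ndarray,
    z_values: np.ndarray,
    Ne: int = 10,
    n_rand: int = 1000,
    seed: int = 0,
) -> NullModel:
    """Permutation null of the MI for a module of this size in this sample."""
    if n_rand < 100:
        raise ValueError(f"n_rand must be ≥ 100, got {n_rand}")
    membership = np.asarray(membership, dtype=bool)
    bins = quantize_sample(z_values, Ne)
    col_totals = np.bincount(bins, minlength=Ne)
    mis = _null_mis(col_totals, int(membership.sum()), membership.size, n_rand,
                    np.random.default_rng(seed))
    return NullModel(
        n_randomizations=n_rand,
        mu=float(mis.mean()),
        sigma=float(mis.std()),
        top_quantile_cut=float(np.quantile(mis, 0.99, method="higher")),
        seed=seed,
    )


@dataclass
class ModulePerturbation:
    mi: float
    z: float
    r: float
    significant: bool
    mps: float


def _observed_mi(membership: np.ndarray, bins: np.ndarray, col_totals: np.ndarray) -> float:
    c1 = np.bincount(bins[membership], minlength=col_totals.size)
    return float(_mi_from_member_counts(c1[None, :], col_totals, membership.size)[0])


def _pearson_sign(membership: np.ndarray, z_values: np.ndarray) -> float:
    x = membership.astype(float)
    if x.std() == 0 or np.std(z_values) == 0:
        return 0.0
    r = float(np.corrcoef(x, z_values)[0, 1])
    return 0.0 if np.isnan(r) else r


def mps(
    membership: np.ndarray,
    z_values: np.ndarray,
    Ne: int = 10,
    n_rand: int = 1000,
    seed: int = 0,
    magnitude: Magnitude = "gated_z",
    null: Optional[NullModel] = None,
) -> ModulePerturbation:
    """Module perturbation score of one module in one sample.

    ``membership`` is boolean over the genes of ``z_values`` (the sample's
    z-scores in the cohort's gene order). A precomputed ``null`` for the
    same (sample, module size) may be supplied to share randomizations.
    """
    membership = np.asarray(membership, dtype=bool)
    z_values = np.asarray(z_values, dtype=float)
    if membership.sum() < 2:
        warnings.warn("module has <2 genes in the universe; scored as 0")
        return ModulePerturbation(0.0, 0.0, 0.0, False, 0.0)
    if null is None:
        null = null_model(membership, z_values, Ne, n_rand, seed)
    bins = quantize_sample(z_values, Ne)
    col_totals = np.bincount(bins, minlength=Ne)
    mi_obs = _observed_mi(membership, bins, col_totals)
    zval = null.z(mi_obs)
    sig = null.significant(mi_obs)
    r = _pearson_sign(membership, z_values)
    if magnitude == "gated_z":
        score = np.sign(r) * zval * float(sig)
    elif magnitude == "heaviside":
        score = np.sign(r) * float(zval > 0) * float(sig)
    else:
        raise ValueError(f"unknown magnitude mode {magnitude!r}")
    return ModulePerturbation(mi_obs, zval, r, bool(sig), float(score))


@dataclass
class PerturbationMatrix:
    """Modules × samples MPS values with significance flags.

    ``labels`` maps each (module, sample) to "plus" / "minus" / "none"
    according to the sign of the (significance-gated) score.
    """

    mps: pd.DataFrame
    significant: pd.DataFrame
    skipped: list[str] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    @property
    def module_names(self) -> list[str]:
        return list(self.mps.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.mps.columns)

    def labels(self) -> pd.DataFrame:
        lab = pd.DataFrame("none", index=self.mps.index, columns=self.mps.columns)
        lab = lab.mask(self.mps > 0, "plus").mask(self.mps < 0, "minus")
        return lab


def score_cohort(
    catalog: ModuleCatalog,
    x: ExpressionMatrix,
    Ne: int = 10,
    n_rand: int = 1000,
    seed: int = 0,
    min_module_size: int = 5,
    magnitude: Magnitude = "gated_z",
) -> PerturbationMatrix:
    """Score every module of the catalog in every sample of a z-scored cohort.

    One permutation null is drawn per (sample, module size): the null MI
    depends on membership only through the module size, so modules of equal
    size share randomizations. Deterministic given (seed, input order);
    per-(sample, size) substream seeds are derived from ``seed``.
    """
    if not x.standardized:
        raise ValueError("score_cohort expects standardized expression")
    genes = pd.Index(x.gene_ids)
    n = len(genes)
    memberships: dict[str, np.ndarray] = {}
    skipped: list[str] = []
    for mod in catalog:
        memb = genes.isin(mod.genes)
        if memb.sum() < min_module_size:
            warnings.warn(
                f"module {mod.name!r}: {int(memb.sum())} genes in universe "
                f"(< {min_module_size}); scored as 0"
            )
            skipped.append(mod.name)
        memberships[mod.name] = memb
    sizes = sorted({int(m.sum()) for name, m in memberships.items() if name not in skipped})

    vals = x.values.to_numpy(dtype=float)
    names = catalog.names
    active = [(i, name) for i, name in enumerate(names) if name not in skipped]
    member_idx = {name: np.flatnonzero(memberships[name]) for _, name in active}
    module_sizes = np.array([member_idx[name].size for _, name in active])
    score_mat = np.zeros((len(names), len(x.sample_ids)))
    sig_mat = np.zeros_like(score_mat, dtype=bool)
    kth = int(np.ceil(0.99 * (n_rand - 1)))  # == quantile(..., method="higher")
    for j, sid in enumerate(x.sample_ids):
        zcol = vals[:, j]
        bins = quantize_sample(zcol, Ne)
        col_totals = np.bincount(bins, minlength=Ne)
        nulls: dict[int, NullModel] = {}
        sid_key = zlib.crc32(str(sid).encode())  # keyed by id, not position:
        for m_size in sizes:                     # column order is immaterial
            child = np.random.SeedSequence(entropy=seed, spawn_key=(sid_key, m_size))
            mis = _null_mis(col_totals, m_size, n, n_rand, np.random.default_rng(child))
            nulls[m_size] = NullModel(
                n_rand, float(mis.mean()), float(mis.std()),
                float(np.partition(mis, kth)[kth]), seed,
            )
        if not active:
            continue
        c1_all = np.vstack([
            np.bincount(bins[member_idx[name]], minlength=Ne)
            for _, name in active])
        mis_obs = _mi_from_member_counts(c1_all, col_totals, n)
        for (i, name), m_size, mi_obs in zip(active, module_sizes, mis_obs):
            null = nulls[m_size]
            if not null.significant(mi_obs):
                continue
            zval = null.z(mi_obs)
            r = _pearson_sign(memberships[name], zcol)
            mag = zval if magnitude == "gated_z" else float(zval > 0)
            score_mat[i, j] = np.sign(r) * mag
            sig_mat[i, j] = True
    meta = {"Ne": Ne, "n_rand": n_rand, "seed": seed, "magnitude": magnitude,
            "log_base": "e"}
    return PerturbationMatrix(
        pd.DataFrame(score_mat, index=names, columns=x.sample_ids),
        pd.DataFrame(sig_mat, index=names, columns=x.sample_ids),
        skipped,
        meta,
    )


def cohort_specific_modules(
    P: PerturbationMatrix,
    mean_quantile: float = 0.50,
    var_quantile: float = 0.40,
) -> list[str]:
    """Modules with high mean |MPS| (top ``mean_quantile``) and low variance
    (bottom ``var_quantile``), ranking the activation (MPS⁺) and repression
    (MPS⁻) streams independently and returning the union."""
    for q in (mean_quantile, var_quantile):
        if not (0 < q <= 1):
            raise ValueError(f"quantiles must lie in (0, 1], got {q}")
    if P.mps.empty:
        raise ValueError("empty perturbation matrix")
    selected: set[str] = set()
    M = P.mps.to_numpy(dtype=float)
    for stream in (np.clip(M, 0, None), np.clip(-M, 0, None)):
        means = stream.mean(axis=1)
        variances = stream.var(axis=1)
        active = means > 0
        if not active.any():
            continue
        mean_cut = np.quantile(means[active], 1 - mean_quantile)
        var_cut = np.quantile(variances[active], var_quantile)
        keep = active & (means >= mean_cut) & (variances <= var_cut)
        selected.update(np.asarray(P.module_names)[keep])
    return sorted(selected)


def tissue_specific_modules(
    P_tumor: PerturbationMatrix,
    P_normal: PerturbationMatrix,
    frac: float = 0.75,
) -> list[str]:
    """Modules significantly perturbed with opposite signs in tumor vs matched
    normal (MPS_tumor · MPS_normal < 0) in at least ``frac`` of pairs."""
    common = [s for s in P_tumor.sample_ids if s in set(P_normal.sample_ids)]
    if len(common) < 1:
        raise ValueError("no matched tumor/normal pairs")
    t = P_tumor.mps.loc[:, common]
    nrm = P_normal.mps.loc[P_tumor.mps.index, common]
    opposite = (t.to_numpy() * nrm.to_numpy()) < 0
    keep = opposite.mean(axis=1) >= frac
    return sorted(np.asarray(P_tumor.module_names)[keep])
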