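"""Cross-validated discovery of prognostic cancer modules (PCMs).

The cohort is split 3-fold (stratified by event status). Each training
split is standardized stand-alone and its samples scored for MPS; held-out
samples are z-scored with the training split's per-gene means and SDs and
scored with their own permutation nulls. Fixed-size MPS⁺/MPS⁻ arms are
selected on training; the least-extreme selected score of each polarity is
propagated as a closed boundary to label test samples; the three labeled
test folds are concatenated and arms re-formed at the same fixed size. A
module is a PCM at a given arm size when the empirical log-rank FDR clears
the gate in all three training splits (< 0.05), in the propagated test set
(< 0.01), and in the full un-split cohort (< 0.01) together with a Cox
p < 0.05 there.

The same scaffolding, with a Fisher test on the 4 × 2 stage-by-arm table in
place of the survival gates, finds modules associated with disease stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from pcmkit.io import ExpressionMatrix, ModuleCatalog, standardize, gene_statistics
from pcmkit.mps import PerturbationMatrix, score_cohort
from pcmkit.survival import (
    auto_schedule,
    compare_survival,
    empirical_fdr,
    null_logrank_pvalues,
    stratify_by_mps,
)

logger = logging.getLogger(__name__)

__all__ = [
    "make_folds",
    "propagate_boundaries",
    "BoundaryConditions",
    "PcmDecision",
    "PcmThresholds",
    "discover_pcms",
    "decisions_to_frame",
    "stage_association",
    "fisher_association_p",
    "SubCohortSpec",
    "partition_cohort",
    "select_mutated_genes",
    "categorize_cna",
    "rank_product_cna",
]


def _seed(root: int, *key: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=root, spawn_key=tuple(key))


def _seed_int(root: int, *key: int) -> int:
    return int(_seed(root, *key).generate_state(1)[0] % (2**31))


def make_folds(
    sample_ids: Sequence[str],
    n_folds: int = 3,
    seed: int = 0,
    event: Optional[Sequence[bool]] = None,
) -> pd.Series:
    """Assign samples to folds 1..n_folds, stratified by event status.

    Every sample lands in exactly one fold; fold sizes differ by at most
    one (a single round-robin pointer runs across the strata).
    """
    ids = list(sample_ids)
    rng = np.random.default_rng(_seed(seed, 0xF01D))
    fold = pd.Series(0, index=pd.Index(ids), dtype=int)
    if event is None:
        strata = [np.arange(len(ids))]
    else:
        event = np.asarray(event, dtype=bool)
        strata = [np.flatnonzero(event), np.flatnonzero(~event)]
    ptr = 0
    for stratum in strata:
        stratum = rng.permutation(stratum)
        for idx in stratum:
            fold.iloc[idx] = ptr % n_folds + 1
            ptr += 1
    return fold


@dataclass
class BoundaryConditions:
    """Per (module, fold, size) MPS cuts propagated from training to test."""

    plus_cut: float  # least positive selected training MPS
    minus_cut: float  # least-extreme selected negative (mirror rule)


def boundary_from_arms(
    train_mps: pd.Series,
    labels: pd.Series,
    literal_repressed: bool = False,
) -> BoundaryConditions:
    """Cuts from the selected training arms.

    Activated cut: the least positive selected MPS. Repressed cut: by
    default the least-extreme (closest to zero) selected negative value,
    mirroring the activated rule; ``literal_repressed`` instead uses the
    most negative selected value, which propagates almost no labels.
    """
    plus_vals = train_mps[labels == "plus"]
    minus_vals = train_mps[labels == "minus"]
    plus_cut = float(plus_vals.min()) if len(plus_vals) else float("inf")
    if len(minus_vals) == 0:
        minus_cut = float("-inf")
    elif literal_repressed:
        minus_cut = float(minus_vals.min())
    else:
        minus_cut = float(minus_vals.max())
    return BoundaryConditions(plus_cut, minus_cut)


def propagate_boundaries(
    bounds: BoundaryConditions,
    test_mps: pd.Series,
) -> pd.Series:
    """Label test samples by the propagated training cuts (closed bounds)."""
    labels = pd.Series("none", index=test_mps.index, dtype=object)
    labels[test_mps >= bounds.plus_cut] = "plus"
    labels[(test_mps < 0) & (test_mps <= bounds.minus_cut)] = "minus"
    return labels


@dataclass
class PcmThresholds:
    alpha_train: float = 0.05
    alpha_test: float = 0.01
    alpha_full: float = 0.01
    alpha_cox: float = 0.05


# relaxed gates for a-priori patient sub-groups (smaller cohorts): train
# FDR < 0.2, propagated test < 0.1, full < 0.05, no separate Cox gate
SUBCOHORT_THRESHOLDS = PcmThresholds(
    alpha_train=0.2, alpha_test=0.1, alpha_full=0.05, alpha_cox=1.0)


@dataclass
class PcmDecision:
    module: str
    group_size: int
    train_fdrs: tuple[float, ...]
    test_fdr: float
    full_fdr: float
    full_cox_p: float
    full_wald_z: float
    full_log2_hr: float
    is_pcm: bool
    skipped: Optional[str] = None  # reason, when gates could not be evaluated


@dataclass
class DiscoveryDetails:
    """Intermediate state of a discovery run (for audits and tests)."""

    folds: pd.Series
    train_scores: dict[int, PerturbationMatrix]
    test_scores: dict[int, PerturbationMatrix]
    full_scores: PerturbationMatrix


def _fold_scores(
    x: ExpressionMatrix,
    catalog: ModuleCatalog,
    folds: pd.Series,
    Ne: int,
    n_rand: int,
    seed: int,
    magnitude: str,
    min_module_size: int,
) -> DiscoveryDetails:
    """Score training and test splits of every fold, plus the full cohort.

    Test-fold samples are z-scored with the training split's statistics;
    the training split never sees test values.
    """
    import warnings as _w

    train_scores: dict[int, PerturbationMatrix] = {}
    test_scores: dict[int, PerturbationMatrix] = {}
    with _w.catch_warnings():
        _w.simplefilter("ignore")
        for f in sorted(folds.unique()):
            train_ids = list(folds.index[folds != f])
            test_ids = list(folds.index[folds == f])
            x_train = x.subset_samples(train_ids)
            means, sds = gene_statistics(x_train)
            z_train = standardize(x_train)
            z_test = standardize(x.subset_samples(test_ids), means, sds)
            train_scores[f] = score_cohort(
                catalog, z_train, Ne, n_rand, _seed_int(seed, 1, f),
                min_module_size, magnitude)
            test_scores[f] = score_cohort(
                catalog, z_test, Ne, n_rand, _seed_int(seed, 2, f),
                min_module_size, magnitude)
        full = score_cohort(catalog, standardize(x), Ne, n_rand,
                            _seed_int(seed, 3), min_module_size, magnitude)
    return DiscoveryDetails(folds, train_scores, test_scores, full)


class _NullCache:
    """Lazily drawn null log-rank p-value sets per (context, arm size)."""

    def __init__(self, outcomes_by_context: Mapping[str, pd.DataFrame],
                 n_null: int, seed: int):
        self._outcomes = outcomes_by_context
        self._n_null = n_null
        self._seed = seed
        self._cache: dict[tuple[str, int], np.ndarray] = {}

    def get(self, context: str, k: int) -> np.ndarray:
        key = (context, k)
        if key not in self._cache:
            ctx_id = sorted(self._outcomes).index(context)
            self._cache[key] = null_logrank_pvalues(
                self._outcomes[context], k, self._n_null,
                _seed_int(self._seed, 4, ctx_id, k))
        return self._cache[key]


def _reform_test_arms(
    test_labels: pd.Series,
    test_mps: pd.Series,
    k: int,
    min_arm: int,
) -> Optional[tuple[pd.Series, int]]:
    """Re-form fixed-size arms on the concatenated, label-propagated test set.

    If fewer than ``k`` labels of a polarity were propagated, the
    stratification is evaluated at the achievable size when both arms still
    hold at least ``min_arm`` samples, else skipped.
    """
    plus_ids = test_labels.index[test_labels == "plus"]
    minus_ids = test_labels.index[test_labels == "minus"]
    k_eff = min(k, len(plus_ids), len(minus_ids))
    if k_eff < min_arm:
        return None
    plus_ranked = test_mps.loc[plus_ids].sort_index().sort_values(
        ascending=False, kind="stable")
    minus_ranked = test_mps.loc[minus_ids].sort_index().sort_values(
        ascending=True, kind="stable")
    labels = pd.Series("none", index=test_labels.index, dtype=object)
    labels.loc[plus_ranked.index[:k_eff]] = "plus"
    labels.loc[minus_ranked.index[:k_eff]] = "minus"
    return labels, k_eff


def discover_pcms(
    x: ExpressionMatrix,
    catalog: ModuleCatalog,
    outcomes: pd.DataFrame,
    schedule: Optional[Sequence[int]] = None,
    thresholds: PcmThresholds = PcmThresholds(),
    Ne: int = 10,
    n_rand: int = 1000,
    n_null: int = 1000,
    seed: int = 0,
    min_test_arm: int = 10,
    min_module_size: int = 5,
    magnitude: str = "gated_z",
    literal_repressed: bool = False,
    return_details: bool = False,
):
    """Run the full cross-validated PCM discovery protocol.

    Returns a list of :class:`PcmDecision` (one per module × arm size that
    had enough nonzero-MPS samples to stratify), or ``(decisions, details)``
    with ``return_details=True``.
    """
    samples = [s for s in x.sample_ids if s in outcomes.index]
    if len(samples) < len(x.sample_ids):
        logger.info("discover_pcms: %d samples lack outcomes and are dropped",
                    len(x.sample_ids) - len(samples))
    x = x.subset_samples(samples)
    outcomes = outcomes.loc[samples]
    if schedule is None:
        schedule = auto_schedule(len(samples))

    folds = make_folds(samples, 3, seed, outcomes["event"].to_numpy(dtype=bool))
    details = _fold_scores(x, catalog, folds, Ne, n_rand, seed,
                           magnitude, min_module_size)

    contexts = {f"train{f}": outcomes.loc[folds != f] for f in sorted(folds.unique())}
    contexts["full"] = outcomes
    nulls = _NullCache(contexts, n_null, seed)

    decisions: list[PcmDecision] = []
    for name in catalog.names:
        if name in details.full_scores.skipped:
            continue
        test_mps_all = pd.concat(
            [details.test_scores[f].mps.loc[name] for f in sorted(details.test_scores)])
        for k in schedule:
            dec = _evaluate_module(
                name, k, details, outcomes, folds, nulls, thresholds,
                min_test_arm, literal_repressed, test_mps_all)
            if dec is not None:
                decisions.append(dec)
    if return_details:
        return decisions, details
    return decisions


def _evaluate_module(
    name: str,
    k: int,
    details: DiscoveryDetails,
    outcomes: pd.DataFrame,
    folds: pd.Series,
    nulls: _NullCache,
    thresholds: PcmThresholds,
    min_test_arm: int,
    literal_repressed: bool,
    test_mps_all: pd.Series,
) -> Optional[PcmDecision]:
    # training gates + boundary propagation
    train_fdrs: list[float] = []
    test_labels_parts: list[pd.Series] = []
    for f in sorted(details.train_scores):
        row = details.train_scores[f].mps.loc[name]
        labels = stratify_by_mps(row, k)
        if labels is None:
            # insufficient nonzero-MPS samples at this size in this fold
            return None
        res = compare_survival(labels, outcomes.loc[labels.index], fit_cox=False,
                               p_method="asymptotic")
        fdr = empirical_fdr(res.logrank_p, nulls.get(f"train{f}", k))
        train_fdrs.append(fdr)
        bounds = boundary_from_arms(row, labels, literal_repressed)
        test_labels_parts.append(
            propagate_boundaries(bounds, details.test_scores[f].mps.loc[name]))

    # concatenated test gate
    test_labels = pd.concat(test_labels_parts)
    reformed = _reform_test_arms(test_labels, test_mps_all, k, min_test_arm)
    if reformed is None:
        return None
    test_arm_labels, k_eff = reformed
    res_test = compare_survival(test_arm_labels, outcomes, fit_cox=False,
                                p_method="asymptotic")
    test_fdr = empirical_fdr(res_test.logrank_p, nulls.get("full", k_eff))

    # full-cohort gate (no split), same fixed size
    full_labels = stratify_by_mps(details.full_scores.mps.loc[name], k)
    if full_labels is None:
        return None
    res_full = compare_survival(full_labels, outcomes, p_method="asymptotic")
    full_fdr = empirical_fdr(res_full.logrank_p, nulls.get("full", k))

    is_pcm = (
        all(f < thresholds.alpha_train for f in train_fdrs)
        and test_fdr < thresholds.alpha_test
        and full_fdr < thresholds.alpha_full
        and not np.isnan(res_full.cox_p)
        and res_full.cox_p < thresholds.alpha_cox
    )
    return PcmDecision(name, k, tuple(train_fdrs), test_fdr, full_fdr,
                       res_full.cox_p, res_full.wald_z, res_full.log2_hr,
                       bool(is_pcm))


def apply_thresholds(
    decisions: Iterable[PcmDecision],
    thresholds: PcmThresholds,
) -> set[str]:
    """Re-evaluate stored gate statistics under different α's.

    The gate stack is a conjunction of fixed statistics against the
    thresholds, so relaxing any α can only grow the returned PCM set.
    """
    out: set[str] = set()
    for d in decisions:
        if (all(f < thresholds.alpha_train for f in d.train_fdrs)
                and d.test_fdr < thresholds.alpha_test
                and d.full_fdr < thresholds.alpha_full
                and not np.isnan(d.full_cox_p)
                and d.full_cox_p < thresholds.alpha_cox):
            out.add(d.module)
    return out


def decisions_to_frame(decisions: Iterable[PcmDecision]) -> pd.DataFrame:
    rows = []
    for d in decisions:
        row = {
            "module": d.module, "group_size": d.group_size,
            "test_fdr": d.test_fdr, "full_fdr": d.full_fdr,
            "full_cox_p": d.full_cox_p, "full_wald_z": d.full_wald_z,
            "full_log2_hr": d.full_log2_hr, "is_pcm": d.is_pcm,
        }
        for i, f in enumerate(d.train_fdrs, start=1):
            row[f"train_fdr_{i}"] = f
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# stage association
# ---------------------------------------------------------------------------

def fisher_association_p(
    table: np.ndarray,
    seed: int = 0,
    n_mc: int = 10_000,
) -> float:
    """Fisher exact p for an r × 2 contingency table.

    2 × 2 tables use the exact (hypergeometric) test; larger tables use a
    seeded Monte-Carlo estimate with fixed margins (the statistic is the
    table probability, as in the classical simulated Fisher test).
    """
    t = np.asarray(table, dtype=np.int64)
    t = t[t.sum(axis=1) > 0][:, :]  # all-zero rows carry no information
    if t.shape == (2, 2):
        return float(stats.fisher_exact(t)[1])

    def log_prob(tab: np.ndarray) -> float:
        r = tab.sum(axis=1)
        c = tab.sum(axis=0)
        n = tab.sum()
        return float(gammaln(r + 1).sum() + gammaln(c + 1).sum()
                     - gammaln(n + 1) - gammaln(tab + 1).sum())

    obs = log_prob(t)
    rows = np.repeat(np.arange(t.shape[0]), t.sum(axis=1))
    cols = np.repeat(np.arange(t.shape[1]), t.sum(axis=0))
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_mc):
        sim = np.zeros_like(t)
        np.add.at(sim, (rows, rng.permutation(cols)), 1)
        if log_prob(sim) <= obs + 1e-9:
            hits += 1
    return (1 + hits) / (1 + n_mc)


@dataclass
class StageDecision:
    module: str
    group_size: int
    train_ps: tuple[float, ...]
    test_p: float
    full_p: float
    is_associated: bool


def _stage_table(labels: pd.Series, stages: pd.Series,
                 levels: Sequence[str]) -> np.ndarray:
    tab = np.zeros((len(levels), 2), dtype=np.int64)
    for i, lev in enumerate(levels):
        in_stage = stages == lev
        tab[i, 0] = int(((labels == "plus") & in_stage).sum())
        tab[i, 1] = int(((labels == "minus") & in_stage).sum())
    return tab


def stage_association(
    x: ExpressionMatrix,
    catalog: ModuleCatalog,
    stages: pd.Series,
    schedule: Optional[Sequence[int]] = None,
    alphas: tuple[float, float, float] = (0.05, 0.01, 0.01),
    Ne: int = 10,
    n_rand: int = 1000,
    seed: int = 0,
    min_test_arm: int = 10,
    min_module_size: int = 5,
    magnitude: str = "gated_z",
) -> list[StageDecision]:
    """Modules whose MPS⁺/MPS⁻ membership is enriched or depleted across
    disease stages, under the same cross-validation structure as PCM
    discovery but gated by Fisher tests on the stage × arm table."""
    samples = [s for s in x.sample_ids if s in stages.index and pd.notna(stages[s])]
    x = x.subset_samples(samples)
    stages = stages.loc[samples].astype(str)
    levels = sorted(stages.unique())
    if len(levels) < 2:
        raise ValueError("need at least 2 distinct stages")
    if schedule is None:
        schedule = auto_schedule(len(samples))

    folds = make_folds(samples, 3, seed)
    details = _fold_scores(x, catalog, folds, Ne, n_rand, seed,
                           magnitude, min_module_size)

    decisions: list[StageDecision] = []
    for name in catalog.names:
        if name in details.full_scores.skipped:
            continue
        test_mps_all = pd.concat(
            [details.test_scores[f].mps.loc[name] for f in sorted(details.test_scores)])
        for j, k in enumerate(schedule):
            train_ps: list[float] = []
            test_labels_parts: list[pd.Series] = []
            ok = True
            for f in sorted(details.train_scores):
                row = details.train_scores[f].mps.loc[name]
                labels = stratify_by_mps(row, k)
                if labels is None:
                    ok = False
                    break
                tab = _stage_table(labels, stages, levels)
                train_ps.append(fisher_association_p(tab, _seed_int(seed, 5, f, j)))
                bounds = boundary_from_arms(row, labels)
                test_labels_parts.append(
                    propagate_boundaries(bounds, details.test_scores[f].mps.loc[name]))
            if not ok:
                continue
            reformed = _reform_test_arms(pd.concat(test_labels_parts),
                                         test_mps_all, k, min_test_arm)
            if reformed is None:
                continue
            test_arm_labels, _ = reformed
            test_p = fisher_association_p(
                _stage_table(test_arm_labels, stages, levels), _seed_int(seed, 6, j))
            full_labels = stratify_by_mps(details.full_scores.mps.loc[name], k)
            if full_labels is None:
                continue
            full_p = fisher_association_p(
                _stage_table(full_labels, stages, levels), _seed_int(seed, 7, j))
            is_assoc = (all(p < alphas[0] for p in train_ps)
                        and test_p < alphas[1] and full_p < alphas[2])
            decisions.append(StageDecision(name, k, tuple(train_ps),
                                           test_p, full_p, bool(is_assoc)))
    return decisions


# ---------------------------------------------------------------------------
# sub-cohort partitioning
# ---------------------------------------------------------------------------

_STAGE_ORDER = ("IV", "III", "II", "I")  # prefix-match from the longest numeral


def merge_stage(value: str) -> Optional[str]:
    """Collapse sub-stages: I/IA/IB → I, II/IIA/IIB/IIC → II, etc."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    v = str(value).upper().replace("STAGE", "").strip()
    for base in _STAGE_ORDER:
        if v.startswith(base):
            return base
    return None


def age_bucket(age: float) -> Optional[str]:
    if pd.isna(age):
        return None
    if age < 30:
        return "<30"
    if age < 60:
        return "30-60"
    return ">60"


@dataclass
class SubCohortSpec:
    name: str
    attribute: str
    value: str
    members: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.members)


def partition_cohort(
    clinical: pd.DataFrame,
    cna: Optional[pd.DataFrame] = None,
    snv: Optional[pd.DataFrame] = None,
    coding_lengths: Optional[pd.Series] = None,
    attributes: Optional[Sequence[str]] = None,
    min_size: int = 21,
    deep_quantile: float = 0.25,
    top_k_genes: int = 3,
) -> list[SubCohortSpec]:
    """Enumerate clinically and molecularly defined patient sub-cohorts.

    Clinical attributes partition by value (stages merged to I–IV, ages
    binned <30 / 30–60 / >60); mutation partitions use the most prominent
    mutated genes (mutations per coding base pair, ≥5% prevalence, TTN
    excluded); CNA partitions use the top rank-product genes categorized as
    deep/shallow amplification/deletion. Sub-cohorts must exceed
    ``min_size − 1`` samples (the "more than 20 samples" rule at the
    default).
    """
    specs: list[SubCohortSpec] = []
    cols = list(attributes) if attributes is not None else list(clinical.columns)
    for col in cols:
        if col not in clinical.columns:
            raise ValueError(f"unknown clinical attribute {col!r}")
        if col.lower() == "stage":
            values = clinical[col].map(merge_stage)
        elif col.lower() == "age":
            values = clinical[col].map(age_bucket)
        else:
            values = clinical[col]
        for val in sorted(values.dropna().unique()):
            members = list(values.index[values == val])
            specs.append(SubCohortSpec(f"{col}={val}", col, str(val), members))
    if snv is not None:
        if coding_lengths is None:
            raise ValueError("mutation partitioning requires coding lengths")
        for gene in select_mutated_genes(snv, coding_lengths, top_k=top_k_genes):
            mut = snv.loc[gene].astype(bool)
            specs.append(SubCohortSpec(f"{gene}=mutant", gene, "mutant",
                                       list(mut.index[mut])))
            specs.append(SubCohortSpec(f"{gene}=wild_type", gene, "wild_type",
                                       list(mut.index[~mut])))
    if cna is not None:
        for gene in rank_product_cna(cna, top_k=top_k_genes):
            cats = categorize_cna(cna.loc[gene], deep_quantile)
            for cat in sorted(cats.dropna().unique()):
                members = list(cats.index[cats == cat])
                specs.append(SubCohortSpec(f"{gene}={cat}", gene, cat, members))
    return [s for s in specs if len(s) >= min_size]


def select_mutated_genes(
    snv: pd.DataFrame,
    coding_lengths: pd.Series,
    min_frac: float = 0.05,
    top_k: int = 3,
    exclude: Sequence[str] = ("TTN",),
) -> list[str]:
    """Most prominently mutated genes: prevalence ≥ ``min_frac`` of samples,
    ranked by mutation count per coding base pair, top ``top_k`` after
    exclusions. ``snv`` is a genes × samples 0/1 matrix."""
    counts = snv.sum(axis=1)
    prevalence = snv.astype(bool).mean(axis=1)
    rows = []
    for gene in snv.index:
        if gene in set(exclude) or prevalence[gene] < min_frac:
            continue
        if gene not in coding_lengths.index or coding_lengths[gene] <= 0:
            logger.warning("select_mutated_genes: %s has no coding length; skipped", gene)
            continue
        rows.append((gene, counts[gene] / coding_lengths[gene]))
    rows.sort(key=lambda t: (-t[1], t[0]))
    return [g for g, _ in rows[:top_k]]


def categorize_cna(
    values: pd.Series,
    deep_quantile: float = 0.25,
) -> pd.Series:
    """Categorize per-sample copy-number values for one gene.

    The top ``deep_quantile`` of positive values are "deep_amplified" (rest
    of the positives "amplified"); the bottom ``deep_quantile`` of non-zero
    negative values are "deep_deleted" (rest "deleted"). Zeros stay
    uncategorized.
    """
    if not (0 < deep_quantile <= 0.5):
        raise ValueError(f"deep_quantile must lie in (0, 0.5], got {deep_quantile}")
    out = pd.Series(np.nan, index=values.index, dtype=object)
    pos = values[values > 0]
    if len(pos):
        cut = np.quantile(pos.to_numpy(dtype=float), 1 - deep_quantile)
        out[pos.index] = np.where(pos >= cut, "deep_amplified", "amplified")
    neg = values[values < 0]
    if len(neg):
        cut = np.quantile(neg.to_numpy(dtype=float), deep_quantile)
        out[neg.index] = np.where(neg <= cut, "deep_deleted", "deleted")
    return out


def rank_product_cna(
    cna: pd.DataFrame,
    whitelist: Optional[Iterable[str]] = None,
    corr_cut: float = 0.5,
    top_k: int = 3,
    pool_size: int = 1000,
) -> list[str]:
    """Prominent copy-number genes by rank product.

    RP(g) is the product of the gene's ascending ranks by |median CNA| and
    by CNA SD across samples; the candidate pool is the ``pool_size``
    highest-RP genes (optionally intersected with a cancer-gene whitelist),
    from which genes are picked greedily by RP while discarding candidates
    whose CNA profile correlates (|Pearson r| > ``corr_cut``) with any pick.
    """
    if len(cna) < 2:
        raise ValueError("need at least 2 genes")
    vals = cna.to_numpy(dtype=float)
    med = np.abs(np.median(vals, axis=1))
    sd = vals.std(axis=1, ddof=1)
    rp = stats.rankdata(med) * stats.rankdata(sd)
    order = np.argsort(-rp, kind="stable")
    pool = [cna.index[i] for i in order[:pool_size]]
    if whitelist is not None:
        wl = set(whitelist)
        pool = [g for g in pool if g in wl]
    if not pool:
        logger.warning("rank_product_cna: empty candidate pool")
        return []
    picked: list[str] = []
    remaining = list(pool)
    while remaining and len(picked) < top_k:
        g = remaining.pop(0)
        picked.append(g)
        gvec = cna.loc[g].to_numpy(dtype=float)
        keep = []
        for h in remaining:
            hvec = cna.loc[h].to_numpy(dtype=float)
            if gvec.std() == 0 or hvec.std() == 0:
                keep.append(h)
                continue
            if abs(np.corrcoef(gvec, hvec)[0, 1]) <= corr_cut:
                keep.append(h)
        remaining = keep
    return picked
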