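"""Combined risk models and external validation.

PCM scores, clinical factors and genomic aberrations are combined in
random survival forests (delegated to scikit-survival) under repeated
10-fold cross-validation; collated out-of-fold risks define high/low risk
groups whose size follows the cohort-size rule

    size = argmin_c | floor(f·N/50)·25 − c |,  c ∈ {25, 50, 100, ..., 500}

with f = 0.666 by default. Feature sets are compared by the distribution
of |log2 hazard ratios| across repeats (one-sided Mann-Whitney).
External-cohort validation re-scores discovery-cohort PCMs on the new
cohort and checks significance and direction; an AUC over
randomized-profile negatives summarizes discrimination.
"""

from __future__ import annotations

import logging
import warnings
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold
from sksurv.ensemble import RandomSurvivalForest
from sksurv.util import Surv

from pcmkit.io import ExpressionMatrix, ModuleCatalog, standardize
from pcmkit.mps import score_cohort
from pcmkit.survival import compare_survival, stratify_by_mps

logger = logging.getLogger(__name__)

__all__ = [
    "GROUP_SIZE_CANDIDATES",
    "risk_group_size",
    "risk_groups",
    "fit_risk_model",
    "compare_feature_sets",
    "external_validation",
    "validation_auc",
    "mann_whitney_auc",
    "prognostic_enrichment_p",
]

GROUP_SIZE_CANDIDATES = (25, 50, 100, 150, 200, 250, 300, 350, 400, 450, 500)


def risk_group_size(
    n: int,
    f: float = 0.666,
    candidates: Sequence[int] = GROUP_SIZE_CANDIDATES,
) -> int:
    """Per-arm risk-group size: the candidate nearest floor(f·N/50)·25.

    Ties go to the smaller candidate; the result is clipped to ⌊N/2⌋ (with
    a warning) so the two arms stay disjoint.
    """
    target = np.floor(f * n / 50) * 25
    cands = sorted(candidates)
    best = min(cands, key=lambda c: (abs(target - c), c))
    if best > n // 2:
        logger.warning("risk group size %d clipped to %d (N=%d)", best, n // 2, n)
        best = n // 2
    return int(best)


def risk_groups(
    pred: pd.Series,
    f: float = 0.666,
    candidates: Sequence[int] = GROUP_SIZE_CANDIDATES,
    fraction: Optional[float] = None,
) -> pd.Series:
    """High/low risk labels from collated risk predictions.

    Group size follows :func:`risk_group_size`; ``fraction`` switches to the
    cross-cohort mode where the top and bottom ``fraction`` of patients are
    used instead of the formula.
    """
    n = len(pred)
    size = int(round(fraction * n)) if fraction is not None else risk_group_size(n, f, candidates)
    size = min(size, n // 2)
    ranked = pred.sort_index().sort_values(ascending=False, kind="stable")
    labels = pd.Series("none", index=pred.index, dtype=object)
    labels.loc[ranked.index[:size]] = "high"
    labels.loc[ranked.index[-size:]] = "low"
    return labels


def fit_risk_model(
    features: pd.DataFrame,
    outcomes: pd.DataFrame,
    n_trees: int = 1000,
    min_node: int = 15,
    n_folds: int = 10,
    repeats: int = 10,
    seed: int = 0,
    min_events: int = 50,
) -> pd.DataFrame:
    """Repeated cross-validated random-survival-forest risk predictions.

    Forests use ``n_trees`` trees, terminal-node size ``min_node``,
    mtry = ⌈ln(#features)⌉ and log-rank splitting. Folds are stratified by
    event status so every training fold carries events. Returns a
    samples × repeats table of out-of-fold risks (each sample predicted
    exactly once per repeat). Deterministic given ``seed``.
    """
    feats = pd.get_dummies(features, dtype=float)
    samples = feats.index.intersection(outcomes.index)
    feats = feats.loc[samples]
    out = outcomes.loc[samples]
    event = out["event"].to_numpy(dtype=bool)
    if event.sum() < min_events:
        raise ValueError(f"need ≥ {min_events} events, got {int(event.sum())}")
    y = Surv.from_arrays(event=event, time=out["time"].to_numpy(dtype=float))
    X = feats.to_numpy(dtype=float)
    mtry = max(1, int(np.ceil(np.log(max(feats.shape[1], 2)))))

    preds = pd.DataFrame(index=samples, columns=range(repeats), dtype=float)
    for rep in range(repeats):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                              random_state=(seed * 1000 + rep) % (2**31))
        for fold_i, (tr, te) in enumerate(skf.split(X, event)):
            rsf = RandomSurvivalForest(
                n_estimators=n_trees, min_samples_leaf=min_node,
                max_features=mtry, n_jobs=1,
                random_state=(seed * 100_003 + rep * 101 + fold_i) % (2**31))
            rsf.fit(X[tr], y[tr])
            preds.iloc[te, rep] = rsf.predict(X[te])
    assert not preds.isna().any().any()
    return preds


def compare_feature_sets(
    preds_by_model: Mapping[str, pd.DataFrame],
    outcomes: pd.DataFrame,
    f: float = 0.666,
) -> tuple[pd.DataFrame, dict[tuple[str, str], float]]:
    """Compare models by per-repeat |log2 HR| of their risk-group split.

    Returns the models × repeats |log2 HR| table and one-sided
    Mann-Whitney p-values for every ordered model pair (alternative: the
    first model separates more strongly).
    """
    hr_rows = {}
    for model, preds in preds_by_model.items():
        if preds.shape[1] < 3:
            raise ValueError(f"model {model!r} has <3 repeats")
        vals = []
        for rep in preds.columns:
            labels = risk_groups(preds[rep], f=f)
            labels = labels.map({"high": "plus", "low": "minus"}).fillna("none")
            res = compare_survival(labels, outcomes.loc[labels.index])
            vals.append(abs(res.log2_hr))
        hr_rows[model] = vals
    hr_table = pd.DataFrame(hr_rows).T
    pvals: dict[tuple[str, str], float] = {}
    names = list(hr_table.index)
    for a in names:
        for b in names:
            if a == b:
                continue
            pvals[(a, b)] = float(stats.mannwhitneyu(
                hr_table.loc[a], hr_table.loc[b], alternative="greater").pvalue)
    return hr_table, pvals


def external_validation(
    pcm_names: Sequence[str],
    catalog: ModuleCatalog,
    x_ext: ExpressionMatrix,
    outcomes_ext: pd.DataFrame,
    sizes: Sequence[int],
    discovery_direction: Mapping[str, float],
    Ne: int = 10,
    n_rand: int = 1000,
    seed: int = 0,
    p_cut: float = 0.05,
    hr_cut: float = 0.4,
    min_arm: int = 20,
    max_missing: float = 0.5,
) -> pd.DataFrame:
    """Consistency of discovery-cohort PCMs on an external cohort.

    MPS is recomputed on the external cohort and each PCM stratified at the
    listed per-arm sizes (only sizes with ≥ ``min_arm`` per arm). A PCM is
    prognostic externally when some size gives log-rank p < ``p_cut`` or
    |log2 HR| > ``hr_cut``, and consistent when additionally the direction
    (sign of the log2 HR) matches ``discovery_direction``. PCMs with more
    than ``max_missing`` of their genes absent are flagged not evaluable.
    """
    if not x_ext.standardized:
        x_ext = standardize(x_ext)
    universe = set(x_ext.gene_ids)
    mods = [catalog[n] for n in pcm_names]
    sub = ModuleCatalog(mods)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        P = score_cohort(sub, x_ext, Ne, n_rand, seed)
    rows = []
    for mod in mods:
        missing = 1 - len(mod.genes & universe) / len(mod.genes)
        if missing > max_missing:
            rows.append(dict(module=mod.name, evaluable=False, prognostic=False,
                             consistent=False, best_p=np.nan, best_log2_hr=np.nan))
            continue
        best_p, best_hr = np.nan, np.nan
        prognostic = False
        direction = 0.0
        for k in sizes:
            if k < min_arm:
                continue
            labels = stratify_by_mps(P.mps.loc[mod.name], k)
            if labels is None:
                continue
            res = compare_survival(labels, outcomes_ext.loc[labels.index])
            if not res.valid:
                continue
            if np.isnan(best_p) or res.logrank_p < best_p:
                best_p, best_hr = res.logrank_p, res.log2_hr
            if res.logrank_p < p_cut or (not np.isnan(res.log2_hr)
                                         and abs(res.log2_hr) > hr_cut):
                prognostic = True
                direction = np.sign(res.log2_hr)
        consistent = bool(prognostic and direction != 0
                          and direction == np.sign(discovery_direction.get(mod.name, 0)))
        rows.append(dict(module=mod.name, evaluable=True, prognostic=prognostic,
                         consistent=consistent, best_p=best_p, best_log2_hr=best_hr))
    return pd.DataFrame(rows).set_index("module")


def mann_whitney_auc(pos_scores, neg_scores) -> float:
    """ROC AUC via the Mann-Whitney U identity, midranks on ties."""
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2
    return float(u / (pos.size * neg.size))


def _stratification_score(mps_row: pd.Series, outcomes: pd.DataFrame,
                          sizes: Sequence[int]) -> float:
    """−log10 of the best log-rank p over the tested sizes (0 when no size
    could be stratified)."""
    best = 1.0
    for k in sizes:
        labels = stratify_by_mps(mps_row, k)
        if labels is None:
            continue
        res = compare_survival(labels, outcomes.loc[labels.index], fit_cox=False)
        if res.valid and res.logrank_p < best:
            best = res.logrank_p
    return -np.log10(max(best, 1e-300))


def validation_auc(
    pos_names: Sequence[str],
    catalog: ModuleCatalog,
    x_ext: ExpressionMatrix,
    outcomes_ext: pd.DataFrame,
    sizes: Sequence[int],
    n_neg: int = 100,
    repeats: int = 10,
    seed: int = 0,
    Ne: int = 10,
    n_rand: int = 200,
) -> np.ndarray:
    """AUC of external stratification significance, positives vs negatives.

    Positives are the given modules scored on the external cohort;
    negatives apply the identical procedure to cohorts whose per-sample
    profiles have been independently permuted (destroying module
    coherence). One AUC per repeat.
    """
    if n_neg < 10:
        raise ValueError(f"n_neg must be ≥ 10, got {n_neg}")
    if not x_ext.standardized:
        x_ext = standardize(x_ext)
    sub = ModuleCatalog([catalog[n] for n in pos_names])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        P_pos = score_cohort(sub, x_ext, Ne, n_rand, seed)
        pos_scores = np.array([
            _stratification_score(P_pos.mps.loc[n], outcomes_ext, sizes)
            for n in pos_names])
        aucs = np.empty(repeats)
        for rep in range(repeats):
            rng = np.random.default_rng(np.random.SeedSequence(
                entropy=seed, spawn_key=(rep,)))
            vals = x_ext.values.to_numpy(dtype=float).copy()
            for j in range(vals.shape[1]):
                rng.shuffle(vals[:, j])
            x_neg = ExpressionMatrix(
                pd.DataFrame(vals, index=x_ext.gene_ids, columns=x_ext.sample_ids),
                standardized=True)
            P_neg = score_cohort(sub, x_neg, Ne, n_rand,
                                 int(rng.integers(2**31)))
            neg_scores = []
            i = 0
            while len(neg_scores) < n_neg:
                name = pos_names[i % len(pos_names)]
                neg_scores.append(
                    _stratification_score(P_neg.mps.loc[name], outcomes_ext, sizes))
                i += 1
            aucs[rep] = mann_whitney_auc(pos_scores, np.asarray(neg_scores))
    return aucs


def prognostic_enrichment_p(
    n_consistent_pcm: int,
    non_pcm_prognostic_flags: Sequence[bool],
    n_pcm: int,
    n_draws: int = 100_000,
    seed: int = 0,
) -> float:
    """Resampling p for enrichment of externally prognostic modules among
    PCMs: draw ``n_pcm`` modules from the non-PCM pool and count how often
    at least ``n_consistent_pcm`` of them are prognostic."""
    flags = np.asarray(non_pcm_prognostic_flags, dtype=bool)
    rng = np.random.default_rng(seed)
    draws = np.array([
        flags[rng.choice(flags.size, size=n_pcm, replace=False)].sum()
        for _ in range(n_draws)])
    return float((draws >= n_consistent_pcm).mean())
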