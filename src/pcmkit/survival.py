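"""Survival stratification statistics.

Patients are split into MPS⁺ / MPS⁻ arms of a fixed per-arm size and the
arms compared with the two-group log-rank test and a univariate Cox
proportional-hazards fit (delegated to lifelines). Significance of a
stratification is calibrated against an empirical null built from random
same-size patient arms; the reported "FDR" is the exceedance fraction of
that null. Evidence across the modules of one driver is combined with
Stouffer's method.

Orientation convention: ``log2_hr`` and ``wald_z`` are positive when the
MPS⁺ arm survives longer. Swapping arm labels flips both signs and leaves
p-values unchanged.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Literal, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "logrank_test",
    "LogrankResult",
    "CompareResult",
    "compare_survival",
    "stratify_by_mps",
    "null_logrank_pvalues",
    "empirical_fdr",
    "single_locus_prognosis",
    "stouffer_combine",
    "module_vs_locus_ratio",
    "multivariate_cox",
    "auto_schedule",
    "SCHEDULE_CANDIDATES",
]

# Per-arm sizes used across cohorts; a cohort of size n is tested at every
# candidate strictly below n/2 (this reproduces the per-cohort lists used in
# the original study for all 25 cohorts).
SCHEDULE_CANDIDATES = (25, 50, 75, 100, 150, 200, 250, 400, 500)


def auto_schedule(n: int) -> list[int]:
    """Per-arm group sizes to test for a cohort of ``n`` patients."""
    return [c for c in SCHEDULE_CANDIDATES if c < n / 2]


@dataclass
class LogrankResult:
    statistic: float  # chi-square on 1 df
    p: float
    z: float  # signed; positive when group-1 has fewer events than expected
    observed_minus_expected: float
    variance: float


# Below this included-sample count the permutation null of the log-rank
# statistic is used instead of the chi-square approximation (which is
# noticeably anti-conservative at such sizes). Pipeline stratifications
# always involve ≥ 50 patients and use the asymptotic p.
SMALL_SAMPLE_N = 40
_EXACT_ENUM_LIMIT = 500_000


def _logrank_core(time, event, ingroup) -> tuple[float, float]:
    """(O − E, V) at each distinct event time, summed (group-1 oriented)."""
    event_times = np.unique(time[event])
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        at_risk = time >= t
        n = int(at_risk.sum())
        n1 = int((at_risk & ingroup).sum())
        here = (time == t) & event
        d = int(here.sum())
        d1 = int((here & ingroup).sum())
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e, var


def logrank_test(
    time, event, ingroup,
    p_method: Literal["auto", "asymptotic", "permutation"] = "auto",
    n_mc: int = 10_000,
    seed: int = 0,
) -> LogrankResult:
    """Two-group log-rank test by the standard O−E / hypergeometric-variance
    formula. ``ingroup`` is the boolean indicator of group 1.

    ``p_method="auto"`` uses the asymptotic chi-square p except for small
    samples (n ≤ 40 included), where the permutation null of the statistic
    is evaluated — exhaustively over all group assignments when that
    enumeration is feasible, else by seeded Monte Carlo.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    ingroup = np.asarray(ingroup, dtype=bool)
    order = np.argsort(time, kind="stable")
    time, event, ingroup = time[order], event[order], ingroup[order]

    o_minus_e, var = _logrank_core(time, event, ingroup)
    if var <= 0:
        return LogrankResult(0.0, 1.0, 0.0, o_minus_e, var)
    chi2 = o_minus_e**2 / var
    z = -o_minus_e / np.sqrt(var)  # positive: group 1 has fewer events

    use_perm = p_method == "permutation" or (
        p_method == "auto" and time.size <= SMALL_SAMPLE_N)
    if use_perm:
        p = _permutation_p(time, event, ingroup, chi2, n_mc, seed)
    else:
        p = float(stats.chi2.sf(chi2, 1))
    return LogrankResult(float(chi2), p, float(z), float(o_minus_e), float(var))


def _permutation_p(time, event, ingroup, observed_chi2, n_mc, seed) -> float:
    """Permutation p of the log-rank statistic: exhaustive over all group
    assignments when their count is below the enumeration limit."""
    from itertools import combinations
    from math import comb

    n = time.size
    n1 = int(ingroup.sum())
    n_assign = comb(n, n1)
    if n_assign <= _EXACT_ENUM_LIMIT:
        members = np.ones((n, n_assign), dtype=bool)
        g = np.zeros((n, n_assign), dtype=bool)
        combs = np.fromiter(
            (i for idx in combinations(range(n), n1) for i in idx),
            dtype=np.int64, count=n_assign * n1).reshape(n_assign, n1)
        g[combs.T, np.arange(n_assign)[None, :]] = True
        chi2s = _logrank_chi2_batch(time, event, members, g)
        return float((chi2s >= observed_chi2 - 1e-12).mean())
    rng = np.random.default_rng(seed)
    members = np.ones((n, n_mc), dtype=bool)
    g = np.zeros((n, n_mc), dtype=bool)
    base = ingroup.copy()
    for b in range(n_mc):
        g[:, b] = rng.permutation(base)
    chi2s = _logrank_chi2_batch(time, event, members, g)
    # add-one: the observed assignment counts as one permutation
    return float((1 + (chi2s >= observed_chi2 - 1e-12).sum()) / (1 + n_mc))


@dataclass
class CompareResult:
    logrank_p: float
    logrank_z: float
    cox_p: float
    wald_z: float
    log2_hr: float
    median_plus: float
    median_minus: float
    n_plus: int
    n_minus: int
    valid: bool = True


def _km_median(time, event) -> float:
    kmf = KaplanMeierFitter()
    kmf.fit(time, event)
    med = kmf.median_survival_time_
    return float("nan") if np.isinf(med) else float(med)


def compare_survival(
    labels: pd.Series,
    outcomes: pd.DataFrame,
    fit_cox: bool = True,
    p_method: Literal["auto", "asymptotic", "permutation"] = "auto",
) -> CompareResult:
    """Compare the "plus" and "minus" arms of a stratification.

    ``labels`` maps sample id → {"plus", "minus", "none"}; ``outcomes`` is
    indexed by sample id with float ``time`` and boolean ``event`` columns.
    Samples labeled "none" are excluded. The Cox fit is a univariate PH
    model on the arm indicator (Efron ties); with no events the statistics
    are undefined and flagged invalid.
    """
    keep = labels[labels.isin(["plus", "minus"])]
    sub = outcomes.loc[keep.index]
    time = sub["time"].to_numpy(dtype=float)
    event = sub["event"].to_numpy(dtype=bool)
    plus = (keep == "plus").to_numpy()
    n_plus, n_minus = int(plus.sum()), int((~plus).sum())
    if n_plus == 0 or n_minus == 0 or event.sum() == 0:
        return CompareResult(*([float("nan")] * 7), n_plus, n_minus, valid=False)

    lr = logrank_test(time, event, plus, p_method=p_method)
    median_plus = _km_median(time[plus], event[plus])
    median_minus = _km_median(time[~plus], event[~plus])

    cox_p = wald_z = log2_hr = float("nan")
    if fit_cox:
        df = pd.DataFrame({"time": time, "event": event.astype(int),
                           "arm": plus.astype(float)})
        cph = CoxPHFitter()
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(df, duration_col="time", event_col="event")
            beta = float(cph.params_["arm"])
            se = float(cph.standard_errors_["arm"])
            cox_p = float(cph.summary.loc["arm", "p"])
            wald_z = -beta / se  # positive: plus arm survives longer
            log2_hr = -beta / np.log(2)
        except (ConvergenceError, ValueError) as exc:
            logger.warning("Cox fit failed: %s", exc)
    return CompareResult(lr.p, lr.z, cox_p, wald_z, log2_hr,
                         median_plus, median_minus, n_plus, n_minus)


def stratify_by_mps(mps_row: pd.Series, k: int) -> Optional[pd.Series]:
    """Fixed-size arms from one module's per-sample MPS values.

    MPS⁺ arm: the ``k`` samples with the largest positive scores; MPS⁻ arm:
    the ``k`` most negative. Requires at least ``k`` nonzero samples of each
    polarity, otherwise returns None (the (module, size) is skipped). Ties
    are broken by sample-id order.
    """
    if k <= 0:
        raise ValueError(f"per-arm size must be positive, got {k}")
    pos = mps_row[mps_row > 0]
    neg = mps_row[mps_row < 0]
    if len(pos) < k or len(neg) < k:
        return None
    pos = pos.sort_index().sort_values(ascending=False, kind="stable")
    neg = neg.sort_index().sort_values(ascending=True, kind="stable")
    labels = pd.Series("none", index=mps_row.index, dtype=object)
    labels.loc[pos.index[:k]] = "plus"
    labels.loc[neg.index[:k]] = "minus"
    return labels


def logrank_pvalues_batch(
    time: np.ndarray,
    event: np.ndarray,
    member: np.ndarray,
    group1: np.ndarray,
) -> np.ndarray:
    """Vectorized asymptotic log-rank p-values for B simultaneous splits.

    ``member`` (n × B) marks the samples included in each split and
    ``group1`` (n × B) its group-1 subset. Same O/E/V formula as
    :func:`logrank_test`, evaluated for all B columns at once.
    """
    chi2 = _logrank_chi2_batch(time, event, member, group1)
    return stats.chi2.sf(chi2, 1)


def _logrank_chi2_batch(
    time: np.ndarray,
    event: np.ndarray,
    member: np.ndarray,
    group1: np.ndarray,
) -> np.ndarray:
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    order = np.argsort(-time, kind="stable")
    ts, ev = time[order], event[order]
    m = np.asarray(member, dtype=float)[order]
    g = np.asarray(group1, dtype=float)[order]
    cum_n = np.cumsum(m, axis=0)
    cum_n1 = np.cumsum(g, axis=0)

    B = m.shape[1]
    o_minus_e = np.zeros(B)
    var = np.zeros(B)
    i = 0
    n_rows = ts.size
    while i < n_rows:
        j = i
        while j + 1 < n_rows and ts[j + 1] == ts[i]:
            j += 1
        ev_rows = [r for r in range(i, j + 1) if ev[r]]
        if ev_rows:
            n_at = cum_n[j]
            n1_at = cum_n1[j]
            d = m[ev_rows].sum(axis=0)
            d1 = g[ev_rows].sum(axis=0)
            with np.errstate(divide="ignore", invalid="ignore"):
                frac = np.where(n_at > 0, n1_at / np.maximum(n_at, 1), 0.0)
                o_minus_e += d1 - d * frac
                ok = n_at > 1
                var += np.where(
                    ok, d * frac * (1 - frac) * (n_at - d) / np.maximum(n_at - 1, 1), 0.0)
        i = j + 1
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(var > 0, o_minus_e**2 / np.maximum(var, 1e-300), 0.0)
    return chi2


def null_logrank_pvalues(
    outcomes: pd.DataFrame,
    k: int,
    n_null: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Log-rank p-values of ``n_null`` random disjoint k-vs-k patient arms.

    The null depends only on the outcome set and the arm size, never on the
    module, so one draw per (cohort, k) is shared across all modules.
    """
    n = len(outcomes)
    if 2 * k > n:
        raise ValueError(f"2k={2 * k} exceeds cohort size {n}")
    time = outcomes["time"].to_numpy(dtype=float)
    event = outcomes["event"].to_numpy(dtype=bool)
    rng = np.random.default_rng(seed)
    member = np.zeros((n, n_null), dtype=bool)
    group1 = np.zeros((n, n_null), dtype=bool)
    for b in range(n_null):
        idx = rng.permutation(n)[: 2 * k]
        member[idx, b] = True
        group1[idx[:k], b] = True
    return logrank_pvalues_batch(time, event, member, group1)


def empirical_fdr(
    observed_p: float,
    null_ps: np.ndarray = None,
    outcomes: pd.DataFrame = None,
    k: int = None,
    n_null: int = 1000,
    seed: int = 0,
    pseudo_count: bool = False,
) -> float:
    """Fraction of null stratifications at least as significant as observed.

    Either pass precomputed ``null_ps`` (see :func:`null_logrank_pvalues`)
    or the outcome table plus ``k``. With ``pseudo_count`` the add-one
    estimator (1 + #null ≤ p)/(1 + n_null) guards exact zeros; default off.
    """
    if null_ps is None:
        if outcomes is None or k is None:
            raise ValueError("supply null_ps or (outcomes, k)")
        if n_null < 100:
            raise ValueError(f"n_null must be ≥ 100, got {n_null}")
        null_ps = null_logrank_pvalues(outcomes, k, n_null, seed)
    null_ps = np.asarray(null_ps, dtype=float)
    hits = int((null_ps <= observed_p).sum())
    if pseudo_count:
        return (1 + hits) / (1 + null_ps.size)
    return hits / null_ps.size


@dataclass
class LocusResult:
    feature: str
    mode: str
    n_plus: int
    n_minus: int
    result: CompareResult
    prognostic: bool


def single_locus_prognosis(
    feature: pd.Series,
    mode: Literal["mutation", "cna", "expression"],
    outcomes: pd.DataFrame,
    min_arm: int = 15,
) -> Optional[LocusResult]:
    """Survival stratification by a single gene's measurement.

    mutation: mutant vs wild-type (binary input required); cna/expression:
    positive vs negative values (amplified/deleted, activated/repressed on
    z-scores; zeros belong to neither arm). Evaluated only when both arms
    hold strictly more than ``min_arm`` patients; "prognostic" means Cox
    p < 0.05.
    """
    feature = feature.loc[feature.index.intersection(outcomes.index)].dropna()
    if mode == "mutation":
        uniq = set(np.unique(feature.to_numpy()))
        if not uniq <= {0, 1, False, True}:
            raise ValueError(f"mutation mode requires binary input, got values {sorted(uniq)[:5]}")
        plus_mask = feature.astype(bool)
        minus_mask = ~plus_mask
    elif mode in ("cna", "expression"):
        plus_mask = feature > 0
        minus_mask = feature < 0
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if plus_mask.sum() <= min_arm or minus_mask.sum() <= min_arm:
        return None
    labels = pd.Series("none", index=feature.index, dtype=object)
    labels[plus_mask] = "plus"
    labels[minus_mask] = "minus"
    res = compare_survival(labels, outcomes)
    prognostic = res.valid and not np.isnan(res.cox_p) and res.cox_p < 0.05
    return LocusResult(str(feature.name), mode, int(plus_mask.sum()),
                       int(minus_mask.sum()), res, prognostic)


def stouffer_combine(wald_zs: Sequence[float]) -> float:
    """Stouffer's method: Σz / √k."""
    zs = np.asarray(list(wald_zs), dtype=float)
    if zs.size == 0:
        raise ValueError("no z-scores to combine")
    return float(zs.sum() / np.sqrt(zs.size))


def module_vs_locus_ratio(
    module_zs: Sequence[float],
    locus_zs: Mapping[str, float],
) -> float:
    """log2 of |Stouffer-combined module z| over the best single-locus |z|
    (maximum across expression / copy-number / mutation stratifications).
    Infinite when the locus side is exactly zero."""
    if not locus_zs:
        raise ValueError("no locus results")
    num = abs(stouffer_combine(module_zs))
    den = max(abs(v) for v in locus_zs.values())
    if den == 0:
        return float("inf")
    return float(np.log2(num / den))


@dataclass
class MultivariateCoxResult:
    summary: pd.DataFrame  # per-covariate HR, p
    arm_significant: bool
    n_dropped: int
    flagged: list[str]


def multivariate_cox(
    labels: pd.Series,
    outcomes: pd.DataFrame,
    covariates: pd.DataFrame,
) -> MultivariateCoxResult:
    """Joint Cox PH fit of the arm indicator plus clinical covariates.

    Categorical covariates are one-hot encoded (first level dropped); rows
    with missing values are excluded (count logged). Collinear or otherwise
    unstable covariates are flagged rather than fatal.
    """
    keep = labels[labels.isin(["plus", "minus"])].index
    cov = covariates.loc[covariates.index.intersection(keep)]
    cov = pd.get_dummies(cov, drop_first=True, dtype=float)
    df = cov.join(outcomes.loc[cov.index, ["time", "event"]])
    df["arm"] = (labels.loc[cov.index] == "plus").astype(float)
    n_before = len(df)
    df = df.dropna()
    n_dropped = n_before - len(df)
    if n_dropped:
        logger.info("multivariate_cox: dropped %d rows with missing covariates", n_dropped)
    df["event"] = df["event"].astype(int)

    flagged = [c for c in cov.columns if df[c].nunique() <= 1
               or np.isclose(abs(np.corrcoef(df[c], df["arm"])[0, 1]), 1.0)]
    fit_cols = [c for c in df.columns if c not in flagged]
    cph = CoxPHFitter(penalizer=0.0)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df[fit_cols], duration_col="time", event_col="event")
        summary = cph.summary[["exp(coef)", "p"]].rename(
            columns={"exp(coef)": "hr"})
        arm_sig = bool(summary.loc["arm", "p"] < 0.05)
    except (ConvergenceError, ValueError) as exc:
        logger.warning("multivariate Cox failed: %s", exc)
        summary = pd.DataFrame(columns=["hr", "p"])
        arm_sig = False
        flagged = flagged + ["<fit failed>"]
    return MultivariateCoxResult(summary, arm_sig, n_dropped, flagged)
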