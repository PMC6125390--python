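"""Prognostic evaluation of image features against time-to-event outcomes.

The evaluation frame mirrors common practice for small retrospective
biomarker cohorts:

* discrimination of the raw continuous feature by the ROC AUC
  (Mann-Whitney estimator, bootstrap CI and over-optimism correction),
* outcome-based dichotomization at the cutpoint maximizing the two-group
  log-rank statistic (an exhaustive X-tile-style scan with a minimum group
  size), with the optimism this induces exposed by re-running the scan
  inside every bootstrap resample,
* univariate Cox proportional-hazards regression on the dichotomized
  groups (Efron ties, via lifelines) with bootstrap bias-corrected CIs,
* a Schoenfeld-residual check of the PH assumption,
* forward-entry (P < 0.20) / backward-stay (P < 0.05) multivariate Cox
  selection,
* Kaplan-Meier summaries and a Spearman feature-correlation matrix.

A feature may legitimately point either way: AUC < 0.5 / HR < 1 flags an
association with LOW risk, and the report keeps that direction explicit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test, proportional_hazard_test
from scipy import stats


class EvaluationError(ValueError):
    """The requested statistic is undefined for this input."""


# --------------------------------------------------------------------- ROC


@dataclass(frozen=True)
class AUCResult:
    auc: float
    auc_corrected: float
    ci_low: float
    ci_high: float
    p_value: float
    low_risk_direction: bool  # AUC < 0.5: higher values associate with low risk
    n_boot: int
    seed: int


def mann_whitney_auc(feature: np.ndarray, outcome: np.ndarray) -> float:
    """AUC as the Mann-Whitney U statistic / (n1 * n0), ties counted half."""
    x = np.asarray(feature, dtype=np.float64)
    y = np.asarray(outcome).astype(bool)
    if y.all() or not y.any():
        raise EvaluationError("both outcome classes must be present")
    pos, neg = x[y], x[~y]
    # rank-based U: robust to ties, O(n log n)
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def roc_auc(
    feature: np.ndarray,
    outcome: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
) -> AUCResult:
    """Continuous-value ROC AUC with bootstrap CI and optimism correction.

    The p-value comes from the normal approximation to the Mann-Whitney
    null (tie-corrected, two-sided).  The bootstrap resamples patients with
    replacement; the bias-corrected point estimate is
    ``2 * observed - mean(bootstrap)``.
    """
    x = np.asarray(feature, dtype=np.float64)
    y = np.asarray(outcome).astype(bool)
    auc = mann_whitney_auc(x, y)
    mw = stats.mannwhitneyu(x[y], x[~y], alternative="two-sided", method="asymptotic")

    rng = np.random.default_rng(seed)
    n = x.size
    boots = []
    attempts = 0
    while len(boots) < n_boot and attempts < 20 * max(n_boot, 1):
        attempts += 1
        idx = rng.integers(0, n, n)
        yb = y[idx]
        if yb.all() or not yb.any():
            continue  # resample lost one class; draw again
        boots.append(mann_whitney_auc(x[idx], yb))
    boots = np.asarray(boots)
    if boots.size:
        lo, hi = np.percentile(boots, [2.5, 97.5])
        corrected = 2 * auc - boots.mean()
    else:
        lo = hi = corrected = auc
    return AUCResult(
        auc=auc,
        auc_corrected=float(corrected),
        ci_low=float(lo),
        ci_high=float(hi),
        p_value=float(mw.pvalue),
        low_risk_direction=auc < 0.5,
        n_boot=int(boots.size),
        seed=seed,
    )


# ------------------------------------------------------------- log-rank scan


def _logrank_chi2_grid(
    feature: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    cuts: np.ndarray,
) -> np.ndarray:
    """Two-group log-rank chi-square for every cutpoint, vectorized.

    Group 1 = feature > cut.  Returns one chi-square per cut (NaN where a
    group has no variance contribution).
    """
    order = np.argsort(time, kind="stable")
    t, d = time[order], event[order].astype(bool)
    x = feature[order]
    g1 = x[None, :] > cuts[:, None]  # (cuts, patients), sorted by time

    et = t[d]
    uniq, first = np.unique(et, return_index=True)
    # at-risk sets: patients with t >= each unique event time
    at_risk_start = np.searchsorted(t, uniq, side="left")
    n_total = t.size

    n1_cum = np.cumsum(g1, axis=1)  # group-1 patients with time <= t[i]
    n1_at_risk = g1.sum(axis=1, keepdims=True) - np.concatenate(
        [np.zeros((cuts.size, 1)), n1_cum], axis=1
    )[:, at_risk_start]
    n_at_risk = (n_total - at_risk_start)[None, :].astype(np.float64)

    # events per unique time, split by group
    d1_by_time = np.zeros((cuts.size, uniq.size))
    d_by_time = np.zeros(uniq.size)
    ev_idx = np.nonzero(d)[0]
    pos = np.searchsorted(uniq, t[ev_idx])
    np.add.at(d_by_time, pos, 1.0)
    for k, i in zip(pos, ev_idx):
        d1_by_time[:, k] += g1[:, i]

    p1 = n1_at_risk / n_at_risk
    o = d1_by_time.sum(axis=1)
    e = (d_by_time[None, :] * p1).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        v_terms = (
            d_by_time[None, :]
            * p1
            * (1 - p1)
            * (n_at_risk - d_by_time[None, :])
            / np.maximum(n_at_risk - 1.0, 1.0)
        )
    v = v_terms.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = np.where(v > 0, (o - e) ** 2 / v, np.nan)
    return chi2


def optimal_cutpoint(
    feature: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    min_group_frac: float = 0.10,
) -> float:
    """Outcome-based cutpoint: exhaustive log-rank scan over midpoints.

    Every midpoint between consecutive sorted distinct feature values that
    leaves at least ``min_group_frac`` of patients on each side is scored by
    the two-group log-rank statistic; the maximizing cut is returned, ties
    broken toward the more balanced split.
    """
    x = np.asarray(feature, dtype=np.float64)
    t = np.asarray(time, dtype=np.float64)
    d = np.asarray(event).astype(int)
    uniq = np.unique(x)
    if uniq.size < 10:
        raise EvaluationError("need >= 10 distinct feature values for a cutpoint scan")
    cuts = (uniq[:-1] + uniq[1:]) / 2.0
    n = x.size
    n_high = (x[None, :] > cuts[:, None]).sum(axis=1)
    min_n = min_group_frac * n
    ok = (n_high >= min_n) & ((n - n_high) >= min_n)
    if not ok.any():
        raise EvaluationError("no admissible split at the given minimum group size")
    cuts = cuts[ok]
    chi2 = _logrank_chi2_grid(x, t, d, cuts)
    if np.all(np.isnan(chi2)):
        raise EvaluationError("log-rank statistic undefined at every admissible split")
    best = np.nanmax(chi2)
    tied = np.nonzero(np.isclose(chi2, best, rtol=0, atol=1e-12))[0]
    if tied.size > 1:
        balance = np.abs((x[None, :] > cuts[tied, None]).sum(axis=1) - n / 2.0)
        tied = tied[np.argsort(balance, kind="stable")]
    return float(cuts[tied[0]])


# ----------------------------------------------------------------- Cox fits


@dataclass(frozen=True)
class CoxResult:
    hr: float
    ci_low: float
    ci_high: float
    p_value: float
    coef: float
    low_risk_direction: bool
    monotone_likelihood: bool
    n_boot: int
    seed: int
    boot_ci_low: float = float("nan")
    boot_ci_high: float = float("nan")


def _fit_cox(df: pd.DataFrame, penalizer: float = 0.0) -> CoxPHFitter:
    cph = CoxPHFitter(penalizer=penalizer)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col="time", event_col="event")
    return cph


def cox_univariate(
    group: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
) -> CoxResult:
    """Univariate Cox PH fit on a binary risk grouping.

    Efron tie handling (lifelines default).  The Wald CI/p come from the
    partial-likelihood fit; when ``n_boot > 0`` a nonparametric bootstrap
    stratified by group adds a bias-corrected percentile CI.  If every event
    falls in one group the partial likelihood is monotone (HR diverges);
    the fit is then stabilized with a small ridge penalty and flagged.
    """
    g = np.asarray(group).astype(int)
    t = np.asarray(time, dtype=np.float64)
    d = np.asarray(event).astype(int)
    if d.sum() == 0:
        raise EvaluationError("no events: hazard ratio undefined")
    if np.unique(g).size != 2:
        raise EvaluationError("group must be binary")

    monotone = d[g == 0].sum() == 0 or d[g == 1].sum() == 0
    df = pd.DataFrame({"group": g, "time": t, "event": d})
    try:
        cph = _fit_cox(df, penalizer=0.01 if monotone else 0.0)
    except ConvergenceError:
        monotone = True
        cph = _fit_cox(df, penalizer=0.1)
    coef = float(cph.params_["group"])
    ci = cph.confidence_intervals_.loc["group"]
    p = float(cph.summary.loc["group", "p"])

    rng = np.random.default_rng(seed)
    boots = []
    if n_boot > 0:
        idx0, idx1 = np.nonzero(g == 0)[0], np.nonzero(g == 1)[0]
        attempts = 0
        while len(boots) < n_boot and attempts < 10 * n_boot:
            attempts += 1
            bi = np.concatenate(
                [
                    rng.choice(idx0, idx0.size, replace=True),
                    rng.choice(idx1, idx1.size, replace=True),
                ]
            )
            if d[bi].sum() == 0:
                continue
            bd = df.iloc[bi]
            try:
                boots.append(float(_fit_cox(bd, penalizer=0.01).params_["group"]))
            except ConvergenceError:
                continue
    if boots:
        b = np.asarray(boots)
        bias_corr = 2 * coef - b.mean()
        blo, bhi = np.percentile(b, [2.5, 97.5])
        shift = bias_corr - b.mean()
        boot_lo, boot_hi = float(np.exp(blo + shift)), float(np.exp(bhi + shift))
    else:
        boot_lo = boot_hi = float("nan")

    with np.errstate(over="ignore"):  # separation: HR legitimately diverges
        hr_point = float(np.exp(coef))
        ci_lo_hr = float(np.exp(ci.iloc[0]))
        ci_hi_hr = float(np.exp(ci.iloc[1]))
    return CoxResult(
        hr=hr_point,
        ci_low=ci_lo_hr,
        ci_high=ci_hi_hr,
        p_value=p,
        coef=coef,
        low_risk_direction=coef < 0,
        monotone_likelihood=monotone,
        n_boot=len(boots),
        seed=seed,
        boot_ci_low=boot_lo,
        boot_ci_high=boot_hi,
    )


def schoenfeld_ph_test(
    covariates: pd.DataFrame, time: np.ndarray, event: np.ndarray
) -> dict[str, float]:
    """Schoenfeld-residual PH check: per-covariate p-values.

    Tests the correlation of scaled Schoenfeld residuals with (rank-
    transformed) event time for each covariate of a Cox fit.
    """
    d = np.asarray(event).astype(int)
    if d.sum() < 5:
        raise EvaluationError("need >= 5 events for a Schoenfeld PH test")
    df = covariates.copy()
    df["time"] = np.asarray(time, dtype=np.float64)
    df["event"] = d
    cph = _fit_cox(df)
    res = proportional_hazard_test(cph, df, time_transform="rank")
    out = {}
    for name in covariates.columns:
        out[name] = float(res.summary.loc[name, "p"].iloc[0]) if isinstance(
            res.summary.loc[name, "p"], pd.Series
        ) else float(res.summary.loc[name, "p"])
    return out


@dataclass
class MultivariateResult:
    selected: pd.DataFrame  # coef, hr, ci_low, ci_high, p per retained feature
    entered: list[str]
    dropped_collinear: list[str]


def cox_multivariate(
    features: pd.DataFrame,
    time: np.ndarray,
    event: np.ndarray,
    entry_p: float = 0.20,
    stay_p: float = 0.05,
) -> MultivariateResult:
    """Forward-entry / backward-elimination multivariate Cox selection.

    Candidates with univariate Wald P < ``entry_p`` enter the full model;
    backward elimination then drops the worst covariate until every retained
    one satisfies P < ``stay_p``.  Perfectly collinear candidates (|rho| >
    0.999 with an earlier one) are dropped up front and flagged.  An empty
    final model is a legitimate outcome, not an error.
    """
    if features.shape[1] < 2:
        raise EvaluationError("need >= 2 candidate features")
    d = np.asarray(event).astype(int)
    t = np.asarray(time, dtype=np.float64)
    if d.sum() < 5:
        raise EvaluationError("need >= 5 events for multivariate selection")

    cols = list(features.columns)
    dropped = []
    corr = features.corr().abs()
    for i, c in enumerate(cols):
        if c in dropped:
            continue
        for c2 in cols[i + 1 :]:
            if c2 not in dropped and corr.loc[c, c2] > 0.999:
                dropped.append(c2)
    cols = [c for c in cols if c not in dropped]

    entered = []
    for c in cols:
        df = pd.DataFrame({c: features[c].to_numpy(), "time": t, "event": d})
        try:
            cph = _fit_cox(df)
        except ConvergenceError:
            continue
        if float(cph.summary.loc[c, "p"]) < entry_p:
            entered.append(c)

    current = list(entered)
    cph = None
    while current:
        df = features[current].copy()
        df["time"], df["event"] = t, d
        try:
            cph = _fit_cox(df)
        except ConvergenceError:
            cph = _fit_cox(df, penalizer=0.1)
        pvals = cph.summary["p"]
        worst = pvals.idxmax()
        if pvals[worst] >= stay_p:
            current.remove(worst)
            cph = None
        else:
            break

    if current and cph is not None:
        s = cph.summary
        selected = pd.DataFrame(
            {
                "coef": s["coef"],
                "hr": np.exp(s["coef"]),
                "ci_low": np.exp(s["coef lower 95%"]),
                "ci_high": np.exp(s["coef upper 95%"]),
                "p": s["p"],
            }
        )
    else:
        selected = pd.DataFrame(columns=["coef", "hr", "ci_low", "ci_high", "p"])
    return MultivariateResult(selected=selected, entered=entered, dropped_collinear=dropped)


# ----------------------------------------------------- KM, Spearman, report


def km_summary(
    group: np.ndarray, time: np.ndarray, event: np.ndarray
) -> tuple[pd.DataFrame, float]:
    """Kaplan-Meier step curves per group plus the two-sided log-rank p."""
    g = np.asarray(group)
    t = np.asarray(time, dtype=np.float64)
    d = np.asarray(event).astype(int)
    labels = np.unique(g)
    if labels.size != 2 or min((g == l).sum() for l in labels) == 0:
        raise EvaluationError("need two non-empty groups")
    frames = []
    for lab in labels:
        sel = g == lab
        kmf = KaplanMeierFitter()
        kmf.fit(t[sel], d[sel], label=str(lab))
        sf = kmf.survival_function_
        frames.append(
            pd.DataFrame(
                {
                    "group": lab,
                    "time_months": sf.index.to_numpy(),
                    "survival": sf.iloc[:, 0].to_numpy(),
                }
            )
        )
    lr = logrank_test(t[g == labels[0]], t[g == labels[1]], d[g == labels[0]], d[g == labels[1]])
    return pd.concat(frames, ignore_index=True), float(lr.p_value)


def spearman_matrix(features: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Spearman rank correlations (average ranks for ties) with p-values.

    Returns (rho, p, constant_columns); correlations involving a constant
    column are undefined and reported as NaN.
    """
    if len(features) < 3:
        raise EvaluationError("need >= 3 records for rank correlation")
    cols = list(features.columns)
    constant = [c for c in cols if features[c].nunique() <= 1]
    k = len(cols)
    rho = np.full((k, k), np.nan)
    pvals = np.full((k, k), np.nan)
    for i in range(k):
        rho[i, i], pvals[i, i] = 1.0, 0.0
        for j in range(i + 1, k):
            if cols[i] in constant or cols[j] in constant:
                continue
            r, p = stats.spearmanr(features[cols[i]], features[cols[j]])
            rho[i, j] = rho[j, i] = r
            pvals[i, j] = pvals[j, i] = p
    return (
        pd.DataFrame(rho, index=cols, columns=cols),
        pd.DataFrame(pvals, index=cols, columns=cols),
        constant,
    )


def evaluate_feature(
    feature: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
    min_group_frac: float = 0.10,
) -> dict[str, float]:
    """Full per-feature report row: AUC, cutpoint, Cox HR, optimism-corrected p.

    The uncorrected Cox p is the Wald p at the outcome-optimized cutpoint and
    is biased optimistic; the bootstrap-corrected p re-runs the cutpoint scan
    inside every resample, shrinks the observed coefficient by the median
    resampling optimism (median is used because near-separation resamples
    produce heavy-tailed coefficients) and refers it to the observed Wald
    standard error.  Both p-values are reported side by side.
    """
    x = np.asarray(feature, dtype=np.float64)
    t = np.asarray(time, dtype=np.float64)
    d = np.asarray(event).astype(int)
    auc = roc_auc(x, d, n_boot=n_boot, seed=seed)
    cut = optimal_cutpoint(x, t, d, min_group_frac)
    g = (x > cut).astype(int)
    cox = cox_univariate(g, t, d, n_boot=0, seed=seed)

    # optimism correction: repeat selection + fit inside each resample
    rng = np.random.default_rng(seed + 1)
    coefs = []
    n = x.size
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        if d[idx].sum() == 0:
            continue
        try:
            c = optimal_cutpoint(x[idx], t[idx], d[idx], min_group_frac)
            gb = (x[idx] > c).astype(int)
            if np.unique(gb).size < 2:
                continue
            coefs.append(cox_univariate(gb, t[idx], d[idx], n_boot=0).coef)
        except (EvaluationError, ConvergenceError):
            continue
    if coefs:
        b = np.asarray(coefs)
        optimism = float(np.median(b)) - cox.coef  # selection inflates |coef|
        coef_corr = cox.coef - optimism
        se_obs = (np.log(cox.ci_high) - np.log(cox.ci_low)) / (2 * stats.norm.ppf(0.975))
        z = coef_corr / se_obs if np.isfinite(se_obs) and se_obs > 0 else float("nan")
        p_boot = float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else float("nan")
        hr_lo, hr_hi = np.exp(np.percentile(b, [2.5, 97.5]))
    else:
        p_boot, hr_lo, hr_hi = float("nan"), float("nan"), float("nan")

    return {
        "auc": auc.auc,
        "auc_corrected": auc.auc_corrected,
        "auc_lo": auc.ci_low,
        "auc_hi": auc.ci_high,
        "auc_p": auc.p_value,
        "cutpoint": cut,
        "hr": cox.hr,
        "hr_lo": cox.ci_low,
        "hr_hi": cox.ci_high,
        "hr_boot_lo": float(hr_lo),
        "hr_boot_hi": float(hr_hi),
        "hr_p": cox.p_value,
        "hr_p_boot": p_boot,
        "low_risk_direction": float(auc.low_risk_direction),
        "seed": float(seed),
    }
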