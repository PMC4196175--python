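"""Survival-based performance metrics for risk stratifications.

Per cohort: Kaplan-Meier curves, the logrank (Mantel-Haenszel) test, the
hazard ratio between predicted risk groups from a univariate Cox fit,
Harrell's concordance index, and sensitivity/specificity/BCR for
classifying progression within a horizon. Cohort estimates are pooled by
fixed-effect inverse-variance weighting (log-HR pooled on the log scale).

KM, logrank and the concordance index are implemented here as vectorized
numpy primitives: the random-signature null recomputes them thousands of
times, so they must be cheap; tests check them against brute-force
enumeration and against lifelines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from scipy import stats

from .datatypes import CychypError, KMCurve


def km_estimate(time: Sequence[float], event: Sequence[int]) -> KMCurve:
    """Product-limit survival estimate.

    Steps occur at distinct event times; censored observations only shrink
    the risk sets.
    """
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    if t.size == 0:
        raise CychypError("need at least one observation")
    order = np.argsort(t, kind="mergesort")
    t, e = t[order], e[order]
    n = t.size
    event_times = np.unique(t[e == 1])
    surv, at_risk = [], []
    s = 1.0
    for et in event_times:
        nr = int(np.sum(t >= et))
        d = int(np.sum((t == et) & (e == 1)))
        s *= 1.0 - d / nr
        surv.append(s)
        at_risk.append(nr)
    return KMCurve(event_times, np.asarray(surv), np.asarray(at_risk, dtype=int))


def logrank_test(group: Sequence, time: Sequence[float],
                 event: Sequence[int]) -> tuple[float, float]:
    """Two-group logrank (Mantel-Haenszel) test.

    Observed-minus-expected events in group 1 with hypergeometric variance
    at each distinct event time; returns (chi-square, p) with df = 1.
    """
    g = np.asarray(group)
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    uniq = np.unique(g)
    if len(uniq) != 2:
        raise CychypError("logrank needs exactly two non-empty groups")
    in1 = g == uniq[1]
    o_minus_e, var = 0.0, 0.0
    for et in np.unique(t[e == 1]):
        at = t >= et
        n = int(at.sum())
        n1 = int((at & in1).sum())
        dead = (t == et) & (e == 1)
        d = int(dead.sum())
        d1 = int((dead & in1).sum())
        o_minus_e += d1 - n1 * d / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0, 1.0
    chi2 = o_minus_e ** 2 / var
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def cox_hr(group: Sequence, time: Sequence[float],
           event: Sequence[int]) -> tuple[float, tuple[float, float], float]:
    """Univariate Cox hazard ratio of group 1 versus group 0.

    Returns (HR, (lo95, hi95), Wald p). When one group has no events the
    likelihood is monotone; the fit is flagged with a warning and the CI
    bound diverges.
    """
    g = np.asarray(group)
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    uniq = np.unique(g)
    if len(uniq) != 2:
        raise CychypError("hazard ratio needs two groups")
    if e.sum() == 0:
        raise CychypError("no events")
    ind = (g == uniq[1]).astype(float)
    monotone = e[ind == 1].sum() == 0 or e[ind == 0].sum() == 0
    df = pd.DataFrame({"t": t, "e": e, "x": ind})
    fitter = CoxPHFitter(penalizer=1e-6 if monotone else 0.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fitter.fit(df, duration_col="t", event_col="e")
    beta = float(fitter.params_.iloc[0])
    se = float(fitter.standard_errors_.iloc[0])
    if monotone:
        warnings.warn("monotone partial likelihood: a group has no events; "
                      "HR confidence bound diverges")
        lo, hi = (0.0, np.inf) if beta < 0 else (np.exp(beta - 1.96 * se), np.inf)
        return float(np.exp(beta)), (lo, hi), 1.0
    lo, hi = np.exp(beta - 1.96 * se), np.exp(beta + 1.96 * se)
    p = 2 * stats.norm.sf(abs(beta) / se) if se > 0 else (0.0 if beta else 1.0)
    return float(np.exp(beta)), (float(lo), float(hi)), float(p)


def concordance_index(score: Sequence[float], time: Sequence[float],
                      event: Sequence[int]) -> tuple[float, float]:
    """Harrell's c over usable pairs, with a pair-based standard error.

    A pair is usable when the earlier time is an event (censoring makes the
    ordering of the other pairs unknowable). Score ties get half credit.
    The standard error is the binomial-style sqrt(c(1-c)/m) over the m
    usable pairs.
    """
    s = np.asarray(score, dtype=float)
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    if s.size < 2:
        raise CychypError("need at least two patients")
    # usable pair (i, j): t_i < t_j and event_i
    ti, tj = t[:, None], t[None, :]
    si, sj = s[:, None], s[None, :]
    usable = (ti < tj) & (e[:, None] == 1)
    m = int(usable.sum())
    if m == 0:
        raise CychypError("no usable pairs under censoring")
    conc = float((usable & (si > sj)).sum())
    ties = float((usable & (si == sj)).sum())
    c = (conc + 0.5 * ties) / m
    se = float(np.sqrt(max(c * (1 - c), 1e-12) / m))
    return float(c), se


def binary_metrics_at_horizon(
    group: Sequence, time: Sequence[float], event: Sequence[int],
    horizon: float = 5.0,
) -> tuple[float, float, float, float]:
    """Sensitivity, specificity, BCR and Z-test p at a survival horizon.

    Cases are events within the horizon; controls are patients event-free
    with follow-up reaching the horizon; patients censored earlier are
    excluded. ``group`` is boolean-like with True/1 = high risk. The p-value
    is a one-sample Z-test of BCR against the no-discrimination value 0.5.
    """
    g = np.asarray(group).astype(bool)
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    case = (e == 1) & (t <= horizon)
    control = (t >= horizon) & ~case
    n_case, n_ctrl = int(case.sum()), int(control.sum())
    if n_case == 0 or n_ctrl == 0:
        raise CychypError("need at least one case and one control at the horizon")
    sens = float(g[case].mean())
    spec = float((~g[control]).mean())
    bcr = 0.5 * (sens + spec)
    var = 0.25 * (sens * (1 - sens) / n_case + spec * (1 - spec) / n_ctrl)
    if var == 0:
        p = 1.0 if bcr == 0.5 else 0.0
    else:
        p = float(2 * stats.norm.sf(abs(bcr - 0.5) / np.sqrt(var)))
    return sens, spec, bcr, p


def pool_estimates(per_cohort: Sequence[tuple[float, float]],
                   scale: str = "log-HR") -> tuple[float, float, float]:
    """Fixed-effect inverse-variance pooling of per-cohort estimates.

    ``scale`` is documentation of what is being pooled ("log-HR",
    "c-index", "BCR", ...); estimates must already be on the additive
    scale (pass log HRs, not HRs). Returns (pooled, se, two-sided p versus
    the scale's null: 0 for log-HR, 0.5 otherwise).
    """
    if len(per_cohort) == 0:
        raise CychypError("nothing to pool")
    est = np.array([x for x, _ in per_cohort], dtype=float)
    se = np.array([s for _, s in per_cohort], dtype=float)
    if (se <= 0).any():
        raise CychypError("standard errors must be positive")
    w = 1.0 / se ** 2
    pooled = float(np.sum(w * est) / np.sum(w))
    pooled_se = float(np.sqrt(1.0 / np.sum(w)))
    null = 0.0 if scale == "log-HR" else 0.5
    p = float(2 * stats.norm.sf(abs(pooled - null) / pooled_se))
    return pooled, pooled_se, p


def compare_paired(
    metric_fn: Callable[[np.ndarray, np.ndarray], float],
    strat_a: Sequence, strat_b: Sequence,
    time: Sequence[float], event: Sequence[int],
    n_boot: int = 1000, seed: int = 0,
) -> float:
    """Two-sided p for metric(A) - metric(B) on the same patients.

    Patient-level bootstrap: resample patients with replacement, recompute
    both metrics on each replicate, and form a normal-approximation p from
    the observed difference and the bootstrap standard deviation of the
    difference. ``metric_fn(groups, idx)`` maps a stratification restricted
    to resampled indices to a scalar (larger = better).
    """
    a = np.asarray(strat_a)
    b = np.asarray(strat_b)
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    if a.shape != b.shape:
        raise CychypError("stratifications must cover the same patients")
    rng = np.random.default_rng(seed)
    n = len(a)

    def metric(groups: np.ndarray, idx: np.ndarray) -> float:
        return metric_fn(groups[idx], idx)

    idx0 = np.arange(n)
    d_obs = metric(a, idx0) - metric(b, idx0)
    diffs = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            diffs.append(metric(a, idx) - metric(b, idx))
        except CychypError:
            continue  # degenerate replicate (e.g. one group vanished)
    sd = float(np.std(diffs)) if diffs else 0.0
    if sd == 0:
        warnings.warn("degenerate bootstrap: zero variance of the difference")
        return 1.0
    return float(2 * stats.norm.sf(abs(d_obs) / sd))


@dataclass
class EvalReport:
    """One row per cohort plus a pooled row of survival metrics."""

    rows: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(self.rows.to_json(orient="records", indent=2))

    def to_tsv(self, path: str | Path) -> None:
        self.rows.to_csv(path, sep="\t", index=False)


def evaluate_stratification(
    scores: Sequence[float], groups: Sequence, time: Sequence[float],
    event: Sequence[int], horizon: float = 5.0, cohort_id: str = "cohort",
) -> dict:
    """All per-cohort metrics for one risk stratification."""
    g = np.asarray(groups).astype(bool)
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    hr, (lo, hi), hr_p = cox_hr(g.astype(int), t, e)
    c, c_se = concordance_index(scores, t, e)
    c_p = float(2 * stats.norm.sf(abs(c - 0.5) / c_se)) if c_se > 0 else 1.0
    sens, spec, bcr, bcr_p = binary_metrics_at_horizon(g, t, e, horizon)
    chi2, lr_p = logrank_test(g.astype(int), t, e)
    return {
        "cohort": cohort_id, "n": int(len(t)), "n_events": int(e.sum()),
        "hr": hr, "hr_lo95": lo, "hr_hi95": hi, "hr_p": hr_p,
        "log_hr_se": (np.log(hi) - np.log(hr)) / 1.96 if np.isfinite(hi) and hi > 0 else np.nan,
        "cindex": c, "cindex_se": c_se, "cindex_p": c_p,
        "sensitivity": sens, "specificity": spec, "bcr": bcr, "bcr_p": bcr_p,
        "bcr_se": float(np.sqrt(0.25 * (sens * (1 - sens) / max(((e == 1) & (t <= horizon)).sum(), 1)
                                        + spec * (1 - spec) / max(((t >= horizon) & ~((e == 1) & (t <= horizon))).sum(), 1)))),
        "logrank_chi2": chi2, "logrank_p": lr_p,
    }


def evaluate_cohorts(
    per_cohort: Sequence[tuple[str, np.ndarray, np.ndarray, np.ndarray, np.ndarray]],
    horizon: float = 5.0,
) -> EvalReport:
    """Evaluate (cohort_id, scores, groups, time, event) tuples and pool.

    The pooled row combines log-HR, c-index and BCR by fixed-effect
    inverse-variance weighting; the pooled HR is the exponentiated pooled
    log-HR.
    """
    rows = [evaluate_stratification(s, g, t, e, horizon, cid)
            for cid, s, g, t, e in per_cohort]
    report = pd.DataFrame(rows)
    pooled: dict = {"cohort": "pooled",
                    "n": int(report["n"].sum()),
                    "n_events": int(report["n_events"].sum())}
    ok = report["log_hr_se"].notna() & (report["log_hr_se"] > 0)
    if ok.any():
        lhr, lhr_se, p = pool_estimates(
            list(zip(np.log(report.loc[ok, "hr"]), report.loc[ok, "log_hr_se"])),
            scale="log-HR")
        pooled.update(hr=float(np.exp(lhr)),
                      hr_lo95=float(np.exp(lhr - 1.96 * lhr_se)),
                      hr_hi95=float(np.exp(lhr + 1.96 * lhr_se)), hr_p=p)
    for key, se_key in (("cindex", "cindex_se"), ("bcr", "bcr_se")):
        okk = report[se_key] > 0
        if okk.any():
            est, se, p = pool_estimates(
                list(zip(report.loc[okk, key], report.loc[okk, se_key])),
                scale=key)
            pooled.update({key: est, f"{key}_se": se, f"{key}_p": p})
    return EvalReport(pd.concat([report, pd.DataFrame([pooled])],
                                ignore_index=True))
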