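"""Penalized Cox risk model over signature probesets.

The model is a linear risk score from an elastic-net-penalized Cox
proportional-hazards fit on a training cohort, with the penalty pair chosen
by cross-validated held-out partial likelihood, and a high/low decision
threshold placed on the training scores to balance sensitivity and
specificity for progression within a 5-year horizon.

Penalty convention: the objective is the negative Cox partial
log-likelihood plus l1*||b||_1 + l2/2*||b||_2^2. Penalized fits run through
scikit-survival's coxnet coordinate descent (alpha = l1+l2, l1_ratio =
l1/(l1+l2)); the unpenalized and pure-ridge cases run through lifelines'
Newton solver, which also provides standard errors.
"""

from __future__ import annotations

import warnings
from itertools import product
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

from .datatypes import (CohortDataset, CychypError, ExpressionMatrix,
                        RiskModel, Signature)


def censor_at(time: Sequence[float], event: Sequence[int],
              horizon: float) -> tuple[np.ndarray, np.ndarray]:
    """Administrative censoring: cap follow-up at a horizon.

    Events after the horizon are recoded as censored at the horizon; the
    event count can only decrease.
    """
    if horizon <= 0:
        raise CychypError("horizon must be positive")
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    if (t < 0).any():
        raise CychypError("negative survival times")
    capped = np.minimum(t, horizon)
    e_out = np.where(t > horizon, 0, e)
    return capped, e_out


def cox_partial_loglik(eta: np.ndarray, time: np.ndarray,
                       event: np.ndarray) -> float:
    """Breslow partial log-likelihood of a linear predictor."""
    order = np.argsort(time, kind="mergesort")
    t, e, lp = time[order], event[order], eta[order]
    # log of reverse-cumulative sum of exp(lp), stabilized
    m = lp.max()
    rev = np.log(np.cumsum(np.exp(lp[::-1] - m))[::-1]) + m
    # ties (Breslow): every event at time t uses the risk set {j: t_j >= t}
    first = np.searchsorted(t, t, side="left")
    return float(np.sum((lp - rev[first])[e == 1]))


def _fit_cox_coefs(X: np.ndarray, time: np.ndarray, event: np.ndarray,
                   l1: float, l2: float) -> np.ndarray:
    """Elastic-net Cox coefficients for one penalty pair on standardized X."""
    if l1 < 0 or l2 < 0:
        raise CychypError("penalty weights must be non-negative")
    if l1 > 0:
        alpha = l1 + l2
        ratio = l1 / alpha
        y = Surv.from_arrays(event=event.astype(bool), time=time)
        model = CoxnetSurvivalAnalysis(alphas=[alpha], l1_ratio=ratio,
                                       normalize=False,
                                       fit_baseline_model=False,
                                       max_iter=100000, tol=1e-7)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model.fit(X, y)
            return model.coef_[:, 0]
        except ArithmeticError:
            # coordinate descent can overflow at very small alphas;
            # fall through to the Newton solver
            warnings.warn("coxnet failed numerically at alpha="
                          f"{alpha:g}; refitting with the Newton solver")
    # lifelines penalty: penalizer*((1-l1_ratio)/2*||b||^2 + l1_ratio*||b||_1)
    df = pd.DataFrame(X, columns=[f"x{i}" for i in range(X.shape[1])])
    df["t"], df["e"] = time, event
    total = l1 + l2
    f = CoxPHFitter(penalizer=total, l1_ratio=l1 / total if total > 0 else 0.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f.fit(df, duration_col="t", event_col="e")
    return f.params_.to_numpy()


def fit_penalized_cox(
    train: CohortDataset,
    sig: Signature,
    l1_grid: Sequence[float] = (0.001, 0.01, 0.1),
    l2_grid: Sequence[float] = (0.001, 0.01, 0.1),
    cv_folds: int = 5,
    seed: int = 0,
    standardize: str = "per_cohort",
    horizon_years: float = 5.0,
) -> RiskModel:
    """Fit the elastic-net Cox model on a training cohort.

    Expression is restricted to the signature probesets and z-scored with
    training constants. The (l1, l2) pair is chosen from the grid by k-fold
    cross-validation on held-out Breslow partial log-likelihood (minimizer
    of the deviance; no one-standard-error rule); a single-pair grid skips
    cross-validation. The returned model has no threshold yet (see
    ``select_threshold``).
    """
    missing = [p for p in sig.probeset_ids if p not in train.expr.values.index]
    if missing:
        raise CychypError(f"signature probesets missing from training "
                          f"expression: {missing[:5]}...")
    time, event = train.time, train.event
    if event.sum() < cv_folds:
        raise CychypError("training cohort has fewer events than folds")

    X_raw = train.expr.values.loc[sig.probeset_ids].to_numpy(dtype=float).T
    center = X_raw.mean(axis=0)
    scale = X_raw.std(axis=0, ddof=0)
    scale[scale == 0] = 1.0
    X = (X_raw - center) / scale

    pairs = list(product(l1_grid, l2_grid))
    if len(pairs) == 1:
        best = pairs[0]
    else:
        rng = np.random.default_rng(seed)
        n = len(time)
        fold = rng.permutation(n) % cv_folds
        # re-deal folds that end up with no events (degenerate partial likelihood)
        for _ in range(20):
            bad = [f for f in range(cv_folds) if event[fold != f].sum() == 0]
            if not bad:
                break
            warnings.warn("degenerate cross-validation fold; resampling folds")
            fold = rng.permutation(n) % cv_folds
        score = {}
        for pair in pairs:
            total = 0.0
            for f in range(cv_folds):
                tr, te = fold != f, fold == f
                if event[te].sum() == 0:
                    continue
                beta = _fit_cox_coefs(X[tr], time[tr], event[tr], *pair)
                total += cox_partial_loglik(X[te] @ beta, time[te], event[te])
            score[pair] = total
        best = max(pairs, key=lambda p: (score[p], -p[0] - p[1]))

    beta = _fit_cox_coefs(X, time, event, *best)
    return RiskModel(list(sig.probeset_ids), beta, best[0], best[1],
                     center, scale, standardize=standardize,
                     horizon_years=horizon_years)


def risk_score(model: RiskModel, expr) -> np.ndarray:
    """Per-patient risk scores: coefficients dot standardized expression.

    ``expr`` is an ExpressionMatrix (or probesets x patients frame).
    Standardization follows the model's mode: per-cohort z-scoring by
    default, or the stored training constants.
    """
    values = expr.values if isinstance(expr, ExpressionMatrix) else pd.DataFrame(expr)
    missing = [p for p in model.probeset_ids if p not in values.index]
    if missing:
        raise CychypError(f"missing probesets for scoring: {missing}")
    X = values.loc[model.probeset_ids].to_numpy(dtype=float).T
    if model.standardize == "per_cohort":
        center = X.mean(axis=0)
        scale = X.std(axis=0, ddof=0)
        scale[scale == 0] = 1.0
    else:
        center, scale = model.center, model.scale
    return (X - center) / scale @ model.coefficients


def select_threshold(scores: Sequence[float], time: Sequence[float],
                     event: Sequence[int], horizon: float = 5.0) -> float:
    """Decision threshold maximizing balanced sensitivity/specificity.

    Cases are events within the horizon, controls are patients event-free
    with follow-up past the horizon; patients censored before the horizon
    are excluded. Candidate cuts are midpoints between consecutive distinct
    scores (high risk = score strictly above the cut); ties in the balanced
    classification rate break toward the higher cut, i.e. higher
    specificity.
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    case = (e == 1) & (t <= horizon)
    control = (t >= horizon) & ~case
    usable = case | control
    if case.sum() == 0 or control.sum() == 0:
        raise CychypError("need at least one case and one control at the horizon")
    s_u, case_u = s[usable], case[usable]
    uniq = np.unique(s_u)
    if len(uniq) == 1:
        return float(uniq[0])
    cuts = (uniq[:-1] + uniq[1:]) / 2
    high = s_u[None, :] > cuts[:, None]
    sens = (high & case_u).sum(axis=1) / case_u.sum()
    spec = (~high & ~case_u).sum(axis=1) / (~case_u).sum()
    bcr = 0.5 * (sens + spec)
    best = np.flatnonzero(bcr == bcr.max())[-1]  # last = highest cut
    return float(cuts[best])


def classify(scores: Sequence[float], model: RiskModel) -> pd.DataFrame:
    """High/low risk groups from the model's threshold (score > t = high)."""
    if model.threshold is None:
        raise CychypError("model has no decision threshold")
    s = np.asarray(scores, dtype=float)
    return pd.DataFrame({"score": s,
                         "group": np.where(s > model.threshold, "high", "low")})
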