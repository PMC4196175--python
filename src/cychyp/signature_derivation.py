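"""Resampling-based derivation of a discriminative probeset signature.

The derivation contrasts two oxygenation conditions: over many random
90/10 sample splits, probesets are scored on the training split by a Welch
t-test with Benjamini-Hochberg FDR correction, corrected p-values are
averaged across splits, and the top-k probesets by mean corrected p form
the signature. The held-out 10% estimates the discrimination potential via
a nearest-class-centroid classifier on the per-split top-k probesets.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import (CychypError, DegenerateSplitError, ExpressionMatrix,
                        ResamplingSummary, Signature)


def resample_split(
    design: pd.DataFrame,
    condition_pair: tuple[str, str],
    fraction: float = 0.9,
    seed: int | np.random.Generator = 0,
) -> tuple[list[str], list[str]]:
    """Random train/test partition of the samples of two conditions.

    Train size is round(fraction * n); the split is uniform over samples
    (not stratified by cell line). Raises ``DegenerateSplitError`` if a
    condition ends up with fewer than two training samples.
    """
    if not (0 < fraction < 1):
        raise CychypError("fraction must be in (0, 1)")
    sub = design[design["condition"].isin(condition_pair)]
    for cond in condition_pair:
        if (sub["condition"] == cond).sum() == 0:
            raise CychypError(f"condition {cond!r} absent from design")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    ids = sub["sample_id"].to_numpy()
    n_train = int(round(fraction * len(ids)))
    perm = rng.permutation(len(ids))
    train = list(ids[perm[:n_train]])
    test = list(ids[perm[n_train:]])
    cond_of = dict(zip(sub["sample_id"], sub["condition"]))
    for cond in condition_pair:
        if sum(cond_of[s] == cond for s in train) < 2:
            raise DegenerateSplitError(
                f"fewer than 2 training samples of condition {cond!r}")
    return train, test


def differential_test(
    values: np.ndarray | pd.DataFrame,
    labels: Sequence,
) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Welch two-sample t-test between the two label groups.

    ``labels`` assigns each column to one of two groups; the t sign follows
    mean(group2) - mean(group1) with groups in sorted label order. Rows with
    zero variance in both groups get t = 0, p = 1 when the means agree and
    p = 0 otherwise. Returns (t, p) arrays, one entry per row.
    """
    X = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise CychypError("labels must define exactly two groups")
    g1, g2 = X[:, labels == uniq[0]], X[:, labels == uniq[1]]
    if g1.shape[1] < 2 or g2.shape[1] < 2:
        raise CychypError("each group needs at least 2 samples")

    n1, n2 = g1.shape[1], g2.shape[1]
    m1, m2 = g1.mean(axis=1), g2.mean(axis=1)
    v1, v2 = g1.var(axis=1, ddof=1), g2.var(axis=1, ddof=1)
    se2 = v1 / n1 + v2 / n2
    diff = m2 - m1
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
        df = se2 ** 2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    degenerate = se2 == 0
    with np.errstate(invalid="ignore"):
        t[degenerate] = np.where(diff[degenerate] == 0, 0.0,
                                 np.sign(diff[degenerate]) * np.inf)
    p = np.ones_like(t)
    ok = ~degenerate
    p[ok] = 2 * stats.t.sf(np.abs(t[ok]), df[ok])
    p[degenerate & (diff != 0)] = 0.0
    return t, p


def fdr_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise CychypError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _top_k(mean_q: np.ndarray, mean_abs_t: np.ndarray,
           probes: np.ndarray, k: int) -> np.ndarray:
    """Top-k probes by ascending q; ties by larger |t|, then probe id."""
    order = np.lexsort((probes, -mean_abs_t, mean_q))
    return probes[order[:k]]


def holdout_accuracy(
    train_expr: pd.DataFrame,
    train_labels: Sequence,
    test_expr: pd.DataFrame,
    test_labels: Sequence,
    signature: Signature | Sequence[str],
) -> float:
    """Nearest-class-centroid accuracy on held-out samples.

    Centroids are per-condition means of the signature probesets in the
    training split; test samples are assigned to the closer centroid in
    Euclidean distance on log2 values.
    """
    probes = (signature.probeset_ids if isinstance(signature, Signature)
              else list(signature))
    if len(test_labels) == 0:
        raise CychypError("empty test set: accuracy undefined")
    Xtr = train_expr.loc[probes].to_numpy(dtype=float)
    Xte = test_expr.loc[probes].to_numpy(dtype=float)
    train_labels = np.asarray(train_labels)
    classes = np.unique(train_labels)
    centroids = np.column_stack([Xtr[:, train_labels == c].mean(axis=1)
                                 for c in classes])
    d = ((Xte[:, :, None] - centroids[:, None, :]) ** 2).sum(axis=0)
    pred = classes[np.argmin(d, axis=1)]
    return float(np.mean(pred == np.asarray(test_labels)))


def derive_signature(
    expr: ExpressionMatrix,
    design: pd.DataFrame,
    condition_pair: tuple[str, str] = ("normoxia", "cychyp"),
    k: int = 100,
    n_resamples: int = 200,
    fraction: float = 0.9,
    seed: int = 0,
) -> tuple[Signature, ResamplingSummary]:
    """Derive the top-k signature over repeated random splits.

    Per resampling: split, Welch t-test + BH correction on the training
    split only, and held-out nearest-centroid accuracy using that split's
    own top-k probesets. Probesets are ranked by the arithmetic mean of the
    corrected p-values across resamplings (ascending), ties broken by
    larger mean |t| then lexicographic probeset id.
    """
    if k > len(expr.probeset_ids):
        raise CychypError("k exceeds the number of probesets")
    if n_resamples < 1:
        raise CychypError("need at least one resampling")

    probes = np.asarray(expr.probeset_ids)
    cond_of = dict(zip(design["sample_id"], design["condition"]))
    rng = np.random.default_rng(seed)

    q_sum = np.zeros(len(probes))
    abs_t_sum = np.zeros(len(probes))
    accuracies: list[float] = []
    for _ in range(n_resamples):
        train, test = resample_split(design, condition_pair, fraction, rng)
        tr_labels = np.asarray([cond_of[s] for s in train])
        te_labels = np.asarray([cond_of[s] for s in test])
        tr = expr.values[train]
        t, p = differential_test(tr, tr_labels)
        q = fdr_adjust(p)
        q_sum += q
        abs_t = np.abs(t)
        abs_t = np.where(np.isfinite(abs_t), abs_t, np.finfo(float).max)
        abs_t_sum += abs_t
        top = _top_k(q, abs_t, probes, k)
        accuracies.append(holdout_accuracy(tr, tr_labels,
                                           expr.values[test], te_labels, top))

    mean_q = q_sum / n_resamples
    mean_abs_t = abs_t_sum / n_resamples
    top = _top_k(mean_q, mean_abs_t, probes, k)
    scores = pd.Series(mean_q, index=probes)
    signature = Signature(list(top), expr.platform, scores.loc[top])
    summary = ResamplingSummary(scores, pd.Series(mean_abs_t, index=probes),
                                n_resamples, fraction, accuracies)
    return signature, summary


def expand_signature(summary: ResamplingSummary, q_threshold: float) -> list[str]:
    """All probesets with mean corrected p below a threshold, best first."""
    if not (0 < q_threshold <= 1):
        raise CychypError("threshold must be in (0, 1]")
    hits = summary.mean_q[summary.mean_q < q_threshold]
    return list(hits.sort_values(kind="mergesort").index)
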