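"""Random-signature nulls, NPI risk groups, reclassification, subtypes.

The random-signature comparison asks whether a signature's prognostic
value exceeds what arbitrary probeset lists of the same size achieve: for
each random signature the *whole* pipeline (penalized Cox fit on the
training cohort, threshold, classification of the validation patients,
metric) is rerun, and the observed signature's metric is ranked within the
null values with the add-one empirical p-value (1+k)/(N+1), which never
reaches 0 and reproduces "P < 0.001" reporting at N = 1000.

The Nottingham Prognostic Index (NPI) combines tumour size, histological
grade and nodal stage: npi = 0.2*size_cm + grade + stage with stage 1 for
0 nodes, 2 for 1-3, 3 for >= 4; bands good <= 3.4 < moderate <= 5.4 < poor.
Moderate and poor are merged into a single high-risk group for comparison
with two-group molecular stratifications.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from .datatypes import CohortDataset, CychypError, NullDistribution, Signature
from .risk_model import classify, fit_penalized_cox, risk_score, select_threshold
from .survival_eval import (binary_metrics_at_horizon, concordance_index,
                            cox_hr, logrank_test)

#: configurable NPI constants
NPI_SIZE_WEIGHT = 0.2
NPI_GOOD_MAX = 3.4
NPI_MODERATE_MAX = 5.4

#: metric value recorded when a random-signature pipeline cannot discriminate
NO_SIGNAL_VALUE = {"logrank_logp": 0.0, "HR": 1.0, "cindex": 0.5, "BCR": 0.5}


def sample_random_signature(platform_probesets: Sequence[str], size: int,
                            seed: int, platform: str = "") -> Signature:
    """Uniform sample of probesets without replacement."""
    probes = list(platform_probesets)
    if size > len(probes):
        raise CychypError("signature size exceeds the probeset universe")
    rng = np.random.default_rng(seed)
    picked = rng.choice(len(probes), size=size, replace=False)
    return Signature([probes[i] for i in picked], platform)


def _pipeline_metric(
    train: CohortDataset,
    validations: Sequence[CohortDataset],
    sig: Signature,
    metric: str,
    l1: float,
    l2: float,
    horizon: float,
) -> float:
    """Fit -> threshold -> classify validations -> metric on pooled patients."""
    model = fit_penalized_cox(train, sig, l1_grid=[l1], l2_grid=[l2],
                              horizon_years=horizon)
    model.threshold = select_threshold(risk_score(model, train.expr),
                                       train.time, train.event, horizon)
    scores, groups, times, events = [], [], [], []
    for cohort in validations:
        s = risk_score(model, cohort.expr)
        scores.append(s)
        groups.append(classify(s, model)["group"].to_numpy() == "high")
        times.append(cohort.time)
        events.append(cohort.event)
    s = np.concatenate(scores)
    g = np.concatenate(groups)
    t = np.concatenate(times)
    e = np.concatenate(events)
    if metric == "logrank_logp":
        _, p = logrank_test(g.astype(int), t, e)
        return float(-np.log10(max(p, 1e-300)))
    if metric == "HR":
        return cox_hr(g.astype(int), t, e)[0]
    if metric == "cindex":
        return concordance_index(s, t, e)[0]
    if metric == "BCR":
        return binary_metrics_at_horizon(g, t, e, horizon)[2]
    raise CychypError(f"unknown metric {metric!r}")


def null_distribution(
    train: CohortDataset,
    validations: Sequence[CohortDataset],
    observed_signature: Signature,
    size: int,
    n_signatures: int,
    metric: str = "logrank_logp",
    seed: int = 0,
    l1: float = 1e-4,
    l2: float = 0.1,
    horizon: float = 5.0,
) -> NullDistribution:
    """Observed-vs-random-signature null for one metric.

    Random signatures of ``size`` probesets are drawn from the training
    cohort's (clinical-platform) probeset universe; each runs the full
    fit/threshold/classify pipeline at a fixed light penalty. A pipeline
    failure (e.g. a single predicted group) records the metric's
    no-discrimination value with a warning.
    """
    if n_signatures < 1:
        raise CychypError("need at least one random signature")
    universe = train.expr.probeset_ids
    rng = np.random.default_rng(seed)

    def run(sig: Signature) -> float:
        try:
            return _pipeline_metric(train, validations, sig, metric,
                                    l1, l2, horizon)
        except CychypError:
            warnings.warn("non-discriminating random signature; recording "
                          "the no-signal metric value")
            return NO_SIGNAL_VALUE[metric]

    observed = run(observed_signature)
    nulls = np.array([
        run(sample_random_signature(universe, size,
                                    seed=int(rng.integers(2 ** 31)),
                                    platform=train.expr.platform))
        for _ in range(n_signatures)
    ])
    return NullDistribution(metric, observed, nulls, n_signatures)


@dataclass
class NPIRecord:
    size_cm: float
    grade: int
    nodal_stage: int
    npi_value: float
    band: str
    merged_group: str


def npi_score(size_cm: float, grade: int, n_nodes: int) -> NPIRecord:
    """Nottingham Prognostic Index for one patient.

    Band boundaries are closed on the left group: a value of exactly 3.4 is
    good, exactly 5.4 is moderate. The merged two-group reading keeps good
    as low risk and pools moderate+poor as high risk.
    """
    if grade not in (1, 2, 3):
        raise CychypError("grade must be 1, 2 or 3")
    if size_cm < 0 or n_nodes < 0:
        raise CychypError("size and node count must be non-negative")
    stage = 1 if n_nodes == 0 else (2 if n_nodes <= 3 else 3)
    npi = NPI_SIZE_WEIGHT * size_cm + grade + stage
    band = ("good" if npi <= NPI_GOOD_MAX
            else "moderate" if npi <= NPI_MODERATE_MAX
            else "poor")
    return NPIRecord(float(size_cm), int(grade), stage, float(npi), band,
                     "low" if band == "good" else "high")


def npi_groups(clinical: pd.DataFrame) -> pd.Series:
    """Merged NPI risk group per patient of a clinical table."""
    recs = [npi_score(r.size_cm, int(r.grade), int(r.n_nodes))
            for r in clinical.itertuples()]
    return pd.Series([r.merged_group for r in recs], index=clinical.index)


def reclassification(npi_group: Sequence, model_group: Sequence,
                     time: Sequence[float], event: Sequence[int]) -> dict:
    """Cross-tabulate NPI versus model risk groups on the same patients.

    Reports the 2x2 counts, the fraction of NPI-high patients the model
    reclassifies as low (candidate over-treatment) and of NPI-low patients
    reclassified high (candidate under-treatment), and the four survival
    subgroups for downstream KM/logrank.
    """
    npi = np.asarray(npi_group)
    mod = np.asarray(model_group)
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    if npi.shape != mod.shape:
        raise CychypError("groupings must cover the same patients")
    table = {(a, b): int(np.sum((npi == a) & (mod == b)))
             for a in ("high", "low") for b in ("high", "low")}
    n_npi_high = table[("high", "high")] + table[("high", "low")]
    n_npi_low = table[("low", "high")] + table[("low", "low")]
    subgroups = {
        f"npi_{a}_model_{b}": {"time": t[(npi == a) & (mod == b)].tolist(),
                               "event": e[(npi == a) & (mod == b)].tolist()}
        for a in ("high", "low") for b in ("high", "low")
    }
    return {
        "table": {f"npi_{a}_model_{b}": table[(a, b)]
                  for a in ("high", "low") for b in ("high", "low")},
        "frac_npi_high_reclassified_low":
            table[("high", "low")] / n_npi_high if n_npi_high else np.nan,
        "frac_npi_low_reclassified_high":
            table[("low", "high")] / n_npi_low if n_npi_low else np.nan,
        "subgroups": subgroups,
    }


def assign_subtype(cohort: CohortDataset, er_probe: str | None = None,
                   her2_probe: str | None = None) -> pd.Series:
    """ER/HER2 subtype per patient.

    Clinical labels win when present. Otherwise each marker probeset's
    expression is split by a two-component Gaussian mixture per cohort
    (positive = higher-mean component). HER2-positive takes precedence:
    subtypes are HER2+, ER+/HER2- and ER-/HER2-.
    """
    clin = cohort.clinical
    if {"er", "her2"}.issubset(clin.columns) and clin["er"].notna().all():
        er_pos = clin["er"].astype(str) == "+"
        her2_pos = clin["her2"].astype(str) == "+"
    elif er_probe is not None and her2_probe is not None:
        er_pos = _mixture_positive(cohort.expr.values.loc[er_probe])
        her2_pos = _mixture_positive(cohort.expr.values.loc[her2_probe])
    else:
        raise CychypError("need clinical ER/HER2 labels or marker probesets")
    out = np.where(her2_pos, "HER2+",
                   np.where(er_pos, "ER+/HER2-", "ER-/HER2-"))
    return pd.Series(out, index=clin.index)


def _mixture_positive(values: pd.Series) -> np.ndarray:
    x = values.to_numpy(dtype=float).reshape(-1, 1)
    gm = GaussianMixture(n_components=2, n_init=1, random_state=0,
                         means_init=np.quantile(x, [0.25, 0.75]).reshape(-1, 1))
    labels = gm.fit_predict(x)
    hi = int(np.argmax(gm.means_.ravel()))
    return labels == hi


def score_external_signature(scorer, cohort: CohortDataset) -> pd.DataFrame:
    """Adapt any external risk scorer to the pipeline's prediction shape.

    ``scorer`` must provide ``score(cohort) -> array`` and a ``threshold``
    attribute; groups follow the same convention as ``classify`` (strictly
    above the threshold = high risk). Raises if the scorer reports missing
    genes via a ``required_probesets`` attribute.
    """
    required = getattr(scorer, "required_probesets", None)
    if required is not None:
        missing = [p for p in required if p not in cohort.expr.values.index]
        if missing:
            raise CychypError(f"scorer is missing required probesets: {missing}")
    s = np.asarray(scorer.score(cohort), dtype=float)
    return pd.DataFrame(
        {"score": s,
         "group": np.where(s > scorer.threshold, "high", "low")},
        index=cohort.clinical.index)


class RiskModelScorer:
    """Wrap a fitted RiskModel in the external-scorer interface."""

    def __init__(self, model):
        self.model = model
        self.threshold = model.threshold
        self.required_probesets = list(model.probeset_ids)

    def score(self, cohort: CohortDataset) -> np.ndarray:
        return risk_score(self.model, cohort.expr)
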