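"""End-to-end orchestration: derive -> map -> fit -> classify -> evaluate
-> random-signature null -> NPI reclassification.

``run_pipeline`` executes the whole analysis from one configuration on
synthetic data (or files prepared by the CLI verbs), writes every stage
artefact as delimited text/JSON under an output directory, and returns a
machine-readable run report with sha256 checksums for each artefact.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import synthetic_data as syn
from .baselines_null import (RiskModelScorer, npi_groups, null_distribution,
                             reclassification)
from .datatypes import CohortDataset, CychypError, Signature
from .platform_mapping import map_signature
from .risk_model import (censor_at, classify, fit_penalized_cox, risk_score,
                         select_threshold)
from .signature_derivation import derive_signature
from .survival_eval import evaluate_cohorts

log = logging.getLogger("cychyp")

SUBSET_ORDER = ("all", "er_pos_her2_neg", "node_negative", "untreated")


@dataclass
class PipelineConfig:
    """Flat configuration for a full synthetic run.

    Derivation defaults mirror the study design the pipeline implements:
    90/10 splits, 200 resamplings, a 100-probeset signature, a 10-year
    administrative censoring horizon and a 5-year decision horizon, and
    1000 random signatures for the null (scaled down in tests).
    """

    # synthetic experiment
    n_lines: int = 20
    n_probes: int = 5000
    n_planted: int = 100
    effect_size: float = 1.0
    noise_sd: float = 0.5
    # derivation
    k: int = 100
    n_resamples: int = 200
    split_fraction: float = 0.9
    condition_pair: tuple[str, str] = ("normoxia", "cychyp")
    # annotation / mapping
    n_genes: int = 2000
    n_dst_probes: int = 3000
    # cohorts
    n_train_patients: int = 344
    n_validation_patients: int = 300
    n_validation_cohorts: int = 4
    hr_per_sd: float = 2.0
    baseline_rate: float = 0.08
    cohort_censor_rate: float = 0.3
    background_probes: int = 500
    # modelling
    censor_years: float = 10.0
    horizon_years: float = 5.0
    l1_grid: tuple[float, ...] = (0.001, 0.01, 0.1)
    l2_grid: tuple[float, ...] = (0.001, 0.01, 0.1)
    cv_folds: int = 5
    # null
    n_null_signatures: int = 1000
    null_metric: str = "logrank_logp"
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Read a flat key=value file; keyword overrides win."""
        values: dict = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, raw = line.partition("=")
            values[key.strip()] = _coerce(raw.strip())
        values.update({k: v for k, v in overrides.items() if v is not None})
        fields = cls.__dataclass_fields__
        unknown = set(values) - set(fields)
        if unknown:
            raise CychypError(f"unknown config keys: {sorted(unknown)}")
        for key, val in values.items():  # single-element grids parse as scalars
            if isinstance(fields[key].default, tuple) and not isinstance(val, tuple):
                values[key] = (val,)
        return cls(**values)


def _coerce(raw: str):
    if "," in raw:
        return tuple(_coerce(x) for x in raw.split(","))
    for cast in (int, float):
        try:
            return cast(raw)
        except ValueError:
            pass
    return raw


def apply_subset(cohort: CohortDataset, subset: str) -> CohortDataset:
    """Nested clinical restriction: all -> ER+/HER2- -> node-neg -> untreated."""
    if subset not in SUBSET_ORDER:
        raise CychypError(f"unknown subset {subset!r}")
    clin = cohort.clinical
    for col in ("er", "her2", "node_pos", "treated"):
        if col not in clin.columns:
            raise CychypError(f"missing clinical column {col!r}")
    mask = np.ones(len(clin), dtype=bool)
    depth = SUBSET_ORDER.index(subset)
    if depth >= 1:
        mask &= (clin["er"].astype(str) == "+").to_numpy()
        mask &= (clin["her2"].astype(str) == "-").to_numpy()
    if depth >= 2:
        mask &= (clin["node_pos"] == 0).to_numpy()
    if depth >= 3:
        mask &= (clin["treated"] == 0).to_numpy()
    return cohort.subset(mask, f"{cohort.cohort_id}_{subset}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run every stage on synthetic data and write all artefacts.

    Returns the run report (also written as ``run_report.json``); the
    report is byte-stable for a fixed configuration and seed.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    report: dict = {"config": {k: (list(v) if isinstance(v, tuple) else v)
                               for k, v in asdict(cfg).items()},
                    "stages": {}, "artifacts": {}}

    def emit(name: str, path: Path) -> None:
        report["artifacts"][name] = {"path": str(path.relative_to(out)),
                                     "sha256": _sha256(path)}

    # -- stage 1: synthetic cell-line experiment + signature derivation
    expr, design, truth = syn.gen_cell_line_experiment(
        cfg.n_lines, cfg.n_probes, cfg.n_planted,
        effect_size=cfg.effect_size, noise_sd=cfg.noise_sd,
        seed=int(rng.integers(2 ** 31)))
    sig, summary = derive_signature(
        expr, design, cfg.condition_pair, k=cfg.k,
        n_resamples=cfg.n_resamples, fraction=cfg.split_fraction,
        seed=int(rng.integers(2 ** 31)))
    log.info("derived %d-probeset signature, mean held-out accuracy %.3f",
             sig.size, summary.mean_accuracy)
    sig.to_files(out / "signature_src.tsv", out / "signature_src.json",
                 k=cfg.k, n_resamples=cfg.n_resamples)
    emit("signature_src", out / "signature_src.tsv")
    recovered = len(set(sig.probeset_ids) & truth.planted_cyc)
    report["stages"]["derive"] = {
        "mean_holdout_accuracy": summary.mean_accuracy,
        "planted_recovered": recovered,
        "n_planted": cfg.n_planted,
    }

    # -- stage 2: annotation + cross-platform mapping
    annot_src, annot_dst = syn.gen_annotation(
        cfg.n_probes, cfg.n_dst_probes, cfg.n_genes,
        seed=int(rng.integers(2 ** 31)),
        src_platform=expr.platform)
    mapped, map_report = map_signature(sig, annot_src, annot_dst)
    map_report.to_json(out / "mapping_report.json")
    emit("mapping_report", out / "mapping_report.json")
    mapped.to_files(out / "signature_mapped.tsv")
    emit("signature_mapped", out / "signature_mapped.tsv")
    report["stages"]["map"] = {
        "n_source_probesets": map_report.n_source_probesets,
        "n_unique_genes": map_report.n_unique_genes,
        "n_genes_on_destination": map_report.n_genes_on_destination,
        "n_destination_probesets": map_report.n_destination_probesets,
    }

    # -- stage 3: cohorts (destination platform), censoring, model fit
    train, _ = syn.gen_cohort(
        cfg.n_train_patients, mapped.probeset_ids,
        hr_per_sd=cfg.hr_per_sd, baseline_rate=cfg.baseline_rate,
        censor_rate=cfg.cohort_censor_rate, horizon=cfg.censor_years,
        clinical_link=True, seed=int(rng.integers(2 ** 31)),
        background_probes=cfg.background_probes,
        platform=mapped.platform, cohort_id="train")
    validations = [
        syn.gen_cohort(cfg.n_validation_patients, mapped.probeset_ids,
                       hr_per_sd=cfg.hr_per_sd, baseline_rate=cfg.baseline_rate,
                       censor_rate=cfg.cohort_censor_rate,
                       horizon=cfg.censor_years, clinical_link=True,
                       seed=int(rng.integers(2 ** 31)),
                       background_probes=cfg.background_probes,
                       platform=mapped.platform, cohort_id=f"valid{i}")[0]
        for i in range(cfg.n_validation_cohorts)
    ]
    for cohort in [train] + validations:
        t, e = censor_at(cohort.time, cohort.event, cfg.censor_years)
        cohort.clinical["time_years"], cohort.clinical["event"] = t, e

    model = fit_penalized_cox(train, mapped, cfg.l1_grid, cfg.l2_grid,
                              cv_folds=cfg.cv_folds,
                              seed=int(rng.integers(2 ** 31)),
                              horizon_years=cfg.horizon_years)
    train_scores = risk_score(model, train.expr)
    model.threshold = select_threshold(train_scores, train.time, train.event,
                                       cfg.horizon_years)
    model.to_json(out / "risk_model.json")
    emit("risk_model", out / "risk_model.json")
    report["stages"]["fit"] = {"l1": model.l1, "l2": model.l2,
                               "threshold": model.threshold,
                               "n_nonzero_coefficients":
                                   int(np.sum(model.coefficients != 0))}

    # -- stage 4: classify validations, evaluate the nested subsets
    predictions: dict[str, pd.DataFrame] = {}
    for cohort in validations:
        s = risk_score(model, cohort.expr)
        pred = classify(s, model)
        pred.index = cohort.clinical.index
        predictions[cohort.cohort_id] = pred
        pred.to_csv(out / f"predictions_{cohort.cohort_id}.tsv", sep="\t",
                    index_label="patient_id")
        emit(f"predictions_{cohort.cohort_id}",
             out / f"predictions_{cohort.cohort_id}.tsv")

    report["stages"]["evaluate"] = {}
    for subset in SUBSET_ORDER:
        entries = []
        for cohort in validations:
            sub = apply_subset(cohort, subset)
            log.info("subset %s of %s: %d patients", subset,
                     cohort.cohort_id, sub.n_patients)
            if sub.n_patients < 10 or sub.event.sum() == 0:
                continue
            pred = predictions[cohort.cohort_id].loc[sub.clinical.index]
            entries.append((sub.cohort_id, pred["score"].to_numpy(),
                            pred["group"].to_numpy() == "high",
                            sub.time, sub.event))
        if not entries:
            continue
        eval_report = evaluate_cohorts(entries, cfg.horizon_years)
        eval_report.to_tsv(out / f"eval_{subset}.tsv")
        emit(f"eval_{subset}", out / f"eval_{subset}.tsv")
        pooled = eval_report.rows.iloc[-1]
        report["stages"]["evaluate"][subset] = {
            "n": int(pooled["n"]),
            "hr": float(pooled.get("hr", np.nan)),
            "cindex": float(pooled.get("cindex", np.nan)),
            "bcr": float(pooled.get("bcr", np.nan)),
        }

    # -- stage 5: random-signature null
    if cfg.n_null_signatures > 0:
        null = null_distribution(
            train, validations, mapped, size=mapped.size,
            n_signatures=cfg.n_null_signatures, metric=cfg.null_metric,
            seed=int(rng.integers(2 ** 31)), horizon=cfg.horizon_years)
        null.write(out / "null_values.tsv", out / "null_summary.json")
        emit("null_summary", out / "null_summary.json")
        report["stages"]["null"] = {"metric": null.metric,
                                    "observed": null.observed,
                                    "empirical_p": null.empirical_p}
    else:
        report["stages"]["null"] = {"skipped": True}

    # -- stage 6: NPI reclassification on the deepest usable subset
    pooled_frames = []
    for cohort in validations:
        sub = apply_subset(cohort, "untreated")
        if sub.n_patients == 0:
            continue
        pred = predictions[cohort.cohort_id].loc[sub.clinical.index]
        frame = sub.clinical.copy()
        frame["model_group"] = pred["group"]
        pooled_frames.append(frame)
    pooled_clin = pd.concat(pooled_frames)
    recl = reclassification(npi_groups(pooled_clin).to_numpy(),
                            pooled_clin["model_group"].to_numpy(),
                            pooled_clin["time_years"].to_numpy(),
                            pooled_clin["event"].to_numpy())
    (out / "reclassification.json").write_text(json.dumps(recl, indent=2))
    emit("reclassification", out / "reclassification.json")
    report["stages"]["npi"] = {
        k: recl[k] for k in ("table", "frac_npi_high_reclassified_low",
                             "frac_npi_low_reclassified_high")}

    (out / "run_report.json").write_text(json.dumps(report, indent=2))
    return report
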