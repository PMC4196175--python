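"""Core containers shared across the pipeline.

All tabular data travel as pandas objects; the dataclasses here add the
platform/identifier bookkeeping that plain frames lack, plus delimited-text
and JSON (de)serialisation so every stage artefact is a small text file.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

CONDITIONS = ("normoxia", "cychyp", "conthyp")

#: documented clinical column names (times in years, size in cm)
CLINICAL_COLUMNS = (
    "time_years", "event", "er", "her2", "node_pos",
    "treated", "size_cm", "grade", "n_nodes",
)


class CychypError(Exception):
    """Base error for the package."""


class DegenerateSplitError(CychypError):
    """A resampling split left fewer than two samples of a condition in train."""


@dataclass
class ExpressionMatrix:
    """Probesets x samples matrix of log2 expression values.

    ``values`` is a DataFrame indexed by probeset id with sample ids as
    columns; ``platform`` names the array design the probesets belong to.
    """

    values: pd.DataFrame
    platform: str

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates or self.values.columns.has_duplicates:
            raise CychypError("duplicate probeset or sample identifiers")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise CychypError("expression matrix contains non-finite values")

    @property
    def probeset_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values[list(sample_ids)], self.platform)

    def to_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", index_label="probeset_id")

    @classmethod
    def from_tsv(cls, path: str | Path, platform: str) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col="probeset_id")
        return cls(df, platform)


@dataclass
class Signature:
    """Ordered probeset list with the platform it lives on.

    ``scores`` carries the ranking statistic (mean FDR-corrected p-value)
    for derived signatures; random/external signatures may leave it empty.
    """

    probeset_ids: list[str]
    platform: str
    scores: pd.Series | None = None

    def __post_init__(self) -> None:
        if len(set(self.probeset_ids)) != len(self.probeset_ids):
            raise CychypError("signature probeset ids must be unique")

    @property
    def size(self) -> int:
        return len(self.probeset_ids)

    def to_files(self, table_path: str | Path, meta_path: str | Path | None = None,
                 **meta) -> None:
        scores = (self.scores.reindex(self.probeset_ids)
                  if self.scores is not None
                  else pd.Series(np.nan, index=self.probeset_ids))
        pd.DataFrame({"probeset_id": self.probeset_ids,
                      "mean_q": scores.to_numpy()}
                     ).to_csv(table_path, sep="\t", index=False)
        if meta_path is not None:
            payload = {"platform": self.platform, "size": self.size, **meta}
            Path(meta_path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_files(cls, table_path: str | Path, platform: str) -> "Signature":
        df = pd.read_csv(table_path, sep="\t")
        scores = pd.Series(df["mean_q"].to_numpy(), index=df["probeset_id"])
        return cls(list(df["probeset_id"]), platform,
                   scores if scores.notna().any() else None)


@dataclass
class ResamplingSummary:
    """Per-probeset mean corrected p-values and held-out accuracies."""

    mean_q: pd.Series
    mean_abs_t: pd.Series
    n_resamples: int
    split_fraction: float
    per_resample_accuracy: list[float]

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.per_resample_accuracy))


@dataclass
class CohortDataset:
    """Expression plus one clinical row per patient.

    Clinical columns: time_years, event, er ('+'/'-'), her2 ('+'/'-'),
    node_pos (0/1), treated (0/1), size_cm, grade (1-3), n_nodes.
    """

    expr: ExpressionMatrix
    clinical: pd.DataFrame
    cohort_id: str = "cohort"

    def __post_init__(self) -> None:
        if list(self.expr.sample_ids) != list(self.clinical.index):
            raise CychypError("expression samples and clinical rows must match one-to-one")
        if (self.clinical["time_years"] < 0).any():
            raise CychypError("negative survival times")
        if not self.clinical["event"].isin((0, 1)).all():
            raise CychypError("event indicator must be 0/1")

    @property
    def n_patients(self) -> int:
        return len(self.clinical)

    @property
    def time(self) -> np.ndarray:
        return self.clinical["time_years"].to_numpy(dtype=float)

    @property
    def event(self) -> np.ndarray:
        return self.clinical["event"].to_numpy(dtype=int)

    def subset(self, mask: np.ndarray, cohort_id: str | None = None) -> "CohortDataset":
        keep = self.clinical.index[np.asarray(mask, dtype=bool)]
        return CohortDataset(self.expr.subset_samples(keep),
                             self.clinical.loc[keep],
                             cohort_id or self.cohort_id)

    def write(self, expr_path: str | Path, clinical_path: str | Path) -> None:
        self.expr.to_tsv(expr_path)
        self.clinical.to_csv(clinical_path, sep="\t", index_label="patient_id")

    @classmethod
    def read(cls, expr_path: str | Path, clinical_path: str | Path,
             platform: str, cohort_id: str = "cohort") -> "CohortDataset":
        expr = ExpressionMatrix.from_tsv(expr_path, platform)
        clin = pd.read_csv(clinical_path, sep="\t", index_col="patient_id")
        return cls(expr, clin, cohort_id)


@dataclass
class ProbeAnnotation:
    """Many-to-one probeset -> gene map for one platform."""

    platform: str
    probe_to_gene: dict[str, str]

    def genes(self) -> set[str]:
        return set(self.probe_to_gene.values())

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame({"probeset_id": list(self.probe_to_gene),
                      "gene_id": list(self.probe_to_gene.values())}
                     ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, platform: str) -> "ProbeAnnotation":
        df = pd.read_csv(path, sep="\t", dtype=str)
        return cls(platform, dict(zip(df["probeset_id"], df["gene_id"])))


@dataclass
class MappingReport:
    n_source_probesets: int
    n_unique_genes: int
    n_genes_on_destination: int
    n_destination_probesets: int
    dropped: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


@dataclass
class RiskModel:
    """Linear Cox risk score over signature probesets.

    ``standardize`` selects how expression is scaled before scoring:
    ``"per_cohort"`` re-z-scores each cohort (absorbs MAS5-vs-RMA scale
    shifts between studies), ``"training"`` reuses the training constants.
    """

    probeset_ids: list[str]
    coefficients: np.ndarray
    l1: float
    l2: float
    center: np.ndarray
    scale: np.ndarray
    standardize: str = "per_cohort"
    threshold: float | None = None
    horizon_years: float = 5.0

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.center = np.asarray(self.center, dtype=float)
        self.scale = np.asarray(self.scale, dtype=float)
        n = len(self.probeset_ids)
        if not (len(self.coefficients) == len(self.center) == len(self.scale) == n):
            raise CychypError("coefficient vector must be indexed by the signature probesets")
        if not (np.isfinite(self.center).all() and np.isfinite(self.scale).all()
                and (self.scale > 0).all()):
            raise CychypError("standardization constants must be finite with scale > 0")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "probeset_ids": self.probeset_ids,
            "coefficients": self.coefficients.tolist(),
            "l1": self.l1, "l2": self.l2,
            "center": self.center.tolist(), "scale": self.scale.tolist(),
            "standardize": self.standardize,
            "threshold": self.threshold,
            "horizon_years": self.horizon_years,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "RiskModel":
        d = json.loads(Path(path).read_text())
        return cls(**d)


@dataclass
class KMCurve:
    """Product-limit survival estimate evaluated at the event times."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame({"time": self.times, "survival": self.survival,
                      "at_risk": self.at_risk}).to_csv(path, sep="\t", index=False)


@dataclass
class NullDistribution:
    metric: str
    observed: float
    null_values: np.ndarray
    n_signatures: int

    @property
    def empirical_p(self) -> float:
        # add-one estimator: never 0, floor 1/(n+1)
        k = int(np.sum(np.asarray(self.null_values) >= self.observed))
        return (1 + k) / (self.n_signatures + 1)

    def write(self, values_path: str | Path, summary_path: str | Path) -> None:
        pd.Series(self.null_values, name=self.metric).to_csv(
            values_path, sep="\t", index=False)
        Path(summary_path).write_text(json.dumps({
            "metric": self.metric, "observed": self.observed,
            "n_signatures": self.n_signatures,
            "empirical_p": self.empirical_p,
            "null_mean": float(np.mean(self.null_values)),
            "null_sd": float(np.std(self.null_values)),
        }, indent=2))


def as_dataframe(mapping: Mapping[str, Sequence]) -> pd.DataFrame:
    return pd.DataFrame(dict(mapping))
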