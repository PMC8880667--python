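"""CSV readers/writers and the end-to-end pipeline.

Patient CSVs carry one column per record field (header fixed,
case-insensitive); empty cells mean "none" for findings and "unknown" for
histories.  Risk tables are plain CSVs with columns ``R1a..R4`` and
``label``.  All configuration and model artifacts are JSON.

:func:`run_pipeline` ties the stages together: cascade -> normalization ->
Safe-Level SMOTE balancing -> assumption battery + EFA -> classifier
training with cross-validation -> per-patient hazard and triage.  All
randomness flows from the single configured seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .alerts import TriageLimits, triage_table
from .cascade import RISK_COLUMNS, CascadeConfig, PatientRecord, cascade_table
from .classify import BaggedTreesSpec, KnnSpec, build_model, cross_validate
from .data_prep import AugmentationConfig, augment_dataset, zscore
from .efa import assumption_report, fit_efa

__all__ = [
    "PatientCSVError",
    "PipelineConfig",
    "PipelineResult",
    "read_patients",
    "write_patients",
    "read_risk_table",
    "write_risk_table",
    "run_pipeline",
]

logger = logging.getLogger("mammotriage")

_BOOL_FIELDS = ("mass_present", "calc_present", "asym_present", "distortion_present")
_EMPTY_DEFAULTS = {
    "mass_shape": "none", "mass_margins": "none", "mass_density": "none",
    "calc_primacy": "none", "calc_shape": "none", "calc_distribution": "none",
    "asym_type": "none", "distortion_primacy": "none",
    "patient_history": "unknown", "family_history": "unknown", "label": None,
}
PATIENT_COLUMNS = [f.name for f in dataclasses.fields(PatientRecord)]


class PatientCSVError(ValueError):
    """A patient CSV fails schema validation; the message names the row."""


def _parse_bool(value: str, row: int, column: str) -> bool:
    v = value.strip().lower()
    if v in ("true", "1", "yes", "present"):
        return True
    if v in ("false", "0", "no", "absent", ""):
        return False
    raise PatientCSVError(f"row {row}: {column}={value!r} is not a boolean")


def read_patients(path: str | Path) -> list[PatientRecord]:
    """Read and validate a patient CSV into records."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    unknown = set(df.columns) - set(PATIENT_COLUMNS)
    if unknown:
        raise PatientCSVError(f"unknown column(s) {sorted(unknown)}; "
                              f"expected a subset of {PATIENT_COLUMNS}")
    records = []
    for i, row in df.iterrows():
        rownum = int(i) + 2  # 1-based, after the header line
        kwargs: dict = {}
        for col in df.columns:
            raw = str(row[col]).strip()
            if col in _BOOL_FIELDS:
                kwargs[col] = _parse_bool(raw, rownum, col)
            elif col == "age":
                try:
                    kwargs[col] = float(raw)
                except ValueError:
                    raise PatientCSVError(
                        f"row {rownum}: age={raw!r} is not numeric"
                    ) from None
            elif raw == "" and col in _EMPTY_DEFAULTS:
                kwargs[col] = _EMPTY_DEFAULTS[col]
            else:
                kwargs[col] = raw
        try:
            records.append(PatientRecord(**kwargs))
        except ValueError as exc:
            raise PatientCSVError(f"row {rownum}: {exc}") from exc
    return records


def write_patients(records: list[PatientRecord], path: str | Path) -> None:
    rows = []
    for rec in records:
        d = dataclasses.asdict(rec)
        d["label"] = d["label"] if d["label"] is not None else ""
        rows.append(d)
    pd.DataFrame(rows, columns=PATIENT_COLUMNS).to_csv(path, index=False)


def read_risk_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(RISK_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"risk table missing column(s) {sorted(missing)}")
    return df


def write_risk_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


@dataclass
class PipelineConfig:
    """Everything the end-to-end pipeline needs, validated before any work."""

    cascade_dir: str | Path | None = None   # None -> packaged demo rule bases
    model: str = "bagged"                   # "bagged" | "knn"
    n_factors: int | str = 3
    k_neighbors: int = 4
    balance_to: int | None = None           # None -> match the majority class
    folds: int = 5
    limits: TriageLimits = field(default_factory=TriageLimits)
    seed: int = 0

    def load_cascade(self) -> CascadeConfig:
        if self.cascade_dir is None:
            return CascadeConfig.default()
        path = Path(self.cascade_dir)
        if not path.is_dir():
            raise FileNotFoundError(f"cascade config directory {path} does not exist")
        return CascadeConfig.load(path)

    def model_spec(self):
        if self.model == "knn":
            return KnnSpec()
        if self.model == "bagged":
            return BaggedTreesSpec(seed=self.seed)
        raise ValueError(f"unknown model {self.model!r}; use 'knn' or 'bagged'")


@dataclass
class PipelineResult:
    risk_table: pd.DataFrame
    augmented: pd.DataFrame
    augmentation_summary: dict
    assumption_report: object
    factor_model: object
    evaluation: object
    hazards: np.ndarray
    triage_counts: dict
    triage_results: list

    def summary(self) -> dict:
        return {
            "n_patients": int(len(self.risk_table)),
            "augmentation": self.augmentation_summary,
            "n_factors": int(self.factor_model.n_factors),
            "cumulative_variance": float(self.factor_model.cumulative_variance),
            "cv_auc": float(self.evaluation.auc),
            "triage_counts": self.triage_counts,
            "hazards": [round(float(h), 2) for h in self.hazards],
        }


def run_pipeline(cfg: PipelineConfig, patients: list[PatientRecord]) -> PipelineResult:
    """Run cascade -> prep -> EFA -> classifier -> triage on a labeled cohort.

    Every patient is triaged with an out-of-training hazard in the sense
    that the classifier is evaluated by stratified cross-validation; the
    reported per-patient hazards come from a model trained on the full
    augmented table, which is how the system scores a new patient.
    """
    cascade_cfg = cfg.load_cascade()  # fail fast before any computation
    labels = {rec.label for rec in patients}
    if None in labels or labels - {"cancer", "non-cancer"}:
        raise ValueError("every patient needs a 'cancer'/'non-cancer' label")

    logger.info("stage cascade: %d patients", len(patients))
    risk_table = cascade_table(patients, cascade_cfg)

    logger.info("stage prep: normalization + balancing")
    normalized, stats = zscore(risk_table)
    counts = risk_table["label"].value_counts()
    target = cfg.balance_to if cfg.balance_to is not None else int(counts.max())
    requests = {label: max(0, target - int(counts[label])) for label in counts.index}
    aug_cfg = AugmentationConfig(counts=requests, k_neighbors=cfg.k_neighbors,
                                 seed=cfg.seed)
    augmented, aug_summary = augment_dataset(normalized, aug_cfg)

    logger.info("stage efa: assumption battery + factor extraction")
    report = assumption_report(augmented)
    for flag, ok in report.flags.items():
        if not ok:
            logger.warning("assumption not met (proceeding): %s", flag)
    model = fit_efa(augmented, n_factors=cfg.n_factors)
    scores = model.score(augmented)

    logger.info("stage classify: %s, %d-fold cross-validation", cfg.model, cfg.folds)
    spec = cfg.model_spec()
    evaluation = cross_validate(scores.to_numpy(), augmented["label"].to_numpy(),
                                spec, folds=cfg.folds, seed=cfg.seed)

    scorer = build_model(spec).fit(scores.to_numpy(), augmented["label"].to_numpy())
    patient_scores = model.score(stats.transform(risk_table))
    hazards = scorer.hazard(patient_scores.to_numpy())
    triage_counts, triage_results = triage_table(hazards, cfg.limits)
    return PipelineResult(
        risk_table=risk_table,
        augmented=augmented,
        augmentation_summary=aug_summary,
        assumption_report=report,
        factor_model=model,
        evaluation=evaluation,
        hazards=hazards,
        triage_counts=triage_counts,
        triage_results=triage_results,
    )
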