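"""Delimited-text and JSON I/O: cohorts, model documents, configs.

Cohort tables travel as CSV with a JSON sidecar mapping each variable to
its dataset type.  A fitted model is serialized as a self-contained,
versioned JSON document (variables, preprocessing parameters, weight and
loading vectors, decision threshold and sigmoid calibration) so scoring
a new cohort needs nothing but the document.  Pipeline configurations
round-trip through YAML.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .opls import OplsDiscriminant
from .scoring import ScoreCalibration
from .synthetic import DATASET_TYPES, CohortTable

MODEL_FORMAT_VERSION = 1


def write_cohort(cohort: CohortTable, path, types_path=None) -> None:
    path = Path(path)
    if types_path is None:
        types_path = path.with_suffix(".types.json")
    cohort.data.to_csv(path, index=False)
    with open(types_path, "w") as fh:
        json.dump(cohort.variable_types, fh, indent=1, sort_keys=True)


def read_cohort(path, types_path=None) -> CohortTable:
    """Read a cohort CSV + variable-type sidecar, validating as it goes."""
    path = Path(path)
    if types_path is None:
        types_path = path.with_suffix(".types.json")
    with open(types_path) as fh:
        variable_types = json.load(fh)
    bad = {v: t for v, t in variable_types.items() if t not in DATASET_TYPES}
    if bad:
        raise ValueError(f"unknown variable types in {types_path}: {bad}")
    data = pd.read_csv(path, dtype={"sample_id": str, "gender": str,
                                    "age_group": str, "profile": str})
    if data.columns.duplicated().any():
        dups = data.columns[data.columns.duplicated()].tolist()
        raise ValueError(f"duplicate header names in {path}: {dups}")
    value_cols = [c for c in data.columns if c in variable_types]
    for col in value_cols:
        converted = pd.to_numeric(data[col], errors="coerce")
        bad_rows = data.index[converted.isna() & data[col].notna()]
        if len(bad_rows):
            raise ValueError(
                f"non-numeric value in column {col!r} at row "
                f"{int(bad_rows[0]) + 2} of {path}")
        data[col] = converted
    return CohortTable(data, variable_types)


@dataclass
class ModelDocument:
    """Self-contained serialized discriminant + calibration."""

    variables: list[str]
    log_transform: bool
    offsets: np.ndarray
    center: np.ndarray
    scale: np.ndarray
    w: np.ndarray
    p: np.ndarray
    w_orth: np.ndarray
    p_orth: np.ndarray
    c: float
    calibration: ScoreCalibration | None = None
    seed: int | None = None
    config_hash: str | None = None
    version: int = MODEL_FORMAT_VERSION
    metadata: dict = field(default_factory=dict)

    @classmethod
    def from_fitted(cls, model: OplsDiscriminant,
                    calibration: ScoreCalibration | None = None,
                    seed: int | None = None,
                    config_hash: str | None = None,
                    metadata: dict | None = None) -> "ModelDocument":
        return cls(
            variables=list(model.variables_),
            log_transform=model.log_transform,
            offsets=model.offsets_, center=model.center_, scale=model.scale_,
            w=model.w_, p=model.p_, w_orth=model.w_orth_, p_orth=model.p_orth_,
            c=model.c_, calibration=calibration, seed=seed,
            config_hash=config_hash, metadata=metadata or {})

    def to_estimator(self) -> OplsDiscriminant:
        est = OplsDiscriminant(n_orth=self.w_orth.shape[0],
                               log_transform=self.log_transform)
        est.variables_ = list(self.variables)
        est.offsets_, est.center_, est.scale_ = self.offsets, self.center, self.scale
        est.w_, est.p_, est.c_ = self.w, self.p, self.c
        est.w_orth_, est.p_orth_ = self.w_orth, self.p_orth
        est.classes_ = np.array([0, 1])
        return est

    def to_dict(self) -> dict:
        return {
            "format_version": self.version,
            "variables": self.variables,
            "log_transform": self.log_transform,
            "offsets": self.offsets.tolist(),
            "center": self.center.tolist(),
            "scale": self.scale.tolist(),
            "w": self.w.tolist(),
            "p": self.p.tolist(),
            "w_orth": self.w_orth.tolist(),
            "p_orth": self.p_orth.tolist(),
            "c": self.c,
            "calibration": (self.calibration.to_dict()
                            if self.calibration else None),
            "seed": self.seed,
            "config_hash": self.config_hash,
            "metadata": self.metadata,
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "ModelDocument":
        if doc.get("format_version") != MODEL_FORMAT_VERSION:
            raise ValueError(
                f"unsupported model format version {doc.get('format_version')}")
        cal = doc.get("calibration")
        return cls(
            variables=list(doc["variables"]),
            log_transform=bool(doc["log_transform"]),
            offsets=np.asarray(doc["offsets"], dtype=float),
            center=np.asarray(doc["center"], dtype=float),
            scale=np.asarray(doc["scale"], dtype=float),
            w=np.asarray(doc["w"], dtype=float),
            p=np.asarray(doc["p"], dtype=float),
            w_orth=np.asarray(doc["w_orth"], dtype=float).reshape(
                -1, len(doc["variables"])),
            p_orth=np.asarray(doc["p_orth"], dtype=float).reshape(
                -1, len(doc["variables"])),
            c=float(doc["c"]),
            calibration=ScoreCalibration.from_dict(cal) if cal else None,
            seed=doc.get("seed"), config_hash=doc.get("config_hash"),
            metadata=doc.get("metadata", {}))


def save_model(doc: ModelDocument, path) -> None:
    with open(path, "w") as fh:
        json.dump(doc.to_dict(), fh, indent=1, sort_keys=True)


def load_model(path) -> ModelDocument:
    with open(path) as fh:
        return ModelDocument.from_dict(json.load(fh))


def config_hash(config_dict: dict) -> str:
    canonical = json.dumps(config_dict, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def write_yaml(obj: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)


def read_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
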