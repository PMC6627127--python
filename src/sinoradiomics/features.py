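"""Per-patient feature assembly: the 27-feature vector and outcome label.

This is the single interchange format between the imaging extractors and
the machine-learning layer.  Column order is fixed and versioned; the CSV
serialization round-trips exactly.  Extraction failures surface as typed
errors naming the failing stage — never as NaNs in the table.

Features (units as reported clinically): 2 clinical ordinals (T-stage 1-4
with 4a/4b collapsed, N-stage 0-3), 3 morphological (volume mL, surface
cm^2, sphericity), 6 intratumoral T2 (relative mean signal, CV, GLCM
contrast / correlation / energy / homogeneity), 2 perfusion (absolute TBF
mL/100g/min, relative TBF), 14 diffusion (coefficients in 1e-3 mm^2/s,
fractions dimensionless).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import diffusion, perfusion, shape_texture
from .volumes import DWISeries, ImageVolume, RoiMask

__all__ = [
    "FEATURE_NAMES",
    "FEATURE_SCHEMA_VERSION",
    "OUTCOME_COLUMN",
    "ExtractionError",
    "PatientFeatureVector",
    "extract_all",
    "standardize",
    "Scaler",
    "table_json_schema",
    "vectors_to_frame",
    "collapse_t_stage",
]

FEATURE_SCHEMA_VERSION = "1"

#: The 27 candidate features, in fixed report order.
FEATURE_NAMES: tuple[str, ...] = (
    "t_stage", "n_stage",
    "volume_ml", "surface_cm2", "sphericity",
    "relative_mean_signal", "cv",
    "contrast", "correlation", "energy", "homogeneity",
    "tbf_abs", "tbf_rel",
    "adc", "ivim_f", "ivim_d_star", "ivim_d",
    "dki_k", "dki_d_k", "sem_alpha", "sem_ddc",
    "tri_f1", "tri_f2", "tri_f3", "tri_d1", "tri_d2", "tri_d3",
)

OUTCOME_COLUMN = "outcome"
OUTCOME_LABELS = ("control", "failure")


def table_json_schema() -> dict:
    """JSON-schema description of one feature-table row (shipped with the
    CSV so consumers can validate column names, order and types)."""
    properties: dict[str, dict] = {"id": {"type": "string"}}
    for name in FEATURE_NAMES:
        properties[name] = {"type": "number"}
    properties[OUTCOME_COLUMN] = {"type": "string", "enum": list(OUTCOME_LABELS)}
    return {
        "$schema": "https://json-schema.org/draft/2020-12/schema",
        "title": f"patient feature vector v{FEATURE_SCHEMA_VERSION}",
        "type": "object",
        "properties": properties,
        "required": ["id", *FEATURE_NAMES, OUTCOME_COLUMN],
        "additionalProperties": False,
    }


class ExtractionError(RuntimeError):
    """An extractor failed; ``stage`` identifies where."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PatientFeatureVector:
    patient_id: str
    features: dict[str, float]
    outcome: str

    def __post_init__(self) -> None:
        missing = [k for k in FEATURE_NAMES if k not in self.features]
        extra = [k for k in self.features if k not in FEATURE_NAMES]
        if missing or extra:
            raise ValueError(f"feature roster mismatch: missing={missing} extra={extra}")
        bad = [k for k, v in self.features.items() if not np.isfinite(v)]
        if bad:
            raise ValueError(f"non-finite feature values: {bad}")
        if self.outcome not in OUTCOME_LABELS:
            raise ValueError(f"outcome must be one of {OUTCOME_LABELS}")

    def as_row(self) -> dict[str, object]:
        row: dict[str, object] = {"id": self.patient_id}
        row.update({k: self.features[k] for k in FEATURE_NAMES})
        row[OUTCOME_COLUMN] = self.outcome
        return row


def collapse_t_stage(t_stage: str | int) -> int:
    """Collapse T4a/T4b to ordinal 4; accept 1..4 directly."""
    s = str(t_stage).strip().lower().lstrip("t")
    if s in ("4a", "4b"):
        return 4
    value = int(s)
    if not 1 <= value <= 4:
        raise ValueError(f"T-stage out of range: {t_stage!r}")
    return value


def _stage(clinical: dict, key: str, lo: int, hi: int) -> int:
    if key not in clinical:
        raise ExtractionError("clinical", f"missing {key}")
    value = collapse_t_stage(clinical[key]) if key == "t_stage" else int(clinical[key])
    if not lo <= value <= hi:
        raise ExtractionError("clinical", f"{key}={value} outside [{lo}, {hi}]")
    return value


def extract_all(
    *,
    patient_id: str,
    t2: ImageVolume,
    dwi: DWISeries,
    asl_control: ImageVolume,
    asl_label: ImageVolume,
    tumor_mask: RoiMask,
    muscle_mask: RoiMask,
    clinical: dict,
    asl_cfg: perfusion.AslQuantConfig = perfusion.AslQuantConfig(),
    glcm_levels: int = shape_texture.DEFAULT_GLCM_LEVELS,
) -> PatientFeatureVector:
    """Run every extractor on one aligned patient dataset.

    The tumor ROI drawn on T2 propagates to the ASL and DWI grids (all
    synthetic volumes share one geometry, so propagation is the identity
    here); necrotic voxels flagged in the mask sidecar are excluded from
    every ROI statistic.  Any stage failure raises ``ExtractionError``
    naming the stage.
    """
    if tumor_mask.data[muscle_mask.data].any():
        raise ExtractionError("roi", "tumor and muscle masks overlap")

    try:
        morph = shape_texture.measure_morphology(tumor_mask)
    except Exception as e:  # noqa: BLE001 - re-raise with stage tag
        raise ExtractionError("morphology", str(e)) from e

    try:
        intra = shape_texture.intratumoral_features(
            t2, tumor_mask, muscle_mask, levels=glcm_levels)
    except Exception as e:
        raise ExtractionError("texture", str(e)) from e

    try:
        dm = perfusion.subtract(asl_control, asl_label)
        tumor_tbf = perfusion.quantify_tbf(dm, asl_control, tumor_mask, asl_cfg)
        muscle_tbf = perfusion.quantify_tbf(dm, asl_control, muscle_mask, asl_cfg)
        rel_tbf = perfusion.relative_tbf(tumor_tbf, muscle_tbf)
    except Exception as e:
        raise ExtractionError("perfusion", str(e)) from e

    try:
        diff = diffusion.extract_diffusion_features(dwi, tumor_mask)
    except Exception as e:
        raise ExtractionError("diffusion", str(e)) from e

    features = {
        "t_stage": float(_stage(clinical, "t_stage", 1, 4)),
        "n_stage": float(_stage(clinical, "n_stage", 0, 3)),
        "volume_ml": morph.volume_ml,
        "surface_cm2": morph.surface_cm2,
        "sphericity": morph.sphericity,
        "relative_mean_signal": intra.relative_mean_signal,
        "cv": intra.cv,
        "contrast": intra.contrast,
        "correlation": intra.correlation,
        "energy": intra.energy,
        "homogeneity": intra.homogeneity,
        "tbf_abs": tumor_tbf,
        "tbf_rel": rel_tbf,
        **diff,
    }
    outcome = clinical.get(OUTCOME_COLUMN)
    if outcome not in OUTCOME_LABELS:
        raise ExtractionError("clinical", f"outcome must be one of {OUTCOME_LABELS}")
    return PatientFeatureVector(patient_id, features, outcome)


def vectors_to_frame(vectors: list[PatientFeatureVector]) -> pd.DataFrame:
    """Stack feature vectors into the canonical 28-column table (+ id)."""
    return pd.DataFrame([v.as_row() for v in vectors],
                        columns=["id", *FEATURE_NAMES, OUTCOME_COLUMN])


@dataclass(frozen=True)
class Scaler:
    """Per-feature z-score parameters learned on the training rows only."""

    mean: pd.Series
    scale: pd.Series

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        out = table.copy()
        cols = self.mean.index
        out[cols] = (table[cols] - self.mean) / self.scale
        return out


def standardize(table: pd.DataFrame, fit_rows: np.ndarray | list[int],
                ) -> tuple[pd.DataFrame, Scaler]:
    """Z-score every feature column using statistics of ``fit_rows`` only.

    The scaler is fitted on the training fold and applied to the whole
    table (held-out rows reuse the training statistics — no leakage).
    Zero-variance features get unit scale with a warning, so a constant
    column standardizes to zeros instead of NaN.
    """
    fit_rows = np.asarray(fit_rows)
    if fit_rows.size == 0:
        raise ValueError("fit_rows must be nonempty")
    cols = [c for c in FEATURE_NAMES if c in table.columns]
    sub = table.iloc[fit_rows][cols]
    mean = sub.mean()
    scale = sub.std(ddof=0)
    # exact-constant columns can carry an O(eps) floating-point std
    tol = 1e-9 * np.maximum(mean.abs(), 1.0)
    degenerate = scale[scale <= tol].index.tolist()
    if degenerate:
        warnings.warn(f"zero-variance features get unit scale: {degenerate}",
                      stacklevel=2)
        scale[degenerate] = 1.0
    scaler = Scaler(mean=mean, scale=scale)
    return scaler.transform(table), scaler
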