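"""Synthetic serum-biomarker cohorts with known cluster structure.

Generates subjects x markers concentration tables that mimic the statistical
shape of LC-MS/MS lipid panels: log-normal per-marker concentrations, a
patient and a control group, optional disease effects on a subset of
markers, optional partial "responder" substructure, age and sex covariate
effects, and rare extreme outliers.  Three named scenarios cover the
qualitative outcomes the analysis can meet:

``full_separation``
    every patient carries the effect — clusters should coincide with the
    diagnosis almost perfectly.
``partial_separation``
    only a responder fraction of patients carries the effect — a patient
    cluster exists but sensitivity is limited by the responder fraction.
``no_structure``
    groups are drawn from the same distribution — any discovered structure
    is noise and agreement should sit at chance level.

The synthetic defaults are stand-ins for unpublished cohort quantities
(effect sizes, marker correlations, absolute concentration ranges are not
reproduced); see docs/methods.md.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

SCENARIOS = ("full_separation", "partial_separation", "no_structure")

META_COLUMNS = ["subject_id", "group", "age", "sex"]


class ScenarioConfig(BaseModel):
    """Parameters of one synthetic cohort draw.

    ``log_mean``/``log_sd`` may be scalars (broadcast over markers) or
    per-marker sequences on the natural-log concentration scale.
    ``effect_size`` is expressed in units of ``log_sd`` and shifts the
    log-mean of affected markers in affected patients.
    """

    n_patients: int = Field(default=102, ge=1)
    n_controls: int = Field(default=301, ge=1)
    n_markers: int = Field(default=10, ge=1)
    scenario: Literal["full_separation", "partial_separation", "no_structure"] = "full_separation"
    log_mean: float | Sequence[float] = 1.0
    log_sd: float | Sequence[float] = 0.5
    effect_size: float = 3.0
    affected_marker_fraction: float = Field(default=0.5, ge=0.0, le=1.0)
    responder_fraction: float = Field(default=0.55, gt=0.0, le=1.0)
    age_range: tuple[float, float] = (18.0, 63.0)
    age_slope: float | Sequence[float] = 0.0
    sex_offset: float | Sequence[float] = 0.0
    male_fraction: float = Field(default=0.3, ge=0.0, le=1.0)
    outlier_rate: float = Field(default=0.0, ge=0.0, lt=1.0)
    outlier_magnitude: float = Field(default=10.0, gt=0.0)
    seed: int = 0

    @field_validator("log_sd")
    @classmethod
    def _positive_sd(cls, v):
        arr = np.atleast_1d(np.asarray(v, dtype=float))
        if (arr <= 0).any():
            raise ValueError("log_sd must be positive")
        return v

    @model_validator(mode="after")
    def _check_lengths(self):
        for name in ("log_mean", "log_sd", "age_slope", "sex_offset"):
            val = getattr(self, name)
            if not np.isscalar(val) and len(np.atleast_1d(val)) not in (1, self.n_markers):
                raise ValueError(f"{name} must be scalar or length n_markers")
        if self.age_range[0] >= self.age_range[1]:
            raise ValueError("age_range must satisfy min < max")
        return self

    def _per_marker(self, name: str) -> np.ndarray:
        return np.broadcast_to(np.asarray(getattr(self, name), dtype=float), (self.n_markers,)).copy()


def marker_names(d: int) -> list[str]:
    return [f"marker_{j + 1:02d}" for j in range(d)]


def generate_cohort(config: ScenarioConfig) -> pd.DataFrame:
    """Draw one cohort table.

    Concentrations follow, on the natural-log scale,
    ``log x = log_mean + age_slope * (age - mean age) + sex_offset * 1[male]
    + effect_size * log_sd * 1[affected patient and affected marker]
    + N(0, log_sd)`` and are exponentiated; a fraction ``outlier_rate`` of
    cells then gains ``outlier_magnitude * log_sd`` on the log scale.  The
    same seed yields a bit-identical table.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_patients + cfg.n_controls
    d = cfg.n_markers

    group = np.array(["patient"] * cfg.n_patients + ["control"] * cfg.n_controls)
    age = rng.uniform(cfg.age_range[0], cfg.age_range[1], size=n)
    sex = np.where(rng.random(n) < cfg.male_fraction, "male", "female")

    log_mean = cfg._per_marker("log_mean")
    log_sd = cfg._per_marker("log_sd")
    age_slope = cfg._per_marker("age_slope")
    sex_offset = cfg._per_marker("sex_offset")

    # disease effect layout
    n_affected_markers = int(np.ceil(cfg.affected_marker_fraction * d))
    affected_marker = np.zeros(d, dtype=bool)
    affected_marker[:n_affected_markers] = True

    responder = np.zeros(n, dtype=bool)
    if cfg.scenario != "no_structure":
        rf = 1.0 if cfg.scenario == "full_separation" else cfg.responder_fraction
        patient_idx = np.flatnonzero(group == "patient")
        n_resp = int(round(rf * len(patient_idx)))
        chosen = rng.permutation(patient_idx)[:n_resp]
        responder[chosen] = True

    log_x = (
        log_mean[None, :]
        + age_slope[None, :] * (age - age.mean())[:, None]
        + sex_offset[None, :] * (sex == "male")[:, None]
        + cfg.effect_size * log_sd[None, :] * (responder[:, None] & affected_marker[None, :])
        + rng.normal(0.0, log_sd[None, :], size=(n, d))
    )
    if cfg.outlier_rate > 0:
        hit = rng.random((n, d)) < cfg.outlier_rate
        log_x = log_x + hit * (cfg.outlier_magnitude * log_sd[None, :])

    table = pd.DataFrame(np.exp(log_x), columns=marker_names(d))
    table.insert(0, "sex", sex)
    table.insert(0, "age", age)
    table.insert(0, "group", group)
    table.insert(0, "subject_id", [f"subj_{i + 1:04d}" for i in range(n)])
    return table


def split_cohort(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a cohort table into (metadata, concentrations)."""
    markers = [c for c in table.columns if c not in META_COLUMNS]
    return table[META_COLUMNS], table[markers]


def validate_cohort(table: pd.DataFrame) -> None:
    """Raise if the table violates the cohort contract (completeness, non-negativity)."""
    missing = [c for c in META_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"cohort table lacks columns {missing}")
    if table.isna().any().any():
        raise ValueError("cohort table contains missing values")
    _, conc = split_cohort(table)
    if conc.shape[1] == 0:
        raise ValueError("cohort table has no marker columns")
    if (conc.to_numpy() < 0).any():
        raise ValueError("concentrations must be non-negative")
    bad = set(table["group"]) - {"patient", "control"}
    if bad:
        raise ValueError(f"unknown group labels {sorted(bad)}")


def write_cohort(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_cohort(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    validate_cohort(table)
    return table
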