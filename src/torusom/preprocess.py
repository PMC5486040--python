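"""Preprocessing chain for biomarker concentration tables.

The chain runs in a fixed order: Grubbs single-outlier scan and row removal,
age/sex covariate correction, percent scaling to [0, 100], zero-invariant
log transform ln(x + 1), and z-transform to zero mean / unit sample
standard deviation.  After the full chain every marker column is
dimensionless with mean 0 and sd 1, suitable for Euclidean distances.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .simulate import META_COLUMNS, split_cohort, validate_cohort


class DegenerateMarkerError(ValueError):
    """A marker column is constant (zero variance) where spread is required."""

    def __init__(self, marker: str, context: str):
        super().__init__(f"marker {marker!r} is constant; cannot apply {context}")
        self.marker = marker


@dataclasses.dataclass(frozen=True)
class GrubbsResult:
    """Outcome of the two-sided one-outlier Grubbs test on one marker."""

    marker: str
    G: float
    U: float
    p_value: float
    outlier_row: str
    significant: bool


@dataclasses.dataclass
class PreprocessedMatrix:
    """Subjects x markers values after the full chain, with provenance."""

    subjects: list[str]
    markers: list[str]
    values: np.ndarray
    meta: pd.DataFrame  # group/age/sex aligned with rows
    provenance: list[dict]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.markers)
        df.insert(0, "subject_id", self.subjects)
        return df


def grubbs_statistic(x: np.ndarray) -> tuple[float, int, float, float]:
    """Two-sided one-outlier Grubbs test on a vector.

    Returns (G, index of most extreme value, U, p-value) where
    G = max|x - mean| / s with the sample (n-1) standard deviation,
    U = SSD without the flagged value / SSD with it, and the p-value is the
    standard t-distribution bound p = min(1, 2n * P(T_{n-2} > t)) with
    t^2 = n (n-2) G^2 / ((n-1)^2 - n G^2).  Among tied extremes the lowest
    index is reported.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    mean = x.mean()
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("constant vector has no Grubbs statistic")
    dev = np.abs(x - mean)
    idx = int(np.argmax(dev))
    G = float(dev[idx] / sd)
    ssd_with = float(((x - mean) ** 2).sum())
    rest = np.delete(x, idx)
    ssd_without = float(((rest - rest.mean()) ** 2).sum())
    U = ssd_without / ssd_with

    denom = (n - 1) ** 2 - n * G * G
    if denom <= 0:
        p = 0.0
    else:
        t = np.sqrt(n * (n - 2) * G * G / denom)
        p = float(min(1.0, 2 * n * stats.t.sf(t, df=n - 2)))
    return G, idx, U, p


def grubbs_scan(table: pd.DataFrame, alpha: float = 0.05) -> list[GrubbsResult]:
    """Run the one-outlier Grubbs test on every marker column."""
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    validate_cohort(table)
    meta, conc = split_cohort(table)
    results = []
    for marker in conc.columns:
        x = conc[marker].to_numpy(dtype=float)
        if x.std(ddof=1) == 0:
            raise DegenerateMarkerError(marker, "Grubbs test")
        if len(np.unique(x)) < 3:
            raise ValueError(f"marker {marker!r} needs at least 3 distinct values")
        G, idx, U, p = grubbs_statistic(x)
        results.append(GrubbsResult(
            marker=marker, G=G, U=U, p_value=p,
            outlier_row=str(table["subject_id"].iloc[idx]),
            significant=p < alpha,
        ))
    return results


def remove_outliers(table: pd.DataFrame, results: list[GrubbsResult]) -> pd.DataFrame:
    """Drop each subject row flagged by a significant Grubbs result.

    Whole rows are removed (the analysis works on per-subject vectors);
    a single pass removes at most one row per significant marker.
    """
    flagged = {r.outlier_row for r in results if r.significant}
    if not flagged:
        return table.copy()
    return table[~table["subject_id"].astype(str).isin(flagged)].copy()


def covariate_correct(table: pd.DataFrame) -> pd.DataFrame:
    """Reduce age and sex influences on each marker.

    Age: replace values with the residuals of an ordinary least-squares
    regression of the marker on age, plus the marker's original mean
    (mean-preserving).  Sex: shift the smaller sex group by the difference
    of sex-wise medians so the post-correction medians are equal.  Age is
    corrected first, then sex.
    """
    out = table.copy()
    markers = [c for c in table.columns if c not in META_COLUMNS]
    age = out["age"].to_numpy(dtype=float)
    sexes = out["sex"].to_numpy()
    both_sexes = len(np.unique(sexes)) == 2
    if not both_sexes:
        warnings.warn("single-sex cohort: sex correction skipped", stacklevel=2)

    for marker in markers:
        y = out[marker].to_numpy(dtype=float)
        fit = stats.linregress(age, y)
        y = y - (fit.intercept + fit.slope * age) + y.mean()
        if both_sexes:
            male = sexes == "male"
            med_m, med_f = np.median(y[male]), np.median(y[~male])
            if male.sum() <= (~male).sum():
                y[male] += med_f - med_m      # shift the smaller group
            else:
                y[~male] += med_m - med_f
        out[marker] = y
    return out


def percent_scale(values: np.ndarray, marker: str = "column") -> np.ndarray:
    """Map a column linearly onto [0, 100]: min -> 0, max -> 100."""
    values = np.asarray(values, dtype=float)
    lo, hi = values.min(), values.max()
    if hi == lo:
        raise DegenerateMarkerError(marker, "percent scaling")
    out = 100.0 * (values - lo) / (hi - lo)
    out[values == lo] = 0.0     # endpoints exact despite rounding
    out[values == hi] = 100.0
    return out


def log_z(values: np.ndarray, marker: str = "column") -> np.ndarray:
    """Zero-invariant log then z-score: x -> ln(x + 1), then (· - mean)/sd.

    ln(x + 1) keeps zeros finite; the z-score uses the sample (n-1) sd.
    """
    values = np.asarray(values, dtype=float)
    logged = np.log1p(values)
    sd = logged.std(ddof=1)
    if sd == 0:
        raise DegenerateMarkerError(marker, "z-transform")
    return (logged - logged.mean()) / sd


def preprocess_cohort(
    table: pd.DataFrame,
    *,
    grubbs_alpha: float = 0.05,
    remove_grubbs_outliers: bool = True,
    iterative_grubbs: bool = False,
    covariate_correction: bool = True,
) -> tuple[PreprocessedMatrix, list[GrubbsResult]]:
    """Apply the full chain and return the z-scored matrix plus Grubbs report."""
    validate_cohort(table)
    provenance: list[dict] = []
    all_results: list[GrubbsResult] = []
    work = table.copy()

    if remove_grubbs_outliers:
        while True:
            results = grubbs_scan(work, grubbs_alpha)
            all_results.extend(results)
            removed = {r.outlier_row for r in results if r.significant}
            work = remove_outliers(work, results)
            provenance.append({"step": "grubbs_outlier_removal",
                               "alpha": grubbs_alpha, "removed": sorted(removed)})
            if not (iterative_grubbs and removed):
                break

    if covariate_correction:
        work = covariate_correct(work)
        provenance.append({"step": "covariate_correction", "order": ["age", "sex"]})

    meta, conc = split_cohort(work)
    values = conc.to_numpy(dtype=float).copy()
    for j, marker in enumerate(conc.columns):
        values[:, j] = percent_scale(values[:, j], marker)
    provenance.append({"step": "percent_scale", "range": [0, 100]})
    for j, marker in enumerate(conc.columns):
        values[:, j] = log_z(values[:, j], marker)
    provenance.append({"step": "log_z", "log": "ln(x+1)", "sd": "sample (n-1)"})

    pm = PreprocessedMatrix(
        subjects=[str(s) for s in work["subject_id"]],
        markers=list(conc.columns),
        values=values,
        meta=meta.reset_index(drop=True),
        provenance=provenance,
    )
    return pm, all_results


class CohortPreprocessor(BaseEstimator):
    """Sklearn-style wrapper around the preprocessing chain.

    ``fit_transform`` takes a cohort DataFrame (metadata columns plus marker
    columns) and returns the subjects x markers z-scored array; removed
    outlier rows shrink n.  Fitted attributes expose the Grubbs report,
    the removed subjects and the step provenance.
    """

    def __init__(self, grubbs_alpha: float = 0.05, remove_grubbs_outliers: bool = True,
                 iterative_grubbs: bool = False, covariate_correction: bool = True):
        self.grubbs_alpha = grubbs_alpha
        self.remove_grubbs_outliers = remove_grubbs_outliers
        self.iterative_grubbs = iterative_grubbs
        self.covariate_correction = covariate_correction

    def fit(self, X: pd.DataFrame, y=None) -> "CohortPreprocessor":
        matrix, results = preprocess_cohort(
            X,
            grubbs_alpha=self.grubbs_alpha,
            remove_grubbs_outliers=self.remove_grubbs_outliers,
            iterative_grubbs=self.iterative_grubbs,
            covariate_correction=self.covariate_correction,
        )
        self.matrix_ = matrix
        self.grubbs_results_ = results
        self.removed_subjects_ = sorted(
            {r.outlier_row for r in results if r.significant})
        self.provenance_ = matrix.provenance
        return self

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        return self.fit(X).matrix_.values

    def fit_transform(self, X: pd.DataFrame, y=None) -> np.ndarray:
        return self.fit(X).matrix_.values
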