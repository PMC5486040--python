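"""Valley clusters on the U*-matrix and agreement with a prior grouping.

Low regions (valleys) of the U*-landscape are taken as clusters and high
regions (ridges/watersheds) as borders.  Valley units below a height
quantile are grouped into toroidal 8-connected components; ridge units are
then filled to the nearest valley component so that every best-matching
unit, and hence every subject, receives a cluster.  Superimposing the known
patient/control grouping on the clusters yields standard diagnostic-test
measures: sensitivity, specificity and balanced accuracy.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from skimage.measure import label as _planar_label
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .heights import HeightMatrix, RadiusSpec, p_matrix, u_matrix, u_star_matrix
from .som import GridSpec, ToroidalESOM, _axis_delta


@dataclasses.dataclass
class ClusterAssignment:
    """Cluster ids per lattice unit and (after assignment) per subject."""

    grid: GridSpec
    unit_labels: np.ndarray        # (rows, cols) int, >= 1 after ridge fill
    valley_labels: np.ndarray      # (rows, cols) int, 0 on ridge units
    n_clusters: int
    threshold_quantile: float
    subject_labels: np.ndarray | None = None  # (n,) int cluster ids

    def to_frame(self, subject_ids, truth=None, predicted=None) -> pd.DataFrame:
        if self.subject_labels is None:
            raise ValueError("subjects not assigned yet")
        df = pd.DataFrame({"subject_id": subject_ids, "cluster": self.subject_labels})
        if truth is not None:
            df["true_class"] = truth
        if predicted is not None:
            df["predicted_class"] = predicted
        return df


@dataclasses.dataclass
class PerformanceReport:
    """Confusion counts and diagnostic-test measures (percent scale).

    ``sensitivity``, ``specificity`` and ``balanced_accuracy`` hold exact
    (unrounded) percentages; :meth:`rounded` gives one-decimal values for
    reporting.  ``balanced_accuracy`` is exactly the mean of sensitivity and
    specificity.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    balanced_accuracy: float
    cluster_to_class: dict[int, str]

    def rounded(self, ndigits: int = 1) -> dict[str, float]:
        return {
            "sensitivity": round(self.sensitivity, ndigits),
            "specificity": round(self.specificity, ndigits),
            "balanced_accuracy": round(self.balanced_accuracy, ndigits),
        }

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "sensitivity_pct": round(self.sensitivity, 1),
            "specificity_pct": round(self.specificity, 1),
            "balanced_accuracy_pct": round(self.balanced_accuracy, 1),
            "cluster_to_class": {str(k): v for k, v in self.cluster_to_class.items()},
        }


def _merge_torus_seams(labels: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Union planar component labels that touch across the wrap seams (8-conn)."""
    rows, cols = labels.shape
    parent = {}

    def find(a):
        parent.setdefault(a, a)
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    for c in range(cols):
        if mask[rows - 1, c]:
            for dc in (-1, 0, 1):
                cc = (c + dc) % cols
                if mask[0, cc]:
                    union(labels[rows - 1, c], labels[0, cc])
    for r in range(rows):
        if mask[r, cols - 1]:
            for dr in (-1, 0, 1):
                rr = (r + dr) % rows
                if mask[rr, 0]:
                    union(labels[r, cols - 1], labels[rr, 0])

    out = labels.copy()
    for lab in np.unique(labels[mask]):
        out[labels == lab] = find(lab)
    return out


def connected_valley_components(mask: np.ndarray, toroidal: bool = True) -> tuple[np.ndarray, int]:
    """8-connected components of a boolean valley mask, with optional wrap.

    Returns labels (0 outside the mask, components numbered 1..k in
    row-major order of first appearance) and the component count k.
    """
    mask = np.asarray(mask, dtype=bool)
    labels = _planar_label(mask, connectivity=2)
    if toroidal:
        labels = _merge_torus_seams(labels, mask)
    # relabel 1..k by first row-major occurrence
    out = np.zeros_like(labels)
    next_id = 0
    seen: dict[int, int] = {}
    for lab in labels.ravel():
        if lab and lab not in seen:
            next_id += 1
            seen[lab] = next_id
    for lab, new in seen.items():
        out[labels == lab] = new
    return out, next_id


def extract_clusters(ustar: HeightMatrix, threshold_quantile: float = 0.8) -> ClusterAssignment:
    """Threshold the U*-landscape into valley clusters and fill the ridges.

    Units with height at or below the given quantile of all heights form
    valleys; their toroidal 8-connected components become clusters 1..k.
    Each above-threshold (ridge) unit is then assigned the cluster of the
    nearest valley unit by lattice distance, ties going to the lower
    cluster id.
    """
    if ustar.kind != "Ustar":
        raise ValueError("extract_clusters expects a U*-matrix")
    if not (0 < threshold_quantile < 1):
        raise ValueError("threshold_quantile must lie in (0, 1)")
    grid = ustar.grid
    h = ustar.heights
    if np.ptp(h) == 0:
        warnings.warn("constant U*-matrix: no structure, single cluster", stacklevel=2)
        ones = np.ones_like(h, dtype=int)
        return ClusterAssignment(grid, ones, ones.copy(), 1, threshold_quantile)

    thr = np.quantile(h, threshold_quantile)
    mask = h <= thr
    valley_labels, k = connected_valley_components(mask, grid.toroidal)

    unit_labels = valley_labels.copy()
    ridge = ~mask
    if ridge.any():
        vr, vc = np.nonzero(mask)
        rr, rc = np.nonzero(ridge)
        dr = _axis_delta(rr[:, None] - vr[None, :], grid.rows, grid.toroidal)
        dc = _axis_delta(rc[:, None] - vc[None, :], grid.cols, grid.toroidal)
        d2 = dr * dr + dc * dc  # exact integer squared distances
        vlab = valley_labels[vr, vc]
        for i in range(len(rr)):
            row = d2[i]
            cand = vlab[row == row.min()]
            unit_labels[rr[i], rc[i]] = cand.min()  # tie -> lower cluster id
    return ClusterAssignment(grid, unit_labels, valley_labels, k, threshold_quantile)


def assign_subjects(assignment: ClusterAssignment, bmu_coords: np.ndarray) -> ClusterAssignment:
    """Give each subject the (post-fill) cluster id of its best-matching unit."""
    bmu_coords = np.asarray(bmu_coords, dtype=int)
    r, c = bmu_coords[:, 0], bmu_coords[:, 1]
    if (r < 0).any() or (r >= assignment.grid.rows).any() or (c < 0).any() or (c >= assignment.grid.cols).any():
        raise IndexError("BMU coordinates outside the lattice")
    return dataclasses.replace(assignment, subject_labels=assignment.unit_labels[r, c])


def evaluate_agreement(assignment: ClusterAssignment | np.ndarray, truth) -> PerformanceReport:
    """Score how well the discovered clusters reproduce the prior grouping.

    Each cluster is mapped to the class forming the majority of its members
    (ties go to ``control``, the conservative choice).  Subjects in
    patient-majority clusters are counted as predicted patients.  Returns
    sensitivity = tp/(tp+fn), specificity = tn/(tn+fp) and their mean
    (balanced accuracy), all as exact percentages.
    """
    if isinstance(assignment, ClusterAssignment):
        if assignment.subject_labels is None:
            raise ValueError("assignment has no subject labels; run assign_subjects first")
        clusters = np.asarray(assignment.subject_labels)
    else:
        clusters = np.asarray(assignment)
    truth = np.asarray(truth)
    if clusters.shape != truth.shape:
        raise ValueError("cluster labels and truth labels differ in length")
    is_patient = truth == "patient"
    if not is_patient.any() or is_patient.all():
        raise ValueError("both classes must be present to compute sensitivity and specificity")

    cluster_to_class: dict[int, str] = {}
    for cid in np.unique(clusters):
        members = clusters == cid
        n_pat = int((members & is_patient).sum())
        n_ctl = int(members.sum()) - n_pat
        cluster_to_class[int(cid)] = "patient" if n_pat > n_ctl else "control"

    predicted_patient = np.array([cluster_to_class[int(c)] == "patient" for c in clusters])
    tp = int((predicted_patient & is_patient).sum())
    fn = int((~predicted_patient & is_patient).sum())
    tn = int((~predicted_patient & ~is_patient).sum())
    fp = int((predicted_patient & ~is_patient).sum())
    sens = 100.0 * tp / (tp + fn)
    spec = 100.0 * tn / (tn + fp)
    return PerformanceReport(tp, fp, tn, fn, sens, spec, (sens + spec) / 2.0, cluster_to_class)


def report_from_confusion(tp: int, fn: int, tn: int, fp: int) -> PerformanceReport:
    """Diagnostic-test measures from explicit confusion counts.

    Builds the corresponding two-cluster assignment (one pure predicted-
    patient group, one predicted-control group) and scores it through
    :func:`evaluate_agreement`, so the rates are computed, not transcribed.
    """
    clusters = np.concatenate([
        np.full(tp + fp, 2, dtype=int),      # predicted-patient cluster
        np.full(fn + tn, 1, dtype=int),      # predicted-control cluster
    ])
    truth = np.concatenate([
        np.repeat(["patient"], tp), np.repeat(["control"], fp),
        np.repeat(["patient"], fn), np.repeat(["control"], tn),
    ])
    return evaluate_agreement(clusters, truth)


class UStarClusterer(BaseEstimator, ClusterMixin):
    """End-to-end structure discovery: ESOM -> U*/P landscape -> valley clusters.

    Fitting trains a :class:`~torusom.som.ToroidalESOM` on the (already
    preprocessed) subjects x markers matrix, computes the U-, P- and
    U*-matrices, extracts valley clusters and labels every subject through
    its BMU.

    Attributes
    ----------
    som_ : ToroidalESOM
    u_matrix_, p_matrix_, u_star_matrix_ : HeightMatrix
    assignment_ : ClusterAssignment
    labels_ : ndarray of per-subject cluster ids
    """

    def __init__(
        self,
        rows: int = 30,
        cols: int = 48,
        toroidal: bool = True,
        epochs: int = 20,
        lr_start: float = 0.5,
        lr_end: float = 0.05,
        radius_start: float = 12.0,
        radius_end: float = 1.0,
        radius_method: str = "distance_quantile",
        sphere_radius: float | None = None,
        sphere_quantile: float = 0.2013,
        threshold_quantile: float = 0.8,
        random_state: int | None = None,
    ):
        self.rows = rows
        self.cols = cols
        self.toroidal = toroidal
        self.epochs = epochs
        self.lr_start = lr_start
        self.lr_end = lr_end
        self.radius_start = radius_start
        self.radius_end = radius_end
        self.radius_method = radius_method
        self.sphere_radius = sphere_radius
        self.sphere_quantile = sphere_quantile
        self.threshold_quantile = threshold_quantile
        self.random_state = random_state

    def fit(self, X, y=None) -> "UStarClusterer":
        X = check_array(X, dtype=float)
        self.som_ = ToroidalESOM(
            rows=self.rows, cols=self.cols, toroidal=self.toroidal,
            epochs=self.epochs, lr_start=self.lr_start, lr_end=self.lr_end,
            radius_start=self.radius_start, radius_end=self.radius_end,
            random_state=self.random_state,
        ).fit(X)
        grid = self.som_.grid_
        self.u_matrix_ = u_matrix(self.som_.weights_, grid)
        spec = RadiusSpec(method=self.radius_method, r=self.sphere_radius,
                          quantile=self.sphere_quantile)
        self.p_matrix_ = p_matrix(self.som_.weights_, X, grid, spec)
        self.u_star_matrix_ = u_star_matrix(self.u_matrix_, self.p_matrix_)
        assignment = extract_clusters(self.u_star_matrix_, self.threshold_quantile)
        self.assignment_ = assign_subjects(assignment, self.som_.bmu_coords(X))
        self.labels_ = self.assignment_.subject_labels
        return self

    def score_agreement(self, truth) -> PerformanceReport:
        """Diagnostic-test agreement between clusters and a patient/control truth."""
        check_is_fitted(self, "assignment_")
        return evaluate_agreement(self.assignment_, truth)
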