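"""Quantitative evaluation: tracing consistency, diameter discrepancy,
landmark variability and before/after registration error.

The tracing score is the mean of two directed consistencies computed on
densely resampled centerlines:

* ``c_miss`` — the length-weighted fraction of the ground-truth cable that
  has an extracted point within tolerance ``tau`` (1 means no existing
  branch was missed);
* ``c_false`` — the length-weighted fraction of the extracted cable that
  has a ground-truth point within ``tau`` (1 means no nonexistent branch
  was detected).

``consistency = (c_miss + c_false) / 2``.  Both trees are resampled to
point chains at <= 0.5 um arc-length so the score weights cable length, not
node count.  Diameter discrepancy is the mean relative diameter error over
mutually matched points.  An empty extraction scores 0, not 0.5 — a null
answer earns no credit for "detecting nothing falsely".

Landmark-based atlas evaluation measures plain Euclidean distances of named
points between landmark sets, per sample and per point, with the mean and
standard deviation recomputable from the returned table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .formats import LandmarkSet, Morphology

__all__ = [
    "ConsistencyReport",
    "LandmarkErrorReport",
    "resample_to_chain",
    "consistency",
    "landmark_error",
    "registration_error",
]


@dataclass
class ConsistencyReport:
    """Bidirectional tracing score against a ground truth at tolerance tau."""

    c_miss: float
    c_false: float
    consistency: float
    diameter_discrepancy: float
    tau: float
    gt_length: float
    test_length: float


def resample_to_chain(m: Morphology, step: float = 0.5
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Resample all edges into points with per-point length weight and radius.

    Each edge of length L contributes ``ceil(L/step)`` midpoint samples of
    weight ``L/n``; radii are linearly interpolated.  A morphology with no
    edges yields zero points (zero cable length).
    """
    pts, wts, rads = [], [], []
    for child, parent in m.edges():
        a, b = m.xyz[parent], m.xyz[child]
        ra, rb = m.radii[parent], m.radii[child]
        L = float(np.linalg.norm(b - a))
        if L == 0:
            continue
        n = max(int(np.ceil(L / step)), 1)
        t = (np.arange(n) + 0.5) / n
        pts.append(a + t[:, None] * (b - a))
        wts.append(np.full(n, L / n))
        rads.append(ra + t * (rb - ra))
    if not pts:
        return np.zeros((0, 3)), np.zeros(0), np.zeros(0)
    return np.concatenate(pts), np.concatenate(wts), np.concatenate(rads)


def consistency(gt: Morphology, test: Morphology, tau: float = 2.0,
                step: float = 0.5) -> ConsistencyReport:
    """Score an extracted morphology against ground truth.

    ``tau`` (um, default 2 — about one optical-section step) is the match
    tolerance.  Self-comparison gives consistency 1 and discrepancy 0;
    spatially disjoint trees give 0.
    """
    if tau <= 0:
        raise ValueError("tau must be > 0")
    gt_pts, gt_w, gt_r = resample_to_chain(gt, step)
    te_pts, te_w, te_r = resample_to_chain(test, step)
    gt_len, te_len = float(gt_w.sum()), float(te_w.sum())

    if gt_len == 0 or te_len == 0:
        return ConsistencyReport(0.0, 0.0, 0.0, float("nan"), tau, gt_len, te_len)

    te_kdt = cKDTree(te_pts)
    d_gt, j_gt = te_kdt.query(gt_pts, k=1)
    gt_matched = d_gt <= tau
    c_miss = float(gt_w[gt_matched].sum() / gt_len)

    gt_kdt = cKDTree(gt_pts)
    d_te, _ = gt_kdt.query(te_pts, k=1)
    te_matched = d_te <= tau
    c_false = float(te_w[te_matched].sum() / te_len)

    if gt_matched.any():
        d_gt_diam = 2.0 * gt_r[gt_matched]
        d_te_diam = 2.0 * te_r[j_gt[gt_matched]]
        discrepancy = float(np.average(
            np.abs(d_te_diam - d_gt_diam) / d_gt_diam, weights=gt_w[gt_matched]))
    else:
        discrepancy = float("nan")

    return ConsistencyReport(c_miss, c_false, (c_miss + c_false) / 2.0,
                             discrepancy, tau, gt_len, te_len)


@dataclass
class LandmarkErrorReport:
    """Per-sample, per-landmark Euclidean distances to a base landmark set."""

    table: pd.DataFrame  # columns: sample, name, distance (um)
    mean: float
    std: float

    def per_landmark_mean(self) -> pd.Series:
        return self.table.groupby("name")["distance"].mean()


def landmark_error(base: LandmarkSet, others: list[LandmarkSet],
                   sample_names: list[str] | None = None) -> LandmarkErrorReport:
    """Distances of each sample's landmarks to the base set, matched by name.

    The grand mean over all (sample, landmark) pairs is the atlas
    variability statistic; choosing the average brain as the base minimizes
    it.
    """
    if sample_names is None:
        sample_names = [f"sample{i}" for i in range(len(others))]
    shared: list[str] | None = None
    for other in others:
        names = base.common_names(other)
        shared = names if shared is None else [n for n in shared if n in names]
    if not shared:
        raise ValueError("no landmark names shared between base and all samples")
    rows = []
    for sname, other in zip(sample_names, others):
        for n in shared:
            rows.append((sname, n, float(np.linalg.norm(base[n] - other[n]))))
    table = pd.DataFrame(rows, columns=["sample", "name", "distance"])
    return LandmarkErrorReport(table, float(table["distance"].mean()),
                               float(table["distance"].std(ddof=1))
                               if len(table) > 1 else 0.0)


def registration_error(point_names: list[str], standard: LandmarkSet,
                       sample_before: LandmarkSet,
                       sample_after: LandmarkSet) -> pd.DataFrame:
    """Held-out distinct-point errors before and after registration.

    ``point_names`` are evaluation points (e.g. CCB, RMC, LMC, RMP, LMP)
    that were *not* used to fit the transform.  Returns a table with
    ``before``, ``after`` (um) and ``improvement = before - after`` per
    point.
    """
    rows = []
    for n in point_names:
        for lm in (standard, sample_before, sample_after):
            if n not in lm:
                raise KeyError(f"point {n!r} missing from a landmark set")
        before = float(np.linalg.norm(standard[n] - sample_before[n]))
        after = float(np.linalg.norm(standard[n] - sample_after[n]))
        rows.append((n, before, after, before - after))
    return pd.DataFrame(rows, columns=["name", "before", "after", "improvement"])
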