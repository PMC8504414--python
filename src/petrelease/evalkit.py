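"""Scoring of challenge submissions against ground truth.

Two performance criteria are used:

* percentage root-mean-squared error,
  ``RMSE = 100 * sqrt(sum_i (y_i - yhat_i)^2 / N) / ybar`` with ``yhat``
  the ground truth and ``ybar`` the mean of the ground truth over the
  scored voxels -- applied to the BP_ND maps and, normalised by the
  simulated displacement, to the voxelwise change in the displacement
  regions; and
* the Jaccard similarity index ``J = TP / (TP + FP + FN)`` between the
  submitted and true displacement masks, with the FP/TP ratio as a
  specificity summary.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ChallengeTruth",
    "Submission",
    "ScoreReport",
    "rmse_percent",
    "rmse_displacement",
    "jaccard",
    "fp_tp_ratio",
    "score_submission",
]


class GridMismatchError(ValueError):
    pass


def _map_array(m) -> np.ndarray:
    """Accept a bare array or a BPMap-like object with a ``data`` volume."""
    if not isinstance(m, np.ndarray) and hasattr(m, "data"):
        m = m.data
    return np.asarray(m, dtype=float)


def rmse_percent(estimates, truth) -> float:
    """Percentage RMSE of ``estimates`` against ``truth``.

    ``100 * sqrt(mean((y - yhat)^2)) / mean(yhat)``; scale-invariant under
    joint positive rescaling of both vectors.
    """
    y = np.asarray(estimates, dtype=float).ravel()
    yhat = np.asarray(truth, dtype=float).ravel()
    if y.shape != yhat.shape:
        raise ValueError("estimates and truth must have equal length")
    ybar = yhat.mean()
    if ybar == 0:
        raise ZeroDivisionError("truth mean is zero; percentage RMSE undefined")
    return float(100.0 * np.sqrt(np.mean((y - yhat) ** 2)) / ybar)


def rmse_displacement(est_pre, est_post, truth_pre, truth_post, region) -> float:
    """Percentage RMSE of the voxelwise change within a displacement region.

    The change ``Delta = BP_pre - BP_post`` is compared voxel by voxel and
    normalised by the mean *simulated* displacement in the region, so a
    constant bias common to both scans cancels exactly.
    """
    region = np.asarray(region, dtype=bool)
    if not region.any():
        raise ValueError("region is empty")
    d_est = (np.asarray(est_pre, dtype=float) - np.asarray(est_post, dtype=float))[region]
    d_true = (np.asarray(truth_pre, dtype=float) - np.asarray(truth_post, dtype=float))[region]
    if d_true.mean() == 0:
        raise ZeroDivisionError("simulated displacement is zero in the region")
    return float(100.0 * np.sqrt(np.mean((d_est - d_true) ** 2)) / d_true.mean())


def _counts(mask, truth_mask):
    m = np.asarray(mask, dtype=bool)
    t = np.asarray(truth_mask, dtype=bool)
    if m.shape != t.shape:
        raise GridMismatchError(f"grid mismatch: {m.shape} vs {t.shape}")
    tp = int(np.sum(m & t))
    fp = int(np.sum(m & ~t))
    fn = int(np.sum(~m & t))
    return tp, fp, fn


def jaccard(mask, truth_mask) -> float:
    """Jaccard overlap ``TP / (TP + FP + FN)``; two empty masks give 1."""
    tp, fp, fn = _counts(mask, truth_mask)
    if tp + fp + fn == 0:
        warnings.warn("both masks empty; Jaccard defined as 1", stacklevel=2)
        return 1.0
    return tp / (tp + fp + fn)


def fp_tp_ratio(mask, truth_mask) -> float:
    """False positives as a percentage of true positives (undefined if TP=0)."""
    tp, fp, _ = _counts(mask, truth_mask)
    if tp == 0:
        return float("nan")
    return 100.0 * fp / tp


@dataclass
class ChallengeTruth:
    """Ground-truth bundle: per-subject pre/post BP maps, regions, mask."""

    bp_pre: list          # n_subjects arrays (x, y, z)
    bp_post: list
    roi_labels: np.ndarray
    deltas: tuple
    brain_mask: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def n_subjects(self) -> int:
        return len(self.bp_pre)

    @property
    def displacement_mask(self) -> np.ndarray:
        return self.roi_labels > 0

    def region_mask(self, r: int) -> np.ndarray:
        return self.roi_labels == r


@dataclass
class Submission:
    """A participant-style answer: pre/post BP maps + displacement mask."""

    bp_pre: list
    bp_post: list
    displacement_mask: np.ndarray
    provenance: dict = field(default_factory=dict)


@dataclass
class ScoreReport:
    """Scores of one submission."""

    rmse_bp_per_map: list
    rmse_bp_mean: float
    rmse_bp_sd: float
    rmse_bp_pooled: float
    rmse_displacement_per_region: dict
    rmse_displacement_pooled: float
    jaccard: float
    tp: int
    fp: int
    fn: int
    fp_tp_percent: float
    n_excluded_voxels: int = 0
    provenance: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        def convert(o):
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            raise TypeError(type(o))

        s = json.dumps(self.__dict__, indent=2, default=convert)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    def to_table(self) -> pd.DataFrame:
        rows = [
            ("RMSE BP_ND mean over maps (%)", self.rmse_bp_mean),
            ("RMSE BP_ND sd over maps (%)", self.rmse_bp_sd),
            ("RMSE BP_ND pooled voxels (%)", self.rmse_bp_pooled),
            ("RMSE displacement pooled (%)", self.rmse_displacement_pooled),
            ("Jaccard index", self.jaccard),
            ("FP/TP (%)", self.fp_tp_percent),
            ("TP voxels", self.tp),
            ("FP voxels", self.fp),
            ("FN voxels", self.fn),
        ]
        rows += [
            (f"RMSE displacement region {r} (%)", v)
            for r, v in sorted(self.rmse_displacement_per_region.items())
        ]
        return pd.DataFrame(rows, columns=["metric", "value"])


def _validate_submission(sub: Submission, truth: ChallengeTruth) -> list:
    problems = []
    if len(sub.bp_pre) != truth.n_subjects or len(sub.bp_post) != truth.n_subjects:
        problems.append(
            f"expected {truth.n_subjects} pre and post maps, got "
            f"{len(sub.bp_pre)}/{len(sub.bp_post)}"
        )
    shape = truth.brain_mask.shape
    for kind, maps in (("pre", sub.bp_pre), ("post", sub.bp_post)):
        for i, m in enumerate(maps):
            arr = _map_array(m)
            if arr.shape != shape:
                problems.append(f"{kind} map {i}: shape {arr.shape} != {shape}")
    if np.asarray(sub.displacement_mask).shape != shape:
        problems.append("displacement mask shape mismatch")
    return problems


def score_submission(sub: Submission, truth: ChallengeTruth) -> ScoreReport:
    """Score a submission with the RMSE and overlap criteria.

    BP_ND RMSE is computed per map over brain voxels (non-finite estimates
    are excluded and counted), then summarised as mean +/- sd across the
    2 x n_subjects maps; displacement RMSE is computed per region and
    pooled over all region voxels of all subjects.
    """
    problems = _validate_submission(sub, truth)
    if problems:
        raise GridMismatchError("; ".join(problems))

    as_arr = _map_array

    brain = truth.brain_mask
    per_map = []
    pooled_est, pooled_truth = [], []
    n_excluded = 0
    for est_maps, true_maps in ((sub.bp_pre, truth.bp_pre), (sub.bp_post, truth.bp_post)):
        for est, tru in zip(est_maps, true_maps):
            e, t = as_arr(est)[brain], as_arr(tru)[brain]
            ok = np.isfinite(e)
            n_excluded += int((~ok).sum())
            per_map.append(rmse_percent(e[ok], t[ok]))
            pooled_est.append(e[ok])
            pooled_truth.append(t[ok])
    pooled = rmse_percent(np.concatenate(pooled_est), np.concatenate(pooled_truth))

    per_region = {}
    pooled_d_est, pooled_d_true = [], []
    for r in range(1, len(truth.deltas) + 1):
        region = truth.region_mask(r)
        vals_e, vals_t = [], []
        for s in range(truth.n_subjects):
            de = (as_arr(sub.bp_pre[s]) - as_arr(sub.bp_post[s]))[region]
            dt = (truth.bp_pre[s] - truth.bp_post[s])[region]
            ok = np.isfinite(de)
            vals_e.append(de[ok])
            vals_t.append(dt[ok])
        e = np.concatenate(vals_e)
        t = np.concatenate(vals_t)
        per_region[r] = float(100.0 * np.sqrt(np.mean((e - t) ** 2)) / t.mean())
        pooled_d_est.append(e)
        pooled_d_true.append(t)
    e = np.concatenate(pooled_d_est)
    t = np.concatenate(pooled_d_true)
    disp_pooled = float(100.0 * np.sqrt(np.mean((e - t) ** 2)) / t.mean())

    tp, fp, fn = _counts(sub.displacement_mask, truth.displacement_mask)
    return ScoreReport(
        rmse_bp_per_map=per_map,
        rmse_bp_mean=float(np.mean(per_map)),
        rmse_bp_sd=float(np.std(per_map, ddof=1)),
        rmse_bp_pooled=pooled,
        rmse_displacement_per_region=per_region,
        rmse_displacement_pooled=disp_pooled,
        jaccard=jaccard(sub.displacement_mask, truth.displacement_mask),
        tp=tp,
        fp=fp,
        fn=fn,
        fp_tp_percent=fp_tp_ratio(sub.displacement_mask, truth.displacement_mask),
        n_excluded_voxels=n_excluded,
        provenance=dict(sub.provenance),
    )
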