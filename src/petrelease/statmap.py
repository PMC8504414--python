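"""Voxelwise detection of tracer displacement across subjects.

Displacement is a *reduction* of binding after the pharmacological
challenge, so all tests are one-sided on the paired difference
``Delta = BP_pre - BP_post``:

* a parametric paired t-test (optionally after Gaussian smoothing of the
  difference maps), and
* a nonparametric sign-flipping permutation test with max-T family-wise
  error control (the distribution of the image-wide maximum statistic under
  random sign flips of the subject differences), optionally with variance
  smoothing of the denominator (pseudo-t).

Suprathreshold voxels are grouped into connected components and small
clusters removed to form the final displacement mask.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage, stats

__all__ = [
    "paired_t_map",
    "permutation_test",
    "threshold_and_cluster",
    "delta_maps",
]

_FWHM_TO_SIGMA = 1.0 / 2.3548200450309493
#: cap applied to t statistics at zero-variance, non-zero-mean voxels
T_CAP = 1e6


def delta_maps(pairs, smoothing_fwhm_mm: float = 0.0,
               voxel_size_mm: float = 1.0) -> np.ndarray:
    """Stack of per-subject difference maps ``pre - post`` (n, x, y, z)."""
    def as_arr(m):
        if not isinstance(m, np.ndarray) and hasattr(m, "data"):
            m = m.data
        return np.asarray(m, dtype=float)

    deltas = []
    for pre, post in pairs:
        pre_d = as_arr(pre)
        post_d = as_arr(post)
        if pre_d.shape != post_d.shape:
            raise ValueError("pre/post maps must share a grid")
        d = pre_d - post_d
        if smoothing_fwhm_mm > 0:
            d = ndimage.gaussian_filter(
                d, smoothing_fwhm_mm * _FWHM_TO_SIGMA / voxel_size_mm
            )
        deltas.append(d)
    return np.stack(deltas)


def _t_stat(deltas: np.ndarray):
    """One-sample t over axis 0 with zero-variance guards."""
    n = deltas.shape[0]
    mean = deltas.mean(axis=0)
    sd = deltas.std(axis=0, ddof=1)
    zero = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(zero, 0.0, mean / np.where(zero, 1.0, sd / np.sqrt(n)))
    t = np.where(zero & (mean > 0), T_CAP, t)
    t = np.where(zero & (mean < 0), -T_CAP, t)
    return t, mean, sd


def paired_t_map(pairs, smoothing_fwhm_mm: float = 0.0,
                 voxel_size_mm: float = 1.0,
                 brain_mask: np.ndarray | None = None):
    """One-sided paired t-test (pre > post) across subjects.

    Returns ``(t_map, p_map)``; degrees of freedom are n-1.  Zero-variance
    voxels get t=0 (p=1) when the mean difference is zero, and a capped
    maximal t when it is not.
    """
    if len(pairs) < 2:
        raise ValueError("need at least 2 subject pairs")
    deltas = delta_maps(pairs, smoothing_fwhm_mm, voxel_size_mm)
    t, mean, sd = _t_stat(deltas)
    n = deltas.shape[0]
    p = stats.t.sf(np.clip(t, -T_CAP, T_CAP), df=n - 1)
    p = np.where((sd == 0) & (mean == 0), 1.0, p)  # excluded voxels
    if brain_mask is not None:
        t = np.where(brain_mask, t, 0.0)
        p = np.where(brain_mask, p, 1.0)
    return t, p


def _sign_patterns(n: int, n_perm: int, rng: np.random.Generator):
    """All 2^n sign patterns if enumerable within n_perm, else random draws."""
    if 2**n <= n_perm:
        bits = np.arange(2**n)[:, None] >> np.arange(n)[None, :]
        return 1.0 - 2.0 * (bits & 1), True
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    return signs, False


def permutation_test(
    pairs,
    n_perm: int = 10000,
    seed: int = 0,
    smoothing_fwhm_mm: float = 0.0,
    variance_smoothing_fwhm_mm: float = 0.0,
    voxel_size_mm: float = 1.0,
    brain_mask: np.ndarray | None = None,
):
    """Sign-flipping permutation test with max-T FWE correction.

    Under the null of no displacement the subject differences are symmetric
    about zero, so their signs are exchangeable.  For every sign pattern the
    image-wide maximum t (or pseudo-t when ``variance_smoothing_fwhm_mm`` >
    0) is recorded; the FWE-corrected p-value of a voxel is the fraction of
    patterns whose maximum reaches its observed statistic.  With n subjects
    only 2^n distinct patterns exist; they are enumerated exactly whenever
    ``2^n <= n_perm`` (p-values are then multiples of ``2^-n``).

    Returns ``(t_map, p_fwe_map)``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    n = len(pairs)
    if n < 4:
        warnings.warn(
            f"only {n} subjects: at most {2**n} distinct sign patterns",
            stacklevel=2,
        )
    deltas = delta_maps(pairs, smoothing_fwhm_mm, voxel_size_mm)
    if brain_mask is None:
        brain_mask = np.ones(deltas.shape[1:], dtype=bool)
    flat = deltas[:, brain_mask]  # (n, nvox)

    def pseudo_t(d):
        mean = d.mean(axis=0)
        sd = d.std(axis=0, ddof=1)
        if variance_smoothing_fwhm_mm > 0:
            var = np.zeros(deltas.shape[1:])
            var[brain_mask] = sd**2
            var = ndimage.gaussian_filter(
                var, variance_smoothing_fwhm_mm * _FWHM_TO_SIGMA / voxel_size_mm
            )
            sd = np.sqrt(np.maximum(var[brain_mask], 0.0))
        zero = sd == 0
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(zero, 0.0, mean / np.where(zero, 1.0, sd / np.sqrt(d.shape[0])))
        t = np.where(zero & (mean > 0), T_CAP, t)
        t = np.where(zero & (mean < 0), -T_CAP, t)
        return t

    t_obs = pseudo_t(flat)
    rng = np.random.default_rng(seed)
    signs, exact = _sign_patterns(n, n_perm, rng)
    max_ts = np.empty(signs.shape[0])
    for i, s in enumerate(signs):
        max_ts[i] = pseudo_t(flat * s[:, None]).max()
    if exact:
        counts = (max_ts[None, :] >= t_obs[:, None] - 1e-12).sum(axis=1)
        p_vox = counts / signs.shape[0]
    else:
        counts = (max_ts[None, :] >= t_obs[:, None] - 1e-12).sum(axis=1)
        p_vox = (1.0 + counts) / (1.0 + signs.shape[0])

    t_map = np.zeros(deltas.shape[1:])
    p_map = np.ones(deltas.shape[1:])
    t_map[brain_mask] = t_obs
    p_map[brain_mask] = p_vox
    return t_map, p_map


def _connectivity_structure(connectivity: int) -> np.ndarray:
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    if connectivity == 18:
        return ndimage.generate_binary_structure(3, 2)
    if connectivity == 26:
        return ndimage.generate_binary_structure(3, 3)
    raise ValueError("connectivity must be 6, 18 or 26")


def threshold_and_cluster(
    stat_map: np.ndarray,
    threshold: float,
    cluster_extent: int = 0,
    connectivity: int = 18,
    mode: str = "greater",
) -> np.ndarray:
    """Binary displacement mask from a statistic or p-value map.

    ``mode='greater'`` keeps voxels with value > threshold (t maps);
    ``mode='less'`` keeps value < threshold (p maps).  Connected components
    (default 18-connectivity) smaller than ``cluster_extent`` voxels are
    removed.
    """
    if mode == "greater":
        supra = stat_map > threshold
    elif mode == "less":
        supra = stat_map < threshold
    else:
        raise ValueError("mode must be 'greater' or 'less'")
    if not supra.any() or cluster_extent <= 1:
        return supra
    labels, n = ndimage.label(supra, structure=_connectivity_structure(connectivity))
    if n == 0:
        return supra
    sizes = ndimage.sum_labels(supra, labels, index=np.arange(1, n + 1))
    keep = np.flatnonzero(sizes >= cluster_extent) + 1
    return np.isin(labels, keep)
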