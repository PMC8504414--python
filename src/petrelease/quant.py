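"""Voxelwise reference-tissue quantification of binding potential.

Three method families produce BP_ND parametric maps from a dynamic scan and
a reference-region TAC:

* **SRTM** (simplified reference tissue model) solved with basis functions:
  ``CT = R1*Cref + (k2 - R1*k2a) * Cref (x) exp(-k2a t)`` with
  ``BP_ND = k2/k2a - 1``; ``k2a`` is scanned over a log-spaced grid and the
  two linear coefficients are solved by (weighted) least squares.
* **Reference Logan**: after a settling time t*, the plot of
  ``int_0^T CT / CT(T)`` against ``(int_0^T Cref [+ Cref/k2']) / CT(T)``
  becomes linear with slope DVR = BP_ND + 1.
* **MRTM2**: the two-parameter multilinear form
  ``CT(T) = b1*(int_0^T Cref + Cref(T)/k2') + b2*int_0^T CT`` with a fixed
  reference efflux constant k2'; ``BP_ND = -(b1/b2) - 1``.  This form is
  exact for SRTM-consistent kinetics (integrate the one-tissue ODE and
  eliminate the plasma input through the reference region).

All functions accept frame-domain data: TAC values are frame averages and
``times`` are frame mid-times in minutes.  Dynamic data must be decay
corrected before quantification.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from scipy.integrate import cumulative_trapezoid

from petrelease.acquisition import CARBON11_HALF_LIFE_MIN, DynamicImage, Framing
from petrelease.kinetics import TAC, expconv

__all__ = [
    "QuantSettings",
    "BPMap",
    "extract_reference_tac",
    "srtm_basis",
    "logan_ref",
    "mrtm2",
    "estimate_k2prime",
    "parametric_map",
    "FitError",
]

_FWHM_TO_SIGMA = 1.0 / 2.3548200450309493


class FitError(RuntimeError):
    pass


@dataclass(frozen=True)
class QuantSettings:
    """Settings shared by the parametric-mapping methods.

    Attributes
    ----------
    pre_smoothing_fwhm_mm : Gaussian kernel applied to the 4D data before
        quantification (0 = none).  Kernels of 4.6-10 mm are typical.
    t_star_min : settling time for the graphical methods (minutes).
    k2_prime : fixed reference efflux rate (min^-1) for MRTM2 / the Logan
        k2' term; ``None`` drops the term (simplified Logan), ``"estimate"``
        derives it from a high-binding region with MRTM.
    weighting : ``"uniform"`` or ``"frame"`` (duration x decay weights).
    n_basis, basis_range : log-spaced k2a grid for the SRTM basis search.
    brain_mask_auc_fraction : voxels whose TAC area exceeds this fraction of
        the reference TAC area form the default analysis mask.
    """

    pre_smoothing_fwhm_mm: float = 0.0
    t_star_min: float = 10.0
    k2_prime: float | str | None = None
    weighting: str = "uniform"
    n_basis: int = 128
    basis_range: tuple = (0.01, 1.0)
    brain_mask_auc_fraction: float = 0.05
    half_life_min: float = CARBON11_HALF_LIFE_MIN

    def __post_init__(self) -> None:
        if self.basis_range[0] <= 0 or self.basis_range[1] <= self.basis_range[0]:
            raise ValueError("basis range must be positive and increasing")
        if self.weighting not in ("uniform", "frame"):
            raise ValueError("weighting must be 'uniform' or 'frame'")


@dataclass
class BPMap:
    """A 3D BP_ND parametric map with provenance."""

    data: np.ndarray
    method: str
    settings: dict
    brain_mask: np.ndarray
    invalid_mask: np.ndarray

    @property
    def shape(self) -> tuple:
        return self.data.shape


def extract_reference_tac(dynimg: DynamicImage, mask: np.ndarray) -> TAC:
    """Frame-wise mean TAC over the mask voxels."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("reference mask is empty")
    values = dynimg.data[mask].mean(axis=0)
    return TAC(dynimg.framing.mid_times_min, np.asarray(values, dtype=float))


def _frame_weights(framing: Framing, settings: QuantSettings) -> np.ndarray:
    if settings.weighting == "uniform":
        return np.ones(framing.n_frames)
    lam = np.log(2.0) / settings.half_life_min
    w = framing.durations_s * np.exp(-lam * framing.mid_times_min)
    return w / w.mean()


def _cumint(times: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Cumulative trapezoid integral from t=0 (curve assumed 0 at t=0).

    ``values`` may be (nf,) or (nvox, nf); returns the same shape.
    """
    v = np.atleast_2d(values)
    t = np.concatenate([[0.0], times])
    v0 = np.concatenate([np.zeros((v.shape[0], 1)), v], axis=1)
    ci = cumulative_trapezoid(v0, t, axis=1)
    return ci[0] if np.ndim(values) == 1 else ci


def _fine_grid_basis(
    ref_values: np.ndarray, times: np.ndarray, framing: Framing, thetas: np.ndarray
) -> np.ndarray:
    """Frame-averaged ``Cref (x) exp(-theta t)`` basis functions.

    The reference TAC is linearly interpolated onto a 1 s grid, convolved
    exactly, then averaged within each frame -- the same operation that
    produced the frame data.
    """
    dt = 1.0 / 60.0
    tf = np.arange(0.0, framing.total_duration_s / 60.0 + dt / 2, dt)
    ref_fine = np.interp(tf, np.concatenate([[0.0], times]),
                         np.concatenate([[0.0], ref_values]))
    conv = expconv(thetas, tf, ref_fine)
    edges = np.round(framing.starts_s).astype(int)
    ends = np.round(framing.ends_s).astype(int)
    out = np.empty((thetas.size, framing.n_frames))
    for f in range(framing.n_frames):
        out[:, f] = conv[:, edges[f]:ends[f] + 1].mean(axis=1)
    return out


def _as_matrix(values) -> tuple:
    v = np.asarray(values, dtype=float)
    single = v.ndim == 1
    return (v[None, :] if single else v), single


def srtm_basis(tac, ref_tac: TAC, framing: Framing, settings: QuantSettings | None = None):
    """SRTM by basis functions.

    ``tac`` may be a :class:`TAC` or an (nvox, nf) array of frame values.
    Returns a dict with arrays ``R1``, ``k2``, ``k2a``, ``BPND`` and a
    boolean ``valid`` mask (all scalars for a single TAC).
    """
    settings = settings or QuantSettings()
    Y, single = _as_matrix(tac.values if isinstance(tac, TAC) else tac)
    if framing.n_frames < 3:
        raise FitError("need at least 3 frames")
    ref = np.asarray(ref_tac.values, dtype=float)
    if not np.any(ref > 0):
        raise FitError("reference TAC is identically zero")
    times = ref_tac.times
    w = _frame_weights(framing, settings)

    thetas = np.geomspace(*settings.basis_range, settings.n_basis)
    B = _fine_grid_basis(ref, times, framing, thetas)

    wy2 = (w * Y**2).sum(axis=1)
    best_rss = np.full(Y.shape[0], np.inf)
    best = np.zeros((3, Y.shape[0]))  # R1, phi, theta
    ref_w = w * ref
    a11 = float(np.sum(ref_w * ref))
    yr = Y @ ref_w
    for i, th in enumerate(thetas):
        b = B[i]
        a12 = float(np.sum(ref_w * b))
        a22 = float(np.sum(w * b * b))
        det = a11 * a22 - a12 * a12
        if det <= 1e-300:
            continue
        yb = Y @ (w * b)
        r1 = (a22 * yr - a12 * yb) / det
        phi = (a11 * yb - a12 * yr) / det
        rss = wy2 - 2.0 * (r1 * yr + phi * yb) + (
            a11 * r1**2 + 2.0 * a12 * r1 * phi + a22 * phi**2
        )
        # strict '<' with ascending thetas keeps the smallest theta on ties
        better = rss < best_rss
        best_rss[better] = rss[better]
        best[0, better] = r1[better]
        best[1, better] = phi[better]
        best[2, better] = th
    r1, phi, th = best
    valid = (th > 0) & np.any(Y != 0, axis=1)
    k2 = phi + r1 * th
    with np.errstate(divide="ignore", invalid="ignore"):
        bp = np.where(valid, k2 / np.where(th > 0, th, 1.0) - 1.0, 0.0)
    out = {"R1": r1, "k2": k2, "k2a": th, "BPND": bp, "valid": valid}
    if single:
        out = {k: v[0] for k, v in out.items()}
    return out


def logan_ref(tac, ref_tac: TAC, framing: Framing, settings: QuantSettings | None = None):
    """Reference Logan graphical analysis.

    OLS on the Logan transform for frames with mid-time >= t*; slope = DVR,
    ``BPND = DVR - 1``.  Without a k2' the reference-integral term drops the
    correction (simplified transform).
    """
    settings = settings or QuantSettings()
    Y, single = _as_matrix(tac.values if isinstance(tac, TAC) else tac)
    times = ref_tac.times
    sel = times >= settings.t_star_min
    if sel.sum() < 2:
        raise FitError("fewer than 2 frames after t*")
    ref = np.asarray(ref_tac.values, dtype=float)
    int_ref = _cumint(times, ref)
    int_y = _cumint(times, Y)

    num_ref = int_ref[None, :].repeat(Y.shape[0], axis=0)
    k2p = settings.k2_prime
    if isinstance(k2p, (int, float)) and k2p is not None:
        num_ref = num_ref + ref[None, :] / float(k2p)
    with np.errstate(divide="ignore", invalid="ignore"):
        X = num_ref[:, sel] / Y[:, sel]
        Z = int_y[:, sel] / Y[:, sel]
    valid = np.all(Y[:, sel] > 0, axis=1) & np.all(np.isfinite(X), axis=1)
    X = np.where(valid[:, None], X, 0.0)
    Z = np.where(valid[:, None], Z, 0.0)
    m = sel.sum()
    sx, sz = X.sum(axis=1), Z.sum(axis=1)
    sxx = (X * X).sum(axis=1)
    sxz = (X * Z).sum(axis=1)
    den = sxx - sx * sx / m
    valid &= den > 1e-300
    with np.errstate(divide="ignore", invalid="ignore"):
        dvr = np.where(valid, (sxz - sx * sz / m) / np.where(den > 0, den, 1.0), 1.0)
    bp = np.where(valid, dvr - 1.0, 0.0)
    out = {"DVR": dvr, "BPND": bp, "valid": valid}
    if single:
        out = {k: v[0] for k, v in out.items()}
    return out


def mrtm2(tac, ref_tac: TAC, framing: Framing, k2_prime: float,
          settings: QuantSettings | None = None):
    """Two-parameter multilinear reference tissue model with fixed k2'.

    ``CT(T) = b1*(int Cref + Cref/k2') + b2*int CT``;
    ``BPND = -(b1/b2) - 1``.
    """
    settings = settings or QuantSettings(t_star_min=0.0)
    if not k2_prime or k2_prime <= 0:
        raise FitError("k2_prime must be positive")
    Y, single = _as_matrix(tac.values if isinstance(tac, TAC) else tac)
    times = ref_tac.times
    sel = times >= settings.t_star_min
    if sel.sum() < 3:
        raise FitError("fewer than 3 frames after t*")
    ref = np.asarray(ref_tac.values, dtype=float)
    w = _frame_weights(framing, settings)[sel]
    x1 = (_cumint(times, ref) + ref / k2_prime)[sel]
    x2 = _cumint(times, Y)[:, sel]
    y = Y[:, sel]

    a11 = float(np.sum(w * x1 * x1))
    a12 = (x2 * (w * x1)).sum(axis=1)
    a22 = (w * x2 * x2).sum(axis=1)
    c1 = y @ (w * x1)
    c2 = (w * x2 * y).sum(axis=1)
    det = a11 * a22 - a12 * a12
    scale = np.maximum(a11 * a22, 1e-300)
    valid = det > 1e-12 * scale
    det_safe = np.where(valid, det, 1.0)
    b1 = (a22 * c1 - a12 * c2) / det_safe
    b2 = (a11 * c2 - a12 * c1) / det_safe
    valid &= np.abs(b2) > 1e-300
    with np.errstate(divide="ignore", invalid="ignore"):
        bp = np.where(valid, -(b1 / np.where(valid, b2, 1.0)) - 1.0, 0.0)
    out = {"b1": b1, "b2": b2, "BPND": bp, "valid": valid}
    if single:
        out = {k: v[0] for k, v in out.items()}
    return out


def mrtm(tac: TAC, ref_tac: TAC, framing: Framing,
         settings: QuantSettings | None = None):
    """Three-parameter multilinear reference tissue model (single TAC).

    ``CT(T) = b1*int Cref + b2*Cref(T) + b3*int CT``; ``k2' = b1/b2`` and
    ``DVR = -b1/b3``.  Raises :class:`FitError` on an ill-conditioned
    design (e.g. target kinetically identical to the reference).
    """
    settings = settings or QuantSettings(t_star_min=0.0)
    y = np.asarray(tac.values if isinstance(tac, TAC) else tac, dtype=float)
    times = ref_tac.times
    sel = times >= settings.t_star_min
    if sel.sum() < 4:
        raise FitError("fewer than 4 frames after t*")
    ref = np.asarray(ref_tac.values, dtype=float)
    X = np.column_stack([
        _cumint(times, ref)[sel], ref[sel], _cumint(times, y)[sel]
    ])
    w = np.sqrt(_frame_weights(framing, settings)[sel])
    Xw, yw = X * w[:, None], y[sel] * w
    # condition of the normalized design detects collinear regressors
    norms = np.linalg.norm(Xw, axis=0)
    if np.any(norms == 0):
        raise FitError("degenerate design (zero regressor)")
    cond = np.linalg.cond(Xw / norms)
    if cond > 1e8:
        raise FitError(f"ill-conditioned MRTM design (cond={cond:.2e}); "
                       "target may be kinetically identical to the reference")
    b, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    if b[1] == 0 or b[2] == 0:
        raise FitError("MRTM fit returned degenerate coefficients")
    return {"b": b, "k2_prime": b[0] / b[1], "DVR": -b[0] / b[2],
            "BPND": -b[0] / b[2] - 1.0}


def estimate_k2prime(high_binding_tac: TAC, ref_tac: TAC, framing: Framing,
                     settings: QuantSettings | None = None) -> float:
    """Reference efflux constant k2' from an MRTM fit of a high-binding TAC."""
    fit = mrtm(high_binding_tac, ref_tac, framing, settings)
    k2p = fit["k2_prime"]
    if not np.isfinite(k2p) or k2p <= 0:
        raise FitError(f"implausible k2' estimate: {k2p}")
    return float(k2p)


def default_brain_mask(dynimg: DynamicImage, ref_tac: TAC,
                       auc_fraction: float = 0.05) -> np.ndarray:
    """Voxels whose TAC area exceeds ``auc_fraction`` of the reference area."""
    times = dynimg.framing.mid_times_min
    auc = np.trapezoid(dynimg.data, times, axis=3)
    ref_auc = np.trapezoid(ref_tac.values, times)
    return auc > auc_fraction * ref_auc


def _auto_k2prime(dynimg, ref_tac, brain_mask, framing, settings) -> float:
    """k2' from the top-decile-AUC (high-binding) voxels' mean TAC."""
    times = framing.mid_times_min
    auc = np.trapezoid(dynimg.data, times, axis=3)
    vals = auc[brain_mask]
    thr = np.quantile(vals, 0.9)
    high = brain_mask & (auc >= thr)
    high_tac = TAC(times, dynimg.data[high].mean(axis=0))
    return estimate_k2prime(high_tac, ref_tac, framing,
                            replace(settings, t_star_min=0.0))


def parametric_map(
    dynimg: DynamicImage,
    reference_mask: np.ndarray,
    method: str = "srtm",
    settings: QuantSettings | None = None,
    brain_mask: np.ndarray | None = None,
) -> BPMap:
    """Voxelwise BP_ND map with the chosen method.

    Applies optional Gaussian pre-smoothing to every frame, derives the
    analysis mask (TAC-area rule) unless one is given, and runs the method
    over all mask voxels.  Per-voxel failures are flagged in the invalid
    mask and set to 0; they never abort the map.
    """
    settings = settings or QuantSettings()
    method = method.lower()
    if method not in ("srtm", "logan", "mrtm2"):
        raise ValueError(f"unknown method '{method}'")
    if not dynimg.decay_corrected:
        raise ValueError("quantification requires decay-corrected data")

    data = dynimg.data
    if settings.pre_smoothing_fwhm_mm > 0:
        sigma = settings.pre_smoothing_fwhm_mm * _FWHM_TO_SIGMA / dynimg.voxel_size_mm
        data = ndimage.gaussian_filter(
            np.asarray(data, dtype=float), sigma=(sigma, sigma, sigma, 0.0)
        )
        dynimg = DynamicImage(data, dynimg.framing, dynimg.voxel_size_mm, True)

    ref_tac = extract_reference_tac(dynimg, reference_mask)
    if brain_mask is None:
        brain_mask = default_brain_mask(dynimg, ref_tac,
                                        settings.brain_mask_auc_fraction)
    framing = dynimg.framing
    Y = data[brain_mask].astype(float)

    k2p = settings.k2_prime
    if k2p == "estimate":
        k2p = _auto_k2prime(dynimg, ref_tac, brain_mask, framing, settings)

    if method == "srtm":
        fit = srtm_basis(Y, ref_tac, framing, settings)
    elif method == "logan":
        fit = logan_ref(Y, ref_tac, framing,
                        replace(settings, k2_prime=k2p))
    else:
        if k2p is None:
            k2p = _auto_k2prime(dynimg, ref_tac, brain_mask, framing, settings)
        fit = mrtm2(Y, ref_tac, framing, k2p, settings)

    bp = np.zeros(dynimg.shape[:3])
    bad = np.zeros(dynimg.shape[:3], dtype=bool)
    vox_bp = np.where(fit["valid"] & np.isfinite(fit["BPND"]), fit["BPND"], 0.0)
    bp[brain_mask] = vox_bp
    bad[brain_mask] = ~(fit["valid"] & np.isfinite(fit["BPND"]))
    recorded = {
        "pre_smoothing_fwhm_mm": settings.pre_smoothing_fwhm_mm,
        "t_star_min": settings.t_star_min,
        "k2_prime": None if k2p is None else float(k2p),
        "weighting": settings.weighting,
        "n_basis": settings.n_basis,
        "basis_range": tuple(settings.basis_range),
    }
    return BPMap(data=bp, method=method, settings=recorded,
                 brain_mask=brain_mask, invalid_mask=bad)
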