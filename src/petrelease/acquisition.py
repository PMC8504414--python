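"""Framed dynamic emission synthesis and noisy tomographic acquisition.

The scanner is a stacked-2D parallel-beam ring: each axial slice is
projected independently over ``n_angles`` view angles and ``n_radial``
radial bins.  Line integrals are exact (Siddon ray tracing through the
pixel grid, segment lengths in mm) and assembled once per geometry into a
sparse matrix, so the forward projector and its adjoint (back-projector)
form an exactly matched pair.

The acquisition chain mirrors a clinical brain protocol: the image is
blurred with the scanner resolution kernel, projected, attenuated by
``exp(-int mu dl)``, scaled to the prescribed total count budget, and
prompts are drawn Poisson per bin with additive randoms (uniform) and
scatter (broad radial blur of the attenuated trues) contributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, sparse

__all__ = [
    "Framing",
    "DynamicImage",
    "ScannerModel",
    "SinogramSet",
    "make_framing",
    "synthesize_dynamic",
    "forward_project",
    "back_project",
    "attenuation_factors",
    "simulate_counts",
    "CARBON11_HALF_LIFE_MIN",
    "MU_WATER_MM",
]

#: physical half-life of carbon-11 (minutes)
CARBON11_HALF_LIFE_MIN = 20.34
#: 511 keV linear attenuation coefficient of water (mm^-1)
MU_WATER_MM = 0.0096

_FWHM_TO_SIGMA = 1.0 / 2.3548200450309493


class ParameterError(ValueError):
    pass


@dataclass(frozen=True)
class Framing:
    """Contiguous acquisition frames; times in seconds post-injection."""

    starts_s: np.ndarray
    durations_s: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.starts_s, dtype=float)
        d = np.asarray(self.durations_s, dtype=float)
        if s.shape != d.shape:
            raise ValueError("starts and durations must match")
        if np.any(d <= 0):
            raise ValueError("durations must be positive")
        if s.size and (s[0] != 0 or not np.allclose(s[1:], (s + d)[:-1])):
            raise ValueError("frames must be contiguous from 0")
        object.__setattr__(self, "starts_s", s)
        object.__setattr__(self, "durations_s", d)

    @property
    def n_frames(self) -> int:
        return self.starts_s.size

    @property
    def ends_s(self) -> np.ndarray:
        return self.starts_s + self.durations_s

    @property
    def total_duration_s(self) -> float:
        return float(self.ends_s[-1]) if self.n_frames else 0.0

    @property
    def mid_times_min(self) -> np.ndarray:
        return (self.starts_s + self.durations_s / 2.0) / 60.0


def make_framing(scheme) -> Framing:
    """Expand a ``[(count, duration_s), ...]`` scheme into contiguous frames.

    The default challenge scheme ``[(4, 15), (4, 60), (2, 150), (10, 300),
    (3, 600)]`` yields 23 frames spanning 90 minutes.
    """
    durations = []
    for count, dur in scheme:
        if count <= 0 or dur <= 0:
            raise ValueError("counts and durations must be positive")
        durations.extend([float(dur)] * int(count))
    d = np.asarray(durations)
    starts = np.concatenate([[0.0], np.cumsum(d)[:-1]]) if d.size else np.empty(0)
    return Framing(starts, d)


DEFAULT_FRAMING_SCHEME = ((4, 15), (4, 60), (2, 150), (10, 300), (3, 600))


@dataclass
class DynamicImage:
    """4D activity-concentration volume (x, y, z, frame) in kBq/mL."""

    data: np.ndarray
    framing: Framing
    voxel_size_mm: float
    decay_corrected: bool = False

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ValueError("data must be 4D (x, y, z, frame)")
        if self.data.shape[3] != self.framing.n_frames:
            raise ValueError("frame count mismatch between data and framing")

    @property
    def shape(self) -> tuple:
        return self.data.shape


def synthesize_dynamic(
    pmap,
    plasma,
    framing: Framing,
    half_life_min: float = CARBON11_HALF_LIFE_MIN,
    grid_dt_s: float = 1.0,
    chunk: int = 4096,
) -> DynamicImage:
    """Noise-free framed 4D phantom from a micro-parameter map.

    Every brain voxel's TAC is evaluated on a fine grid (default 1 s) with
    the closed-form 2TCM, multiplied by the physical decay factor
    ``exp(-ln2 t / T_half)``, and averaged within each frame.  The result is
    *not* decay corrected (``decay_corrected=False``), as measured by a
    scanner.
    """
    from petrelease.kinetics import _tissue_response_tm

    if half_life_min is not None and half_life_min <= 0:
        raise ParameterError("half_life_min must be positive (or None/inf)")
    total_min = framing.total_duration_s / 60.0
    if plasma.end_time + 1e-9 < total_min:
        raise ParameterError("plasma input does not cover the framing")
    dt_min = grid_dt_s / 60.0
    t = np.arange(0.0, total_min + dt_min / 2, dt_min)
    cp = plasma.plasma_at(t)
    cb = plasma.blood_at(t)
    if half_life_min is None or np.isinf(half_life_min):
        decay = np.ones_like(t)
    else:
        decay = np.exp(-np.log(2.0) / half_life_min * t)

    # frame-averaging weights: mean of fine-grid samples within each frame
    edges = np.round(framing.starts_s / grid_dt_s).astype(int)
    ends = np.round(framing.ends_s / grid_dt_s).astype(int)
    brain_idx = np.flatnonzero(pmap.brain_mask.ravel())
    K1 = pmap.K1.ravel()[brain_idx]
    k2 = pmap.k2.ravel()[brain_idx]
    k3 = pmap.k3.ravel()[brain_idx]
    k4 = pmap.k4.ravel()[brain_idx]
    vb = pmap.VB.ravel()[brain_idx]

    nf = framing.n_frames
    out = np.zeros(pmap.shape + (nf,), dtype=np.float32)
    flat = out.reshape(-1, nf)
    for lo in range(0, brain_idx.size, chunk):
        hi = min(lo + chunk, brain_idx.size)
        # C_PET = [(1-VB)*(C1+C2) + VB*C_blood] * decay, built in place
        ct = _tissue_response_tm(K1[lo:hi], k2[lo:hi], k3[lo:hi], k4[lo:hi], t, cp)
        ct *= (1.0 - vb[lo:hi])[None, :]
        ct += vb[lo:hi][None, :] * cb[:, None]
        ct *= decay[:, None]
        for f in range(nf):
            a, b = edges[f], ends[f]
            flat[brain_idx[lo:hi], f] = ct[a:b + 1].mean(axis=0)
    return DynamicImage(out, framing, pmap.voxel_size_mm, decay_corrected=False)


# ---------------------------------------------------------------------------
# parallel-beam projector (Siddon ray tracing, cached sparse matrix)


@dataclass(frozen=True)
class ScannerModel:
    """Desk-scale stacked-2D ring scanner.

    ``n_angles`` views over 180 degrees, ``n_radial`` bins spanning the
    transaxial field of view; ``psf_fwhm_mm`` is the image-domain
    resolution kernel applied before projection (and inside the MLEM
    projector pair).
    """

    n_angles: int
    n_radial: int
    voxel_size_mm: float
    image_shape_xy: tuple
    psf_fwhm_mm: float = 2.5

    def __post_init__(self) -> None:
        if self.psf_fwhm_mm < 0:
            raise ParameterError("PSF FWHM must be >= 0")
        nx, ny = self.image_shape_xy
        if self.fov_mm < self.voxel_size_mm * float(np.hypot(nx, ny)):
            raise ParameterError("radial bins do not cover the image diagonal")

    @property
    def fov_mm(self) -> float:
        return self.n_radial * self.voxel_size_mm * 1.0

    @property
    def radial_offsets_mm(self) -> np.ndarray:
        """Signed distance of each radial bin's ray from the image centre."""
        return (np.arange(self.n_radial) - self.n_radial / 2.0 + 0.5) * self.voxel_size_mm

    @classmethod
    def for_image(cls, shape, voxel_size_mm, n_angles=None, psf_fwhm_mm=2.5):
        nx, ny = shape[0], shape[1]
        # even bin count + half-bin shift => rays through pixel centres for
        # the usual even image sizes
        n_radial = int(np.ceil(np.hypot(nx, ny))) + 3
        n_radial += n_radial % 2
        return cls(
            n_angles=int(n_angles or max(nx, 32)),
            n_radial=n_radial,
            voxel_size_mm=float(voxel_size_mm),
            image_shape_xy=(nx, ny),
            psf_fwhm_mm=float(psf_fwhm_mm),
        )


_MATRIX_CACHE: dict = {}


def _siddon_matrix(scanner: ScannerModel) -> sparse.csr_matrix:
    """Sparse system matrix: rows (angle, radial bin), cols (x, y) pixels.

    Entries are exact ray/pixel intersection lengths in mm for the central
    ray of each bin.
    """
    key = (scanner.n_angles, scanner.n_radial, scanner.voxel_size_mm,
           scanner.image_shape_xy)
    if key in _MATRIX_CACHE:
        return _MATRIX_CACHE[key]
    nx, ny = scanner.image_shape_xy
    v = scanner.voxel_size_mm
    # image occupies [0, nx*v] x [0, ny*v]; rays parametrised p = o + t*dir
    cx, cy = nx * v / 2.0, ny * v / 2.0
    # half-bin shift keeps axis-aligned rays off the pixel boundaries
    offsets = (np.arange(scanner.n_radial) - scanner.n_radial / 2.0 + 0.5) * v
    angles = np.arange(scanner.n_angles) * np.pi / scanner.n_angles
    half_diag = np.hypot(nx, ny) * v / 2.0 + v

    rows, cols, vals = [], [], []
    xplanes = np.arange(nx + 1) * v
    yplanes = np.arange(ny + 1) * v
    for ia, ang in enumerate(angles):
        d = np.array([np.cos(ang), np.sin(ang)])
        nrm = np.array([-np.sin(ang), np.cos(ang)])
        for ir, off in enumerate(offsets):
            o = np.array([cx, cy]) + off * nrm - half_diag * d
            alphas = [np.array([0.0, 2.0 * half_diag])]
            if abs(d[0]) > 1e-12:
                alphas.append((xplanes - o[0]) / d[0])
            if abs(d[1]) > 1e-12:
                alphas.append((yplanes - o[1]) / d[1])
            a = np.unique(np.concatenate(alphas))
            a = a[(a >= 0.0) & (a <= 2.0 * half_diag)]
            if a.size < 2:
                continue
            mid = (a[:-1] + a[1:]) / 2.0
            seg = np.diff(a)
            px = o[0] + mid * d[0]
            py = o[1] + mid * d[1]
            ix = np.floor(px / v).astype(int)
            iy = np.floor(py / v).astype(int)
            ok = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny) & (seg > 1e-12)
            if not ok.any():
                continue
            row = ia * scanner.n_radial + ir
            rows.append(np.full(ok.sum(), row))
            cols.append(ix[ok] * ny + iy[ok])
            vals.append(seg[ok])
    A = sparse.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(scanner.n_angles * scanner.n_radial, nx * ny),
    )
    _MATRIX_CACHE[key] = A
    return A


def _smooth3d(image: np.ndarray, fwhm_mm: float, voxel_mm: float) -> np.ndarray:
    if fwhm_mm <= 0:
        return image
    return ndimage.gaussian_filter(image, fwhm_mm * _FWHM_TO_SIGMA / voxel_mm)


def forward_project(
    image_3d: np.ndarray, scanner: ScannerModel, smoothing_fwhm_mm: float | None = None
) -> np.ndarray:
    """Line integrals of a 3D image: sinogram (n_angles, n_radial, nz).

    The image is first blurred with the scanner resolution kernel (default
    the scanner's ``psf_fwhm_mm``); pass 0 to project the raw image.
    """
    fwhm = scanner.psf_fwhm_mm if smoothing_fwhm_mm is None else smoothing_fwhm_mm
    img = _smooth3d(np.asarray(image_3d, dtype=float), fwhm, scanner.voxel_size_mm)
    nx, ny, nz = img.shape
    A = _siddon_matrix(scanner)
    sino = A @ img.reshape(nx * ny, nz)
    return sino.reshape(scanner.n_angles, scanner.n_radial, nz)


def back_project(
    sino: np.ndarray, scanner: ScannerModel, smoothing_fwhm_mm: float | None = None
) -> np.ndarray:
    """Adjoint of :func:`forward_project` (including the symmetric PSF)."""
    A = _siddon_matrix(scanner)
    nx, ny = scanner.image_shape_xy
    nz = sino.shape[2]
    img = (A.T @ sino.reshape(-1, nz)).reshape(nx, ny, nz)
    fwhm = scanner.psf_fwhm_mm if smoothing_fwhm_mm is None else smoothing_fwhm_mm
    return _smooth3d(img, fwhm, scanner.voxel_size_mm)


def attenuation_factors(mu_map: np.ndarray, scanner: ScannerModel) -> np.ndarray:
    """Per-bin survival probabilities ``exp(-int mu dl)``, in (0, 1].

    ``mu_map`` is the linear attenuation coefficient in mm^-1 on the image
    grid (no resolution blurring is applied to mu).
    """
    line = forward_project(mu_map, scanner, smoothing_fwhm_mm=0.0)
    return np.exp(-line)


def water_mu_map(head_mask: np.ndarray, mu: float = MU_WATER_MM) -> np.ndarray:
    """Synthetic water-equivalent attenuation map over a head mask."""
    return np.where(head_mask, mu, 0.0)


@dataclass
class SinogramSet:
    """Per-frame prompts plus the expectation terms of the forward model."""

    prompts: np.ndarray        # (nf, n_angles, n_radial, nz) integer counts
    trues: np.ndarray          # expectation of unscattered true counts
    randoms: np.ndarray        # expectation of random coincidences
    scatter: np.ndarray        # expectation of scattered counts
    attenuation: np.ndarray    # (n_angles, n_radial, nz) survival factors
    count_scale: float         # counts per (kBq/mL * mm * s) calibration
    framing: Framing
    meta: dict = field(default_factory=dict)


def simulate_counts(
    trues_line_integrals: np.ndarray,
    framing: Framing,
    scanner: ScannerModel,
    total_counts: float,
    randoms_fraction: float = 0.20,
    scatter_fraction: float = 0.25,
    mu_map: np.ndarray | None = None,
    scatter_fwhm_mm: float = 40.0,
    seed: int = 0,
) -> SinogramSet:
    """Poisson acquisition with attenuation, randoms and scatter.

    ``trues_line_integrals`` is the (nf, n_angles, n_radial, nz) stack of
    noise-free line integrals (kBq/mL * mm).  Expected unscattered trues are
    attenuated, weighted by frame duration and globally scaled so that the
    whole-scan expectation splits ``total_counts`` into
    ``(1 - randoms_fraction - scatter_fraction)`` trues, a spatially uniform
    randoms background (allocated across frames by duration) and a scatter
    term modelled as a broad radial blur of the attenuated trues.  Prompts
    are drawn Poisson per bin per frame with deterministically spawned
    per-frame seeds.
    """
    fr, fs = float(randoms_fraction), float(scatter_fraction)
    if fr < 0 or fs < 0 or fr + fs >= 1.0:
        raise ParameterError("fractions must be >= 0 and sum to < 1")
    if total_counts < 0:
        raise ParameterError("total_counts must be >= 0")
    y = np.asarray(trues_line_integrals, dtype=float)
    if y.ndim != 4 or y.shape[0] != framing.n_frames:
        raise ParameterError("expected per-frame sinograms (nf, na, nr, nz)")

    attn = (
        attenuation_factors(mu_map, scanner)
        if mu_map is not None
        else np.ones(y.shape[1:])
    )
    trues_w = y * attn[None] * framing.durations_s[:, None, None, None]
    tsum = trues_w.sum()
    scale = (1.0 - fr - fs) * total_counts / tsum if tsum > 0 else 0.0
    trues_exp = scale * trues_w

    nbins = y[0].size
    randoms_exp = np.broadcast_to(
        (fr * total_counts * framing.durations_s / framing.total_duration_s / nbins)[
            :, None, None, None
        ],
        y.shape,
    ).copy()

    sigma_bins = scatter_fwhm_mm * _FWHM_TO_SIGMA / scanner.voxel_size_mm
    scatter_exp = ndimage.gaussian_filter1d(trues_exp, sigma_bins, axis=2)
    ssum = scatter_exp.sum()
    if ssum > 0:
        scatter_exp *= fs * total_counts / ssum
    else:
        scatter_exp = np.zeros_like(trues_exp)

    expectation = trues_exp + randoms_exp + scatter_exp
    seeds = np.random.SeedSequence(seed).spawn(framing.n_frames)
    prompts = np.empty_like(expectation)
    for f in range(framing.n_frames):
        rng = np.random.default_rng(seeds[f])
        prompts[f] = rng.poisson(expectation[f])
    return SinogramSet(
        prompts=prompts,
        trues=trues_exp,
        randoms=randoms_exp,
        scatter=scatter_exp,
        attenuation=attn,
        count_scale=scale,
        framing=framing,
        meta={
            "seed": seed,
            "total_counts": total_counts,
            "randoms_fraction": fr,
            "scatter_fraction": fs,
            "scatter_fwhm_mm": scatter_fwhm_mm,
        },
    )
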