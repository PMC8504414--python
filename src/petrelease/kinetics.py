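"""Forward compartmental models for reversible PET tracers.

All times are minutes, all rate constants min^-1, activity concentrations
kBq/mL.  The reversible two-tissue compartment model (2TCM) describes the
tissue tracer concentration as two coupled first-order compartments driven
by the arterial plasma concentration Cp(t)::

    dC1/dt = K1*Cp - (k2 + k3)*C1 + k4*C2
    dC2/dt = k3*C1 - k4*C2

and the measured PET signal as

    C_PET(t) = (1 - VB) * (C1(t) + C2(t)) + VB * C_blood(t).

The model has the closed-form solution

    C1 + C2 = K1/(th2-th1) * [(k3+k4-th1) e^{-th1 t}
                              + (th2-k3-k4) e^{-th2 t}] (x) Cp

with th1,2 the eigenvalues of the 2x2 rate matrix and ``(x)`` temporal
convolution.  Convolution with the tabulated input is evaluated exactly for
a piecewise-linear input (no FFT, no grid aliasing); the repeated-eigenvalue
degenerate case switches to the limiting ``t e^{-th t}`` kernel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MicroParams",
    "MacroParams",
    "PlasmaInput",
    "TAC",
    "simulate_2tcm",
    "simulate_1tcm",
    "macro_from_micro",
    "synthetic_plasma_input",
]

#: eigenvalue gap (min^-1) below which the repeated-eigenvalue formula is used
_DEGENERATE_GAP = 1e-10


class ParameterError(ValueError):
    """Invalid kinetic parameters."""


class DomainError(ValueError):
    """Requested times fall outside the support of the input function."""


@dataclass(frozen=True)
class MicroParams:
    """Micro-parameters of the reversible 2TCM.

    Attributes
    ----------
    K1 : plasma-to-tissue transfer constant (mL cm^-3 min^-1)
    k2 : tissue-to-plasma efflux rate (min^-1)
    k3 : binding rate (min^-1)
    k4 : dissociation rate (min^-1)
    VB : fractional blood volume (unitless, 0..1)
    """

    K1: float
    k2: float
    k3: float = 0.0
    k4: float = 0.0
    VB: float = 0.0

    def __post_init__(self) -> None:
        for name in ("K1", "k2", "k3", "k4", "VB"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.VB > 1:
            raise ParameterError(f"VB must be <= 1, got {self.VB}")
        if self.k3 > 0 and self.k4 == 0:
            raise ParameterError("k4 must be > 0 when k3 > 0 (BP_ND undefined)")


@dataclass(frozen=True)
class MacroParams:
    """Macro-parameters derived from the micro rate constants."""

    VND: float
    VT: float
    BPND: float
    DVR: float


@dataclass(frozen=True)
class TAC:
    """A time-activity curve: concentrations sampled at given times (min)."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.shape != v.shape:
            raise ValueError("times and values must have the same length")
        if not np.all(np.isfinite(v)):
            raise ValueError("TAC values must be finite")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class PlasmaInput:
    """Tabulated arterial input function.

    ``concentration`` drives the tissue compartments; the whole-blood curve
    enters only through the fractional-blood-volume term.  Times are minutes
    from injection, strictly increasing and starting at 0 with a zero
    concentration (no tracer before injection).
    """

    sample_times: np.ndarray
    concentration: np.ndarray
    whole_blood_concentration: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.sample_times, dtype=float)
        c = np.asarray(self.concentration, dtype=float)
        if t.ndim != 1 or t.size < 2:
            raise ValueError("need at least two samples")
        if t[0] != 0:
            raise ValueError("sample_times must start at 0")
        if np.any(np.diff(t) <= 0):
            raise ValueError("sample_times must be strictly increasing")
        if c.shape != t.shape:
            raise ValueError("concentration length mismatch")
        if np.any(c < 0):
            raise ValueError("concentrations must be >= 0")
        if c[0] != 0:
            raise ValueError("concentration at t=0 must be 0")
        wb = self.whole_blood_concentration
        wb = c if wb is None else np.asarray(wb, dtype=float)
        if wb.shape != t.shape:
            raise ValueError("whole_blood_concentration length mismatch")
        object.__setattr__(self, "sample_times", t)
        object.__setattr__(self, "concentration", c)
        object.__setattr__(self, "whole_blood_concentration", wb)

    @property
    def end_time(self) -> float:
        return float(self.sample_times[-1])

    def plasma_at(self, times: np.ndarray) -> np.ndarray:
        return np.interp(times, self.sample_times, self.concentration)

    def blood_at(self, times: np.ndarray) -> np.ndarray:
        return np.interp(times, self.sample_times, self.whole_blood_concentration)

    def to_text(self, path) -> None:
        """Write as 2-column delimited text (time_min, kBq_per_mL)."""
        np.savetxt(
            path,
            np.column_stack([self.sample_times, self.concentration]),
            header="time_min kBq_per_mL",
        )

    @classmethod
    def from_text(cls, path) -> "PlasmaInput":
        arr = np.loadtxt(path)
        return cls(arr[:, 0], arr[:, 1])


# ---------------------------------------------------------------------------
# exact convolution with a piecewise-linear input


def _exp_seg_coeffs(theta: np.ndarray, dt: float):
    """Per-segment update coefficients for y' = -theta*y + f, f linear.

    Returns (E, c0, c1) with y(t+dt) = E*y(t) + c0*f(t) + c1*f(t+dt), the
    exact integral of e^{-theta(dt-u)} against the linear interpolant of f.
    Supports complex theta (used for complex-step differentiation).
    """
    theta = np.asarray(theta)
    a = theta * dt
    E = np.exp(-a)
    small = np.abs(a) < 1e-6
    with np.errstate(divide="ignore", invalid="ignore"):
        one_m_E = -np.expm1(-a)
        g1 = one_m_E / theta          # int e^{-theta(dt-u)} du
        c1 = (a - one_m_E) / (theta**2 * dt)
        c0 = g1 - c1
    # series expansion keeps theta -> 0 (pure integrator) exact
    c0 = np.where(small, dt * (0.5 - a / 3.0 + a**2 / 8.0), c0)
    c1 = np.where(small, dt * (0.5 - a / 6.0 + a**2 / 24.0), c1)
    return E, c0, c1


def expconv(theta: np.ndarray, times: np.ndarray, f: np.ndarray) -> np.ndarray:
    """Convolve ``f`` (piecewise linear on ``times``) with ``e^{-theta t}``.

    Parameters
    ----------
    theta : array of decay rates, shape (m,) or scalar
    times : sample times (min), shape (n,), increasing
    f : input samples, shape (n,)

    Returns
    -------
    array of shape (m, n) (or (n,) for scalar theta) with
    ``y(t_i) = int_0^{t_i} e^{-theta (t_i - s)} f(s) ds``.
    """
    scalar = np.isscalar(theta) or np.ndim(theta) == 0
    y = _expconv_tm(theta, times, f)
    out = np.ascontiguousarray(y.T)
    return out[0] if scalar else out


def _expconv_tm(theta, times, f) -> np.ndarray:
    """Time-major workhorse of :func:`expconv`: returns shape (n, m).

    The recursion advances one contiguous row per time step, which is what
    makes voxel-batched synthesis affordable.
    """
    th = np.atleast_1d(np.asarray(theta))
    t = np.asarray(times, dtype=float)
    fv = np.asarray(f)
    n = t.size
    y = np.zeros((n, th.size), dtype=np.result_type(th.dtype, fv.dtype, float))
    dts = np.diff(t)
    uniform = dts.size > 0 and np.allclose(dts, dts[0], rtol=1e-9, atol=0)
    if uniform:
        E, c0, c1 = _exp_seg_coeffs(th, float(dts[0]))
        for i in range(n - 1):
            np.multiply(y[i], E, out=y[i + 1])
            y[i + 1] += c0 * fv[i]
            y[i + 1] += c1 * fv[i + 1]
    else:
        for i in range(n - 1):
            E, c0, c1 = _exp_seg_coeffs(th, float(dts[i]))
            np.multiply(y[i], E, out=y[i + 1])
            y[i + 1] += c0 * fv[i]
            y[i + 1] += c1 * fv[i + 1]
    return y


def expconv_t(theta: np.ndarray, times: np.ndarray, f: np.ndarray) -> np.ndarray:
    """Convolve ``f`` with ``t e^{-theta t}`` (repeated-eigenvalue kernel).

    Computed by complex-step differentiation of :func:`expconv` with respect
    to theta (the kernel is ``-d/dtheta e^{-theta t}``), exact to machine
    precision.
    """
    h = 1e-150
    th = np.atleast_1d(np.asarray(theta, dtype=float)).astype(complex) + 1j * h
    y = expconv(th, times, np.asarray(f, dtype=float))
    out = -y.imag / h
    return out[0] if (np.isscalar(theta) or np.ndim(theta) == 0) else out


def _tissue_response_tm(K1, k2, k3, k4, times, cp):
    """Time-major extra-vascular tissue concentration, shape (ntimes, nvox)."""
    K1 = np.atleast_1d(np.asarray(K1, dtype=float))
    k2 = np.atleast_1d(np.asarray(k2, dtype=float))
    k3 = np.atleast_1d(np.asarray(k3, dtype=float))
    k4 = np.atleast_1d(np.asarray(k4, dtype=float))
    s = k2 + k3 + k4
    disc = np.sqrt(np.maximum(s**2 - 4.0 * k2 * k4, 0.0))
    th1 = 0.5 * (s - disc)
    th2 = 0.5 * (s + disc)
    gap = th2 - th1
    out = np.zeros((np.asarray(times).size, K1.size))
    deg = gap < _DEGENERATE_GAP
    reg = ~deg
    if np.any(reg):
        y1 = _expconv_tm(th1[reg], times, cp)
        y2 = _expconv_tm(th2[reg], times, cp)
        g = gap[reg]
        y1 *= (K1[reg] * (k3[reg] + k4[reg] - th1[reg]) / g)[None, :]
        y2 *= (K1[reg] * (th2[reg] - k3[reg] - k4[reg]) / g)[None, :]
        y1 += y2
        out[:, reg] = y1
    if np.any(deg):
        # limiting formula: CT = K1 [e^{-th t} + (k3+k4-th) t e^{-th t}] (x) Cp
        th = th1[deg]
        y = _expconv_tm(th, times, cp)
        yt = expconv_t(th, times, cp).T
        y += (k3[deg] + k4[deg] - th)[None, :] * yt
        y *= K1[deg][None, :]
        out[:, deg] = y
    return out


def _tissue_response_batch(K1, k2, k3, k4, times, cp):
    """Extra-vascular tissue concentration C1+C2 for arrays of parameters.

    Parameters are broadcast 1-D arrays (one entry per voxel); returns an
    array of shape (nvox, ntimes).
    """
    return np.ascontiguousarray(_tissue_response_tm(K1, k2, k3, k4, times, cp).T)


def _check_times(times: np.ndarray, input: PlasmaInput) -> np.ndarray:
    t = np.asarray(times, dtype=float)
    if t.min() < 0 or t.max() > input.end_time + 1e-9:
        raise DomainError(
            f"times [{t.min()}, {t.max()}] outside input support [0, {input.end_time}]"
        )
    return t


def simulate_2tcm(params: MicroParams, input: PlasmaInput, times) -> TAC:
    """Noise-free 2TCM time-activity curve at the requested times.

    The tissue response is the exact bi-exponential convolution of the
    piecewise-linear input; the blood-volume term adds
    ``VB * C_blood(t)``.
    """
    t = _check_times(times, input)
    # convolve on the union of the input's native grid and the requested
    # times: exact for the piecewise-linear input, regardless of how
    # coarsely the output is sampled
    support = input.sample_times
    grid = np.union1d(support[support <= t.max() + 1e-12], t)
    cp = input.plasma_at(grid)
    ct = _tissue_response_batch(params.K1, params.k2, params.k3, params.k4, grid, cp)[0]
    idx = np.searchsorted(grid, t)
    values = (1.0 - params.VB) * ct[idx] + params.VB * input.blood_at(t)
    return TAC(t, values)


def simulate_1tcm(params: MicroParams, input: PlasmaInput, times) -> TAC:
    """One-tissue model TAC; requires k3 = k4 = 0."""
    if params.k3 != 0 or params.k4 != 0:
        raise ParameterError("simulate_1tcm requires k3 = k4 = 0")
    return simulate_2tcm(params, input, times)


def macro_from_micro(params: MicroParams) -> MacroParams:
    """Macro-parameters (VND, VT, BPND, DVR) from the rate constants."""
    if params.k2 == 0:
        raise ParameterError("VND undefined for k2 = 0")
    vnd = params.K1 / params.k2
    if params.k3 == 0:
        bp = 0.0
    elif params.k4 == 0:
        raise ParameterError("BPND undefined for k4 = 0 with k3 > 0")
    else:
        bp = params.k3 / params.k4
    return MacroParams(VND=vnd, VT=vnd * (1.0 + bp), BPND=bp, DVR=1.0 + bp)


@dataclass(frozen=True)
class InputSpec:
    """Parameters of the analytic plasma input (linear rise, tri-exponential).

    ``Cp(t) = [A1 (t-t0) - A2 - A3] e^{-l1 (t-t0)} + A2 e^{-l2 (t-t0)}
    + A3 e^{-l3 (t-t0)}`` for t >= t0, else 0.  The default parameters give
    a sharp bolus peaking ~1 min post-injection followed by a slow
    bi-exponential washout, a kinetically plausible 90-min input for a
    carbon-11 ligand.  Units: A1 kBq mL^-1 min^-1, A2/A3 kBq mL^-1,
    l1..l3 min^-1, t0 min.
    """

    A1: float = 850.0
    A2: float = 21.0
    A3: float = 20.0
    l1: float = 4.1
    l2: float = 0.12
    l3: float = 0.01
    t0: float = 0.5

    def __post_init__(self) -> None:
        if self.A1 <= 0 or self.A2 < 0 or self.A3 < 0:
            raise ParameterError("amplitudes must be positive")
        if min(self.l1, self.l2, self.l3) <= 0 or self.t0 < 0:
            raise ParameterError("rates and delay must be positive")


def synthetic_plasma_input(
    spec: InputSpec | None = None,
    duration_min: float = 90.0,
    dt_s: float = 1.0,
) -> PlasmaInput:
    """Analytic plasma input sampled on a fine grid (default 1 s).

    Whole blood is taken equal to plasma: the toolkit targets reference-
    tissue quantification, where the input never enters the analysis, so no
    metabolite or plasma-to-blood model is layered on top.
    """
    spec = spec or InputSpec()
    if duration_min <= 0 or dt_s <= 0:
        raise DomainError("duration and grid step must be positive")
    t = np.arange(0.0, duration_min + dt_s / 60.0 / 2, dt_s / 60.0)
    tau = t - spec.t0
    rising = (spec.A1 * tau - spec.A2 - spec.A3) * np.exp(-spec.l1 * tau)
    tail = spec.A2 * np.exp(-spec.l2 * tau) + spec.A3 * np.exp(-spec.l3 * tau)
    c = np.where(tau > 0, rising + tail, 0.0)
    c = np.maximum(c, 0.0)
    return PlasmaInput(t, c)
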