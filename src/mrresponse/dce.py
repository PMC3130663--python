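"""Tofts pharmacokinetic modelling of DCE-MRI with a biexponential
vascular input function (VIF).

The one-compartment Tofts model describes the tissue contrast-agent
concentration as the convolution of the plasma concentration C_p with an
exponential impulse response:

    C_t(t) = Ktrans * int_0^t C_p(tau) * exp(-k_ep (t - tau)) dtau,
    k_ep   = Ktrans / v_e,

where Ktrans (1/s) is the plasma-to-interstitium volume transfer constant and
v_e the extravascular extracellular volume fraction.  With a biexponential
VIF, C_p(t) = A1 exp(-m1 t) + A2 exp(-m2 t), the convolution has the closed
form

    C_t(t) = Ktrans * sum_i A_i (exp(-m_i t) - exp(-k_ep t)) / (k_ep - m_i),

with the L'Hopital limit ``A_i * Ktrans * t * exp(-m_i t)`` when k_ep == m_i.

Default VIF amplitudes/decays (3.57 mM @ 0.025 1/s plus 1.45 mM @ 0.0074 1/s)
describe a mouse tail-vein Gd-DTPA bolus idealized as instantaneous at t = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

#: |k_ep - m_i| below this (1/s) switches to the degenerate-exponent limit.
DEGENERATE_TOL = 1e-9

#: Bounds of the voxel fit: Ktrans in [0, 0.1] 1/s, v_e in (1e-3, 1].
KTRANS_BOUNDS = (0.0, 0.1)
VE_BOUNDS = (1e-3, 1.0)

#: Coarse multi-start grid for the voxel fit.
KTRANS_STARTS = (1e-4, 1e-3, 5e-3, 1e-2)
VE_STARTS = (0.1, 0.3, 0.6)


@dataclass
class VIFParams:
    """Biexponential vascular input function: amplitudes in mM, decays in 1/s."""

    a1: float = 3.57
    m1: float = 0.025
    a2: float = 1.45
    m2: float = 0.0074

    def __post_init__(self) -> None:
        if self.a1 < 0 or self.a2 < 0:
            raise ValueError("VIF amplitudes must be non-negative")
        if self.m1 <= 0 or self.m2 <= 0:
            raise ValueError("VIF decay rates must be positive")


@dataclass
class ToftsParams:
    """Kinetic parameters: ktrans (1/s), ve (fraction); kep = ktrans/ve."""

    ktrans: float
    ve: float

    def __post_init__(self) -> None:
        if self.ktrans < 0:
            raise ValueError("ktrans must be non-negative")
        if not 0 < self.ve <= 1:
            raise ValueError("ve must lie in (0, 1]")

    @property
    def kep(self) -> float:
        return self.ktrans / self.ve


@dataclass
class ConcentrationSeries:
    """Tissue contrast-agent concentration (mM) on an ascending time grid (s)."""

    times: np.ndarray
    conc: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.conc = np.asarray(self.conc, dtype=float)
        if self.times.size == 0:
            raise ValueError("empty time grid")
        if self.times.size != self.conc.size:
            raise ValueError("times and conc length mismatch")
        if self.times[0] < 0 or np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly ascending and start at >= 0")


@dataclass
class SignalSeries:
    """Dynamic T1-weighted signal with ``n_pre`` pre-contrast frames."""

    times: np.ndarray
    signal: np.ndarray
    n_pre: int = 5

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.n_pre < 1:
            raise ValueError("need at least one pre-contrast frame")
        if self.times.size != self.signal.size:
            raise ValueError("times and signal length mismatch")
        if self.times.size <= self.n_pre:
            raise ValueError("no post-contrast frames")


@dataclass
class FitResult:
    """Outcome of a single-voxel Tofts fit."""

    params: ToftsParams
    rss: float
    converged: bool
    n_iter: int = 0

    def __post_init__(self) -> None:
        if self.rss < 0:
            raise ValueError("rss must be non-negative")


def vif_concentration(t, vif: VIFParams = VIFParams()) -> np.ndarray:
    """Plasma concentration C_p(t) = A1 exp(-m1 t) + A2 exp(-m2 t), in mM."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("negative time")
    return vif.a1 * np.exp(-vif.m1 * t) + vif.a2 * np.exp(-vif.m2 * t)


def _closed_form(ktrans: float, kep: float, vif: VIFParams, t: np.ndarray) -> np.ndarray:
    out = np.zeros_like(t)
    if ktrans == 0:
        return out
    e_kep = np.exp(-kep * t)
    for a, m in ((vif.a1, vif.m1), (vif.a2, vif.m2)):
        if abs(kep - m) < DEGENERATE_TOL:
            out += a * ktrans * t * np.exp(-m * t)
        else:
            out += ktrans * a * (np.exp(-m * t) - e_kep) / (kep - m)
    return out


def tofts_forward_closed(
    params: ToftsParams, vif: VIFParams, times
) -> ConcentrationSeries:
    """Noise-free tissue curve from the closed-form Tofts solution."""
    t = np.asarray(times, dtype=float)
    return ConcentrationSeries(times=t, conc=_closed_form(params.ktrans, params.kep, vif, t))


def tofts_forward_numeric(
    params: ToftsParams, vif: VIFParams, times, dt: float = 0.1
) -> ConcentrationSeries:
    """Tissue curve by trapezoidal convolution on a fine grid (test oracle).

    The integrand C_p(tau) exp(-kep (t - tau)) is accumulated with the
    trapezoid rule on a grid of step ``dt`` and linearly resampled to
    ``times``.
    """
    t = np.asarray(times, dtype=float)
    if dt <= 0:
        raise ValueError("dt must be positive")
    if t.size > 1 and dt > np.min(np.diff(t)):
        raise ValueError("dt larger than the minimum spacing of times")
    grid = np.arange(0.0, t[-1] + dt, dt)
    cp = vif_concentration(grid, vif)
    kep = params.kep
    # exp(-kep t) * cumtrapz(cp * exp(kep tau)) is numerically unstable for
    # large kep*t; integrate incrementally instead.
    conv = np.zeros_like(grid)
    decay = np.exp(-kep * dt)
    for i in range(1, grid.size):
        conv[i] = conv[i - 1] * decay + 0.5 * dt * (cp[i] + cp[i - 1] * decay)
    ct = params.ktrans * np.interp(t, grid, conv)
    return ConcentrationSeries(times=t, conc=ct)


def signal_to_concentration(
    sig: SignalSeries, r1: float = 4.5, t10: float = 1.5
) -> ConcentrationSeries:
    """Convert dynamic signal to concentration by a linear fast-exchange rule.

    The baseline S0 is the mean of the pre-contrast frames and
    ``C(t) = (S(t)/S0 - 1) / (r1 * t10)`` with relaxivity r1 (1/s/mM) and
    pre-contrast longitudinal relaxation time t10 (s).  Times are shifted so
    the first post-injection frame is t = 0.
    """
    if t10 <= 0 or r1 <= 0:
        raise ValueError("r1 and t10 must be positive")
    s0 = float(np.mean(sig.signal[: sig.n_pre]))
    if s0 <= 0:
        raise ValueError("non-positive baseline signal")
    post = slice(sig.n_pre, None)
    conc = (sig.signal[post] / s0 - 1.0) / (r1 * t10)
    times = sig.times[post] - sig.times[sig.n_pre]
    return ConcentrationSeries(times=times, conc=conc)


def concentration_to_signal(
    conc: ConcentrationSeries,
    s0: float = 1000.0,
    r1: float = 4.5,
    t10: float = 1.5,
    n_pre: int = 5,
    frame_interval: float = 12.0,
) -> SignalSeries:
    """Inverse of :func:`signal_to_concentration` (synthetic signal maker).

    Prepends ``n_pre`` baseline frames at signal s0, spaced ``frame_interval``
    seconds before the first post-injection frame.
    """
    pre_times = conc.times[0] - frame_interval * np.arange(n_pre, 0, -1)
    times = np.concatenate([pre_times, conc.times]) - pre_times[0]
    signal = np.concatenate([np.full(n_pre, s0), s0 * (1.0 + r1 * t10 * conc.conc)])
    return SignalSeries(times=times, signal=signal, n_pre=n_pre)


def fit_tofts_voxel(conc: ConcentrationSeries, vif: VIFParams = VIFParams()) -> FitResult:
    """Bounded nonlinear least squares for (Ktrans, v_e) on one voxel.

    Residuals are evaluated at every point of a coarse (ktrans, ve) start
    grid; the optimizer is run from the three best grid points and the lowest
    residual sum of squares wins.  A voxel never raises on fit failure: the
    result carries ``converged=False`` and the best grid point instead.
    """
    if conc.times.size < 8:
        raise ValueError("need at least 8 time points to fit two parameters")
    t, y = conc.times, conc.conc

    def residuals(theta: np.ndarray) -> np.ndarray:
        return _closed_form(theta[0], theta[0] / theta[1], vif, t) - y

    starts = [
        np.array([kt, ve]) for kt in KTRANS_STARTS for ve in VE_STARTS
    ]
    grid_rss = [float(np.sum(residuals(s) ** 2)) for s in starts]
    order = np.argsort(grid_rss)

    best: tuple[float, np.ndarray] | None = None
    n_iter = 0
    any_ok = False
    for idx in order[:3]:
        try:
            sol = least_squares(
                residuals,
                starts[idx],
                bounds=([KTRANS_BOUNDS[0], VE_BOUNDS[0]], [KTRANS_BOUNDS[1], VE_BOUNDS[1]]),
                method="trf",
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
            )
        except Exception:
            continue
        rss = float(np.sum(sol.fun**2))
        n_iter += sol.nfev
        if sol.success:
            any_ok = True
        if best is None or rss < best[0]:
            best = (rss, sol.x)
    if best is None or not any_ok:
        idx = int(order[0])
        theta = starts[idx]
        return FitResult(
            params=ToftsParams(ktrans=float(theta[0]), ve=float(theta[1])),
            rss=grid_rss[idx],
            converged=False,
            n_iter=n_iter,
        )
    rss, theta = best
    return FitResult(
        params=ToftsParams(ktrans=float(theta[0]), ve=float(theta[1])),
        rss=rss,
        converged=True,
        n_iter=n_iter,
    )


def fit_tofts_batch(
    conc_matrix: np.ndarray, times, vif: VIFParams = VIFParams()
) -> tuple[list[FitResult], float]:
    """Fit every row of a (voxel x time) concentration array.

    Returns the per-voxel results and the fraction of voxels whose fit did
    not converge.
    """
    conc_matrix = np.asarray(conc_matrix, dtype=float)
    results = [
        fit_tofts_voxel(ConcentrationSeries(times=times, conc=row), vif)
        for row in conc_matrix
    ]
    n_fail = sum(not r.converged for r in results)
    return results, n_fail / len(results) if results else 0.0


def roi_mean_ktrans(results: list[FitResult], roi) -> "ROISummary":
    """Mean Ktrans over converged voxels of an ROI; excluded count reported."""
    from .dwi import ROIMask, ROISummary

    if not isinstance(roi, ROIMask):
        roi = ROIMask(indices=np.asarray(roi))
    if roi.indices.size == 0:
        raise ValueError("empty ROI")
    chosen = [results[i] for i in roi.indices]
    ok = [r.params.ktrans for r in chosen if r.converged]
    if not ok:
        raise ValueError("no converged voxels inside ROI")
    return ROISummary(
        mean=float(np.mean(ok)), n_used=len(ok), n_excluded=len(chosen) - len(ok)
    )
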