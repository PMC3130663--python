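"""Voxel-wise apparent diffusion coefficient (ADC) mapping.

Diffusion-weighted MR signal decays mono-exponentially with diffusion
weighting b (s/mm^2): ``S(b) = S(0) * exp(-b * ADC)``.  With one b = 0
acquisition and one or more diffusion-weighted acquisitions per gradient
direction, the per-direction coefficient is

    ADC_d = ln(S(0) / S(b, d)) / b

and the isotropic ADC is the arithmetic mean over directions.  Averaging the
per-direction log-ratios is algebraically identical to computing a single ADC
from the geometric mean of the directional signals, which is the identity the
test suite asserts.

Voxels with any non-positive measurement cannot enter the log domain and are
flagged invalid rather than clipped: clipping would convert noise into a
systematic ADC bias.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class DWStack:
    """Per-voxel diffusion signals on a (b-value, direction) grid.

    ``signals`` has shape (n_voxels, n_b, n_directions); arbitrary units.
    Exactly one b-value must be zero.  The b = 0 row carries one (possibly
    noisy) acquisition per direction slot; noise-free, the slots are equal.
    """

    signals: np.ndarray
    b_values: np.ndarray
    directions: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        self.b_values = np.asarray(self.b_values, dtype=float)
        if self.signals.ndim != 3:
            raise ValueError("signals must have shape (n_voxels, n_b, n_directions)")
        if self.signals.shape[1] != self.b_values.size:
            raise ValueError("b axis of signals does not match b_values")
        if np.any(self.b_values < 0):
            raise ValueError("negative b-value")
        if int(np.sum(self.b_values == 0)) != 1:
            raise ValueError("exactly one b = 0 entry is required")
        if not np.all(np.isfinite(self.signals)):
            raise ValueError("non-finite signal values")

    @property
    def n_voxels(self) -> int:
        return self.signals.shape[0]


@dataclass
class ADCMap:
    """Per-voxel ADC (mm^2/s) with an explicit validity mask."""

    adc: np.ndarray
    valid_mask: np.ndarray

    def __post_init__(self) -> None:
        self.adc = np.asarray(self.adc, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.adc.shape != self.valid_mask.shape:
            raise ValueError("adc and valid_mask shapes differ")
        if not np.all(np.isfinite(self.adc[self.valid_mask])):
            raise ValueError("non-finite ADC in valid voxels")


@dataclass
class ROIMask:
    """Indices of the voxels belonging to a region of interest."""

    indices: np.ndarray

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if self.indices.ndim != 1:
            raise ValueError("ROI indices must be a flat index list")


@dataclass
class ROISummary:
    """ROI statistic with bookkeeping of how many voxels were usable."""

    mean: float
    n_used: int
    n_excluded: int

    @property
    def excluded_fraction(self) -> float:
        total = self.n_used + self.n_excluded
        return self.n_excluded / total if total else 0.0


def compute_adc_map(stack: DWStack) -> ADCMap:
    """Voxel-wise isotropic ADC from a diffusion-weighted stack.

    Per direction and nonzero b, ``ADC = ln(S0/S)/b``; the isotropic value is
    the arithmetic mean over all (b > 0, direction) measurements.  S0 is the
    mean over the b = 0 acquisitions.  Any voxel with a non-positive
    measurement anywhere in the stack is flagged invalid (its ADC is NaN).
    """
    nz = stack.b_values > 0
    if not np.any(nz):
        raise ValueError("ADC mapping needs at least one nonzero b-value")

    s0_reps = stack.signals[:, ~nz, :]  # (n_vox, 1, n_dir)
    s_dw = stack.signals[:, nz, :]      # (n_vox, n_b>0, n_dir)
    valid = np.all(s0_reps > 0, axis=(1, 2)) & np.all(s_dw > 0, axis=(1, 2))

    adc = np.full(stack.n_voxels, np.nan)
    if np.any(valid):
        s0 = s0_reps[valid].mean(axis=(1, 2))
        b = stack.b_values[nz][np.newaxis, :, np.newaxis]
        per_meas = np.log(s0[:, np.newaxis, np.newaxis] / s_dw[valid]) / b
        adc[valid] = per_meas.mean(axis=(1, 2))
    return ADCMap(adc=adc, valid_mask=valid)


def roi_mean(adc_map: ADCMap, roi: ROIMask) -> ROISummary:
    """Mean ADC over the valid voxels of an ROI.

    Invalid voxels are excluded and counted; an ROI with no valid voxel is an
    error rather than a silent NaN.
    """
    if roi.indices.size == 0:
        raise ValueError("empty ROI")
    inside_valid = adc_map.valid_mask[roi.indices]
    n_used = int(inside_valid.sum())
    if n_used == 0:
        raise ValueError("no valid voxels inside ROI")
    values = adc_map.adc[roi.indices][inside_valid]
    return ROISummary(
        mean=float(values.mean()),
        n_used=n_used,
        n_excluded=int(roi.indices.size - n_used),
    )
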