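"""Relaxation-rate time curves from dynamic GE/SE perfusion signals.

During the first pass of a paramagnetic contrast bolus the transverse
relaxation rates of tissue water increase roughly in proportion to the
intravascular contrast concentration.  With a dual-echo acquisition the
gradient-echo (GE) signal reports the susceptibility effect of vessels of
all sizes while the spin-echo (SE) signal is selectively sensitive to
microvessels (radius < 10 um).  This module converts the raw dynamic
signals S(t) into relaxation-rate changes

    dR2*(t) = -ln(S_GE(t) / S_GE,0) / TE_GE
    dR2(t)  = -ln(S_SE(t) / S_SE,0) / TE_SE

where S_0 is the mean pre-contrast (baseline) signal, and locates the
first-pass analysis window around the bolus peak (4 dynamics before, 8
after at the default 1.6 s sampling).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np


class Contrast(str, Enum):
    """Acquisition contrast of a dynamic series."""

    GE = "GE"
    SE = "SE"


@dataclass(frozen=True)
class AcquisitionParams:
    """Timing and echo parameters of the dynamic dual-echo protocol.

    Parameters
    ----------
    te_ge, te_se:
        Echo times in seconds of the gradient-echo and spin-echo readouts.
    dt:
        Dynamic scan interval in seconds.
    n_dynamics:
        Number of dynamic volumes.
    injection_dynamic:
        1-based index of the dynamic at whose start the contrast agent is
        injected (default 9).
    baseline_range:
        Inclusive 0-based index range of pre-contrast dynamics used for the
        baseline signal S0.
    """

    te_ge: float = 0.025
    te_se: float = 0.078
    dt: float = 1.6
    n_dynamics: int = 100
    injection_dynamic: int = 9
    baseline_range: tuple[int, int] = (0, 7)

    def __post_init__(self) -> None:
        if self.te_ge <= 0 or self.te_se <= 0:
            raise ValueError("echo times must be positive")
        if self.dt <= 0:
            raise ValueError("dynamic scan interval must be positive")
        lo, hi = self.baseline_range
        if lo > hi:
            raise ValueError(f"empty baseline range {self.baseline_range}")
        if lo < 0 or hi >= self.n_dynamics:
            raise ValueError("baseline range out of bounds")
        # baseline must end before the first post-injection dynamic (0-based
        # index injection_dynamic - 1)
        if hi >= self.injection_dynamic - 1:
            raise ValueError(
                "baseline range must end before the injection dynamic"
            )
        if self.n_dynamics < self.injection_dynamic:
            raise ValueError("n_dynamics smaller than injection dynamic")

    def te(self, contrast: Contrast) -> float:
        return self.te_ge if Contrast(contrast) is Contrast.GE else self.te_se

    @property
    def time(self) -> np.ndarray:
        """Time of each dynamic in seconds (0-based, t=0 at first dynamic)."""
        return np.arange(self.n_dynamics) * self.dt


@dataclass
class DynamicSeries:
    """A 4D dynamic signal volume (x, y, z, dynamic) with its parameters."""

    data: np.ndarray
    contrast: Contrast
    params: AcquisitionParams

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.contrast = Contrast(self.contrast)
        if self.data.ndim != 4:
            raise ValueError(f"expected 4D data, got shape {self.data.shape}")
        if self.data.shape[-1] != self.params.n_dynamics:
            raise ValueError(
                f"series has {self.data.shape[-1]} dynamics, "
                f"params say {self.params.n_dynamics}"
            )
        if not np.isfinite(self.data).all():
            raise ValueError("dynamic signal contains non-finite values")

    @property
    def te(self) -> float:
        return self.params.te(self.contrast)


@dataclass(frozen=True)
class FirstPassWindow:
    """Inclusive index window around the bolus peak used for Q and MTI."""

    peak_index: int
    start: int
    end: int
    clamped: bool

    def __post_init__(self) -> None:
        if not (self.start <= self.peak_index <= self.end):
            raise ValueError("peak index outside window")
        if self.end - self.start > 12:
            raise ValueError("window longer than 13 timepoints")

    @property
    def slice(self) -> slice:
        return slice(self.start, self.end + 1)

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass
class RelaxationCurves:
    """Paired dR2*(t) / dR2(t) traces on one time grid with their window."""

    dr2s: np.ndarray
    dr2: np.ndarray
    window: FirstPassWindow

    def __post_init__(self) -> None:
        self.dr2s = np.asarray(self.dr2s, dtype=float)
        self.dr2 = np.asarray(self.dr2, dtype=float)
        if self.dr2s.shape != self.dr2.shape:
            raise ValueError("dR2* and dR2 series must share one time grid")


def estimate_baseline(series: DynamicSeries) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel mean pre-contrast signal S0 and a validity mask.

    Voxels with any non-positive baseline sample are flagged invalid (the
    log-ratio is undefined there) and must be excluded downstream.

    Returns
    -------
    s0 : ndarray
        3D map of the arithmetic mean over the baseline dynamics.
    valid : ndarray of bool
        3D mask, False where any baseline sample is <= 0.
    """
    lo, hi = series.params.baseline_range
    base = series.data[..., lo : hi + 1]
    if base.shape[-1] == 0:
        raise ValueError("empty baseline range")
    valid = (base > 0).all(axis=-1)
    if not valid.any():
        raise ValueError(
            f"all {valid.size} voxels have non-positive baseline signal"
        )
    s0 = base.mean(axis=-1)
    return s0, valid


def delta_r2_series(
    series: DynamicSeries,
    s0: np.ndarray,
    valid: np.ndarray | None = None,
) -> np.ndarray:
    """Relaxation-rate change dR(t) = -ln(S(t)/S0)/TE per voxel, in 1/s.

    Non-positive signals at any dynamic yield NaN at that voxel-timepoint;
    missing values propagate (they are never zero-filled).  Voxels flagged
    invalid in ``valid`` are NaN throughout.
    """
    te = series.te
    s0 = np.asarray(s0, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = series.data / s0[..., None]
        dr = -np.log(ratio) / te
    dr = np.where(series.data > 0, dr, np.nan)
    if valid is not None:
        dr = np.where(np.asarray(valid, bool)[..., None], dr, np.nan)
    return dr


def find_bolus_peak(dr2s: np.ndarray, search_from: int = 0) -> int:
    """0-based index of the maximum dR2* value at or after ``search_from``.

    Ties break to the earliest index.  Raises if no finite positive value
    exists in the search range (no bolus); warns when the peak falls on the
    last dynamic (truncated first pass).
    """
    y = np.asarray(dr2s, dtype=float).ravel()
    seg = y[search_from:]
    finite = np.isfinite(seg)
    if not finite.any():
        raise ValueError("no bolus detected: no finite values in search range")
    if np.nanmax(seg) <= 0:
        raise ValueError("no bolus detected: dR2* never rises above zero")
    peak = search_from + int(np.nanargmax(seg))
    if peak == len(y) - 1:
        warnings.warn(
            "bolus peak at the last dynamic: first pass truncated",
            stacklevel=2,
        )
    return peak


def first_pass_window(
    peak: int, n_dynamics: int, pre: int = 4, post: int = 8
) -> FirstPassWindow:
    """Window of ``pre`` dynamics before and ``post`` after the bolus peak.

    Nominal length is pre + post + 1 (13 at the defaults); bounds are
    clamped to the acquisition and the ``clamped`` flag records truncation.
    """
    if not 0 <= peak < n_dynamics:
        raise ValueError(f"peak {peak} outside 0..{n_dynamics - 1}")
    start = max(0, peak - pre)
    end = min(n_dynamics - 1, peak + post)
    clamped = (start != peak - pre) or (end != peak + post)
    return FirstPassWindow(peak_index=peak, start=start, end=end, clamped=clamped)


def smooth_curve(y: np.ndarray, width: int = 3) -> np.ndarray:
    """Optional centered moving average along the last axis (edges shrink)."""
    if width < 1 or width % 2 == 0:
        raise ValueError("width must be a positive odd integer")
    if width == 1:
        return np.asarray(y, dtype=float).copy()
    y = np.asarray(y, dtype=float)
    kernel = np.ones(width) / width
    pad = width // 2
    padded = np.concatenate(
        [y[..., :1].repeat(pad, axis=-1), y, y[..., -1:].repeat(pad, axis=-1)],
        axis=-1,
    )
    return np.apply_along_axis(
        lambda v: np.convolve(v, kernel, mode="valid"), -1, padded
    )
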