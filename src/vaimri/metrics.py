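"""Vessel-architecture measures: vessel density Q, vessel size index VSI and
microvessel type indicator MTI.

The three measures combine the GE and SE relaxation-rate curves over the
first-pass bolus window:

* ``Q = dR2 / (dR2*)^(2/3)`` (units s^(-1/3)) rises with microvessel
  density;
* ``VSI = 0.867 * sqrt(D * rCBV) * Q^(-3/2)`` (um) is a weighted mean
  vessel radius, with D the parenchymal diffusion coefficient in um^2/s
  and rCBV the blood volume fraction;
* MTI is the signed area of the vortex loop traced by plotting dR2*(t)
  against dR2(t) over the window: inter-compartment bolus delays open a
  hysteresis loop whose orientation separates arteriole-dominated
  (clockwise, positive) from venule-dominated (counter-clockwise,
  negative) voxels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .relaxometry import FirstPassWindow

VSI_CONSTANT = 0.867

_Q_ESTIMATORS = ("slope", "ratio_of_means", "pointwise")


def _signed_power(x: np.ndarray, p: float) -> np.ndarray:
    """sign(x)*|x|^p — keeps fractional powers defined for noisy negatives."""
    return np.sign(x) * np.abs(x) ** p


def vessel_density_q(
    dr2_window: np.ndarray,
    dr2s_window: np.ndarray,
    estimator: str = "slope",
) -> float:
    """Vessel density index Q from paired window curves, in s^(-1/3).

    Estimators (all equal when dR2* is constant over the window):

    ``slope``
        Through-origin least-squares slope of dR2 on (dR2*)^(2/3); exact
        whenever dR2(t) = c*(dR2*(t))^(2/3) and robust to noise because
        low-amplitude window edges get low weight.  Default.
    ``ratio_of_means``
        mean(dR2) / mean(dR2*)^(2/3).
    ``pointwise``
        mean over the window of the pointwise ratios dR2/(dR2*)^(2/3).

    Returns NaN (voxel invalid) for missing values or non-positive
    denominators.
    """
    if estimator not in _Q_ESTIMATORS:
        raise ValueError(f"unknown Q estimator {estimator!r}")
    y = np.asarray(dr2_window, dtype=float)
    x = np.asarray(dr2s_window, dtype=float)
    if y.shape != x.shape:
        raise ValueError("window curves differ in length")
    if not (np.isfinite(y).all() and np.isfinite(x).all()):
        return float("nan")
    if estimator == "ratio_of_means":
        mx = x.mean()
        my = y.mean()
        if mx <= 0 or my < 0:
            return float("nan")
        return float(my / mx ** (2.0 / 3.0))
    u = _signed_power(x, 2.0 / 3.0)
    if estimator == "slope":
        denom = (u * u).sum()
        if denom <= 0:
            return float("nan")
        q = float((y * u).sum() / denom)
    else:  # pointwise
        ok = u > 0
        if not ok.any():
            return float("nan")
        q = float((y[ok] / u[ok]).mean())
    return q if q > 0 else float("nan")


def vessel_size_index(d, rcbv, q):
    """Vessel size index VSI = 0.867*sqrt(D*rCBV)*Q^(-3/2), in um.

    Unit contract: D in um^2/s and Q in s^(-1/3) yield um.  Any
    non-positive input marks the voxel invalid (NaN).  Accepts scalars or
    arrays (broadcast).
    """
    d = np.asarray(d, dtype=float)
    rcbv = np.asarray(rcbv, dtype=float)
    q = np.asarray(q, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        vsi = VSI_CONSTANT * np.sqrt(d * rcbv) * q ** -1.5
        vsi = np.where((d > 0) & (rcbv > 0) & (q > 0), vsi, np.nan)
    if vsi.ndim == 0:
        return float(vsi)
    return vsi


def mti_loop_area(dr2_window: np.ndarray, dr2s_window: np.ndarray) -> float:
    """Signed vortex-loop area (MTI) from paired window curves.

    Vertices (x_i, y_i) = (dR2(t_i), dR2*(t_i)) taken in window order and
    closed last-to-first; the shoelace sum is negated so a clockwise loop
    (arteriole-dominated: the GE effect leads the SE effect) is positive
    and a counter-clockwise loop (venule-dominated) negative.  Units are
    s^-2.  Returns NaN for < 3 points or missing values.
    """
    x = np.asarray(dr2_window, dtype=float)
    y = np.asarray(dr2s_window, dtype=float)
    if x.shape != y.shape:
        raise ValueError("window curves differ in length")
    if x.size < 3 or not (np.isfinite(x).all() and np.isfinite(y).all()):
        return float("nan")
    xn = np.roll(x, -1)
    yn = np.roll(y, -1)
    shoelace = 0.5 * np.sum(x * yn - xn * y)
    return float(-shoelace)


def _mti_vectorized(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Shoelace MTI along the last axis for stacked window curves."""
    xn = np.roll(x, -1, axis=-1)
    yn = np.roll(y, -1, axis=-1)
    return -0.5 * np.sum(x * yn - xn * y, axis=-1)


def roi_vai_from_curves(
    dr2s_4d: np.ndarray,
    dr2_4d: np.ndarray,
    window: FirstPassWindow,
    mask: np.ndarray,
    d_roi: float,
    rcbv_roi: float,
    q_estimator: str = "slope",
) -> dict[str, float]:
    """ROI metrics computed from ROI-averaged curves.

    Alternative to averaging voxel-wise metrics: the dR2*/dR2 curves are
    first averaged over the mask, then the scalar operations applied once
    (``d_roi`` in um^2/s, ``rcbv_roi`` a fraction).  Equivalent for a
    homogeneous ROI; more noise-tolerant but blind to within-ROI
    heterogeneity.
    """
    mask = np.asarray(mask, bool)
    x = np.nanmean(np.asarray(dr2_4d, float)[mask], axis=0)[window.slice]
    y = np.nanmean(np.asarray(dr2s_4d, float)[mask], axis=0)[window.slice]
    q = vessel_density_q(x, y, q_estimator)
    return {
        "Q": q,
        "VSI": vessel_size_index(d_roi, rcbv_roi, q),
        "MTI": mti_loop_area(x, y),
    }


@dataclass
class VAIMaps:
    """Voxel-wise vessel-architecture maps on one spatial grid.

    ``q`` s^(-1/3); ``vsi`` um; ``mti`` s^-2 (signed loop area); ``rcbv``
    fraction; ``cbf_ge``/``cbf_se`` relative units; ``d`` um^2/s;
    ``validity`` marks voxels where all inputs were usable.
    """

    q: np.ndarray
    vsi: np.ndarray
    mti: np.ndarray
    rcbv: np.ndarray
    d: np.ndarray
    validity: np.ndarray
    cbf_ge: np.ndarray | None = None
    cbf_se: np.ndarray | None = None

    def __post_init__(self) -> None:
        shape = self.q.shape
        for name in ("vsi", "mti", "rcbv", "d", "validity"):
            arr = getattr(self, name)
            if arr.shape != shape:
                raise ValueError(
                    f"grid mismatch: q has shape {shape}, {name} has {arr.shape}"
                )


def voxelwise_vai(
    dr2s_4d: np.ndarray,
    dr2_4d: np.ndarray,
    window: FirstPassWindow,
    d_map: np.ndarray,
    rcbv_map: np.ndarray,
    validity: np.ndarray | None = None,
    q_estimator: str = "slope",
) -> VAIMaps:
    """Apply the scalar Q/VSI/MTI operations per voxel.

    ``d_map`` must be in um^2/s (the VSI unit contract).  Voxels with any
    missing window sample, invalid diffusion/rCBV input, or excluded by an
    upstream validity mask come out NaN with ``validity`` False.
    """
    dr2s_4d = np.asarray(dr2s_4d, dtype=float)
    dr2_4d = np.asarray(dr2_4d, dtype=float)
    if dr2s_4d.shape != dr2_4d.shape:
        raise ValueError(
            f"grid mismatch: dR2* {dr2s_4d.shape} vs dR2 {dr2_4d.shape}"
        )
    spatial = dr2s_4d.shape[:-1]
    for name, arr in (("d", d_map), ("rcbv", rcbv_map)):
        if np.asarray(arr).shape != spatial:
            raise ValueError(
                f"grid mismatch: curves {spatial} vs {name} {np.asarray(arr).shape}"
            )

    xw = dr2_4d[..., window.slice]
    yw = dr2s_4d[..., window.slice]
    ok = np.isfinite(xw).all(axis=-1) & np.isfinite(yw).all(axis=-1)
    if validity is not None:
        ok &= np.asarray(validity, bool)

    if q_estimator == "slope":
        u = _signed_power(yw, 2.0 / 3.0)
        denom = (u * u).sum(axis=-1)
        with np.errstate(invalid="ignore", divide="ignore"):
            q = (xw * u).sum(axis=-1) / denom
        q = np.where(denom > 0, q, np.nan)
    elif q_estimator == "ratio_of_means":
        mx = yw.mean(axis=-1)
        my = xw.mean(axis=-1)
        with np.errstate(invalid="ignore", divide="ignore"):
            q = my / _signed_power(mx, 2.0 / 3.0)
        q = np.where((mx > 0) & (my >= 0), q, np.nan)
    elif q_estimator == "pointwise":
        u = _signed_power(yw, 2.0 / 3.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            ratios = np.where(u > 0, xw / u, np.nan)
            q = np.nanmean(ratios, axis=-1)
    else:
        raise ValueError(f"unknown Q estimator {q_estimator!r}")
    q = np.where(ok & (q > 0), q, np.nan)

    mti = np.where(ok, _mti_vectorized(xw, yw), np.nan)
    vsi = vessel_size_index(d_map, rcbv_map, q)
    valid = ok & np.isfinite(q)
    if not valid.any():
        warnings.warn(
            f"all {valid.size} voxels invalid in voxel-wise VAI", stacklevel=2
        )
    return VAIMaps(
        q=q,
        vsi=np.asarray(vsi),
        mti=mti,
        rcbv=np.asarray(rcbv_map, dtype=float),
        d=np.asarray(d_map, dtype=float),
        validity=valid,
    )
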