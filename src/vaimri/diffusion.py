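"""Parenchymal diffusion coefficient from multi-b diffusion-weighted MRI.

A mono-exponential decay S(b) = S0 * exp(-b*D) is fitted to the
direction-averaged signal for b >= 200 s/mm^2; restricting the fit to the
higher b-values removes the intravascular (perfusion) contribution that
contaminates b = 0.  Direction averaging uses the geometric mean over the
three orthogonal gradient directions so that the fitted D equals the mean
of the per-direction ADCs (the trace ADC).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

MM2_TO_UM2 = 1.0e6  # mm^2/s -> um^2/s

DEFAULT_BVALUES = (0.0, 200.0, 300.0, 400.0, 500.0, 600.0, 800.0, 1000.0)


@dataclass(frozen=True)
class DiffusionProtocol:
    """b-value scheme of the diffusion acquisition.

    ``bvalues`` in s/mm^2, strictly increasing; ``n_directions`` orthogonal
    gradient directions per b; the fit uses only b >= ``fit_bmin``.
    """

    bvalues: tuple[float, ...] = DEFAULT_BVALUES
    n_directions: int = 3
    fit_bmin: float = 200.0

    def __post_init__(self) -> None:
        b = np.asarray(self.bvalues, dtype=float)
        if (b < 0).any():
            raise ValueError("b-values must be non-negative")
        if not (np.diff(b) > 0).all():
            raise ValueError("b-values must be strictly increasing")
        if (b >= self.fit_bmin).sum() < 2:
            raise ValueError("need >= 2 b-values at or above fit_bmin")

    @property
    def fitted_bvalues(self) -> np.ndarray:
        b = np.asarray(self.bvalues, dtype=float)
        return b[b >= self.fit_bmin]


@dataclass
class DiffusionFit:
    """Result of the mono-exponential fit.

    ``d`` in mm^2/s (NaN where invalid); ``validity`` False where any
    fitted signal was non-positive; ``implausible`` True where the fitted
    slope implies D <= 0 (kept in the map but flagged).
    """

    d: np.ndarray
    validity: np.ndarray
    implausible: np.ndarray

    @property
    def d_um2_per_s(self) -> np.ndarray:
        """D in um^2/s, the unit the VSI formula consumes."""
        return self.d * MM2_TO_UM2


def direction_average(
    signals: np.ndarray, bvals: np.ndarray, combine: str = "geometric"
) -> tuple[np.ndarray, np.ndarray]:
    """Average repeated-b volumes across gradient directions.

    ``signals`` has the volume axis last; ``bvals`` gives the b-value of
    each volume.  Returns (averaged signals over unique b, unique b).  The
    geometric mean (default) makes log-averaging exact for per-direction
    mono-exponentials; ``combine="arithmetic"`` is available.
    """
    signals = np.asarray(signals, dtype=float)
    bvals = np.asarray(bvals, dtype=float)
    if signals.shape[-1] != bvals.size:
        raise ValueError(
            f"{signals.shape[-1]} volumes but {bvals.size} b-values"
        )
    ub = np.unique(bvals)
    out = np.empty(signals.shape[:-1] + (ub.size,))
    for i, b in enumerate(ub):
        grp = signals[..., bvals == b]
        if combine == "geometric":
            with np.errstate(divide="ignore", invalid="ignore"):
                out[..., i] = np.where(
                    (grp > 0).all(axis=-1),
                    np.exp(np.log(np.where(grp > 0, grp, 1.0)).mean(axis=-1)),
                    np.nan,
                )
        elif combine == "arithmetic":
            out[..., i] = grp.mean(axis=-1)
        else:
            raise ValueError(f"unknown combine rule {combine!r}")
    return out, ub


def fit_adc(
    signals: np.ndarray,
    bvals: np.ndarray,
    protocol: DiffusionProtocol | None = None,
    combine: str = "geometric",
    weighted: bool = False,
) -> DiffusionFit:
    """Mono-exponential diffusion fit per voxel for b >= fit_bmin.

    D is minus the least-squares slope of ln(signal) against b over the
    fitted b-values.  With ``weighted`` the log-linear fit is weighted by
    signal^2 (useful for noisy data); the default is ordinary least
    squares.  Non-positive signal at a fitted b invalidates the voxel;
    D <= 0 is kept but flagged implausible.
    """
    protocol = protocol or DiffusionProtocol()
    avg, ub = direction_average(signals, bvals, combine=combine)
    sel = ub >= protocol.fit_bmin
    if sel.sum() < 2:
        raise ValueError("need >= 2 b-values at or above fit_bmin")
    b = ub[sel]
    y = avg[..., sel]
    valid = np.isfinite(y).all(axis=-1) & (y > 0).all(axis=-1)
    logy = np.where(y > 0, np.log(np.where(y > 0, y, 1.0)), np.nan)

    bc = b - b.mean()
    if weighted:
        w = y**2
        wsum = w.sum(axis=-1)
        bbar = (w * b).sum(axis=-1) / wsum
        ybar = (w * logy).sum(axis=-1) / wsum
        num = (w * (b - bbar[..., None]) * (logy - ybar[..., None])).sum(axis=-1)
        den = (w * (b - bbar[..., None]) ** 2).sum(axis=-1)
    else:
        num = (bc * (logy - logy.mean(axis=-1, keepdims=True))).sum(axis=-1)
        den = float((bc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        slope = num / den
    d = -slope
    d = np.where(valid, d, np.nan)
    # numerical floor well below tissue D (~1e-3 mm^2/s) so a flat or
    # rising decay registers as implausible despite rounding residue
    implausible = valid & (d <= 1e-12)
    return DiffusionFit(d=d, validity=valid, implausible=implausible)


def read_bvals(path) -> np.ndarray:
    """Read an FSL-style bval file (whitespace-separated, one or more rows)."""
    vals = np.loadtxt(path, ndmin=1)
    return vals.ravel().astype(float)
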