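"""Digital perfusion/diffusion phantoms with known microvascular ground truth.

The generator runs the vessel-architecture model forward: a gamma-variate
arterial bolus is convolved with an exponential residue function to give
each tissue's concentration curve; the GE relaxation change is linear in
concentration while the SE change follows the 2/3-power law
dR2(t) = q * [dR2*(t - tau)]^(2/3), where the temporal offset ``tau``
between the two compartments encodes vessel-type dominance (positive: the
GE effect leads, an arteriole-dominated clockwise vortex loop; negative:
venule-dominated).  Signals follow S = S0*exp(-dR*TE); diffusion-weighted
signals decay mono-exponentially in b.  Optional Rician noise is seeded
and reproducible.

Ground-truth maps of Q, rCBV, D, MTT, relative CBF and the SE lag are
emitted alongside the signals so every pipeline stage can be tested by
forward-inverse consistency.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .diffusion import DEFAULT_BVALUES
from .perfusion import GammaVariateParams
from .relaxometry import AcquisitionParams, Contrast, DynamicSeries
from .rois import LABEL_CODES, ROISet

DEFAULT_VOXEL_SIZE = (3.0, 3.3, 5.0)  # mm, the acquisition resolution scale

_FINE_OVERSAMPLE = 16  # forward model runs on a dt/16 grid before sampling


@dataclass(frozen=True)
class TissueParams:
    """Ground-truth microvascular parameters of one tissue class.

    ``q`` vessel density index, s^(-1/3); ``rcbv`` blood volume fraction;
    ``d`` diffusion coefficient, mm^2/s; ``mtt`` mean transit time, s;
    ``tau_se`` SE-vs-GE bolus lag, s (sign encodes vessel-type dominance);
    ``s0_ge``/``s0_se`` baseline signals.  ``rcbv = 0`` means no bolus
    passage (e.g. CSF).
    """

    q: float
    rcbv: float
    d: float
    mtt: float
    tau_se: float = 0.0
    s0_ge: float = 1000.0
    s0_se: float = 1000.0

    def __post_init__(self) -> None:
        if self.rcbv < 0 or self.d <= 0 or self.mtt <= 0:
            raise ValueError("tissue parameters must be positive")
        if self.rcbv > 0 and self.q <= 0:
            raise ValueError("q must be positive for perfused tissue")

    @property
    def cbf_rel(self) -> float:
        """Relative flow implied by the central volume theorem, rCBV/MTT."""
        return self.rcbv / self.mtt


DEFAULT_TISSUES: dict[str, TissueParams] = {
    # values on the scale reported for elderly subjects: NAWM Q ~ 0.39
    # s^(-1/3), rCBV 3.2%, D ~ 8e-4 mm^2/s; WMH lower Q / higher D;
    # gray matter denser and better perfused; arteries are pure blood.
    "CGM": TissueParams(q=0.45, rcbv=0.055, d=8.5e-4, mtt=3.5, tau_se=-0.8),
    "DGM": TissueParams(q=0.44, rcbv=0.045, d=7.5e-4, mtt=3.5, tau_se=-0.8),
    "NAWM": TissueParams(q=0.39, rcbv=0.032, d=8.0e-4, mtt=4.0, tau_se=-0.8),
    "WMH": TissueParams(q=0.29, rcbv=0.028, d=1.0e-3, mtt=5.0, tau_se=-0.8),
    "ARTERIES": TissueParams(q=0.30, rcbv=1.0, d=3.0e-3, mtt=1.0, tau_se=0.4),
    "VENTRICLES": TissueParams(q=1.0, rcbv=0.0, d=3.0e-3, mtt=1.0),
}

DEFAULT_AIF = GammaVariateParams(k=1.0, t0=14.4, alpha=3.0, beta=1.5)


@dataclass(frozen=True)
class PhantomConfig:
    """Full specification of a phantom subject.

    ``snr`` is baseline signal-to-noise (np.inf = noise-free, the
    default); ``k_ge`` maps concentration to dR2* (None: chosen so the
    NAWM peak dR2* is ~10 1/s, a physiologic scale at these echo times).
    Identical seed + config give bit-identical output.
    """

    dims: tuple[int, int, int] = (32, 32, 8)
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE
    tissues: dict[str, TissueParams] = field(
        default_factory=lambda: dict(DEFAULT_TISSUES)
    )
    aif: GammaVariateParams = DEFAULT_AIF
    snr: float = np.inf
    seed: int = 0
    acquisition: AcquisitionParams = AcquisitionParams()
    bvalues: tuple[float, ...] = DEFAULT_BVALUES
    n_directions: int = 3
    k_ge: float | None = None
    nawm_peak_dr2s: float = 10.0


@dataclass
class PhantomDataset:
    """A generated subject: signals, masks and per-voxel ground truth."""

    ge: DynamicSeries
    se: DynamicSeries
    dwi: np.ndarray
    bvals: np.ndarray
    roi_set: ROISet
    truth: dict[str, np.ndarray]
    config: PhantomConfig


def default_label_map(dims: tuple[int, int, int] = (32, 32, 8)) -> np.ndarray:
    """Blocky anatomical layout: cortical rim, white matter interior,
    central ventricles, a deep-gray band, two WMH patches, an arterial
    column and a small lesion-exclusion patch."""
    nx, ny, nz = dims
    if nx < 32 or ny < 32 or nz < 2:
        raise ValueError("dims must be at least 32 x 32 x 2")
    lab = np.zeros(dims, dtype=np.int16)
    lab[2:30, 2:30, :] = LABEL_CODES["CGM"]
    lab[4:28, 4:28, :] = LABEL_CODES["NAWM"]
    lab[10:22, 19:22, :] = LABEL_CODES["DGM"]
    lab[14:18, 14:18, :] = LABEL_CODES["VENTRICLES"]
    lab[5:9, 5:9, :] = LABEL_CODES["WMH"]
    lab[22:26, 22:26, :] = LABEL_CODES["WMH"]
    lab[4:6, 15:17, :] = LABEL_CODES["ARTERIES"]
    lab[24:26, 6:8, : max(1, nz // 4)] = LABEL_CODES["EXCLUDE_LESION"]
    return lab


def _tissue_concentration(
    cfg: PhantomConfig, mtt: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fine-grid AIF and residue-convolved tissue curve (unit area ratio)."""
    acq = cfg.acquisition
    dt_f = acq.dt / _FINE_OVERSAMPLE
    t_f = np.arange(0.0, acq.n_dynamics * acq.dt, dt_f)
    ca = cfg.aif(t_f)
    residue = np.exp(-t_f / mtt)
    ct = np.convolve(ca, residue)[: len(t_f)] * dt_f
    return t_f, ca, ct


def generate_phantom(config: PhantomConfig | None = None) -> PhantomDataset:
    """Run the forward model and return signals, masks and ground truth."""
    cfg = config or PhantomConfig()
    acq = cfg.acquisition
    window_span = 12 * acq.dt
    for name, tp in cfg.tissues.items():
        if abs(tp.tau_se) >= window_span:
            raise ValueError(
                f"{name}: |tau_se| = {abs(tp.tau_se)} s >= window span "
                f"{window_span} s gives a degenerate loop"
            )
    label_map = default_label_map(cfg.dims)
    roi_set = ROISet.from_label_map(label_map, voxel_size=cfg.voxel_size)
    t_acq = acq.time

    # per-tissue curves on the fine grid, then sampled at acquisition times
    curves: dict[str, dict[str, np.ndarray]] = {}
    # first pass: NAWM concentration fixes the concentration->rate constant
    t_f, ca_f, ct_nawm = _tissue_concentration(cfg, cfg.tissues["NAWM"].mtt)
    area_ca = np.trapezoid(ca_f, t_f)
    ct_nawm = ct_nawm * (
        cfg.tissues["NAWM"].rcbv * area_ca / np.trapezoid(ct_nawm, t_f)
    )
    k_ge = cfg.k_ge
    if k_ge is None:
        k_ge = cfg.nawm_peak_dr2s / ct_nawm.max()

    for name, tp in cfg.tissues.items():
        if tp.rcbv == 0:
            dr2s = np.zeros_like(t_acq)
            dr2 = np.zeros_like(t_acq)
            curves[name] = {"dr2s": dr2s, "dr2": dr2, "rcbv_num": 0.0}
            continue
        _, _, ct = _tissue_concentration(cfg, tp.mtt)
        ct = ct * (tp.rcbv * area_ca / np.trapezoid(ct, t_f))
        dr2s_f = k_ge * ct
        dr2s = np.interp(t_acq, t_f, dr2s_f)
        # SE compartment: same first-pass shape, shifted by tau_se
        shifted = np.interp(t_acq - tp.tau_se, t_f, dr2s_f, left=0.0, right=0.0)
        dr2 = tp.q * shifted ** (2.0 / 3.0)
        curves[name] = {
            "dr2s": dr2s,
            "dr2": dr2,
            "rcbv_num": float(np.trapezoid(ct, t_f) / area_ca),
        }

    shape4 = cfg.dims + (acq.n_dynamics,)
    s_ge = np.ones(shape4)
    s_se = np.ones(shape4)
    nb = len(cfg.bvalues)
    dwi = np.ones(cfg.dims + (nb * cfg.n_directions,))
    bvals = np.tile(np.asarray(cfg.bvalues, dtype=float), cfg.n_directions)

    truth = {
        "labels": label_map,
        "q": np.full(cfg.dims, np.nan),
        "rcbv": np.full(cfg.dims, np.nan),
        "d": np.full(cfg.dims, np.nan),
        "mtt": np.full(cfg.dims, np.nan),
        "cbf": np.full(cfg.dims, np.nan),
        "tau_se": np.full(cfg.dims, np.nan),
    }

    background_s0 = 100.0  # weak signal outside the head
    s_ge *= background_s0
    s_se *= background_s0
    dwi *= background_s0

    for name, tp in cfg.tissues.items():
        mask = roi_set.get(name)
        if mask is None or not mask.any():
            continue
        c = curves[name]
        s_ge[mask] = tp.s0_ge * np.exp(-c["dr2s"] * acq.te_ge)
        s_se[mask] = tp.s0_se * np.exp(-c["dr2"] * acq.te_se)
        dwi[mask] = tp.s0_ge * np.exp(-bvals * tp.d)
        truth["q"][mask] = tp.q if tp.rcbv > 0 else np.nan
        truth["rcbv"][mask] = tp.rcbv
        truth["d"][mask] = tp.d
        truth["mtt"][mask] = tp.mtt
        truth["cbf"][mask] = tp.cbf_rel
        truth["tau_se"][mask] = tp.tau_se
    # the lesion-exclusion patch sits on white matter tissue
    lesion = roi_set.get("EXCLUDE_LESION")
    if lesion is not None and lesion.any():
        tp = cfg.tissues["NAWM"]
        c = curves["NAWM"]
        s_ge[lesion] = tp.s0_ge * np.exp(-c["dr2s"] * acq.te_ge)
        s_se[lesion] = tp.s0_se * np.exp(-c["dr2"] * acq.te_se)
        dwi[lesion] = tp.s0_ge * np.exp(-bvals * tp.d)
        truth["q"][lesion] = tp.q
        truth["rcbv"][lesion] = tp.rcbv
        truth["d"][lesion] = tp.d
        truth["mtt"][lesion] = tp.mtt
        truth["cbf"][lesion] = tp.cbf_rel
        truth["tau_se"][lesion] = tp.tau_se

    if np.isfinite(cfg.snr):
        rng = np.random.default_rng(cfg.seed)
        for arr, s0 in ((s_ge, 1000.0), (s_se, 1000.0), (dwi, 1000.0)):
            sigma = s0 / cfg.snr
            n1 = rng.normal(0.0, sigma, size=arr.shape)
            n2 = rng.normal(0.0, sigma, size=arr.shape)
            arr[...] = np.sqrt((arr + n1) ** 2 + n2**2)

    ge = DynamicSeries(data=s_ge, contrast=Contrast.GE, params=acq)
    se = DynamicSeries(data=s_se, contrast=Contrast.SE, params=acq)
    return PhantomDataset(
        ge=ge,
        se=se,
        dwi=dwi,
        bvals=bvals,
        roi_set=roi_set,
        truth=truth,
        config=cfg,
    )


# ---------------------------------------------------------------------------
# cohort-level simulation for the statistics layer


@dataclass(frozen=True)
class MetricModel:
    """Linear generative model of one ROI-mean metric across subjects.

    value = baseline(roi) + group_effect*group + age_slope*(age - 70)
            + sex_effect*sex + N(0, sd)
    """

    baseline: dict[str, float]
    sd: float
    group_effect: float = 0.0
    age_slope: float = 0.0
    sex_effect: float = 0.0

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("sd must be positive")


def default_cohort_effects() -> dict[str, MetricModel]:
    """Effect directions seen in small vessel disease: lower vessel
    density, larger vessel size, higher (less negative) MTI in patients;
    age and male sex push the same way."""
    return {
        "Q": MetricModel(
            baseline={"NAWM": 0.40, "DGM": 0.45, "CGM": 0.46, "WMH": 0.30},
            sd=0.03,
            group_effect=-0.02,
            age_slope=-0.001,
            sex_effect=-0.01,
        ),
        "VSI": MetricModel(
            baseline={"NAWM": 17.0, "DGM": 22.0, "CGM": 25.0, "WMH": 28.0},
            sd=3.0,
            group_effect=3.0,
            age_slope=0.1,
            sex_effect=1.0,
        ),
        "MTI": MetricModel(
            baseline={"NAWM": -0.9, "DGM": -1.0, "CGM": -1.0, "WMH": -1.1},
            sd=0.8,
            group_effect=0.3,
            age_slope=0.02,
            sex_effect=0.2,
        ),
    }


def make_cohort(
    n_patients: int = 40,
    n_controls: int = 21,
    effect_config: dict[str, MetricModel] | None = None,
    seed: int = 0,
    rois=("NAWM", "DGM", "CGM", "WMH"),
):
    """Simulate a subject-level cohort table for the statistics layer.

    Returns a wide pandas DataFrame with identifiers, covariates
    (group 0 = control / 1 = patient, age, sex 0 = female / 1 = male,
    cardiovascular risk factors) and one column per metric_roi.
    """
    import pandas as pd

    if n_patients < 2 or n_controls < 2:
        raise ValueError("need at least 2 subjects per group")
    effects = effect_config or default_cohort_effects()
    rng = np.random.default_rng(seed)
    n = n_patients + n_controls
    group = np.concatenate([np.ones(n_patients), np.zeros(n_controls)])
    age = np.clip(rng.normal(70.0 - 2.0 * (1 - group), 8.0), 45.0, 92.0)
    sex = rng.integers(0, 2, size=n).astype(float)
    rows = {
        "subject_id": [f"sub-{i + 1:03d}" for i in range(n)],
        "group": group.astype(int),
        "age": age,
        "sex": sex.astype(int),
        "hypertension": rng.binomial(1, 0.35 + 0.35 * group),
        "diabetes": rng.binomial(1, 0.08 + 0.12 * group),
        "hypercholesterolemia": rng.binomial(1, 0.25 + 0.25 * group),
        "smoking": rng.binomial(1, 0.15 + 0.15 * group),
        "alcohol": rng.binomial(1, 0.10 + 0.05 * group),
        "bmi": rng.normal(26.0 + 0.8 * group, 3.5),
    }
    for metric, model in effects.items():
        for roi in rois:
            if roi not in model.baseline:
                continue
            mu = (
                model.baseline[roi]
                + model.group_effect * group
                + model.age_slope * (age - 70.0)
                + model.sex_effect * sex
            )
            rows[f"{metric}_{roi}"] = mu + rng.normal(0.0, model.sd, size=n)
    return pd.DataFrame(rows)
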