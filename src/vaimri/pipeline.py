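"""End-to-end subject and cohort analysis.

``run_subject_data`` composes the stages on in-memory arrays:
relaxometry -> AIF / rCBV (anchoring + large-vessel exclusion) ->
diffusion -> voxel-wise Q/VSI/MTI -> GE and SE CBF -> ROI construction and
summaries.  ``run_subject`` is the file-based wrapper (NIfTI in, NIfTI +
CSV + provenance JSON out) and ``run_cohort`` reproduces the group
statistics on a stacked subject table.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .diffusion import DiffusionProtocol, fit_adc, read_bvals
from .io import (
    acquisition_from_config,
    config_hash,
    load_nifti,
    load_yaml,
    save_nifti,
    sha256_of_file,
)
from .metrics import VAIMaps, voxelwise_vai
from .perfusion import (
    cbf_map,
    exclude_top_rcbv,
    fit_gamma_variate,
    fit_tissue_curves,
    rcbv_map,
    scale_aif_to_nawm,
    select_aif,
)
from .relaxometry import (
    AcquisitionParams,
    delta_r2_series,
    estimate_baseline,
    find_bolus_peak,
    first_pass_window,
)
from .rois import ANALYSIS_ROIS, ROISet, build_analysis_rois, summarize_maps
from .stats import (
    independent_ttest,
    interaction_model,
    ols_fit,
    paired_ttest,
    regression_table,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Stage failure with a machine-readable stage code."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass(frozen=True)
class PipelineOptions:
    """Analysis switches (defaults follow the published procedure)."""

    q_estimator: str = "slope"
    oi_threshold: float = 0.095
    rcbv_scaling: bool = True
    nawm_rcbv_target: float = 0.032
    exclusion_fraction: float = 0.10
    exclusion_scope: str = "global"  # or "per_roi"
    periventricular_mm: float = 10.0
    n_aif: int = 10
    vsi_hist_max_um: float = 50.0
    compute_cbf: bool = True


@dataclass
class SubjectResult:
    """Outputs of one subject analysis."""

    maps: VAIMaps
    rois: ROISet
    summaries: pd.DataFrame
    vsi_histogram: pd.DataFrame
    aif_fit: object
    window: object
    aif_scale: float
    provenance: dict = field(default_factory=dict)


def _vsi_histogram(
    vsi: np.ndarray, mask: np.ndarray, max_um: float, bin_um: float = 2.0
) -> pd.DataFrame:
    """Binned VSI distribution; voxels above ``max_um`` are counted but
    flagged rather than binned."""
    vals = vsi[np.asarray(mask, bool)]
    vals = vals[np.isfinite(vals)]
    edges = np.arange(0.0, max_um + bin_um, bin_um)
    counts, _ = np.histogram(vals[vals <= max_um], bins=edges)
    df = pd.DataFrame(
        {"bin_low": edges[:-1], "bin_high": edges[1:], "count": counts}
    )
    df.attrs["n_above_max"] = int((vals > max_um).sum())
    return df


def run_subject_data(
    ge,
    se,
    dwi: np.ndarray,
    bvals: np.ndarray,
    roi_set: ROISet,
    options: PipelineOptions | None = None,
    subject: str = "subject",
) -> SubjectResult:
    """Run the full analysis on in-memory inputs (see module docstring)."""
    opt = options or PipelineOptions()
    acq: AcquisitionParams = ge.params

    # --- ROI construction ------------------------------------------------
    try:
        rois = build_analysis_rois(
            roi_set, periventricular_mm=opt.periventricular_mm
        )
    except Exception as exc:
        raise PipelineError("roi_construction", str(exc)) from exc
    brain = rois.analysis_union()
    if not brain.any():
        raise PipelineError("roi_construction", "no analysis voxels")

    # --- relaxometry ------------------------------------------------------
    try:
        s0_ge, valid_ge = estimate_baseline(ge)
        s0_se, valid_se = estimate_baseline(se)
        dr2s = delta_r2_series(ge, s0_ge, valid_ge)
        dr2 = delta_r2_series(se, s0_se, valid_se)
        mean_curve = np.nanmean(dr2s[brain & valid_ge], axis=0)
        peak = find_bolus_peak(mean_curve, search_from=acq.injection_dynamic - 1)
        window = first_pass_window(peak, acq.n_dynamics)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("relaxometry", str(exc)) from exc
    logger.info(
        "%s: bolus peak at dynamic %d, window %d-%d%s",
        subject,
        window.peak_index,
        window.start,
        window.end,
        " (clamped)" if window.clamped else "",
    )

    # --- AIF and rCBV -----------------------------------------------------
    artery_mask = roi_set.get("ARTERIES")
    if artery_mask is None or not artery_mask.any():
        raise PipelineError("aif", "no arterial mask")
    try:
        aif = select_aif(dr2s, artery_mask, t=acq.time, n_aif=opt.n_aif)
        aif.fit = fit_gamma_variate(acq.time, aif.conc)
        fits, fit_valid = fit_tissue_curves(dr2s, acq.time, brain)
        rcbv_raw = rcbv_map(fits, aif, shape=brain.shape)
        nawm_valid = rois["NAWM"] & fit_valid
        rcbv, scale = scale_aif_to_nawm(
            rcbv_raw,
            nawm_valid,
            target=opt.nawm_rcbv_target,
            enabled=opt.rcbv_scaling,
        )
        aif.scale = aif.scale * scale if scale > 0 else aif.scale
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("perfusion", str(exc)) from exc

    # --- large-vessel exclusion ------------------------------------------
    if opt.exclusion_scope == "global":
        keep = exclude_top_rcbv(rcbv, brain, fraction=opt.exclusion_fraction)
    elif opt.exclusion_scope == "per_roi":
        keep = np.zeros_like(brain)
        for name in ANALYSIS_ROIS:
            m = rois.get(name)
            if m is not None and m.any():
                keep |= exclude_top_rcbv(
                    rcbv, m, fraction=opt.exclusion_fraction
                )
    else:
        raise PipelineError(
            "exclusion", f"unknown exclusion scope {opt.exclusion_scope!r}"
        )
    n_excluded = int(brain.sum() - keep.sum())
    logger.info("%s: large-vessel filter removed %d voxels", subject, n_excluded)

    # --- diffusion --------------------------------------------------------
    try:
        dfit = fit_adc(dwi, bvals, protocol=DiffusionProtocol(
            bvalues=tuple(np.unique(bvals))
        ))
    except Exception as exc:
        raise PipelineError("diffusion", str(exc)) from exc

    # --- voxel-wise VAI ---------------------------------------------------
    validity = keep & valid_ge & valid_se & dfit.validity
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        maps = voxelwise_vai(
            dr2s,
            dr2,
            window,
            dfit.d_um2_per_s,
            rcbv,
            validity=validity,
            q_estimator=opt.q_estimator,
        )

    # --- CBF --------------------------------------------------------------
    if opt.compute_cbf:
        maps.cbf_ge = cbf_map(
            np.nan_to_num(dr2s), aif, acq.dt, brain & validity,
            oi_threshold=opt.oi_threshold,
        )
        maps.cbf_se = cbf_map(
            np.nan_to_num(dr2), aif, acq.dt, brain & validity,
            oi_threshold=opt.oi_threshold,
        )

    # --- summaries --------------------------------------------------------
    named = {
        "Q": maps.q,
        "VSI": maps.vsi,
        "MTI": maps.mti,
        "rCBV_percent": maps.rcbv * 100.0,
        "D": maps.d,
    }
    if maps.cbf_ge is not None:
        named["CBF_GE"] = maps.cbf_ge
        named["CBF_SE"] = maps.cbf_se
    summaries = summarize_maps(
        named, rois, validity=maps.validity, subject=subject
    )
    vsi_hist = _vsi_histogram(
        maps.vsi, rois.analysis_union() & maps.validity, opt.vsi_hist_max_um
    )

    provenance = {
        "package_version": __version__,
        "options": asdict(opt),
        "acquisition": {
            "te_ge": acq.te_ge,
            "te_se": acq.te_se,
            "dt": acq.dt,
            "n_dynamics": acq.n_dynamics,
            "injection_dynamic": acq.injection_dynamic,
            "baseline_range": list(acq.baseline_range),
        },
        "window": {
            "peak": window.peak_index,
            "start": window.start,
            "end": window.end,
            "clamped": window.clamped,
        },
        "aif_scale": aif.scale,
        "n_voxels_excluded_rcbv": n_excluded,
    }
    provenance["config_hash"] = config_hash(provenance)
    return SubjectResult(
        maps=maps,
        rois=rois,
        summaries=summaries,
        vsi_histogram=vsi_hist,
        aif_fit=aif.fit,
        window=window,
        aif_scale=aif.scale,
        provenance=provenance,
    )


def run_subject(
    subject_dir,
    output_dir=None,
    options: PipelineOptions | None = None,
) -> SubjectResult:
    """File-based subject analysis.

    ``subject_dir`` must contain ge.nii.gz, se.nii.gz, dwi.nii.gz,
    dwi.bval, labels.nii.gz and acquisition.yaml (the layout
    :func:`vaimri.io.write_phantom_subject` emits).  Validation happens
    before any computation; outputs are the seven maps, the per-ROI CSV,
    the VSI histogram and a provenance JSON.
    """
    from .relaxometry import Contrast, DynamicSeries

    sdir = Path(subject_dir)
    paths = {
        name: sdir / name
        for name in (
            "ge.nii.gz",
            "se.nii.gz",
            "dwi.nii.gz",
            "dwi.bval",
            "labels.nii.gz",
            "acquisition.yaml",
        )
    }
    missing = [str(p) for p in paths.values() if not p.exists()]
    if missing:
        raise PipelineError("validation", f"missing inputs: {missing}")
    acq = acquisition_from_config(load_yaml(paths["acquisition.yaml"]))
    ge_data, affine = load_nifti(paths["ge.nii.gz"])
    se_data, _ = load_nifti(paths["se.nii.gz"])
    dwi, _ = load_nifti(paths["dwi.nii.gz"])
    bvals = read_bvals(paths["dwi.bval"])
    labels, _ = load_nifti(paths["labels.nii.gz"])
    truth_path = sdir / "truth.json"
    voxel_size = (1.0, 1.0, 1.0)
    if truth_path.exists():
        import json

        with open(truth_path) as fh:
            voxel_size = tuple(json.load(fh).get("voxel_size", voxel_size))
    roi_set = ROISet.from_label_map(labels.astype(int), voxel_size=voxel_size)
    ge = DynamicSeries(data=ge_data, contrast=Contrast.GE, params=acq)
    se = DynamicSeries(data=se_data, contrast=Contrast.SE, params=acq)
    result = run_subject_data(
        ge, se, dwi, bvals, roi_set, options=options, subject=sdir.name
    )
    result.provenance["input_checksums"] = {
        k: sha256_of_file(p) for k, p in paths.items()
    }

    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        m = result.maps
        for name, arr in (
            ("q", m.q),
            ("vsi", m.vsi),
            ("mti", m.mti),
            ("rcbv", m.rcbv),
            ("cbf_ge", m.cbf_ge),
            ("cbf_se", m.cbf_se),
            ("d", m.d),
        ):
            if arr is not None:
                save_nifti(out / f"{name}.nii.gz", arr, affine)
        result.summaries.to_csv(out / "roi_summary.csv", index=False)
        result.vsi_histogram.to_csv(out / "vsi_histogram.csv", index=False)
        import json

        with open(out / "provenance.json", "w") as fh:
            json.dump(result.provenance, fh, indent=2, default=str)
    return result


def run_cohort(
    table: pd.DataFrame,
    metrics=("Q", "VSI", "MTI"),
    rois=("NAWM", "DGM", "CGM"),
    interaction: bool = False,
) -> dict:
    """Group statistics on a stacked subject table.

    For each metric x ROI: univariable regression on group, multivariable
    on group + age + sex (optionally with a group x age interaction);
    paired NAWM-vs-WMH tests within patients; independent tests on any
    ``IQR_VSI_<roi>`` columns.  Returns dict with 'regressions' (tidy
    DataFrame), 'paired', 'iqr' DataFrames and a formatted 'report'.
    """
    if table["group"].nunique() < 2:
        raise ValueError("cohort must contain both groups")
    if (table["group"].value_counts() < 2).any():
        raise ValueError("need at least 2 subjects per group")
    uni: dict[str, list] = {}
    multi: dict[str, list] = {}
    inter: dict[str, list] = {}
    for metric in metrics:
        for roi in rois:
            col = f"{metric}_{roi}"
            if col not in table:
                continue
            y = table[col].to_numpy(float)
            uni[col] = ols_fit(y, table[["group"]])
            multi[col] = ols_fit(y, table[["group", "age", "sex"]])
            if interaction:
                inter[col] = interaction_model(
                    y, table["group"], table["age"], table["sex"]
                )
    frames = []
    for name, res in (("univariable", uni), ("multivariable", multi),
                      ("interaction", inter)):
        if res:
            t = regression_table(res)
            t.insert(0, "model", name)
            frames.append(t)
    regressions = pd.concat(frames, ignore_index=True)

    patients = table[table["group"] == 1]
    paired_rows = []
    for metric in metrics:
        a, b = f"{metric}_WMH", f"{metric}_NAWM"
        if a in patients and b in patients:
            sub = patients[[a, b]].dropna()
            if len(sub) >= 2:
                t, df, p = paired_ttest(sub[a], sub[b])
                paired_rows.append(
                    {"metric": metric, "contrast": "WMH-NAWM", "t": t,
                     "df": df, "p_value": p, "n": len(sub)}
                )
    paired = pd.DataFrame(paired_rows)

    iqr_rows = []
    for col in table.columns:
        if col.startswith("IQR_"):
            a = table.loc[table["group"] == 1, col].dropna()
            b = table.loc[table["group"] == 0, col].dropna()
            if len(a) >= 2 and len(b) >= 2:
                t, df, p = independent_ttest(a, b)
                iqr_rows.append(
                    {"measure": col, "t": t, "df": df, "p_value": p,
                     "mean_patients": a.mean(), "mean_controls": b.mean()}
                )
    iqr = pd.DataFrame(iqr_rows)

    from .stats import format_regression_report

    report = format_regression_report(regressions)
    return {
        "regressions": regressions,
        "paired": paired,
        "iqr": iqr,
        "report": report,
    }
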