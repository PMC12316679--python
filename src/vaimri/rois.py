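"""ROI construction and per-ROI summaries.

Analysis regions are cortical gray matter (CGM), deep gray matter (DGM),
normal-appearing white matter (NAWM) and white matter hyperintensities
(WMH).  Construction applies three rules before any statistics: WMH voxels
are removed from NAWM, a 1 cm periventricular zone is excluded from NAWM
(periventricular white matter composition differs systematically between
patients and controls), and manually segmented lesions (infarcts,
hemorrhages, venous anomalies, cavernomas) are removed from every analysis
ROI.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt

logger = logging.getLogger(__name__)

ANALYSIS_ROIS = ("CGM", "DGM", "NAWM", "WMH")
ALL_LABELS = ANALYSIS_ROIS + ("VENTRICLES", "ARTERIES", "EXCLUDE_LESION")

# integer codes used in label-map NIfTI files
LABEL_CODES = {
    "CGM": 1,
    "DGM": 2,
    "NAWM": 3,
    "WMH": 4,
    "VENTRICLES": 5,
    "ARTERIES": 6,
    "EXCLUDE_LESION": 7,
}


@dataclass
class ROISet:
    """Named binary masks on one voxel grid with physical voxel size (mm)."""

    labels: dict[str, np.ndarray]
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        shapes = {m.shape for m in self.labels.values()}
        if len(shapes) > 1:
            raise ValueError(f"masks on different grids: {shapes}")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel size must be positive")
        self.labels = {k: np.asarray(v, bool) for k, v in self.labels.items()}

    def __getitem__(self, name: str) -> np.ndarray:
        return self.labels[name]

    def get(self, name: str) -> np.ndarray | None:
        return self.labels.get(name)

    @classmethod
    def from_label_map(
        cls,
        label_map: np.ndarray,
        voxel_size=(1.0, 1.0, 1.0),
        codes: dict[str, int] = LABEL_CODES,
    ) -> "ROISet":
        label_map = np.asarray(label_map)
        return cls(
            labels={name: label_map == code for name, code in codes.items()},
            voxel_size=tuple(voxel_size),
        )

    def analysis_union(self) -> np.ndarray:
        """Union of the four analysis ROIs."""
        out = np.zeros(next(iter(self.labels.values())).shape, bool)
        for name in ANALYSIS_ROIS:
            if name in self.labels:
                out |= self.labels[name]
        return out


def periventricular_exclusion(
    nawm_mask: np.ndarray,
    ventricle_mask: np.ndarray,
    distance_mm: float = 10.0,
    voxel_size=(1.0, 1.0, 1.0),
) -> np.ndarray:
    """Remove NAWM voxels within ``distance_mm`` of the ventricles.

    Distance is the 3D Euclidean distance transform from the ventricle
    mask, center-to-center in mm (anisotropy-aware).  The boundary is
    inclusive: a voxel exactly at ``distance_mm`` is excluded.  An empty
    ventricle mask returns NAWM unchanged with a warning.
    """
    nawm = np.asarray(nawm_mask, bool)
    vent = np.asarray(ventricle_mask, bool)
    if nawm.shape != vent.shape:
        raise ValueError(
            f"grid mismatch: NAWM {nawm.shape} vs ventricles {vent.shape}"
        )
    if not vent.any():
        warnings.warn(
            "empty ventricle mask: NAWM returned unchanged", stacklevel=2
        )
        return nawm.copy()
    dist = distance_transform_edt(~vent, sampling=voxel_size)
    return nawm & (dist > distance_mm)


def apply_lesion_exclusions(roi_set: ROISet) -> ROISet:
    """Subtract the manual lesion-exclusion mask from every analysis ROI."""
    excl = roi_set.get("EXCLUDE_LESION")
    if excl is None:
        raise ValueError("ROISet has no EXCLUDE_LESION mask")
    labels = dict(roi_set.labels)
    for name in ANALYSIS_ROIS:
        if name not in labels:
            continue
        before = int(labels[name].sum())
        labels[name] = labels[name] & ~excl
        removed = before - int(labels[name].sum())
        logger.info("lesion exclusion removed %d voxels from %s", removed, name)
    return ROISet(labels=labels, voxel_size=roi_set.voxel_size)


def build_analysis_rois(
    roi_set: ROISet, periventricular_mm: float = 10.0
) -> ROISet:
    """Full ROI construction: NAWM minus WMH, periventricular exclusion,
    lesion exclusion.  Idempotent."""
    labels = dict(roi_set.labels)
    if "NAWM" in labels and "WMH" in labels:
        labels["NAWM"] = labels["NAWM"] & ~labels["WMH"]
    if "NAWM" in labels and "VENTRICLES" in labels:
        labels["NAWM"] = periventricular_exclusion(
            labels["NAWM"],
            labels["VENTRICLES"],
            distance_mm=periventricular_mm,
            voxel_size=roi_set.voxel_size,
        )
    out = ROISet(labels=labels, voxel_size=roi_set.voxel_size)
    if out.get("EXCLUDE_LESION") is not None:
        out = apply_lesion_exclusions(out)
    return out


@dataclass
class RoiSummary:
    """Summary statistics of one metric over one ROI."""

    roi: str
    metric: str
    mean: float
    sd: float
    median: float
    iqr: float
    n_voxels: int


def roi_summary(
    map_3d: np.ndarray, mask: np.ndarray, roi: str = "", metric: str = ""
) -> RoiSummary | None:
    """Mean, SD (n-1), median and IQR of valid map voxels inside the mask.

    Quantiles use the linear-interpolation rule (IQR = Q3 - Q1).  Returns
    None with a warning when no valid voxel falls inside the mask.
    """
    vals = np.asarray(map_3d, dtype=float)[np.asarray(mask, bool)]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        warnings.warn(f"no valid voxels for {metric} in {roi}", stacklevel=2)
        return None
    q1, med, q3 = np.percentile(vals, [25, 50, 75])
    return RoiSummary(
        roi=roi,
        metric=metric,
        mean=float(vals.mean()),
        sd=float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
        median=float(med),
        iqr=float(q3 - q1),
        n_voxels=int(vals.size),
    )


def summarize_maps(
    maps: dict[str, np.ndarray],
    roi_set: ROISet,
    validity: np.ndarray | None = None,
    rois=ANALYSIS_ROIS,
    subject: str | None = None,
) -> pd.DataFrame:
    """Long-format summary table: one row per ROI x metric."""
    rows = []
    for roi in rois:
        mask = roi_set.get(roi)
        if mask is None:
            continue
        if validity is not None:
            mask = mask & np.asarray(validity, bool)
        for metric, arr in maps.items():
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                s = roi_summary(arr, mask, roi=roi, metric=metric)
            if s is None:
                continue
            row = {
                "roi": s.roi,
                "metric": s.metric,
                "mean": s.mean,
                "sd": s.sd,
                "median": s.median,
                "iqr": s.iqr,
                "n_voxels": s.n_voxels,
            }
            if subject is not None:
                row = {"subject": subject, **row}
            rows.append(row)
    return pd.DataFrame(rows)
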