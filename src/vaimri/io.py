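"""File I/O: NIfTI volumes, acquisition/pipeline configuration, phantom
subject layout.

All volumes are treated as voxel-grid aligned (0-based indices); NIfTI
affines are carried through untouched and never used to resample.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .relaxometry import AcquisitionParams


def load_nifti(path) -> tuple[np.ndarray, np.ndarray]:
    """Return (data as float64 array, affine)."""
    img = nib.load(str(path))
    return np.asarray(img.get_fdata(), dtype=float), img.affine


def save_nifti(path, data: np.ndarray, affine: np.ndarray | None = None) -> None:
    """Write a float32 NIfTI (maps) or int16 (label volumes)."""
    data = np.asarray(data)
    if np.issubdtype(data.dtype, np.integer) or data.dtype == bool:
        out = data.astype(np.int16)
    else:
        out = data.astype(np.float32)
    img = nib.Nifti1Image(out, affine if affine is not None else np.eye(4))
    nib.save(img, str(path))


_ACQ_KEYS = {
    "te_ge_s": "te_ge",
    "te_se_s": "te_se",
    "dt_s": "dt",
    "n_dynamics": "n_dynamics",
    "injection_dynamic": "injection_dynamic",
    "baseline_range": "baseline_range",
}


def acquisition_from_config(cfg: dict) -> AcquisitionParams:
    """Build AcquisitionParams from config keys (te_ge_s, te_se_s, dt_s,
    n_dynamics, injection_dynamic, baseline_range); unknown keys rejected."""
    unknown = set(cfg) - set(_ACQ_KEYS)
    if unknown:
        raise ValueError(f"unknown acquisition keys: {sorted(unknown)}")
    kwargs = {}
    for key, attr in _ACQ_KEYS.items():
        if key in cfg:
            val = cfg[key]
            kwargs[attr] = tuple(val) if attr == "baseline_range" else val
    return AcquisitionParams(**kwargs)


def acquisition_to_config(acq: AcquisitionParams) -> dict:
    return {
        "te_ge_s": acq.te_ge,
        "te_se_s": acq.te_se,
        "dt_s": acq.dt,
        "n_dynamics": acq.n_dynamics,
        "injection_dynamic": acq.injection_dynamic,
        "baseline_range": list(acq.baseline_range),
    }


def load_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def save_yaml(path, obj: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)


def sha256_of_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()


def write_phantom_subject(dataset, out_dir) -> Path:
    """Write a phantom subject in the layout the pipeline consumes.

    Emits GE/SE/DWI NIfTI volumes, an FSL-style bval table, the integer
    label mask, an acquisition config and a truth.json with the
    per-tissue ground-truth parameters.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_nifti(out / "ge.nii.gz", dataset.ge.data)
    save_nifti(out / "se.nii.gz", dataset.se.data)
    save_nifti(out / "dwi.nii.gz", dataset.dwi)
    np.savetxt(out / "dwi.bval", dataset.bvals[None, :], fmt="%g")
    save_nifti(out / "labels.nii.gz", dataset.truth["labels"])
    save_yaml(
        out / "acquisition.yaml",
        acquisition_to_config(dataset.config.acquisition),
    )
    truth_tissues = {
        name: {
            "q": tp.q,
            "rcbv": tp.rcbv,
            "d": tp.d,
            "mtt": tp.mtt,
            "tau_se": tp.tau_se,
        }
        for name, tp in dataset.config.tissues.items()
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(
            {
                "tissues": truth_tissues,
                "seed": dataset.config.seed,
                "snr": None
                if not np.isfinite(dataset.config.snr)
                else dataset.config.snr,
                "voxel_size": list(dataset.config.voxel_size),
            },
            fh,
            indent=2,
        )
    return out
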