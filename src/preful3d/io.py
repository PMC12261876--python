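"""File-level interfaces: NIfTI volumes, CSV tables, JSON reports.

Directory layout written by the ``simulate`` stage and consumed by ``map``:

    out/
      config_used.yaml
      manifest.json
      cohort.csv                      # one row per measurement, with paths
      meas/<subject>__<scanner>__m<k>/
        images.nii.gz                 # 4D phase-resolved series (RAS+)
        parenchyma_mask.nii.gz  vessel_mask.nii.gz
        insp_mask.nii.gz  exp_mask.nii.gz
        sv_true.nii.gz  rvent_true.nii.gz  defect_mask.nii.gz
        navigator.csv                 # timestamp, amplitude, waveform
        meta.json                     # phase indices, voxel size, provenance

The ``map`` stage writes per-measurement derived maps (RVent static, FVL-CM,
binary VV maps, analysis mask) and a cohort ``summaries.csv``; ``stats``
reads those back and writes the report tables.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .gating import GatingSeries
from .synth import GroundTruth, SyntheticMeasurement
from .ventmaps import MeasurementMaps, PhaseResolvedImage

__all__ = [
    "save_nifti",
    "load_nifti",
    "save_measurement",
    "load_measurement",
    "measurement_key",
    "save_maps",
    "load_vv_maps",
]


def _affine(voxel_size) -> np.ndarray:
    """RAS+ affine with the voxel size on the diagonal."""
    return np.diag(list(voxel_size) + [1.0])


def save_nifti(data: np.ndarray, voxel_size, path) -> None:
    arr = np.asarray(data)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    else:
        arr = arr.astype(np.float32)
    nib.save(nib.Nifti1Image(arr, _affine(voxel_size)), str(path))


def load_nifti(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.dataobj), voxel_size


def measurement_key(meas: SyntheticMeasurement) -> str:
    return f"{meas.subject_id}__{meas.scanner}__m{meas.measurement_index}"


def save_measurement(meas: SyntheticMeasurement, directory) -> Path:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    vs = meas.images.voxel_size
    save_nifti(meas.images.data, vs, d / "images.nii.gz")
    save_nifti(meas.parenchyma_mask, vs, d / "parenchyma_mask.nii.gz")
    save_nifti(meas.vessel_mask, vs, d / "vessel_mask.nii.gz")
    save_nifti(meas.insp_lung_mask, vs, d / "insp_mask.nii.gz")
    save_nifti(meas.exp_lung_mask, vs, d / "exp_mask.nii.gz")
    gt = meas.ground_truth
    save_nifti(gt.sv_field, vs, d / "sv_true.nii.gz")
    save_nifti(gt.rvent_true_field, vs, d / "rvent_true.nii.gz")
    save_nifti(gt.defect_mask, vs, d / "defect_mask.nii.gz")
    pd.DataFrame(
        {
            "timestamp": meas.navigator.timestamps,
            "amplitude": meas.navigator.amplitude,
            "waveform": gt.cycle_waveform,
        }
    ).to_csv(d / "navigator.csv", index=False)
    meta = {
        "subject_id": meas.subject_id,
        "scanner": meas.scanner,
        "measurement_index": meas.measurement_index,
        "seed": meas.seed,
        "exp_idx": meas.images.exp_idx,
        "insp_idx": meas.images.insp_idx,
        "voxel_size": list(vs),
        "true_tidal_volume": gt.true_tidal_volume,
        "true_breathing_frequency": gt.true_breathing_frequency,
    }
    (d / "meta.json").write_text(json.dumps(meta, indent=1))
    return d


def load_measurement(directory) -> SyntheticMeasurement:
    d = Path(directory)
    meta = json.loads((d / "meta.json").read_text())
    vs = tuple(meta["voxel_size"])
    data, _ = load_nifti(d / "images.nii.gz")
    images = PhaseResolvedImage(
        data=np.asarray(data, dtype=float),
        voxel_size=vs,
        exp_idx=int(meta["exp_idx"]),
        insp_idx=int(meta["insp_idx"]),
    )
    nav_df = pd.read_csv(d / "navigator.csv")
    navigator = GatingSeries(
        nav_df["timestamp"].to_numpy(), nav_df["amplitude"].to_numpy()
    )
    gt = GroundTruth(
        sv_field=np.asarray(load_nifti(d / "sv_true.nii.gz")[0], dtype=float),
        rvent_true_field=np.asarray(load_nifti(d / "rvent_true.nii.gz")[0], dtype=float),
        defect_mask=np.asarray(load_nifti(d / "defect_mask.nii.gz")[0], dtype=bool),
        cycle_waveform=nav_df["waveform"].to_numpy(),
        true_tidal_volume=float(meta["true_tidal_volume"]),
        true_breathing_frequency=float(meta["true_breathing_frequency"]),
    )
    return SyntheticMeasurement(
        images=images,
        parenchyma_mask=np.asarray(load_nifti(d / "parenchyma_mask.nii.gz")[0], dtype=bool),
        vessel_mask=np.asarray(load_nifti(d / "vessel_mask.nii.gz")[0], dtype=bool),
        insp_lung_mask=np.asarray(load_nifti(d / "insp_mask.nii.gz")[0], dtype=bool),
        exp_lung_mask=np.asarray(load_nifti(d / "exp_mask.nii.gz")[0], dtype=bool),
        navigator=navigator,
        ground_truth=gt,
        subject_id=str(meta["subject_id"]),
        scanner=str(meta["scanner"]),
        measurement_index=int(meta["measurement_index"]),
        seed=int(meta["seed"]),
    )


def save_maps(result: MeasurementMaps, voxel_size, directory) -> Path:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    save_nifti(result.rvent_static, voxel_size, d / "rvent_static.nii.gz")
    save_nifti(result.fvlcm, voxel_size, d / "fvlcm.nii.gz")
    save_nifti(result.vv_rvent, voxel_size, d / "vv_rvent.nii.gz")
    save_nifti(result.vv_fvlcm, voxel_size, d / "vv_fvlcm.nii.gz")
    save_nifti(result.analysis_mask, voxel_size, d / "analysis_mask.nii.gz")
    return d


def load_vv_maps(directory) -> dict[str, np.ndarray]:
    d = Path(directory)
    return {
        "vv_rvent": np.asarray(load_nifti(d / "vv_rvent.nii.gz")[0], dtype=bool),
        "vv_fvlcm": np.asarray(load_nifti(d / "vv_fvlcm.nii.gz")[0], dtype=bool),
        "mask": np.asarray(load_nifti(d / "analysis_mask.nii.gz")[0], dtype=bool),
    }
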