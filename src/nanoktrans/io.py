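"""Reading and writing studies, maps and sidecars.

Volumes travel as NIfTI (via nibabel); acquisition metadata and ground
truth as JSON/CSV sidecars next to the image files. A saved study
directory contains::

    series.nii.gz     4D magnitude series
    rois.nii.gz       integer ROI label volume
    meta.json         TR, frame times, flip angles, baseline indices, tracer
    truth_rois.csv    per-ROI ground-truth parameters (synthetic data only)
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import DynamicStudy, TracerProperties
from .synth import SceneTruth

__all__ = ["save_study", "load_study", "save_volume", "load_volume"]


def save_volume(data: np.ndarray, path: str | Path) -> Path:
    """Write an array as NIfTI with identity affine."""
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(data), affine=np.eye(4))
    nib.save(img, str(path))
    return path


def load_volume(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata())


def save_study(
    study: DynamicStudy, out_dir: str | Path, truth: SceneTruth | None = None
) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_volume(study.series, out / "series.nii.gz")
    save_volume(study.rois.astype(np.int16), out / "rois.nii.gz")
    meta = {
        "times_s": study.times_s.tolist(),
        "tr_s": study.tr_s,
        "flip_angles_deg": study.flip_angles_deg.tolist(),
        "baseline_indices": list(study.baseline_indices),
        "tracer": asdict(study.tracer),
    }
    (out / "meta.json").write_text(json.dumps(meta, indent=2))
    if truth is not None:
        truth.roi_params.to_csv(out / "truth_rois.csv", index=False)
    return out


def load_study(study_dir: str | Path) -> DynamicStudy:
    d = Path(study_dir)
    meta = json.loads((d / "meta.json").read_text())
    return DynamicStudy(
        series=load_volume(d / "series.nii.gz"),
        times_s=np.asarray(meta["times_s"]),
        tr_s=float(meta["tr_s"]),
        flip_angles_deg=np.asarray(meta["flip_angles_deg"]),
        baseline_indices=tuple(meta["baseline_indices"]),
        rois=load_volume(d / "rois.nii.gz").astype(np.int16),
        tracer=TracerProperties(**meta["tracer"]),
    )
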