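"""Dynamic R1, delta-R1 and concentration mapping.

The dynamic frames (single flip angle) are inverted voxel-by-voxel to
R1(t) using the baseline M0 map, and converted to tracer concentration
by the linear relaxation law C(t) = (R1(t) - R1_0) / r. Negative
concentrations arising from noise are kept (clipping would bias the
downstream kinetic fits) and only flagged in summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.typing import NDArray

from .core import ROI_LABELS, DynamicStudy, TracerProperties, spgr_invert_r1
from .relaxometry import BaselineMaps

__all__ = [
    "ConcentrationSeries",
    "compute_dynamic_r1",
    "compute_concentration",
    "summarize_roi_concentration",
]


@dataclass
class ConcentrationSeries:
    """Per-voxel concentration time course with its provenance maps.

    ``c`` and ``delta_r1`` have shape (nx, ny, nz, n_dynamic);
    ``times_s`` are the dynamic frame times (injection at t = 0).
    ``valid`` marks voxel/frame pairs where the signal inversion was
    well-posed; ``voxel_valid`` collapses it over frames.
    """

    c: NDArray[np.floating]
    delta_r1: NDArray[np.floating]
    r1: NDArray[np.floating]
    r1_0: NDArray[np.floating]
    times_s: NDArray[np.floating]
    valid: NDArray[np.bool_]
    unit: str = "mM"

    @property
    def times_min(self) -> NDArray[np.floating]:
        return self.times_s / 60.0

    @property
    def voxel_valid(self) -> NDArray[np.bool_]:
        return self.valid.all(axis=-1)

    @property
    def negative_fraction(self) -> float:
        """Fraction of valid voxel/frame samples with C < 0 (noise floor)."""
        v = self.valid
        return float((self.c[v] < 0).mean()) if v.any() else 0.0


def compute_dynamic_r1(
    study: DynamicStudy, baseline: BaselineMaps
) -> tuple[NDArray[np.floating], NDArray[np.bool_]]:
    """Invert the dynamic SPGR frames to R1(t) per voxel.

    Uses the baseline M0 map and the (single) dynamic flip angle; frames
    whose implied E1 leaves (0, 1) and voxels with invalid baselines are
    masked. Returns (r1_t, valid) with shape (..., n_dynamic).
    """
    dyn_idx = study.dynamic_indices
    angles = study.flip_angles_deg[dyn_idx]
    if np.ptp(angles) != 0:
        raise ValueError("dynamic frames must share a single flip angle")
    flip = float(angles[0])
    signal = study.series[..., dyn_idx]
    r1, valid = spgr_invert_r1(signal, baseline.m0[..., None], study.tr_s, flip)
    valid = valid & baseline.valid[..., None]
    r1 = np.where(valid, r1, np.nan)
    return r1, valid


def compute_concentration(
    r1_series: NDArray[np.floating],
    valid: NDArray[np.bool_],
    baseline: BaselineMaps,
    tracer: TracerProperties,
    times_s: NDArray[np.floating],
) -> ConcentrationSeries:
    """Convert R1(t) to concentration: C(t) = (R1(t) - R1_0) / r."""
    delta_r1 = r1_series - baseline.r1_0[..., None]
    c = delta_r1 / tracer.r1_relaxivity
    return ConcentrationSeries(
        c=c,
        delta_r1=delta_r1,
        r1=r1_series,
        r1_0=baseline.r1_0,
        times_s=np.asarray(times_s, dtype=float),
        valid=valid & baseline.valid[..., None],
        unit=tracer.concentration_unit,
    )


def concentration_from_study(
    study: DynamicStudy, baseline: BaselineMaps
) -> ConcentrationSeries:
    """Convenience chain: dynamic inversion then concentration mapping."""
    r1, valid = compute_dynamic_r1(study, baseline)
    return compute_concentration(
        r1, valid, baseline, study.tracer, study.dynamic_times_s
    )


def summarize_roi_concentration(
    conc: ConcentrationSeries,
    rois: NDArray[np.integer],
    roi_names: dict[str, int] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean concentration time course and final-frame mean per ROI.

    The "final concentration" is the mean over the last acquired frame
    (the end of the ~1 h session). Returns (timecourses, final) frames;
    timecourses has columns roi, frame, time_s, mean, sd, n_voxels.
    """
    roi_names = roi_names or {k: v for k, v in ROI_LABELS.items() if v > 0}
    rows = []
    final_rows = []
    for name, lab in roi_names.items():
        mask = (rois == lab) & conc.voxel_valid
        if not np.any(rois == lab):
            raise ValueError(f"ROI {name!r} (label {lab}) is empty")
        traces = conc.c[mask]  # (n_voxels, n_frames)
        n = traces.shape[0]
        mean = traces.mean(axis=0)
        sd = traces.std(axis=0, ddof=1) if n > 1 else np.zeros(traces.shape[1])
        for j, t in enumerate(conc.times_s):
            rows.append(
                {
                    "roi": name,
                    "frame": j,
                    "time_s": t,
                    "mean": mean[j],
                    "sd": sd[j],
                    "n_voxels": n,
                }
            )
        final_rows.append(
            {
                "roi": name,
                "final_mean": mean[-1],
                "final_sd": sd[-1],
                "n_voxels": n,
                "negative_fraction": float((traces < 0).mean()),
            }
        )
    return pd.DataFrame(rows), pd.DataFrame(final_rows)
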