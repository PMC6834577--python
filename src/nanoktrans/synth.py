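"""Synthetic DCE-MRI study generation with known ground truth.

Everything the analysis pipeline consumes can be generated here: multi-TR
relaxivity phantoms, dual-flip-angle baselines and a full 4D dynamic
study driven by a biexponential plasma curve and single-compartment
tissue kinetics. Each generator returns the rendered data together with
the ground truth it was rendered from, so every downstream stage can be
validated by parameter recovery.

Acquisition defaults mirror a small-animal protocol at 9.4 T: SPGR with
TR = 54.24 ms, two pre-injection baselines at flip angles 10 deg / 30 deg,
then ~100 post-injection frames at 34 s per frame (about an hour), all
post-injection frames at 30 deg.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.typing import ArrayLike, NDArray

from .core import (
    ROI_LABELS,
    DynamicStudy,
    GroundTruthScene,
    PlasmaParams,
    TracerProperties,
    TRACERS,
    expconv,
    saturation_recovery_signal,
    spgr_signal,
)

__all__ = [
    "PhantomSeries",
    "SceneTruth",
    "simulate_phantom_series",
    "simulate_plasma_curve",
    "simulate_tissue_curve",
    "render_dynamic_study",
    "default_scene",
]


@dataclass
class PhantomSeries:
    """Multi-TR phantom acquisition: one tube per concentration.

    ``signals`` has shape (n_tubes, n_voxels, n_tr): each tube is imaged
    as a small ROI of voxels at every TR. ``truth`` records the per-tube
    concentration and T1 used to render the signals.
    """

    signals: NDArray[np.floating]
    tr_s: NDArray[np.floating]
    concentrations: NDArray[np.floating]
    truth: pd.DataFrame

    def tube_means(self) -> NDArray[np.floating]:
        """ROI-mean signal per tube and TR, shape (n_tubes, n_tr)."""
        return self.signals.mean(axis=1)


def simulate_phantom_series(
    concentrations: ArrayLike,
    base_r1_s: float,
    r1_relaxivity: float,
    tr_list_s: ArrayLike,
    noise_sigma: float = 0.0,
    seed: int | None = None,
    s0: float = 1.0,
    voxels_per_tube: int = 25,
) -> PhantomSeries:
    """Render a saturation-recovery phantom series for relaxivity calibration.

    Each tube holds the agent at one concentration C; its relaxation rate
    is R1 = base_r1 + r * C and its signal at repetition time TR follows
    S = S0 (1 - exp(-TR * R1)). Additive Gaussian noise of standard
    deviation ``noise_sigma`` (same units as S0) is applied per voxel.
    """
    conc = np.asarray(concentrations, dtype=float)
    tr = np.asarray(tr_list_s, dtype=float)
    if tr.size == 0:
        raise ValueError("TR list must be non-empty")
    if np.any(tr <= 0):
        bad = tr[tr <= 0][0]
        raise ValueError(f"TR values must be positive, got {bad}")
    if np.any(conc < 0):
        raise ValueError("concentrations must be non-negative")
    if r1_relaxivity <= 0 or base_r1_s <= 0:
        raise ValueError("base R1 and relaxivity must be positive")
    r1 = base_r1_s + r1_relaxivity * conc
    clean = saturation_recovery_signal(
        s0, 1.0 / r1[:, None, None], tr[None, None, :]
    )
    clean = np.broadcast_to(clean, (len(conc), voxels_per_tube, len(tr))).copy()
    rng = np.random.default_rng(seed)
    signals = clean + rng.normal(0.0, noise_sigma, clean.shape) if noise_sigma > 0 else clean
    truth = pd.DataFrame(
        {
            "tube": np.arange(len(conc)),
            "concentration": conc,
            "r1_s": r1,
            "t1_s": 1.0 / r1,
            "s0": s0,
        }
    )
    return PhantomSeries(signals=signals, tr_s=tr, concentrations=conc, truth=truth)


def simulate_plasma_curve(
    times_min: ArrayLike, plasma: PlasmaParams
) -> NDArray[np.floating]:
    """Evaluate the biexponential plasma curve on a time grid (minutes).

    Cp(t) = A exp(-alpha t) + B exp(-beta t) from injection (t = 0)
    onward; zero before injection. Phase ordering (alpha >= beta) is
    enforced by :class:`PlasmaParams`.
    """
    t = np.asarray(times_min, dtype=float)
    cp = plasma.a * np.exp(-plasma.alpha * t) + plasma.b * np.exp(-plasma.beta * t)
    return np.where(t < 0, 0.0, cp)


def simulate_tissue_curve(
    plasma: PlasmaParams | tuple[ArrayLike, ArrayLike],
    times_s: ArrayLike,
    ktrans: float,
    ve: float,
    fine_dt_s: float = 1.0,
) -> NDArray[np.floating]:
    """Single-compartment tissue response to the plasma curve.

    Ct(T) = ktrans * int_0^T Cp(t) exp(-(ktrans/ve)(T - t)) dt, with
    ktrans in min^-1 and ve dimensionless. No plasma-volume term: the
    fitted reference-region model has none, so the generator matches it.

    The convolution is evaluated on an internal fine grid (``fine_dt_s``
    seconds per step) and sampled at the requested frame times, which
    keeps forward-model discretization error far below fitting
    tolerances at 34 s frame spacing.

    ``plasma`` is either a :class:`PlasmaParams` or a pre-sampled
    ``(times_s, values)`` pair (interpolated onto the fine grid).
    """
    if ktrans < 0:
        raise ValueError("ktrans must be non-negative")
    if ktrans > 0 and ve <= 0:
        raise ValueError("ve = 0 with ktrans > 0 implies infinite washout rate")
    if not 0 <= ve <= 1 and ktrans > 0:
        raise ValueError("ve must lie in (0, 1]")
    t = np.asarray(times_s, dtype=float)
    if ktrans == 0:
        return np.zeros_like(t)
    t_end = float(t.max())
    fine = np.arange(0.0, t_end + fine_dt_s, fine_dt_s)
    if fine[-1] < t_end:
        fine = np.append(fine, t_end)
    if isinstance(plasma, PlasmaParams):
        cp_fine = simulate_plasma_curve(fine / 60.0, plasma)
    else:
        pt, pv = (np.asarray(a, dtype=float) for a in plasma)
        cp_fine = np.interp(fine, pt, pv)
    kep_per_s = (ktrans / ve) / 60.0
    ct_fine = (ktrans / 60.0) * expconv(fine, cp_fine, kep_per_s)
    return np.interp(t, fine, ct_fine)


@dataclass
class SceneTruth:
    """Ground-truth sidecar for a rendered study.

    ``c_true`` holds the noiseless concentration of every voxel at the
    dynamic frame times (shape nx, ny, nz, n_dynamic); ``r1_true`` the
    corresponding R1(t) in s^-1; ``roi_params`` the per-ROI kinetic
    parameters; ``plasma_true`` the plasma curve at the frame times.
    """

    c_true: NDArray[np.floating]
    r1_true: NDArray[np.floating]
    r1_0: NDArray[np.floating]
    plasma_true: NDArray[np.floating]
    roi_params: pd.DataFrame


def _unique_param_curves(
    scene: GroundTruthScene,
) -> tuple[NDArray[np.intp], NDArray[np.floating]]:
    """Concentration curves for each unique (ktrans, ve) pair in the scene.

    Returns (index map into curves for every voxel, curves array of shape
    (n_unique, n_frames)). Vessel voxels are handled by the caller.
    """
    pairs = np.stack([scene.ktrans.ravel(), scene.ve.ravel()], axis=1)
    uniq, inverse = np.unique(pairs, axis=0, return_inverse=True)
    curves = np.zeros((len(uniq), len(scene.frame_times_s)))
    for i, (kt, ve) in enumerate(uniq):
        if kt > 0:
            curves[i] = simulate_tissue_curve(
                scene.plasma, scene.frame_times_s, kt, ve, scene.fine_dt_s
            )
    return inverse.reshape(scene.shape), curves


def render_dynamic_study(
    scene: GroundTruthScene,
) -> tuple[DynamicStudy, SceneTruth]:
    """Render a 4D SPGR magnitude series from a ground-truth scene.

    Frame layout: two baseline frames (both flip angles, pre-injection,
    C = 0) followed by the dynamic frames at the single dynamic angle.
    Per voxel, R1(t) = R1_0 + r * C(t) and the SPGR steady-state signal
    is evaluated at the frame's flip angle. Vessel voxels carry the
    plasma curve; background voxels are air (zero signal). Noise is
    additive Gaussian on the magnitude by default (Rician optional),
    seeded by the scene seed, so renders are reproducible bit-for-bit.
    """
    nt_dyn = len(scene.frame_times_s)
    idx_map, curves = _unique_param_curves(scene)
    c_true = curves[idx_map]  # (nx, ny, nz, nt_dyn)
    plasma_true = simulate_plasma_curve(scene.frame_times_s / 60.0, scene.plasma)
    vessel = scene.labels == ROI_LABELS["vessel"]
    c_true[vessel] = plasma_true
    background = scene.labels == ROI_LABELS["background"]
    c_true[background] = 0.0

    with np.errstate(divide="ignore"):
        r1_0 = np.where(background, np.nan, 1.0 / scene.t1_0_s)
    r1_true = r1_0[..., None] + scene.tracer.r1_relaxivity * c_true

    dt = float(np.min(np.diff(scene.frame_times_s))) if nt_dyn > 1 else 34.0
    baseline_times = np.array([-2.0 * dt, -dt])
    times = np.concatenate([baseline_times, scene.frame_times_s])
    angles = np.concatenate(
        [np.asarray(scene.baseline_flip_deg, dtype=float),
         np.full(nt_dyn, scene.dynamic_flip_deg)]
    )

    series = np.zeros(scene.shape + (nt_dyn + 2,))
    tissue = ~background
    m0_map = np.where(tissue, scene.m0, 0.0)
    for j, ang in enumerate(scene.baseline_flip_deg):
        series[..., j] = np.where(
            tissue, spgr_signal(m0_map, np.nan_to_num(r1_0), scene.tr_s, ang), 0.0
        )
    dyn = spgr_signal(
        m0_map[..., None],
        np.nan_to_num(r1_true),
        scene.tr_s,
        scene.dynamic_flip_deg,
    )
    series[..., 2:] = np.where(tissue[..., None], dyn, 0.0)

    if scene.noise_sigma > 0:
        rng = np.random.default_rng(scene.seed)
        if scene.noise_model == "gaussian":
            series = series + rng.normal(0.0, scene.noise_sigma, series.shape)
        else:  # rician magnitude: two orthogonal gaussian channels
            re = series + rng.normal(0.0, scene.noise_sigma, series.shape)
            im = rng.normal(0.0, scene.noise_sigma, series.shape)
            series = np.hypot(re, im)

    study = DynamicStudy(
        series=series,
        times_s=times,
        tr_s=scene.tr_s,
        flip_angles_deg=angles,
        baseline_indices=(0, 1),
        rois=scene.labels.copy(),
        tracer=scene.tracer,
    )
    rows = []
    for name, lab in ROI_LABELS.items():
        mask = scene.labels == lab
        if not np.any(mask):
            continue
        rows.append(
            {
                "roi": name,
                "label": lab,
                "n_voxels": int(mask.sum()),
                "ktrans_true": float(np.mean(scene.ktrans[mask])),
                "ve_true": float(np.mean(scene.ve[mask])),
                "t1_0_s": float(np.mean(scene.t1_0_s[mask])),
            }
        )
    truth = SceneTruth(
        c_true=c_true,
        r1_true=r1_true,
        r1_0=r1_0,
        plasma_true=plasma_true,
        roi_params=pd.DataFrame(rows),
    )
    return study, truth


def _block(mask: NDArray, x: slice, y: slice) -> None:
    mask[x, y, :] = True


def default_scene(
    tracer: str | TracerProperties = "PLGA",
    focal_ktrans: float = 0.170,
    focal_ve: float = 0.30,
    contralateral_ktrans: float = 0.00135,
    contralateral_ve: float = 0.05,
    reference_ktrans: float = 0.10,
    reference_ve: float = 0.10,
    plasma: PlasmaParams | None = None,
    shape: tuple[int, int, int] = (64, 64, 3),
    n_frames: int = 100,
    frame_dt_s: float = 34.0,
    noise_sigma: float = 0.002,
    noise_model: str = "gaussian",
    seed: int = 0,
) -> GroundTruthScene:
    """Construct the default synthetic study.

    A 64 x 64 x 3 grid shaped like a downsampled mouse-brain acquisition:
    a focal-injury block, a contralateral block, a muscular reference
    region and a small vessel, embedded in air. Default kinetics place a
    two-orders-of-magnitude permeability contrast between the focal
    injury and the intact contralateral hemisphere; muscle kinetics
    equal the reference-region constants assumed by the fitting stage.

    The default plasma curve uses distribution/elimination half-lives of
    3.1 / 44 min (rates ln2 / t_half) with amplitudes A = 0.5,
    B = 0.25 in the tracer's concentration unit.
    """
    tr_props = TRACERS[tracer] if isinstance(tracer, str) else tracer
    shape = tuple(int(s) for s in shape)
    if plasma is None:
        plasma = PlasmaParams(
            a=0.5, alpha=np.log(2) / 3.12, b=0.25, beta=np.log(2) / 44.02
        )
    nx, ny, nz = shape
    labels = np.zeros(shape, dtype=np.int16)

    def blk(cx: float, cy: float, half: float) -> tuple[slice, slice]:
        x0 = max(int(cx - half), 0)
        y0 = max(int(cy - half), 0)
        # at least one voxel wide even on coarse grids
        x1 = min(max(int(cx + half), x0 + 1), nx)
        y1 = min(max(int(cy + half), y0 + 1), ny)
        return slice(x0, x1), slice(y0, y1)

    focal = np.zeros(shape, dtype=bool)
    _block(focal, *blk(nx * 0.28, ny * 0.30, nx * 0.08))
    contra = np.zeros(shape, dtype=bool)
    _block(contra, *blk(nx * 0.72, ny * 0.30, nx * 0.08))
    reference = np.zeros(shape, dtype=bool)
    _block(reference, *blk(nx * 0.30, ny * 0.75, nx * 0.08))
    vessel = np.zeros(shape, dtype=bool)
    _block(vessel, *blk(nx * 0.70, ny * 0.75, nx * 0.03))
    labels[focal] = ROI_LABELS["focal"]
    labels[contra] = ROI_LABELS["contralateral"]
    labels[reference] = ROI_LABELS["reference"]
    labels[vessel] = ROI_LABELS["vessel"]

    t1_0 = np.full(shape, 1.8)  # brain-like T1 at high field, s
    t1_0[reference] = 1.9  # muscle
    t1_0[vessel] = 2.4  # blood
    ktrans = np.zeros(shape)
    ve = np.full(shape, 0.1)
    ktrans[focal] = focal_ktrans
    ve[focal] = focal_ve
    ktrans[contra] = contralateral_ktrans
    ve[contra] = contralateral_ve
    ktrans[reference] = reference_ktrans
    ve[reference] = reference_ve

    return GroundTruthScene(
        shape=shape,
        t1_0_s=t1_0,
        ktrans=ktrans,
        ve=ve,
        labels=labels,
        tracer=tr_props,
        plasma=plasma,
        frame_times_s=frame_dt_s * np.arange(1, n_frames + 1),
        noise_sigma=noise_sigma,
        noise_model=noise_model,
        seed=seed,
    )
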