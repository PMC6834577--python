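"""Core domain types and MR signal primitives shared across the pipeline.

The pipeline quantifies contrast-agent (nanoparticle or small-molecule)
delivery from dynamic contrast-enhanced MRI:

* spoiled gradient-echo (SPGR) signal model, used both to render synthetic
  studies and to invert measured signal to the longitudinal relaxation
  rate R1 = 1/T1;
* saturation-recovery signal model for multi-TR phantom relaxometry;
* exact convolution of a sampled curve with an exponential kernel, the
  workhorse integral of single-compartment tracer kinetics.

Units: relaxation rates are s^-1 everywhere in this module; kinetic rate
constants (ktrans, kep, plasma phase rates) are min^-1 and live in the
kinetics / plasma modules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import ArrayLike, NDArray


@dataclass(frozen=True)
class TracerProperties:
    """Contrast-agent properties relevant to concentration quantification.

    Parameters
    ----------
    name : str
        Agent label, e.g. ``"PLGA"`` or ``"Gd-DTPA"``.
    r1_relaxivity : float
        Longitudinal relaxivity r1, the slope of R1 versus concentration,
        in s^-1 per concentration unit (see ``concentration_unit``).
    r2_over_r1 : float, optional
        Transverse-to-longitudinal relaxivity ratio; metadata only, the
        pipeline models pure T1 enhancement.
    dose : str, optional
        Injected dose, free text (metadata).
    concentration_unit : str
        Unit tag the relaxivity refers to (``"mM"`` or ``"mg/mL"``).
        Carried through to outputs, never converted between agents.
    """

    name: str
    r1_relaxivity: float
    r2_over_r1: float | None = None
    dose: str | None = None
    concentration_unit: str = "mM"

    def __post_init__(self) -> None:
        if not self.r1_relaxivity > 0:
            raise ValueError(
                f"r1_relaxivity must be positive, got {self.r1_relaxivity}"
            )


#: Agents characterized at 9.4 T. Relaxivities are with respect to the
#: concentration unit in the tag; for PLGA the mM refers to Gd in the
#: particle, for the other particles to the contrast agent itself.
TRACERS: dict[str, TracerProperties] = {
    "Cj-1": TracerProperties("Cj-1", 2.60, 12.3, "0.9 mg/mouse", "mM"),
    "PLGA": TracerProperties("PLGA", 4.78, 5.32, "0.2 mg/mouse", "mM"),
    "Pro-NP": TracerProperties("Pro-NP", 2.63, 42.0, "2 mg/mouse", "mM"),
    "Gd-DTPA": TracerProperties("Gd-DTPA", 4.1, 1.12, "0.05 umol/mouse", "mM"),
}


@dataclass(frozen=True)
class PlasmaParams:
    """Biexponential plasma (blood) concentration model.

    Cp(t) = A exp(-alpha t) + B exp(-beta t) for t >= 0, zero before
    injection. ``alpha`` is the distribution-phase rate and ``beta`` the
    elimination-phase rate, both in min^-1 with alpha >= beta > 0.
    Amplitudes are in the tracer's concentration unit.
    """

    a: float
    alpha: float
    b: float
    beta: float

    def __post_init__(self) -> None:
        if self.a < 0 or self.b < 0:
            raise ValueError("plasma amplitudes must be non-negative")
        if not (self.alpha > 0 and self.beta > 0):
            raise ValueError("plasma rates must be positive")
        if self.alpha < self.beta:
            raise ValueError(
                "distribution rate alpha must not be slower than elimination "
                f"rate beta (got alpha={self.alpha}, beta={self.beta}); "
                "phases are not identifiable as labelled"
            )


@dataclass
class DynamicStudy:
    """A 4D magnitude image series with its acquisition metadata.

    ``series`` has shape (nx, ny, nz, nframes). Baseline (pre-injection)
    frames carry negative times and their own flip angles; injection is
    at t = 0.
    """

    series: NDArray[np.floating]
    times_s: NDArray[np.floating]
    tr_s: float
    flip_angles_deg: NDArray[np.floating]
    baseline_indices: tuple[int, ...]
    rois: NDArray[np.integer]
    tracer: TracerProperties

    def __post_init__(self) -> None:
        self.series = np.asarray(self.series, dtype=float)
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.flip_angles_deg = np.asarray(self.flip_angles_deg, dtype=float)
        nt = self.series.shape[-1]
        if not (len(self.times_s) == len(self.flip_angles_deg) == nt):
            raise ValueError("times and flip angles must match frame count")
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def dynamic_indices(self) -> NDArray[np.intp]:
        mask = np.ones(self.series.shape[-1], dtype=bool)
        mask[list(self.baseline_indices)] = False
        return np.flatnonzero(mask)

    @property
    def dynamic_times_s(self) -> NDArray[np.floating]:
        return self.times_s[self.dynamic_indices]


# ROI label conventions used throughout; 0 is background (air).
ROI_LABELS = {
    "background": 0,
    "focal": 1,
    "contralateral": 2,
    "reference": 3,
    "vessel": 4,
}


def spgr_signal(
    m0: ArrayLike, r1_s: ArrayLike, tr_s: float, flip_deg: ArrayLike
) -> NDArray[np.floating]:
    """Steady-state spoiled gradient-echo magnitude signal.

    S = M0 sin(a) (1 - E1) / (1 - E1 cos(a)), with E1 = exp(-TR * R1).
    """
    a = np.deg2rad(np.asarray(flip_deg, dtype=float))
    e1 = np.exp(-tr_s * np.asarray(r1_s, dtype=float))
    return np.asarray(m0) * np.sin(a) * (1.0 - e1) / (1.0 - e1 * np.cos(a))


def spgr_invert_r1(
    signal: ArrayLike, m0: ArrayLike, tr_s: float, flip_deg: float
) -> tuple[NDArray[np.floating], NDArray[np.bool_]]:
    """Invert the SPGR equation for R1 at a known flip angle and M0.

    Solving S = M0 sin(a)(1-E1)/(1-E1 cos(a)) for E1 gives
    E1 = (S - M0 sin a) / (S cos a - M0 sin a); R1 = -ln(E1)/TR.

    Returns (r1, valid). Entries where E1 falls outside (0, 1) or M0 <= 0
    are invalid (set to NaN).
    """
    s = np.asarray(signal, dtype=float)
    m0 = np.asarray(m0, dtype=float)
    a = np.deg2rad(flip_deg)
    denom = s * np.cos(a) - m0 * np.sin(a)
    with np.errstate(divide="ignore", invalid="ignore"):
        e1 = np.where(denom != 0, (s - m0 * np.sin(a)) / denom, np.nan)
        valid = (m0 > 0) & np.isfinite(e1) & (e1 > 0) & (e1 < 1)
        r1 = np.where(valid, -np.log(np.where(valid, e1, 1.0)) / tr_s, np.nan)
    return r1, valid


def saturation_recovery_signal(
    s0: ArrayLike, t1_s: ArrayLike, tr_s: ArrayLike
) -> NDArray[np.floating]:
    """Saturation-recovery signal S = S0 (1 - exp(-TR / T1))."""
    return np.asarray(s0) * -np.expm1(
        -np.asarray(tr_s, dtype=float) / np.asarray(t1_s, dtype=float)
    )


def expconv(
    times: ArrayLike, curve: ArrayLike, rate: float
) -> NDArray[np.floating]:
    """Convolve a sampled curve with an exponential decay kernel.

    Computes y(T_i) = integral_{t_0}^{T_i} c(u) exp(-rate (T_i - u)) du,
    treating ``curve`` as piecewise linear between samples. Each segment
    integral is evaluated in closed form, so the result is exact for
    piecewise-linear input at any kernel rate — including rates fast
    relative to the sampling interval, where naive trapezoidal weighting
    of the kernel breaks down.

    ``times`` and 1/``rate`` must share the same time unit; ``rate`` may
    be 0 (plain cumulative integral).
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(curve, dtype=float)
    if t.ndim != 1 or c.shape != t.shape:
        raise ValueError("times and curve must be matching 1-D arrays")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if rate < 0:
        raise ValueError("kernel rate must be non-negative")
    dt = np.diff(t)
    x = rate * dt
    e = np.exp(-x)
    # phi = (1-e^-x)/x, psi = (x-(1-e^-x))/x^2; series below x ~ 1e-4
    # keeps both stable through x -> 0 (pure trapezoid limit).
    small = x < 1e-4
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = np.where(small, 1.0 - x / 2.0 + x * x / 6.0, -np.expm1(-x) / np.where(small, 1.0, x))
        psi = np.where(
            small, 0.5 - x / 6.0 + x * x / 24.0, (x + np.expm1(-x)) / np.where(small, 1.0, x * x)
        )
    seg = dt * (c[:-1] * phi + (c[1:] - c[:-1]) * psi)
    out = np.empty_like(c)
    out[0] = 0.0
    acc = 0.0
    for i in range(len(dt)):
        acc = acc * e[i] + seg[i]
        out[i + 1] = acc
    return out


@dataclass
class GroundTruthScene:
    """Fully specified synthetic study: geometry, tissue, kinetics, noise.

    Per-voxel maps (``t1_0_s``, ``ktrans``, ``ve``) share the 3-D grid
    ``shape``; ``labels`` assigns each voxel to one of the ROI classes in
    :data:`ROI_LABELS`. Kinetic rates are min^-1; ve is the fractional
    extravascular-extracellular volume in (0, 1]. Vessel voxels carry the
    plasma curve itself rather than a tissue response.
    """

    shape: tuple[int, int, int]
    t1_0_s: NDArray[np.floating]
    ktrans: NDArray[np.floating]
    ve: NDArray[np.floating]
    labels: NDArray[np.integer]
    tracer: TracerProperties
    plasma: PlasmaParams
    frame_times_s: NDArray[np.floating]
    baseline_flip_deg: tuple[float, float] = (10.0, 30.0)
    dynamic_flip_deg: float = 30.0
    tr_s: float = 0.05424
    m0: float = 1.0
    noise_sigma: float = 0.002
    noise_model: str = "gaussian"
    seed: int = 0
    fine_dt_s: float = 1.0

    def __post_init__(self) -> None:
        for name in ("t1_0_s", "ktrans", "ve", "labels"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != tuple(self.shape):
                raise ValueError(f"{name} shape {arr.shape} != scene {self.shape}")
            setattr(self, name, arr)
        self.frame_times_s = np.asarray(self.frame_times_s, dtype=float)
        self.validate()

    def validate(self) -> None:
        tissue = self.labels > 0
        if np.any(self.t1_0_s[tissue] <= 0):
            raise ValueError("T1_0 must be positive in tissue")
        if np.any(self.ktrans[tissue] < 0):
            raise ValueError("ktrans must be non-negative")
        ve_t = self.ve[tissue]
        if np.any((ve_t <= 0) | (ve_t > 1)):
            raise ValueError("ve must lie in (0, 1] in tissue")
        kt = self.ktrans[tissue]
        if np.any((kt > 0) & (self.ve[tissue] <= 0)):
            raise ValueError("ve = 0 with ktrans > 0 implies infinite washout")
        for roi in ("reference", "vessel"):
            if not np.any(self.labels == ROI_LABELS[roi]):
                raise ValueError(f"{roi} region must be non-empty")
        if np.any(np.diff(self.frame_times_s) <= 0):
            raise ValueError("frame times must be strictly increasing")
        if np.any(self.frame_times_s <= 0):
            raise ValueError("dynamic frame times must follow injection (t=0)")
        if len(self.baseline_flip_deg) != 2:
            raise ValueError("exactly two baseline flip angles are required")
        if self.noise_model not in ("gaussian", "rician"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
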