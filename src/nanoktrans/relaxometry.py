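"""Relaxivity calibration and baseline T1/M0 mapping.

Two acquisitions feed this module:

* a multi-TR phantom series, from which per-tube T1 is estimated by the
  saturation-recovery model S = S0 (1 - exp(-TR/T1)) and the agent's
  relaxivity r by the linear law R1 = r C + b;
* the two pre-injection baseline frames of the dynamic study, acquired
  at two flip angles, from which per-voxel R1_0 and M0 follow in closed
  form from the variable-flip-angle (VFA) slope-intercept relation
  S/sin(a) = E1 * S/tan(a) + M0 (1 - E1).

All rates are s^-1 here; the kinetics module converts to min^-1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import ArrayLike, NDArray
from scipy import optimize, stats

__all__ = [
    "SaturationRecoveryFit",
    "RelaxivityFit",
    "BaselineMaps",
    "fit_saturation_recovery",
    "fit_relaxivity",
    "fit_vfa_baseline",
]

T1_BOUNDS_S = (1e-3, 20.0)


@dataclass
class SaturationRecoveryFit:
    """T1 estimate from signals at multiple repetition times."""

    t1_s: float
    s0: float
    residual_norm: float
    tr_s: NDArray[np.floating]
    converged: bool
    message: str = ""


@dataclass
class RelaxivityFit:
    """Linear fit of R1 against concentration: R1 = r C + b."""

    relaxivity: float
    intercept: float
    r_squared: float
    concentration_unit: str = "mM"
    n_points: int = 0


@dataclass
class BaselineMaps:
    """Per-voxel pre-contrast R1_0 (s^-1) and M0 from the two-angle VFA fit."""

    r1_0: NDArray[np.floating]
    m0: NDArray[np.floating]
    valid: NDArray[np.bool_]
    flip_angles_deg: tuple[float, float] = (10.0, 30.0)
    tr_s: float = 0.05424

    @property
    def n_invalid(self) -> int:
        return int((~self.valid).sum())


def fit_saturation_recovery(
    signals: ArrayLike, tr_list_s: ArrayLike
) -> SaturationRecoveryFit:
    """Fit S = S0 (1 - exp(-TR/T1)) to signals observed at several TRs.

    Nonlinear least squares with T1 initialized at half the longest TR
    and S0 at the largest signal; T1 bounded to (1 ms, 20 s). A fit on
    signals that carry no TR dependence (T1 unidentifiable) is returned
    with ``converged=False`` and a diagnostic message rather than a
    silent NaN.
    """
    s = np.asarray(signals, dtype=float)
    tr = np.asarray(tr_list_s, dtype=float)
    if s.shape != tr.shape or s.ndim != 1:
        raise ValueError("signals and TR list must be matching 1-D arrays")
    if len(np.unique(tr)) < 2:
        raise ValueError("at least two distinct TR values are required")
    if np.any(s < 0):
        raise ValueError("signals must be non-negative")

    smax = float(s.max())
    if smax <= 0 or np.ptp(s) < 1e-12 * max(smax, 1.0):
        return SaturationRecoveryFit(
            t1_s=np.nan,
            s0=smax,
            residual_norm=np.nan,
            tr_s=tr,
            converged=False,
            message="signals carry no TR dependence; T1 unidentifiable",
        )

    def resid(p: NDArray) -> NDArray:
        s0, t1 = p
        return s0 * -np.expm1(-tr / t1) - s

    x0 = np.array([smax, 0.5 * tr.max()])
    sol = optimize.least_squares(
        resid,
        x0,
        bounds=([0.0, T1_BOUNDS_S[0]], [np.inf, T1_BOUNDS_S[1]]),
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    return SaturationRecoveryFit(
        t1_s=float(sol.x[1]),
        s0=float(sol.x[0]),
        residual_norm=float(np.linalg.norm(sol.fun)),
        tr_s=tr,
        converged=bool(sol.success),
        message="" if sol.success else sol.message,
    )


def fit_relaxivity(
    t1_per_tube_s: ArrayLike,
    concentrations: ArrayLike,
    concentration_unit: str = "mM",
) -> RelaxivityFit:
    """Ordinary least-squares line of R1 = 1/T1 against concentration.

    The slope is the agent's relaxivity r (s^-1 per concentration unit);
    the intercept absorbs the solvent's own relaxation rate.
    """
    t1 = np.asarray(t1_per_tube_s, dtype=float)
    conc = np.asarray(concentrations, dtype=float)
    if t1.shape != conc.shape:
        raise ValueError("T1 and concentration arrays must match")
    if t1.size < 3:
        raise ValueError("relaxivity fit requires at least 3 tubes")
    if np.ptp(conc) == 0:
        raise ValueError("concentrations are constant; slope undefined")
    res = stats.linregress(conc, 1.0 / t1)
    return RelaxivityFit(
        relaxivity=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        concentration_unit=concentration_unit,
        n_points=int(t1.size),
    )


def fit_vfa_baseline(
    signal_angle1: ArrayLike,
    signal_angle2: ArrayLike,
    angles_deg: tuple[float, float],
    tr_s: float,
) -> BaselineMaps:
    """Closed-form two-point VFA estimation of R1_0 and M0 per voxel.

    With exactly two angles the slope-intercept VFA relation is solved
    directly: the two points (S/tan a, S/sin a) define a line whose
    slope is E1 = exp(-TR R1) and whose intercept is M0 (1 - E1).
    Voxels where E1 falls outside (0, 1), or with non-positive signal at
    both angles, are masked invalid (NaN in the maps).
    """
    a1, a2 = (np.deg2rad(a) for a in angles_deg)
    if not (0 < a1 <= np.pi / 2 and 0 < a2 <= np.pi / 2) or a1 == a2:
        raise ValueError("two distinct flip angles in (0, 90] degrees required")
    if tr_s <= 0:
        raise ValueError("TR must be positive")
    s1 = np.asarray(signal_angle1, dtype=float)
    s2 = np.asarray(signal_angle2, dtype=float)
    x1, y1 = s1 / np.tan(a1), s1 / np.sin(a1)
    x2, y2 = s2 / np.tan(a2), s2 / np.sin(a2)
    dx = x2 - x1
    with np.errstate(divide="ignore", invalid="ignore"):
        e1 = np.where(dx != 0, (y2 - y1) / dx, np.nan)
        valid = np.isfinite(e1) & (e1 > 0) & (e1 < 1) & ((s1 > 0) | (s2 > 0))
        e1v = np.where(valid, e1, 0.5)
        r1_0 = np.where(valid, -np.log(e1v) / tr_s, np.nan)
        m0 = np.where(valid, (y1 - e1v * x1) / (1.0 - e1v), np.nan)
    valid = valid & np.where(np.isfinite(m0), m0 > 0, False)
    r1_0 = np.where(valid, r1_0, np.nan)
    m0 = np.where(valid, m0, np.nan)
    return BaselineMaps(
        r1_0=r1_0,
        m0=m0,
        valid=valid,
        flip_angles_deg=tuple(float(np.rad2deg(a)) for a in (a1, a2)),
        tr_s=tr_s,
    )
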