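"""Plasma pharmacokinetics from vessel ROIs.

The carotid-artery concentration curve is fit to a biexponential

    Cp(t) = A exp(-alpha t) + B exp(-beta t)

from the observed peak onward (the rising limb is contaminated by the
injection duration). The fast phase (alpha) is the distribution phase
and the slow phase (beta) the elimination phase; per-phase half-lives
and elimination constants obey t_half = ln 2 / rate, equivalently
K_el = ln 2 / t_half. The area under the concentration-time curve is a
trapezoidal integral over the imaging session.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import ArrayLike, NDArray
from scipy import optimize

from .concentration import ConcentrationSeries

__all__ = ["PlasmaFit", "extract_plasma_curve", "fit_biexponential", "compute_auc"]

LN2 = float(np.log(2.0))


@dataclass
class PlasmaFit:
    """Biexponential plasma fit with derived half-lives and rate constants.

    Amplitudes in the tracer's concentration unit, rates in min^-1,
    half-lives in minutes, AUC-compatible time base in minutes.
    ``kel_dist``/``kel_elim`` equal ln2 / t_half per phase, which for a
    pure exponential phase is the phase rate itself.
    """

    a: float
    alpha: float
    b: float
    beta: float
    rss: float
    converged: bool
    flag: str = ""  # "", "monoexponential", "swapped_phases"
    window_min: tuple[float, float] = (0.0, 0.0)

    @property
    def t_half_dist(self) -> float:
        return LN2 / self.alpha

    @property
    def t_half_elim(self) -> float:
        return LN2 / self.beta

    @property
    def kel_dist(self) -> float:
        return LN2 / self.t_half_dist

    @property
    def kel_elim(self) -> float:
        return LN2 / self.t_half_elim


def extract_plasma_curve(
    conc: ConcentrationSeries, vessel_mask: NDArray[np.bool_]
) -> NDArray[np.floating]:
    """Voxel-mean concentration over the vessel ROI (all marked slices)."""
    mask = np.asarray(vessel_mask, dtype=bool) & conc.voxel_valid
    if not mask.any():
        raise ValueError("vessel mask is empty (or fully invalid)")
    return conc.c[mask].mean(axis=0)


def _strip_init(t: NDArray, y: NDArray) -> tuple[float, float, float, float]:
    """Curve-stripping start values: log-linear tail for the slow phase,
    log-linear positive residual for the fast phase."""
    n_tail = max(len(t) // 3, 3)
    tt, yt = t[-n_tail:], y[-n_tail:]
    pos = yt > 0
    if pos.sum() >= 2:
        slope, inter = np.polyfit(tt[pos], np.log(yt[pos]), 1)
        beta0 = max(-slope, 1e-4)
        b0 = max(float(np.exp(inter)), 1e-12)
    else:
        beta0, b0 = 0.02, max(float(y[-1]), 1e-12)
    resid = y - b0 * np.exp(-beta0 * t)
    pos = resid > 0
    if pos.sum() >= 2:
        slope, inter = np.polyfit(t[pos], np.log(resid[pos]), 1)
        alpha0 = max(-slope, 2 * beta0)
        a0 = max(float(np.exp(inter)), 1e-12)
    else:
        alpha0, a0 = 10 * beta0, max(float(y[0] - b0), 1e-12)
    return a0, alpha0, b0, beta0


def fit_biexponential(
    plasma: ArrayLike, times_min: ArrayLike
) -> PlasmaFit:
    """Nonlinear least-squares biexponential fit of the plasma curve.

    Fitting starts at the observed peak frame. If the two phases come
    out mislabelled (alpha < beta) they are swapped and flagged; if a
    single exponential fits within 1% of the biexponential residual sum
    of squares, the phases are unidentifiable and the fit is flagged
    ``"monoexponential"``.
    """
    y_all = np.asarray(plasma, dtype=float)
    t_all = np.asarray(times_min, dtype=float)
    if y_all.shape != t_all.shape or y_all.ndim != 1:
        raise ValueError("plasma curve and times must be matching 1-D arrays")
    peak = int(np.argmax(y_all))
    if y_all[peak] <= 0:
        raise ValueError("plasma curve has no positive peak")
    t, y = t_all[peak:], y_all[peak:]
    if len(t) < 6:
        raise ValueError("at least 6 post-peak frames are required")

    a0, alpha0, b0, beta0 = _strip_init(t, y)

    def resid(p: NDArray) -> NDArray:
        a, alpha, b, beta = p
        return a * np.exp(-alpha * t) + b * np.exp(-beta * t) - y

    sol = optimize.least_squares(
        resid,
        [a0, alpha0, b0, beta0],
        bounds=([0, 1e-6, 0, 1e-6], [np.inf, np.inf, np.inf, np.inf]),
        xtol=1e-14,
        ftol=1e-14,
    )
    a, alpha, b, beta = (float(v) for v in sol.x)
    flag = ""
    if alpha < beta:
        a, alpha, b, beta = b, beta, a, alpha
        flag = "swapped_phases"
    rss = float(np.sum(sol.fun**2))

    # mono-exponential comparison: phases unidentifiable if it fits as well
    def resid1(p: NDArray) -> NDArray:
        return p[0] * np.exp(-p[1] * t) - y

    sol1 = optimize.least_squares(
        resid1, [y[0], max(beta, 1e-4)], bounds=([0, 1e-6], [np.inf, np.inf])
    )
    rss1 = float(np.sum(sol1.fun**2))
    scale = float(np.sum(y**2))
    if b <= 1e-10 * max(a, 1.0) or a <= 1e-10 * max(b, 1.0) or (
        rss1 <= rss + 0.01 * scale and rss1 <= 1.01 * max(rss, 1e-300)
    ):
        flag = "monoexponential"
        a, alpha = (float(sol1.x[0]), float(sol1.x[1]))
        b, beta = 0.0, alpha
        rss = rss1

    return PlasmaFit(
        a=a,
        alpha=alpha,
        b=b,
        beta=beta,
        rss=rss,
        converged=bool(sol.success),
        flag=flag,
        window_min=(float(t[0]), float(t[-1])),
    )


def compute_auc(
    plasma: ArrayLike,
    times_min: ArrayLike,
    window_min: tuple[float, float] | None = None,
) -> float:
    """Trapezoidal area under the concentration-time curve.

    ``window_min`` defaults to the full sampled range; its endpoints
    must lie within the acquired times (values at interior endpoints are
    linearly interpolated). Result is in min x concentration unit.
    """
    y = np.asarray(plasma, dtype=float)
    t = np.asarray(times_min, dtype=float)
    if y.shape != t.shape or y.ndim != 1:
        raise ValueError("plasma curve and times must be matching 1-D arrays")
    if window_min is None:
        window_min = (float(t[0]), float(t[-1]))
    lo, hi = window_min
    if lo < t[0] or hi > t[-1] or lo >= hi:
        raise ValueError(
            f"window {window_min} outside acquired times [{t[0]}, {t[-1]}]"
        )
    inside = (t > lo) & (t < hi)
    tt = np.concatenate([[lo], t[inside], [hi]])
    yy = np.concatenate([[np.interp(lo, t, y)], y[inside], [np.interp(hi, t, y)]])
    return float(np.trapezoid(yy, tt))
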