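"""End-to-end pipeline orchestration, group statistics and fold tables.

``run_pipeline`` chains baseline mapping -> dynamic R1 -> concentration
-> reference-region K^trans -> plasma pharmacokinetics on a (synthetic
or loaded) study and writes volumes, summary tables and a reproducible
run manifest. Group comparisons use one-way ANOVA followed by Tukey's
HSD post-test (Tukey-Kramer for unequal group sizes) at the 0.05 level.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import __version__
from .concentration import concentration_from_study, summarize_roi_concentration
from .core import ROI_LABELS, PlasmaParams, TracerProperties, TRACERS
from .io import save_study, save_volume
from .kinetics import RRMConfig, map_ktrans
from .plasma_pk import compute_auc, extract_plasma_curve, fit_biexponential
from .relaxometry import fit_vfa_baseline
from .synth import default_scene, render_dynamic_study

__all__ = ["PipelineError", "GroupComparison", "run_pipeline", "compare_groups", "emit_fold_table"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name for context."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class GroupComparison:
    """One-way ANOVA across groups with Tukey HSD pairwise post-test."""

    groups: pd.DataFrame  # group, n, mean, sd
    f_statistic: float
    p_value: float
    tukey: pd.DataFrame  # group_a, group_b, p_adj, significant
    alpha: float = 0.05
    excluded: list[str] = field(default_factory=list)


def _tracer_from_config(cfg: dict) -> TracerProperties:
    entry = cfg.get("tracer", "PLGA")
    if isinstance(entry, str):
        return TRACERS[entry]
    if "r1_relaxivity" not in entry:
        raise PipelineError("config", "tracer is missing required field 'r1_relaxivity'")
    return TracerProperties(**entry)


def run_pipeline(
    config: dict | str | Path, out_dir: str | Path, seed: int | None = None
) -> dict:
    """Run the whole analysis on a synthetic scene described by ``config``.

    ``config`` is a mapping (or a YAML file path) with optional keys
    ``scene`` (arguments of :func:`nanoktrans.synth.default_scene`,
    ``tracer`` may be a name or a property mapping, ``plasma`` a mapping
    of A/alpha/B/beta) and ``rrm`` (reference-region constants). ``seed``
    overrides the scene seed. Writes K^trans/ve/ratio volumes, ROI
    time-course and summary CSVs, the plasma fit, and a JSON manifest;
    returns the in-memory results.
    """
    if not isinstance(config, dict):
        config = yaml.safe_load(Path(config).read_text())
    config = config or {}
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    scene_cfg = dict(config.get("scene", {}))
    if seed is not None:
        scene_cfg["seed"] = int(seed)
    tracer = _tracer_from_config(scene_cfg) if "tracer" in scene_cfg else TRACERS["PLGA"]
    scene_cfg["tracer"] = tracer
    if isinstance(scene_cfg.get("plasma"), dict):
        scene_cfg["plasma"] = PlasmaParams(**scene_cfg["plasma"])

    try:
        scene = default_scene(**scene_cfg)
        study, truth = render_dynamic_study(scene)
    except Exception as e:  # noqa: BLE001 - re-raise with stage context
        raise PipelineError("simulate", str(e)) from e
    save_study(study, out / "study", truth)

    try:
        b_idx = study.baseline_indices
        baseline = fit_vfa_baseline(
            study.series[..., b_idx[0]],
            study.series[..., b_idx[1]],
            tuple(study.flip_angles_deg[list(b_idx)]),
            study.tr_s,
        )
    except Exception as e:
        raise PipelineError("baseline", str(e)) from e

    try:
        conc = concentration_from_study(study, baseline)
        timecourses, final = summarize_roi_concentration(conc, study.rois)
    except Exception as e:
        raise PipelineError("concentration", str(e)) from e

    try:
        rrm_cfg = RRMConfig(**config.get("rrm", {}))
        kres = map_ktrans(conc, study.rois, rrm_cfg)
    except Exception as e:
        raise PipelineError("ktrans", str(e)) from e

    try:
        cp = extract_plasma_curve(conc, study.rois == ROI_LABELS["vessel"])
        pk = fit_biexponential(cp, conc.times_min)
        auc = compute_auc(cp, conc.times_min)
    except Exception as e:
        raise PipelineError("plasma_pk", str(e)) from e

    save_volume(baseline.r1_0, out / "r1_0.nii.gz")
    save_volume(kres.ktrans, out / "ktrans.nii.gz")
    save_volume(kres.ve, out / "ve.nii.gz")
    save_volume(kres.ratio, out / "ktrans_ratio.nii.gz")
    timecourses.to_csv(out / "roi_timecourses.csv", index=False)
    plot_roi_timecourses(timecourses, out / "roi_timecourses.png", unit=conc.unit)
    final.to_csv(out / "final_concentration.csv", index=False)
    kres.summary.to_csv(out / "ktrans_summary.csv", index=False)
    pk_row = pd.DataFrame(
        [
            {
                "a": pk.a,
                "alpha": pk.alpha,
                "b": pk.b,
                "beta": pk.beta,
                "t_half_dist_min": pk.t_half_dist,
                "kel_dist": pk.kel_dist,
                "t_half_elim_min": pk.t_half_elim,
                "kel_elim": pk.kel_elim,
                "auc": auc,
                "unit": conc.unit,
                "flag": pk.flag,
            }
        ]
    )
    pk_row.to_csv(out / "pk_table.csv", index=False)

    manifest = {
        "package_version": __version__,
        "seed": int(scene.seed),
        "tracer": tracer.name,
        "scene": {
            k: (v if isinstance(v, (int, float, str, list, tuple)) else str(v))
            for k, v in scene_cfg.items()
        },
        "rrm": {"ktrans_rr": rrm_cfg.ktrans_rr, "ve_rr": rrm_cfg.ve_rr},
        "outputs": sorted(p.name for p in out.iterdir()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))

    return {
        "scene": scene,
        "study": study,
        "truth": truth,
        "baseline": baseline,
        "concentration": conc,
        "timecourses": timecourses,
        "final_concentration": final,
        "ktrans": kres,
        "plasma_fit": pk,
        "auc": auc,
    }


def plot_roi_timecourses(
    timecourses: pd.DataFrame, path: str | Path, unit: str = "mM"
) -> Path:
    """Mean concentration-versus-time figure, one line per ROI (PNG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for roi, sub in timecourses.groupby("roi"):
        ax.plot(sub["time_s"] / 60.0, sub["mean"], label=roi)
    ax.set_xlabel("time post injection (min)")
    ax.set_ylabel(f"mean concentration ({unit})")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def compare_groups(
    values: pd.DataFrame,
    value_col: str = "value",
    group_col: str = "group",
    alpha: float = 0.05,
) -> GroupComparison:
    """One-way ANOVA followed by Tukey's HSD across the groups in a table.

    Groups with fewer than two observations are excluded with a warning
    (small unbalanced groups are common in animal studies; the test
    proceeds on what remains). Requires at least two usable groups.
    """
    samples: dict[str, np.ndarray] = {}
    excluded: list[str] = []
    for g, sub in values.groupby(group_col, sort=True):
        x = np.asarray(sub[value_col], dtype=float)
        if len(x) < 2:
            excluded.append(str(g))
            warnings.warn(f"group {g!r} has n < 2; excluded from comparison")
        else:
            samples[str(g)] = x
    if len(samples) < 2:
        raise ValueError("at least two groups with n >= 2 are required")
    names = list(samples)
    arrays = [samples[n] for n in names]
    f, p = stats.f_oneway(*arrays)
    hsd = stats.tukey_hsd(*arrays)
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            p_adj = float(hsd.pvalue[i, j])
            rows.append(
                {
                    "group_a": names[i],
                    "group_b": names[j],
                    "p_adj": p_adj,
                    "significant": p_adj < alpha,
                }
            )
    groups = pd.DataFrame(
        {
            "group": names,
            "n": [len(a) for a in arrays],
            "mean": [float(np.mean(a)) for a in arrays],
            "sd": [float(np.std(a, ddof=1)) for a in arrays],
        }
    )
    return GroupComparison(
        groups=groups,
        f_statistic=float(f),
        p_value=float(p),
        tukey=pd.DataFrame(rows),
        alpha=alpha,
        excluded=excluded,
    )


def emit_fold_table(summaries: pd.DataFrame) -> pd.DataFrame:
    """Focal/contralateral fold ratios per tracer (and per measure).

    ``summaries`` needs columns ``tracer``, ``focal`` and
    ``contralateral`` (an optional ``measure`` column distinguishes
    e.g. final concentration from K^trans). Ratios are reported
    unrounded plus display-rounded; a zero contralateral mean yields an
    undefined (NaN) ratio rather than infinity.
    """
    required = {"tracer", "focal", "contralateral"}
    if not required.issubset(summaries.columns):
        raise ValueError(f"summaries must have columns {sorted(required)}")
    out = summaries.copy()
    contra = out["contralateral"].to_numpy(dtype=float)
    focal = out["focal"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.where(contra != 0, focal / contra, np.nan)
    out["fold"] = fold
    out["fold_rounded"] = np.round(fold).astype(object)
    out.loc[~np.isfinite(fold), "fold_rounded"] = None
    return out
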