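import numpy as np
import pytest

from nanoktrans.concentration import concentration_from_study
from nanoktrans.core import PlasmaParams
from nanoktrans.relaxometry import fit_vfa_baseline
from nanoktrans.synth import default_scene, render_dynamic_study


@pytest.fixture(scope="session")
def plasma():
    """Default biexponential plasma parameters (half-lives 3.12 / 44.02 min)."""
    return PlasmaParams(a=0.5, alpha=np.log(2) / 3.12, b=0.25, beta=np.log(2) / 44.02)


@pytest.fixture(scope="session")
def frame_times_s():
    return 34.0 * np.arange(1, 101)


def chain(study):
    """Baseline VFA fit then signal -> R1 -> concentration."""
    i, j = study.baseline_indices
    baseline = fit_vfa_baseline(
        study.series[..., i],
        study.series[..., j],
        tuple(study.flip_angles_deg[[i, j]]),
        study.tr_s,
    )
    return baseline, concentration_from_study(study, baseline)


@pytest.fixture(scope="session")
def small_noiseless():
    """Small noiseless rendered scene with the analysis chain applied."""
    scene = default_scene(shape=(32, 32, 1), noise_sigma=0.0)
    study, truth = render_dynamic_study(scene)
    baseline, conc = chain(study)
    return {
        "scene": scene,
        "study": study,
        "truth": truth,
        "baseline": baseline,
        "conc": conc,
    }
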