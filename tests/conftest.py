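import numpy as np
import pytest

import icgflow as icg
from icgflow.classify import default_candidates  # noqa: F401  (re-export convenience)
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler


def light_candidates():
    """Single fast classifier for CV tests where model choice is not the point."""
    return [
        (
            "logreg",
            Pipeline([("scale", StandardScaler()), ("clf", LogisticRegression(max_iter=2000))]),
        )
    ]


def separable_cohort_config(seed=3, gap_scale=1.0, noise_frac=0.005):
    """Small cohort whose class washout distributions are far apart.

    ``gap_scale`` shrinks/widens the spread of class downslopes around their
    common centre, which dials downstream class separability.
    """
    centre = -0.005
    offsets = {"healthy": -0.007, "benign": -0.001, "cancer": 0.0045}
    slopes = {c: centre + gap_scale * o for c, o in offsets.items()}
    return icg.SyntheticCohortConfig(
        n_patients=12,
        n_benign_patients=5,
        class_counts={"healthy": 30, "benign": 20, "cancer": 40},
        class_kinetics=icg.preset_class_kinetics(slopes, 0.05),
        movement_noise_frac=noise_frac,
        durations=icg.DurationSpec(missing_counts={}, complete_post_peak_s=(405.0, 455.0)),
        seed=seed,
    )


@pytest.fixture(scope="session")
def default_cohort():
    """The clinically anchored 251-ROI cohort (seed 1) plus its ground truth."""
    return icg.generate_cohort(icg.default_cohort_config(seed=1))


@pytest.fixture(scope="session")
def default_features(default_cohort):
    traces, _ = default_cohort
    return icg.prepare_cohort(traces)


@pytest.fixture(scope="session")
def separable_features():
    traces, _ = icg.generate_cohort(separable_cohort_config())
    return icg.prepare_cohort(traces)


def grid_aligned_params(rng, cls, fs=5.0):
    """Sample class-preset kinetics with the peak snapped onto the sample grid
    so discrete milestones admit exact closed-form comparison."""
    base = icg.CLASS_PRESETS[cls].sample(rng)
    onset = round(base.onset_time_s * fs) / fs
    ttp = round(base.time_to_peak_s * fs) / fs
    return icg.KineticParams(
        onset, ttp, base.peak_intensity_gs, base.washout_rate_per_s, base.plateau_fraction
    )
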