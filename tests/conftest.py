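import numpy as np
import pytest

from enoselab import CohortSpec, generate_cohort, representative_curves
from enoselab.features_time import parse_time_index


@pytest.fixture(scope="session")
def small_spec():
    """Tiny cohort on a coarse grid: fast, still divisible by 10/40 windows."""
    return CohortSpec(
        n_per_group=5, n_sweeps=3, layers=3, temp_step_c=2.0,
        effect_layer=2, effect_window=(90.0, 100.0), effect_size=3.0, seed=42,
    )


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return generate_cohort(small_spec)


@pytest.fixture(scope="session")
def small_curves(small_spec, small_cohort):
    return representative_curves(small_cohort, small_spec.grid())


@pytest.fixture(scope="session")
def default_spec():
    """Full-size study-design cohort: 2x20 subjects, 10 sweeps, 3 layers."""
    return CohortSpec(n_per_group=20, effect_size=3.0, seed=7)


@pytest.fixture(scope="session")
def default_curves(default_spec):
    return representative_curves(generate_cohort(default_spec), default_spec.grid())


def index_hits_effect_window(name: str, features, spec: CohortSpec) -> bool:
    """Does a selected time-domain index localize the injected effect?

    True when the index's covered temperature span on the effect layer
    contains at least one perturbed grid point: subareas cover their own
    window; slope indices cover the p-point window around the group-B mean
    Tmax; whole-curve totals never count as localized.
    """
    info = parse_time_index(name)
    if info["layer"] != spec.effect_layer:
        return False
    lo, hi = spec.effect_window
    step = spec.temp_step_c
    # perturbed grid points (relative degrees), half-open window
    pert = np.arange(np.ceil(lo / step) * step, hi, step)
    if info["kind"] == "subarea":
        w, k = info["width"], info["window"]
        a, b = (k - 1) * w, k * w
        return bool(np.any((pert >= a) & (pert <= b)))
    if info["kind"] in ("max_slope", "tmax_slope"):
        p = info["points"]
        tmax_col = f"Tmax_slope_{p}_S{info['layer']}"
        center = features.loc[features["group"] == "B", tmax_col].mean() - spec.temp_start_c
        half = (p - 1) / 2.0 * step
        return bool(np.any((pert >= center - half) & (pert <= center + half)))
    return False
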