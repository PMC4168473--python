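"""Synthetic cohort generator.

Emulates a two-group skin-odor study: each subject contributes ``n_sweeps``
conductance-vs-temperature sweeps per sensor layer.  Layer baselines are sums
of Gaussian bumps; subjects perturb bump amplitudes (random effect), sweeps
add i.i.d. Gaussian noise, and group "B" receives an additive shift of
``effect_size * subject_sd`` inside a configurable relative-temperature
window on one layer only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .preprocess import SensorSweep, temperature_grid

__all__ = ["CohortSpec", "generate_cohort", "DEFAULT_BASELINES", "GROUP_A", "GROUP_B"]

GROUP_A = "A"  # reference group
GROUP_B = "B"  # effect (positive) group

# (amplitude, center in relative degrees, width in degrees) per bump, per layer.
# Layers cycle through this tuple if spec.layers exceeds its length.
DEFAULT_BASELINES: tuple[tuple[tuple[float, float, float], ...], ...] = (
    ((1.00, 55.0, 24.0), (0.35, 120.0, 30.0)),
    ((0.90, 80.0, 28.0), (0.45, 25.0, 14.0)),
    ((1.10, 100.0, 32.0), (0.40, 140.0, 16.0)),
)

#: constant added to every baseline so curves stay well away from zero
BASELINE_OFFSET = 0.5


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of one synthetic cohort.

    ``effect_window`` is a half-open interval in relative degrees
    (0 == ``temp_start_c``).  ``signal`` selects the recorded quantity:
    ``"conductance"`` (default) or ``"resistance"`` (reciprocal convention).
    """

    n_per_group: int
    n_sweeps: int = 10
    layers: int = 3
    temp_start_c: float = 195.0
    temp_end_c: float = 355.0
    temp_step_c: float = 1.0
    effect_layer: int = 2
    effect_window: tuple[float, float] = (90.0, 100.0)
    effect_size: float = 0.0
    subject_sd: float = 0.1
    sweep_noise_sd: float = 0.05
    seed: int = 0
    signal: str = "conductance"
    baselines: tuple = DEFAULT_BASELINES

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group: need at least 2 subjects per group")
        if self.n_sweeps < 1:
            raise ValueError("n_sweeps: must be positive")
        if self.layers < 1:
            raise ValueError("layers: must be positive")
        if self.temp_end_c <= self.temp_start_c:
            raise ValueError("temp_end_c: must exceed temp_start_c")
        if self.temp_step_c <= 0:
            raise ValueError("temp_step_c: must be positive")
        span = self.temp_end_c - self.temp_start_c
        lo, hi = self.effect_window
        if not (0 <= lo < hi <= span):
            raise ValueError(
                f"effect_window: ({lo}, {hi}) must lie within [0, {span}) with lo < hi"
            )
        if not 1 <= self.effect_layer <= self.layers:
            raise ValueError("effect_layer: outside 1..layers")
        if self.subject_sd < 0:
            raise ValueError("subject_sd: must be non-negative")
        if self.sweep_noise_sd < 0:
            raise ValueError("sweep_noise_sd: must be non-negative")
        if self.signal not in ("conductance", "resistance"):
            raise ValueError("signal: must be 'conductance' or 'resistance'")

    @property
    def span(self) -> float:
        return self.temp_end_c - self.temp_start_c

    def grid(self) -> np.ndarray:
        return temperature_grid(self.temp_start_c, self.temp_end_c, self.temp_step_c)

    def layer_bumps(self, layer: int) -> tuple[tuple[float, float, float], ...]:
        return self.baselines[(layer - 1) % len(self.baselines)]

    def to_dict(self) -> dict:
        return asdict(self)


def _bump(rel: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((rel - center) / width) ** 2)


def baseline_curve(spec: CohortSpec, layer: int, rel: np.ndarray) -> np.ndarray:
    """Noise-free group-A mean curve for one layer, on relative degrees."""
    out = np.full_like(rel, BASELINE_OFFSET, dtype=float)
    for amp, center, width in spec.layer_bumps(layer):
        out += amp * _bump(rel, center, width)
    return out


def generate_cohort(spec: CohortSpec) -> list[SensorSweep]:
    """Generate all sweeps of a two-group cohort.

    Returns ``2 * n_per_group`` subjects x ``n_sweeps`` x ``layers`` sweeps,
    in subject order (group A first).  Fixed seed gives bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    grid = spec.grid()
    rel = grid - spec.temp_start_c
    lo, hi = spec.effect_window
    effect_mask = (rel >= lo) & (rel < hi)
    shift = spec.effect_size * spec.subject_sd

    sweeps: list[SensorSweep] = []
    for group in (GROUP_A, GROUP_B):
        for subj in range(1, spec.n_per_group + 1):
            sid = f"{group}{subj:03d}"
            for layer in range(1, spec.layers + 1):
                bumps = spec.layer_bumps(layer)
                curve = baseline_curve(spec, layer, rel)
                # subject random effect on bump amplitudes
                amps = rng.normal(0.0, spec.subject_sd, size=len(bumps))
                for a, (_, center, width) in zip(amps, bumps):
                    curve = curve + a * _bump(rel, center, width)
                if group == GROUP_B and layer == spec.effect_layer:
                    curve = curve + shift * effect_mask
                for k in range(1, spec.n_sweeps + 1):
                    values = curve + rng.normal(0.0, spec.sweep_noise_sd, size=rel.size)
                    if spec.signal == "resistance":
                        values = 1.0 / np.maximum(values, 1e-9)
                    sweeps.append(
                        SensorSweep(
                            subject_id=sid,
                            group=group,
                            sweep=k,
                            layer=layer,
                            temperatures=grid.copy(),
                            conductance=values,
                        )
                    )
    return sweeps
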