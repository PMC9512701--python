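"""Experiment-design calculators.

Local NTP generation removes the one-field-of-view-per-experiment limit of
irreversible single-molecule reactions, so acquisition is planned across many
fields of view (FOVs); these helpers size that plan: illumination power
density over the uncaging spot, total acquisition time and molecule counts,
and the photobleaching budget of the fluorophores under the uncaging laser.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ParameterError

__all__ = ["ThroughputPlan", "power_density", "throughput_plan", "bleach_budget"]

UM2_PER_CM2 = 1e8


@dataclass(frozen=True)
class ThroughputPlan:
    """Acquisition plan across sequential fields of view."""

    n_fov: int
    time_per_fov_s: float
    overhead_per_fov_s: float
    molecules_per_fov: int

    def __post_init__(self) -> None:
        if self.n_fov < 0 or self.molecules_per_fov < 0:
            raise ParameterError("counts must be non-negative")
        if self.time_per_fov_s < 0 or self.overhead_per_fov_s < 0:
            raise ParameterError("times must be non-negative")

    @property
    def total_hours(self) -> float:
        return self.n_fov * (self.time_per_fov_s + self.overhead_per_fov_s) / 3600.0

    @property
    def total_molecules(self) -> int:
        return self.n_fov * self.molecules_per_fov

    def summary(self) -> str:
        return (
            f"{self.n_fov} FOVs x {self.time_per_fov_s:g} s "
            f"(+{self.overhead_per_fov_s:g} s overhead) = {self.total_hours:.2f} h, "
            f"{self.total_molecules} molecules"
        )


def power_density(power_mw: float, spot_um: tuple[float, float]) -> float:
    """Power density (W cm⁻²) of ``power_mw`` mW over a rectangular spot (µm).

    Uses the rectangle area of the stated spot dimensions (not a Gaussian
    beam model): 1 mW over a 180 × 60 µm² spot gives ≈ 9.26 W cm⁻².
    """
    if power_mw <= 0:
        raise ParameterError("power must be > 0")
    w, h = spot_um
    if w <= 0 or h <= 0:
        raise ParameterError("spot area must be > 0")
    return (power_mw * 1e-3) / (w * h / UM2_PER_CM2)


def throughput_plan(
    n_fov: int,
    time_per_fov_s: float,
    overhead_per_fov_s: float = 0.0,
    molecules_per_fov: int = 1000,
) -> ThroughputPlan:
    """Total acquisition time and molecule count for sequential FOV imaging."""
    return ThroughputPlan(
        n_fov=n_fov,
        time_per_fov_s=time_per_fov_s,
        overhead_per_fov_s=overhead_per_fov_s,
        molecules_per_fov=molecules_per_fov,
    )


def bleach_budget(half_lives_s: dict[str, float], exposure_s: float) -> dict[str, float]:
    """Surviving fraction per fluorophore after ``exposure_s`` of illumination.

    Exponential photobleaching: fraction = 2^(−t / t_half).
    """
    if exposure_s < 0:
        raise ParameterError("exposure must be >= 0")
    out = {}
    for name, t_half in half_lives_s.items():
        if t_half <= 0:
            raise ParameterError(f"half-life of {name!r} must be > 0")
        out[name] = 2.0 ** (-exposure_s / t_half)
    return out
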