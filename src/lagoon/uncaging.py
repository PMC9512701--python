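"""Deterministic model of caged-NTP photolysis, diffusion and enzymatic scavenging.

Local generation of NTPs confines an NTP-driven reaction to an illuminated
region: near-UV light photolyses a caged (biologically inert) NTP analog at a
rate proportional to the light intensity, while a scavenger enzyme
(hexokinase for ATP) consumes the free nucleotide, so the free-NTP
concentration is high only where and when the uncaging laser is on.

This module predicts the free-NTP concentration in space and time under
continuous or pulsed illumination:

* 0-D (well mixed):  d[free]/dt = k_unc(t)·[caged] − v_scav([free])
* 1-D / 2-D:         ∂[free]/∂t = D∇²[free] + k_unc(x,t)·[caged] − v_scav

with v_scav either full Michaelis–Menten, activity·vmax_per_unit·c/(km + c),
or its linearization k_scav·c with k_scav = activity·vmax_per_unit/km.

Units throughout: µm, s, µM, W cm⁻².  The photolysis rate constant is

    k_unc = ln(10)·ε·Φ·I·λ / (N_A·h·c)

(decadic absorption cross-section × photon flux × quantum yield).

The absorptivity ε and quantum yield Φ of the DMNPE/NPE cages are
CALIBRATION PARAMETERS: the defaults below are literature-style placeholder
values and the absolute free-NTP scale they produce should not be trusted
until :func:`calibrate_photolysis` has anchored it to a measured effective
concentration (e.g. the ~40 µM reached in the helicase assay).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import sparse
from scipy.integrate import solve_ivp, trapezoid

from .errors import ConfigurationError, NumericalError, ParameterError

__all__ = [
    "PulseTrain",
    "IlluminationProtocol",
    "PhotolysisParams",
    "ScavengerParams",
    "DiffusionParams",
    "GridSpec",
    "ChemicalField",
    "photolysis_rate_constant",
    "decay_length",
    "simulate_well_mixed",
    "simulate_spatial",
    "effective_concentration",
    "calibrate_photolysis",
]

LN10 = math.log(10.0)
N_AVOGADRO = 6.02214076e23  # mol⁻¹
PLANCK_H = 6.62607015e-34  # J s
LIGHT_SPEED = 2.99792458e8  # m s⁻¹


# --------------------------------------------------------------------------
# parameter containers
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PulseTrain:
    """A periodic illumination pulse train: ``n_pulses`` repeats of
    (``on_s`` light on, ``off_s`` light off)."""

    on_s: float
    off_s: float
    n_pulses: int
    lead_in_s: float = 0.0  # dark baseline before the first pulse

    def __post_init__(self) -> None:
        if self.on_s <= 0 or self.off_s <= 0:
            raise ParameterError("pulse on/off durations must be positive")
        if self.n_pulses < 1:
            raise ParameterError("n_pulses must be >= 1")
        if self.lead_in_s < 0:
            raise ParameterError("lead_in_s must be >= 0")

    @property
    def period(self) -> float:
        return self.on_s + self.off_s

    @property
    def duration(self) -> float:
        return self.lead_in_s + self.period * self.n_pulses


@dataclass(frozen=True)
class IlluminationProtocol:
    """Spatial spot plus temporal structure of the uncaging illumination.

    Parameters
    ----------
    power_density:
        W cm⁻² inside the spot while the laser is on.
    wavelength:
        Uncaging wavelength in nm (near-UV, 300–450).
    spot:
        Rectangle (width, height) in µm, centred on the origin; the spot
        edge lies at ±width/2 (±height/2).
    pulses:
        ``None`` for continuous illumination, else a :class:`PulseTrain`.
    total_duration:
        Simulated time span in s; must cover the pulse train.
    """

    power_density: float
    total_duration: float
    wavelength: float = 360.0
    spot: tuple[float, float] = (180.0, 60.0)
    pulses: PulseTrain | None = None

    def __post_init__(self) -> None:
        if self.power_density < 0:
            raise ParameterError("power_density must be >= 0")
        if not (300.0 <= self.wavelength <= 450.0):
            raise ParameterError("wavelength must lie in 300-450 nm")
        if self.spot[0] <= 0 or self.spot[1] <= 0:
            raise ParameterError("spot dimensions must be positive")
        if self.total_duration <= 0:
            raise ParameterError("total_duration must be positive")
        if self.pulses is not None and self.total_duration < self.pulses.duration - self.pulses.off_s:
            raise ParameterError("total_duration shorter than the pulse train")

    def segments(self) -> list[tuple[float, float, bool]]:
        """Piecewise-constant illumination as (t_start, t_end, light_on)."""
        T = self.total_duration
        if self.pulses is None:
            return [(0.0, T, True)]
        segs: list[tuple[float, float, bool]] = []
        t = 0.0
        if self.pulses.lead_in_s > 0:
            t = min(self.pulses.lead_in_s, T)
            segs.append((0.0, t, False))
        for _ in range(self.pulses.n_pulses):
            if t >= T:
                break
            t_on = min(t + self.pulses.on_s, T)
            segs.append((t, t_on, True))
            t_off = min(t_on + self.pulses.off_s, T)
            if t_off > t_on:
                segs.append((t_on, t_off, False))
            t = t_off
        if t < T:
            segs.append((t, T, False))
        return segs

    def intensity(self, t: np.ndarray) -> np.ndarray:
        """Power density (W cm⁻²) at times ``t``."""
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        for t0, t1, on in self.segments():
            if on:
                out[(t >= t0) & (t < t1)] = self.power_density
        return out


@dataclass(frozen=True)
class PhotolysisParams:
    """Photochemistry of the caged compound.

    ``molar_absorptivity`` (M⁻¹ cm⁻¹) and ``quantum_yield`` are calibration
    parameters (placeholder defaults); see :func:`calibrate_photolysis`.
    """

    molar_absorptivity: float = 4000.0
    quantum_yield: float = 0.07

    def __post_init__(self) -> None:
        if self.molar_absorptivity <= 0:
            raise ParameterError("molar_absorptivity must be > 0")
        if not (0.0 < self.quantum_yield <= 1.0):
            raise ParameterError("quantum_yield must lie in (0, 1]")


@dataclass(frozen=True)
class ScavengerParams:
    """NTP-consuming enzyme (hexokinase for ATP).

    1 U converts 1 µmol substrate per minute at saturation, so 1 U ml⁻¹
    corresponds to vmax_per_unit = 1000/60 ≈ 16.7 µM s⁻¹ (glucose assumed
    saturating).  ``mode`` selects full Michaelis–Menten consumption or its
    first-order linearization k_scav = activity·vmax_per_unit/km.
    """

    activity: float = 10.0  # U ml⁻¹
    vmax_per_unit: float = 1000.0 / 60.0  # µM s⁻¹ per U ml⁻¹
    km: float = 120.0  # µM
    mode: Literal["full_MM", "linearized"] = "linearized"

    def __post_init__(self) -> None:
        if min(self.activity, self.vmax_per_unit, self.km) <= 0:
            raise ParameterError("scavenger parameters must be positive")
        if self.mode not in ("full_MM", "linearized"):
            raise ParameterError(f"unknown scavenger mode {self.mode!r}")

    @classmethod
    def from_rate(cls, k_linear: float, km: float = 120.0) -> "ScavengerParams":
        """Linearized scavenger with a given first-order clearance rate (s⁻¹).

        Useful when the relevant constant is an *effective* clearance (enzyme
        consumption plus diffusive escape from the observed region) rather
        than a measured enzyme activity.
        """
        if k_linear <= 0:
            raise ParameterError("k_linear must be > 0")
        vmax_per_unit = 1000.0 / 60.0
        return cls(activity=k_linear * km / vmax_per_unit,
                   vmax_per_unit=vmax_per_unit, km=km, mode="linearized")

    @property
    def vmax(self) -> float:
        """Saturated consumption rate, µM s⁻¹."""
        return self.activity * self.vmax_per_unit

    @property
    def k_linear(self) -> float:
        """First-order rate constant of the linearized scavenger, s⁻¹."""
        return self.vmax / self.km

    def rate(self, free: np.ndarray) -> np.ndarray:
        """Consumption rate (µM s⁻¹) at free-NTP concentration ``free``."""
        free = np.asarray(free, dtype=float)
        if self.mode == "linearized":
            return self.k_linear * free
        return self.vmax * free / (self.km + free)

    def rate_derivative(self, free: np.ndarray) -> np.ndarray:
        free = np.asarray(free, dtype=float)
        if self.mode == "linearized":
            return np.full_like(free, self.k_linear)
        return self.vmax * self.km / (self.km + free) ** 2


@dataclass(frozen=True)
class DiffusionParams:
    """Free-NTP diffusion; the caged compound is treated as a constant
    reservoir (its depletion is negligible at mM stocks)."""

    D: float = 300.0  # µm² s⁻¹

    def __post_init__(self) -> None:
        if self.D <= 0:
            raise ParameterError("D must be > 0")


@dataclass(frozen=True)
class GridSpec:
    """Spatial grid for :func:`simulate_spatial`.

    ``extent`` is the half-width of the domain (µm) measured from the spot
    centre along each axis; ``spacing`` the node spacing (µm).  ``boundary``
    is ``"absorbing"`` (far-field sink, free NTP = 0 at the edge) or
    ``"reflecting"`` (no-flux).
    """

    ndim: Literal[1, 2] = 1
    extent: float = 250.0
    spacing: float = 1.0
    boundary: Literal["absorbing", "reflecting"] = "absorbing"

    def __post_init__(self) -> None:
        if self.ndim not in (1, 2):
            raise ParameterError("ndim must be 1 or 2")
        if self.extent <= 0 or self.spacing <= 0:
            raise ParameterError("extent and spacing must be positive")

    def axis(self) -> np.ndarray:
        n = int(round(2 * self.extent / self.spacing)) + 1
        return np.linspace(-self.extent, self.extent, n)


@dataclass
class ChemicalField:
    """Time-resolved caged/free/consumed NTP concentrations (µM).

    0-D: arrays of shape (nt,).  1-D: (nt, nx) with coordinate ``x``.
    2-D: (nt, ny, nx) with coordinates ``x`` and ``y``.  ``consumed`` is the
    cumulative amount removed by the scavenger.
    """

    times: np.ndarray
    free: np.ndarray
    caged: np.ndarray
    consumed: np.ndarray
    x: np.ndarray | None = None
    y: np.ndarray | None = None

    @property
    def ndim(self) -> int:
        return self.free.ndim - 1

    def spatial_mean_free(self) -> np.ndarray:
        """Spatial mean of free NTP at each time (identity in 0-D)."""
        if self.ndim == 0:
            return self.free
        return self.free.reshape(len(self.times), -1).mean(axis=1)

    def to_frame(self):
        """Tidy table (time, x[, y], caged, free, consumed)."""
        import pandas as pd

        if self.ndim == 0:
            return pd.DataFrame(
                {"time": self.times, "caged": self.caged, "free": self.free,
                 "consumed": self.consumed}
            )
        if self.ndim == 1:
            t = np.repeat(self.times, len(self.x))
            x = np.tile(self.x, len(self.times))
            return pd.DataFrame(
                {"time": t, "x": x,
                 "caged": self.caged.ravel(), "free": self.free.ravel(),
                 "consumed": self.consumed.ravel()}
            )
        ny, nx = self.free.shape[1:]
        t = np.repeat(self.times, ny * nx)
        yy, xx = np.meshgrid(self.y, self.x, indexing="ij")
        return pd.DataFrame(
            {"time": t,
             "x": np.tile(xx.ravel(), len(self.times)),
             "y": np.tile(yy.ravel(), len(self.times)),
             "caged": self.caged.reshape(len(self.times), -1).ravel(),
             "free": self.free.reshape(len(self.times), -1).ravel(),
             "consumed": self.consumed.reshape(len(self.times), -1).ravel()}
        )


# --------------------------------------------------------------------------
# elementary relations
# --------------------------------------------------------------------------


def photolysis_rate_constant(
    p: PhotolysisParams, power_density: float, wavelength: float = 360.0
) -> float:
    """First-order photolysis rate constant k_unc (s⁻¹).

    k_unc = σ·Φ·φ_photon where σ = ln(10)·ε·1000/N_A is the decadic
    absorption cross-section (cm² molecule⁻¹) and φ_photon = I·λ/(h·c) the
    photon flux (photons cm⁻² s⁻¹).  Linear in the power density, which is
    what makes the effective free-NTP concentration proportional to the
    uncaging laser intensity.
    """
    if power_density < 0:
        raise ParameterError("power_density must be >= 0")
    if not (300.0 <= wavelength <= 450.0):
        raise ParameterError("wavelength must lie in 300-450 nm")
    cross_section = LN10 * p.molar_absorptivity * 1000.0 / N_AVOGADRO  # cm²
    photon_flux = power_density * (wavelength * 1e-9) / (PLANCK_H * LIGHT_SPEED)
    return cross_section * p.quantum_yield * photon_flux


def decay_length(diffusion: DiffusionParams, scavenger: ScavengerParams) -> float:
    """Steady-state spatial decay length outside the spot, µm.

    In the linearized regime the reaction–diffusion balance outside a wide
    spot gives an exponential profile with length L = sqrt(D/k_scav)
    = sqrt(D·km/(activity·vmax_per_unit)).
    """
    return math.sqrt(diffusion.D / scavenger.k_linear)


# --------------------------------------------------------------------------
# 0-D solver
# --------------------------------------------------------------------------


def _check_dt(protocol: IlluminationProtocol, dt: float) -> None:
    if dt <= 0:
        raise ParameterError("dt must be > 0")
    if protocol.pulses is not None and dt > protocol.pulses.on_s / 20.0:
        raise ParameterError(
            f"dt = {dt:g} does not resolve the {protocol.pulses.on_s}-s pulse; "
            f"use dt <= {protocol.pulses.on_s / 20.0:g} (>= 20 points per pulse)"
        )


def simulate_well_mixed(
    protocol: IlluminationProtocol,
    photolysis: PhotolysisParams,
    scavenger: ScavengerParams,
    caged0: float,
    dt: float,
    reservoir: bool = True,
    rtol: float = 1e-9,
    atol: float = 1e-12,
) -> ChemicalField:
    """Integrate the well-mixed (0-D) uncaging/scavenging kinetics.

    d[free]/dt = k_unc(t)·[caged] − v_scav([free]); with ``reservoir=True``
    the caged pool is held constant (mM caged stock vs µM-scale release),
    otherwise it depletes and caged + free + consumed is conserved.

    Returns the full time series sampled every ``dt`` seconds.
    """
    if caged0 <= 0:
        raise ParameterError("caged0 must be > 0")
    _check_dt(protocol, dt)

    k_on_light = photolysis_rate_constant(photolysis, protocol.power_density,
                                          protocol.wavelength)

    times = [np.array([0.0])]
    free = [np.array([0.0])]
    caged = [np.array([float(caged0)])]
    consumed = [np.array([0.0])]

    state = np.array([caged0, 0.0, 0.0])  # caged, free, consumed

    for t0, t1, light in protocol.segments():
        k_unc = k_on_light if light else 0.0

        def rhs(t, y):
            cg, fr, _ = y
            release = k_unc * (caged0 if reservoir else cg)
            scav = scavenger.rate(max(fr, 0.0))
            return [0.0 if reservoir else -release, release - scav, scav]

        n_eval = max(int(math.ceil((t1 - t0) / dt)), 2)
        t_eval = np.linspace(t0, t1, n_eval + 1)
        sol = solve_ivp(rhs, (t0, t1), state, method="LSODA",
                        t_eval=t_eval, rtol=rtol, atol=atol)
        if not sol.success:
            raise NumericalError(
                f"solver diverged in segment ({t0:g}, {t1:g}); try dt = {dt / 2:g}"
            )
        state = sol.y[:, -1]
        times.append(sol.t[1:])
        caged.append(sol.y[0, 1:])
        free.append(sol.y[1, 1:])
        consumed.append(sol.y[2, 1:])

    t = np.concatenate(times)
    fr = np.concatenate(free)
    cg = np.concatenate(caged)
    cs = np.concatenate(consumed)

    # tolerate solver-scale negative undershoot only
    if fr.min() < -1e-6 * max(caged0, 1.0):
        raise NumericalError(f"negative free-NTP concentration; try dt = {dt / 2:g}")
    fr = np.clip(fr, 0.0, None)

    if not reservoir:
        balance = np.abs(cg + fr + cs - caged0) / caged0
        if balance.max() > 1e-6:
            raise NumericalError(
                f"mass balance violated (max rel. error {balance.max():.2e}); "
                f"try dt = {dt / 2:g}"
            )
    return ChemicalField(times=t, free=fr, caged=cg, consumed=cs)


# --------------------------------------------------------------------------
# spatial solver (method of lines)
# --------------------------------------------------------------------------


def _laplacian_1d(n: int, h: float, boundary: str) -> sparse.spmatrix:
    main = np.full(n, -2.0)
    off = np.ones(n - 1)
    L = sparse.diags([off, main, off], [-1, 0, 1], format="lil")
    if boundary == "reflecting":
        L[0, 1] = 2.0
        L[-1, -2] = 2.0
    # absorbing: ghost node at 0 -> nothing to add
    return (L / h**2).tocsr()


def simulate_spatial(
    protocol: IlluminationProtocol,
    photolysis: PhotolysisParams,
    scavenger: ScavengerParams,
    diffusion: DiffusionParams,
    caged0: float,
    grid: GridSpec,
    dt: float = 0.05,
    reservoir: bool = True,
    rtol: float = 1e-6,
    atol: float = 1e-9,
    check_grid: bool = True,
) -> ChemicalField:
    """Solve ∂c/∂t = D∇²c + k_unc(x,t)·caged0 − v_scav(c) on a 1-D or 2-D grid.

    The spot is centred at the origin with edges at ±width/2 (±height/2 in
    2-D); coordinates are µm and distances "from the edge of the illuminated
    area" are measured outward from those edges.  The caged compound is a
    constant reservoir (see module docstring).

    With ``check_grid`` the grid is validated against the predicted decay
    length L = sqrt(D/k_scav): spacing ≤ L/10 and ≥ 5·L of domain beyond the
    spot edge, so the steady-state exponential tail is resolved and not
    truncated by the boundary.
    """
    if caged0 <= 0:
        raise ParameterError("caged0 must be > 0")
    if not reservoir:
        raise ParameterError(
            "spatial solver supports the constant-reservoir mode only "
            "(caged depletion is negligible at mM caged stocks)"
        )
    _check_dt(protocol, dt)

    L_decay = decay_length(diffusion, scavenger)
    half_w, half_h = protocol.spot[0] / 2.0, protocol.spot[1] / 2.0
    if check_grid and grid.boundary == "absorbing":
        if grid.spacing > L_decay / 10.0:
            raise ConfigurationError(
                f"grid spacing {grid.spacing:g} µm too coarse for decay length "
                f"{L_decay:.3g} µm (need <= {L_decay / 10:.3g} µm)"
            )
        margin = half_h if grid.ndim == 2 else half_w
        if grid.extent - margin < 5.0 * L_decay:
            raise ConfigurationError(
                f"domain must extend >= 5 decay lengths ({5 * L_decay:.3g} µm) "
                f"beyond the spot edge"
            )

    x = grid.axis()
    k_light = photolysis_rate_constant(photolysis, protocol.power_density,
                                       protocol.wavelength)

    if grid.ndim == 1:
        inside = np.abs(x) <= half_w
        lap = diffusion.D * _laplacian_1d(len(x), grid.spacing, grid.boundary)
        shape = (len(x),)
        y_ax = None
    else:
        y_ax = x
        Lx = _laplacian_1d(len(x), grid.spacing, grid.boundary)
        Ly = _laplacian_1d(len(y_ax), grid.spacing, grid.boundary)
        Ix = sparse.identity(len(x))
        Iy = sparse.identity(len(y_ax))
        lap = diffusion.D * (sparse.kron(Iy, Lx) + sparse.kron(Ly, Ix))
        yy, xx = np.meshgrid(y_ax, x, indexing="ij")
        inside = (np.abs(xx) <= half_w) & (np.abs(yy) <= half_h)
        shape = inside.shape
        inside = inside.ravel()

    n = lap.shape[0]
    source_on = k_light * caged0 * inside.astype(float)

    jac_base = lap.tocsc()
    identity = sparse.identity(n, format="csc")

    state = np.zeros(n)
    all_t = [np.array([0.0])]
    all_c = [state.copy()[None, :]]

    for t0, t1, light in protocol.segments():
        src = source_on if light else 0.0

        def rhs(t, y):
            return lap @ y + src - scavenger.rate(np.clip(y, 0.0, None))

        if scavenger.mode == "linearized":
            jac_lin = jac_base - scavenger.k_linear * identity

            def jac(t, y):
                return jac_lin
        else:

            def jac(t, y):
                deriv = scavenger.rate_derivative(np.clip(y, 0.0, None))
                return jac_base - sparse.diags(deriv, format="csc")

        n_eval = max(int(math.ceil((t1 - t0) / dt)), 2)
        t_eval = np.linspace(t0, t1, n_eval + 1)
        sol = solve_ivp(rhs, (t0, t1), state, method="BDF", jac=jac,
                        t_eval=t_eval, rtol=rtol, atol=atol)
        if not sol.success:
            raise NumericalError(f"spatial solver failed in segment ({t0:g}, {t1:g})")
        state = sol.y[:, -1]
        all_t.append(sol.t[1:])
        all_c.append(sol.y[:, 1:].T)

    t = np.concatenate(all_t)
    free = np.concatenate(all_c, axis=0)
    if free.min() < -1e-6 * max(caged0, 1.0):
        raise NumericalError("negative concentration in spatial solve")
    free = np.clip(free, 0.0, None)

    # cumulative consumption per node (trapezoid over the output samples)
    scav_rate = scavenger.rate(free)
    consumed = np.zeros_like(free)
    dt_steps = np.diff(t)
    consumed[1:] = np.cumsum(
        0.5 * (scav_rate[1:] + scav_rate[:-1]) * dt_steps[:, None], axis=0
    )

    free = free.reshape((len(t),) + shape)
    consumed = consumed.reshape((len(t),) + shape)
    caged = np.full_like(free, caged0)
    return ChemicalField(times=t, free=free, caged=caged, consumed=consumed,
                         x=x, y=y_ax)


# --------------------------------------------------------------------------
# derived quantities
# --------------------------------------------------------------------------


def effective_concentration(
    field: ChemicalField,
    region: tuple[float, float] | tuple[tuple[float, float], tuple[float, float]] | None = None,
    window: tuple[float, float] | None = None,
) -> float:
    """Time-averaged spatial mean of free NTP over ``region`` × ``window`` (µM).

    ``region`` is (xmin, xmax) in 1-D, ((xmin, xmax), (ymin, ymax)) in 2-D,
    or None for the whole grid; ``window`` is (t0, t1) or None for the whole
    simulated span.
    """
    t = field.times
    if window is None:
        tmask = np.ones_like(t, dtype=bool)
    else:
        t0, t1 = window
        if t1 <= t0:
            raise ParameterError("empty time window")
        tmask = (t >= t0) & (t <= t1)
        if tmask.sum() < 2:
            raise ParameterError("time window contains fewer than 2 samples")

    if field.ndim == 0:
        series = field.free
    elif field.ndim == 1:
        if region is None:
            sel = np.ones_like(field.x, dtype=bool)
        else:
            xmin, xmax = region
            sel = (field.x >= xmin) & (field.x <= xmax)
        if not sel.any():
            raise ParameterError("region contains no grid nodes")
        series = field.free[:, sel].mean(axis=1)
    else:
        if region is None:
            selx = np.ones_like(field.x, dtype=bool)
            sely = np.ones_like(field.y, dtype=bool)
        else:
            (xmin, xmax), (ymin, ymax) = region
            selx = (field.x >= xmin) & (field.x <= xmax)
            sely = (field.y >= ymin) & (field.y <= ymax)
        if not (selx.any() and sely.any()):
            raise ParameterError("region contains no grid nodes")
        series = field.free[:, sely][:, :, selx].reshape(len(t), -1).mean(axis=1)

    tt = t[tmask]
    ss = series[tmask]
    return float(trapezoid(ss, tt) / (tt[-1] - tt[0]))


def calibrate_photolysis(
    target_concentration: float,
    power_density: float,
    scavenger: ScavengerParams,
    caged0: float,
    base: PhotolysisParams | None = None,
    wavelength: float = 360.0,
) -> PhotolysisParams:
    """Anchor the photolysis parameters to a measured effective concentration.

    Scales the quantum yield so the linearized 0-D steady state under
    continuous illumination, free_ss = k_unc·caged0/k_scav, equals
    ``target_concentration`` at the stated ``power_density``.  Because the
    true (ε, Φ) of the cage are not known to the model, the returned value is
    an *effective* photochemistry: it reproduces the observed free-NTP scale
    for this optical geometry, including losses the explicit model omits.
    """
    if target_concentration <= 0 or power_density <= 0:
        raise ParameterError("target concentration and power density must be > 0")
    base = base or PhotolysisParams()
    k_needed = target_concentration * scavenger.k_linear / caged0
    k_base = photolysis_rate_constant(base, power_density, wavelength)
    scale = k_needed / k_base
    phi = base.quantum_yield * scale
    eps = base.molar_absorptivity
    if phi > 1.0:  # keep Φ physical; put the remainder on ε
        eps *= phi
        phi = 1.0
    return PhotolysisParams(molar_absorptivity=eps, quantum_yield=phi)
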