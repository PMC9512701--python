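"""Synthetic single-molecule traces with ground-truth annotations.

Turns ground-truth :class:`~lagoon.kinetics.StatePath` trajectories into
realistic measurement traces so that every stage of the analysis pipeline is
testable without experimental data:

* three-channel smFRET traces — donor-excitation donor (I_DD),
  donor-excitation acceptor (I_DA) and direct-excitation acceptor (I_AA) —
  with donor→acceptor bleedthrough, direct acceptor excitation,
  photobleaching and Gaussian noise;
* acoustic force spectroscopy (AFS) bead-position traces of a transcribing
  polymerase under intermittent uncaging.

Forward model per frame (before noise):

    I_DD = γ_D·(1 − E)·I_tot
    I_DA = E·I_tot + β·I_DD + α·I_AA_base
    I_AA = I_AA_base                       (on interleaved frames)

where E is the ideal FRET efficiency, β the donor bleedthrough fraction,
α the direct-excitation fraction and γ_D the relative donor detection/quantum
yield.  Donor bleaching sends I_DD and I_DA to the noise floor; acceptor
bleaching sends E to zero channel-wise; donor-strand loss (helicase
completion) kills I_DD and I_DA while I_AA persists.  Bleach times are
exponential with configured half-lives.

Noise is an additive Gaussian approximation of EMCCD shot noise — adequate
for exercising detectors, not a camera model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError
from .kinetics import StatePath

__all__ = [
    "OpticalModel",
    "TraceSet",
    "fret_from_state",
    "synthesize_fret_trace",
    "synthesize_traces",
    "make_elongation_profile",
    "synthesize_afs_trace",
]


@dataclass(frozen=True)
class OpticalModel:
    """Optical/detection parameters of the emulated smFRET microscope.

    ``bleedthrough`` β: fraction of donor signal detected in the acceptor
    channel; ``direct_excitation`` α: acceptor signal excited directly by the
    donor laser, expressed as a fraction of I_AA; ``gamma`` γ_D: donor
    detection/quantum-yield scale; ``sigma``: additive Gaussian noise s.d.
    per channel in units of the total intensity; ``bleach half-lives`` in
    seconds under the active lasers; ``aa_interleave``: one direct-excitation
    frame per this many donor-excitation frames.
    """

    bleedthrough: float = 0.10
    direct_excitation: float = 0.05
    gamma: float = 1.0
    sigma: tuple[float, float, float] = (0.02, 0.02, 0.02)  # DD, DA, AA
    donor_bleach_half_life: float = 180.0
    acceptor_bleach_half_life: float = 90.0
    frame_rate: float = 10.0
    aa_interleave: int = 10

    def __post_init__(self) -> None:
        if not (0.0 <= self.bleedthrough < 1.0 and 0.0 <= self.direct_excitation < 1.0):
            raise ParameterError("alpha and beta must lie in [0, 1)")
        if self.gamma <= 0:
            raise ParameterError("gamma must be > 0")
        if any(s < 0 for s in self.sigma):
            raise ParameterError("noise sigma must be >= 0")
        if self.donor_bleach_half_life <= 0 or self.acceptor_bleach_half_life <= 0:
            raise ParameterError("bleach half-lives must be > 0")
        if self.frame_rate <= 0:
            raise ParameterError("frame_rate must be > 0")
        if self.aa_interleave < 1:
            raise ParameterError("aa_interleave must be >= 1")


@dataclass
class TraceSet:
    """Multi-channel fluorescence time series for many molecules.

    ``i_dd``, ``i_da``, ``i_aa`` have shape (n_traces, n_frames); I_AA is NaN
    on frames without direct acceptor excitation.  ``annotations`` records
    per-trace ground truth (bleach times, donor-strand loss, step count);
    ``truth`` holds the generating :class:`StatePath` objects when available.
    """

    times: np.ndarray
    i_dd: np.ndarray
    i_da: np.ndarray
    i_aa: np.ndarray
    annotations: pd.DataFrame
    truth: list[StatePath] | None = None

    def __post_init__(self) -> None:
        shapes = {self.i_dd.shape, self.i_da.shape, self.i_aa.shape}
        if len(shapes) != 1 or self.i_dd.shape[1] != len(self.times):
            raise ParameterError("channel arrays must share shape (n_traces, n_frames)")

    @property
    def n_traces(self) -> int:
        return self.i_dd.shape[0]

    def to_long(self) -> pd.DataFrame:
        """Long-format table (trace_id, frame, time, I_DD, I_DA, I_AA)."""
        n, m = self.i_dd.shape
        return pd.DataFrame(
            {
                "trace_id": np.repeat(np.arange(n), m),
                "frame": np.tile(np.arange(m), n),
                "time": np.tile(self.times, n),
                "I_DD": self.i_dd.ravel(),
                "I_DA": self.i_da.ravel(),
                "I_AA": self.i_aa.ravel(),
            }
        )

    @classmethod
    def from_long(cls, df: pd.DataFrame) -> "TraceSet":
        """Rebuild a TraceSet from the long-format column contract."""
        required = {"trace_id", "time", "I_DD", "I_DA", "I_AA"}
        missing = required - set(df.columns)
        if missing:
            raise ParameterError(f"missing columns: {sorted(missing)}")
        ids = np.sort(df["trace_id"].unique())
        times = np.sort(df["time"].unique())
        n, m = len(ids), len(times)
        piv = df.sort_values(["trace_id", "time"])
        if len(piv) != n * m:
            raise ParameterError("traces do not share a common time base")
        return cls(
            times=times,
            i_dd=piv["I_DD"].to_numpy().reshape(n, m),
            i_da=piv["I_DA"].to_numpy().reshape(n, m),
            i_aa=piv["I_AA"].to_numpy().reshape(n, m),
            annotations=pd.DataFrame({"trace_id": ids}),
        )


# --------------------------------------------------------------------------
# ideal FRET from a state path
# --------------------------------------------------------------------------


def fret_from_state(path: StatePath, times: np.ndarray) -> np.ndarray:
    """Ideal (noise-free) FRET series of a ground-truth trajectory.

    Remodeling paths give a piecewise-constant staircase; unwinding paths a
    linear FRET decay over the unwinding interval (the exact trajectory shape
    during unwinding is not observable at this resolution; a linear ramp is
    the declared stand-in).  Values are clipped to [0, 1].
    """
    e = path.value_at(np.asarray(times, dtype=float))
    if np.any(np.isnan(e)):
        raise ParameterError("state path evaluates to NaN (unmapped state)")
    return np.clip(e, 0.0, 1.0)


# --------------------------------------------------------------------------
# smFRET forward model
# --------------------------------------------------------------------------


def synthesize_fret_trace(
    ideal: np.ndarray,
    times: np.ndarray,
    om: OpticalModel,
    total_intensity: float = 1.0,
    rng: np.random.Generator | int = 0,
    donor_loss_time: float = math.inf,
    aa_base: float | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict]:
    """Apply the optical forward model to one ideal FRET series.

    Returns (I_DD, I_DA, I_AA, truth) where ``truth`` records the drawn
    bleach times.  See the module docstring for the per-frame model.
    """
    if total_intensity <= 0:
        raise ParameterError("total_intensity must be > 0")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    ideal = np.asarray(ideal, dtype=float)
    times = np.asarray(times, dtype=float)

    aa_base = total_intensity if aa_base is None else aa_base
    t_donor = rng.exponential(om.donor_bleach_half_life / math.log(2.0))
    t_acceptor = rng.exponential(om.acceptor_bleach_half_life / math.log(2.0))

    e = ideal.copy()
    acceptor_dark = times >= min(t_acceptor, math.inf)
    e[acceptor_dark] = 0.0  # acceptor bleached: no transfer

    i_dd = om.gamma * (1.0 - e) * total_intensity
    i_da = e * total_intensity
    i_aa_full = np.full_like(e, aa_base)
    i_aa_full[acceptor_dark] = 0.0
    i_da = i_da + om.bleedthrough * i_dd + om.direct_excitation * i_aa_full

    donor_dark = (times >= t_donor) | (times >= donor_loss_time)
    i_dd[donor_dark] = 0.0
    # donor gone: no transfer and no bleedthrough; direct excitation persists
    i_da[donor_dark] = om.direct_excitation * i_aa_full[donor_dark]

    if om.sigma[0] > 0:
        i_dd = i_dd + rng.normal(0.0, om.sigma[0] * total_intensity, i_dd.shape)
    if om.sigma[1] > 0:
        i_da = i_da + rng.normal(0.0, om.sigma[1] * total_intensity, i_da.shape)
    if om.sigma[2] > 0:
        i_aa_full = i_aa_full + rng.normal(0.0, om.sigma[2] * total_intensity,
                                           i_aa_full.shape)

    i_aa = np.full_like(i_aa_full, np.nan)
    idx = np.arange(len(times)) % om.aa_interleave == 0
    i_aa[idx] = i_aa_full[idx]

    truth = {
        "donor_bleach": t_donor,
        "acceptor_bleach": t_acceptor,
        "donor_loss": donor_loss_time,
    }
    return i_dd, i_da, i_aa, truth


def synthesize_traces(
    paths: Sequence[StatePath],
    om: OpticalModel,
    duration: float | None = None,
    total_intensity: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> TraceSet:
    """Synthesize a :class:`TraceSet` from ground-truth state paths.

    Helicase-completion paths (``kind="ramp"`` with ``completed=True``) lose
    the donor strand at onset+duration; remodeling paths keep it.  Each
    trace's annotations carry the bleach/loss times and, for step paths, the
    true step times and sizes for detector scoring.
    """
    if not paths:
        raise ParameterError("no state paths given")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if duration is None:
        duration = max(
            (p.meta.get("duration", 0.0) if p.kind == "steps"
             else (p.meta["onset"] + p.meta["duration"]
                   if math.isfinite(p.meta["onset"]) else 0.0))
            for p in paths
        )
        if duration <= 0:
            raise ParameterError("could not infer duration; pass it explicitly")
    n_frames = int(round(duration * om.frame_rate))
    times = np.arange(n_frames) / om.frame_rate

    i_dd = np.empty((len(paths), n_frames))
    i_da = np.empty_like(i_dd)
    i_aa = np.empty_like(i_dd)
    rows = []
    for k, path in enumerate(paths):
        ideal = fret_from_state(path, times)
        loss = math.inf
        if path.kind == "ramp" and path.meta.get("completed", False):
            loss = path.meta["onset"] + path.meta["duration"]
        dd, da, aa, truth = synthesize_fret_trace(
            ideal, times, om, total_intensity=total_intensity, rng=rng,
            donor_loss_time=loss,
        )
        i_dd[k], i_da[k], i_aa[k] = dd, da, aa
        rows.append(
            {
                "trace_id": k,
                "donor_bleach": truth["donor_bleach"],
                "acceptor_bleach": truth["acceptor_bleach"],
                "donor_loss": loss,
                "n_steps": len(path.times) if path.kind == "steps" else np.nan,
                "onset": path.meta.get("onset", np.nan),
                "unwind_duration": (path.meta.get("duration", np.nan)
                                    if path.kind == "ramp" else np.nan),
                "completed": path.meta.get("completed", np.nan),
            }
        )
    return TraceSet(
        times=times, i_dd=i_dd, i_da=i_da, i_aa=i_aa,
        annotations=pd.DataFrame(rows), truth=list(paths),
    )


# --------------------------------------------------------------------------
# AFS bead-position traces
# --------------------------------------------------------------------------


def make_elongation_profile(
    total_duration: float,
    frame_rate: float,
    windows: Sequence[tuple[float, float]],
    rate_bp_s: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Transcribed-bp profile: constant elongation inside uncaging windows,
    stalled outside.  Returns (times, bp)."""
    if rate_bp_s < 0:
        raise ParameterError("rate_bp_s must be >= 0")
    n = int(round(total_duration * frame_rate))
    times = np.arange(n) / frame_rate
    speed = np.zeros(n)
    for t0, t1 in windows:
        speed[(times >= t0) & (times < t1)] = rate_bp_s
    bp = np.concatenate([[0.0], np.cumsum(speed[:-1] * np.diff(times))])
    return times, bp


def synthesize_afs_trace(
    times: np.ndarray,
    elongation_bp: np.ndarray,
    rise_per_bp: float = 0.3,
    noise_sigma: float = 5.0,
    drift_nm_s: float = 0.0,
    rng: np.random.Generator | int = 0,
) -> pd.DataFrame:
    """AFS bead-position trace (nm) from a transcribed-bp profile.

    position = −bp(t)·rise_per_bp + drift·t + Gaussian noise; the bead moves
    toward the chip surface as the polymerase elongates.  The profile must be
    monotone non-decreasing (a polymerase does not untranscribe).
    """
    times = np.asarray(times, dtype=float)
    elongation_bp = np.asarray(elongation_bp, dtype=float)
    if times.shape != elongation_bp.shape:
        raise ParameterError("times and elongation_bp must match")
    if np.any(np.diff(elongation_bp) < -1e-9):
        raise ParameterError("elongation profile must be monotone non-decreasing")
    if rise_per_bp <= 0:
        raise ParameterError("rise_per_bp must be > 0")
    if noise_sigma < 0:
        raise ParameterError("noise_sigma must be >= 0")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)

    position = -elongation_bp * rise_per_bp + drift_nm_s * times
    if noise_sigma > 0:
        position = position + rng.normal(0.0, noise_sigma, position.shape)
    return pd.DataFrame({"time": times, "position": position,
                         "true_bp": elongation_bp})
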