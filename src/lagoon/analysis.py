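"""Trace-analysis pipeline for LAGOON-style single-molecule experiments.

Stages, in the order a dataset flows through them:

1. :func:`correct_channels` — bleedthrough/direct-excitation/γ corrections
   and the FRET efficiency E = acceptor'/(acceptor' + donor').
2. :func:`cy5_ratio` — per-molecule ratio of acceptor emission under donor
   vs direct excitation; classifies intact vs donor-strand-lost molecules
   (the FRET-sensitized acceptor emission disappears with the donor strand).
3. :func:`find_steps` — change-point staircase fitting by iterative greedy
   χ² minimization; each candidate fit is scored against a counter-fit with
   change points at plateau midpoints, and steps are accepted while the
   fit/counter-fit quality ratio stays above a threshold.
4. :func:`first_step_sizes` / :func:`fit_two_gaussians` — the size of the
   first detected step per trace within the monotone FRET-increase phase,
   decomposed into elementary vs compound steps by a two-Gaussian mixture
   (EM; the second component's centre/width can be frozen to values derived
   from a reference condition).
5. :func:`unwinding_rate`, :func:`michaelis_menten_fit`,
   :func:`effective_atp_mapping` — unwinding-rate estimates, ATP titration
   fits, and the mapping from uncaging power to effective [ATP] obtained by
   comparing titration curves measured with regular vs caged ATP.
6. :func:`afs_elongation` — median + Savitzky–Golay smoothing of AFS
   bead-position traces and windowed elongation rates around uncaging
   transitions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.signal import medfilt, savgol_filter

from .errors import ConvergenceError, ParameterError
from .traces import TraceSet

__all__ = [
    "CorrectionParams",
    "CorrectedTraces",
    "StepFit",
    "MixtureFit",
    "RateEstimate",
    "correct_channels",
    "cy5_ratio",
    "find_steps",
    "first_step_sizes",
    "fit_two_gaussians",
    "unwinding_rate",
    "michaelis_menten_fit",
    "effective_atp_mapping",
    "afs_elongation",
    "DEFAULT_STEP_THRESHOLD",
]

# Counter-fit acceptance threshold; tuned once on synthetic flat traces so
# that fewer than 5% of step-free noisy traces yield a spurious step
# (see docs/methods.md).
DEFAULT_STEP_THRESHOLD = 2.0


# --------------------------------------------------------------------------
# channel corrections
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class CorrectionParams:
    """Channel-correction coefficients.

    ``alpha``: direct acceptor excitation by the donor laser, as a fraction
    of the direct-excitation channel I_AA; ``beta``: donor bleedthrough into
    the acceptor channel; ``gamma``: scale applied to the donor channel to
    equalize detection/quantum yields (the inverse of the generator's γ_D).
    """

    alpha: float = 0.0
    beta: float = 0.0
    gamma: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha < 1.0 and 0.0 <= self.beta < 1.0):
            raise ParameterError("alpha and beta must lie in [0, 1)")
        if self.gamma <= 0:
            raise ParameterError("gamma must be > 0")


@dataclass
class CorrectedTraces:
    """Corrected donor/acceptor intensities and FRET, with post-bleach mask.

    ``fret`` is clamped to [−0.1, 1.1]; frames outside that range are kept
    but flagged in ``out_of_range``.  ``masked`` marks frames whose total
    corrected intensity fell below the noise floor (donor bleached or donor
    strand lost) — they carry no FRET information and are excluded rather
    than errored.
    """

    times: np.ndarray
    donor: np.ndarray
    acceptor: np.ndarray
    fret: np.ndarray
    masked: np.ndarray
    out_of_range: np.ndarray


def correct_channels(
    raw: TraceSet,
    params: CorrectionParams,
    noise_floor: float | None = None,
) -> CorrectedTraces:
    """Apply channel corrections and compute FRET.

    acceptor' = I_DA − β·I_DD − α·I_AA;  donor' = γ·I_DD;
    E = acceptor'/(acceptor' + donor').

    I_AA is recorded only on interleaved frames; each trace's correction uses
    its median direct-excitation level (constant acceptor assumed between
    bleaching events).  Frames whose denominator falls below ``noise_floor``
    (default: 10% of the per-trace median total intensity) are masked.
    """
    i_dd, i_da, i_aa = raw.i_dd, raw.i_da, raw.i_aa
    aa_level = np.nanmedian(np.where(np.isnan(i_aa), np.nan, i_aa), axis=1)
    aa_level = np.where(np.isfinite(aa_level), aa_level, 0.0)

    acceptor = i_da - params.beta * i_dd - params.alpha * aa_level[:, None]
    donor = params.gamma * i_dd
    total = acceptor + donor

    if noise_floor is None:
        # per-trace signal scale from the bright end of the distribution, so
        # a molecule that bleaches early still gets a meaningful floor
        floor = 0.1 * np.percentile(total, 98, axis=1)
    else:
        floor = np.full(raw.n_traces, float(noise_floor))
    masked = total < np.maximum(floor, 1e-12)[:, None]

    with np.errstate(divide="ignore", invalid="ignore"):
        fret = np.where(masked, np.nan, acceptor / total)
    out_of_range = ~masked & ((fret < -0.1) | (fret > 1.1))
    fret = np.clip(fret, -0.1, 1.1)

    return CorrectedTraces(
        times=raw.times, donor=donor, acceptor=acceptor, fret=fret,
        masked=masked, out_of_range=out_of_range,
    )


# --------------------------------------------------------------------------
# acceptor-ratio classification (donor-strand loss)
# --------------------------------------------------------------------------


def _otsu_threshold(values: np.ndarray, bins: int = 128) -> float:
    """Otsu's threshold (maximal between-class variance) on a 1-D sample."""
    hist, edges = np.histogram(values, bins=bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    w = hist.astype(float)
    total = w.sum()
    best, thr = -1.0, centers[len(centers) // 2]
    cum_w = np.cumsum(w)
    cum_m = np.cumsum(w * centers)
    for i in range(1, bins):
        w0, w1 = cum_w[i - 1], total - cum_w[i - 1]
        if w0 == 0 or w1 == 0:
            continue
        m0 = cum_m[i - 1] / w0
        m1 = (cum_m[-1] - cum_m[i - 1]) / w1
        var_between = w0 * w1 * (m0 - m1) ** 2
        if var_between > best:
            best, thr = var_between, 0.5 * (centers[i - 1] + centers[i])
    return float(thr)


def cy5_ratio(
    raw: TraceSet,
    window_frames: int = 20,
    aa_floor: float = 0.05,
) -> pd.DataFrame:
    """Per-molecule acceptor 532/638 ratio before vs after the reaction.

    ratio = mean(I_DA)/mean(I_AA) over the first (``before``) and last
    (``after``) ``window_frames`` frames.  Intact high-FRET molecules show a
    large ratio (FRET-sensitized acceptor emission); molecules that lost the
    donor strand drop to the direct-excitation floor while I_AA persists.
    Molecules with I_AA below ``aa_floor`` × median (no acceptor present) are
    excluded.  Classification threshold: Otsu on the pooled log-ratios; the
    returned frame carries the threshold and the fraction classified as
    unwound (after window).
    """
    if raw.i_dd.shape[1] < 2 * window_frames:
        raise ParameterError("traces shorter than two ratio windows")

    def _window_ratio(sl: slice) -> tuple[np.ndarray, np.ndarray]:
        da = np.nanmean(raw.i_da[:, sl], axis=1)
        aa = np.nanmean(raw.i_aa[:, sl], axis=1)
        return da, aa

    da_b, aa_b = _window_ratio(slice(0, window_frames))
    da_a, aa_a = _window_ratio(slice(-window_frames, None))

    aa_scale = np.nanmedian(np.concatenate([aa_b, aa_a]))
    ok = (aa_b > aa_floor * aa_scale) & (aa_a > aa_floor * aa_scale)
    if not ok.any():
        raise ParameterError("no molecules with detectable acceptor")

    ratio_before = np.where(ok, da_b / np.where(ok, aa_b, 1.0), np.nan)
    ratio_after = np.where(ok, da_a / np.where(ok, aa_a, 1.0), np.nan)

    pooled = np.log(np.clip(np.concatenate([ratio_before[ok], ratio_after[ok]]),
                            1e-6, None))
    thr = math.exp(_otsu_threshold(pooled))

    unwound = ratio_after < thr
    df = pd.DataFrame(
        {
            "trace_id": np.arange(raw.n_traces),
            "ratio_before": ratio_before,
            "ratio_after": ratio_after,
            "included": ok,
            "unwound": np.where(ok, unwound, False),
        }
    )
    df.attrs["threshold"] = thr
    df.attrs["fraction_unwound"] = float(unwound[ok].mean())
    return df


# --------------------------------------------------------------------------
# step detection (iterative χ² change-point placement with counter-fit)
# --------------------------------------------------------------------------


@dataclass
class StepFit:
    """Result of staircase change-point fitting on one trace.

    ``change_points[i]`` is the index of the first frame of plateau i+1;
    ``plateaus`` the segment means (len = steps + 1); ``step_sizes`` the
    plateau differences; ``scores[i]`` the counter-fit quality ratio after
    accepting step i+1 (steps were accepted while score > threshold).
    """

    change_points: np.ndarray
    plateaus: np.ndarray
    step_sizes: np.ndarray
    scores: np.ndarray
    residual_chi2: float
    n_frames: int

    @property
    def n_steps(self) -> int:
        return len(self.change_points)

    def reconstruction(self) -> np.ndarray:
        """Piecewise-constant staircase implied by the fit."""
        out = np.empty(self.n_frames)
        bounds = np.concatenate([[0], self.change_points, [self.n_frames]])
        for i, mean in enumerate(self.plateaus):
            out[bounds[i]:bounds[i + 1]] = mean
        return out


def _segment_best_split(y: np.ndarray, lo: int, hi: int, min_plateau: int):
    """Best single change point inside y[lo:hi].

    Returns (SSE_gain, split_index) or None.  The gain of splitting at k
    (left block y[lo:k], right y[k:hi]) is n_l·n_r/(n_l+n_r)·(mean_l−mean_r)²;
    ties broken toward the earliest index.
    """
    n = hi - lo
    if n < 2 * min_plateau:
        return None
    seg = y[lo:hi]
    csum = np.cumsum(seg)
    total = csum[-1]
    k = np.arange(min_plateau, n - min_plateau + 1)  # left block length
    mean_l = csum[k - 1] / k
    mean_r = (total - csum[k - 1]) / (n - k)
    gain = k * (n - k) / n * (mean_l - mean_r) ** 2
    best = int(np.argmax(gain))  # argmax returns first maximum: earliest index
    if gain[best] <= 0:
        return None
    return float(gain[best]), lo + int(k[best])


def _sse_for_changepoints(y: np.ndarray, lo: int, hi: int,
                          cps: Sequence[int]) -> float:
    bounds = [lo, *cps, hi]
    sse = 0.0
    for i in range(len(bounds) - 1):
        seg = y[bounds[i]:bounds[i + 1]]
        if seg.size:
            sse += float(np.sum((seg - seg.mean()) ** 2))
    return sse


def _counter_sse(y: np.ndarray, cps) -> float:
    """SSE of the counter-fit: change points at the midpoints of the plateaus
    defined by ``cps`` -- a staircase of the same complexity placed
    deliberately wrong (between the fitted transitions)."""
    n = len(y)
    bounds = np.concatenate([[0], np.sort(np.asarray(cps, dtype=int)), [n]])
    mids = (bounds[:-1] + bounds[1:]) // 2
    mids = sorted(set(int(m) for m in mids if 0 < m < n))
    return _sse_for_changepoints(y, 0, n, mids)


def find_steps(
    series: np.ndarray,
    max_steps: int = 20,
    acceptance_threshold: float = DEFAULT_STEP_THRESHOLD,
    min_plateau: int = 5,
) -> StepFit:
    """Detect steps in a noisy staircase by greedy chi-square change-point placement.

    The trace is segmented iteratively: at each round the single split (over
    all current plateaus) that most reduces the residual chi-square is added,
    with plateaus constrained to at least ``min_plateau`` frames and equal-
    chi-square ties broken toward the earliest index.  Each k-step fit along
    the way is scored against a counter-fit with the same number of change
    points placed at the plateau midpoints -- deliberately *between* the
    fitted transitions:

        S(k) = chi2_counter(k) / chi2_fit(k).

    Genuine staircases make S(k) peak sharply at the true step count (the fit
    removes the step variance, the counter-fit cannot); on step-free noise S
    stays near 1.  The fit with the maximal S is kept if that score exceeds
    ``acceptance_threshold``, otherwise zero steps are reported (a valid
    outcome for a flat trace).
    """
    y = np.asarray(series, dtype=float)
    if y.ndim != 1 or len(y) < 10:
        raise ParameterError("series must be 1-D with at least 10 frames")
    if max_steps < 0:
        raise ParameterError("max_steps must be >= 0")

    n = len(y)
    sse0 = _sse_for_changepoints(y, 0, n, [])
    scale = max(1.0, float(np.abs(y).max()) ** 2)

    # full greedy expansion, recording the S-curve
    all_cps: list[int] = []
    s_curve: list[float] = []
    sse_fit = sse0
    candidates: dict[tuple[int, int], tuple[float, int] | None] = {
        (0, n): _segment_best_split(y, 0, n, min_plateau)
    }
    while len(all_cps) < max_steps:
        best_gain, best_idx, best_seg = 0.0, None, None
        for (lo, hi), cand in candidates.items():
            if cand is None:
                continue
            gain, idx = cand
            if gain > best_gain:
                best_gain, best_idx, best_seg = gain, idx, (lo, hi)
        # stop on numerically exhausted residual (noiseless staircase solved)
        if best_idx is None or best_gain <= 1e-15 * n * scale:
            break
        all_cps.append(best_idx)
        sse_fit -= best_gain
        s_curve.append(_counter_sse(y, all_cps) / max(sse_fit, 1e-300))
        lo, hi = best_seg
        del candidates[(lo, hi)]
        candidates[(lo, best_idx)] = _segment_best_split(y, lo, best_idx, min_plateau)
        candidates[(best_idx, hi)] = _segment_best_split(y, best_idx, hi, min_plateau)

    if s_curve and max(s_curve) > acceptance_threshold:
        # smallest k within 2% of the S-curve maximum: beyond the true step
        # count S keeps creeping up as noise-chasing splits shave the fit
        # chi-square without helping the counter-fit, so the plain argmax
        # systematically overshoots by a step or two
        s_arr = np.asarray(s_curve)
        k_best = int(np.nonzero(s_arr >= 0.98 * s_arr.max())[0][0]) + 1
    else:
        k_best = 0
    cps = all_cps[:k_best]
    scores = s_curve[:k_best]

    cps_arr = np.array(sorted(cps), dtype=int)
    bounds = np.concatenate([[0], cps_arr, [n]])
    plateaus = np.array([y[bounds[i]:bounds[i + 1]].mean()
                         for i in range(len(bounds) - 1)])
    return StepFit(
        change_points=cps_arr,
        plateaus=plateaus,
        step_sizes=np.diff(plateaus),
        scores=np.array(scores)[np.argsort(cps)] if cps else np.empty(0),
        residual_chi2=_sse_for_changepoints(y, 0, n, list(cps_arr)),
        n_frames=n,
    )


def first_step_sizes(
    fits: Sequence[StepFit],
    monotone_only: bool = True,
) -> tuple[np.ndarray, int]:
    """First detected step size per trace, restricted to the initial
    monotone-increase phase.

    For each fit, steps after the first FRET *decrease* are discarded
    (continuous remodeling eventually reverses the FRET change, which cannot
    be distinguished from non-processive events); the first remaining
    positive step contributes one value.  Returns (sizes, n_excluded) where
    excluded traces had no qualifying step.
    """
    sizes = []
    excluded = 0
    for fit in fits:
        steps = fit.step_sizes
        if monotone_only:
            neg = np.nonzero(steps < 0)[0]
            if neg.size:
                steps = steps[: neg[0]]
        steps = steps[steps > 0]
        if steps.size:
            sizes.append(float(steps[0]))
        else:
            excluded += 1
    return np.asarray(sizes), excluded


# --------------------------------------------------------------------------
# two-Gaussian mixture (elementary vs compound steps)
# --------------------------------------------------------------------------


@dataclass
class MixtureFit:
    """Two-component Gaussian mixture of step sizes.

    Component order follows the means; ``compound_fraction`` is the weight of
    the larger-mean (compound-step) component.  ``fixed_component2`` records
    whether that component's centre/width were frozen to reference values.
    """

    weights: np.ndarray
    means: np.ndarray
    sigmas: np.ndarray
    log_likelihood: float
    n: int
    converged: bool
    fixed_component2: tuple[float, float] | None = None

    @property
    def compound_fraction(self) -> float:
        return float(self.weights[int(np.argmax(self.means))])

    def summary(self) -> pd.DataFrame:
        order = np.argsort(self.means)
        return pd.DataFrame(
            {
                "component": ["elementary", "compound"],
                "weight": self.weights[order],
                "mean": self.means[order],
                "sigma": self.sigmas[order],
            }
        )


def _norm_pdf(x: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((x - mu) / sigma) ** 2) / (sigma * math.sqrt(2 * math.pi))


def fit_two_gaussians(
    sizes: np.ndarray,
    fix_component2: tuple[float, float] | None = None,
    n_restarts: int = 10,
    max_iter: int = 500,
    tol: float = 1e-9,
    seed: int = 0,
    min_n: int = 50,
) -> MixtureFit:
    """Maximum-likelihood two-Gaussian mixture of raw step sizes (EM).

    With ``fix_component2 = (mean, sigma)`` the second (compound) component's
    centre and width are frozen — as done when transferring the compound-peak
    parameters from a reference pulse-duration condition — and only the
    weights and the first component are estimated.  EM restarts from
    ``n_restarts`` randomized initializations; failure of all restarts raises
    :class:`~lagoon.errors.ConvergenceError` with diagnostics.
    """
    x = np.asarray(sizes, dtype=float)
    if x.ndim != 1 or len(x) < min_n:
        raise ParameterError(f"need at least {min_n} step sizes (got {len(x)})")
    rng = np.random.default_rng(seed)
    scale = max(np.std(x), 1e-6)
    sigma_floor = 1e-3 * scale

    best: MixtureFit | None = None
    diagnostics = []
    for r in range(n_restarts):
        if r == 0:
            mu = np.array([np.quantile(x, 0.3), np.quantile(x, 0.85)])
        else:
            mu = np.sort(rng.choice(x, 2, replace=False))
        sg = np.array([scale / 2, scale / 2])
        w = np.array([0.6, 0.4])
        if fix_component2 is not None:
            mu[1], sg[1] = fix_component2
            if sg[1] <= 0:
                raise ParameterError("fixed component sigma must be > 0")

        prev_ll = -np.inf
        converged = False
        for _ in range(max_iter):
            pdf = np.column_stack(
                [w[0] * _norm_pdf(x, mu[0], sg[0]), w[1] * _norm_pdf(x, mu[1], sg[1])]
            )
            norm = pdf.sum(axis=1)
            norm = np.where(norm <= 0, 1e-300, norm)
            ll = float(np.sum(np.log(norm)))
            resp = pdf / norm[:, None]
            nk = resp.sum(axis=0)
            w = nk / len(x)
            # a component may collapse to ~zero weight (e.g. a fixed compound
            # component with no compound steps in the sample) — keep its
            # parameters and let its weight go to zero instead of aborting
            if nk[0] > 1e-10:
                mu[0] = float(resp[:, 0] @ x / nk[0])
                sg[0] = max(
                    math.sqrt(float(resp[:, 0] @ (x - mu[0]) ** 2 / nk[0])),
                    sigma_floor,
                )
            if fix_component2 is None and nk[1] > 1e-10:
                mu[1] = float(resp[:, 1] @ x / nk[1])
                sg[1] = max(
                    math.sqrt(float(resp[:, 1] @ (x - mu[1]) ** 2 / nk[1])),
                    sigma_floor,
                )
            if abs(ll - prev_ll) < tol * (1 + abs(ll)):
                converged = True
                break
            prev_ll = ll
        diagnostics.append((r, ll, converged))
        if converged and (best is None or ll > best.log_likelihood):
            best = MixtureFit(
                weights=w.copy(), means=mu.copy(), sigmas=sg.copy(),
                log_likelihood=ll, n=len(x), converged=True,
                fixed_component2=fix_component2,
            )

    if best is None:
        raise ConvergenceError(
            f"EM failed to converge in {n_restarts} restarts; "
            f"(restart, loglik, converged) = {diagnostics}"
        )
    return best


# --------------------------------------------------------------------------
# unwinding rates and titrations
# --------------------------------------------------------------------------


@dataclass
class RateEstimate:
    """Aggregate rate estimate: unweighted mean ± s.e.m. over molecules."""

    rates: np.ndarray
    n_excluded: int = 0

    @property
    def n(self) -> int:
        return len(self.rates)

    @property
    def mean(self) -> float:
        return float(np.mean(self.rates)) if self.n else math.nan

    @property
    def sem(self) -> float:
        if self.n < 2:
            return math.nan
        return float(np.std(self.rates, ddof=1) / math.sqrt(self.n))

    def summary(self) -> str:
        return f"{self.mean:.3g} ± {self.sem:.2g} s⁻¹ (n = {self.n})"


def unwinding_rate(
    corrected: "CorrectedTraces",
    e_high: float = 0.9,
    e_low: float = 0.1,
    delta: float = 0.1,
    min_below: int = 3,
) -> RateEstimate:
    """Per-molecule unwinding rate from corrected FRET traces.

    The transit time of one molecule runs from its departure below
    ``e_high − delta`` (sustained for ``min_below`` consecutive frames, to
    resist noise) to donor-strand loss (the first masked frame).  Because the
    departure threshold is crossed a fraction δ/(E_high−E_low) into the
    unwinding interval, the per-molecule rate is reported as

        rate = (1 − δ/(E_high−E_low)) / transit_time,

    an unbiased reciprocal of the full unwinding interval (a molecule
    unwinding in 4 s reports 0.25 s⁻¹).  Molecules without a detected
    departure or completion are excluded and counted.
    """
    if not e_high - delta > e_low:
        raise ParameterError("need e_high - delta > e_low")
    correction = 1.0 - delta / (e_high - e_low)
    rates = []
    excluded = 0
    times = corrected.times
    for i in range(corrected.fret.shape[0]):
        e = corrected.fret[i]
        masked = corrected.masked[i]
        loss_idx = np.nonzero(masked)[0]
        if not loss_idx.size:
            excluded += 1
            continue
        loss = loss_idx[0]
        below = (e[:loss] < e_high - delta).astype(int)
        if below.size < min_below:
            excluded += 1
            continue
        run = np.convolve(below, np.ones(min_below, dtype=int), mode="valid")
        dep_idx = np.nonzero(run == min_below)[0]
        if not dep_idx.size:
            excluded += 1
            continue
        dep = dep_idx[0]
        dt = times[loss] - times[dep]
        if dt <= 0:
            excluded += 1
            continue
        rates.append(correction / dt)
    return RateEstimate(rates=np.asarray(rates), n_excluded=excluded)


def michaelis_menten_fit(
    conc: np.ndarray, rates: np.ndarray
) -> tuple[float, float]:
    """Fit rate = vmax·c/(km + c); returns (vmax, km)."""
    conc = np.asarray(conc, dtype=float)
    rates = np.asarray(rates, dtype=float)
    if conc.shape != rates.shape or conc.size < 3:
        raise ParameterError("need matching conc/rate arrays with >= 3 points")

    def mm(c, vmax, km):
        return vmax * c / (km + c)

    p0 = (rates.max(), np.median(conc))
    popt, _ = curve_fit(mm, conc, rates, p0=p0, maxfev=20000,
                        bounds=([0, 0], [np.inf, np.inf]))
    return float(popt[0]), float(popt[1])


def effective_atp_mapping(
    rate_vs_power: pd.DataFrame,
    rate_vs_atp: pd.DataFrame,
) -> pd.DataFrame:
    """Map uncaging power density to effective [ATP].

    For each power density, finds the [ATP] at which the regular-ATP
    titration reaches the same rate, by monotone (PCHIP) interpolation of the
    inverse titration curve.  Powers whose rate falls outside the titration's
    observed range are flagged (no extrapolation).  Expects columns
    ``power``/``rate`` and ``atp``/``rate``; both curves must be monotone
    non-decreasing in their abscissa.
    """
    from scipy.interpolate import PchipInterpolator

    for df, col in ((rate_vs_power, "power"), (rate_vs_atp, "atp")):
        if col not in df.columns or "rate" not in df.columns:
            raise ParameterError(f"expected columns ({col}, rate)")
        if np.any(np.diff(df[col].to_numpy()) <= 0):
            raise ParameterError(f"{col} values must be strictly increasing")
        if np.any(np.diff(df["rate"].to_numpy()) < 0):
            raise ParameterError(f"rate must be monotone non-decreasing in {col}")

    atp = rate_vs_atp["atp"].to_numpy(dtype=float)
    r_atp = rate_vs_atp["rate"].to_numpy(dtype=float)
    # strictly increasing rate needed for inversion; collapse plateaus
    keep = np.concatenate([[True], np.diff(r_atp) > 0])
    inverse = PchipInterpolator(r_atp[keep], atp[keep], extrapolate=False)

    rows = []
    for _, row in rate_vs_power.iterrows():
        r = float(row["rate"])
        in_range = r_atp.min() <= r <= r_atp.max()
        rows.append(
            {
                "power": float(row["power"]),
                "rate": r,
                "effective_atp": float(inverse(r)) if in_range else math.nan,
                "flagged": not in_range,
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# AFS elongation analysis
# --------------------------------------------------------------------------


def afs_elongation(
    times: np.ndarray,
    position: np.ndarray,
    uncaging_windows: Sequence[tuple[float, float]],
    median_window_s: float = 10.0,
    sg_window_s: float = 3.0,
    sg_order: int = 3,
    rate_window_s: float = 6.25,
    interval_s: float = 30.0,
    rise_per_bp: float | None = None,
) -> dict:
    """Smoothed AFS elongation profile and windowed rates around uncaging.

    The raw bead position is smoothed with a ``median_window_s`` median
    filter followed by Savitzky–Golay filtering (window ``sg_window_s``,
    polynomial order ``sg_order``).  For every uncaging-window start, average
    elongation rates over consecutive ``rate_window_s`` windows are computed
    for the ``interval_s`` preceding (laser off) and following (laser on) the
    transition; rates are slopes of the smoothed position (sign-flipped so
    elongation is positive; converted to bp/s when ``rise_per_bp`` is given).

    Returns a dict with ``smoothed``, ``rates_on``, ``rates_off`` and the
    per-window table ``rates``.
    """
    times = np.asarray(times, dtype=float)
    position = np.asarray(position, dtype=float)
    if times.shape != position.shape or times.size < 3:
        raise ParameterError("times and position must be matching 1-D arrays")
    fs = 1.0 / np.median(np.diff(times))

    med_k = int(round(median_window_s * fs))
    med_k = max(med_k + (med_k % 2 == 0), 3)  # odd, >= 3
    sg_k = int(round(sg_window_s * fs))
    sg_k = max(sg_k + (sg_k % 2 == 0), sg_order + 2 - ((sg_order + 2) % 2 == 0))
    if sg_k % 2 == 0:
        sg_k += 1
    if len(position) <= max(med_k, sg_k):
        raise ParameterError(
            f"trace shorter than the filter span ({max(med_k, sg_k)} samples)"
        )

    smoothed = savgol_filter(medfilt(position, med_k), sg_k, sg_order)

    win_n = int(round(rate_window_s * fs))
    rows = []
    for t_on, _t_off in uncaging_windows:
        for phase, t0, t1 in (
            ("off", t_on - interval_s, t_on),
            ("on", t_on, t_on + interval_s),
        ):
            start = t0
            while start + rate_window_s <= t1 + 1e-9:
                sel = (times >= start) & (times < start + rate_window_s)
                if sel.sum() >= max(win_n // 2, 3):
                    slope = np.polyfit(times[sel], smoothed[sel], 1)[0]
                    rate = -slope  # bead moves toward the chip during elongation
                    if rise_per_bp:
                        rate /= rise_per_bp
                    rows.append({"t_start": start, "phase": phase, "rate": rate})
                start += rate_window_s

    rates = pd.DataFrame(rows, columns=["t_start", "phase", "rate"])
    on = rates.loc[rates["phase"] == "on", "rate"].to_numpy()
    off = rates.loc[rates["phase"] == "off", "rate"].to_numpy()
    return {"smoothed": smoothed, "rates": rates, "rates_on": on, "rates_off": off}
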