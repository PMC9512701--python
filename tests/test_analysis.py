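"""Analysis pipeline: corrections, step detection, mixtures, rates, AFS."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lagoon import analysis as an
from lagoon import kinetics as kin
from lagoon import traces as tr
from lagoon import uncaging as unc
from lagoon.errors import ParameterError
from tests.conftest import correction_for, staircase_paths


class TestCorrectChannels:
    def test_identity_when_no_crosstalk(self, rng):
        n, m = 4, 120
        ts = tr.TraceSet(
            times=np.arange(m) / 10.0,
            i_dd=rng.uniform(0.2, 1.0, (n, m)),
            i_da=rng.uniform(0.2, 1.0, (n, m)),
            i_aa=rng.uniform(0.5, 1.0, (n, m)),
            annotations=pd.DataFrame({"trace_id": range(n)}),
        )
        out = an.correct_channels(ts, an.CorrectionParams(0.0, 0.0, 1.0))
        np.testing.assert_allclose(out.donor, ts.i_dd)
        np.testing.assert_allclose(out.acceptor, ts.i_da)

    def test_round_trip_recovers_ideal_fret(self, rng, make_staircase_paths):
        # noiseless, bleach-free forward model with crosstalk and gamma, then
        # the matching correction: the pipeline identity of the package
        om = tr.OpticalModel(
            bleedthrough=0.12, direct_excitation=0.07, gamma=1.3,
            sigma=(0.0, 0.0, 0.0), donor_bleach_half_life=1e9,
            acceptor_bleach_half_life=1e9, aa_interleave=1,
        )
        paths = make_staircase_paths(6, rng)
        ts = tr.synthesize_traces(paths, om, duration=15.0, seed=3)
        out = an.correct_channels(ts, correction_for(om))
        ideal = np.vstack([tr.fret_from_state(p, ts.times) for p in paths])
        assert np.nanmax(np.abs(out.fret - ideal)) < 1e-9

    def test_post_bleach_frames_masked_not_errored(self, rng,
                                                   make_staircase_paths):
        om = tr.OpticalModel(sigma=(0.01, 0.01, 0.01),
                             donor_bleach_half_life=2.0,
                             acceptor_bleach_half_life=1e9)
        paths = make_staircase_paths(10, rng)
        ts = tr.synthesize_traces(paths, om, duration=30.0, seed=4)
        out = an.correct_channels(ts, correction_for(om))
        assert out.masked.any()
        assert np.all(np.isnan(out.fret[out.masked]))

    def test_acceptor_dark_gives_near_zero_fret(self, rng):
        n, m = 3, 100
        i_dd = np.full((n, m), 1.0)
        ts = tr.TraceSet(
            times=np.arange(m) / 10.0,
            i_dd=i_dd,
            i_da=np.zeros((n, m)),
            i_aa=np.full((n, m), 1.0),
            annotations=pd.DataFrame({"trace_id": range(n)}),
        )
        out = an.correct_channels(ts, an.CorrectionParams(0.0, 0.0, 1.0))
        assert np.nanmax(np.abs(out.fret)) < 1e-9


class TestCy5Ratio:
    def _population(self, rng, n=1000, frac_unwound=0.6):
        m = 100
        times = np.arange(m) / 10.0
        unwound = rng.random(n) < frac_unwound
        i_aa = np.full((n, m), 1.0)
        i_da = np.full((n, m), 0.9)  # FRET-sensitized acceptor emission
        i_dd = np.full((n, m), 0.2)
        for i in range(n):
            if unwound[i]:
                i_da[i, 50:] = 0.05  # donor strand gone: direct floor only
                i_dd[i, 50:] = 0.0
        noise = rng.normal(0, 0.02, (3, n, m))
        ts = tr.TraceSet(
            times=times, i_dd=i_dd + noise[0], i_da=i_da + noise[1],
            i_aa=i_aa + noise[2],
            annotations=pd.DataFrame({"trace_id": range(n)}),
        )
        return ts, unwound

    def test_intact_ratio_exceeds_unwound_ratio(self, rng):
        ts, unwound = self._population(rng, n=200)
        table = an.cy5_ratio(ts)
        intact_after = table.loc[~unwound & table.included, "ratio_after"]
        lost_after = table.loc[unwound & table.included, "ratio_after"]
        assert intact_after.median() > 5 * lost_after.median()

    def test_fraction_unwound_recovered(self, rng):
        ts, unwound = self._population(rng, n=1000, frac_unwound=0.6)
        table = an.cy5_ratio(ts)
        assert abs(table.attrs["fraction_unwound"] - unwound.mean()) < 0.03

    def test_acceptorless_molecules_excluded(self, rng):
        ts, _ = self._population(rng, n=100)
        ts.i_aa[:5] = 0.0
        table = an.cy5_ratio(ts)
        assert not table["included"][:5].any()

    def test_dark_da_channel_hits_direct_excitation_floor(self, rng):
        # with the donor gone, I_DA contains only direct acceptor excitation:
        # ratio -> alpha
        alpha, m, n = 0.06, 100, 50
        ts = tr.TraceSet(
            times=np.arange(m) / 10.0,
            i_dd=np.zeros((n, m)),
            i_da=np.full((n, m), alpha),
            i_aa=np.full((n, m), 1.0),
            annotations=pd.DataFrame({"trace_id": range(n)}),
        )
        table = an.cy5_ratio(ts)
        np.testing.assert_allclose(table["ratio_after"], alpha, rtol=1e-9)


class TestFindSteps:
    def test_flat_noise_rarely_yields_steps(self):
        rng = np.random.default_rng(0)
        fp = sum(
            an.find_steps(rng.normal(0.0, 1.0, 300)).n_steps > 0
            for _ in range(1000)
        )
        assert fp / 1000 < 0.05

    def test_noiseless_staircase_recovered_exactly(self):
        y = np.concatenate([np.full(30, 0.3), np.full(25, 0.4),
                            np.full(40, 0.5), np.full(30, 0.6)])
        fit = an.find_steps(y)
        np.testing.assert_array_equal(fit.change_points, [30, 55, 95])
        np.testing.assert_allclose(fit.step_sizes, [0.1, 0.1, 0.1], atol=1e-12)
        assert fit.residual_chi2 < 1e-20

    def test_recall_and_precision_at_step_sigma_three(self):
        rng = np.random.default_rng(1)
        hits = tot = found = 0
        for _ in range(250):
            levels = np.repeat(np.arange(5) * 0.1, 25)
            y = levels + rng.normal(0.0, 0.1 / 3.0, len(levels))
            fit = an.find_steps(y)
            true_cp = np.arange(1, 5) * 25
            tot += len(true_cp)
            found += fit.n_steps
            for cp in fit.change_points:
                if np.min(np.abs(true_cp - cp)) <= 3:
                    hits += 1
        assert hits / tot >= 0.9
        assert hits / found >= 0.9

    def test_idempotent_on_own_reconstruction(self):
        rng = np.random.default_rng(5)
        y = np.repeat([0.0, 0.1, 0.3], 40) + rng.normal(0, 0.03, 120)
        fit1 = an.find_steps(y)
        fit2 = an.find_steps(fit1.reconstruction())
        np.testing.assert_array_equal(fit1.change_points, fit2.change_points)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, derandomize=True, deadline=None)
    def test_structural_invariants(self, seed):
        rng = np.random.default_rng(seed)
        n_steps = rng.integers(0, 4)
        bounds = np.sort(rng.choice(np.arange(10, 140), n_steps, replace=False))
        y = np.zeros(150)
        for b in bounds:
            y[b:] += rng.uniform(0.05, 0.3)
        y += rng.normal(0, 0.02, 150)
        fit = an.find_steps(y)
        assert np.all(np.diff(fit.change_points) > 0)
        assert len(fit.plateaus) == fit.n_steps + 1
        assert len(fit.step_sizes) == fit.n_steps


class TestFirstStepSizes:
    def _fit(self, sizes):
        sizes = np.asarray(sizes, dtype=float)
        plateaus = np.concatenate([[0.3], 0.3 + np.cumsum(sizes)])
        cps = 10 * np.arange(1, len(sizes) + 1)
        return an.StepFit(change_points=cps, plateaus=plateaus,
                          step_sizes=sizes, scores=np.ones(len(sizes)),
                          residual_chi2=0.0, n_frames=10 * (len(sizes) + 2))

    def test_single_step_traces(self):
        fits = [self._fit([0.1]) for _ in range(5)]
        sizes, excluded = an.first_step_sizes(fits)
        np.testing.assert_allclose(sizes, 0.1)
        assert excluded == 0

    def test_steps_after_first_decrease_ignored(self):
        fits = [self._fit([-0.2, 0.1])]
        sizes, excluded = an.first_step_sizes(fits)
        assert len(sizes) == 0 and excluded == 1
        fits = [self._fit([0.15, -0.2, 0.4])]
        sizes, _ = an.first_step_sizes(fits)
        np.testing.assert_allclose(sizes, [0.15])

    def test_mixed_population_proportions(self, rng):
        # 70/30 mixture of 0.1 / 0.2 single-step traces: the sample proportion
        # of large steps must fall within a 3-sigma binomial interval
        n = 600
        big = rng.random(n) < 0.3
        fits = [self._fit([0.2 if b else 0.1]) for b in big]
        sizes, _ = an.first_step_sizes(fits)
        p_hat = np.mean(sizes > 0.15)
        assert abs(p_hat - 0.3) < 3 * math.sqrt(0.3 * 0.7 / n)

    def test_all_flat_traces_counted(self):
        fits = [self._fit([]) for _ in range(4)]
        sizes, excluded = an.first_step_sizes(fits)
        assert len(sizes) == 0 and excluded == 4


class TestTwoGaussianMixture:
    def test_single_gaussian_sample_has_negligible_compound_weight(self, rng):
        x = rng.normal(0.1, 0.02, 800)
        fit = an.fit_two_gaussians(x, fix_component2=(0.2, 0.02), seed=0)
        assert fit.compound_fraction < 0.05

    def test_parameter_recovery_5050(self, rng):
        x = np.concatenate([rng.normal(0.1, 0.01, 500),
                            rng.normal(0.2, 0.01, 500)])
        fit = an.fit_two_gaussians(x, seed=0)
        w = np.sort(fit.weights)
        assert np.all(np.abs(w - 0.5) < 0.04)
        means = np.sort(fit.means)
        assert means[0] == pytest.approx(0.1, abs=0.005)
        assert means[1] == pytest.approx(0.2, abs=0.005)

    def test_degenerate_fixed_component_weight_is_count_fraction(self, rng):
        # zero overlap between the components: the EM weight must equal the
        # exact fraction of points under the fixed component
        n_big = 37
        x = np.concatenate([rng.normal(0.1, 0.001, 163),
                            rng.normal(5.0, 0.001, n_big)])
        fit = an.fit_two_gaussians(x, fix_component2=(5.0, 0.001), seed=0)
        assert fit.compound_fraction == pytest.approx(n_big / 200, abs=1e-6)

    def test_weights_sum_to_one_and_permutation_invariant(self, rng):
        x = np.concatenate([rng.normal(0.1, 0.02, 300),
                            rng.normal(0.22, 0.03, 200)])
        fit1 = an.fit_two_gaussians(x, seed=0)
        fit2 = an.fit_two_gaussians(rng.permutation(x), seed=0)
        assert fit1.weights.sum() == pytest.approx(1.0)
        assert fit1.compound_fraction == pytest.approx(fit2.compound_fraction,
                                                       abs=1e-3)

    def test_small_sample_rejected(self, rng):
        with pytest.raises(ParameterError):
            an.fit_two_gaussians(rng.normal(0, 1, 10))


def synthesize_unwinding_traces(atp_conc, n_molecules, hk, seed, duration=80.0,
                                sigma=0.01):
    """Helicase traces at constant [ATP] through the full forward model."""
    t = np.arange(0.0, duration, 0.05)
    paths = kin.simulate_unwinding(t, np.full_like(t, atp_conc), hk,
                                   n_molecules=n_molecules, seed=seed)
    om = tr.OpticalModel(sigma=(sigma,) * 3, frame_rate=10.0,
                         donor_bleach_half_life=1e9,
                         acceptor_bleach_half_life=1e9, aa_interleave=1)
    ts = tr.synthesize_traces(paths, om, duration=duration, seed=seed + 1)
    return an.correct_channels(ts, correction_for(om))


class TestUnwindingRate:
    def test_fixed_interval_gives_reciprocal_rate(self):
        hk = kin.HelicaseKinetics(vmax=0.25, km=1.0, onset_rate=50.0,
                                  speed_cv=0.0)
        corrected = synthesize_unwinding_traces(1e6, 20, hk, seed=0, sigma=0.0)
        est = an.unwinding_rate(corrected)
        # every molecule unwinds in exactly 4 s; rate exact to frame quantization
        assert est.n == 20
        np.testing.assert_allclose(est.rates, 0.25, rtol=0.1)
        assert est.mean == pytest.approx(0.25, rel=0.05)

    def test_incomplete_traces_excluded_and_counted(self):
        hk = kin.HelicaseKinetics(vmax=0.01, km=1.0, onset_rate=0.01)
        corrected = synthesize_unwinding_traces(1e6, 30, hk, seed=1)
        est = an.unwinding_rate(corrected)
        assert est.n + est.n_excluded == 30
        assert est.n_excluded > 0

    def test_titration_recovers_km(self):
        # full synthetic Michaelis-Menten titration through traces
        hk = kin.HelicaseKinetics(vmax=1.0, km=40.0, onset_rate=2.0,
                                  speed_cv=0.15)
        conc = np.array([2.0, 5.0, 10.0, 20.0, 40.0, 80.0, 160.0, 320.0])
        rates = []
        for i, c in enumerate(conc):
            corrected = synthesize_unwinding_traces(c, 200, hk, seed=10 + i,
                                                    duration=150.0)
            rates.append(an.unwinding_rate(corrected).mean)
        vmax_fit, km_fit = an.michaelis_menten_fit(conc, np.array(rates))
        assert abs(km_fit - 40.0) / 40.0 < 0.15


class TestEffectiveAtpMapping:
    def _mm(self, x, vmax=1.0, km=50.0):
        return vmax * x / (km + x)

    def test_rescaled_curves_map_is_multiplication(self):
        atp = np.array([1, 5, 10, 30, 60, 120, 300, 600], dtype=float)
        c = 12.5  # µM effective per W/cm²
        power = atp / c
        tbl_atp = pd.DataFrame({"atp": atp, "rate": self._mm(atp)})
        tbl_pow = pd.DataFrame({"power": power, "rate": self._mm(power * c)})
        mapped = an.effective_atp_mapping(tbl_pow, tbl_atp)
        ok = ~mapped["flagged"]
        np.testing.assert_allclose(mapped.loc[ok, "effective_atp"],
                                   c * mapped.loc[ok, "power"], rtol=0.02)

    def test_rate_above_saturation_flagged(self):
        atp = np.array([1, 10, 100, 1000], dtype=float)
        tbl_atp = pd.DataFrame({"atp": atp, "rate": self._mm(atp)})
        tbl_pow = pd.DataFrame({"power": [1.0], "rate": [2.0]})
        mapped = an.effective_atp_mapping(tbl_pow, tbl_atp)
        assert mapped["flagged"].iloc[0]
        assert math.isnan(mapped["effective_atp"].iloc[0])

    def test_non_monotone_titration_rejected(self):
        tbl_atp = pd.DataFrame({"atp": [1.0, 2.0, 3.0],
                                "rate": [0.1, 0.3, 0.2]})
        tbl_pow = pd.DataFrame({"power": [1.0], "rate": [0.15]})
        with pytest.raises(ParameterError):
            an.effective_atp_mapping(tbl_pow, tbl_atp)


class TestAfsElongation:
    def _trace(self, rng, rate=5.0, noise=3.0):
        windows = [(60.0, 120.0), (180.0, 240.0)]
        t, bp = tr.make_elongation_profile(300.0, 20.0, windows, rate_bp_s=rate)
        trace = tr.synthesize_afs_trace(t, bp, rise_per_bp=0.3,
                                        noise_sigma=noise, rng=rng)
        return t, trace["position"].to_numpy(), windows

    def test_constant_rate_recovered_noiselessly(self):
        t, pos, windows = self._trace(np.random.default_rng(0), noise=0.0)
        out = an.afs_elongation(t, pos, windows, rise_per_bp=0.3)
        # windows away from filter edges: rate equals the set 5 bp/s
        inner = out["rates"].query("phase == 'on' and t_start > 65 and t_start < 105")
        np.testing.assert_allclose(inner["rate"], 5.0, rtol=0.05)

    def test_on_off_histograms_separate(self):
        t, pos, windows = self._trace(np.random.default_rng(1), noise=3.0)
        out = an.afs_elongation(t, pos, windows, rise_per_bp=0.3)
        on, off = out["rates_on"], out["rates_off"]
        assert len(on) and len(off)
        se = on.std(ddof=1) / math.sqrt(len(on)) + off.std(ddof=1) / math.sqrt(len(off))
        assert on.mean() - off.mean() > 5.0 - 3 * se - 1.0
        assert abs(off.mean()) < 1.0

    def test_median_filter_removes_single_sample_outlier(self):
        t = np.arange(0, 100, 0.05)
        pos = np.zeros_like(t)
        pos[1000] = 500.0
        out = an.afs_elongation(t, pos, [(50.0, 60.0)])
        assert np.abs(out["smoothed"]).max() < 1.0

    def test_trace_shorter_than_filter_rejected(self):
        t = np.arange(0, 2, 0.05)
        with pytest.raises(ParameterError):
            an.afs_elongation(t, np.zeros_like(t), [(1.0, 2.0)])
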