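"""Simulator validation against closed-form and distributional oracles."""

import math

import numpy as np
import pytest
from scipy import stats

from sptkinetics import (AcquisitionSettings, DwellGroundTruth, ImagingModel,
                         StateModel, collect_jumps, simulate_bleach_control,
                         simulate_dwell, simulate_frap, simulate_spaspt)

DT = 0.007477


def wide_open(sigma=0.0):
    """Acquisition with an effectively unbounded detection slab."""
    return AcquisitionSettings(frame_interval_s=DT, exposure_s=0.001,
                               localization_error_um=sigma,
                               detection_depth_um=90.0, gaps_allowed=1)


class TestSpaSPT:
    def test_degenerate_immobile_noiseless(self):
        """D = 0, sigma = 0, no bleach/blink: every displacement is 0."""
        im = ImagingModel(settings=wide_open(), n_molecules=50, n_frames=30,
                          axial_range_um=100.0)
        ds, _ = simulate_spaspt(StateModel((1.0,), (0.0,)), im, seed=3)
        r = np.concatenate(list(collect_jumps(ds).jumps.values()))
        assert r.size > 0
        assert np.all(r == 0.0)

    def test_msd_oracle_single_state(self):
        """Mean squared planar displacement per frame = 4 D dt."""
        im = ImagingModel(settings=wide_open(), n_molecules=2000, n_frames=120,
                          axial_range_um=100.0)
        ds, _ = simulate_spaspt(StateModel((1.0,), (1.0,)), im, seed=4)
        r = collect_jumps(ds).jumps[1]
        assert r.size >= 1e5
        msd = (r**2).mean()
        se = (r**2).std() / math.sqrt(r.size)
        assert abs(msd - 4 * 1.0 * DT) < 3 * se

    def test_jump_cdf_matches_rayleigh_closed_form(self):
        """Empirical lag-1 jump CDF vs 1 - exp(-R^2/(4 D dt)) (KS)."""
        im = ImagingModel(settings=wide_open(), n_molecules=1500, n_frames=100,
                          axial_range_um=100.0)
        ds, _ = simulate_spaspt(StateModel((1.0,), (2.0,)), im, seed=5)
        r = collect_jumps(ds).jumps[1]
        ks = stats.kstest(r, lambda x: 1.0 - np.exp(-x**2 / (4 * 2.0 * DT)))
        assert r.size > 5e4
        assert ks.statistic < 0.015

    def test_markov_switching_occupancy(self):
        """With a transition-rate matrix, time-in-state occupancy matches
        the stationary fractions within ±0.02."""
        pi = np.array([0.3, 0.3, 0.4])
        c = 20.0
        q = c * np.tile(pi, (3, 1))
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        model = StateModel(tuple(pi), (0.0025, 0.5, 5.0), transition_rates_per_s=q)
        im = ImagingModel(settings=wide_open(), n_molecules=150, n_frames=400,
                          axial_range_um=100.0)
        _, record = simulate_spaspt(model, im, seed=6, keep_states=True)
        states = record.state_per_molecule
        occ = np.array([(states == k).mean() for k in range(3)])
        assert np.abs(occ - pi).max() < 0.02

    def test_track_lengths_geometric_under_bleach_only(self):
        """No defocalization, no blinking: observed track lengths are
        geometric with per-frame survival exp(-k_bleach dt)."""
        k_bleach = 20.0
        p_surv = math.exp(-k_bleach * DT)
        im = ImagingModel(settings=wide_open(), bleach_rate_per_s=k_bleach,
                          n_molecules=4000, n_frames=500, axial_range_um=100.0)
        ds, _ = simulate_spaspt(StateModel((1.0,), (0.5,)), im, seed=7)
        lengths = np.array([len(t) for t in ds.trajectories])
        # bin lengths 1..8 plus tail; expected geometric counts
        edges = np.arange(1, 9)
        obs = np.array([(lengths == k).sum() for k in edges]
                       + [(lengths > 8).sum()])
        pk = (1 - p_surv) * p_surv ** (edges - 1)
        exp = np.append(pk, p_surv**8) * lengths.size
        chi2 = stats.chisquare(obs, exp)
        assert chi2.pvalue > 0.01

    def test_seeded_determinism(self):
        model = StateModel((0.4, 0.6), (0.0, 3.0))
        im = ImagingModel(settings=wide_open(0.03), bleach_rate_per_s=5.0,
                          gap_probability=0.1, n_molecules=300, n_frames=80,
                          axial_range_um=100.0)
        a, ra = simulate_spaspt(model, im, seed=11)
        b, rb = simulate_spaspt(model, im, seed=11)
        assert a == b
        assert ra.to_dict() == rb.to_dict()
        c, _ = simulate_spaspt(model, im, seed=12)
        assert c != a

    def test_config_errors(self):
        with pytest.raises(ValueError):
            ImagingModel(settings=wide_open(), n_molecules=0)
        with pytest.raises(ValueError):
            ImagingModel(settings=wide_open(), n_frames=0)
        with pytest.raises(ValueError):
            StateModel((0.5, 0.4), (0.0, 1.0))  # fractions do not sum to 1


class TestDwellGenerator:
    def slow_imaging(self, n_frames=10_000):
        s = AcquisitionSettings(frame_interval_s=0.5, exposure_s=0.5,
                                localization_error_um=0.03,
                                detection_depth_um=0.7)
        return ImagingModel(settings=s, n_molecules=1, n_frames=n_frames)

    def test_exponential_mean_oracle(self):
        """No bleach, all specific: sample mean ~ 1/k within 3 SE (long
        movie so censoring is negligible; half-frame discretization offset
        included)."""
        k = 1.0 / 88.0
        gt = DwellGroundTruth(1.0, k, 10 * k, 0.0)
        sample, _ = simulate_dwell(gt, self.slow_imaging(), 5000, seed=21)
        d = sample.durations_s
        se = d.std(ddof=1) / math.sqrt(d.size)
        # floor-discretized exponential conditioned on >= 1 frame has mean
        # dt / (1 - exp(-k dt)) ~ 1/k + dt/2
        expected = 0.5 / (1 - math.exp(-k * 0.5))
        assert abs(d.mean() - expected) < 3 * se
        assert abs(d.mean() - 1.0 / k) < 3 * se + 0.25

    def test_control_hazard_equals_bleach_rate(self):
        """k_off ~ 0 control: -log S(t) is linear with slope k_bleach."""
        from sptkinetics import survival
        kb = 0.02
        sample, _ = simulate_bleach_control(kb, self.slow_imaging(), 8000, seed=22)
        curve = survival(sample)
        keep = (curve.s > 0.02) & (curve.t_s > 0)
        slope = np.polyfit(curve.t_s[keep], -np.log(curve.s[keep]), 1)[0]
        assert slope == pytest.approx(kb, rel=0.05)

    def test_single_event_reproducible(self):
        gt = DwellGroundTruth(0.8, 0.01, 0.1, 0.01)
        a, _ = simulate_dwell(gt, self.slow_imaging(), 1, seed=23)
        b, _ = simulate_dwell(gt, self.slow_imaging(), 1, seed=23)
        assert np.array_equal(a.durations_s, b.durations_s)
        assert a.durations_s.size == 1

    def test_invalid_ground_truth(self):
        with pytest.raises(ValueError):
            DwellGroundTruth(0.8, 0.1, 0.05, 0.01)  # non-specific slower


class TestFrapGenerator:
    T = np.arange(-5.0, 120.0, 1.0)

    def test_noiseless_matches_closed_form(self):
        curve = simulate_frap(1.0, [(0.7, 0.05)], 0.0, self.T, seed=1)
        from sptkinetics import normalize_frap
        nf = normalize_frap(curve)
        post = nf.t_s >= 0
        expected = 1.0 - 0.7 * np.exp(-0.05 * nf.t_s[post])
        assert np.allclose(nf.intensity[post], expected, atol=1e-12)
        assert np.allclose(nf.intensity[~post], 1.0)

    def test_zero_amplitude_is_flat_and_degenerate(self):
        from sptkinetics import normalize_frap
        curve = simulate_frap(1.0, [], 0.0, self.T, seed=1)
        nf = normalize_frap(curve)
        assert nf.degenerate
        assert np.allclose(nf.intensity, 1.0)

    def test_negative_post_bleach_intensity_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            simulate_frap(0.5, [(0.8, 0.05)], 0.0, self.T, seed=1)

    def test_clt_mean_recovery(self):
        """Mean of 30 noisy replicates within 3 SEM of the closed form."""
        from sptkinetics import aggregate_frap, normalize_frap
        curves = [normalize_frap(simulate_frap(0.9, [(0.6, 0.08)], 0.03,
                                               self.T, seed=100 + i))
                  for i in range(30)]
        summ = aggregate_frap(curves)
        post = summ.t_s >= 0
        expected = 0.9 - 0.6 * np.exp(-0.08 * summ.t_s[post])
        resid = np.abs(summ.mean[post] - expected)
        assert (resid <= 3 * np.maximum(summ.sem[post], 1e-9)).mean() > 0.95
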