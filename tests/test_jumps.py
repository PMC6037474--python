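"""Jump collection, mixture CDF model, fitting, and model comparison."""

import math

import numpy as np
import pytest

from sptkinetics import (AcquisitionSettings, ImagingModel, KineticModelSpec,
                         StateModel, collect_jumps, compare_models,
                         fit_kinetic_model, jump_cdf_model,
                         merge_distributions, simulate_spaspt,
                         summarize_bound_fraction)
from sptkinetics.jumps import EmptyDistributionError, JumpLengthDistribution

from conftest import make_dataset, make_track

DT = 0.007477


def rayleigh_jump_sample(rng, fractions, diffusions, sigma, lag_s, n):
    """Independent sampler of the mixture jump-length law (oracle for the
    fitter, bypassing the spatial simulator)."""
    states = rng.choice(len(fractions), size=n, p=fractions)
    s2 = np.asarray(diffusions)[states] * lag_s + sigma**2
    return np.sqrt(-4.0 * s2 * np.log(rng.random(n)))


class TestCollectJumps:
    def test_hand_geometry(self, fast_settings):
        tr = make_track("a", [0, 1, 2], [0.0, 0.1, 0.3], [0.0, 0.0, 0.0], DT)
        dist = collect_jumps(make_dataset(fast_settings, [tr]))
        assert sorted(dist.jumps[1].tolist()) == pytest.approx([0.1, 0.2])
        assert dist.jumps[2].tolist() == pytest.approx([0.3])
        assert dist.jumps[3].size == 0

    def test_gap_spanning_goes_to_doubled_lag(self, fast_settings):
        """Frames {0,1,3}: 0->1 is lag 1; 1->3 spans the blink and is lag 2."""
        tr = make_track("a", [0, 1, 3], [0.0, 0.1, 0.4], [0.0] * 3, DT)
        dist = collect_jumps(make_dataset(fast_settings, [tr]))
        assert dist.jumps[1].tolist() == pytest.approx([0.1])
        assert dist.jumps[2].tolist() == pytest.approx([0.3])
        assert dist.jumps[3].tolist() == pytest.approx([0.4])  # 0->3

    def test_immobile_cdf_is_step_at_zero(self, fast_settings):
        tr = make_track("a", [0, 1, 2], [0.5, 0.5, 0.5], [0.5] * 3, DT)
        dist = collect_jumps(make_dataset(fast_settings, [tr]))
        grid = np.linspace(0, 1, 11)
        assert np.all(dist.empirical_cdf(1, grid) == 1.0)

    def test_singletons_only_raise(self, fast_settings):
        tracks = [make_track(f"t{i}", [0], [0.0], [0.0], DT) for i in range(3)]
        with pytest.raises(EmptyDistributionError):
            collect_jumps(make_dataset(fast_settings, tracks))

    def test_pooling_invariance(self, fast_settings):
        """Splitting a dataset into cells and merging their distributions
        equals collecting from the pooled dataset."""
        im = ImagingModel(settings=fast_settings, bleach_rate_per_s=9.0,
                          n_molecules=200, n_frames=60)
        model = StateModel((0.3, 0.7), (0.0025, 3.0))
        ds1, _ = simulate_spaspt(model, im, seed=31)
        ds2, _ = simulate_spaspt(model, im, seed=32)
        merged = merge_distributions([collect_jumps(ds1), collect_jumps(ds2)])
        from sptkinetics.trajectories import Trajectory, TrajectoryDataset
        relabeled = tuple(
            Trajectory(f"b{t.track_id}", tuple(
                type(l)(f"b{t.track_id}", l.frame, l.t_s, l.x_um, l.y_um)
                for l in t.localizations))
            for t in ds2.trajectories)
        pooled = TrajectoryDataset(fast_settings,
                                   ds1.trajectories + relabeled, {})
        direct = collect_jumps(pooled)
        for n in direct.lags:
            assert np.array_equal(np.sort(direct.jumps[n]),
                                  np.sort(merged.jumps[n]))
        # longer lags can never yield more displacements than lag 1
        counts = direct.counts()
        assert all(counts[n] <= counts[1] for n in direct.lags)


class TestJumpCdfModel:
    GRID = np.linspace(0.0, 2.0, 100)

    def test_delta_distribution(self):
        cdf = jump_cdf_model([1.0], [0.0], 0.0, DT, self.GRID)
        assert np.all(cdf[self.GRID > 0] == 1.0)

    def test_median_at_closed_form_radius(self):
        d, sigma = 1.5, 0.045
        r_half = math.sqrt(4 * (d * DT + sigma**2) * math.log(2))
        cdf = jump_cdf_model([1.0], [d], sigma, DT, np.array([r_half]))
        assert cdf[0] == pytest.approx(0.5, abs=1e-12)

    def test_median_against_monte_carlo(self):
        rng = np.random.default_rng(41)
        r = rayleigh_jump_sample(rng, [1.0], [1.5], 0.045, DT, 200_000)
        r_half = math.sqrt(4 * (1.5 * DT + 0.045**2) * math.log(2))
        assert (r <= r_half).mean() == pytest.approx(0.5, abs=0.005)

    def test_mixture_degeneracy_equal_diffusivities(self):
        one = jump_cdf_model([1.0], [0.8], 0.045, DT, self.GRID)
        two = jump_cdf_model([0.5, 0.5], [0.8, 0.8], 0.045, DT, self.GRID)
        assert np.allclose(one, two)

    def test_nondecreasing_to_one(self):
        cdf = jump_cdf_model([0.3, 0.7], [0.01, 5.0], 0.045, DT,
                             np.linspace(0, 50, 500), dz_um=0.7,
                             frame_interval_s=DT, gaps_allowed=1)
        assert (np.diff(cdf) >= -1e-12).all()
        assert cdf[-1] == pytest.approx(1.0, abs=1e-6)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            jump_cdf_model([1.0], [-1.0], 0.045, DT, self.GRID)
        with pytest.raises(ValueError):
            jump_cdf_model([1.0], [1.0], -0.1, DT, self.GRID)


class TestFitKineticModel:
    def _dist_from_sample(self, rng, fractions, diffusions, sigma, n):
        jumps = {n_lag: rayleigh_jump_sample(rng, fractions, diffusions,
                                             sigma, n_lag * DT,
                                             max(n // n_lag, 100))
                 for n_lag in (1, 2, 3, 4)}
        return JumpLengthDistribution(DT, jumps)

    def test_three_state_recovery(self):
        """F within ±0.03 and mobile-state D within 15% at >= 5e4 jumps."""
        rng = np.random.default_rng(51)
        truth_f = (0.30, 0.30, 0.40)
        truth_d = (0.002, 0.5, 5.0)
        dist = self._dist_from_sample(rng, truth_f, truth_d, 0.045, 60_000)
        spec = KineticModelSpec(n_states=3, dz_um=None, n_starts=6)
        fit = fit_kinetic_model(dist, spec)
        assert np.abs(np.array(fit.fractions) - truth_f).max() < 0.03
        assert fit.diffusion_um2s[1] == pytest.approx(0.5, rel=0.15)
        assert fit.diffusion_um2s[2] == pytest.approx(5.0, rel=0.15)
        assert sum(fit.fractions) == pytest.approx(1.0, abs=1e-9)

    def test_all_immobile_saturates_bound_state(self):
        rng = np.random.default_rng(52)
        dist = self._dist_from_sample(rng, [1.0], [0.003], 0.045, 20_000)
        spec = KineticModelSpec(n_states=3, dz_um=None, n_starts=6)
        fit = fit_kinetic_model(dist, spec)
        assert fit.bound_fraction >= 0.97

    def test_correction_reduces_bound_fraction_bias(self, fast_settings):
        """With defocalization in the data, fitting with the correction ON
        is closer to the true bound fraction than with it OFF."""
        model = StateModel((0.271, 0.30, 0.429), (0.0025, 0.5, 5.0))
        im = ImagingModel(settings=fast_settings, bleach_rate_per_s=9.0,
                          gap_probability=0.05, n_molecules=4000, n_frames=250)
        ds, _ = simulate_spaspt(model, im, seed=53)
        dist = collect_jumps(ds)
        on = fit_kinetic_model(dist, KineticModelSpec(n_states=3, dz_um=0.7,
                                                      n_starts=6))
        off = fit_kinetic_model(dist, KineticModelSpec(n_states=3, dz_um=None,
                                                       n_starts=6))
        assert abs(on.bound_fraction - 0.271) < abs(off.bound_fraction - 0.271)

    def test_deterministic_given_spec(self):
        rng = np.random.default_rng(54)
        dist = self._dist_from_sample(rng, (0.3, 0.7), (0.003, 3.0), 0.045, 10_000)
        spec = KineticModelSpec(n_states=2, dz_um=None, n_starts=4)
        a = fit_kinetic_model(dist, spec)
        b = fit_kinetic_model(dist, spec)
        assert a == b

    def test_sparse_lags_dropped(self, fast_settings):
        rng = np.random.default_rng(55)
        jumps = {1: rayleigh_jump_sample(rng, [1.0], [1.0], 0.045, DT, 5000),
                 2: rayleigh_jump_sample(rng, [1.0], [1.0], 0.045, 2 * DT, 10)}
        dist = JumpLengthDistribution(DT, jumps)
        fit = fit_kinetic_model(dist, KineticModelSpec(n_states=2, dz_um=None,
                                                       n_starts=4))
        assert list(fit.n_jumps) == [1]


class TestCompareModels:
    def test_prefers_generating_model(self, fast_settings):
        im = ImagingModel(settings=fast_settings, bleach_rate_per_s=9.0,
                          gap_probability=0.05, n_molecules=1500, n_frames=150)
        spec2 = KineticModelSpec(n_states=2, dz_um=0.7, n_starts=4)
        spec3 = KineticModelSpec(n_states=3, dz_um=0.7, n_starts=4)
        ds3, _ = simulate_spaspt(StateModel((0.27, 0.30, 0.43),
                                            (0.0025, 0.5, 5.0)), im, seed=61)
        assert compare_models(collect_jumps(ds3), spec2, spec3).preferred == 3
        ds2, _ = simulate_spaspt(StateModel((0.3, 0.7), (0.0025, 3.0)),
                                 im, seed=62)
        assert compare_models(collect_jumps(ds2), spec2, spec3).preferred == 2

    def test_criterion_penalizes_parameters_at_equal_fit(self):
        """With the same log-likelihood, the 3-state model's criterion
        exceeds the 2-state one by exactly (5 - 3) ln n."""
        from sptkinetics.jumps import KineticFit
        n = 10_000
        ll = -1234.5
        bic2 = -2 * ll + 3 * math.log(n)
        bic3 = -2 * ll + 5 * math.log(n)
        assert bic3 - bic2 == pytest.approx(2 * math.log(n))


class TestSummaries:
    def _fit(self, fb, cell):
        from sptkinetics.jumps import KineticFit
        return KineticFit(fractions=(fb, 0.3, 0.7 - fb + 1e-16),
                          diffusion_um2s=(0.002, 0.5, 5.0),
                          localization_error_um=0.045, rss=0.1,
                          n_jumps={1: 1000}, bic=0.0, n_states=3,
                          cell_id=cell)

    def test_hand_arithmetic(self):
        fits = [self._fit(0.10, "a"), self._fit(0.20, "b")]
        out = summarize_bound_fraction(fits, ["g", "g"])
        row = out.iloc[0]
        assert row["mean_bound_fraction"] == pytest.approx(0.15)
        assert row["sd"] == pytest.approx(0.070710678, abs=1e-6)
        assert row["n"] == 2

    def test_single_fit_group_has_nan_spread(self):
        out = summarize_bound_fraction([self._fit(0.25, "a")], ["g"])
        assert out.iloc[0]["mean_bound_fraction"] == pytest.approx(0.25)
        assert math.isnan(out.iloc[0]["sd"])

    def test_group_order_preserved(self):
        fits = [self._fit(0.1, "a"), self._fit(0.2, "b"), self._fit(0.3, "c")]
        out = summarize_bound_fraction(fits, ["t30", "t0", "t30"])
        assert out["group"].tolist() == ["t30", "t0"]
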