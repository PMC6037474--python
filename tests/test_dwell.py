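"""Dwell extraction, survival curves, bi-exponential fitting, bleach
correction."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from sptkinetics import (BiexpFit, DwellGroundTruth, DwellTimeSample,
                         EmptySampleError, ImagingModel, correct_and_summarize,
                         extract_dwells, fit_biexp, simulate_bleach_control,
                         simulate_dwell, survival)
from sptkinetics.dwell import (DegenerateCurveError, SurvivalCurve,
                               read_dwell_sample, write_dwell_sample)

from conftest import make_dataset, make_track


def biexp_curve(a, kf, ks, t_max=300.0, dt=0.5, n=10_000):
    """Noiseless survival curve built from the closed form, with at-risk
    counts scaled to n events."""
    t = np.arange(0.0, t_max, dt)
    s = a * np.exp(-kf * t) + (1 - a) * np.exp(-ks * t)
    return SurvivalCurve(t, s, n, np.maximum((s * n).astype(np.int64), 1))


class TestExtractDwells:
    def test_immobile_track_arithmetic(self, slow_settings):
        """11 frames at 0.5 s -> dwell 5.0 s, uncensored if movie longer."""
        tr = make_track("a", range(11), np.zeros(11), np.zeros(11), 0.5)
        end = make_track("b", range(50, 61), np.zeros(11), np.zeros(11), 0.5)
        ds = make_dataset(slow_settings, [tr, end])
        sample = extract_dwells(ds, bound_criterion_um=0.22, min_frames=2)
        assert sample.durations_s.tolist() == [5.0, 5.0]
        assert sample.censored.tolist() == [False, True]  # b touches movie end

    def test_mobile_track_excluded(self, slow_settings):
        mob = make_track("m", [0, 1, 2], [0.0, 1.0, 2.0], [0.0] * 3, 0.5)
        imm = make_track("i", [0, 1, 2], [0.0, 0.01, 0.0], [0.0] * 3, 0.5)
        ds = make_dataset(slow_settings, [mob, imm])
        sample = extract_dwells(ds, bound_criterion_um=0.22, min_frames=2)
        assert len(sample) == 1

    def test_no_qualifying_track_raises(self, slow_settings):
        mob = make_track("m", [0, 1], [0.0, 5.0], [0.0, 0.0], 0.5)
        with pytest.raises(EmptySampleError):
            extract_dwells(make_dataset(slow_settings, [mob]), 0.22, 2)

    def test_fast_tracking_data_rejected(self, fast_settings):
        tr = make_track("a", [0, 1], [0.0, 0.0], [0.0, 0.0], 0.007477)
        with pytest.raises(ValueError, match="slow-tracking"):
            extract_dwells(make_dataset(fast_settings, [tr]), 0.22, 2)

    def test_recovers_immobile_labels_on_simulated_mixture(self):
        """Bound/free classification from the displacement criterion agrees
        with generator labels to within 1% at sigma = 0.03 um."""
        from sptkinetics import AcquisitionSettings, StateModel, simulate_spaspt
        settings = AcquisitionSettings(frame_interval_s=0.5, exposure_s=0.5,
                                       localization_error_um=0.03,
                                       detection_depth_um=50.0, gaps_allowed=0)
        im = ImagingModel(settings=settings, bleach_rate_per_s=0.05,
                          n_molecules=800, n_frames=60, axial_range_um=60.0)
        model = StateModel((0.5, 0.5), (0.0, 0.5))
        ds, record = simulate_spaspt(model, im, seed=71, keep_states=True)
        states = record.state_per_molecule
        sample = extract_dwells(ds, bound_criterion_um=0.22, min_frames=2)
        qualified = set()
        for tr in ds.trajectories:
            xy = tr.xy
            if len(tr) >= 2 and (np.linalg.norm(np.diff(xy, axis=0), axis=1)
                                 <= 0.22).all():
                qualified.add(int(tr.track_id.split(".")[0]))
        labels = states[sorted(qualified)]
        assert (labels != 0).mean() <= 0.01  # qualified tracks are bound
        assert len(sample) == len(qualified)


class TestSurvival:
    def test_counting_examples(self):
        sample = DwellTimeSample(np.array([1.0, 1.0, 2.0, 4.0]),
                                 np.zeros(4, bool), 0.5)
        curve = survival(sample)
        assert curve.s[curve.t_s == 0.0][0] == 1.0
        assert curve.s[curve.t_s == 2.0][0] == 0.5

    def test_exponential_slope_oracle(self):
        rng = np.random.default_rng(81)
        k = 0.1
        d = np.maximum(np.floor(rng.exponential(1 / k, 10_000) / 0.5), 1) * 0.5
        curve = survival(DwellTimeSample(d, np.zeros(d.size, bool), 0.5))
        keep = (curve.s > 0.05) & (curve.t_s > 0)
        slope = np.polyfit(curve.t_s[keep], -np.log(curve.s[keep]), 1)[0]
        assert slope == pytest.approx(k, rel=0.05)

    def test_monotonicity_enforced(self):
        with pytest.raises(ValueError):
            SurvivalCurve(np.array([0.0, 1.0]), np.array([1.0, 1.1]), 2,
                          np.array([2, 2]))


class TestFitBiexp:
    def test_noiseless_parameter_recovery(self):
        fit = fit_biexp(biexp_curve(0.8, 0.5, 1 / 30))
        assert fit.amplitude_fast == pytest.approx(0.8, rel=0.01)
        assert fit.k_fast_per_s == pytest.approx(0.5, rel=0.01)
        assert fit.k_slow_per_s == pytest.approx(1 / 30, rel=0.01)

    def test_monoexponential_limit_flagged(self):
        fit = fit_biexp(biexp_curve(0.0, 1.0, 0.05))
        assert fit.effectively_monoexponential
        assert fit.k_slow_per_s == pytest.approx(0.05, rel=0.02)

    def test_degenerate_curve_raises(self):
        t = np.array([0.0, 0.5])
        with pytest.raises(DegenerateCurveError):
            fit_biexp(SurvivalCurve(t, np.array([1.0, 0.4]), 10,
                                    np.array([10, 4])))

    def test_simulated_sample_recovers_apparent_rate(self):
        """k_slow estimates k_off_specific + k_bleach within 10% at n=5000."""
        gt = DwellGroundTruth(0.8, 0.01, 0.1, 0.008)
        s = ImagingModel(
            settings=__import__("sptkinetics").AcquisitionSettings(
                frame_interval_s=0.5, exposure_s=0.5,
                localization_error_um=0.03, detection_depth_um=0.7),
            n_molecules=1, n_frames=600)
        sample, _ = simulate_dwell(gt, s, 5000, seed=82)
        fit = fit_biexp(survival(sample))
        assert fit.k_slow_per_s == pytest.approx(0.018, rel=0.10)


class TestCorrection:
    def test_hand_arithmetic(self):
        f = BiexpFit(0.5, 0.5, 0.05, 0.0, 100)
        c = BiexpFit(0.5, 0.5, 0.03, 0.0, 100)
        res = correct_and_summarize(f, c)
        assert res.k_corrected_per_s == pytest.approx(0.02)
        assert res.residence_time_s == pytest.approx(50.0)
        assert res.half_life_s == pytest.approx(math.log(2) / 0.02)
        assert res.half_life_s == pytest.approx(34.657, abs=0.01)

    def test_zero_bleach_identity(self):
        f = BiexpFit(0.5, 0.5, 0.04, 0.0, 100)
        c = BiexpFit(0.5, 0.5, 1e-12, 0.0, 100)
        res = correct_and_summarize(f, c)
        assert res.residence_time_s == pytest.approx(25.0, rel=1e-6)

    def test_bleach_limited_unresolvable(self):
        f = BiexpFit(0.5, 0.5, 0.02, 0.0, 100)
        c = BiexpFit(0.5, 0.5, 0.03, 0.0, 100)
        res = correct_and_summarize(f, c)
        assert not res.resolvable
        assert res.residence_time_s is None
        assert res.half_life_s is None
        assert "unresolvable" in res.to_dict()["status"]

    @given(st.floats(min_value=1e-4, max_value=1.0),
           st.floats(min_value=1e-6, max_value=0.9))
    def test_half_life_identity(self, k_app_scale, bleach_frac):
        """half_life = ln2 * residence_time, exactly, whenever resolvable."""
        k_app = k_app_scale
        k_b = bleach_frac * k_app
        res = correct_and_summarize(BiexpFit(0.5, 2 * k_app, k_app, 0.0, 10),
                                    BiexpFit(0.5, 2 * k_app, k_b, 0.0, 10))
        assert res.half_life_s == pytest.approx(math.log(2) * res.residence_time_s,
                                                rel=1e-12)
        assert res.half_life_s < res.residence_time_s

    def test_bleach_rate_invariance_of_corrected_estimate(self):
        """Sweeping the simulated bleach rate leaves the corrected residence
        time unbiased (each within 15% of truth at n=4000)."""
        imaging = ImagingModel(
            settings=__import__("sptkinetics").AcquisitionSettings(
                frame_interval_s=0.5, exposure_s=0.5,
                localization_error_um=0.03, detection_depth_um=0.7),
            n_molecules=1, n_frames=600)
        truth = 1.0 / 60.0
        for i, kb in enumerate((0.005, 0.01, 0.02)):
            gt = DwellGroundTruth(0.8, truth, 10 * truth, kb)
            sample, _ = simulate_dwell(gt, imaging, 4000, seed=90 + i)
            ctrl, _ = simulate_bleach_control(kb, imaging, 4000, seed=190 + i)
            res = correct_and_summarize(fit_biexp(survival(sample)),
                                        fit_biexp(survival(ctrl)))
            assert res.residence_time_s == pytest.approx(60.0, rel=0.15)


def test_dwell_sample_roundtrip(tmp_path):
    sample = DwellTimeSample(np.array([0.5, 1.5, 299.5]),
                             np.array([False, False, True]), 0.5)
    p = tmp_path / "dwells.csv"
    write_dwell_sample(sample, p)
    back = read_dwell_sample(p, 0.5)
    assert np.array_equal(back.durations_s, sample.durations_s)
    assert np.array_equal(back.censored, sample.censored)
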