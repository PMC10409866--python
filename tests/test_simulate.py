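"""Synthetic trace rendering, photobleaching, dataset and course generation."""

import numpy as np
import pytest
from scipy import stats

from ribodecode import (
    CameraModel,
    FRETMap,
    RateSet,
    build_scheme,
    compute_fret,
    correct_bleedthrough,
    ensemble_timecourse,
    exponential_course,
    generate_dataset,
    generate_ensemble_timecourse,
    render_trace,
    sample_bleach_time,
)
from ribodecode.scheme import StateTrajectory
from ribodecode.simulate import add_bleedthrough


def noiseless_cam(**kw):
    base = dict(noise_sd=0.0, bleedthrough=0.0, k_photobleach=0.0)
    base.update(kw)
    return CameraModel(**base)


class TestRenderTrace:
    def test_constant_state_noiseless_reproduces_fret_mean(self, fmap):
        cam = noiseless_cam()
        traj = StateTrajectory([("CR", 0.0, 33.0)], 33.0)
        trace = render_trace(traj, fmap, cam, seed=0, bleach_time=np.inf)
        e = compute_fret(trace)
        np.testing.assert_allclose(e.efficiency[e.valid], 0.9, atol=1e-9)

    def test_mid_frame_switch_is_occupancy_weighted(self, fmap):
        cam = noiseless_cam()
        dt = cam.frame_interval
        # switch exactly at the middle of frame 3
        t_sw = 3.5 * dt
        traj = StateTrajectory([("CR", 0.0, t_sw), ("HYBRID_APstar", t_sw, 33.0)], 33.0)
        trace = render_trace(traj, fmap, cam, seed=0, bleach_time=np.inf)
        e = compute_fret(trace).efficiency
        assert e[2] == pytest.approx(0.9, abs=1e-9)
        assert e[3] == pytest.approx(0.75, abs=1e-9)
        assert e[4] == pytest.approx(0.6, abs=1e-9)

    def test_bleedthrough_forward_inverse_recovers_truth(self, fmap):
        cam = noiseless_cam(bleedthrough=0.13)
        traj = StateTrajectory([("HYBRID_APstar", 0.0, 33.0)], 33.0)
        trace = render_trace(traj, fmap, cam, seed=0, bleach_time=np.inf)
        # raw acceptor is contaminated by 0.13 * donor ...
        raw_e = trace.acceptor / (trace.donor + trace.acceptor)
        assert raw_e[0] > 0.6
        # ... and the pipeline correction inverts it exactly
        e = compute_fret(correct_bleedthrough(trace, 0.13))
        np.testing.assert_allclose(e.efficiency[e.valid], 0.6, atol=1e-9)

    def test_add_then_correct_bleedthrough_is_identity(self, fmap, rng):
        cam = CameraModel(bleedthrough=0.0)
        traj = StateTrajectory([("CR", 0.0, 33.0)], 33.0)
        trace = render_trace(traj, fmap, cam, seed=5, bleach_time=np.inf)
        before = trace.acceptor.copy()
        for beta in (0.13, 0.5, 0.9):
            add_bleedthrough(trace, beta)
            corrected = correct_bleedthrough(trace, beta)
            np.testing.assert_allclose(corrected.acceptor, before, atol=1e-12)
            trace.acceptor = before.copy()

    def test_donor_bleach_darkens_both_channels(self, fmap):
        cam = noiseless_cam()
        traj = StateTrajectory([("CR", 0.0, 33.0)], 33.0)
        trace = render_trace(traj, fmap, cam, seed=0, bleach_time=10.0, bleach_mode="donor")
        i = int(10.0 / cam.frame_interval) + 1
        assert np.allclose(trace.donor[i:], 0.0) and np.allclose(trace.acceptor[i:], 0.0)

    def test_acceptor_bleach_turns_fret_dark(self, fmap):
        cam = noiseless_cam()
        traj = StateTrajectory([("CR", 0.0, 33.0)], 33.0)
        trace = render_trace(traj, fmap, cam, seed=0, bleach_time=10.0, bleach_mode="acceptor")
        i = int(10.0 / cam.frame_interval) + 1
        assert np.allclose(trace.acceptor[i:], 0.0)
        assert np.allclose(trace.donor[i:], cam.total_intensity)

    def test_empty_trajectory_rejected(self, fmap, cam):
        with pytest.raises(ValueError, match="empty"):
            render_trace(StateTrajectory([], 33.0), fmap, cam, seed=0)


class TestBleachTime:
    def test_zero_rate_never_bleaches(self):
        cam = CameraModel(k_photobleach=0.0)
        assert sample_bleach_time(cam, 0) == np.inf

    def test_mean_matches_exponential(self, cam, rng):
        draws = np.array([sample_bleach_time(cam, rng) for _ in range(10_000)])
        se = draws.std(ddof=1) / np.sqrt(draws.size)
        assert abs(draws.mean() - 1 / 0.03) < 3 * se

    def test_survival_is_exponential(self, cam, rng):
        draws = np.array([sample_bleach_time(cam, rng) for _ in range(10_000)])
        ks = stats.kstest(draws, "expon", args=(0, 1 / 0.03))
        assert ks.pvalue > 0.01

    def test_bleach_at_zero_gives_dark_trace(self, fmap):
        cam = noiseless_cam()
        traj = StateTrajectory([("CR", 0.0, 33.0)], 33.0)
        trace = render_trace(traj, fmap, cam, seed=0, bleach_time=0.0, bleach_mode="donor")
        assert np.allclose(trace.donor, 0.0) and np.allclose(trace.acceptor, 0.0)


class TestGenerateDataset:
    def test_no_association_means_all_dark(self, fmap, cam):
        rs = RateSet(k1_app=0.0)
        ts = generate_dataset(rs, fmap, cam, n_traces=5, scenario="injection",
                              n_replicates=2, seed=1)
        for trace in ts.traces:
            assert trace.ground_truth["class"] == "dark"

    def test_preformed_hybrid_only_fluctuates_between_two_levels(self, aaa_rates, fmap, cam):
        ts = generate_dataset(aaa_rates, fmap, cam, n_traces=5, protocol="hybrid_only",
                              scenario="preformed_postdecoding", n_replicates=1, seed=2)
        for trace in ts.traces:
            states = set(trace.ground_truth["trajectory"].visited())
            assert states <= {"ACCOMMODATED_CLASSICAL", "HYBRID_APstar"}

    def test_unknown_scenario_rejected(self, aaa_rates, fmap, cam):
        with pytest.raises(ValueError, match="scenario"):
            generate_dataset(aaa_rates, fmap, cam, 3, scenario="bad", seed=0)

    def test_replicate_structure_and_determinism(self, aaa_rates, fmap, cam):
        a = generate_dataset(aaa_rates, fmap, cam, 4, n_replicates=3, seed=9)
        b = generate_dataset(aaa_rates, fmap, cam, 4, n_replicates=3, seed=9)
        assert sorted({t.replicate for t in a.traces}) == [0, 1, 2]
        for ta, tb in zip(a.traces, b.traces):
            np.testing.assert_array_equal(ta.donor, tb.donor)
            np.testing.assert_array_equal(ta.acceptor, tb.acceptor)


class TestEnsembleCourses:
    def test_noise_free_course_equals_analytic(self, aaa_rates):
        s = build_scheme(aaa_rates)
        t = np.linspace(0, 5, 20)
        noisy = generate_ensemble_timecourse(s, "ACCOMMODATED_CLASSICAL", t,
                                             noise_sd=0.0, n_replicates=2, seed=0)
        clean = ensemble_timecourse(s, "ACCOMMODATED_CLASSICAL", t)
        for _, g in noisy.groupby("replicate"):
            np.testing.assert_allclose(g["signal"].to_numpy(), clean["signal"].to_numpy())

    def test_single_step_fit_recovers_rate(self):
        from ribodecode import fit_exponential

        t = np.linspace(0, 0.1, 300)
        tc = exponential_course(t, [70.0], [1.0], rising=True, noise_sd=0.01,
                                n_replicates=3, seed=4)
        fit = fit_exponential(tc, phases=1)
        assert fit.k_app[0] == pytest.approx(70.0, rel=0.05)

    def test_parallel_accommodation_routes_look_biphasic(self):
        from ribodecode.ensemble import fit_exponential_single

        rs = RateSet(k1_app=50.0, k_rev1=0.0, k2=50.0, k_rev2=0.0, k_gtp=50.0,
                     k4=50.0, k5=8.0, k7=0.0, k_hyb_fwd=0.0, k_hyb_rev=0.0,
                     k_slow=2.0, k5b=0.15)
        s = build_scheme(rs)
        t = np.linspace(0.02, 30, 200)
        tc = ensemble_timecourse(s, "ACCOMMODATED_CLASSICAL", t)
        y = tc["signal"].to_numpy()

        def sse(phases):
            y0, amps, ks, _ = fit_exponential_single(t, y, phases, rising=True)
            decay = np.exp(-np.outer(t, ks))
            pred = y0 + (amps * (1 - decay)).sum(axis=1)
            return ((pred - y) ** 2).sum()

        n = t.size
        aic1 = n * np.log(sse(1) / n) + 2 * 2
        aic2 = n * np.log(sse(2) / n) + 2 * 4
        assert aic2 < aic1  # second phase strongly preferred
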