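"""Kinetic-scheme construction, stochastic simulation and analytic solvers."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ribodecode import (
    RateSet,
    absorption_probability,
    build_scheme,
    chain_cycles,
    ensemble_timecourse,
    hitting_probability,
    mean_first_passage,
    simulate_trajectory,
)
from ribodecode.scheme import SchemeGraph

rate = st.floats(min_value=0.05, max_value=30.0, allow_nan=False)


def random_rateset(**kw):
    return RateSet(**kw)


class TestBuildScheme:
    def test_linear_chain_without_rejection_cannot_drop_off(self):
        rs = RateSet(k1_app=1.0, k_rev1=0.0, k2=2.0, k_rev2=0.0, k_gtp=3.0,
                     k4=8.0, k5=8.0, k7=0.0, k_hyb_fwd=0.0, k_hyb_rev=0.0)
        s = build_scheme(rs, "wildtype")
        assert "DROPPED" not in s.reachable_from("UNBOUND")

    def test_gtpase_deficient_protocol_stalls_at_codon_reading(self, m6_rates):
        s = build_scheme(m6_rates, "H84A")
        reach = s.reachable_from("UNBOUND")
        assert reach == {"UNBOUND", "IB", "CR"}
        # CR exits only by dissociation
        cr = s.index("CR")
        out = np.flatnonzero(s.generator[cr] > 0)
        assert [s.states[i] for i in out] == ["UNBOUND"]
        assert np.isclose(s.generator[cr, s.index("UNBOUND")], m6_rates.k_rev2)

    def test_hybrid_only_generator_is_two_state(self, aaa_rates):
        s = build_scheme(aaa_rates, "hybrid_only")
        expected = np.array([[-2.9, 2.9], [4.4, -4.4]])
        assert s.states == ("ACCOMMODATED_CLASSICAL", "HYBRID_APstar")
        np.testing.assert_allclose(s.generator, expected)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError, match="finite and >= 0"):
            RateSet(k2=-1.0)

    def test_unknown_protocol_rejected(self, aaa_rates):
        with pytest.raises(ValueError, match="protocol"):
            build_scheme(aaa_rates, "nonsense")

    @given(k1=rate, km1=rate, k2=rate, km2=rate, kg=rate, k7=rate)
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_generator_rows_sum_to_zero(self, k1, km1, k2, km2, kg, k7):
        rs = RateSet(k1_app=k1, k_rev1=km1, k2=k2, k_rev2=km2, k_gtp=kg, k7=k7)
        s = build_scheme(rs)
        np.testing.assert_allclose(s.generator.sum(axis=1), 0.0, atol=1e-12)
        off = s.generator - np.diag(np.diag(s.generator))
        assert (off >= 0).all()


class TestSimulateTrajectory:
    def test_exponential_dwell_mean(self):
        s = SchemeGraph(("A", "B"), np.array([[-1.0, 1.0], [0.0, 0.0]]))
        rng = np.random.default_rng(0)
        dwells = [simulate_trajectory(s, 100.0, rng).segments[0] for _ in range(10_000)]
        durations = np.array([t1 - t0 for _, t0, t1 in dwells])
        se = durations.std(ddof=1) / np.sqrt(durations.size)
        assert abs(durations.mean() - 1.0) < 3 * se

    def test_zero_horizon(self, aaa_rates):
        s = build_scheme(aaa_rates)
        traj = simulate_trajectory(s, 0.0, 1)
        assert traj.segments == [("UNBOUND", 0.0, 0.0)]

    def test_seed_reproducibility(self, aaa_rates):
        s = build_scheme(aaa_rates)
        a = simulate_trajectory(s, 33.0, 42)
        b = simulate_trajectory(s, 33.0, 42)
        assert a.segments == b.segments

    def test_absorbing_start_spans_horizon(self):
        s = SchemeGraph(("A",), np.array([[0.0]]))
        traj = simulate_trajectory(s, 5.0, 0)
        assert traj.segments == [("A", 0.0, 5.0)]


class TestMeanFirstPassage:
    def test_series_of_exponentials(self):
        ka, kb = 2.0, 5.0
        Q = np.array([[-ka, ka, 0.0], [0.0, -kb, kb], [0.0, 0.0, 0.0]])
        s = SchemeGraph(("A", "B", "C"), Q)
        assert mean_first_passage(s, "A", "C") == pytest.approx(1 / ka + 1 / kb)

    def test_hybrid_only_forward_passage(self, aaa_rates):
        s = build_scheme(aaa_rates, "hybrid_only")
        got = mean_first_passage(s, "ACCOMMODATED_CLASSICAL", "HYBRID_APstar")
        assert got == pytest.approx(1 / aaa_rates.k_hyb_fwd)

    def test_unreachable_target_raises(self):
        # absorbing sink cannot reach the transient states
        Q = np.array([[-1.0, 1.0], [0.0, 0.0]])
        s = SchemeGraph(("A", "B"), Q)
        with pytest.raises(ValueError, match="unreachable"):
            mean_first_passage(s, "B", {"A"})

    def test_matches_gillespie_on_branched_scheme(self):
        rs = RateSet(k1_app=1.2, k_rev1=2.0, k2=3.0, k_rev2=0.8, k_gtp=2.5,
                     k4=6.0, k5=4.0, k7=1.0, k_hyb_fwd=0.0, k_hyb_rev=0.0)
        s = build_scheme(rs)
        target = "ACCOMMODATED_CLASSICAL"
        analytic = mean_first_passage(s, "UNBOUND", target)
        rng = np.random.default_rng(7)
        hits = []
        n = 10_000
        for _ in range(n):
            traj = simulate_trajectory(s, 600.0, rng)
            for st_, t0, _ in traj.segments:
                if st_ == target:
                    hits.append(t0)
                    break
        hits = np.asarray(hits)
        se = hits.std(ddof=1) / np.sqrt(hits.size)
        assert abs(hits.mean() - analytic) < 3 * se


class TestAbsorption:
    def test_no_drop_off_means_certain_accommodation(self):
        rs = RateSet(k1_app=1.0, k_rev1=1.0, k2=2.0, k_rev2=0.5, k_gtp=3.0, k7=0.0,
                     k_hyb_fwd=0.0, k_hyb_rev=0.0)
        s = build_scheme(rs)
        h = hitting_probability(s, "ACCOMMODATED_CLASSICAL")
        assert h[s.index("UNBOUND")] == pytest.approx(1.0)

    def test_symmetric_branch_splits_evenly(self):
        rs = RateSet(k1_app=1.0, k_rev1=0.0, k2=2.0, k_rev2=0.0, k_gtp=3.0,
                     k4=4.0, k5=1e9, k7=4.0 / (1 + 4.0 / 1e9),  # k7 == k_acc
                     k_hyb_fwd=0.0, k_hyb_rev=0.0)
        s = build_scheme(rs)
        p_drop = absorption_probability(s, "DROPPED")
        assert p_drop == pytest.approx(0.5, abs=1e-6)

    def test_probabilities_sum_to_one(self, aaa_rates):
        s = build_scheme(aaa_rates)
        p_drop = absorption_probability(s, "DROPPED")
        p_acc = hitting_probability(s, {"ACCOMMODATED_CLASSICAL", "HYBRID_APstar"})[0]
        assert p_drop + p_acc == pytest.approx(1.0, abs=1e-12)

    def test_non_absorbing_target_rejected(self, aaa_rates):
        s = build_scheme(aaa_rates)
        with pytest.raises(ValueError, match="not an absorbing state"):
            absorption_probability(s, "CR")

    def test_matches_gillespie_frequency(self):
        rs = RateSet(k1_app=2.0, k_rev1=1.0, k2=4.0, k_rev2=1.5, k_gtp=3.0,
                     k4=5.0, k5=5.0, k7=2.0, k_hyb_fwd=0.0, k_hyb_rev=0.0)
        s = build_scheme(rs)
        p = absorption_probability(s, "DROPPED")
        rng = np.random.default_rng(21)
        n = 10_000
        dropped = 0
        for _ in range(n):
            traj = simulate_trajectory(s, 500.0, rng)
            if traj.segments[-1][0] == "DROPPED":
                dropped += 1
        sigma = np.sqrt(p * (1 - p) / n)
        assert abs(dropped / n - p) < 3 * sigma


class TestEnsembleTimecourse:
    def test_single_irreversible_step_closed_form(self):
        k = 0.7
        s = SchemeGraph(("A", "B"), np.array([[-k, k], [0.0, 0.0]]))
        t = np.linspace(0.01, 10, 50)
        tc = ensemble_timecourse(s, "B", t)
        np.testing.assert_allclose(tc["signal"], 1 - np.exp(-k * t), rtol=1e-10)

    def test_product_occupancy_zero_at_t0(self, aaa_rates):
        s = build_scheme(aaa_rates)
        tc = ensemble_timecourse(s, "ACCOMMODATED_CLASSICAL", np.array([0.0]))
        assert tc["signal"].iloc[0] == 0.0

    def test_empty_grid(self, aaa_rates):
        s = build_scheme(aaa_rates)
        assert ensemble_timecourse(s, "CR", []).empty

    def test_matches_gillespie_occupancy(self):
        rs = RateSet(k1_app=1.0, k_rev1=2.0, k2=3.0, k_rev2=0.5, k_gtp=2.0,
                     k4=4.0, k5=4.0, k7=0.5, k_hyb_fwd=1.0, k_hyb_rev=2.0)
        s = build_scheme(rs)
        t_grid = np.array([0.5, 1.5, 4.0])
        tc = ensemble_timecourse(s, "ACCOMMODATED_CLASSICAL", t_grid)
        rng = np.random.default_rng(3)
        n = 4000
        occ = np.zeros_like(t_grid)
        for _ in range(n):
            traj = simulate_trajectory(s, float(t_grid[-1] + 0.1), rng)
            for j, tq in enumerate(t_grid):
                occ[j] += traj.state_at(tq) == "ACCOMMODATED_CLASSICAL"
        occ /= n
        for j in range(t_grid.size):
            p = tc["signal"].iloc[j]
            sigma = max(np.sqrt(p * (1 - p) / n), 1e-4)
            assert abs(occ[j] - p) < 3.5 * sigma


class TestChainCycles:
    def test_single_cycle_matches_build_scheme(self, aaa_rates):
        one = chain_cycles([aaa_rates])
        ref = build_scheme(aaa_rates)
        m_one = mean_first_passage(one, "UNBOUND", "ACCOMMODATED_CLASSICAL")
        m_ref = mean_first_passage(ref, "UNBOUND", "ACCOMMODATED_CLASSICAL")
        assert m_one == pytest.approx(m_ref, rel=1e-9)

    def test_mfpt_additivity_without_rejection(self):
        rs = RateSet(k1_app=2.0, k_rev1=0.5, k2=3.0, k_rev2=0.2, k_gtp=4.0,
                     k4=10.0, k5=10.0, k7=0.0, k_hyb_fwd=0.0, k_hyb_rev=0.0)
        per_cycle = mean_first_passage(build_scheme(rs), "UNBOUND", "ACCOMMODATED_CLASSICAL")
        chained = chain_cycles([rs, rs, rs])
        total = mean_first_passage(chained, chained.states[0], "ACCOMMODATED_CLASSICAL_c3")
        assert total == pytest.approx(3 * per_cycle, rel=1e-9)

    def test_slow_last_cycle_delays_product(self, aaa_rates, m6_rates):
        fast = chain_cycles([aaa_rates] * 3 + [aaa_rates], final_hybrid=False)
        slow = chain_cycles([aaa_rates] * 3 + [m6_rates], final_hybrid=False)
        tf = mean_first_passage(fast, fast.states[0], "ACCOMMODATED_CLASSICAL_c4")
        ts_ = mean_first_passage(slow, slow.states[0], "ACCOMMODATED_CLASSICAL_c4")
        assert ts_ > tf

    def test_empty_cycle_list_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            chain_cycles([])
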