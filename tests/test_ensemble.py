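"""Ensemble time-course normalization, exponential fitting and comparisons."""

import numpy as np
import pandas as pd
import pytest

from ribodecode import (
    RateSet,
    build_scheme,
    compare_tau,
    delay_between,
    ensemble_timecourse,
    exponential_course,
    fit_exponential,
    hitting_probability,
    normalize_fluorescence,
    normalize_product,
)


def course(time, signal, replicate=0):
    return pd.DataFrame({"time": time, "signal": signal, "replicate": replicate})


class TestNormalization:
    def test_constant_fluorescence_becomes_ones(self):
        tc = course([0, 1, 2], [5.0, 5.0, 5.0])
        out = normalize_fluorescence(tc)
        np.testing.assert_allclose(out["signal"], 1.0)

    def test_relative_fluorescence(self):
        out = normalize_fluorescence(course([0, 1], [2.0, 3.0]))
        np.testing.assert_allclose(out["signal"], [1.0, 1.5])

    def test_normalizing_twice_is_idempotent(self):
        tc = course([0, 1, 2], [2.0, 3.0, 4.0])
        once = normalize_fluorescence(tc)
        twice = normalize_fluorescence(once)
        np.testing.assert_allclose(once["signal"], twice["signal"])

    def test_zero_initial_value_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            normalize_fluorescence(course([0, 1], [0.0, 1.0]))

    def test_product_rescale(self):
        out = normalize_product(course([0, 1, 2], [0.0, 5.0, 10.0]))
        np.testing.assert_allclose(out["signal"], [0.0, 0.5, 1.0])

    def test_unit_interval_series_unchanged(self):
        out = normalize_product(course([0, 1, 2], [0.0, 0.4, 1.0]))
        np.testing.assert_allclose(out["signal"], [0.0, 0.4, 1.0])

    def test_flat_series_rejected(self):
        with pytest.raises(ValueError, match="flat"):
            normalize_product(course([0, 1], [1.0, 1.0]))

    def test_rate_invariant_under_affine_rescale(self):
        t = np.linspace(0, 10, 60)
        y = 1 - np.exp(-0.5 * t)
        k1 = fit_exponential(course(t, y), phases=1).k_app[0]
        k2 = fit_exponential(normalize_product(course(t, 3.0 + 40.0 * y)), phases=1).k_app[0]
        assert k2 == pytest.approx(k1, rel=1e-6)


class TestFitExponential:
    def test_exact_on_noiseless_single_exponential(self):
        t = np.linspace(0, 0.1, 100)
        y = 0.2 + 0.8 * (1 - np.exp(-70.0 * t))
        fit = fit_exponential(course(t, y), phases=1)
        assert fit.k_app[0] == pytest.approx(70.0, rel=1e-6)
        assert fit.tau[0] * fit.k_app[0] == pytest.approx(1.0)

    def test_decaying_form_inferred(self):
        t = np.linspace(0, 5, 80)
        y = 0.1 + 0.9 * np.exp(-1.3 * t)
        fit = fit_exponential(course(t, y), phases=1)
        assert not fit.rising
        assert fit.k_app[0] == pytest.approx(1.3, rel=1e-6)

    def test_major_phase_identified_in_two_phase_mixture(self):
        t = np.linspace(0, 1.0, 300)
        y = 0.8 * (1 - np.exp(-20.0 * t)) + 0.2 * (1 - np.exp(-2.0 * t))
        fit = fit_exponential(course(t, y), phases=2)
        assert fit.k_app[0] == pytest.approx(20.0, rel=1e-3)
        assert fit.major_amplitude_fraction == pytest.approx(0.8, abs=0.02)

    def test_rate_rescales_with_time_units(self):
        t = np.linspace(0, 10, 80)
        y = 1 - np.exp(-0.5 * t)
        k_s = fit_exponential(course(t, y), phases=1).k_app[0]
        k_ms = fit_exponential(course(t * 1000, y), phases=1).k_app[0]
        assert k_ms == pytest.approx(k_s / 1000, rel=1e-6)

    def test_weak_second_phase_falls_back_with_note(self):
        t = np.linspace(0, 1.0, 200)
        y = 1 - np.exp(-5.0 * t)
        fit = fit_exponential(course(t, y), phases=2)
        assert fit.phases == 1
        assert "fell back" in fit.note

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match=">= 8"):
            fit_exponential(course([0, 1, 2], [0, 1, 2]), phases=1)


class TestComparisons:
    def test_delay_between_printed_lys2_taus(self):
        t = np.linspace(0, 20, 60)
        fast = fit_exponential(course(t, 1 - np.exp(-t / 0.08)), phases=1)
        slow = fit_exponential(course(t, 1 - np.exp(-t / 3.3)), phases=1)
        assert delay_between(fast, slow) == pytest.approx(3.22, abs=0.01)
        assert delay_between(fast, fast) == pytest.approx(0.0, abs=1e-9)

    def test_identical_groups_not_significant(self):
        _, p = compare_tau([1.0, 1.1, 0.9], [1.0, 1.1, 0.9], "student_unpaired")
        assert p == pytest.approx(1.0)

    def test_matches_closed_form_t_statistic(self):
        a = np.array([2.1, 2.5, 1.9, 2.3])
        b = np.array([3.0, 3.4, 2.8])
        t_stat, p = compare_tau(a, b, "student_unpaired")
        na, nb = a.size, b.size
        sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
        expected = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
        assert t_stat == pytest.approx(expected, rel=1e-12)
        assert 0 < p < 1

    def test_eightfold_tau_difference_detected_with_power(self, rng):
        hits = 0
        n_seeds = 100
        for _ in range(n_seeds):
            a = 1.0 + 0.15 * rng.normal(size=3)   # tau ~ 1 s, SEM-scale scatter
            b = 8.0 + 1.2 * rng.normal(size=3)    # 8-fold slower
            _, p = compare_tau(a, b, "student_unpaired")
            hits += p < 0.05
        assert hits / n_seeds >= 0.95

    def test_unknown_test_rejected(self):
        with pytest.raises(ValueError):
            compare_tau([1, 2], [3, 4], "paired")


class TestEndLevel:
    def test_product_end_level_equals_decoding_probability(self):
        # strong drop-off: the product plateau is the probability of ever
        # reaching the accommodated state
        rs = RateSet(k1_app=2.0, k_rev1=1.0, k2=3.0, k_rev2=1.0, k_gtp=2.0,
                     k4=4.0, k5=4.0, k7=2.0, k_hyb_fwd=0.0, k_hyb_rev=0.0)
        s = build_scheme(rs)
        p_success = hitting_probability(s, "ACCOMMODATED_CLASSICAL")[0]
        t = np.linspace(0, 40, 120)
        tc = ensemble_timecourse(s, "ACCOMMODATED_CLASSICAL", t)
        fit = fit_exponential(tc, phases=2)
        assert fit.end_level == pytest.approx(p_success, abs=0.02)
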