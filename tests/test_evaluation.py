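"""Pulse delimitation, loop quantities, error metrics and cohort evaluation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cyclebp import evaluation as ev
from cyclebp.synthetic import SyntheticConfig, central_pressure_pulse, synth_cohort


class TestPulseDetection:
    def test_tiled_pulse_window_length(self):
        pulse = central_pressure_pulse(200, 500.0, dbp=70.0, pp=40.0)
        sig = np.tile(pulse, 3)[:512]
        w = ev.detect_first_pulse(sig, 500.0)
        assert w.length == 200

    def test_constant_signal_has_no_pulse(self):
        with pytest.raises(ev.NoPulseError):
            ev.detect_first_pulse(np.full(400, 80.0), 500.0)

    def test_two_cycles_yield_first_cycle(self):
        pulse = central_pressure_pulse(250, 500.0, dbp=65.0, pp=50.0)
        sig = np.tile(pulse, 2)
        w = ev.detect_first_pulse(sig, 500.0)
        assert (w.start, w.end) == (0, 250)

    def test_short_signal_rejected(self):
        with pytest.raises(ev.NoPulseError):
            ev.detect_first_pulse(np.array([1.0, 2.0]), 500.0)


class TestLoopQuantities:
    @pytest.mark.parametrize("area,diam", [(np.pi, 2.0), (np.pi / 4, 1.0)])
    def test_area_to_diameter_identities(self, area, diam):
        assert ev.area_to_diameter(area) == pytest.approx(diam)

    def test_diameter_monotone_and_guarded(self):
        assert ev.area_to_diameter(4.0) > ev.area_to_diameter(2.0)
        with pytest.raises(ValueError):
            ev.area_to_diameter(-1.0)

    def test_strain_definition(self):
        areas = np.pi * np.array([2.0, 2.2]) ** 2 / 4
        np.testing.assert_allclose(ev.strain_from_area(areas), [0.0, 10.0], atol=1e-9)

    def test_strain_scale_invariance(self, rng):
        areas = rng.uniform(2.0, 3.0, 50)
        np.testing.assert_allclose(
            ev.strain_from_area(areas), ev.strain_from_area(areas * 4.0), atol=1e-9
        )

    def test_constant_area_gives_zero_strain(self):
        np.testing.assert_allclose(ev.strain_from_area(np.full(10, 3.0)), 0.0)

    def test_pe_modulus_exact_linear(self):
        eps = np.linspace(0, 8, 40)
        p = 80.0 + 5.0 * eps
        assert ev.pe_modulus(p, eps) == pytest.approx(5.0, abs=1e-12)

    def test_pe_modulus_translation_invariant(self, rng):
        eps = rng.uniform(0, 10, 64)
        p = rng.uniform(60, 120, 64)
        assert ev.pe_modulus(p, eps) == pytest.approx(
            ev.pe_modulus(p, eps + 3.7), abs=1e-9
        )

    def test_pe_modulus_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            ev.pe_modulus(np.array([1.0, 2.0]), np.array([1.0, 1.0]))

    def test_loop_area_circle(self):
        theta = np.linspace(0, 2 * np.pi, 256, endpoint=False)
        r = 3.0
        # strain lags pressure: traverse so the enclosed area is +pi r^2
        strain, pressure = r * np.cos(theta - 0.4), r * np.cos(theta)
        area = ev.loop_area(pressure + 80, strain + 5)
        assert area == pytest.approx(np.pi * r * r * np.sin(0.4), rel=1e-2)

    def test_loop_orientation_flips_sign(self, rng):
        theta = np.linspace(0, 2 * np.pi, 64, endpoint=False)
        p, e = np.cos(theta), np.sin(theta)
        assert ev.loop_area(p, e) == pytest.approx(-ev.loop_area(p[::-1], e[::-1]))

    def test_collinear_loop_has_zero_area(self):
        eps = np.linspace(0, 5, 30)
        assert ev.loop_area(70 + 8 * eps, eps) == pytest.approx(0.0, abs=1e-9)


class TestErrorMetrics:
    def test_rmse_identities(self, rng):
        a = rng.uniform(60, 120, 100)
        assert ev.pulse_rmse(a, a) == 0.0
        assert ev.pulse_rmse(a, a + 3.0) == pytest.approx(3.0)

    def test_rmse_matches_bruteforce_and_symmetry(self, rng):
        a = rng.uniform(60, 120, 97)
        b = rng.uniform(60, 120, 120)
        t = min(len(a), len(b))
        brute = np.sqrt(sum((a[i] - b[i]) ** 2 for i in range(t)) / t)
        assert ev.pulse_rmse(a, b) == pytest.approx(brute, rel=1e-12)
        assert ev.pulse_rmse(a, b) == ev.pulse_rmse(b, a)

    @pytest.mark.parametrize(
        "bt,be,me,mape",
        [
            ([100.0], [90.0], 10.0, 10.0),
            ([10.0, 20.0], [8.0, 24.0], -1.0, 20.0),
            ([5.0, 5.0], [5.0, 5.0], 0.0, 0.0),
        ],
    )
    def test_beta_errors_hand_cases(self, bt, be, me, mape):
        got_me, got_mape = ev.beta_errors(bt, be)
        assert got_me == pytest.approx(me, abs=1e-12)
        assert got_mape == pytest.approx(mape, abs=1e-12)

    def test_beta_errors_zero_truth_rejected(self):
        with pytest.raises(ZeroDivisionError):
            ev.beta_errors([0.0], [1.0])

    def test_bland_altman_hand_case(self):
        ba = ev.bland_altman([1.0, 0.0], [0.0, 1.0])  # diffs [1, -1]
        assert ba.mean_diff == 0.0
        assert ba.sd_diff == pytest.approx(np.sqrt(2.0))
        assert ba.loa_high == pytest.approx(1.96 * np.sqrt(2.0))
        assert ba.loa_low == pytest.approx(-1.96 * np.sqrt(2.0))

    def test_bland_altman_translation(self, rng):
        t = rng.uniform(0, 10, 30)
        e = rng.uniform(0, 10, 30)
        base = ev.bland_altman(t, e)
        shifted = ev.bland_altman(t, e + 2.5)
        assert shifted.mean_diff == pytest.approx(base.mean_diff - 2.5)
        assert shifted.sd_diff == pytest.approx(base.sd_diff)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_pe_modulus_equals_covariance_oracle(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(3, 200))
        eps = r.uniform(0, 10, n)
        p = 70 + r.uniform(2, 12) * eps + r.normal(0, 5, n)
        # brute-force two-pass covariance/variance oracle
        em, pm = eps.mean(), p.mean()
        oracle = sum((e - em) * (q - pm) for e, q in zip(eps, p)) / sum(
            (e - em) ** 2 for e in eps
        )
        assert ev.pe_modulus(p, eps) == pytest.approx(oracle, rel=1e-12)


class TestEvaluate:
    def test_identity_model_is_exact(self, prepared):
        samples, norm, window, _ = prepared
        rep = ev.evaluate(None, samples, norm, fs=window.fs_target, identity=True)
        assert rep.rmse_pressure_mean == 0.0
        assert rep.rmse_area_mean == 0.0
        assert rep.me_beta == 0.0
        assert rep.mape_beta == 0.0
        for ba in rep.bland_altman.values():
            assert ba.mean_diff == 0.0 and ba.sd_diff == 0.0

    def test_per_subject_counts(self, prepared):
        samples, norm, window, _ = prepared
        rep = ev.evaluate(None, samples, norm, fs=window.fs_target, identity=True)
        assert rep.n_subjects + rep.n_excluded == len(samples)
        assert len(rep.per_subject) == rep.n_subjects

    def test_beta_recovers_wall_modulus_at_low_viscosity(self):
        from cyclebp import preprocessing as pp
        from cyclebp import records

        cfg = SyntheticConfig(n_subjects=8, seed=21, viscosity_range=(0.05, 0.08))
        cohort, truth = synth_cohort(cfg)
        window = pp.WindowSpec.from_cohort(cohort)
        conv = records.Cohort([records.convert_record_area(r) for r in cohort])
        norm = pp.fit_minmax(conv)
        samples = pp.build_dataset(cohort, norm, window)
        rep = ev.evaluate(None, samples, norm, fs=window.fs_target, identity=True)
        df = rep.per_subject.merge(truth, on="subject_id")
        mape = 100 * np.abs(df.beta_true - df.e_true) / df.e_true
        assert mape.mean() < 5.0
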