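"""Stern-Volmer family fits, biphasic detection, mechanism classification."""

import numpy as np
import pytest

from specbind.exceptions import DataError, FitError
from specbind.quenching import (
    DEFAULT_HIGH_WINDOW,
    DEFAULT_LOW_WINDOW,
    KQ_DIFFUSION_LIMIT,
    SternVolmerResult,
    TAU0_BIOPOLYMER_S,
    classify_mechanism,
    detect_biphasic,
    hill_fit,
    modified_sv_fit,
    stern_volmer_fit,
)
from specbind.spectra import TitrationSeries
from specbind.synthetic import (
    SyntheticConfig,
    generate_hill_titration,
    generate_sv_titration,
    generate_titration,
)


def sv_series(ksv, conc_uM=(1, 5, 10, 20, 40, 80), f0=1000.0, temperature=290.0):
    conc = np.concatenate([[0.0], np.asarray(conc_uM, dtype=float) * 1e-6])
    return TitrationSeries(conc, f0 / (1.0 + ksv * conc), temperature=temperature)


class TestSternVolmer:
    def test_no_quenching_is_degenerate_with_zero_ksv(self):
        series = TitrationSeries([0, 1e-6, 2e-6, 4e-6], [500.0] * 4, temperature=290.0)
        res = stern_volmer_fit(series)
        assert res.degenerate and res.ksv == 0.0

    def test_noiseless_points_recovered_exactly(self):
        # closed-form line F0/F = 1 + 6.373e4*[Q] must refit perfectly
        res = stern_volmer_fit(sv_series(6.373e4))
        assert res.ksv == pytest.approx(6.373e4, rel=1e-9)
        assert res.intercept == pytest.approx(1.0, rel=1e-9)
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_kq_is_ksv_over_tau0(self):
        res = stern_volmer_fit(sv_series(6.373e4), tau0=1e-8)
        assert res.kq == res.ksv / res.tau0  # exact, by construction
        assert res.kq == pytest.approx(6.373e12, rel=1e-9)

    def test_too_few_points_rejected(self):
        series = TitrationSeries([0, 1e-6, 2e-6], [100, 90, 80], temperature=290.0)
        with pytest.raises(DataError):
            stern_volmer_fit(series)


class TestModifiedSternVolmer:
    def test_single_site_exact_recovery(self, single_site_config):
        series = generate_titration(single_site_config)[0]
        res = modified_sv_fit(series)
        assert res.ka == pytest.approx(3.1419e4, rel=1e-6)
        assert res.fa == pytest.approx(0.6402, rel=1e-6)
        assert res.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_fully_accessible_gives_unit_intercept(self):
        # fa = 1 limit: the modified plot intercept is exactly 1, Ka == Ksv
        config = SyntheticConfig(sites=((2.0e4, 1.0),), noise_sd=0.0)
        series = generate_titration(config)[0]
        res = modified_sv_fit(series)
        sv = stern_volmer_fit(series)
        assert res.fa == pytest.approx(1.0, rel=1e-9)
        assert res.ka == pytest.approx(sv.ksv, rel=1e-6)

    def test_window_restricts_points(self, noiseless_config):
        series = generate_titration(noiseless_config)[0]
        low = modified_sv_fit(series, DEFAULT_LOW_WINDOW)
        high = modified_sv_fit(series, DEFAULT_HIGH_WINDOW)
        assert low.n_points == 6 and high.n_points == 9
        assert low.ka > high.ka  # strong site dominates at low [Q]

    def test_unquenched_points_dropped_with_warning(self):
        conc = np.array([0, 1, 2, 3, 4]) * 1e-6
        f = np.array([100.0, 100.0, 70.0, 60.0, 55.0])  # F == F0 at 1 uM
        series = TitrationSeries(conc, f, temperature=290.0)
        with pytest.warns(UserWarning, match="F >= F0"):
            res = modified_sv_fit(series)
        assert res.n_points == 3

    def test_too_few_surviving_points_raise(self):
        series = TitrationSeries([0, 1e-6, 2e-6, 3e-6], [100, 100, 100, 90], temperature=290.0)
        with pytest.warns(UserWarning):
            with pytest.raises(FitError):
                modified_sv_fit(series)


class TestBiphasicDetection:
    def test_single_site_is_linear_hence_monophasic(self, single_site_config):
        series = generate_titration(single_site_config)[0]
        res = detect_biphasic(series)
        assert not res.is_biphasic

    def test_two_site_data_flagged_with_default_windows(self):
        config = SyntheticConfig(sites=((3.0e4, 0.64), (0.6e4, 0.36)), noise_sd=0.0)
        series = generate_titration(config)[0]
        res = detect_biphasic(series)
        assert res.is_biphasic
        assert res.curvature < 0  # concave-down in the 1/[Q] coordinates
        assert res.low_window == DEFAULT_LOW_WINDOW  # 1-25 uM
        assert res.high_window == DEFAULT_HIGH_WINDOW  # 15-80 uM

    def test_windowed_fits_bracket_the_two_sites(self):
        config = SyntheticConfig(sites=((3.0e4, 0.64), (0.6e4, 0.36)), noise_sd=0.0)
        series = generate_titration(config)[0]
        res = detect_biphasic(series)
        low = modified_sv_fit(series, res.low_window)
        high = modified_sv_fit(series, res.high_window)
        assert high.ka < low.ka
        assert 0.6e4 < high.ka < low.ka < 3.0e4 * 1.05

    def test_few_points_fall_back_to_single_window(self):
        series = sv_series(1e4, conc_uM=(1, 5, 10, 20, 40))
        res = detect_biphasic(series)
        assert res.insufficient_points and not res.is_biphasic


class TestHillFit:
    def test_forward_generated_parameters_recovered(self, noiseless_config):
        series = generate_hill_titration(1.7459e4, 0.907, noiseless_config)
        res = hill_fit(series)
        assert res.kb == pytest.approx(1.7459e4, rel=1e-6)
        assert res.n == pytest.approx(0.907, rel=1e-6)

    def test_single_site_has_unit_slope(self):
        # (F0-F)/F = Kb[Q] is a proportionality: slope exactly 1 in log-log
        series = sv_series(2.5e4, conc_uM=(1, 2, 5, 10, 20, 50))
        res = hill_fit(series)
        assert res.n == pytest.approx(1.0, rel=1e-9)
        assert res.kb == pytest.approx(2.5e4, rel=1e-6)


class TestMechanismClassification:
    @staticmethod
    def make_sv(ksv, temperature, tau0=TAU0_BIOPOLYMER_S):
        return SternVolmerResult(ksv, ksv / tau0, tau0, 1.0, 1.0, temperature)

    def test_decreasing_ksv_with_large_kq_is_static(self):
        pairs = [
            (t, self.make_sv(k, t))
            for t, k in [(290, 6.373e4), (300, 5.415e4), (310, 4.566e4)]
        ]
        assert all(r.kq > KQ_DIFFUSION_LIMIT for _, r in pairs)
        assert classify_mechanism(pairs) == "static"

    def test_increasing_ksv_with_small_kq_is_dynamic(self):
        # tau0 chosen so kq stays at the collisional level (~1e9)
        pairs = [(t, self.make_sv(k, t, tau0=1e-5)) for t, k in [(290, 1e4), (310, 2e4)]]
        assert classify_mechanism(pairs) == "dynamic"

    def test_upward_curvature_flag_forces_mixed(self):
        pairs = [(t, self.make_sv(k, t)) for t, k in [(290, 1e4), (310, 2e4)]]
        assert classify_mechanism(pairs, curvature_flag=True) == "mixed"

    def test_single_temperature_is_indeterminate(self):
        assert classify_mechanism([(290, self.make_sv(1e4, 290))]) == "indeterminate"

    def test_conflicting_signals_are_indeterminate(self):
        # Ksv decreasing but kq below the collisional limit
        pairs = [(t, self.make_sv(k, t, tau0=1e-3)) for t, k in [(290, 2e4), (310, 1e4)]]
        assert classify_mechanism(pairs) == "indeterminate"
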