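"""Tests of the single-barrier (Bell–Evans/Evans–Ritchie) kinetics."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import quad

from vwforce import (bell_evans_lifetime, effective_spring, evans_ritchie_cdf,
                     evans_ritchie_pdf, evans_ritchie_ppf, fit_bell_evans,
                     gen_rupture_dataset, kbt, loading_rate)
from vwforce.fdc import RuptureEvent


class TestDensity:
    def test_value_at_zero_force(self):
        assert evans_ritchie_pdf(0.0, 1e3, 0.05, 0.5) \
            == pytest.approx(0.05 / 1e3)

    @given(st.floats(1e-3, 1.0), st.floats(0.1, 1.0), st.floats(1e2, 1e5))
    def test_normalization(self, koff, x_beta, r):
        total, _ = quad(lambda F: evans_ritchie_pdf(F, r, koff, x_beta),
                        0, 2000, limit=200)
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_mode_matches_closed_form(self):
        koff, xb, r = 0.05, 0.5, 1e3
        F = np.linspace(0, 300, 60001)
        F_num = F[np.argmax(evans_ritchie_pdf(F, r, koff, xb))]
        F_ana = (kbt() / xb) * np.log(xb * r / (koff * kbt()))
        assert F_num == pytest.approx(F_ana, abs=0.01)

    def test_zero_loading_rate_rejected(self):
        with pytest.raises(ValueError):
            evans_ritchie_pdf(10.0, 0.0, 0.05, 0.5)

    @given(st.floats(0.01, 0.98))
    def test_ppf_inverts_cdf(self, q):
        F = evans_ritchie_ppf(q, 2e3, 0.02, 0.4)
        assert evans_ritchie_cdf(F, 2e3, 0.02, 0.4) == pytest.approx(q,
                                                                     abs=1e-9)


class TestLifetime:
    def test_zero_force_gives_tau0(self):
        assert bell_evans_lifetime(0.0, 12.0, 0.3) == pytest.approx(12.0)

    def test_one_thermal_unit_gives_tau0_over_e(self):
        F = kbt() / 0.3
        assert bell_evans_lifetime(F, 12.0, 0.3) \
            == pytest.approx(12.0 / np.e)

    def test_monotone_decreasing(self):
        taus = bell_evans_lifetime(np.linspace(0, 100, 50), 10.0, 0.3)
        assert np.all(np.diff(taus) < 0)


class TestLoadingRateArithmetic:
    def test_product(self):
        assert loading_rate(3000.0, 30.0) == pytest.approx(9e4)

    def test_zero_velocity(self):
        assert loading_rate(0.0, 30.0) == 0.0

    def test_series_spring_halves_for_equal_constants(self):
        assert effective_spring(10.0, 10.0) == pytest.approx(5.0)

    def test_stiff_protein_limit(self):
        ks = 0.05
        assert effective_spring(ks, 1e9) == pytest.approx(ks, rel=1e-6)
        assert effective_spring(ks, 1000 * ks) == pytest.approx(ks, rel=1e-3)

    @given(st.floats(0.01, 100.0), st.floats(0.01, 100.0))
    def test_series_spring_is_softer_than_both(self, ks, kp):
        ke = effective_spring(ks, kp)
        assert ke <= min(ks, kp) + 1e-12


class TestBellEvansFit:
    def test_log_reparameterization_consistency(self, study_events):
        """The optimum is insensitive to the starting scale."""
        fit1 = fit_bell_evans(study_events)
        scaled = [RuptureEvent(force=e.force, keff=e.keff,
                               velocity=e.velocity) for e in study_events]
        fit2 = fit_bell_evans(scaled)
        assert fit1.koff == pytest.approx(fit2.koff, rel=1e-6)
        assert fit1.x_beta == pytest.approx(fit2.x_beta, rel=1e-6)

    def test_event_order_invariance(self, study_events, rng):
        fit1 = fit_bell_evans(study_events)
        perm = [study_events[i]
                for i in rng.permutation(len(study_events))]
        fit2 = fit_bell_evans(perm)
        assert fit1.koff == pytest.approx(fit2.koff, rel=1e-6)

    def test_recovery_is_scale_invariant(self):
        """Doubling loading rates with matched draws leaves estimates unbiased."""
        for scale, seed in ((1.0, 8), (2.0, 8)):
            ev = gen_rupture_dataset(0.01, 0.3, [v * scale for v in
                                                 (100, 400, 1600, 3000)],
                                     10.0, 2.0, 400, seed=seed)
            fit = fit_bell_evans(ev)
            assert fit.koff == pytest.approx(0.01, rel=0.35)
            assert fit.x_beta == pytest.approx(0.3, rel=0.12)

    def test_single_loading_rate_errors(self):
        events = [RuptureEvent(force=f, keff=10.0, velocity=400.0)
                  for f in (40.0, 50.0, 60.0)]
        with pytest.raises(ValueError):
            fit_bell_evans(events)

    def test_degenerate_forces_error(self):
        events = [RuptureEvent(force=50.0, keff=k, velocity=400.0)
                  for k in (5.0, 10.0, 20.0)]
        with pytest.raises(ValueError):
            fit_bell_evans(events)

    def test_standard_errors_shrink_with_n(self):
        fits = []
        for n in (200, 1600):
            ev = gen_rupture_dataset(0.01, 0.3, (100, 400, 1600), 10.0, 2.0,
                                     n, seed=13)
            fits.append(fit_bell_evans(ev))
        assert fits[1].se_x_beta < fits[0].se_x_beta
        assert fits[1].se_koff < fits[0].se_koff
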