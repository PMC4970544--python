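"""Tests of the cusp-landscape (BSK-type) rupture model and its fit."""

import numpy as np
import pytest
from scipy.stats import kstest

from vwforce import (BSKParams, VelocitySummary, bsk_force_pdf,
                     bsk_mean_force, bsk_rate, fit_bsk, kramers_k0)
from vwforce.bsk import BSKDistribution
from oracles import cusp_mfpt_rate

PARAMS = BSKParams(E=25.0, x_b=0.8, D=1e6)


class TestRate:
    def test_zero_force_limit_matches_kramers_formula(self):
        """The printed k0 formula is the high-barrier limit of the MFPT rate."""
        for E in (15.0, 20.0, 30.0):
            p = BSKParams(E=E, x_b=0.5, D=1e7)
            ratio = kramers_k0(E, 0.5, 1e7) / bsk_rate(0.0, p)
            assert 1.0 < ratio < 1.1  # finite-barrier correction is small

    def test_formula_against_double_quadrature_oracle(self):
        """Spot-check the erf-reduced rate against brute-force MFPT."""
        for F in (0.0, 50.0, 120.0):
            k_impl = bsk_rate(F, PARAMS)
            k_oracle = cusp_mfpt_rate(F, 25.0, 0.8, 1e6)
            assert k_impl == pytest.approx(k_oracle, rel=0.01)

    def test_kramers_k0_scalings(self):
        base = kramers_k0(20.0, 0.5, 1e7)
        assert kramers_k0(20.0, 0.5, 2e7) == pytest.approx(2 * base)
        # dominant exponential beyond the prefactor turnover
        ks = [kramers_k0(E, 0.5, 1e7) for E in (5, 10, 20, 40, 80)]
        assert np.all(np.diff(ks) < 0)

    def test_rate_diverges_at_critical_force(self):
        Fc = PARAMS.critical_force
        assert bsk_rate(Fc, PARAMS) == np.inf
        assert bsk_rate(0.999 * Fc, PARAMS) > 1e6 * bsk_rate(0.0, PARAMS)


class TestDistribution:
    def test_density_nonnegative_and_normalized(self):
        from scipy.integrate import quad
        from vwforce.bsk import _h_table
        d = BSKDistribution(PARAMS, 1e4, n_grid=20001,
                            table=_h_table(PARAMS.E, 20001))
        assert np.all(d.pdf(np.linspace(0, PARAMS.critical_force, 500)) >= 0)
        total, _ = quad(d.pdf, 0, d.F_grid[-1], limit=400)
        assert total + d.survival_end == pytest.approx(1.0, abs=1e-6)

    def test_mean_force_nondecreasing_in_loading_rate(self):
        lrs = np.logspace(3, 11, 17)
        means = bsk_mean_force(PARAMS, lrs)
        assert np.all(np.diff(means) >= 0)

    def test_low_loading_rate_matches_bell_limit(self):
        """At low LR the cusp model reduces to Evans–Ritchie with
        koff = k0 and x_beta = x_b."""
        from vwforce import evans_ritchie_pdf
        lr = 500.0
        mean_bsk = BSKDistribution(PARAMS, lr).mean()
        F = np.linspace(0, 400, 40001)
        pdf = evans_ritchie_pdf(F, lr, PARAMS.k0, PARAMS.x_b)
        mean_er = np.trapezoid(F * pdf, F)
        assert mean_bsk == pytest.approx(mean_er, rel=0.15)

    def test_sampler_matches_own_cdf(self, rng):
        d = BSKDistribution(PARAMS, 1e4)
        x = d.sample(20000, rng)
        assert kstest(x, d.cdf).pvalue > 0.01

    def test_density_vanishes_beyond_critical_force(self):
        Fc = PARAMS.critical_force
        assert bsk_force_pdf(np.array([1.01 * Fc, 2 * Fc]), 1e4,
                             PARAMS).max() == 0.0

    def test_k0_property_consistent(self):
        assert PARAMS.k0 == pytest.approx(
            kramers_k0(PARAMS.E, PARAMS.x_b, PARAMS.D, PARAMS.temperature))


def _summaries(params, n_per_v, rng):
    out = []
    for v in (50, 100, 200, 400, 600, 800, 1200, 2000, 3000):
        lr = 10.0 * v
        x = BSKDistribution(params, lr).sample(n_per_v, rng)
        out.append(VelocitySummary(velocity=v, loading_rate=lr,
                                   mu=float(x.mean()),
                                   sigma=float(x.std(ddof=1))))
    return out


class TestFit:
    def test_too_few_loading_rates_errors(self):
        s = _summaries(PARAMS, 50, np.random.default_rng(0))[:2]
        with pytest.raises(ValueError):
            fit_bsk(s, n_boot=0)

    def test_summary_fit_reproduces_force_curve(self, rng):
        """The Gaussian-summary route tracks the generating mean-force
        curve in the AFM window even though its parameter estimates carry
        the Gaussian-approximation bias."""
        s = _summaries(PARAMS, 300, rng)
        res = fit_bsk(s, n_boot=0, n_starts=4)
        lrs = np.logspace(2.7, 4.5, 7)
        np.testing.assert_allclose(bsk_mean_force(res.params, lrs),
                                   bsk_mean_force(PARAMS, lrs), rtol=0.10)

    def test_exclude_max_md_changes_bridged_fit(self, rng):
        """Dropping the largest MD force (A2-unfolding pathway) is an
        input filter that changes the combined fit."""
        s = _summaries(PARAMS, 200, rng)
        md_lr = 8.3e10
        md = [(float(f), md_lr)
              for f in BSKDistribution(PARAMS, md_lr).sample(4, rng)]
        md.append((1.8 * max(f for f, _ in md), md_lr))  # outlier
        res_all = fit_bsk(s, md=md, n_boot=0, n_starts=4)
        res_excl = fit_bsk(s, md=md, exclude_max_md=True, n_boot=0,
                           n_starts=4)
        assert res_excl.n_md == len(md) - 1
        assert res_excl.params.E != pytest.approx(res_all.params.E, rel=1e-3)

    def test_bootstrap_band_covers_generating_curve(self):
        """95% parametric-bootstrap band on the mean-force curve contains
        the generating curve at >= 90% of evaluated loading rates, on
        average over independent datasets (raw-force likelihood, the
        consistent estimator)."""
        lr_grid = np.logspace(2.5, 11, 15)
        truth = bsk_mean_force(PARAMS, lr_grid)
        coverages = []
        for k, gen_seed in enumerate((101, 102, 103)):
            rng = np.random.default_rng(gen_seed)
            raw = []
            for v in (50, 100, 200, 400, 600, 800, 1200, 2000, 3000):
                lr = 10.0 * v
                for f in BSKDistribution(PARAMS, lr).sample(150, rng):
                    raw.append((float(f), lr))
            md_lr = 8.3e10
            md = [(float(f), md_lr)
                  for f in BSKDistribution(PARAMS, md_lr).sample(5, rng)]
            res = fit_bsk(None, md=md, afm_raw=raw, n_boot=100, seed=k,
                          n_starts=6, band_loading_rates=lr_grid)
            inside = ((truth >= res.band["lo95"].to_numpy())
                      & (truth <= res.band["hi95"].to_numpy()))
            coverages.append(inside.mean())
        assert np.mean(coverages) >= 0.9
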