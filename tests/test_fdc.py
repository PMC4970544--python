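"""Tests of force-distance-cycle event extraction and force statistics."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from vwforce import (FDCTrace, PeakFit, SyntheticFDCParams,
                     binding_probability, detect_rupture, fit_first_peak,
                     gen_bimodal_forces, gen_fdc_traces, select_mu_sigma)


def _manual_trace(force=42.0, keff=3.0, d_r=100.0, extent=300.0,
                  noise=0.0, seed=0):
    d = np.arange(0.0, extent, 1.0)
    d_start = d_r - 2 * force / keff
    amp = keff**2 / (4 * force)
    f = np.where((d >= d_start) & (d <= d_r), -amp * (d - d_start) ** 2, 0.0)
    if noise:
        f = f + np.random.default_rng(seed).normal(0, noise, f.size)
    return FDCTrace(distance=d, force=f, velocity=400.0, cantilever_k=30.0)


class TestDetectRupture:
    def test_flat_noisy_baseline_has_no_events(self, rng):
        d = np.arange(0.0, 200.0, 1.0)
        f = rng.normal(0, 5.0, d.size)
        trace = FDCTrace(distance=d, force=f, velocity=400.0,
                         cantilever_k=30.0)
        assert detect_rupture(trace) == []

    def test_noiseless_single_jump(self):
        ev = detect_rupture(_manual_trace(force=42.0, keff=3.0))
        assert len(ev) == 1
        assert ev[0].force == pytest.approx(42.0, abs=1e-9)
        assert ev[0].keff == pytest.approx(3.0, abs=1e-9)
        assert ev[0].loading_rate == pytest.approx(1200.0)

    def test_noisy_roundtrip_against_generator(self):
        p = SyntheticFDCParams(specific_fraction=1.0,
                               nonspecific_fraction=0.0, noise_sd=5.0,
                               n_cycles=400, seed=2)
        hits, total = 0, 0
        for t in gen_fdc_traces(p):
            ev = detect_rupture(t)
            if not ev:
                continue
            total += 1
            hits += abs(ev[-1].force - t.meta["events"][0]["force"]) \
                <= 2 * p.noise_sd
        assert total >= 380  # detection efficiency
        assert hits / total >= 0.95  # accuracy within 2 noise sd

    def test_trace_shorter_than_fit_window_errors(self):
        d = np.arange(0.0, 10.0, 1.0)
        trace = FDCTrace(distance=d, force=np.zeros_like(d), velocity=400.0,
                         cantilever_k=30.0)
        with pytest.raises(ValueError):
            detect_rupture(trace, fit_window=20.0)


class TestBindingProbability:
    def test_simple_ratio(self):
        evs = [[1]] * 30 + [[]] * 70
        stats = binding_probability(evs)
        assert stats.bp == pytest.approx(0.3)
        assert stats.n_total == 100

    def test_all_empty(self):
        assert binding_probability([[], [], []]).bp == 0.0

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            binding_probability([])

    def test_reorder_invariance(self, rng):
        evs = [[1]] * 13 + [[]] * 37
        perm = [evs[i] for i in rng.permutation(len(evs))]
        assert binding_probability(evs).bp == binding_probability(perm).bp

    def test_blocking_signature(self):
        """Blocking the tip ligand collapses the binding probability."""
        bps = {}
        for label, frac in (("unblocked", 0.4), ("blocked", 0.05)):
            p = SyntheticFDCParams(specific_fraction=frac,
                                   nonspecific_fraction=0.0, noise_sd=5.0,
                                   n_cycles=800, seed=11)
            bps[label] = binding_probability(
                [detect_rupture(t) for t in gen_fdc_traces(p)]).bp
        ratio = bps["blocked"] / bps["unblocked"]
        assert ratio < 0.3  # dramatic decrease; generator truth is 1/8
        assert abs(ratio - 1 / 8) < 0.1


class TestFirstPeak:
    def test_recovers_pure_gaussian(self, rng):
        x = rng.normal(30.0, 5.0, 5000)
        peak = fit_first_peak(x)
        assert peak.mu == pytest.approx(30.0, rel=0.05)
        assert peak.sigma == pytest.approx(5.0, rel=0.05)

    def test_returns_lower_component_of_mixture(self):
        x = gen_bimodal_forces(25, 6, 60, 10, w1=0.6, n=5000, seed=1)
        peak = fit_first_peak(x)
        assert peak.mu == pytest.approx(25.0, rel=0.10)
        assert peak.sigma == pytest.approx(6.0, rel=0.10)
        assert abs(peak.mu - x.mean()) > 5  # not the global mean

    def test_degenerate_distribution_errors(self):
        with pytest.raises(ValueError):
            fit_first_peak(np.full(200, 42.0))

    def test_too_few_forces_errors(self):
        with pytest.raises(ValueError):
            fit_first_peak(np.arange(10.0))


class TestSelection:
    def test_retains_about_683_percent(self, rng):
        x = rng.normal(30.0, 5.0, 20000)
        peak = fit_first_peak(x)
        frac = select_mu_sigma(x, peak).size / x.size
        assert abs(frac - 0.683) < 0.02

    def test_boundary_point_is_kept(self):
        peak = PeakFit(mu=30.0, sigma=5.0)
        kept = select_mu_sigma([35.0, 25.0, 35.0001, 24.9999], peak)
        assert kept.tolist() == [35.0, 25.0]

    def test_all_outside_gives_empty(self):
        peak = PeakFit(mu=30.0, sigma=1.0)
        assert select_mu_sigma([10.0, 50.0], peak).size == 0

    @given(st.lists(st.floats(0.0, 200.0), min_size=0, max_size=50))
    def test_subset_and_idempotent(self, forces):
        peak = PeakFit(mu=50.0, sigma=20.0)
        once = select_mu_sigma(forces, peak)
        assert set(once.tolist()) <= set(forces)
        np.testing.assert_array_equal(select_mu_sigma(once, peak), once)
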