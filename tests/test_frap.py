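"""FRAP normalization, exponential fits, PDE solver and its oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from chromohop import (
    FrapCurve,
    KineticModel,
    NucleusGeometry,
    fit_exponential_recovery,
    fit_reaction_diffusion,
    normalize_frap,
    quantify_intensity,
    solve_reaction_diffusion,
    soumpasis_recovery,
)
from chromohop.models import BleachProtocol, ProtocolError

LN2 = np.log(2.0)


def _raw_table(t, bleach, unbleached, background):
    return pd.DataFrame({
        "t_s": t, "bleach": bleach, "unbleached": unbleached,
        "background": background,
    })


class TestNormalizeFrap:
    def test_single_point_arithmetic(self):
        """background 10, bleached 30, unbleached 90 -> (30-10)/(90-10) = 0.25
        after a unit prebleach ratio."""
        t = np.array([-1.0, 0.0])
        raw = _raw_table(t, [90.0, 30.0], [90.0, 90.0], [10.0, 10.0])
        curve = normalize_frap(raw, n_prebleach=1)
        assert curve.intensity_norm[1] == pytest.approx(0.25)

    def test_prebleach_mean_is_exactly_one(self):
        rng = np.random.default_rng(1)
        t = np.arange(-10.0, 20.0)
        b = 50 + rng.uniform(-5, 5, t.size)
        raw = _raw_table(t, b, 80.0 + np.zeros(t.size), 5.0 + np.zeros(t.size))
        curve = normalize_frap(raw, n_prebleach=10)
        assert curve.intensity_norm[:10].mean() == pytest.approx(1.0, abs=1e-9)

    def test_constant_series_normalizes_to_flat_one(self):
        t = np.arange(-5.0, 30.0)
        raw = _raw_table(t, 60.0 + np.zeros(t.size), 90.0 + np.zeros(t.size),
                         10.0 + np.zeros(t.size))
        curve = normalize_frap(raw, n_prebleach=5)
        assert np.allclose(curve.intensity_norm, 1.0)

    @given(st.floats(0.1, 100.0))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_scale_invariance(self, scale):
        t = np.arange(-5.0, 10.0)
        rng = np.random.default_rng(2)
        b = 40 + rng.uniform(0, 30, t.size)
        raw = _raw_table(t, b, 90.0 + np.zeros(t.size), 10.0 + np.zeros(t.size))
        a = normalize_frap(raw, 5).intensity_norm
        raw2 = raw.copy()
        for c in ("bleach", "unbleached", "background"):
            raw2[c] = raw2[c] * scale
        b_ = normalize_frap(raw2, 5).intensity_norm
        assert np.allclose(a, b_, rtol=1e-9)

    def test_unbleached_below_background_is_an_error(self):
        t = np.array([-1.0, 0.0])
        raw = _raw_table(t, [50.0, 20.0], [90.0, 5.0], [10.0, 10.0])
        with pytest.raises(ValueError):
            normalize_frap(raw, 1)


class TestFitExponentialRecovery:
    @staticmethod
    def _biexp_curve(t, f0, a1, h1, a2, h2, noise=0.0, seed=0):
        y = (f0 + a1 * (1 - np.exp(-LN2 / h1 * t)) + a2 * (1 - np.exp(-LN2 / h2 * t)))
        if noise:
            y = y + np.random.default_rng(seed).normal(scale=noise, size=t.size)
        return FrapCurve(t=t, intensity_norm=y)

    def test_exact_biexponential_recovered_to_four_significant_figures(self):
        t = np.concatenate([np.arange(0.2, 30, 0.2), np.arange(30, 200, 1.0)])
        curve = self._biexp_curve(t, 0.02, 0.50, 3.0, 0.45, 50.0)
        fit = fit_exponential_recovery(curve, 2)
        assert fit.amplitudes[0] == pytest.approx(0.50, rel=1e-4)
        assert fit.amplitudes[1] == pytest.approx(0.45, rel=1e-4)
        assert fit.half_lives[0] == pytest.approx(3.0, rel=1e-4)
        assert fit.half_lives[1] == pytest.approx(50.0, rel=1e-4)
        assert fit.f0 == pytest.approx(0.02, abs=1e-5)

    def test_model_selection_prefers_single_component_when_true(self):
        t = np.arange(0.2, 60, 0.2)
        y = 0.1 + 0.85 * (1 - np.exp(-LN2 / 5.0 * t))
        y = y + np.random.default_rng(3).normal(scale=0.01, size=t.size)
        fit = fit_exponential_recovery(FrapCurve(t=t, intensity_norm=y), None)
        assert fit.model == "SINGLE_EXP"

    def test_model_selection_prefers_two_components_when_true(self):
        t = np.concatenate([np.arange(0.2, 30, 0.2), np.arange(30, 200, 1.0)])
        curve = self._biexp_curve(t, 0.02, 0.5, 2.9, 0.45, 51.0, noise=0.01, seed=4)
        fit = fit_exponential_recovery(curve, None)
        assert fit.model == "BI_EXP"

    def test_too_few_points_is_an_error(self):
        curve = FrapCurve(t=np.arange(5.0), intensity_norm=np.ones(5))
        with pytest.raises(ValueError):
            fit_exponential_recovery(curve, 2)


class TestReactionDiffusionSolver:
    def _protocol(self, times, edge=0.0):
        return BleachProtocol(radius=1.25, edge_sigma=edge, n_prebleach=5,
                              frame_times=times)

    def test_pure_diffusion_matches_soumpasis_within_one_percent(self):
        times = np.concatenate([np.arange(0.1, 5, 0.1), np.arange(5, 40, 0.5)])
        geom = NucleusGeometry(semi_axes=(25.0, 25.0))
        c = solve_reaction_diffusion((0.79, 0.0, 0.0), self._protocol(times),
                                     geom, times=times, n_r=500)
        oracle = soumpasis_recovery(times, 0.79, 1.25)
        assert np.sqrt(np.mean((c.intensity_norm - oracle) ** 2)) < 0.01

    def test_reaction_dominant_limit_matches_well_mixed_closed_form(self):
        """Large D with finite rates: the free pool mixes instantly, so the
        observable follows the closed-form well-mixed solution, whose slow
        phase decays as exp(-k_off t), within 2%."""
        k_on, k_off = 0.08, 0.04
        times = np.arange(1.0, 200, 1.0)
        geom = NucleusGeometry(semi_axes=(8.0, 8.0))
        c = solve_reaction_diffusion((50.0, k_on, k_off), self._protocol(times),
                                     geom, times=times, n_r=200)
        y = c.intensity_norm
        # well-mixed oracle: bleach removes the spot's share beta of all
        # molecules; the free pool instantly re-equilibrates at (1-beta)
        # f_eq, while bound fluorescence relaxes at rate k_off.  Observable
        # is the in/out density ratio.
        beta = (1.25 / 8.0) ** 2
        f_eq = k_off / (k_on + k_off)
        c_eq = 1.0 - f_eq
        E = np.exp(-k_off * times)
        mean_in = (1 - beta) * (1 - c_eq * E)
        mean_out = mean_in + c_eq * E
        oracle = mean_in / mean_out
        mask = times > 2.0
        assert np.max(np.abs(y[mask] - oracle[mask])) < 0.02

    def test_mass_conserved_without_bleach(self):
        times = np.arange(1.0, 30, 1.0)
        geom = NucleusGeometry(semi_axes=(8.0, 8.0))
        prot = BleachProtocol(radius=1e-9, edge_sigma=0.0, n_prebleach=3,
                              frame_times=times)
        curve, r, profiles = solve_reaction_diffusion(
            (0.79, 0.05, 0.04), prot, geom, times=times, n_r=200,
            return_profiles=True)
        n = r.size
        mass = np.array([(p[:n] + p[n:]) @ r for p in profiles])
        assert np.max(np.abs(mass / mass[0] - 1.0)) < 1e-8
        assert np.allclose(curve.intensity_norm, 1.0, atol=1e-8)

    def test_nucleus_smaller_than_spot_is_a_protocol_error(self):
        times = np.arange(1.0, 5.0)
        geom = NucleusGeometry(semi_axes=(1.0, 1.0))
        with pytest.raises(ProtocolError):
            solve_reaction_diffusion((0.5, 0.1, 0.1), self._protocol(times),
                                     geom, times=times)


class TestFitReactionDiffusion:
    def test_inverse_crime_exact_recovery(self):
        """Fitting a curve the solver itself produced recovers the
        parameters to optimizer tolerance."""
        D, k_on, k_off = 0.79, 0.0357, 0.0455
        times = np.concatenate([np.arange(0.2, 10, 0.2), np.arange(10, 120, 2.0)])
        geom = NucleusGeometry(semi_axes=(8.0, 8.0))
        prot = BleachProtocol(radius=1.25, edge_sigma=0.25, n_prebleach=5,
                              frame_times=times)
        curve = solve_reaction_diffusion((D, k_on, k_off), prot, geom,
                                         times=times, n_r=150)
        fit = fit_reaction_diffusion(curve, prot, geom, n_starts=4, n_r=150,
                                     fit_scale=False)
        assert fit.D_free == pytest.approx(D, rel=1e-3)
        assert fit.k_on_star == pytest.approx(k_on, rel=1e-3)
        assert fit.k_off == pytest.approx(k_off, rel=1e-3)

    def test_pure_diffusion_data_yields_negligible_binding(self):
        """Particle simulation without binding: fitted bound fraction < 5%."""
        from chromohop import simulate_frap

        geom = NucleusGeometry(semi_axes=(8.0, 8.0))
        times = np.concatenate([np.arange(0.1, 5, 0.1), np.arange(5, 60, 1.0)])
        prot = BleachProtocol(radius=1.25, edge_sigma=0.25, n_prebleach=10,
                              prebleach_dt=1.0, frame_times=times)
        cs = simulate_frap(KineticModel.free_only(0.79), geom, prot, 30_000,
                           seed=6, dt_sub=0.02, normalize="area")
        fit = fit_reaction_diffusion(cs["BLEACH"], prot, geom, n_starts=6,
                                     n_r=120, fit_scale=False)
        assert fit.bound_fraction < 0.05
        assert fit.D_free == pytest.approx(0.79, rel=0.15)


class TestQuantifyIntensity:
    def test_intensity_tracks_molecule_density(self):
        rng = np.random.default_rng(7)
        mask = np.zeros((40, 40), dtype=bool)
        mask[10:30, 10:30] = True
        base = rng.poisson(100.0, size=(5, 40, 40)).astype(float)
        sig1 = base + 50.0 * mask
        sig3 = base + 150.0 * mask
        r1 = quantify_intensity(sig1, mask)
        r3 = quantify_intensity(sig3, mask)
        assert r3 / r1 == pytest.approx(3.0, rel=0.1)

    def test_zero_signal_is_zero_after_background_subtraction(self):
        rng = np.random.default_rng(8)
        mask = np.zeros((30, 30), dtype=bool)
        mask[5:25, 5:25] = True
        frames = rng.normal(100.0, 2.0, size=(5, 30, 30))
        assert abs(quantify_intensity(frames, mask)) < 1.0

    def test_doubling_signal_doubles_intensity(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[5:15, 5:15] = True
        frame = np.full((20, 20), 10.0)
        one = frame + 40.0 * mask
        two = frame + 80.0 * mask
        assert (quantify_intensity(two, mask)
                == pytest.approx(2 * quantify_intensity(one, mask), rel=0.02))

    def test_empty_mask_is_an_error(self):
        with pytest.raises(ValueError):
            quantify_intensity(np.ones((10, 10)), np.zeros((10, 10), dtype=bool))
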