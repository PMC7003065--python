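"""Apparent diffusion estimator and gamma-mixture fitting."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

import sptmix as sx
from sptmix.linking import Track
from sptmix.mixture import compute_dstar, compute_dstars, dstar_density, fit_mixture


def _track_from_steps(steps, track_id=0):
    pos = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
    return Track(track_id, 0, np.arange(len(pos)), pos)


class TestComputeDstar:
    def test_hand_computed_oracle(self):
        """Four 0.1-um steps at dt = 15 ms: MSD = 0.01 um^2, D* = 1/6."""
        steps = [(0.1, 0), (0, 0.1), (-0.1, 0), (0, -0.1)]
        ad = compute_dstar(_track_from_steps(steps), 0.015)
        assert ad.d_star == pytest.approx(0.01 / (4 * 0.015))
        assert ad.n_steps_used == 4

    def test_stationary_track_zero(self):
        t = Track(0, 0, np.arange(5), np.ones((5, 2)))
        assert compute_dstar(t, 0.015).d_star == 0.0

    def test_only_first_n_steps_used(self):
        # large displacements after step 4 must not affect D*
        steps = [(0.1, 0)] * 4 + [(10.0, 0)]
        ad = compute_dstar(_track_from_steps(steps), 0.015)
        assert ad.d_star == pytest.approx(0.01 / (4 * 0.015))

    def test_short_track_rejected(self):
        t = Track(0, 0, np.arange(3), np.zeros((3, 2)))
        with pytest.raises(ValueError, match="steps"):
            compute_dstar(t, 0.015)

    def test_nonconsecutive_frames_rejected(self):
        t = Track(0, 0, np.array([0, 1, 3, 4, 5]), np.zeros((5, 2)))
        with pytest.raises(ValueError, match="consecutive"):
            compute_dstar(t, 0.015)

    def test_estimator_unbiased(self):
        """Mean D* over noise-free single-species tracks converges to D,
        with variance D^2/n."""
        D, n = 0.41, 4
        tracks, _ = sx.sample_tracks(100_000, [sx.SpeciesModel(D, 1.0)], rng=17)
        ds = compute_dstars(tracks, 0.015)["d_star_um2_s"]
        se = D / np.sqrt(n * len(ds))
        assert abs(ds.mean() - D) < 3 * se
        assert ds.var() == pytest.approx(D**2 / n, rel=0.05)

    def test_batch_matches_scalar(self):
        tracks, _ = sx.sample_tracks(50, sx.CONTROL_SPECIES, rng=3)
        batch = compute_dstars(tracks, 0.015)
        from sptmix.linking import table_to_tracks

        for t in table_to_tracks(tracks):
            ad = compute_dstar(t, 0.015)
            row = batch.loc[batch.track_id == t.track_id, "d_star_um2_s"].iloc[0]
            assert row == pytest.approx(ad.d_star)

    def test_sigma_correction_subtracts_noise_floor(self):
        tracks, _ = sx.sample_tracks(
            2000, [sx.SpeciesModel(0.0, 1.0)], localization_sigma=0.035, rng=9
        )
        raw = compute_dstars(tracks, 0.015)["d_star_um2_s"].mean()
        corrected = compute_dstars(tracks, 0.015, sigma_correction=0.035)[
            "d_star_um2_s"
        ].mean()
        assert raw == pytest.approx(0.035**2 / 0.015, rel=0.1)
        assert corrected < raw


class TestDstarDensity:
    def test_normalizes_to_one(self):
        val, _ = integrate.quad(lambda x: dstar_density(x, 0.41, 4), 0, np.inf)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_shape_one_is_exponential(self):
        x = np.linspace(0.01, 3, 50)
        assert np.allclose(dstar_density(x, 0.7, 1), np.exp(-x / 0.7) / 0.7)

    def test_mean_and_variance(self):
        d, n = 0.41, 4
        mean, _ = integrate.quad(lambda x: x * dstar_density(x, d, n), 0, np.inf)
        second, _ = integrate.quad(lambda x: x**2 * dstar_density(x, d, n), 0, np.inf)
        assert mean == pytest.approx(d, rel=1e-8)
        assert second - mean**2 == pytest.approx(d**2 / n, rel=1e-8)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            dstar_density(0.1, 0.0, 4)
        with pytest.raises(ValueError):
            dstar_density(0.1, 0.4, 0)


class TestFitMixture:
    def test_single_species_recovery(self):
        D = 0.41
        tracks, _ = sx.sample_tracks(10_000, [sx.SpeciesModel(D, 1.0)], rng=23)
        fit = fit_mixture(compute_dstars(tracks, 0.015), k=1, seed=0)
        assert fit.converged
        assert fit.species[0][0] == pytest.approx(D, rel=0.05)
        assert fit.species[0][1] == pytest.approx(1.0)

    def test_fixed_d_constrained_recovery(self):
        """Occupancy-only fit with mobilities pinned at truth: within 0.02."""
        truth_d = [0.11, 0.41, 1.24]
        truth_f = np.array([0.35, 0.325, 0.325])
        tracks, _ = sx.sample_tracks(20_000, sx.DART_SPECIES, rng=31)
        fit = fit_mixture(compute_dstars(tracks, 0.015), k=3, fixed_d=truth_d, seed=0)
        assert fit.converged
        assert fit.fixed_d == truth_d
        assert list(fit.diffusion_coefficients) == truth_d
        assert np.abs(fit.occupancies - truth_f).max() < 0.02

    def test_em_loglik_monotone_and_occupancies_normalized(self):
        tracks, _ = sx.sample_tracks(5_000, sx.CONTROL_SPECIES, rng=41)
        fit = fit_mixture(compute_dstars(tracks, 0.015), seed=4)
        assert np.all(np.diff(fit.loglik_history) > -1e-6)
        assert fit.log_likelihood >= fit.loglik_history[-1] - 1e-6
        assert fit.occupancies.sum() == pytest.approx(1.0, abs=1e-6)

    def test_beats_coarse_grid_search(self):
        """EM log-likelihood dominates a dense grid over (D1, D2, f1)."""
        tracks, _ = sx.sample_tracks(
            600,
            [sx.SpeciesModel(0.15, 0.4), sx.SpeciesModel(1.0, 0.6)],
            rng=47,
        )
        x = compute_dstars(tracks, 0.015)["d_star_um2_s"].to_numpy()
        fit = fit_mixture(x, k=2, seed=5)
        best = -np.inf
        for d1 in np.geomspace(0.02, 3, 25):
            for d2 in np.geomspace(0.02, 3, 25):
                if d2 <= d1:
                    continue
                for f1 in np.linspace(0.05, 0.95, 19):
                    ll = np.log(
                        f1 * dstar_density(x, d1, 4) + (1 - f1) * dstar_density(x, d2, 4)
                    ).sum()
                    best = max(best, ll)
        assert fit.log_likelihood >= best - 1e-9

    def test_label_switching_safety(self):
        """Different seeds agree on the ascending-sorted solution."""
        tracks, _ = sx.sample_tracks(10_000, sx.CONTROL_SPECIES, rng=53)
        ds = compute_dstars(tracks, 0.015)
        fits = [fit_mixture(ds, seed=s) for s in (0, 1, 2)]
        for f in fits:
            assert np.all(np.diff(f.diffusion_coefficients) > 0)
        for f in fits[1:]:
            assert np.allclose(
                f.diffusion_coefficients, fits[0].diffusion_coefficients, atol=1e-3
            )
            assert np.allclose(f.occupancies, fits[0].occupancies, atol=1e-3)

    def test_noise_floor_sets_immobile_mobility(self):
        """With localization noise, a truly immobile species fits at
        ~ sigma^2/dt rather than zero."""
        sigma, dt = 0.035, 0.015
        tracks, _ = sx.sample_tracks(
            5_000, [sx.SpeciesModel(0.0, 1.0)], localization_sigma=sigma, rng=59
        )
        fit = fit_mixture(compute_dstars(tracks, dt), k=1, seed=0)
        assert fit.species[0][0] == pytest.approx(sigma**2 / dt, rel=0.15)
        assert fit.species[0][0] > 0

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError, match="observations"):
            fit_mixture(np.ones(20), k=3)

    def test_zeros_tolerated_via_jitter(self):
        x = np.concatenate([np.zeros(20), np.full(20, 0.5)])
        fit = fit_mixture(x, k=1, seed=0)
        assert np.isfinite(fit.log_likelihood)


class TestClassification:
    @pytest.mark.parametrize(
        "d,expected",
        [(0.11, "immobile"), (0.2, "slow"), (0.5, "slow"), (1.5, "slow"), (2.0, "fast")],
    )
    def test_classes_and_boundary_convention(self, d, expected):
        assert sx.classify_dstar(d) == expected

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            sx.ClassificationThresholds(immobile_max=2.0, fast_min=1.5)


class TestImmobileFraction:
    def test_all_immobile_is_100_percent(self):
        tracks, _ = sx.sample_tracks(500, [sx.SpeciesModel(0.0, 1.0)], rng=61)
        ds = compute_dstars(tracks, 0.015)
        assert sx.immobile_fraction(ds, method="threshold") == 100.0

    def test_mixture_vs_threshold_methods_agree_roughly(self):
        """Both estimates land near the 35% ground truth; the threshold
        method is biased by species overlap across the 0.2 um^2/s cut."""
        tracks, _ = sx.sample_tracks(20_000, sx.DART_SPECIES, rng=67)
        ds = compute_dstars(tracks, 0.015)
        fit = fit_mixture(ds, seed=0)
        by_mix = sx.immobile_fraction(fit)
        by_thr = sx.immobile_fraction(ds, method="threshold")
        assert abs(by_mix - 35.0) < 3.0
        assert abs(by_thr - 35.0) < 6.0

    def test_unconverged_fit_directs_to_threshold(self):
        fit = sx.MixtureFit(
            species=[(0.1, 0.5), (1.0, 0.5)],
            n_steps=4,
            log_likelihood=-1.0,
            n_tracks=100,
            converged=False,
        )
        with pytest.raises(ValueError, match="threshold"):
            sx.immobile_fraction(fit)

    def test_type_errors(self):
        with pytest.raises(TypeError):
            sx.immobile_fraction(np.ones(10), method="mixture")
        with pytest.raises(ValueError, match="method"):
            sx.immobile_fraction(np.ones(10), method="bogus")
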