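"""Density estimation, mode detection, candidate scoring and calling."""

import math

import numpy as np
import pytest

from abploidy.ploidy_model import (
    DensityCurve,
    FractionProfile,
    ModelConfig,
    PloidyModelSpec,
    TooFewSitesError,
    call_ploidy,
    default_candidates,
    detect_modes,
    estimate_density,
    fit_fixed_mean_mixture,
    score_candidates,
)
from abploidy.readsim import SimConfig, simulate_sample


def _profile(fractions, sample_id="t"):
    return FractionProfile(sample_id, tuple(fractions))


def sim_profile(m, seed, n_sites=3000, **kw):
    cfg = SimConfig(m=m, n_sites=n_sites, depth_min=25, depth_max=60,
                    seed=seed, **kw)
    return simulate_sample(cfg, sample_id=f"m{m}")


class TestDensity:
    def test_point_mass_peaks_at_the_mass(self):
        curve = estimate_density(_profile([0.5] * 300))
        assert abs(curve.grid[np.argmax(curve.density)] - 0.5) < 1e-2

    def test_integrates_to_one(self):
        curve = estimate_density(sim_profile(3, seed=11))
        assert np.trapezoid(curve.density, curve.grid) == pytest.approx(1.0, abs=1e-6)

    def test_uniform_sample_is_flat_in_the_interior(self):
        rng = np.random.default_rng(5)
        curve = estimate_density(_profile(rng.uniform(0.05, 0.95, size=20_000)))
        sel = (curve.grid > 0.15) & (curve.grid < 0.85)
        interior = curve.density[sel]
        assert interior.max() / interior.min() < 1.5

    def test_too_few_sites_error_carries_counts(self):
        with pytest.raises(TooFewSitesError) as err:
            estimate_density(_profile([0.5] * 10))
        assert err.value.n_sites == 10 and err.value.minimum == 200

    def test_hexaploid_simulation_modes_near_thirds(self):
        curve = estimate_density(sim_profile(3, seed=2))
        modes = detect_modes(curve)
        assert len(modes) == 2
        assert abs(modes[0] - 1 / 3) < 0.05 and abs(modes[1] - 2 / 3) < 0.05


class TestDetectModes:
    @staticmethod
    def _gaussian_curve(means, sd=0.05, n=512):
        grid = np.linspace(0, 1, n)
        dens = sum(
            np.exp(-0.5 * ((grid - mu) / sd) ** 2) / (sd * math.sqrt(2 * math.pi))
            for mu in means
        ) / len(means)
        return DensityCurve(grid, dens / np.trapezoid(dens, grid))

    def test_unimodal(self):
        modes = detect_modes(self._gaussian_curve([0.5]))
        assert len(modes) == 1 and abs(modes[0] - 0.5) < 0.01

    def test_symmetric_bimodal_is_mirror_symmetric(self):
        curve = self._gaussian_curve([1 / 3, 2 / 3])
        modes = detect_modes(curve)
        assert len(modes) == 2
        dx = curve.grid[1] - curve.grid[0]
        assert abs((modes[0] + modes[1]) - 1.0) <= 2 * dx

    def test_flat_density_yields_at_most_one_low_mode(self):
        grid = np.linspace(0, 1, 512)
        curve = DensityCurve(grid, np.ones_like(grid))
        assert len(detect_modes(curve)) <= 1


class TestMixture:
    def test_em_recovers_weights_of_a_known_mixture(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([
            rng.normal(1 / 3, 0.05, 1400),
            rng.normal(2 / 3, 0.05, 600),
        ])
        w, sigma, ll = fit_fixed_mean_mixture(x, [1 / 3, 2 / 3])
        assert w == pytest.approx([0.7, 0.3], abs=0.03)
        assert sigma == pytest.approx(0.05, abs=0.01)
        assert np.isfinite(ll)

    def test_em_is_deterministic(self):
        x = np.asarray(sim_profile(3, seed=4).fractions)
        a = fit_fixed_mean_mixture(x, [1 / 3, 2 / 3])
        b = fit_fixed_mean_mixture(x, [1 / 3, 2 / 3])
        assert a[2] == b[2] and tuple(a[0]) == tuple(b[0])


class TestScoring:
    def test_unimodal_profile_ranks_m2_first_on_both_scores(self):
        scores = score_candidates(sim_profile(2, seed=8))
        best_peak = max(scores.values(), key=lambda s: s.peak_score)
        best_bic = min(scores.values(), key=lambda s: s.bic)
        assert best_peak.spec.m == 2 and best_bic.spec.m == 2

    def test_thirds_profile_ranks_m3_first_on_both_scores(self):
        scores = score_candidates(sim_profile(3, seed=8))
        assert max(scores.values(), key=lambda s: s.peak_score).spec.m == 3
        assert min(scores.values(), key=lambda s: s.bic).spec.m == 3

    def test_m4_simulations_recovered_by_majority(self):
        wins = sum(
            min(
                score_candidates(sim_profile(4, seed=100 + r)).values(),
                key=lambda s: s.bic,
            ).spec.m
            == 4
            for r in range(10)
        )
        assert wins >= 8

    def test_expected_modes_structure(self):
        spec = PloidyModelSpec(4)
        assert spec.expected_modes == (0.25, 0.5, 0.75)
        mirrored = tuple(1 - m for m in reversed(spec.expected_modes))
        assert mirrored == spec.expected_modes  # symmetric about 0.5
        adj = spec.error_adjusted_modes(0.005)
        assert adj[0] == pytest.approx(0.25 * 0.995 + 0.75 * 0.005)


class TestCallPloidy:
    def test_simulated_calls_and_reported_cytotypes(self):
        assert call_ploidy(sim_profile(2, seed=21)).reported_ploidy == "4x"
        assert call_ploidy(sim_profile(3, seed=21)).reported_ploidy == "6x"
        assert call_ploidy(sim_profile(4, seed=21)).reported_ploidy == "8x"

    def test_cytotype_factor_one_for_autopolyploids(self):
        call = call_ploidy(
            sim_profile(3, seed=21), default_candidates((2, 3, 4), cytotype_factor=1)
        )
        assert call.reported_ploidy == "3x"

    def test_empty_candidate_list_errors(self):
        with pytest.raises(ValueError):
            call_ploidy(sim_profile(2, seed=1), candidates=[])

    def test_low_sites_flagged_but_still_called(self):
        call = call_ploidy(sim_profile(2, seed=3, n_sites=50))
        assert call.confidence_flag == "low_sites"
        assert call.reported_ploidy  # a call is still emitted

    @pytest.mark.parametrize("m", [2, 3, 4])
    def test_mirror_symmetry_of_calls(self, m):
        """Reflecting every fraction f -> 1-f leaves the call unchanged."""
        profile = sim_profile(m, seed=31)
        call = call_ploidy(profile)
        mirrored = call_ploidy(profile.mirrored())
        assert mirrored.reported_ploidy == call.reported_ploidy
        assert mirrored.effective_m == call.effective_m

    def test_calls_are_deterministic(self):
        profile = sim_profile(3, seed=55)
        a, b = call_ploidy(profile), call_ploidy(profile)
        assert a.to_row() == b.to_row()

    def test_recovery_non_decreasing_in_site_count(self):
        """With common random seeds, more sites never hurt recovery."""
        rates = []
        for n in (300, 1000, 3000):
            ok = sum(
                call_ploidy(sim_profile(3, seed=700 + r, n_sites=n)).ploidy_int == 6
                for r in range(15)
            )
            rates.append(ok / 15)
        assert rates == sorted(rates)

    def test_fraction_profile_rejects_boundary_values(self):
        with pytest.raises(ValueError):
            FractionProfile("x", (0.0, 0.5))
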