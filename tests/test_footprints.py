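import math

import numpy as np
import pytest

from circadhs import footprints as fp
from circadhs.simdata import (FootprintElement, FootprintSpec,
                              simulate_cut_profiles, tandem_ebox_spec)


def exact_binom_cdf(k, n, p):
    """Independent exact binomial lower tail via integer arithmetic."""
    total = 0.0
    for j in range(int(k) + 1):
        total += math.comb(int(n), j) * p ** j * (1 - p) ** (int(n) - j)
    return min(total, 1.0)


class TestWellington:
    def test_pvalues_match_exact_binomial_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(1000):
            F = int(rng.choice(fp.DEFAULT_FP_SIZES))
            S = int(rng.choice(fp.DEFAULT_SHOULDER_SIZES))
            k_fp = int(rng.integers(0, 30))
            k_sh = int(rng.integers(0, 60))
            got = fp._binom_lower_tail(np.array([k_fp]), np.array([k_sh]), F, S)[0]
            want = exact_binom_cdf(k_fp, k_fp + k_sh, F / (F + S))
            assert abs(got - want) < 1e-12

    def test_constructed_profile_exact_score(self):
        """F=20, S=20: 2 forward cuts in the footprint out of 40 in
        footprint+upstream gives the Binomial(40, 1/2) lower tail at 2."""
        L = 120
        fw = np.zeros(L)
        rv = np.zeros(L)
        center = 60
        fw[[52, 67]] = 1                    # 2 cuts in the footprint [50, 70)
        fw[center - 30:center - 11] = 2     # 38 cuts upstream shoulder
        rv[[53, 66]] = 1
        rv[center + 11:center + 30] = 2     # 38 cuts downstream shoulder
        scores, _ = fp._best_scores(fw, rv, fp_sizes=[20], shoulder_sizes=[20])
        p_expected = exact_binom_cdf(2, 40, 0.5)
        assert scores[center] == pytest.approx(-2 * np.log10(p_expected), rel=1e-9)

    def test_single_strand_depletion_scores_lower(self):
        L = 120
        base = np.full(L, 2.0)
        fw = base.copy()
        fw[50:70] = 0.0
        rv_flat = base.copy()
        rv_depleted = fw.copy()
        s_single, _ = fp._best_scores(fw, rv_flat, [20], [20])
        s_double, _ = fp._best_scores(fw, rv_depleted, [20], [20])
        assert s_double[60] > s_single[60]

    def test_uniform_profile_yields_no_calls(self):
        rng = np.random.default_rng(8)
        fw = rng.poisson(3, 400).astype(float)
        rv = rng.poisson(3, 400).astype(float)
        calls = fp.wellington_footprints(fw, rv, fdr_max=0.05, seed=0)
        assert len(calls) <= 2  # at most the FDR-expected handful, typically none

    def test_planted_footprint_called_and_flat_dhs_not(self):
        rng = np.random.default_rng(5)
        L = 601
        rate = np.full(L, 3.0)
        rate[290:315] = 0.3
        fw = rng.poisson(rate).astype(float)
        rv = rng.poisson(rate).astype(float)
        calls = fp.wellington_footprints(fw, rv, seed=1)
        assert len(calls) >= 1
        best = max(calls, key=lambda c: c.score)
        assert 280 <= best.start <= 300 and 305 <= best.end <= 325
        # high but featureless signal (transcription-like) yields no calls
        flat_fw = rng.poisson(10.0, L).astype(float)
        flat_rv = rng.poisson(10.0, L).astype(float)
        assert len(fp.wellington_footprints(flat_fw, flat_rv, seed=1)) == 0

    def test_region_too_short_rejected(self):
        with pytest.raises(ValueError):
            fp.wellington_footprints(np.ones(30), np.ones(30))


class TestMixtureModel:
    def make_profiles(self, occupancy=0.6, n_sites=120, depth=100, seed=10,
                      left=-10, right=15, depletion=0.2):
        spec = FootprintSpec((FootprintElement(left, right, depletion),), halfwidth=50)
        counts, bound, offsets = simulate_cut_profiles(
            n_sites, spec, [occupancy], depth=depth, seed=seed)
        return counts[:, 0].sum(axis=1), bound[:, 0, 0], offsets

    def test_recovery_of_planted_parameters(self):
        prof, bound, offsets = self.make_profiles(n_sites=200)
        fit = fp.fit_footprint_mixture(prof, offsets)
        assert fit.has_footprint
        assert abs(fit.left_edge - (-10)) <= 2
        assert abs(fit.right_edge - 15) <= 2
        assert abs(fit.bound_fraction - 0.6) <= 0.1
        assert abs(fit.depletion - 0.2) <= 0.05

    def test_loglik_monotone(self):
        prof, _, offsets = self.make_profiles(n_sites=60)
        fit = fp.fit_footprint_mixture(prof, offsets)
        assert np.all(np.diff(fit.loglik_trace) >= -1e-6)

    def test_flat_null_rejected(self):
        rng = np.random.default_rng(3)
        prof = rng.poisson(2.0, size=(60, 101)).astype(float)
        offsets = np.arange(-50, 51)
        fit = fp.fit_footprint_mixture(prof, offsets)
        assert not fit.has_footprint
        assert fit.bound_fraction == 0.0
        assert np.all(fit.posteriors == 0)

    def test_posterior_ranks_depleted_site_above_flat_site(self):
        prof, _, offsets = self.make_profiles(n_sites=100)
        fit = fp.fit_footprint_mixture(prof, offsets)
        inside = (offsets >= fit.left_edge) & (offsets <= fit.right_edge)
        depleted = np.zeros(101)
        depleted[~inside] = 100 / (~inside).sum()
        flat = np.full(101, 100 / 101)
        both = np.vstack([np.round(depleted), np.round(flat)])
        test_fit = fp._em_one_boundary(
            np.vstack([prof, both]), offsets, fit.left_edge, fit.right_edge)
        posteriors = test_fit[3]
        assert posteriors[-2] > posteriors[-1]

    def test_invariant_to_site_order_and_depth_scaling(self):
        prof, _, offsets = self.make_profiles(n_sites=80)
        grid = [(-12, 13), (-10, 15), (-8, 17)]
        f1 = fp.fit_footprint_mixture(prof, offsets, boundary_grid=grid)
        rng = np.random.default_rng(0)
        perm = rng.permutation(prof.shape[0])
        f2 = fp.fit_footprint_mixture(prof[perm], offsets, boundary_grid=grid)
        f3 = fp.fit_footprint_mixture(prof * 3, offsets, boundary_grid=grid)
        assert (f1.left_edge, f1.right_edge) == (f2.left_edge, f2.right_edge)
        assert np.allclose(f1.posteriors[perm], f2.posteriors, atol=1e-9)
        assert (f1.left_edge, f1.right_edge) == (f3.left_edge, f3.right_edge)
        assert abs(f1.depletion - f3.depletion) < 0.02

    def test_preconditions(self):
        offsets = np.arange(-50, 51)
        with pytest.raises(ValueError):
            fp.fit_footprint_mixture(np.ones((5, 101)), offsets)
        with pytest.raises(ValueError):
            fp.fit_footprint_mixture(np.zeros((30, 101)), offsets)
        prof, _, _ = self.make_profiles(n_sites=30)
        with pytest.raises(ValueError):
            fp.fit_footprint_mixture(prof, offsets, boundary_grid=[])


class TestTemporalSeries:
    def test_tandem_width_halves_at_trough_and_ko_matches_trough(self):
        """Peak time: both E-box dimers protected; trough: only the 5' dimer.
        The fitted protected width at the trough is about half the peak width,
        and a knockout (3' dimer never bound) reproduces the trough width."""
        spec = tandem_ebox_spec(spacer=6, depletion=0.2)
        occ = np.array([[0.8, 0.8], [0.6, 0.0]])    # rows: peak, trough
        counts, _, offsets = simulate_cut_profiles(150, spec, occ, depth=100, seed=21)
        per_time = {"peak": counts[:, 0].sum(axis=1),
                    "trough": counts[:, 1].sum(axis=1)}
        fits, traj = fp.temporal_footprint_series(per_time, offsets)
        w_peak = traj.set_index("time").loc["peak", "width"]
        w_trough = traj.set_index("time").loc["trough", "width"]
        assert 0.35 <= w_trough / w_peak <= 0.65
        assert traj.set_index("time").loc["peak", "bound_fraction"] > \
               traj.set_index("time").loc["trough", "bound_fraction"]

        counts_ko, _, _ = simulate_cut_profiles(
            150, spec, np.array([[0.6, 0.0]]), depth=100, seed=22)
        fit_ko = fp.fit_footprint_mixture(counts_ko[:, 0].sum(axis=1), offsets)
        assert abs(fit_ko.width - w_trough) <= 3

    def test_constant_occupancy_flat_trajectory(self):
        spec = FootprintSpec((FootprintElement(-10, 15, 0.2),), halfwidth=50)
        counts, _, offsets = simulate_cut_profiles(
            120, spec, [0.6, 0.6, 0.6], depth=100, seed=23)
        per_time = {t: counts[:, i].sum(axis=1) for i, t in enumerate([2, 10, 18])}
        _, traj = fp.temporal_footprint_series(per_time, offsets)
        assert traj["width"].max() - traj["width"].min() <= 4
        assert traj["bound_fraction"].max() - traj["bound_fraction"].min() <= 0.15


class TestAggregateProfile:
    def test_single_qualifying_site(self):
        counts = np.array([[2.0, 2.0, 4.0], [1.0, 1.0, 2.0]])
        out = fp.aggregate_cut_profile(counts, np.array([0.9, 0.1]), p_min=0.5)
        assert np.allclose(out, [0.25, 0.25, 0.5])

    def test_pmin_zero_averages_all(self):
        counts = np.array([[1.0, 3.0], [3.0, 1.0]])
        out = fp.aggregate_cut_profile(counts, np.array([0.4, 0.6]), p_min=0.0)
        assert np.allclose(out, [0.5, 0.5])

    def test_normalized_mean_semantics_vs_bruteforce(self, rng):
        counts = rng.poisson(5, size=(30, 21)).astype(float) + 1
        post = rng.uniform(size=30)
        out = fp.aggregate_cut_profile(counts, post, p_min=0.5)
        sel = post > 0.5
        brute = np.mean([c / c.sum() for c in counts[sel]], axis=0)
        assert np.allclose(out, brute)
        # count-weighted pooling differs unless depths are equal
        pooled = counts[sel].sum(axis=0) / counts[sel].sum()
        assert not np.allclose(out, pooled)

    def test_no_qualifying_site_raises(self):
        with pytest.raises(ValueError):
            fp.aggregate_cut_profile(np.ones((3, 5)), np.zeros(3), p_min=0.5)
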