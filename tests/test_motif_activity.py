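import itertools

import numpy as np
import pandas as pd
import pytest

from circadhs import motif_activity as ma
from circadhs.motif_activity import (PWM, build_motif_matrix,
                                     elastic_net_objective, fit_activities,
                                     motif_cooccurrence, phase_vector,
                                     scan_pwm, _coordinate_descent,
                                     _score_distribution)
from circadhs.rhythm_stats import OMEGA
from circadhs.simdata import activity_complex

TIMES = np.array([2.0, 6.0, 10.0, 14.0, 18.0, 22.0, 26.0])
RC = str.maketrans("ACGT", "TGCA")


class TestScanPwm:
    def test_consensus_has_minimal_pvalue(self, rng):
        pwm = PWM.from_consensus("Ebox", "CACGTG")
        bg = "".join(rng.choice(list("ACGT"), 200))
        seq = bg[:100] + "CACGTG" + bg[100:]
        hits = scan_pwm(seq, pwm, p_max=1e-3)
        fwd = [h for h in hits if h.position == 100 and h.strand == "+"]
        assert fwd
        assert fwd[0].pvalue == min(h.pvalue for h in hits)

    def test_exact_pvalue_matches_full_enumeration(self, rng):
        mat = rng.dirichlet(np.ones(4), size=4)
        pwm = PWM("toy", mat, background=np.array([0.3, 0.2, 0.2, 0.3]))
        values, tail, score_lo, scaled = _score_distribution(
            pwm.log_odds, pwm.background)
        # enumerate the 4^4 background-weighted words
        for word in itertools.product(range(4), repeat=4):
            iscore = sum(scaled[j, b] for j, b in enumerate(word))
            expected = sum(
                np.prod([pwm.background[b] for b in w])
                for w in itertools.product(range(4), repeat=4)
                if sum(scaled[j, b] for j, b in enumerate(w)) >= iscore
            )
            got = tail[iscore - score_lo]
            assert got == pytest.approx(expected, abs=1e-12)

    def test_reverse_complement_symmetry(self, rng):
        pwm = PWM.from_consensus("Dbox", "TTATGTAA")
        bg = "".join(rng.choice(list("ACGT"), 120))
        seq = bg[:60] + "TTATGTAA" + bg[60:]
        hits_f = scan_pwm(seq, pwm, p_max=1e-3)
        hits_r = scan_pwm(seq.translate(RC)[::-1], pwm, p_max=1e-3)
        assert sorted(round(h.score, 9) for h in hits_f) == \
               sorted(round(h.score, 9) for h in hits_r)

    def test_windows_with_n_skipped(self):
        pwm = PWM.from_consensus("Ebox", "CACGTG")
        hits = scan_pwm("NNCACGTGNN", pwm, p_max=0.5)
        positions = {h.position for h in hits}
        assert positions == {2}

    def test_pwm_wider_than_sequence(self):
        with pytest.raises(ValueError):
            scan_pwm("ACG", PWM.from_consensus("x", "ACGTACGT"))

    def test_meme_round_trip(self, tmp_path, rng):
        pwms = [PWM("m1", rng.dirichlet(np.ones(4), size=6)),
                PWM("m2", rng.dirichlet(np.ones(4), size=9))]
        path = tmp_path / "motifs.meme"
        ma.write_meme(path, pwms)
        back = ma.read_meme(path)
        assert [p.id for p in back] == ["m1", "m2"]
        for a, b in zip(pwms, back):
            # the reader re-applies the scanning pseudocount
            assert np.allclose(a.matrix, b.matrix, atol=5e-3)


class TestBuildMotifMatrix:
    def _tables(self):
        dhs = pd.DataFrame({"dhs_id": ["d1"], "chrom": ["chr1"], "center": [130_000]})
        tss = pd.DataFrame({"gene_id": ["gA"], "chrom": ["chr1"], "tss": [100_000]})
        hits = pd.DataFrame({"dhs_id": ["d1", "d1"], "motif": ["Ebox", "Ebox"],
                             "position": [129_990, 130_010], "strand": ["+", "+"],
                             "score": [8.0, 8.0], "pvalue": [1e-5, 1e-5]})
        return hits, dhs, tss

    def test_window_inclusion(self):
        hits, dhs, tss = self._tables()
        assert build_motif_matrix(hits, dhs, tss, 50_000).loc["gA", "Ebox"] == 2
        assert build_motif_matrix(hits, dhs, tss, 10_000).loc["gA", "Ebox"] == 0

    def test_equidistant_dhs_counted_for_both_genes(self):
        dhs = pd.DataFrame({"dhs_id": ["d1"], "chrom": ["chr1"], "center": [105_000]})
        tss = pd.DataFrame({"gene_id": ["gA", "gB"], "chrom": ["chr1", "chr1"],
                            "tss": [100_000, 110_000]})
        hits = pd.DataFrame({"dhs_id": ["d1"], "motif": ["Ebox"],
                             "position": [105_000], "strand": ["+"],
                             "score": [8.0], "pvalue": [1e-5]})
        N = build_motif_matrix(hits, dhs, tss, 50_000)
        assert N.loc["gA", "Ebox"] == 1 and N.loc["gB", "Ebox"] == 1
        # brute-force cross-check over all (gene, dhs) pairs
        for g in tss.itertuples():
            expected = sum(
                (hits["dhs_id"] == d.dhs_id).sum()
                for d in dhs.itertuples() if abs(d.center - g.tss) <= 50_000)
            assert N.loc[g.gene_id].sum() == expected

    def test_no_hits_zero_matrix(self):
        _, dhs, tss = self._tables()
        empty = pd.DataFrame(columns=["dhs_id", "motif", "position",
                                      "strand", "score", "pvalue"])
        assert build_motif_matrix(empty, dhs, tss, 50_000).to_numpy().size == 0


class TestPhaseVector:
    def test_constant_profile_is_zero(self):
        mat = pd.DataFrame(np.full((3, 7), 5.0), columns=TIMES)
        P = phase_vector(TIMES, mat)
        assert np.allclose(np.abs(P.to_numpy()), 0, atol=1e-12)

    def test_cosine_peaking_zt0(self):
        mat = pd.DataFrame([np.cos(OMEGA * TIMES)], columns=TIMES)
        P = phase_vector(TIMES, mat)
        assert P.iloc[0].real == pytest.approx(1.0, abs=1e-10)
        assert P.iloc[0].imag == pytest.approx(0.0, abs=1e-10)

    def test_consistent_with_harmonic_fit_phase(self, rng):
        from circadhs.rhythm_stats import harmonic_fit
        peaks = rng.uniform(0, 24, 50)
        amps = rng.uniform(0.2, 2.0, 50)
        mat = pd.DataFrame(
            amps[:, None] * np.cos(OMEGA * (TIMES[None, :] - peaks[:, None])),
            columns=TIMES)
        P = phase_vector(TIMES, mat)
        for i in range(50):
            fit = harmonic_fit(TIMES, mat.iloc[i].to_numpy())
            peak_from_P = (np.angle(P.iloc[i]) / OMEGA) % 24
            d = abs(peak_from_P - fit.phase) % 24
            assert min(d, 24 - d) < 1e-9


class TestElasticNet:
    def _system(self, rng, n=100, p=10):
        X = rng.normal(size=(n, p))
        B_true = rng.normal(size=(p, 2))
        Y = X @ B_true + rng.normal(0, 0.1, size=(n, 2))
        return X, Y

    @pytest.mark.parametrize("seed", range(5))
    def test_lambda_zero_matches_ols_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X, Y = self._system(rng)
        B_hat = _coordinate_descent(Y, X, lam=0.0, alpha=0.1, tol=1e-12,
                                    max_iter=20_000)
        B_ols = np.linalg.solve(X.T @ X, X.T @ Y)
        assert np.abs(B_hat - B_ols).max() < 1e-6

    def test_fit_activities_lambda_zero_ols(self, rng):
        X, Y = self._system(rng, n=80, p=6)
        P = pd.Series(Y[:, 0] + 1j * Y[:, 1], index=[f"g{i}" for i in range(80)])
        N = pd.DataFrame(X, index=P.index, columns=[f"m{i}" for i in range(6)])
        est = fit_activities(P, N, alpha=0.1, fixed_lambda=0.0, tol=1e-12)
        B_ols = np.linalg.solve(X.T @ X, X.T @ Y)
        got = np.column_stack([est.activities["re"], est.activities["im"]])
        assert np.abs(got - B_ols).max() < 1e-6

    def test_orthonormal_design_group_soft_threshold(self, rng):
        n, p = 64, 8
        Q, _ = np.linalg.qr(rng.normal(size=(n, p)))
        X = np.sqrt(n) * Q                     # (1/n) X'X = I
        B_true = rng.normal(size=(p, 2))
        Y = X @ B_true
        lam = 0.8
        B_hat = _coordinate_descent(Y, X, lam=lam, alpha=1.0, tol=1e-14,
                                    max_iter=10_000)
        rho = X.T @ Y / n                      # per-motif OLS solution
        norms = np.linalg.norm(rho, axis=1, keepdims=True)
        B_closed = np.where(norms > lam, (1 - lam / norms), 0.0) * rho
        assert np.abs(B_hat - B_closed).max() < 1e-10

    def test_huge_lambda_gives_zero_and_no_deviance(self, rng):
        X, Y = self._system(rng, n=60, p=5)
        P = pd.Series(Y[:, 0] + 1j * Y[:, 1], index=range(60))
        N = pd.DataFrame(X, index=P.index)
        est = fit_activities(P, N, alpha=0.5, fixed_lambda=1e9)
        assert np.all(est.activities["amplitude"] == 0)
        assert est.deviance_ratio == pytest.approx(0.0, abs=1e-12)

    def test_objective_non_increasing_over_sweeps(self, rng):
        X, Y = self._system(rng)
        lam, alpha = 0.3, 0.4
        objs = []
        B = np.zeros((X.shape[1], 2))
        for _ in range(15):
            B = _coordinate_descent(Y, X, lam, alpha, B0=B, max_iter=1, tol=0)
            objs.append(elastic_net_objective(Y, X, B, lam, alpha))
        assert np.all(np.diff(objs) <= 1e-12)

    def test_solution_permutation_invariant_at_lambda_zero(self, rng):
        X, Y = self._system(rng, n=50, p=6)
        B1 = _coordinate_descent(Y, X, 0.0, 0.1, tol=1e-13, max_iter=20_000)
        perm = rng.permutation(6)
        B2 = _coordinate_descent(Y, X[:, perm], 0.0, 0.1, tol=1e-13, max_iter=20_000)
        assert np.allclose(B1[perm], B2, atol=1e-6)

    def test_all_zero_matrix_rejected(self):
        P = pd.Series([1 + 1j, 2 - 1j, 0j], index=list("abc"))
        N = pd.DataFrame(0.0, index=P.index, columns=["m1"])
        with pytest.raises(ValueError):
            fit_activities(P, N)

    def test_absent_motif_gets_zero_activity(self, rng):
        X, Y = self._system(rng, n=60, p=4)
        X = np.column_stack([X, np.zeros(60)])
        P = pd.Series(Y[:, 0] + 1j * Y[:, 1], index=range(60))
        N = pd.DataFrame(X, index=P.index, columns=list("abcde"))
        est = fit_activities(P, N, fixed_lambda=0.01)
        assert est.activities.loc["e", "amplitude"] == 0


class TestActivityRecovery:
    def test_recovery_and_knockout_contrast(self):
        """Three active motifs recovered in amplitude and phase; zeroing them
        (clock knockout) collapses their estimates while sparing the rest."""
        rng = np.random.default_rng(12)
        n_genes, n_motifs = 400, 12
        N = pd.DataFrame(rng.poisson(1.0, size=(n_genes, n_motifs)),
                         index=[f"g{i}" for i in range(n_genes)],
                         columns=[f"m{i}" for i in range(n_motifs)])
        truth = {0: (0.8, 8.0), 1: (0.5, 12.0), 2: (1.0, 22.0)}

        def make_P(active):
            acts = np.zeros(n_motifs, dtype=complex)
            for i, (amp, peak) in active.items():
                acts[i] = activity_complex(amp, peak)
            levels = np.real(np.outer(N.to_numpy() @ acts,
                                      np.exp(-1j * OMEGA * TIMES)))
            levels = levels + rng.normal(0, 0.25, size=levels.shape)
            return phase_vector(TIMES, pd.DataFrame(levels, index=N.index,
                                                    columns=TIMES))

        est_wt = fit_activities(make_P(truth), N, alpha=0.1, cv_folds=5, seed=0)
        A_wt = est_wt.complex_activities()
        for i, (amp, peak) in truth.items():
            a = A_wt.iloc[i]
            assert abs(abs(a) - amp) / amp < 0.2
            d = abs((np.angle(a) / OMEGA) % 24 - peak) % 24
            assert min(d, 24 - d) < 1.0
        inactive_max = np.abs(A_wt.iloc[3:]).max()
        assert inactive_max < 0.1 * np.abs(A_wt).max()

        est_ko = fit_activities(make_P({}), N, alpha=0.1, cv_folds=5, seed=0)
        A_ko = est_ko.complex_activities()
        for i in truth:
            assert abs(A_ko.iloc[i]) < abs(A_wt.iloc[i]) / 5


class TestCooccurrence:
    def test_forced_overlap_has_p_one(self):
        pres = pd.DataFrame({"u": [True] * 20,
                             "v": [True] * 10 + [False] * 10})
        res = motif_cooccurrence(pres, [("u", "v")])
        assert res.iloc[0]["p_enrich"] == pytest.approx(1.0)

    def test_matches_exact_enumeration(self):
        pres = pd.DataFrame({"u": [True] * 10 + [False] * 10,
                             "v": [True] * 10 + [False] * 10})
        res = motif_cooccurrence(pres, [("u", "v")])
        # enumerate all C(20,10) placements of v's 10 sites
        universe = list(range(20))
        total = 0
        hits = 0
        for comb in itertools.combinations(universe, 10):
            total += 1
            if len(set(comb) & set(range(10))) >= 10:
                hits += 1
        assert res.iloc[0]["p_enrich"] == pytest.approx(hits / total, rel=1e-9)

    def test_disjoint_margins_depleted(self):
        pres = pd.DataFrame({"u": [True] * 8 + [False] * 12,
                             "v": [False] * 12 + [True] * 8})
        res = motif_cooccurrence(pres, [("u", "v")])
        assert res.iloc[0]["direction"] == "depleted"
        assert res.iloc[0]["p_deplete"] < 0.05
        assert res.iloc[0]["p_enrich"] > 0.9

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            motif_cooccurrence(pd.DataFrame(columns=["u", "v"]), [("u", "v")])
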