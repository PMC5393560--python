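"""Rhythmicity statistics for 24-h time courses.

Harmonic (cosinor) regression with a single 24-h component, Fisher's combined
probability test across marks, Benjamini-Hochberg FDR, circular phase
statistics, promoter-enhancer phase pairing, and the Chow test for comparing
rhythms between two conditions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

PERIOD_H = 24.0
OMEGA = 2.0 * np.pi / PERIOD_H


@dataclass
class HarmonicFit:
    """Least-squares fit of m + a*cos(wt) + b*sin(wt) to a log2 time course.

    ``amplitude`` is the log2 peak-to-trough distance, 2*sqrt(a^2+b^2);
    ``phase`` the peak time in hours within [0, 24).
    """

    mesor: float
    coef_cos: float
    coef_sin: float
    amplitude: float
    phase: float
    pvalue: float
    rss: float
    n: int

    @property
    def phase_vector(self) -> complex:
        """Complex first-harmonic coefficient a + ib (peak time = arg/omega)."""
        return complex(self.coef_cos, self.coef_sin)


def _design(times: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones_like(times), np.cos(OMEGA * times), np.sin(OMEGA * times)])


def harmonic_fit(times, values) -> HarmonicFit:
    """Fit the single 24-h harmonic by OLS and test it against a flat model.

    The p-value is an F(2, n-3) test of the two harmonic coefficients.
    ZT26 enters as an independent sample whose regressors coincide with ZT2.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.shape != values.shape:
        raise ValueError("times and values must align")
    n = times.size
    if np.unique(times).size < 4:
        raise ValueError(f"need >=4 distinct time points, got times {sorted(set(times))}")
    X = _design(times)
    if np.linalg.matrix_rank(X) < 3:
        raise ValueError(f"rank-deficient harmonic design for times {sorted(set(times))}")
    beta, _, _, _ = np.linalg.lstsq(X, values, rcond=None)
    resid = values - X @ beta
    rss = float(resid @ resid)
    rss0 = float(np.sum((values - values.mean()) ** 2))
    df2 = n - 3
    if df2 <= 0:
        raise ValueError("insufficient degrees of freedom")
    if rss0 <= 0 or rss >= rss0:
        pvalue = 1.0
    elif rss == 0:
        pvalue = 0.0  # exact harmonic fit
    else:
        f = ((rss0 - rss) / 2.0) / (rss / df2)
        pvalue = float(stats.f.sf(f, 2, df2))
    m, a, b = (float(x) for x in beta)
    amplitude = 2.0 * float(np.hypot(a, b))
    phase = float((np.arctan2(b, a) / OMEGA) % PERIOD_H) if amplitude > 0 else 0.0
    if phase >= PERIOD_H:  # float mod can land exactly on the period
        phase = 0.0
    return HarmonicFit(m, a, b, amplitude, phase, pvalue, rss, n)


def harmonic_fit_many(times, value_matrix) -> pd.DataFrame:
    """Vectorized harmonic_fit over the rows of a (series x time) matrix."""
    times = np.asarray(times, dtype=float)
    Y = np.asarray(value_matrix, dtype=float)
    X = _design(times)
    n = times.size
    beta, _, _, _ = np.linalg.lstsq(X, Y.T, rcond=None)  # 3 x nseries
    resid = Y.T - X @ beta
    rss = (resid ** 2).sum(axis=0)
    rss0 = ((Y - Y.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    df2 = n - 3
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ((rss0 - rss) / 2.0) / (rss / df2)
    pval = stats.f.sf(f, 2, df2)
    pval = np.where((rss0 <= 0) | (rss >= rss0), 1.0, pval)
    m, a, b = beta
    amp = 2.0 * np.hypot(a, b)
    phase = np.where(amp > 0, (np.arctan2(b, a) / OMEGA) % PERIOD_H, 0.0)
    phase = np.where(phase >= PERIOD_H, 0.0, phase)
    idx = value_matrix.index if isinstance(value_matrix, pd.DataFrame) else None
    return pd.DataFrame(
        {"mesor": m, "coef_cos": a, "coef_sin": b, "amplitude": amp,
         "phase": phase, "pvalue": pval, "rss": rss},
        index=idx,
    )


def rhythm_adjusted_column_center(matrix: pd.DataFrame, times,
                                  p_flat: float = 0.3,
                                  min_flat: int = 20) -> pd.DataFrame:
    """Two-pass per-column centering of a (sites x time) log2 matrix.

    Plain column centering (median or quantile) is biased when a substantial
    fraction of sites cycles coherently: the column centers themselves become
    rhythmic and centering imprints an anti-phase artifact on flat sites.
    Pass one centers on the column medians and fits harmonics; pass two
    re-estimates the column effects from the confidently non-rhythmic sites
    (p > p_flat) only. Falls back to the single-pass result when fewer than
    ``min_flat`` sites qualify.
    """
    times = np.asarray(times, dtype=float)
    centered = matrix - matrix.median(axis=0)
    fits = harmonic_fit_many(times, centered)
    flat = fits["pvalue"].to_numpy() > p_flat
    if flat.sum() < min_flat:
        return centered
    resid = matrix.loc[matrix.index[flat]]
    resid = resid.sub(resid.mean(axis=1), axis=0)
    return matrix - resid.median(axis=0)


@dataclass
class CombinedRhythmResult:
    statistic: float
    df: int
    pvalue: float
    qvalue: float | None = None


def fisher_combine(pvals) -> CombinedRhythmResult:
    """Fisher's combined probability test: X = -2 sum(ln p) ~ chi2(2k)."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if np.any(p == 0):
        warnings.warn("p-value of 0 clipped to smallest positive normal float")
        p = np.clip(p, np.finfo(float).tiny, 1.0)
    x = float(-2.0 * np.log(p).sum())
    df = 2 * p.size
    return CombinedRhythmResult(x, df, float(stats.chi2.sf(x, df)))


def fisher_combine_matrix(pmatrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Fisher combination. Returns (statistic, pvalue) arrays."""
    p = np.clip(np.asarray(pmatrix, dtype=float), np.finfo(float).tiny, 1.0)
    x = -2.0 * np.log(p).sum(axis=1)
    return x, stats.chi2.sf(x, 2 * p.shape[1])


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg linear step-up q-values."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def circular_correlation(phases_a, phases_b, n_perm: int = 1000, seed: int = 0):
    """Fisher-Lee circular correlation between two phase samples (hours).

    Returns (T, permutation p-value). The permutation test shuffles the
    pairing of the two samples.
    """
    a = np.asarray(phases_a, dtype=float) * OMEGA
    b = np.asarray(phases_b, dtype=float) * OMEGA
    if a.size != b.size or a.size < 5:
        raise ValueError("need equal-length samples of size >= 5")

    def _stat(x, y):
        dx = np.sin(np.subtract.outer(x, x))
        dy = np.sin(np.subtract.outer(y, y))
        iu = np.triu_indices(x.size, k=1)
        num = float((dx[iu] * dy[iu]).sum())
        den = float(np.sqrt((dx[iu] ** 2).sum() * (dy[iu] ** 2).sum()))
        if den == 0:
            raise ValueError("degenerate phase sample (all phases equal)")
        return num / den

    t_obs = _stat(a, b)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        t_perm = _stat(a, rng.permutation(b))
        if abs(t_perm) >= abs(t_obs):
            exceed += 1
    return t_obs, (exceed + 1) / (n_perm + 1)


def circular_phase_difference(phase_a, phase_b) -> np.ndarray:
    """Signed phase difference b - a mapped into (-12, 12] hours."""
    d = (np.asarray(phase_b, dtype=float) - np.asarray(phase_a, dtype=float)) % PERIOD_H
    return np.where(d > 12.0, d - PERIOD_H, d)


def tss_distal_pairs(dhs_table: pd.DataFrame, q_max: float = 0.1,
                     min_distal: int = 2000, max_distal: int = 20000) -> pd.DataFrame:
    """Pair rhythmic TSS-class DHSs with rhythmic intergenic DHSs of the same gene.

    ``dhs_table`` needs columns: dhs_id, gene, distance (signed bp to nearest
    TSS), qvalue, phase. TSS members must lie within 1 kb of the TSS, the
    intergenic partner at 2-20 kb; both members must pass q <= q_max.
    Returns one row per (tss DHS, distal DHS) pair with the circular phase
    difference (distal minus TSS) in (-12, 12] h.
    """
    t = dhs_table[dhs_table["qvalue"] <= q_max]
    near = t[t["distance"].abs() < 1000]
    far = t[(t["distance"].abs() >= min_distal) & (t["distance"].abs() <= max_distal)]
    rows = []
    far_by_gene = dict(tuple(far.groupby("gene")))
    for _, tssrow in near.iterrows():
        partners = far_by_gene.get(tssrow["gene"])
        if partners is None:
            continue
        for _, frow in partners.iterrows():
            rows.append({
                "gene": tssrow["gene"],
                "tss_dhs": tssrow["dhs_id"],
                "distal_dhs": frow["dhs_id"],
                "tss_phase": tssrow["phase"],
                "distal_phase": frow["phase"],
                "phase_diff": float(circular_phase_difference(tssrow["phase"], frow["phase"])),
            })
    return pd.DataFrame(rows, columns=["gene", "tss_dhs", "distal_dhs",
                                       "tss_phase", "distal_phase", "phase_diff"])


def chow_test(times_a, values_a, times_b, values_b) -> tuple[float, float]:
    """Chow F-test: does one harmonic model fit both groups as well as two?

    F = [(RSS_pooled - RSS_a - RSS_b)/p] / [(RSS_a + RSS_b)/(n_a + n_b - 2p)]
    with p = 3 harmonic parameters.
    """
    fa = harmonic_fit(times_a, values_a)
    fb = harmonic_fit(times_b, values_b)
    pooled = harmonic_fit(np.concatenate([np.asarray(times_a, float), np.asarray(times_b, float)]),
                          np.concatenate([np.asarray(values_a, float), np.asarray(values_b, float)]))
    p = 3
    df2 = fa.n + fb.n - 2 * p
    if df2 <= 0:
        raise ValueError("insufficient degrees of freedom for Chow test")
    rss_sep = fa.rss + fb.rss
    num = (pooled.rss - rss_sep) / p
    scale = float(np.sum(np.square(np.concatenate([np.asarray(values_a, float),
                                                   np.asarray(values_b, float)]))))
    if num <= 1e-12 * max(scale, 1.0):  # pooled fit no worse: identical rhythms
        return 0.0, 1.0
    if rss_sep <= 1e-12 * max(scale, 1.0):
        # both groups fit exactly yet pooling fails: infinitely significant
        return float("inf"), 0.0
    f = max(num / (rss_sep / df2), 0.0)
    return float(f), float(stats.f.sf(f, p, df2))
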