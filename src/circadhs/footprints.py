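"""DNase I footprint detection and occupancy modeling.

Two complementary tools:

* ``wellington_footprints`` -- strand-aware footprint calling inside a DHS
  region: the forward-strand cut deficit of a candidate footprint relative to
  its upstream shoulder, and the reverse-strand deficit relative to the
  downstream shoulder, are each scored with an exact binomial lower tail;
  the combined score is maximized over a footprint-size / shoulder-size grid
  and thresholded by an empirical FDR from circularly shuffled profiles.

* ``fit_footprint_mixture`` -- a two-component multinomial mixture over
  motif-anchored per-base cut profiles at one time point. Unbound sites draw
  cuts from a shared background profile q; bound sites draw from q with the
  protected interval [left, right] multiplied by a depletion factor delta and
  renormalized. EM estimates the mixing weight (bound fraction), delta, q and
  per-site posterior bound probabilities; the boundaries are chosen by
  exhaustive search over a grid. If the optimum shows essentially no
  depletion (delta >= 0.9) the footprint is rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_FP_SIZES = tuple(range(11, 26, 2))
DEFAULT_SHOULDER_SIZES = tuple(range(20, 36, 5))  # 20, 25, 30, 35


@dataclass(frozen=True)
class FootprintCall:
    start: int           # region coordinates, 0-based half-open
    end: int
    fp_size: int
    shoulder_size: int
    score: float         # -log10 p_fw - log10 p_rv
    fdr: float


def _binom_lower_tail(k_fp: np.ndarray, k_shoulder: np.ndarray, fp: int, sh: int) -> np.ndarray:
    n = k_fp + k_shoulder
    return stats.binom.cdf(k_fp, n, fp / (fp + sh))


def _best_scores(fw: np.ndarray, rv: np.ndarray, fp_sizes, shoulder_sizes):
    """Per-position best Wellington score over the (F, S) grid.

    Returns (scores, best_F) arrays over all positions (zero where no
    geometry fits).
    """
    L = fw.size
    cf = np.concatenate([[0], np.cumsum(fw)])
    cr = np.concatenate([[0], np.cumsum(rv)])
    best = np.zeros(L)
    best_f = np.zeros(L, dtype=int)
    centers = np.arange(L)
    for F in fp_sizes:
        for S in shoulder_sizes:
            fp_start = centers - F // 2
            fp_end = fp_start + F
            ok = (fp_start - S >= 0) & (fp_end + S <= L)
            if not ok.any():
                continue
            c = centers[ok]
            s0 = fp_start[ok]
            s1 = fp_end[ok]
            # cut counts are integral; rounding removes cumsum float error
            fw_fp = np.rint(cf[s1] - cf[s0])
            fw_up = np.rint(cf[s0] - cf[s0 - S])
            rv_fp = np.rint(cr[s1] - cr[s0])
            rv_dn = np.rint(cr[s1 + S] - cr[s1])
            p_fw = np.clip(_binom_lower_tail(fw_fp, fw_up, F, S), 1e-300, 1.0)
            p_rv = np.clip(_binom_lower_tail(rv_fp, rv_dn, F, S), 1e-300, 1.0)
            score = -np.log10(p_fw) - np.log10(p_rv)
            upd = score > best[c]
            best[c[upd]] = score[upd]
            best_f[c[upd]] = F
    return best, best_f


def wellington_footprints(fw, rv, fp_sizes=DEFAULT_FP_SIZES,
                          shoulder_sizes=DEFAULT_SHOULDER_SIZES,
                          fdr_max: float = 0.05, n_shuffles: int = 100,
                          seed: int = 0) -> list[FootprintCall]:
    """Call footprints on a strand-split cut profile of one DHS region.

    ``fw``/``rv`` are per-base forward/reverse cut counts over the region.
    The empirical FDR of a score s is the mean number of positions reaching s
    in circularly shuffled profiles divided by the number of observed
    positions reaching s. Calls are selected best-first without overlap.
    """
    fw = np.asarray(fw, dtype=float)
    rv = np.asarray(rv, dtype=float)
    if fw.shape != rv.shape:
        raise ValueError("strand profiles must have equal length")
    min_len = min(fp_sizes) + 2 * min(shoulder_sizes)
    if fw.size < min_len:
        raise ValueError(f"region shorter than footprint + two shoulders ({min_len} bp)")
    scores, best_f = _best_scores(fw, rv, fp_sizes, shoulder_sizes)

    rng = np.random.default_rng(seed)
    null_scores = []
    for _ in range(n_shuffles):
        sf, _ = _best_scores(np.roll(fw, rng.integers(1, fw.size)),
                             np.roll(rv, rng.integers(1, rv.size)),
                             fp_sizes, shoulder_sizes)
        null_scores.append(sf[sf > 0])
    null = np.sort(np.concatenate(null_scores)) if null_scores else np.empty(0)
    obs_sorted = np.sort(scores[scores > 0])

    def empirical_fdr(s: float) -> float:
        n_obs = obs_sorted.size - np.searchsorted(obs_sorted, s, side="left")
        if n_obs == 0:
            return 1.0
        n_null = (null.size - np.searchsorted(null, s, side="left")) / max(n_shuffles, 1)
        return min(1.0, n_null / n_obs)

    calls: list[FootprintCall] = []
    order = np.argsort(scores)[::-1]
    for c in order:
        s = scores[c]
        if s <= 0:
            break
        fdr = empirical_fdr(s)
        if fdr > fdr_max:
            continue
        F = int(best_f[c])
        start, end = int(c - F // 2), int(c - F // 2 + F)
        if any(start < call.end and end > call.start for call in calls):
            continue
        # shoulder that produced the best score is not tracked per-position;
        # report the smallest shoulder (score is maximized over the grid)
        calls.append(FootprintCall(start, end, F, min(shoulder_sizes), float(s), float(fdr)))
    calls.sort(key=lambda call: call.start)
    return calls


def count_footprints(fw, rv, **kwargs) -> int:
    """Number of non-overlapping footprint calls in one DHS region."""
    return len(wellington_footprints(fw, rv, **kwargs))


# ---------------------------------------------------------------------------
# Mixture model for footprint occupancy
# ---------------------------------------------------------------------------

@dataclass
class MixtureFit:
    left_edge: int
    right_edge: int
    depletion: float
    bound_fraction: float
    background: np.ndarray          # q_x, sums to 1
    posteriors: np.ndarray          # per-site P(bound | counts)
    loglik: float
    has_footprint: bool
    loglik_trace: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def width(self) -> int:
        return self.right_edge - self.left_edge + 1 if self.has_footprint else 0


def _em_one_boundary(counts: np.ndarray, offsets: np.ndarray, left: int, right: int,
                     max_iter: int = 200, tol: float = 1e-6):
    """EM for fixed boundaries. Returns (pi, delta, q, posteriors, loglik, trace).

    The complete-data likelihood factorizes so that the background update
    depends on the data only through the per-position column totals and the
    responsibility-weighted in-footprint mass; both M-steps are exact, hence
    the observed log-likelihood is non-decreasing.
    """
    inside = (offsets >= left) & (offsets <= right)
    T = counts.sum(axis=0).astype(float)          # per-position totals
    c_in = counts[:, inside].sum(axis=1).astype(float)
    c_tot = counts.sum(axis=1).astype(float)
    T_in = float(T[inside].sum())
    T_out = float(T[~inside].sum())
    T_sum = T_in + T_out

    pi, delta = 0.5, 0.5
    # background initialized from the column totals
    q = (T + 0.5) / (T + 0.5).sum()
    trace = []
    prev = -np.inf
    for _ in range(max_iter):
        Qin = float(q[inside].sum())
        Z = 1.0 - (1.0 - delta) * Qin
        # E-step: shared q terms cancel from the responsibilities
        log_b = np.log(pi) + c_in * np.log(delta) - c_tot * np.log(Z)
        log_u = np.log1p(-pi) * np.ones_like(log_b)
        denom = np.logaddexp(log_b, log_u)
        gamma = np.exp(log_b - denom)
        loglik = float((T * np.log(q)).sum()) + float(denom.sum())
        trace.append(loglik)
        if loglik - prev < tol and np.isfinite(prev):
            break
        prev = loglik
        # M-step
        pi = float(np.clip(gamma.mean(), 1e-6, 1 - 1e-6))
        B_in = float(gamma @ c_in)
        B_tot = float(gamma @ c_tot)
        # delta given q (exact): Bin/delta = Btot*Qin/Z
        if B_tot > B_in and Qin > 0 and B_in > 0:
            delta = B_in * (1.0 - Qin) / (Qin * (B_tot - B_in))
        else:
            delta = 1.0
        delta = float(np.clip(delta, 1e-4, 1.0))
        # q given delta (exact, via the Lagrangian fixed point on g)
        g = B_tot * (1.0 - delta) / (1.0 - (1.0 - delta) * Qin)
        for _ in range(50):
            a = g + T_sum
            mu = 0.5 * (a + np.sqrt(max(a * a - 4.0 * T_out * g, 0.0)))
            Qin_new = T_in / (mu - g) if mu > g else 1.0
            g_new = B_tot * (1.0 - delta) / (1.0 - (1.0 - delta) * Qin_new)
            if abs(g_new - g) < 1e-12 * (1 + abs(g)):
                g = g_new
                break
            g = g_new
        a = g + T_sum
        mu = 0.5 * (a + np.sqrt(max(a * a - 4.0 * T_out * g, 0.0)))
        q = (T + 1e-9) / np.where(inside, mu - g, mu)
        q = q / q.sum()
    return pi, delta, q, gamma, trace[-1], np.asarray(trace)


def default_boundary_grid(offsets: np.ndarray, max_edge: int = 25,
                          step: int = 1) -> list[tuple[int, int]]:
    """Candidate (left, right) pairs containing the motif midpoint (offset 0)."""
    lo = max(int(offsets.min()) + 1, -max_edge)
    hi = min(int(offsets.max()) - 1, max_edge)
    lefts = range(lo, 1, step)
    rights = range(0, hi + 1, step)
    return [(l, r) for l in lefts for r in rights if l < r]


def fit_footprint_mixture(counts: np.ndarray, offsets: np.ndarray,
                          boundary_grid=None, delta_reject: float = 0.9,
                          max_iter: int = 200, tol: float = 1e-6) -> MixtureFit:
    """Fit the footprint mixture at one time point, searching the boundary grid.

    ``counts`` is (n_sites x n_offsets), strands summed, orientation-aligned.
    The footprint is rejected (bound fraction reported as 0) when the optimum
    shows essentially no depletion (delta >= ``delta_reject``) or when the
    mixture does not beat the single-multinomial null by a BIC margin for its
    four extra parameters (pi, delta and the two boundary edges) -- this keeps
    flat profiles from yielding spurious low-occupancy footprints.
    """
    counts = np.asarray(counts, dtype=float)
    offsets = np.asarray(offsets, dtype=int)
    if counts.ndim != 2 or counts.shape[1] != offsets.size:
        raise ValueError("counts must be (sites x offsets)")
    if counts.shape[0] < 20:
        raise ValueError("need at least 20 sites for the mixture fit")
    if counts.sum() == 0:
        raise ValueError("all-zero profiles")
    if np.any(counts.sum(axis=1) < 10):
        raise ValueError("every site needs at least 10 total cuts")
    if boundary_grid is None:
        boundary_grid = default_boundary_grid(offsets)
    if not boundary_grid:
        raise ValueError("empty boundary grid")

    best = None
    for left, right in boundary_grid:
        if left >= right:
            continue
        pi, delta, q, gamma, ll, trace = _em_one_boundary(
            counts, offsets, left, right, max_iter=max_iter, tol=tol)
        if best is None or ll > best[0]:
            best = (ll, left, right, pi, delta, q, gamma, trace)
    ll, left, right, pi, delta, q, gamma, trace = best
    T = counts.sum(axis=0)
    q0 = T / T.sum()
    ll_null = float((T[T > 0] * np.log(q0[T > 0])).sum())
    bic_margin = 2.0 * np.log(counts.shape[0])  # 0.5 * 4 params * ln(n)
    if delta >= delta_reject or (ll - ll_null) < bic_margin:
        return MixtureFit(left, right, delta, 0.0, q,
                          np.zeros(counts.shape[0]), ll, False, trace)
    return MixtureFit(left, right, delta, pi, q, gamma, ll, True, trace)


def temporal_footprint_series(counts_per_time: dict, offsets: np.ndarray,
                              boundary_grid=None, **kwargs):
    """Independent mixture fits per time point plus a (width, bound fraction)
    trajectory table. ``counts_per_time`` maps time label -> (sites x offsets)."""
    fits = {}
    rows = []
    for t in counts_per_time:
        fit = fit_footprint_mixture(counts_per_time[t], offsets,
                                    boundary_grid=boundary_grid, **kwargs)
        fits[t] = fit
        rows.append({"time": t, "width": fit.width,
                     "bound_fraction": fit.bound_fraction,
                     "left_edge": fit.left_edge, "right_edge": fit.right_edge,
                     "depletion": fit.depletion})
    return fits, pd.DataFrame(rows)


def aggregate_cut_profile(counts: np.ndarray, posteriors: np.ndarray,
                          p_min: float = 0.5) -> np.ndarray:
    """Mean of unit-normalized profiles over sites with posterior > p_min."""
    if not 0 <= p_min <= 1:
        raise ValueError("p_min must be in [0, 1]")
    counts = np.asarray(counts, dtype=float)
    sel = np.asarray(posteriors, dtype=float) > p_min
    if not sel.any():
        raise ValueError("no site passes the posterior threshold")
    sub = counts[sel]
    totals = sub.sum(axis=1, keepdims=True)
    if np.any(totals == 0):
        raise ValueError("qualifying site with zero cuts cannot be normalized")
    return (sub / totals).mean(axis=0)
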