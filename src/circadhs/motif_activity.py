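"""Inference of time-of-day transcription-factor motif activities.

The model explains each gene's 24-h Pol II phase vector P_g (complex first
Fourier coefficient) as a linear combination of motif activities,

    P_g = sum_f N_gf A_f,

where N_gf counts motif-f hits in DHSs within a window of gene g's TSS and
A_f is a complex activity whose modulus is an amplitude (log2 units) and
whose argument maps to a peak time. The fit is an elastic net on the stacked
real/imaginary system with a *grouped* L1 penalty: the (Re, Im) pair of each
motif is penalized by its 2-norm so both components enter or leave together.

Also here: PWM scanning with exact background p-values (dynamic programming
over the discretized score distribution) and hypergeometric motif
co-occurrence tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold

from .rhythm_stats import OMEGA, harmonic_fit_many

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_CODE = {b: i for i, b in enumerate("ACGT")}


# ---------------------------------------------------------------------------
# PWMs and scanning
# ---------------------------------------------------------------------------

@dataclass
class PWM:
    """Position probability matrix over A,C,G,T with a background model."""

    id: str
    matrix: np.ndarray                     # width x 4, rows sum to 1
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 1e-3

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        m = self.matrix + self.pseudocount
        self.matrix = m / m.sum(axis=1, keepdims=True)
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("PWM rows must sum to 1")
        if np.any(self.matrix <= 0):
            raise ValueError("PWM entries must be positive after pseudocount")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        return np.log2(self.matrix / self.background)

    def reverse_complement(self) -> "PWM":
        return PWM(self.id, self.matrix[::-1, ::-1], self.background[::-1],
                   pseudocount=0.0)

    @classmethod
    def from_consensus(cls, motif_id: str, consensus: str, p_major: float = 0.97) -> "PWM":
        """Near-deterministic PWM from a consensus string."""
        w = len(consensus)
        m = np.full((w, 4), (1.0 - p_major) / 3.0)
        for i, b in enumerate(consensus.upper()):
            m[i, _CODE[b]] = p_major
        return cls(motif_id, m, pseudocount=0.0)

    @classmethod
    def consensus_string(cls, pwm: "PWM") -> str:
        return "".join("ACGT"[i] for i in pwm.matrix.argmax(axis=1))


def read_meme(path) -> list[PWM]:
    """Minimal MEME motif format reader (letter-probability matrices)."""
    pwms = []
    background = np.full(4, 0.25)
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            vals = lines[i + 1].split()
            background = np.array([float(vals[j]) for j in (1, 3, 5, 7)])
            i += 2
            continue
        if line.startswith("MOTIF"):
            name = line.split()[1]
            while not lines[i].strip().startswith("letter-probability"):
                i += 1
            header = lines[i]
            w = int(header.split("w=")[1].split()[0])
            rows = [list(map(float, lines[i + 1 + k].split())) for k in range(w)]
            pwms.append(PWM(name, np.array(rows), background.copy()))
            i += 1 + w
            continue
        i += 1
    return pwms


def write_meme(path, pwms: list[PWM]) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        bg = pwms[0].background if pwms else np.full(4, 0.25)
        fh.write("Background letter frequencies\n")
        fh.write(f"A {bg[0]:.5f} C {bg[1]:.5f} G {bg[2]:.5f} T {bg[3]:.5f}\n\n")
        for p in pwms:
            fh.write(f"MOTIF {p.id}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {p.width} nsites= 20 E= 0\n")
            for row in p.matrix:
                fh.write(" ".join(f"{x:.6f}" for x in row) + "\n")
            fh.write("\n")


@dataclass(frozen=True)
class MotifHit:
    motif: str
    position: int      # 0-based start on the forward strand
    strand: str
    score: float
    pvalue: float


def _score_distribution(log_odds: np.ndarray, background: np.ndarray,
                        granularity: float = 1e-3):
    """Exact distribution of the discretized log-odds score under background.

    Returns (score values ascending, tail probabilities P(S >= value)).
    """
    scaled = np.round(log_odds / granularity).astype(np.int64)
    cur_lo, cur_hi = 0, 0
    dist = np.array([1.0])
    for i in range(scaled.shape[0]):
        smin, smax = scaled[i].min(), scaled[i].max()
        new = np.zeros(dist.size + (smax - smin))
        for b in range(4):
            off = scaled[i, b] - smin
            new[off:off + dist.size] += dist * background[b]
        dist = new
        cur_lo += smin
        cur_hi += smax
    values = (np.arange(cur_lo, cur_hi + 1)) * granularity
    tail = np.cumsum(dist[::-1])[::-1]
    return values, np.minimum(tail, 1.0), cur_lo, scaled


def scan_pwm(sequence: str, pwm: PWM, p_max: float = 1e-4,
             granularity: float = 1e-3) -> list[MotifHit]:
    """Scan both strands for hits with exact background p-value <= p_max.

    Windows containing N are skipped. The p-value of a score is the exact
    probability, under the i.i.d. background, of a discretized log-odds score
    at least as large.
    """
    if not 0 < p_max < 1:
        raise ValueError("p_max must be in (0, 1)")
    seq = sequence.upper()
    w = pwm.width
    if w > len(seq):
        raise ValueError("PWM wider than sequence")
    code = np.full(len(seq), 4, dtype=np.int8)
    for b, i in _CODE.items():
        code[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(b)] = i
    n_pos = len(seq) - w + 1
    windows = np.lib.stride_tricks.sliding_window_view(code, w)
    valid = ~(windows == 4).any(axis=1)
    hits: list[MotifHit] = []
    for strand, mat in (("+", pwm), ("-", pwm.reverse_complement())):
        lo = mat.log_odds
        values, tail, score_lo, scaled = _score_distribution(lo, mat.background, granularity)
        safe = np.where(windows == 4, 0, windows)
        scores = np.zeros(n_pos)
        iscores = np.zeros(n_pos, dtype=np.int64)
        for j in range(w):
            scores += lo[j, safe[:, j]]
            iscores += scaled[j, safe[:, j]]
        idx = np.clip(iscores - score_lo, 0, tail.size - 1)
        pvals = tail[idx]
        sel = valid & (pvals <= p_max)
        for pos in np.flatnonzero(sel):
            hits.append(MotifHit(pwm.id, int(pos), strand,
                                 float(scores[pos]), float(pvals[pos])))
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits


def scan_dhs_set(sequences: dict[str, str], dhs: pd.DataFrame, pwms: list[PWM],
                 p_max: float = 1e-4, halfwidth: int = 300) -> pd.DataFrame:
    """Scan +-halfwidth around every DHS center for every PWM.

    Returns a hit table (dhs_id, motif, position, strand, score, pvalue) with
    positions in chromosome coordinates.
    """
    rows = []
    for rec in dhs.itertuples():
        chrom_seq = sequences[rec.chrom]
        lo = max(0, int(rec.center) - halfwidth)
        hi = min(len(chrom_seq), int(rec.center) + halfwidth + 1)
        window = chrom_seq[lo:hi]
        for pwm in pwms:
            for h in scan_pwm(window, pwm, p_max=p_max):
                rows.append({"dhs_id": rec.dhs_id, "motif": h.motif,
                             "position": lo + h.position, "strand": h.strand,
                             "score": h.score, "pvalue": h.pvalue})
    return pd.DataFrame(rows, columns=["dhs_id", "motif", "position",
                                       "strand", "score", "pvalue"])


# ---------------------------------------------------------------------------
# Design matrix and phase vectors
# ---------------------------------------------------------------------------

def build_motif_matrix(hits: pd.DataFrame, dhs: pd.DataFrame, tss: pd.DataFrame,
                       radius: int) -> pd.DataFrame:
    """N_gf: motif-f hit counts in DHSs whose center lies within ``radius``
    of gene g's TSS. A DHS near several TSSs contributes to each of them.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    motifs = sorted(hits["motif"].unique()) if len(hits) else []
    N = pd.DataFrame(0, index=list(tss["gene_id"]), columns=motifs, dtype=int)
    if not motifs:
        return N
    per_dhs = hits.groupby(["dhs_id", "motif"]).size().unstack(fill_value=0)
    dhs_idx = dhs.set_index("dhs_id")
    for gene in tss.itertuples():
        near = dhs_idx[(dhs_idx["chrom"] == gene.chrom)
                       & ((dhs_idx["center"] - gene.tss).abs() <= radius)]
        for dhs_id in near.index:
            if dhs_id in per_dhs.index:
                row = per_dhs.loc[dhs_id]
                N.loc[gene.gene_id, row.index] += row.to_numpy()
    return N


def phase_vector(times, log2_polii) -> pd.Series:
    """Complex 24-h component per gene from harmonic-regression coefficients.

    P_g = a_g + i b_g with a, b the cosine/sine coefficients; this equals the
    discrete Fourier sum up to a constant scale on a balanced grid and is
    exactly 0 for constant profiles even with the repeated ZT2/ZT26 position.
    """
    fits = harmonic_fit_many(times, log2_polii)
    return pd.Series(fits["coef_cos"].to_numpy() + 1j * fits["coef_sin"].to_numpy(),
                     index=fits.index)


# ---------------------------------------------------------------------------
# Grouped elastic net on the complex response
# ---------------------------------------------------------------------------

def _group_soft_threshold(rho: np.ndarray, t: float) -> np.ndarray:
    norm = np.linalg.norm(rho)
    if norm <= t:
        return np.zeros_like(rho)
    return (1.0 - t / norm) * rho


def elastic_net_objective(Y: np.ndarray, X: np.ndarray, B: np.ndarray,
                          lam: float, alpha: float) -> float:
    n = Y.shape[0]
    rss = float(((Y - X @ B) ** 2).sum())
    norms = np.linalg.norm(B, axis=1)
    return rss / (2 * n) + lam * (alpha * norms.sum() + 0.5 * (1 - alpha) * (norms ** 2).sum())


def _coordinate_descent(Y: np.ndarray, X: np.ndarray, lam: float, alpha: float,
                        B0: np.ndarray | None = None, tol: float = 1e-9,
                        max_iter: int = 2000) -> np.ndarray:
    """Cyclic coordinate descent with group soft-thresholding.

    Y is n x 2 (Re, Im), X is n x p; returns B (p x 2). Each sweep updates
    every motif's two components jointly; the objective is non-increasing.
    """
    n, p = X.shape
    z = (X ** 2).sum(axis=0) / n
    B = np.zeros((p, 2)) if B0 is None else B0.copy()
    R = Y - X @ B
    for _ in range(max_iter):
        max_delta = 0.0
        for f in range(p):
            if z[f] == 0:
                continue
            old = B[f].copy()
            rho = X[:, f] @ R / n + z[f] * old
            new = _group_soft_threshold(rho, lam * alpha) / (z[f] + lam * (1 - alpha))
            delta = new - old
            if np.any(delta != 0):
                R -= np.outer(X[:, f], delta)
                B[f] = new
                max_delta = max(max_delta, float(np.abs(delta).max()))
        if max_delta < tol:
            break
    return B


def _peak_time(A: np.ndarray) -> np.ndarray:
    t = np.where(np.abs(A) > 0, (np.angle(A) / OMEGA) % 24.0, 0.0)
    return np.where(t >= 24.0, 0.0, t)


@dataclass
class ActivityEstimate:
    """Fitted motif activities with regularization-path metadata."""

    activities: pd.DataFrame     # motif x (re, im, amplitude, peak_time)
    alpha: float
    lambda_grid: np.ndarray
    chosen_lambda: float
    deviance_ratio: float
    cv_errors: np.ndarray | None = None

    def complex_activities(self) -> pd.Series:
        return pd.Series(self.activities["re"].to_numpy()
                         + 1j * self.activities["im"].to_numpy(),
                         index=self.activities.index)


def fit_activities(P: pd.Series, N: pd.DataFrame, alpha: float = 0.1,
                   lambda_grid=None, cv_folds: int = 10, seed: int = 0,
                   standardize: bool = True, fixed_lambda: float | None = None,
                   tol: float = 1e-9) -> ActivityEstimate:
    """Grouped elastic-net fit of complex motif activities.

    Minimizes (1/2n) sum_g |P_g - sum_f N_gf A_f|^2 + lambda * [alpha *
    sum_f |A_f| + (1-alpha)/2 sum_f |A_f|^2] with |.| the modulus, i.e. the
    2-norm over the (Re, Im) pair. Columns are scaled to unit variance before
    fitting and coefficients rescaled back. Lambda is chosen by k-fold CV
    over genes unless ``fixed_lambda`` is given; ``deviance_ratio`` is
    1 - RSS/TSS on the full data at the chosen lambda.
    """
    if not P.index.equals(N.index):
        N = N.loc[P.index]
    Y = np.column_stack([P.to_numpy().real, P.to_numpy().imag])
    X = N.to_numpy(dtype=float)
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(Y)):
        raise ValueError("non-finite entries in design or response")
    if not X.any():
        raise ValueError("all-zero motif count matrix")
    n, p = X.shape
    if standardize:
        scale = X.std(axis=0)
        scale[scale == 0] = 1.0
    else:
        scale = np.ones(p)
    Xs = X / scale

    if fixed_lambda is not None:
        grid = np.array([fixed_lambda])
    elif lambda_grid is not None:
        grid = np.sort(np.asarray(lambda_grid, dtype=float))[::-1]
    else:
        lam_max = np.max(np.linalg.norm(Xs.T @ Y / n, axis=1)) / max(alpha, 1e-3)
        grid = np.geomspace(lam_max, lam_max * 1e-4, 30)

    cv_errors = None
    if grid.size > 1:
        folds = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
        errors = np.zeros((cv_folds, grid.size))
        for k, (tr, te) in enumerate(folds.split(Xs)):
            B = None
            for li, lam in enumerate(grid):
                B = _coordinate_descent(Y[tr], Xs[tr], lam, alpha, B0=B, tol=tol)
                resid = Y[te] - Xs[te] @ B
                errors[k, li] = float((resid ** 2).sum() / len(te))
        cv_errors = errors.mean(axis=0)
        chosen = float(grid[int(np.argmin(cv_errors))])
    else:
        chosen = float(grid[0])

    # full-data path down to the chosen lambda (warm starts)
    B = None
    for lam in grid[grid >= chosen]:
        B = _coordinate_descent(Y, Xs, lam, alpha, B0=B, tol=tol)
    B = _coordinate_descent(Y, Xs, chosen, alpha, B0=B, tol=tol)
    B_orig = B / scale[:, None]
    rss = float(((Y - X @ B_orig) ** 2).sum())
    tss = float((Y ** 2).sum())
    deviance_ratio = 0.0 if tss == 0 else 1.0 - rss / tss
    A = B_orig[:, 0] + 1j * B_orig[:, 1]
    table = pd.DataFrame({
        "re": A.real, "im": A.imag, "amplitude": np.abs(A),
        "peak_time": _peak_time(A),
    }, index=N.columns)
    return ActivityEstimate(table, alpha, grid, chosen, deviance_ratio, cv_errors)


def window_scan(P: pd.Series, hits: pd.DataFrame, dhs: pd.DataFrame,
                tss: pd.DataFrame, radii, alpha: float = 0.0,
                cv_folds: int = 10, seed: int = 0) -> pd.DataFrame:
    """Deviance ratio of the activity fit as a function of the DHS-inclusion
    radius around active TSSs (identical CV fold seeds at every radius)."""
    rows = []
    for radius in radii:
        N = build_motif_matrix(hits, dhs, tss, radius)
        if not N.to_numpy().any():
            rows.append({"radius": radius, "deviance_ratio": 0.0})
            continue
        est = fit_activities(P, N, alpha=alpha, cv_folds=cv_folds, seed=seed)
        rows.append({"radius": radius, "deviance_ratio": est.deviance_ratio})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Motif co-occurrence
# ---------------------------------------------------------------------------

def motif_cooccurrence(presence: pd.DataFrame, pairs) -> pd.DataFrame:
    """Hypergeometric co-occurrence tests on a binary site x motif matrix.

    For each (u, v) pair reports the observed overlap, its expectation under
    independent margins, the enrichment (upper) and depletion (lower) tails,
    and a two-sided p = 2*min(tails) capped at 1.
    """
    if presence.shape[0] == 0:
        raise ValueError("empty site universe")
    M = presence.shape[0]
    rows = []
    for u, v in pairs:
        ku = int(presence[u].sum())
        kv = int(presence[v].sum())
        obs = int((presence[u] & presence[v]).sum())
        upper = float(stats.hypergeom.sf(obs - 1, M, ku, kv))
        lower = float(stats.hypergeom.cdf(obs, M, ku, kv))
        expected = ku * kv / M
        rows.append({
            "motif_u": u, "motif_v": v, "overlap": obs, "expected": expected,
            "direction": "enriched" if obs >= expected else "depleted",
            "p_enrich": upper, "p_deplete": lower,
            "p_two_sided": min(1.0, 2.0 * min(upper, lower)),
        })
    return pd.DataFrame(rows)
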