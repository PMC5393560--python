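"""DHS atlas construction: peak calling on merged cut tracks, annotation to
the nearest active TSS with distance classes, Z-score site selection against
external ChIP signal, and WT-vs-knockout signal contrasts.

The peak caller follows a cap / sliding-window / merge scheme: per-position
counts are capped, 600-bp windows stepped every 10 bp are scored by their
capped count sum, enriched local maxima become candidate peaks, and maxima
closer than the vicinity radius are merged keeping the stronger one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genomeio import CutTrack, GenomicInterval


@dataclass(frozen=True)
class PeakParams:
    cutoff: int = 100       # per-position count cap
    vicinity: int = 400     # bp merge radius between candidate maxima
    window_size: int = 600  # bp scoring window
    threshold: int = 1000   # min capped count sum per window
    step: int = 10          # bp window step

    def __post_init__(self) -> None:
        if min(self.cutoff, self.vicinity, self.window_size, self.threshold, self.step) <= 0:
            raise ValueError("all peak parameters must be positive")
        if self.threshold <= self.cutoff:
            raise ValueError("threshold must exceed the per-position cutoff")


@dataclass
class DHSRecord:
    interval: GenomicInterval
    center: int
    nearest_tss: str | None = None
    distance: int | None = None      # signed bp, negative upstream of TSS
    dclass: str | None = None        # tss / proximal / distal
    n_footprints: int = 0

    @property
    def dhs_id(self) -> str:
        return self.interval.name


def _window_sums(pos: np.ndarray, val: np.ndarray, starts: np.ndarray,
                 window: int) -> np.ndarray:
    csum = np.concatenate([[0.0], np.cumsum(val)])
    lo = np.searchsorted(pos, starts, side="left")
    hi = np.searchsorted(pos, starts + window, side="left")
    # round away accumulated float error so plateau detection sees exact ties
    return np.round(csum[hi] - csum[lo], 6)


def _plateau_middle(idx: np.ndarray, sums: np.ndarray) -> list[int]:
    """Collapse runs of consecutive equal-score maxima to their middle index."""
    out = []
    i = 0
    while i < idx.size:
        j = i
        while (j + 1 < idx.size and idx[j + 1] == idx[j] + 1
               and sums[idx[j + 1]] == sums[idx[i]]):
            j += 1
        out.append(int(idx[(i + j) // 2]))
        i = j + 1
    return out


def call_peaks(merged_track: CutTrack, params: PeakParams = PeakParams()) -> list[DHSRecord]:
    """Call hypersensitive sites on a time-merged cut track.

    Returns records carrying intervals (center +- window_size/2) and centers
    only; annotation happens downstream. Empty chromosomes yield no peaks.
    """
    records: list[DHSRecord] = []
    w, step = params.window_size, params.step
    for chrom in sorted(merged_track.chrom_sizes):
        size = merged_track.chrom_sizes[chrom]
        pos, val = merged_track.merged_arrays(chrom)
        if pos.size == 0 or size < w:
            continue
        val = np.minimum(val, params.cutoff)
        starts = np.arange(0, size - w + 1, step)
        sums = _window_sums(pos, val, starts, w)
        enriched = sums >= params.threshold
        if not enriched.any():
            continue
        left = np.concatenate([[-np.inf], sums[:-1]])
        right = np.concatenate([sums[1:], [-np.inf]])
        is_max = enriched & (sums >= left) & (sums >= right)
        maxima = _plateau_middle(np.flatnonzero(is_max), sums)
        # best-first merge: keep stronger peak when two maxima are closer
        # than the vicinity radius (ties resolved to the leftmost)
        order = sorted(maxima, key=lambda i: (-sums[i], starts[i]))
        kept_centers: list[int] = []
        for i in order:
            center = int(starts[i] + w // 2)
            if all(abs(center - c) >= params.vicinity for c in kept_centers):
                kept_centers.append(center)
        ordered = sorted(kept_centers)
        for k, center in enumerate(ordered):
            lo = max(0, center - w // 2)
            hi = min(size, center + w // 2)
            # neighbors can sit closer than the window; clip at midpoints so
            # reported intervals never overlap
            if k > 0:
                lo = max(lo, (ordered[k - 1] + center + 1) // 2)
            if k + 1 < len(ordered):
                hi = min(hi, (center + ordered[k + 1]) // 2)
            records.append(DHSRecord(
                GenomicInterval(chrom, lo, hi, ".", f"{chrom}_peak{k:04d}"),
                center))
    return records


def annotate_to_tss(dhs: list[DHSRecord], active_tss: pd.DataFrame) -> list[DHSRecord]:
    """Assign each DHS to the closest active TSS and a distance class.

    ``active_tss`` needs columns gene_id, chrom, tss, strand. Distance is
    signed in the TSS strand frame (negative upstream); the class boundaries
    on |distance| are <=1 kb (tss), 1-10 kb (proximal), >10 kb (distal).
    Ties between equidistant TSSs go to the lexicographically lower gene id.
    """
    if len(active_tss) == 0:
        raise ValueError("active_tss must be nonempty")
    tss_sorted = active_tss.sort_values(["chrom", "tss", "gene_id"]).reset_index(drop=True)
    by_chrom = {c: sub.reset_index(drop=True) for c, sub in tss_sorted.groupby("chrom")}
    for rec in dhs:
        sub = by_chrom.get(rec.interval.chrom)
        if sub is None:
            raise KeyError(f"no active TSS on chromosome {rec.interval.chrom}")
        d = np.abs(sub["tss"].to_numpy() - rec.center)
        best = d.min()
        cands = sub[d == best].sort_values("gene_id").iloc[0]
        signed = rec.center - int(cands["tss"])
        if cands["strand"] == "-":
            signed = -signed
        rec.nearest_tss = str(cands["gene_id"])
        rec.distance = int(signed)
        rec.dclass = classify_distance(signed)
    return dhs


def classify_distance(distance: int) -> str:
    d = abs(int(distance))
    if d <= 1000:
        return "tss"
    if d <= 10000:
        return "proximal"
    return "distal"


def zscore_select(signal, z_min: float = 2.0) -> np.ndarray:
    """Indices of sites whose signal Z-score exceeds z_min."""
    x = np.asarray(signal, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 sites")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance signal vector")
    z = (x - x.mean()) / sd
    return np.flatnonzero(z > z_min)


def compare_genotypes(sig_a, sig_b) -> dict:
    """Per-site log2 ratios (b - a), median shift, and a Welch t-test p-value.

    A shift of -1 means 2-fold lower signal in condition b.
    """
    a = np.asarray(sig_a, dtype=float)
    b = np.asarray(sig_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("signal vectors must align site-by-site")
    if a.size < 3:
        raise ValueError("need at least 3 sites")
    ratios = b - a
    if np.allclose(a, b) and a.std() == 0 and b.std() == 0:
        p = 1.0
    else:
        res = stats.ttest_ind(b, a, equal_var=False)
        p = 1.0 if np.isnan(res.pvalue) else float(res.pvalue)
        if np.array_equal(a, b):
            p = 1.0
    return {"ratios": ratios, "shift": float(np.median(ratios)), "pvalue": p}
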