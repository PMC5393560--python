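"""Synthetic diurnal chromatin time courses with known ground truth.

The generator emulates the design of a liver DNase-seq / ChIP-seq diurnal
study: 7 time points (ZT2..ZT26, 4-h spacing, ZT26 an independent sample
whose clock position repeats ZT2), three marks (DNase I cuts, Pol II,
H3K27ac) cycling in phase at each regulatory site, DHSs in three
TSS-distance classes, motif content that drives gene-level rhythms through
complex-valued motif activities, and per-base cut profiles with time-varying
footprints at single and tandem E-boxes.

The gene model is

    log2 signal_g(t) = mesor_g + Re( sum_f N_gf A_f * exp(-i w t) ) + noise,

with w = 2*pi/24 and A_f = amp_f * exp(i w peak_f), so a motif of activity
amplitude 1 (log2 units) in a single-copy gene produces a pure cosine with
log2 peak-to-trough 2. Sequencing counts are Poisson with mean
seq_depth * 2^(log2 signal).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genomeio import CutTrack, GenomicInterval
from .rhythm_stats import OMEGA

BASES = np.array(list("ACGT"))

DEFAULT_TIME_POINTS = (2.0, 6.0, 10.0, 14.0, 18.0, 22.0, 26.0)

# DHS class composition: roughly a quarter at TSSs, a quarter proximal and
# half distal, the mix typical of mammalian DHS atlases.
DEFAULT_CLASS_FRACTIONS = (24 / 99, 28 / 99, 47 / 99)  # (tss, proximal, distal)


@dataclass(frozen=True)
class MotifSpec:
    """A motif identifier with its planted consensus string."""

    id: str
    consensus: str


# Canonical liver diurnal regulators: the three clock-output elements
# (E-box ~ZT8, D-box ~ZT12, RRE ~ZT22) plus feeding/systemic motifs.
DEFAULT_MOTIF_LIBRARY = (
    MotifSpec("Ebox", "CACGTG"),
    MotifSpec("Dbox", "TTATGTAA"),
    MotifSpec("RRE", "AAAGTAGGTCA"),
    MotifSpec("CREB", "TGACGTCA"),
    MotifSpec("FOX", "TGTTTACTT"),
    MotifSpec("SREBP", "TCACGCCAC"),
    MotifSpec("HSF", "AGAACGTTCT"),
    MotifSpec("GRE", "GGTACATAATGTTCT"),
)

DEFAULT_TRUTH_ACTIVITIES = {
    "Ebox": (0.8, 8.0),
    "Dbox": (0.5, 12.0),
    "RRE": (0.6, 22.0),
    "CREB": (0.35, 7.0),
    "FOX": (0.3, 20.0),
    "SREBP": (0.3, 19.0),
    "HSF": (0.25, 16.0),
    "GRE": (0.25, 10.0),
}

DEFAULT_KO_ZEROED = ("Ebox", "Dbox", "RRE")

MARKS = ("dnase", "polii", "h3k27ac")
MARK_HALFWIDTH = {"dnase": 300, "polii": 300, "h3k27ac": 1000}


def activity_complex(amplitude: float, peak_hours: float) -> complex:
    """Complex activity A = amp * exp(i*w*peak); Re/Im are cos/sin coefficients."""
    return amplitude * np.exp(1j * OMEGA * peak_hours)


@dataclass
class SimConfig:
    genome_length: int = 3_000_000
    n_chromosomes: int = 2
    n_genes: int = 50
    n_dhs: int = 150
    dhs_class_fractions: tuple[float, float, float] = DEFAULT_CLASS_FRACTIONS
    time_points: tuple[float, ...] = DEFAULT_TIME_POINTS
    motif_library: tuple[MotifSpec, ...] = DEFAULT_MOTIF_LIBRARY
    truth_activities: dict = field(default_factory=lambda: dict(DEFAULT_TRUTH_ACTIVITIES))
    noise_sd: float = 0.25
    seq_depth: float = 500.0
    footprint_spec: object | None = None
    genotype: str = "wt"
    ko_zeroed_motifs: tuple[str, ...] = DEFAULT_KO_ZEROED
    seed: int = 0
    # structural knobs
    target_gene_fraction: float = 0.5   # P(gene carries any copies of a motif)
    extra_copy_rate: float = 0.7        # copies-1 ~ Poisson(rate) in target genes
    inactive_gene_fraction: float = 0.2
    distal_max_bp: int = 50_000
    background_cuts_per_kb: float = 0.1
    nb_dispersion: float | None = None  # None -> Poisson counts
    # Pol II also accumulates at non-promoter DHSs (eRNA-like), attenuated
    # relative to the TSS by this many log2 units
    polii_dhs_atten: float = 1.5
    # per-(mark, time) sequencing-depth variation: log2 library factors are
    # drawn N(0, library_log2_sd) and multiply every site's expected counts,
    # which is what between-time normalization must remove downstream
    library_log2_sd: float = 0.2
    # a site counts as rhythmic in the ground truth when its log2
    # peak-to-trough amplitude reaches this value (1.0 = 2-fold, the typical
    # median amplitude of cycling accessibility); weaker oscillations are
    # recorded via the amplitude column but not flagged
    min_rhythmic_amplitude: float = 1.0

    def __post_init__(self) -> None:
        if abs(sum(self.dhs_class_fractions) - 1.0) > 1e-9:
            raise ValueError("dhs_class_fractions must sum to 1")
        tp = np.asarray(self.time_points, dtype=float)
        if np.any(np.diff(tp) <= 0) or tp.min() < 0 or tp.max() > 26:
            raise ValueError("time_points must be strictly increasing within [0, 26]")
        ids = {m.id for m in self.motif_library}
        missing = set(self.ko_zeroed_motifs) - ids
        if missing:
            raise ValueError(f"ko_zeroed_motifs not in motif_library: {sorted(missing)}")
        for mid, act in self.truth_activities.items():
            if mid not in ids:
                raise ValueError(f"truth activity for unknown motif {mid!r}")
            a = self.activity(mid)
            if not np.isfinite(a.real) or not np.isfinite(a.imag):
                raise ValueError(f"non-finite activity for {mid!r}")
        if self.genotype not in ("wt", "ko"):
            raise ValueError("genotype must be 'wt' or 'ko'")
        if self.n_dhs < self.n_genes:
            raise ValueError("need at least one DHS per gene (n_dhs >= n_genes)")
        counts = np.round(np.asarray(self.dhs_class_fractions) * self.n_dhs)
        if np.any((np.asarray(self.dhs_class_fractions) > 0) & (counts < 1)):
            raise ValueError("n_dhs too small to realize dhs_class_fractions")

    def activity(self, motif_id: str) -> complex:
        """Effective complex activity for this genotype."""
        raw = self.truth_activities.get(motif_id, 0.0)
        if isinstance(raw, tuple):
            a = activity_complex(*raw)
        else:
            a = complex(raw)
        if self.genotype == "ko" and motif_id in self.ko_zeroed_motifs:
            return 0j
        return a


@dataclass
class SyntheticTruth:
    """Ground truth emitted next to every simulated dataset."""

    dhs_truth: pd.DataFrame            # dhs_id, gene, rhythmic, amplitude, phase
    activity_truth: dict               # motif id -> complex (genotype-adjusted)
    active_genes: set
    motif_counts: pd.DataFrame         # genes x motifs (N_gf)
    motif_placements: pd.DataFrame     # dhs_id, motif, chrom, start, end
    occupancy_truth: np.ndarray | None = None   # sites x times bound probability
    footprint_truth: list | None = None          # per-element (left, right, depletion)

    def to_json(self, path) -> None:
        payload = {
            "activity_truth": {k: [v.real, v.imag] for k, v in self.activity_truth.items()},
            "active_genes": sorted(self.active_genes),
            "dhs_truth": self.dhs_truth.to_dict(orient="list"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


@dataclass
class SimResult:
    config: SimConfig
    chrom_sizes: dict
    sequences: dict                    # chrom -> str
    genes: pd.DataFrame                # gene_id, chrom, tss, strand, active, ...
    dhs: pd.DataFrame                  # dhs_id, chrom, center, gene, dclass, distance
    tracks: dict                       # mark -> {time: CutTrack}
    log2_levels: dict                  # mark -> DataFrame (sites x times), noise included
    truth: SyntheticTruth

    @property
    def times(self) -> np.ndarray:
        return np.asarray(self.config.time_points, dtype=float)

    def tss_intervals(self, active_only: bool = True) -> list[GenomicInterval]:
        rows = self.genes[self.genes["active"]] if active_only else self.genes
        return [
            GenomicInterval(r.chrom, max(0, int(r.tss) - 1), int(r.tss) + 1, r.strand, r.gene_id)
            for r in rows.itertuples()
        ]

    def dhs_intervals(self, halfwidth: int = 300) -> list[GenomicInterval]:
        return [
            GenomicInterval(r.chrom, int(r.center) - halfwidth, int(r.center) + halfwidth + 1,
                            ".", r.dhs_id)
            for r in self.dhs.itertuples()
        ]


def _draw_counts(rng: np.random.Generator, mean, dispersion: float | None):
    mean = np.asarray(mean, dtype=float)
    if dispersion is None:
        return rng.poisson(mean)
    # negative binomial with var = mean + dispersion * mean^2
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def _plant(seq: np.ndarray, start: int, motif: str) -> None:
    seq[start:start + len(motif)] = list(motif)


def simulate_study(config: SimConfig) -> SimResult:
    """Generate annotations, per-mark time-course cut tracks, and ground truth.

    Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    times = np.asarray(config.time_points, dtype=float)
    n_times = times.size
    motif_ids = [m.id for m in config.motif_library]
    consensus = {m.id: m.consensus for m in config.motif_library}

    # -- genome layout ----------------------------------------------------
    chrom_sizes = {f"chrS{i + 1}": config.genome_length for i in range(config.n_chromosomes)}
    chroms = list(chrom_sizes)
    genes_per_chrom = [config.n_genes // config.n_chromosomes] * config.n_chromosomes
    for i in range(config.n_genes % config.n_chromosomes):
        genes_per_chrom[i] += 1
    max_reach = config.distal_max_bp + 1500
    gene_rows = []
    gid = 0
    for ci, chrom in enumerate(chroms):
        k = genes_per_chrom[ci]
        if k == 0:
            continue
        spacing = config.genome_length / (k + 1)
        if spacing < 2 * max_reach:
            raise ValueError(
                f"genome_length {config.genome_length} too small for {k} genes per "
                f"chromosome with distal DHSs out to {config.distal_max_bp} bp")
        for j in range(k):
            gene_rows.append({
                "gene_id": f"g{gid:04d}",
                "chrom": chrom,
                "tss": int(round(spacing * (j + 1))),
                "strand": "+" if rng.random() < 0.5 else "-",
            })
            gid += 1
    genes = pd.DataFrame(gene_rows)
    active_mask = rng.random(config.n_genes) >= config.inactive_gene_fraction
    if not active_mask.any():
        active_mask[0] = True
    genes["active"] = active_mask
    active_idx = np.flatnonzero(active_mask)

    # -- motif content N_gf (active genes only; inactive genes are flat) ----
    N = np.zeros((config.n_genes, len(motif_ids)), dtype=int)
    targets = rng.random((config.n_genes, len(motif_ids))) < config.target_gene_fraction
    extra = rng.poisson(config.extra_copy_rate, size=N.shape)
    N[targets] = 1 + extra[targets]
    N[~active_mask, :] = 0
    activities = np.array([config.activity(m) for m in motif_ids])
    P_gene = N @ activities  # complex phase vector per gene
    genes["p_re"] = P_gene.real
    genes["p_im"] = P_gene.imag

    # -- DHS placement ----------------------------------------------------
    class_names = np.array(["tss", "proximal", "distal"])
    counts = np.floor(np.asarray(config.dhs_class_fractions) * config.n_dhs).astype(int)
    while counts.sum() < config.n_dhs:
        counts[int(np.argmax(np.asarray(config.dhs_class_fractions) * config.n_dhs - counts))] += 1
    class_pool = np.repeat(class_names, counts)
    rng.shuffle(class_pool)
    owner = active_idx[np.arange(config.n_dhs) % active_idx.size]

    dhs_rows = []
    used: dict[int, list[int]] = {}
    for d in range(config.n_dhs):
        g = int(owner[d])
        dclass = class_pool[d]
        lo, hi = {"tss": (0, 800), "proximal": (1200, 9000),
                  "distal": (11000, config.distal_max_bp - 1000)}[dclass]
        tss = int(genes.at[g, "tss"])
        for _ in range(200):
            mag = int(rng.integers(lo, hi + 1))
            sign = -1 if rng.random() < 0.5 else 1
            center = tss + sign * mag
            # keep quantification windows (up to +-1 kb) from overlapping so
            # each site's signal reflects its own truth label
            if all(abs(center - c) >= 2500 for c in used.get(g, [])):
                break
        used.setdefault(g, []).append(center)
        dhs_rows.append({
            "dhs_id": f"dhs{d:04d}",
            "chrom": genes.at[g, "chrom"],
            "center": center,
            "gene": genes.at[g, "gene_id"],
            "dclass": dclass,
            "distance": sign * mag,
        })
    dhs = pd.DataFrame(dhs_rows)

    # -- sequences with planted motif copies --------------------------------
    sequences = {}
    seq_arrays = {c: BASES[rng.integers(0, 4, size=chrom_sizes[c])] for c in chroms}
    gene_dhs = {g: dhs.index[dhs["gene"] == genes.at[g, "gene_id"]].to_numpy()
                for g in range(config.n_genes)}
    placements = []
    # disjoint 30-bp planting slots inside each DHS window keep motif copies
    # from overwriting each other
    slot_offsets = np.arange(-250, 221, 30)
    free_slots: dict[int, list[int]] = {
        d: list(rng.permutation(slot_offsets)) for d in range(config.n_dhs)}
    for g in range(config.n_genes):
        my_dhs = gene_dhs.get(g, np.array([], dtype=int))
        if my_dhs.size == 0:
            continue
        turn = 0
        for f, mid in enumerate(motif_ids):
            motif = consensus[mid]
            for _ in range(N[g, f]):
                d = None
                for probe in range(my_dhs.size):
                    cand = int(my_dhs[(turn + probe) % my_dhs.size])
                    if free_slots[cand]:
                        d = cand
                        turn += probe + 1
                        break
                if d is None:
                    raise ValueError("motif copies exceed DHS planting capacity; "
                                     "increase n_dhs or lower copy rates")
                start = int(dhs.at[d, "center"]) + int(free_slots[d].pop())
                _plant(seq_arrays[dhs.at[d, "chrom"]], start, motif)
                placements.append({"dhs_id": dhs.at[d, "dhs_id"], "motif": mid,
                                   "chrom": dhs.at[d, "chrom"],
                                   "start": start, "end": start + len(motif)})
    sequences = {c: "".join(seq_arrays[c]) for c in chroms}

    # -- log2 levels and tracks ---------------------------------------------
    harmonic = np.real(np.outer(P_gene, np.exp(-1j * OMEGA * times)))  # genes x times
    gene_of_dhs = dhs["gene"].map(
        pd.Series(np.arange(config.n_genes), index=genes["gene_id"])).to_numpy()

    # per-site relative abundance (log2 around 0); inactive genes are depressed
    mesor_gene = rng.uniform(-1.0, 1.0, size=config.n_genes)
    mesor_gene[~active_mask] -= 5.0
    mesor_dhs = {mark: rng.uniform(-1.0, 1.0, size=config.n_dhs)
                 for mark in ("dnase", "h3k27ac", "polii_dhs")}

    log2_levels: dict[str, pd.DataFrame] = {}
    tracks: dict[str, dict[float, CutTrack]] = {m: {} for m in MARKS}
    site_index = {"polii": genes["gene_id"].tolist(),
                  "dnase": dhs["dhs_id"].tolist(), "h3k27ac": dhs["dhs_id"].tolist()}
    atten = np.where(dhs["dclass"].to_numpy() == "tss", 0.0, config.polii_dhs_atten)
    for mark in MARKS:
        # each placement: (per-site log2 levels, centers, chroms, record?)
        deposits = []
        if mark == "polii":
            base = mesor_gene[:, None] + harmonic
            noise = (rng.normal(0.0, config.noise_sd, size=base.shape)
                     if config.noise_sd > 0 else np.zeros_like(base))
            deposits.append((base + noise, genes["tss"].to_numpy(),
                               genes["chrom"].to_numpy(), True))
            # eRNA-like Pol II at DHSs, in phase with the gene, attenuated
            base_d = (mesor_dhs["polii_dhs"][:, None] + harmonic[gene_of_dhs]
                      - atten[:, None])
            noise_d = (rng.normal(0.0, config.noise_sd, size=base_d.shape)
                       if config.noise_sd > 0 else np.zeros_like(base_d))
            deposits.append((base_d + noise_d, dhs["center"].to_numpy(),
                               dhs["chrom"].to_numpy(), False))
        else:
            base = mesor_dhs[mark][:, None] + harmonic[gene_of_dhs]
            noise = (rng.normal(0.0, config.noise_sd, size=base.shape)
                     if config.noise_sd > 0 else np.zeros_like(base))
            deposits.append((base + noise, dhs["center"].to_numpy(),
                               dhs["chrom"].to_numpy(), True))
        log2_levels[mark] = pd.DataFrame(
            next(lv for lv, _, _, rec in deposits if rec),
            index=site_index[mark], columns=times)
        hw = MARK_HALFWIDTH[mark]
        lib_factor = (np.power(2.0, rng.normal(0.0, config.library_log2_sd, times.size))
                      if config.library_log2_sd > 0 else np.ones(times.size))
        for ti, t in enumerate(times):
            track = CutTrack(chrom_sizes)
            for levels, centers, chrom_arr, _ in deposits:
                mean_counts = (config.seq_depth * lib_factor[ti]
                               * np.power(2.0, levels[:, ti]))
                totals = _draw_counts(rng, mean_counts, config.nb_dispersion)
                for si in range(len(centers)):
                    n_cut = int(totals[si])
                    if n_cut == 0:
                        continue
                    size = chrom_sizes[chrom_arr[si]]
                    pos = rng.integers(max(0, centers[si] - hw),
                                       min(size, centers[si] + hw + 1), size=n_cut)
                    strand = np.where(rng.random(n_cut) < 0.5, "+", "-")
                    for s in ("+", "-"):
                        sel = strand == s
                        if sel.any():
                            track.add(chrom_arr[si], s, pos[sel])
            if mark == "dnase" and config.background_cuts_per_kb > 0:
                for chrom, size in chrom_sizes.items():
                    n_bg = rng.poisson(config.background_cuts_per_kb * size / 1000.0)
                    if n_bg:
                        track.add(chrom, "+", rng.integers(0, size, size=n_bg))
            tracks[mark][t] = track

    amp = 2.0 * np.abs(P_gene[gene_of_dhs])
    phase = np.where(amp > 0,
                     (np.angle(P_gene[gene_of_dhs]) / OMEGA) % 24.0, 0.0)
    dhs_truth = pd.DataFrame({
        "dhs_id": dhs["dhs_id"], "gene": dhs["gene"],
        "rhythmic": amp >= config.min_rhythmic_amplitude,
        "amplitude": amp, "phase": phase,
    })
    truth = SyntheticTruth(
        dhs_truth=dhs_truth,
        activity_truth={m: config.activity(m) for m in motif_ids},
        active_genes=set(genes.loc[genes["active"], "gene_id"]),
        motif_counts=pd.DataFrame(N, index=genes["gene_id"], columns=motif_ids),
        motif_placements=pd.DataFrame(placements,
                                      columns=["dhs_id", "motif", "chrom", "start", "end"]),
    )
    return SimResult(config, chrom_sizes, sequences, genes, dhs, tracks, log2_levels, truth)


def simulate_expression_panel(n_genes: int, activities, motif_ids=None,
                              copy_rate: float = 1.0, noise_sd: float = 0.25,
                              time_points=DEFAULT_TIME_POINTS, seed: int = 0):
    """Gene-level panel: motif counts N_gf ~ Poisson(copy_rate) and log2 Pol II
    time courses mesor-free, driven by the given complex activities plus
    Gaussian noise. Returns (N DataFrame, levels DataFrame genes x times).

    A lighter companion to :func:`simulate_study` for experiments that only
    need the regression layer (no genome, tracks or sequences).
    """
    acts = np.asarray(activities, dtype=complex)
    if motif_ids is None:
        motif_ids = [f"m{i:02d}" for i in range(acts.size)]
    rng = np.random.default_rng(seed)
    times = np.asarray(time_points, dtype=float)
    N = rng.poisson(copy_rate, size=(n_genes, acts.size))
    P = N @ acts
    levels = np.real(np.outer(P, np.exp(-1j * OMEGA * times)))
    if noise_sd > 0:
        levels = levels + rng.normal(0.0, noise_sd, size=levels.shape)
    index = [f"g{i:04d}" for i in range(n_genes)]
    return (pd.DataFrame(N, index=index, columns=list(motif_ids)),
            pd.DataFrame(levels, index=index, columns=times))


# ---------------------------------------------------------------------------
# Per-base cut profiles with footprints
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FootprintElement:
    """A protected interval [left, right] (bp, inclusive, relative to the
    motif center) with its depletion factor (cut rate multiplier when bound)."""

    left: int
    right: int
    depletion: float

    def __post_init__(self) -> None:
        if self.left >= self.right:
            raise ValueError("left edge must be < right edge")
        if not 0 < self.depletion < 1:
            raise ValueError("depletion must be in (0, 1)")


@dataclass(frozen=True)
class FootprintSpec:
    """One or more footprint elements sharing a profile window of +-L bp."""

    elements: tuple[FootprintElement, ...]
    halfwidth: int = 50
    shoulder_bp: int = 15
    sequence: str = ""

    def __post_init__(self) -> None:
        for e in self.elements:
            if e.left < -self.halfwidth or e.right > self.halfwidth:
                raise ValueError("protected interval wider than the profile window")


def single_ebox_spec(depletion: float = 0.2, halfwidth: int = 50) -> FootprintSpec:
    return FootprintSpec((FootprintElement(-10, 15, depletion),),
                         halfwidth=halfwidth, sequence="CACGTG")


def tandem_ebox_spec(spacer: int = 6, depletion: float = 0.2,
                     halfwidth: int = 50) -> FootprintSpec:
    """Tandem E-boxes CACGTG + A-spacer + CACGTG, one element per dimer.

    The 5' element protects the upstream box, the 3' element the downstream
    box; with both bound the protected span covers the whole tandem site.
    """
    if spacer not in (6, 7):
        raise ValueError("tandem E-box spacer must be 6 or 7 bp")
    seq = "CACGTG" + "A" * spacer + "CACGTG"
    total = len(seq)
    # offsets relative to site midpoint
    left0 = -total // 2
    e1 = FootprintElement(left0 - 3, left0 + 6 + 2, depletion)
    e2 = FootprintElement(left0 + 6 + spacer - 2, left0 + total + 3, depletion)
    return FootprintSpec((e1, e2), halfwidth=halfwidth, sequence=seq)


def bound_profile(spec: FootprintSpec, bound: np.ndarray) -> np.ndarray:
    """Expected per-base cut probability profile given element bound flags.

    Starts from a uniform background over the window, multiplies protected
    intervals of bound elements by their depletion, then redistributes the
    removed mass onto shoulder positions just outside the protected span so
    the profile still sums to 1 (total depth is occupancy-independent).
    """
    width = 2 * spec.halfwidth + 1
    offsets = np.arange(-spec.halfwidth, spec.halfwidth + 1)
    q = np.full(width, 1.0 / width)
    protected = np.zeros(width, dtype=bool)
    rate = q.copy()
    for e, is_bound in zip(spec.elements, bound):
        if is_bound:
            inside = (offsets >= e.left) & (offsets <= e.right)
            rate[inside] *= e.depletion
            protected |= inside
    removed = 1.0 - rate.sum()
    if removed > 0:
        shoulder = np.zeros(width, dtype=bool)
        for e, is_bound in zip(spec.elements, bound):
            if is_bound:
                shoulder |= (offsets >= e.left - spec.shoulder_bp) & (offsets < e.left)
                shoulder |= (offsets > e.right) & (offsets <= e.right + spec.shoulder_bp)
        shoulder &= ~protected
        if shoulder.any():
            rate[shoulder] += removed / shoulder.sum()
        else:
            rate += removed / width
    return rate


def simulate_cut_profiles(n_sites: int, spec: FootprintSpec, occupancy,
                          depth: float, seed: int = 0):
    """Per-site, per-time, strand-split cut count profiles around motif sites.

    ``occupancy`` is the per-time bound probability: shape (n_times,) applies
    to every element, shape (n_times, n_elements) controls each element (a
    tandem site whose 3' dimer occupancy is 0 keeps only the 5' protection).

    Returns (counts, bound, offsets): counts has shape
    (n_sites, n_times, 2, 2L+1) with axis 2 = (+ strand, - strand), bound the
    per-site/time/element truth.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    occ = np.atleast_1d(np.asarray(occupancy, dtype=float))
    if occ.ndim == 1:
        occ = np.repeat(occ[:, None], len(spec.elements), axis=1)
    if np.any((occ < 0) | (occ > 1)):
        raise ValueError("occupancy must be within [0, 1]")
    n_times, n_el = occ.shape
    if n_el != len(spec.elements):
        raise ValueError("occupancy columns must match footprint elements")
    rng = np.random.default_rng(seed)
    width = 2 * spec.halfwidth + 1
    counts = np.zeros((n_sites, n_times, 2, width), dtype=np.int64)
    bound = rng.random((n_sites, n_times, n_el)) < occ[None, :, :]
    # cache the 2^n_el possible profiles
    profiles = {}
    for s in range(n_sites):
        for t in range(n_times):
            key = tuple(bound[s, t])
            if key not in profiles:
                profiles[key] = bound_profile(spec, np.array(key))
            rate = profiles[key] * depth / 2.0
            counts[s, t, 0] = rng.poisson(rate)
            counts[s, t, 1] = rng.poisson(rate)
    offsets = np.arange(-spec.halfwidth, spec.halfwidth + 1)
    return counts, bound, offsets


def write_profiles_tsv(path, counts: np.ndarray, offsets: np.ndarray) -> None:
    """TSV dump: site_id, time_index, offset, strand, count (nonzero only)."""
    with open(path, "w") as fh:
        fh.write("site_id\ttime_index\toffset\tstrand\tcount\n")
        n_sites, n_times, _, width = counts.shape
        for s in range(n_sites):
            for t in range(n_times):
                for si, strand in enumerate("+-"):
                    nz = np.flatnonzero(counts[s, t, si])
                    for x in nz:
                        fh.write(f"site{s:04d}\t{t}\t{offsets[x]}\t{strand}\t{counts[s, t, si, x]}\n")
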