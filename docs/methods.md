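# Methods

`circadhs` analyses diurnal (24-h) rhythms in chromatin accessibility and
transcription: it detects rhythmic DNase I hypersensitive sites (DHSs) from
time-course cut tracks, infers which transcription-factor motifs drive the
rhythms, and models how DNase I footprints at bound motifs change over the
day. A synthetic-data generator with full ground truth makes every stage
testable without sequencing data.

## Rhythm model

All signals are analysed on the log2 scale as single-harmonic (cosinor)
regressions with the period fixed at 24 h:

    y(t) = m + a·cos(ωt) + b·sin(ωt) + ε,   ω = 2π/24 h⁻¹.

The fitted quantities are the mesor `m`, the log2 peak-to-trough amplitude
`2·√(a²+b²)` (a value of 1 means a 2-fold oscillation), and the peak time
`atan2(b,a)/ω mod 24` in ZT hours. Significance is an F(2, n−3) test against
the intercept-only model; with the standard design of 7 samples at ZT2…ZT26
(4-h spacing) there are 4 residual degrees of freedom. ZT26 is an
independent biological sample whose harmonic regressors coincide with ZT2 —
it is never averaged into ZT2, it simply adds a replicate at that clock
position.

Per-site rhythmicity across the three marks (DNase I, Pol II, H3K27ac) is
combined with Fisher's method, X = −2·Σ ln p ~ χ²(2k), k = 3, which assumes
the marks' p-values are independent given a flat site; this is an
approximation, since the marks share biological noise sources. Exact zeros
are clipped to the smallest positive float with a warning. Multiple testing
uses the Benjamini–Hochberg linear step-up procedure; cycling sites are
selected at FDR ≤ 0.05 and promoter–enhancer pairs at FDR ≤ 0.1.

Other statistics: the Fisher–Lee circular correlation (permutation p-value)
compares phase sets; the Chow F-test, F = [(RSS_pooled − RSS_a − RSS_b)/3] /
[(RSS_a+RSS_b)/(n_a+n_b−6)], asks whether one harmonic fits two conditions
as well as separate fits.

## DHS atlas

Peaks are called on the time-merged DNase cut track with a
cap/slide/merge scheme: per-base counts capped at 100, 600-bp windows
stepped every 10 bp scored by the capped sum, windows with sum ≥ 1000
kept, local maxima (equal-score plateaus collapsed to their middle window)
merged best-first when closer than 400 bp. The step size, plateau rule and
merge tie-break are this package's choices — the original caller's
internals are not public. Reported intervals are center ± 300 bp, clipped
at the midpoint between adjacent peaks so intervals never overlap. Window
sums are rounded to 6 decimals before comparison so that floating-point
accumulation cannot split an exact plateau.

Each DHS is annotated to the closest active TSS (ties to the
lexicographically lower gene id); signed distance is in the TSS strand
frame and the distance classes are ≤1 kb (tss), 1–10 kb (proximal), >10 kb
(distal) on the absolute distance.

Signals are quantified as total cuts (both strands) in center ± 300 bp
(± 1 kb for H3K27ac), log2-transformed with a pseudocount of 1 (the +1
guards empty windows; any positive constant only shifts the mesor).

### Between-time normalization

Sequencing depth varies between time points, so the per-mark log2 matrices
are column-centered before rhythm fitting. The default is a two-pass robust
centering: center on the column medians, fit harmonics, then re-estimate the
column effects from the confidently non-rhythmic sites (p > 0.3) only. The
second pass matters when a large fraction of sites cycles with coherent
phases: any centering statistic computed over all sites is then itself
rhythmic, and subtracting it imprints an anti-phase artifact on flat sites
(with full quantile normalization this inflated the realized FDR of the
cycling screen several-fold on small site panels). Full quantile
normalization (average-tie ranks mapped to mean order statistics) is
implemented and available (`normalization="quantile"`); it is the safer
choice when the cycling fraction is small and distributional differences go
beyond a shift.

## Active transcripts

Training labels are the top and bottom Pol II RPKM deciles (RPKM =
counts·10⁹ / (length · library size)); a linear maximum-margin classifier
(standardized features + linear SVM) is trained per time point on chromatin
features (Pol II and H3K4me3 at the TSS, DNase at the TES, H3K36me3 over
the gene body end) and applied to all transcripts; a transcript is active
if classified active at ≥ 1 time point. The classifier is a contract, not a
specific algorithm: any linear margin classifier reaching ≥ 95%
cross-validated accuracy on the decile extremes conforms. Transcripts
shorter than 600 bp are rescued iff their RPKM strictly exceeds the lower
quartile (linear interpolation) of the active set.

## Motif activities

The 24-h component of each gene's Pol II time course is summarized as the
complex phase vector P_g = a_g + i·b_g from the harmonic coefficients —
exactly 0 for constant profiles, and equal to the discrete Fourier sum up
to a constant scale on a balanced grid. The model is linear in motif
content:

    P_g = Σ_f N_gf · A_f ,

where N_gf counts motif-f hits (PWM scan p ≤ 10⁻⁴) in DHSs whose centers
lie within a radius W of gene g's TSS (a DHS near several TSSs counts for
each), and A_f is the complex activity of motif f: |A_f| is an amplitude in
log2 units, arg(A_f)/ω a peak time.

PWM scanning computes log-odds scores on both strands and converts them to
exact background p-values by dynamic programming over the score
distribution discretized at 10⁻³ on the log-odds scale; windows containing
N are skipped.

The fit is an elastic net on the stacked (Re, Im) system with a grouped
penalty,

    (1/2n)·Σ_g ‖P_g − Σ_f N_gf A_f‖² + λ[ α·Σ_f ‖A_f‖ + (1−α)/2·Σ_f ‖A_f‖² ],

where ‖A_f‖ is the modulus, so a motif's two components enter or leave the
model together. It is solved by cyclic coordinate descent with group
soft-thresholding (the objective is non-increasing per sweep, asserted in
tests); columns are scaled to unit variance internally and coefficients
rescaled on output; there is no intercept because phase vectors are
mean-free. λ is chosen at the minimum of k-fold cross-validated error over
a geometric grid with warm starts (10 gene-level folds by default, seeded);
α defaults to 0.1 (mostly ridge, which groups redundant motif matrices),
and the window-radius scan uses α = 0 with identical fold seeds at every
radius, reporting the deviance ratio 1 − RSS/TSS. Motif co-occurrence on
binary presence matrices uses hypergeometric enrichment/depletion tails
(two-sided = 2·min(tails), capped at 1).

## Footprints

`wellington_footprints` scores a candidate footprint of size F with
shoulders of size S by the binomial lower tail of the forward-strand cuts
inside the footprint given the forward cuts in footprint + upstream
shoulder and success probability F/(F+S), times the analogous
reverse-strand/downstream term: score = −log10 p_fw − log10 p_rv, maximized
over F ∈ {11,13,…,25} and S ∈ {20,25,30,35}. Cut counts are integral;
window sums are rounded so the binomial arguments stay integers.
Significance is an empirical FDR from ≥ 100 circularly shuffled profiles
(per strand, seeded): FDR(s) = mean null positions reaching s per shuffle /
observed positions reaching s. Calls are selected best-first without
overlap. The footprint-size grid is a package choice (only the shoulder
grid is standard).

The occupancy mixture models motif-anchored per-base cut profiles (strands
summed, orientation-aligned) at one time point as a two-component
multinomial: unbound sites draw from a shared background q_x; bound sites
(weight π) from q_x multiplied by a depletion factor δ inside a protected
interval [left, right] and renormalized. EM estimates π, δ, q and per-site
posterior bound probabilities; the expected complete-data log-likelihood
depends on q only through the per-position column totals, which yields an
exact M-step for q via a one-dimensional Lagrangian fixed point, so the
observed log-likelihood is provably non-decreasing (asserted on every
fit). Boundaries are chosen by exhaustive search over a grid of (left,
right) pairs containing the motif midpoint. A footprint is rejected
(bound fraction reported as 0) when δ ≥ 0.9 or when the mixture fails to
beat the single-multinomial null by a BIC margin of ½·4·ln(n_sites) — the
δ rule alone accepts spurious low-occupancy components on flat Poisson
profiles. Both the per-site posterior and π are reported, since "bound
probability" can reasonably mean either. Temporal series are independent
fits per time point; the trajectory of protected-region width and bound
fraction is the package's readout of complex exchange (a tandem E-box
whose 3' dimer is unoccupied at trough time shows roughly half the peak
width).

## Synthetic data

The generator emulates the study design: 2 chromosomes of i.i.d. uniform
sequence, genes at regular spacing, DHSs assigned to active genes in three
distance classes (defaults 24/28/47% tss/proximal/distal), 7 time points
ZT2–ZT26, three marks. Gene-level log2 signals follow

    log2 y_g(t) = mesor_g + Re(Σ_f N_gf A_f e^{−iωt}) + N(0, noise_sd),

so truth activities propagate exactly through the model the inference
assumes; DNase and H3K27ac at a DHS cycle in phase with the owning gene.
Counts are Poisson with mean seq_depth · 2^(log2 level) (an optional
negative-binomial dispersion knob exists but defaults to Poisson — the
count noise model of pooled DNase libraries is not established). Defaults:
noise_sd 0.25 log2, seq_depth 500 cuts per site per time point, motif
library of eight canonical liver diurnal elements (E-box ZT8, D-box ZT12,
RRE ZT22, CREB ZT7, FOX ZT20, SREBP ZT19, HSF ZT16, GRE ZT10) with planted
consensus copies in disjoint 30-bp slots within ±250 bp of DHS centers.
The `ko` genotype zeroes the clock motifs (E-box, D-box, RRE) before signal
generation, mirroring an arrhythmic-clock animal under rhythmic feeding.

Features deliberately included because the analysis must cope with them:
per-(mark, time) library-size factors (log-normal, sd 0.2 log2) that the
normalization must remove; Pol II deposited at non-promoter DHSs attenuated
by 1.5 log2 (distal Pol II is real but weaker); a genome-wide DNase
background (0.1 cuts/kb/time). Features of real data it does not emulate:
mappability and GC bias, sequence-dependent DNase cleavage preference,
nucleosome positioning, cell-type mixtures, inter-animal variability, and
correlated noise across marks — so passing tests demonstrate correctness of
the inference under its own model assumptions, not robustness to those
artifacts.

Ground-truth bookkeeping: a DHS is flagged rhythmic when its true log2
peak-to-trough amplitude is ≥ 1.0 (2-fold, the typical median amplitude of
cycling accessibility); weaker nonzero oscillations are recorded but are
neither recovery targets nor false positives when called. Same-gene DHS
centers are kept ≥ 2.5 kb apart so that ±1 kb quantification windows never
overlap and truth labels stay attributable to single sites.

Per-base cut profiles for footprint work are drawn per site and time point:
each footprint element (protected interval + depletion) is bound with its
occupancy probability; bound profiles multiply the background by δ inside
the protected span and redistribute the removed mass onto ≤15-bp shoulders
so the expected total depth is occupancy-independent; counts are Poisson,
split evenly between strands. The tandem E-box helper plants
CACGTG-(A×6/7)-CACGTG with one element per CLOCK:BMAL1 dimer, so per-dimer
occupancy schedules reproduce the peak/trough footprint-width signature.

## Benchmarks and problem sizes

The test suite and acceptance script run everything at desk scale, chosen
so the whole suite completes in a few minutes on one CPU: calibration at
1000 null series / 2000 Fisher triples; activity recovery at 500 genes × 20
motifs (3 active, amplitudes 0.5–1.0, peaks ZT8/12/22, noise 0.25); the
window scan at 300 genes with regulatory DHSs out to 45 kb and decoy DHSs
at 60–85 kb, radii {10, 20, 50, 100} kb; mixture recovery at 200 sites of
depth 100 with truth (−10, +15, δ = 0.2, π = 0.6); tandem occupancies
(0.8, 0.8) at peak — P(both dimers bound) ≈ 0.65, the observed maximum
fraction of doubly-protected tandem sites — and (0.6, 0) at trough;
the end-to-end screen on a ~5-Mb genome with 200 DHSs of which ~50 cycle at
2–4-fold amplitudes. Headline counts from genome-scale liver data (tens of
thousands of DHSs, thousands of cycling sites) are not reproducible at
these sizes and are not targets; all checks are property-based against
generator truth or independent oracles (dense enumeration for the peak
caller, normal equations and the group soft-threshold closed form for the
elastic net, exact binomial/hypergeometric arithmetic, χ² quadrature).

## Known limitations

- Fisher's combination assumes mark independence; shared biological noise
  makes the combined p anti-conservative in real data.
- The mixture model fits one shared boundary pair per site set; when one
  sub-element is bound nearly always, EM absorbs it into the background and
  the fitted width covers only the variable part of the protection.
- The peak caller is a reconstruction; it honors the published parameters
  but not necessarily the original tool's edge cases.
- Harmonic regression at n = 7 has limited power near 2-fold amplitudes;
  sub-threshold rhythms are genuinely hard to call and the benchmarks
  treat them as neither hits nor false alarms.
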