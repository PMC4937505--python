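# Methods

This note documents the models, parameter choices and numerical conventions
behind `caspkit`, and what the synthetic-data generator does and does not
emulate.

## Experimental design being modelled

HeLa cells under tunicamycin-induced ER stress, sampled at 0, 4, 8, 24, 48
and 72 h. Three measurement layers share this time course: caspase substrate
profiling (CSP; immunoaffinity-enriched neo-C-terminal Asp peptides,
TMT6plex-labelled, one channel per time point), global protein profiling
(GPP; whole-lysate TMT), and RNA-seq. A second RNA-seq experiment contrasts
stress alone against stress plus the pan-caspase inhibitor z-VAD-FMK at 0,
8, 24 and 72 h with three biological replicates per condition. The channel →
time mapping (126 → 0 h … 131 → 72 h) is a configuration default, not a
measured fact.

## Reporter quantification

Theoretical TMT6plex reporter m/z values are computed at import time from
NIST isotope masses: the reporter cation is C8H16N+ (neutral composition
minus one electron), with channel shifts of one ¹⁵N (127), two ¹³C (128),
two ¹³C + ¹⁵N (129), four ¹³C (130) and four ¹³C + ¹⁵N (131). Extraction
takes the highest peak intensity within a ±20 ppm window around each
theoretical m/z (window computed on the theoretical mass, per the stated
rule); channels without a peak in window report 0. The combined-intensity
filter is strict (> 2000). Rollup: peptide = channel-wise PSM sum,
re-expressed as relative abundance to the maximal channel; protein =
unweighted mean of peptide relative-abundance vectors. Peptides shared
between accessions contribute to every match by default (a uniqueness-only
mode is a config flag); no isotopic-impurity correction is applied.
Channel-loading normalization (column-sum equalization) is available but off
by default, since whether the study normalized loadings is unstated.

## Target–decoy confidence

A Fisher linear discriminant is trained on PSM features (search score, delta
score, |ppm error|, missed cleavages, charge), decoys as the negative class;
a singular within-class scatter is ridge-regularized with a warning. The
FDR estimator is decoys/targets (concatenated-database convention). The
threshold scan keeps the most permissive cut whose estimate does not exceed
the level, with score ties kept inclusively and deterministic ordering.
Protein-level filtering (default 2%) scores each accession by its best
surviving peptide and repeats the decoy-counting rule at protein
granularity; a peptide-level estimate (unique-peptide collapse) is also
reported since the study quotes a peptide-level figure whose exact
construction is unstated.

## Digest model and cleavage sites

A valid captured peptide ends in the caspase P1 aspartate, starts at a
protease-consistent boundary (after K/R for trypsin, after F/W/Y/L for
chymotrypsin, or the protein N-terminus), and contains at most four internal
missed cleavages, counting K, R *and* D — the combined protease+caspase
rule. Sites are 1-based (accession, P1) coordinates; peptides sharing a P1
collapse into one site, digests are unioned, and multi-position matches are
kept but flagged ambiguous rather than discarded. Motif windows cover
P5..P1 + P1′..P6′ (11 positions, Schechter–Berger numbering), padded with a
gap symbol at protein termini; the probability matrix divides by non-padded
counts only, so the P1 column is a point mass on D by construction.
Known-site overlap uses exact-coordinate matching by default with
protein-level matching as an option, because legacy repositories do not
always carry exact coordinates.

## Fuzzy c-means

Trajectories are row-standardized (mean 0, SD 1 across the six time
points); constant rows cannot be standardized and are dropped with a
warning. Clustering alternates the Bezdek updates — centers
vᵢ = Σⱼ uᵢⱼᵐ xⱼ / Σⱼ uᵢⱼᵐ, memberships uᵢⱼ = 1 / Σₖ (dᵢⱼ/dₖⱼ)^(2/(m−1)) with
Euclidean d — until |ΔJ| < 10⁻⁹ or 1000 iterations, where
J = Σᵢⱼ uᵢⱼᵐ dᵢⱼ². A point coinciding with a center takes full membership
there (the m→ limit convention). Because the objective is non-convex, 10
random-membership starts are run and the best J kept; the objective history
is stored so monotonicity is checkable. Cluster counts are fixed by layer
(CSP 5, GPP 6, RNA 9) and the fuzzifier is m = 1.5; none are auto-selected.
Down-regulated protein clusters for the overlay restriction are identified
as clusters whose center correlates negatively with time rank.

## Regulatory-mode classification

Per-layer trend is the Pearson correlation of a trajectory with time-point
*rank* rather than raw hours — sampling is strongly non-uniform (24 h gaps
at the end) and rank is robust to that. Cutoffs default to trend_cut = 0.5
and r_cut = 0.5; the four target patterns are described qualitatively in the
source material, so these are artifact parameters chosen so idealized
monotone/flat trajectories classify correctly. A constant trajectory has
trend 0 (flat) by convention. The decision table is evaluated in order:
(transcript up, protein down, cleavage up) → caspase_degradation;
(up, up) → co_upregulated; (flat, down) → direct_caspase; (down, down) →
transcription_coupled; else ambiguous. The classification is invariant to
positive affine rescaling of any layer. The pooled substrate regression
(protein on transcript across all substrate × time observations of
standardized trajectories) reports Pearson r with least-squares slope and
intercept.

## Differential expression

RPKM = count / (length·10⁻³ × mapped reads·10⁻⁶). The precision-weight
construction follows the voom recipe: genes with zero counts everywhere are
removed; log₂-CPM with a 0.5 offset; an unweighted fit gives gene-wise
residual SDs; √SD is lowess-smoothed (span 0.5) against average log-count;
each observation's weight is the trend-predicted variance inverted at its
fitted count, clipped to configured bounds, with the trend floored at 10⁻⁴
against degenerate zero-variance regions. Library sizes are
composition-corrected by median-of-ratios scaling (genes expressed in all
samples), the standard guard when many genes move in one direction — without
it, strongly asymmetric planted effects bias every null gene's fold change.
Moderation follows the standard empirical-Bayes construction: the prior
(d₀, s₀²) is moment-matched to the log residual variances via the trigamma
inverse; posterior variances s̃² = (d₀s₀² + d·s²)/(d₀+d); moderated t on
d₀+d degrees of freedom. d₀ → ∞ collapses to a pooled-variance z statistic
and d₀ = 0 to the ordinary t (both exposed for testing). Significance uses
strict thresholds: BH-adjusted p < 0.05 and linear fold change > 2. The
inhibitor contrast is arm difference at matched time (default 72 h) under a
cell-means design; an interaction contrast is not fitted, as the matched-time
reading is the more direct one. Sample clustering applies a log₂(scaled
count + 1) variance-stabilizing transform by default (an Anscombe option
exists), takes the 500 most variable genes and runs Ward linkage on
Euclidean sample distances; the full dispersion-fit VST was deliberately
not reproduced since sample clustering is a qualitative readout.

## Competitive gene-set test

Gene-level moderated t statistics are converted to normal equivalents and
each set is compared against the rest of the genome with a two-sample t
(df = G−2) whose set-side variance is inflated by VIF = 1 + (m−1)ρ̄. ρ̄
defaults to 0.01 (the test's published default); it can be supplied (e.g.,
a known generative value in simulations) or estimated as the mean pairwise
correlation of member residual profiles. Sets smaller than 5 measured genes
are skipped. BH adjustment is applied across the tested collection. A TF is
called dual-regulated when its target set is significantly up-regulated
under caspase inhibition (adjusted p < 0.05, direction up) while its own
transcript's fold change stays below 2; TFs above 2-fold are reported but
excluded from calls. "Multiple target genes up" is operationalized as the
set-level test; a stringent per-gene reporting filter (adjusted p < 10⁻⁴,
FC > 2) is provided for volcano-style highlighting.

## Synthetic data: what it emulates, and what it does not

The generator plants ground truth for every stage. Proteins are uniform
random sequences (internal Asp at background frequency); target peptides are
genuine digest products of the emitted database; decoys are
sequence-reversed targets keeping the C-terminal Asp, with score features
from a lower-scoring distribution, and an optional fraction of target PSMs
carries decoy-like scores to benchmark realized FDR. Reporter intensities
are lognormal around archetype templates — five cleavage shapes (early,
post-24 h, post-72 h, two bimodal with a 48 h trough) and six protein shapes
including two down-regulated classes — standardization downstream removes
the scale. Counts are negative-binomial (Var = μ + φμ²) with φ = 0.02 by
default (biological CV ≈ 14%, typical of cultured cell-line replicates);
planted TF target sets are disjoint, up-regulated 4-fold only in the
inhibitor arm from 24 h on, and each dual TF's own transcript is planted
within a 1.25-fold band (the magnitude range of the reported exemplar TFs)
at a quantifiable baseline so its realized fold change stays below the
2-fold flatness bound. Transcript kinetic shapes of genes with planted
protein profiles are trend-matched to the protein shape with probability
0.8, emulating a predominantly co-regulated substrate pool. Regulatory
triads mix the four modes at (0.30, 0.20, 0.20, 0.30) for degradation /
co-up / direct / transcription-coupled, reflecting the reported
predominance of protein-down substrates over the flat-transcript pattern.

Not emulated: raw spectra beyond reporter-region peak lists, chromatographic
or search-engine artifacts (retention-time drift, co-isolation interference,
isotopic impurity), real protein homology and shared-peptide structure,
read-level RNA-seq (no GC/length bias, no multi-mapping), and real gene-set
overlap topology. Passing tests therefore demonstrate correctness of the
computational procedure under the stated noise models, not performance on
raw instrument data.

## Problem sizes and numerics

Default synthetic runs use 300 proteins, ~300 planted peptides / 1200 PSMs,
1500 genes and 20 TF sets — sizes chosen so a full run completes in seconds
while every stage remains statistically exercised; the acceptance script
uses 2000-gene expression simulations, 10 000-PSM FDR benchmarks and
600–1000 simulation replicates for calibration checks. All randomness flows
from a single root seed through fixed per-stage offsets, making runs
bit-reproducible; manifests record a config hash (scientific parameters
only) and per-file SHA-256 checksums. Floating-point conventions worth
noting: membership rows are normalized to sum to 1 within 10⁻⁹; motif
columns to 1 within 10⁻⁹; cluster label ties break to the lowest index;
FDR-threshold ties are kept inclusively.

## Known limitations

- Protein inference is by shared-peptide fan-out or uniqueness filtering
  only; no parsimony model.
- The discriminant is linear; a non-linear scorer would likely separate
  target/decoy features better on real data.
- The regulatory-mode caller uses 6 points per layer; its trend calls on
  flat trajectories carry the sampling noise of a 6-point correlation, which
  bounds attainable accuracy below 100% at realistic noise.
- camera-style ρ̄ estimation from few samples is noisy; the default 0.01 is
  a pragmatic floor, not an estimate.
- RPKM is retained for fidelity to the modelled workflow even though
  TPM-style quantities are now more common.
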