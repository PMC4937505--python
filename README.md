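# caspkit

Multi-omics kinetic profiling of caspase substrates during ER stress.

Prolonged endoplasmic-reticulum stress drives cells from the adaptive
unfolded protein response into caspase-dependent death. `caspkit` implements
the computational side of a systems-level study of that transition in a
single reusable pipeline: it quantifies caspase-cleaved neo-C-terminal
peptides and global protein profiles from TMT6plex proteomics, clusters
their 0–72 h kinetics, overlays them with RNA-seq transcript trajectories,
classifies each substrate's regulatory mode, and infers transcription
factors that caspases silence post-translationally. A first-class synthetic
data module generates every input with planted ground truth, so the whole
stack is testable at desk scale.

## What it computes

- **TMT6plex quantification** — per channel, the highest reporter-region
  peak within 20 ppm of the theoretical reporter m/z (126–131 series,
  computed from isotope masses); PSMs with combined reporter intensity
  ≤ 2000 are discarded; peptide abundances are PSM-level sums expressed
  relative to the maximal channel; protein abundances are unweighted means
  of peptide vectors.
- **Target–decoy confidence** — Fisher linear discriminant over score
  features (w ∝ S_w⁻¹(μ_target − μ_decoy)); PSMs thresholded at
  FDR = decoys/targets ≤ 5%; proteins filtered to 2% by best-peptide score.
- **Cleavage-site mapping** — every surviving peptide must be a valid
  trypsin/chymotrypsin + caspase digest product (C-terminal Asp = P1,
  protease-consistent N-terminal boundary, ≤ 4 internal missed K/R/D
  cleavages); sites are (accession, P1 position) coordinates with P5..P6′
  motif windows, residue-probability matrices and overlap counts against
  known-site repositories.
- **Kinetic clustering** — row-standardized 6-point trajectories clustered
  by fuzzy c-means (Bezdek updates, Euclidean distance, fuzzifier m = 1.5,
  best of 10 random starts), with c = 5 for cleavage peptides, 6 for
  proteins and 9 for transcripts; down-trending protein clusters drive the
  three-layer overlay.
- **Regulatory-mode classification** — per gene, pairwise Pearson
  correlations among cleavage/protein/transcript trajectories and rank-based
  trends feed a decision table: transcript↑ + protein↓ + cleavage↑ ⇒
  caspase-mediated degradation; transcript↑ + protein↑ ⇒ co-up-regulated;
  transcript flat + protein↓ ⇒ direct caspase effect; transcript↓ +
  protein↓ ⇒ transcription-coupled; otherwise ambiguous.
- **Differential expression** — RPKM; voom-style precision weights
  (log-CPM, lowess mean–variance trend, inverse-variance observation
  weights, composition-corrected library sizes) and empirical-Bayes
  moderated t (posterior variance s̃² = (d₀s₀² + d·s²)/(d₀+d)); BH-adjusted
  p with the adjusted p < 0.05, fold change > 2 significance rule; Ward
  clustering of samples on the 500 most variable variance-stabilized genes.
- **TF dual-regulation inference** — competitive gene-set test on moderated
  statistics with variance inflation factor VIF = 1 + (m−1)ρ̄ (ρ̄ = 0.01
  default), BH across sets; a TF is called dual-regulated when its target
  set is significantly up under caspase inhibition while its own transcript
  stays below a 2-fold change.

## Worked example

```bash
caspkit run-all --seed 7 -o demo_run
cat demo_run/report.md
```

prints (abridged):

```
- sites_planted: 286
- sites_mapped: 286
- sites_recovered_fraction: 1.0
- csp_cluster_ari: 1.0
- gpp_cluster_ari: 1.0
- tf_true_calls: 5
- tf_false_calls: 0
- de_target_sensitivity: 1.0
- protein_transcript_r: 0.6084363465288792
- mode_counts: {'ambiguous': 128, 'transcription_coupled': 98, ...}
```

Reading this: all 286 planted cleavage sites were mapped back to exact
(accession, P1) coordinates after FDR filtering; both kinetic layers were
clustered with perfect agreement to the planted archetypes (adjusted Rand
index 1.0); all 5 planted dual-regulated transcription factors were called
with no false positives; every planted 4-fold target gene passed the
adjusted p < 0.05 / FC > 2 filter; and pooled protein–transcript
standardized abundances correlate at r ≈ 0.61, reflecting the predominantly
co-regulated substrate pool the generator plants. The run directory also
holds the per-stage tables (`sites.tsv`, `cluster_report.tsv`,
`overlay.tsv`, `de_results.tsv`, `camera_results.tsv`, `tf_dual_calls.tsv`,
`regulatory_calls.tsv`) and a manifest with output checksums; re-running
with the same seed reproduces every file bit for bit.

Individual stages are exposed as verbs (`generate`, `quantify`, `cluster`,
`de`, `enrich`, `classify`, `report`) over the same run directory, and the
library modules (`caspkit.quantify`, `caspkit.cluster`, ...) can be used
directly on user-supplied TSV/FASTA/GMT inputs via `mode: user-data` in the
YAML config.

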