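# Methods

`dielomix` analyses a matched mRNA–protein time course sampled over a diel
(light:dark) cycle: four time points (T1 mid-day, T2 dusk, T3 pre-dawn, T4
lights-on), three biological replicates, with protein quantified label-free
at the peptide level over four technical replicates per biological sample.
This note describes each stage's model and assumptions, the defaults that
matter, and what the synthetic benchmark does and does not show.

## Proteomics preparation

Peptide log10 intensities are filtered before quantification:

* non-unique peptides (mapping to more than one protein) are excluded from
  abundance work;
* a peptide must be observed in at least ⌈50% × n datasets⌉ instrument
  datasets;
* a *variance filter* drops peptides whose variance, relative to a linear
  mean–variance trend fitted across peptides, exceeds the `variance_quantile`
  quantile of the residuals (default 0.95, i.e. the most erratic 5%;
  0 disables it). The mean–variance trend makes the rule scale-aware — raw
  variance filtering would preferentially remove high-abundance peptides.
* proteins left with a single peptide are removed (one peptide is not
  reproducible evidence for quantification).

Surviving columns are quantile normalized (each column's order statistics
replaced by the across-column means; with missing values columns are mapped
through a common 101-point quantile grid). Technical, then biological
replicates are averaged. Peptides roll up to proteins in the RRollup manner:
the peptide with the most observations (ties → highest median) anchors the
protein; every other peptide is shifted by the median of its paired
differences to the anchor, and the protein value per sample is the median of
the shifted peptides. The rollup is therefore exactly invariant to constant
per-peptide offsets (ionization efficiency) on non-anchor peptides; a
constant added to the anchor shifts the protein's absolute level, which is
irrelevant downstream because profiles are z-scored. Missing values are
excluded pairwise, never imputed.

Presence/absence calls are stricter than quantification: a protein is
"present" at a time point only if ≥ 2 of its unique peptides each satisfy
the 50%-of-datasets rule within that time point (the 50% rule can
alternatively be applied over all datasets; per-time-point is the default).
Progressive differential abundance walks the cycle pre-dawn onward (T3→T4,
T4→T1, T1→T2, T2→T3) with Welch t-tests on biological replicates at raw
p < 0.05, no multiple-testing correction — these are descriptive counts, not
inference.

## Correlation classes

Per-gene mRNA and protein four-point profiles are independently z-scored
(sample SD, n−1). For each circular delay k ∈ {0,1,2,3}, Pearson R is
computed between the mRNA profile and the protein profile shifted back by k.
The exclusive class is the smallest k with |R| > 0.75 (sign decides
correlated vs anti-correlated); otherwise the gene is "low" when
|R at delay 0| ≤ 0.1, else "unclassified". Circular shifts are the only
reading consistent with a delayed-by-3 class on four points, and they match
the periodicity of the diel cycle. The "low" rule reads an ambiguous
threshold statement as a band around zero; this is a documented choice.

Class-frequency significance uses a permutation null: each permutation
re-pairs protein profiles with mRNA profiles by shuffling gene labels
(10,000 permutations by default). The empirical p per class is two-sided on
the count with the add-one estimator, extremity measured as distance from
the null mean — so p ∈ (0, 1] and a maximal count gives 1/(1+n_perm).

For four-point profiles of i.i.d. Gaussian noise the null distribution of
Pearson r is uniform on [−1, 1], so the expected fraction with r > 0.75 at a
fixed delay is exactly 0.125 — a sharp calibration point the test suite
checks by Monte Carlo.

## Pathway concordance

Within each data type, Pearson correlations of across-time profiles are
computed for all gene pairs and ranked. Pathways are expanded to all
unordered gene pairs among their analyzed members, and a GSEA running sum is
walked down the ranked pair list: hits add |score|^p normalized by the hit
total, misses subtract 1/(N − N_hits); the enrichment score ES is the signed
maximum deviation. The weight exponent defaults to p = 1 (the widely used
weighted statistic); p = 0 gives the classic Kolmogorov–Smirnov form with
clean closed-form test cases. Concordance per pathway is

    CS_p = sign(ES_p^mRNA) · sign(ES_p^prot) · |ES_p^mRNA| · |ES_p^prot|

(numerically the product of the two scores, with sign(0) = 0), bounded by
[−1, 1] and symmetric. A pathway whose pairs are the entire ranked list is
rejected (the miss decrement is undefined).

## Consensus clustering

Gene rows of each data type are z-scored independently and concatenated
(gene × 8 matrix). For each candidate k, `n_iter` subsamples (default 80% of
genes, 100 iterations; 50 in the pipeline default) are clustered with an
in-repo PAM (k-medoids; deterministic greedy BUILD, best-improvement SWAP,
ties broken by lowest index, Euclidean distance). consensus(i,j) is the
fraction of co-clustered runs among runs where both genes were sampled.
Final labels cut an average-linkage dendrogram of (1 − consensus) at k; k is
selected by the consensus-CDF delta-area heuristic (k with the largest
relative gain in area under the consensus CDF) unless the user fixes it.
Per-cluster mean within-cluster pairwise Pearson correlation is reported as
the quality screen (≥ 0.75 marks a tight module). Cluster/pathway enrichment
is the hypergeometric upper tail with Bonferroni correction over all
performed tests.

## Sequence features

Computed per gene from CDS, UTRs, transcript and protein sequence
(~117 features): mono- and dinucleotide proportions, GC content, GC3,
lengths and relative CDS length, amino-acid and amino-acid-class proportions
(acidic DE, basic KRH, polar STNQCY, non-polar AVLIPFMWG, aromatic FWY,
aliphatic AVLI — configurable, since class conventions differ), hypothetical
isoelectric point (bisection on the Henderson–Hasselbalch net charge with a
classic pKa table: N-term 9.60, C-term 2.34, D 3.65, E 4.25, C 8.33,
Y 10.07, H 6.00, K 10.53, R 12.48), CAI, and minimum folding energy of the
5' UTR, 3' UTR and first 50 CDS nucleotides. Features of an absent UTR are
missing, never zero, and such genes are flagged incomplete and excluded from
model training.

**CAI.** Relative adaptiveness w(c) = count(c)/max synonymous count in the
reference set (0.5 pseudocount for unobserved codons); CAI is the geometric
mean of w over the gene's codons, excluding Met, Trp and stops (single-codon
families carry no information). The default reference is the aggregate codon
usage of the top decile of genes by mean mRNA abundance — the standard
highly-expressed-reference practice — and can be overridden.

**MFE.** The default folder is a Nussinov-style dynamic program over
non-crossing structures with per-pair energies GC = −3, AU = −2, GU = −1 and
hairpin loops of ≥ 3 unpaired bases. This is intentionally simple: it is
self-contained, exactly checkable against exhaustive enumeration (the test
suite verifies equality on all random sequences up to 12 nt), and monotone
in structure content, which is all the downstream correlation screens use.
It is *not* a thermodynamic model; any callable `str -> float` (e.g. an
RNAfold wrapper) can be plugged in via `compute_mfe(engine=...)`.

## Protein-abundance models

**Screens.** Per feature and time point: Spearman correlation with mRNA
abundance, and the first-order partial correlation with protein given mRNA
on rank-transformed values,

    r_fp·m = (r_fp − r_fm·r_pm) / sqrt((1 − r_fm²)(1 − r_pm²)).

Significance is a bootstrap re-shuffling null (default 10,000 draws; the
pipeline default is 1,000 for runtime) that permutes the gene labels of the
feature vector while keeping each gene's (mRNA, protein) tuple intact;
two-sided add-one p. One permutation set per time point is shared across
features (the null is feature-exchangeable). Collinear inputs (|r| = 1) are
an error naming the offending pair.

**MARS.** An in-repo additive (degree-1) multivariate adaptive regression
splines estimator in scikit-learn style. The forward pass greedily adds
reflected hinge pairs max(0, x−t)/max(0, t−x), evaluating candidate knots at
up to `n_knot_candidates` quantiles of each predictor's unique values
(128 standalone; 32 inside the per-time-point pipeline, where the knot grid
is not the bottleneck for fit quality). Knots are barred from the outermost
3 + log2(p/0.05) observations per predictor (Friedman's end-span rule);
without this guard the forward pass places single-point hinges that chase
individual outliers — which matters here because detecting outliers
(HPTR genes) is the point, and a model that memorizes them hides them. The
backward pass deletes terms along the RSS-optimal path and keeps the subset
minimizing GCV = (RSS/n)/(1 − enp/n)² with enp = M + penalty·(M−1)/2,
penalty 2 (the standard additive default). `max_terms` defaults to
min(21, 2·n_features + 1).

One MARS model is fitted per time point: response = time-point-averaged
protein log10 abundance; predictors = same-time-point mRNA abundance plus
all complete features. Constrained variants (mRNA only; mRNA + CAI) support
the comparison showing sequence features carry real predictive power. A
Gaussian/identity GLM (OLS via statsmodels, collinear columns dropped with a
warning) is the linear baseline. Evaluation reports resubstitution R² and
10-fold cross-validated R² (pooled out-of-fold 1 − RSS/TSS; folds stratified
by response decile with a seeded shuffle, which stabilizes R² at small n).

## HPTR detection and assessment

Residuals use the predicted − observed convention, so residuals above the
95% quantile mark over-estimated proteins. Per time-point model, genes
outside the [5%, 95%] residual quantiles are flagged; genes flagged in ≥ 2
models are HPTR, partitioned into HPTR+ (over-estimated) and HPTR−
(under-estimated) by dominant tail (ties excluded). Quantiles are computed
per model, not pooled.

Refitting without HPTR genes reports the per-time-point change in
cross-validated R², the mean relative improvement, and a sign-randomization
p-value on the gene-level paired difference of squared residuals; both the
original and refit models can additionally be scored on held-out genes never
used in training (an overlap with the training set is an error).

Feature-distribution differences between HPTR and non-HPTR genes use
two-sided Wilcoxon rank-sum tests with Bonferroni correction. Classifiers
(non-HPTR vs HPTR+, non-HPTR vs HPTR−) are elastic-net-regularized binomial
linear models (scikit-learn saga solver, mixing α = 0.5, strength chosen by
10-fold CV log loss) on data balanced with convex pseudo-data (CSD): random
convex combinations λa + (1−λ)b of minority pairs. Performance is the
balanced success rate BSR = (SR₁ + SR₂)/2 on out-of-fold predictions. The
permutation p for BSR permutes the *original* labels and re-runs balancing +
evaluation, so the null experiences the same CSD augmentation as the
observed statistic — balancing before cross-validation leaks pseudo-sample
parents across folds and lifts chance-level BSR above 0.5, so a null that
skips the balancing step would be anti-conservative; the matched null
absorbs the leakage (the test suite checks that uninformative features stay
non-significant while separable classes do not).

## Synthetic data: what it emulates, and what it does not

The generator plants every structure the downstream stages are supposed to
find, with the study's design (4 × 3 mRNA samples; 4 × 3 × 4 peptide-level
datasets):

* **Sequences.** CDS sampled codon-by-codon with a gene-specific bias b:
  with probability b the designated optimal codon, else uniform over the
  synonymous family (b = 1 gives CAI = 1 against any reference dominated by
  those codons). Protein length log-normal (median 200 aa), UTR lengths
  log-normal (median 80 nt — short UTRs typical of a compact picoeukaryote
  genome); a configurable fraction of UTRs is absent. Codon bias is drawn
  correlated with the expression baseline (Gaussian copula, ρ = 0.5), so CAI
  behaves like a translational-optimization proxy.
* **Diel profiles.** Two-harmonic periodic profiles. On four uniform samples
  a phase-shifted second harmonic aliases to sin(φ)·(−1)^t, so the sampled
  second harmonic is built directly as the alternating vector with amplitude
  ratio Uniform(0.6, 0.85) to the first. The ratio's range brackets 1/√2,
  where all spurious cross-shift correlations of the sampled profile are
  ≈ 1/3 — far from the 0.75 class threshold — making the four delay classes
  and the anti class identifiable by construction (a pure sinusoid would
  make delay-2 exactly equal anti-correlation). First-harmonic amplitudes
  Uniform(0.4, 0.9) log10 units reflect strong diel cycling.
* **Coupling.** Protein = 0.8 × (circularly shifted clean mRNA) + a hinge
  term in the gene's baseline (the planted non-linearity MARS should find) +
  planted feature effects (by default +0.5 per SD of CAI and +0.3 per SD of
  5'UTR MFE — a higher MFE means *less* structure, so the positive MFE
  coefficient encodes a structure *penalty*) + Gaussian noise (default SD
  0.1 log10 per data type).
* **HPTR genes.** A configurable fraction (default 10%) departs from the
  program: half follow a stable (arrhythmic) protein profile — the classic
  post-transcriptional signature of flat protein under cycling mRNA — and
  half keep the coupling with inverted feature effects; each gene carries a
  persistent offset (±, split evenly) that determines its residual tail.
  The default offset is 1.0 log10. `SimulationConfig.strong_hptr_regime`
  pins the strong-effect condition (offset 2.0 log10 = 100-fold, all-
  independent program, noise 0.15) under which the residual-quantile
  detector is expected to reach sensitivity ≥ 0.8 at precision ≥ 0.6: the
  q95 threshold self-adapts to the planted cluster's edge, so detection is
  governed by the offset relative to the within-cluster residual spread
  (≈ 0.55 log10 here), not by the offset alone.
* **Peptides.** 1–6 peptides per protein; each = protein replicate value +
  a fixed per-peptide offset (SD 0.3; the artifact RRollup removes) +
  technical noise; entries missing independently (default 5%); 5% of
  peptides mapped to a second protein.
* **Pathways.** Coherent sets = a seed gene plus its best-correlated peers
  among delay-0 genes (these should score positive concordance); random sets
  as negatives.

Not emulated: spectra or peptide-level identification error, chromatographic
artifacts, read-level RNA-Seq, burst-like transcription, shared-peptide
quantification ambiguity beyond the uniqueness flag, mRNA/protein
degradation kinetics, and any organism-specific feature distributions.
Passing tests therefore demonstrate that the *procedures* recover what they
are defined to recover under their stated conditions — not that the
biological effect sizes of any real organism are detectable at these sample
sizes.

## Problem sizes and numerical choices

The test suite and the acceptance script run on a single CPU in minutes; the
sizes were chosen as the smallest that leave the checked properties
comfortable: null calibration at 10,000 genes; delay-class recovery at 2,000
genes across seeds; partial-correlation sign recovery at 500 genes per
replicate; HPTR detection at 1,000 genes (median over seeds) with the
cross-validated refit at 400; consensus clustering at 120 genes. Permutation
and bootstrap defaults (10,000) are kept in the library; orchestrated runs
use smaller counts where only a screen is needed.

Tie-breaks are deterministic throughout (PAM lowest index, rollup anchor by
median, ranked pairs by pair id). Constant profiles are flagged and excluded
rather than z-scored. Quantile normalization is exact for complete
equal-length columns and grid-interpolated otherwise. All seeds flow from a
single integer through `numpy.random.SeedSequence((seed, stage))`, so every
stage is reproducible in isolation.

## Known limitations

* The simplified MFE engine ranks structure content; its absolute values are
  not free energies.
* The variance filter's mean–variance trend is linear; heavy-tailed peptide
  noise may warrant a robust fit.
* Consensus clustering is O(n_iter · k · n²) and is applied to the
  top-variance genes (pipeline default 500) on large inputs.
* The delayed-class reading assumes strict periodicity (circular shifts);
  phase drift across the cycle is not modelled.
* With 10% planted HPTR and 5% residual tails per model, detection operates
  near the quantile ceiling; weak offsets (< ~3× the residual spread) are
  structurally hard to separate regardless of implementation.
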