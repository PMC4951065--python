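# dielomix

Joint analysis of matched mRNA and protein expression over a diel
(light:dark) cycle, for systems biologists integrating a time-course
transcriptome with label-free LC-MS proteomics. The package covers the full
chain from peptide-level intensities to post-transcriptional regulation
candidates:

1. **Proteomics preparation** — peptide filtering (uniqueness, coverage,
   variance), quantile normalization, replicate averaging, and RRollup-style
   peptide→protein summarization; presence/absence and progressive
   adjacent-time-point differential summaries.
2. **Correlation classes** — per-gene Pearson R between z-scored mRNA and
   protein profiles at every circular delay k; genes classified as
   correlated / anti-correlated / delayed-k (|R| > 0.75) or low
   (|R| ≤ 0.1), with a gene-label permutation null for class frequencies.
3. **Pathway concordance** — gene-pair GSEA per data type over ranked
   pairwise profile correlations, scored per pathway p by

   CS_p = sign(ES_p^mRNA) · sign(ES_p^prot) · |ES_p^mRNA| · |ES_p^prot|

4. **Consensus clustering** — subsampled PAM (k-medoids) consensus on the
   concatenated row-z-scored mRNA+protein matrix, average-linkage cut,
   CDF delta-area k selection, hypergeometric cluster/pathway enrichment.
5. **Sequence features** — CAI, UTR/CDS folding energies (self-contained
   dynamic-programming folder, pluggable thermodynamic engine),
   composition, lengths, amino-acid classes, isoelectric point.
6. **Abundance models** — per-time-point MARS (in-repo, GCV-pruned hinge
   basis, scikit-learn estimator API) and GLM models predicting protein
   from mRNA + features; Spearman and bootstrap-tested partial-correlation
   feature screens; resubstitution and 10-fold cross-validated R².
7. **HPTR detection** — genes with residuals outside the [5%, 95%]
   quantiles in ≥ 2 time-point models are called hypothetically
   post-transcriptionally regulated (HPTR±); includes refit-without-HPTR
   evaluation, Wilcoxon feature tests, and convex-pseudo-data-balanced
   elastic-net classifiers scored by balanced success rate.

A first-class synthetic-data generator (`dielomix.synthdata`) emulates the
study design — 4 time points × 3 biological replicates, peptide-level
protein measurements with 4 technical replicates — with planted delay
classes, sequence-feature effects and HPTR genes, so every stage is testable
against known ground truth. See `docs/methods.md` for models, defaults and
assumptions.

## Worked example

```python
from dielomix import SimulationConfig, simulate_study
from dielomix.proteome_prep import filter_peptides, normalize_and_rollup
from dielomix.expression_compare import (
    zscore_profiles, assign_correlation_classes, permutation_class_test,
    pooled_correlations,
)

study = simulate_study(SimulationConfig(n_genes=400, seed=42))
peptides = filter_peptides(study.peptides)
protein = normalize_and_rollup(peptides, level="timepoint")
print(f"{protein.data.shape[0]} proteins quantified from "
      f"{len(peptides.abundance)} peptides")

shared = study.mrna.data.index.intersection(protein.data.index)
pooled = pooled_correlations(study.mrna.subset_genes(shared), protein)
print(f"pooled Spearman R_S = {pooled.pooled_rs:.3f}")

profiles = zscore_profiles(study.mrna.subset_genes(shared), protein)
classes = assign_correlation_classes(profiles)
print(classes["class"].value_counts().to_string())

null = permutation_class_test(profiles, n_perm=1000, seed=0)
print(f"correlated: observed {null.observed_counts['correlated']}, "
      f"null mean {null.null_mean['correlated']:.1f}, "
      f"p = {null.p_values['correlated']:.4g}")
```

prints

```
317 proteins quantified from 1219 peptides
pooled Spearman R_S = 0.407
class
correlated                  87
delayed-1-correlated        86
anti-correlated             59
delayed-2-correlated        43
delayed-3-correlated        26
delayed-2-anticorrelated     5
delayed-1-anticorrelated     4
unclassified                 4
delayed-3-anticorrelated     3
correlated: observed 87, null mean 45.0, p = 0.000999
```

Reading the numbers: 317 of 400 simulated proteins survive the two-peptide /
coverage / variance filters; the pooled mRNA–protein rank correlation is
moderate (0.407) even though most genes track their mRNA at *some* delay —
exactly the decoupling the class table resolves (87 in-phase, 86 delayed by
one time point, 59 anti-correlated). The permutation null expects only ~45
in-phase genes by chance, so the observed 87 is significant at the
granularity of 1000 permutations.

The same stages are available as a CLI for TSV/FASTA/GMT inputs:

```bash
dielomix simulate --outdir sim --seed 3 --n-genes 500
dielomix proteome --peptides sim/peptides.tsv --samples sim/peptide_samples.tsv --outdir prot
dielomix classes  --mrna sim/mrna.tsv --protein sim/protein.tsv --outdir cls --nperm 10000 --seed 1
dielomix concordance --mrna sim/mrna.tsv --protein sim/protein.tsv --gmt sim/pathways.gmt --out conc.tsv
dielomix run --config config.yaml          # full pipeline from YAML
```

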