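# replisig

Replication-strand asymmetry and replication-timing dependence of
mutational signatures.

DNA replication is intrinsically asymmetric: the leading and lagging
strands are synthesized by different polymerase machinery, and different
genomic regions replicate at different times in S phase. `replisig`
quantifies how individual mutational processes — represented as
mutational signatures — interact with this asymmetry in somatic mutation
catalogs from whole-genome-sequenced tumors (or synthetic cohorts with
planted ground truth).

The framework:

1. **Strand-resolved catalogs.** Somatic SNVs are classified into the 96
   pyrimidine-centric trinucleotide types and oriented to the replication
   template of the pyrimidine (leading vs lagging) using left/right
   replicating domain annotations derived from replication timing (slope
   of a 20-kbp window; windows flatter than 250 rtu/Mb are treated as
   peaks/valleys and dropped), giving per-sample 192-element count
   vectors.
2. **Strand-specific signature extraction.** NMF with multiplicative
   updates (Frobenius loss) on bootstrap-resampled catalogs; the rank K is
   chosen by minimizing `error_K / max(error) + (1 − stability_K)` subject
   to stability ≥ 0.8, where stability is the mean silhouette width of the
   clustered, pooled per-resample signatures. Low-exposure signatures
   (95th-percentile exposure / mean total exposure < 0.2) are removed.
   Extracted signatures are trinucleotide-renormalized to genome scale,
   clustered with an optional 96-element reference catalog (cosine
   distance, complete linkage) and condensed into **directional
   signatures**: 96 weights, each type flagged leading or lagging.
3. **Matching / inverse exposures.** For each sample, the stacked strand
   spectrum `m = [m_LD; m_LG]` is decomposed by non-negative least squares
   against the block design matrix

   ```
   S = [ S_LD  S_LG ]        e = [ e_matching ]
       [ S_LG  S_LD ] ,          [ e_inverse  ]
   ```

   where `S_LD`/`S_LG` hold the leading/lagging parts of each directional
   signature. `e_matching` is the exposure in the orientation the
   signature predicts, `e_inverse` the flipped orientation. Spurious
   exposures are suppressed by greedily pruning the least exposed
   signature while the residual stays within 0.5% of the full model, and
   optionally by a perturbation filter (1000 replicates, 5% Gaussian
   noise, 30% quartile-shift rule).
4. **Cohort statistics.** Per signature, the exact two-sided binomial sign
   test across samples (with total exposure ≥ 10) on the matching−inverse
   differences, and on per-sample slopes of exposure versus
   replication-timing quartile (Q1 early … Q4 late), with
   Benjamini-Hochberg correction across signatures; Tukey fences (k = 2)
   for outlier handling and origin-anchored plus/minus strand exposure
   profiles.

A synthetic-data module generates genomes, replication annotations,
signature libraries and mutation cohorts with known ground truth, so every
stage is testable without protected data.

## Worked example

Simulate a 40-sample cohort with three planted directional signatures and
a 3:1 matching:inverse strand-asymmetry ratio, decompose it against the
true signature library, and test the cohort-level asymmetry:

```python
import replisig as rs

truth = rs.make_truth(n_samples=40, n_signatures=3, seed=7, asymmetry_ratio=3.0)
catalog = rs.simulate_catalogs(truth, mutations_per_sample=10_000, seed=8)
table = rs.ExposureDecomposer(signatures=truth.signatures).fit().transform(catalog)
summary = rs.cohort_asymmetry(table, min_exposure=10)
print(summary[["signature", "n_exposed", "median_difference", "pct_matching", "q"]]
      .to_string(index=False, float_format=lambda x: f"{x:.3g}"))
```

```
signature  n_exposed  median_difference  pct_matching        q
planted_0         40           1.62e+03           100 1.82e-12
planted_1         40           1.25e+03           100 1.82e-12
planted_2         40           1.49e+03           100 1.82e-12
```

All 40 samples are exposed to each signature; the median matching−inverse
difference is strongly positive (≈1.2–1.6 thousand mutations of each
sample sit in the predicted orientation beyond the flipped one), every
sample has matching > inverse, and the BH-corrected sign-test q-values are
≈2e−12 — the planted asymmetry is recovered. With `asymmetry_ratio=1.0`
the same pipeline returns q ≈ 1 for all signatures.

The same analysis runs end to end from the shell:

```bash
replisig full --config config.yaml     # simulate -> catalog -> extract ->
                                       # decompose -> stats, with manifest
```

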