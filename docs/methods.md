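# Methods

## Model and rationale

A mutational signature is a probability vector over the 96 contextual
substitution types (pyrimidine-centric substitution × 5′ base × 3′ base,
COSMIC ordering). Because the two strands of the replication fork are
synthesized differently, a mutagenic process may deposit a given
pyrimidine mutation preferentially when that pyrimidine lies on the
leading- or lagging-strand template. `replisig` models this by working in
a 192-element space — each of the 96 types split by template strand — and
by condensing extracted strand-specific signatures into *directional
signatures*: 96 non-negative weights summing to one, each type carrying a
leading/lagging flag.

### Strand orientation

Replication direction is annotated per genomic region as *left*- or
*right*-replicating. In a left-replicating region the fork moves
leftward along the reference, so the reference (plus/Watson) strand
serves as the leading-strand template; in a right-replicating region the
complementary strand does. A pyrimidine mutation observed on the plus
strand in a left-replicating region is therefore a leading-template
event; the other three combinations follow by symmetry. Flipping every
domain direction swaps the two 96-element blocks of a catalog exactly
(this identity is asserted in the tests).

### Replication timing dialect

Timing is carried in abstract rtu (replication timing units). The
direction-from-slope rule (negative window slope → left-replicating,
positive → right) is self-consistent with an orientation in which larger
rtu means *later* replication: an origin is a local timing minimum and
timing rises along the fork's path. That orientation is the package
default; timing quartiles Q1 (earliest) … Q4 (latest) therefore take Q1
from the lowest timings. Datasets whose scores are larger-is-earlier
(common for raw Repli-seq) are handled by `higher_rtu_is_earlier=True`
for quartile assignment and `invert_direction=True` for slope
classification. Slopes are ordinary least squares of bin-midpoint timing
versus position within each fixed-width window; windows with fewer than
two profile bins are dropped, and adjacent same-direction windows are not
merged (each window is one domain). No smoothing is applied before the
slope fit.

### Exposure decomposition

Directional signatures split into disjoint leading parts `S_LD` and
lagging parts `S_LG` (96 × N each). Exposures solve

    min_{e ≥ 0} ‖ m − S e ‖₂ ,  S = [[S_LD, S_LG], [S_LG, S_LD]],
    m = [m_LD; m_LG],            e = [e_matching; e_inverse],

via scipy's NNLS. The matching/inverse split is identifiable because the
two orientations of one signature occupy complementary rows (their
columns are orthogonal). Swapping `m_LD` and `m_LG` swaps `e_matching`
and `e_inverse` exactly. The per-sample asymmetry statistic is the
difference `e_matching − e_inverse` (primary) or the log2 fold change
with a pseudo-exposure ε = 1 (exposures are in mutation-count-like
units).

Pruning removes the least exposed signature (matching + inverse), one per
iteration without backtracking, while the refitted residual does not
exceed the *original full-model* residual by more than the relative
tolerance (default 0.5%). The alternative reading — tolerance relative to
the previous iteration's residual — compounds and is not used; the choice
is configurable. The perturbation filter adds per-entry Gaussian noise
(sd = 5% of the entry, default 1000 replicates, negatives clamped to 0),
refits, and flags a signature unstable when its exposure quartiles move
by ≥30% relative to the unperturbed exposure x ((q75−x)/x ≥ 0.3 or
(x−q25)/x ≥ 0.3). For x = 0 the relative rule is undefined; the signature
is then flagged only if some perturbed exposure exceeds an absolute floor
(default 10, matching the minimal-exposure threshold). Exposures are
recomputed over the surviving signatures.

### Extraction and model selection

NMF uses multiplicative updates under the Frobenius objective,
implemented in-package so the per-iteration monotone decrease of the
reconstruction error can be asserted on every run and per-resample
factors are available for stability pooling (sklearn's `solver="mu"` NMF
serves as an independent quality cross-check in the tests). Defaults:
best of 10 random restarts per resample, 100 multinomial bootstrap
resamples of each sample's counts, ≤10,000 iterations, relative tolerance
1e−9. Pooled per-resample signatures are partitioned into K clusters
(cosine distance, complete linkage); stability_K is the mean silhouette
width of that partition, error_K the mean Frobenius error, and the rank
minimizes `error_K/max(error) + (1 − stability_K)` among ranks with
stability ≥ 0.8 (ties to the smaller K; if none qualifies, the
max-stability rank is returned flagged). Signatures whose 95th-percentile
exposure divided by the mean per-sample total exposure is strictly below
0.2 are removed and exposures refit.

Extracted strand signatures are renormalized by the strand-specific
trinucleotide counts of the analyzed regions and rescaled by whole-genome
counts, making them comparable with genome-based reference signatures.
Reference signatures enter the pooled clustering duplicated equally on
both strand halves; the tree is cut at 27 clusters by default (reduced to
the pool size when fewer signatures are pooled), the cut precedes any
declarative override-table reassignment, and a cluster containing
reference members is represented by the alphabetically first reference in
its original 96-element form, a purely novel cluster by the mean of its
members' leading/lagging averages. Direction flags per type follow the
summed leading-versus-lagging evidence across the cluster's strand
members; types with evidence mass below 0.5% of the total, or exactly
tied, inherit the majority direction of the clear types in their
substitution group (then the overall majority). Clusters with only
reference members get all-leading flags and a `no-evidence` marker.

### Cohort statistics

The sign test is the exact binomial test: zeros discarded, p = twice the
smaller tail of Binomial(n, ½), capped at 1 (the doubling convention is
part of the contract; scipy's `binomtest` uses a different two-sided
rule). Benjamini-Hochberg is the standard step-up, applied separately
within each metric family (asymmetry; timing trend), with unexposed
signatures excluded as NA. "Sufficient exposure" means matching + inverse
≥ 10 (the sum, not the maximum — configurable). The timing trend fits an
OLS line per sample of exposure versus quartile index 1–4 (a mean-timing
predictor is available); the headline p-value is the sign test on
per-sample total-exposure slopes, with matching and inverse medians
reported separately. Numerically-zero slopes (|slope| < 1e−9 × scale) are
snapped to exactly zero so constant samples drop out of the sign test.
Tukey fences use linear-interpolation (type-7) quantiles, k = 2; the
median asymmetry difference is computed after outlier removal when a
fence is requested (off by default). Origin/transition profiles
reattribute per-bin matching/inverse exposures to the plus and minus
reference strands via each bin's replication direction and the
signature's dominant flag, then report across-sample mean ± SE per bin
(SE is NA for a single sample; empty bins are absent, not zero).

## Synthetic data

The generator is the package's study stand-in for protected tumor
cohorts. It emulates: an i.i.d. (optionally first-order Markov, for CpG
enrichment) random genome at GC 0.41; evenly spaced origins (default one
per 1 Mbp) with a triangular timing profile and alternating left/right
20-kbp domains; well-separated directional signatures with
disjoint-support weights and per-substitution-group flags; Dirichlet
per-sample exposures; Poisson totals (default 10,000 mutations/sample, 40
samples); a planted matching:inverse asymmetry ratio (default 3:1, the
power condition; 1:1 is the null); and per-quartile rate multipliers
(default 1, 1.3, 1.6, 2 — the roughly twofold early-to-late increase seen
in tumors). Mutations are placed by sampling genomic sites compatible
with the drawn strand-resolved channel (site-conditional placement), so
trinucleotide normalization is genuinely exercised; sites may repeat, and
channels with no compatible site are resampled within the signature and
logged. A counts-level generator (`simulate_catalogs`) skips placement
for statistics-calibration runs. All randomness flows from one seeded
generator and the serialized ground truth accompanies every simulated
run.

What the generator does *not* emulate: real human sequence composition
and repeat structure, mappability artifacts, transcription-strand
effects, tumor purity, sequencing error, inter-signature correlation of
exposures, or realistic COSMIC signature shapes. Passing tests therefore
demonstrate correctness of the algorithms under the stated generative
model, not biological conclusions about real cohorts.

## Problem sizes and numerical choices

The test suite and the acceptance script run desk-scale versions of the
analysis chosen as representative: 40-sample cohorts at 10,000
mutations/sample for exposure recovery, power (3:1 ratio, 20 seeds) and
null calibration (1:1, 20 seeds); 25-sample cohorts at 8,000
mutations/sample with 8 bootstrap resamples and ranks 2–4 for NMF rank
selection (5 seeds); 1–2 Mbp single-chromosome genomes for
placement-level round trips; and an 8-sample end-to-end pipeline run.
The NNLS oracle is a multilevel dense grid search on the quadratic
objective (up to 3 signatures, i.e. 6 exposure dimensions), refined six
times around the incumbent; agreement is required within the final grid
resolution. Degenerate inputs are defined throughout: zero spectra give
zero exposures and prune to nothing, all-zero sign-test inputs return
p = 1 with a warning, zero trinucleotide divisors raise unless the
pseudocount policy is selected (silent imputation would hide annotation
bugs), and identical timings fall back to positional rank with a
warning.

## Known limitations

- Per-cancer-type extraction is supported mechanically (run the estimator
  per cohort) but the synthetic studies are single-cohort.
- The robustness filter refits once over the surviving signatures; it
  does not iterate the instability test.
- Reference-cluster representatives use the reference as-is; no
  re-weighting toward the extracted members.
- Plotting of the summary panels is not included; all plotted quantities
  are emitted as TSV.
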