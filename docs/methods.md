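# Methods

## Setting

One FACS-dispensed well = one sample = one centroid MS1 spectrum. The
pipeline annotates lipids at sum-composition level only (head-group class
plus total acyl carbons:double bonds, e.g. PC 34:1); fragmentation-based
chain assignment is out of scope because single-cell signal intensities do
not support clean MS2 spectra. Missing values mean "below the lower limit of
detection" and are never encoded as zero; zero intensity is a valid
measurement.

## Signal model and matching

For a target at mass m, the closest peak within the ±10 ppm window is the
candidate signal; deviation is reported unsigned,
`|m_obs − m| / m × 10⁶`. Ties on deviation go to the higher-intensity peak,
then the lower m/z (favouring signal over noise, deterministically). The
candidate search for detection uses the same window as the deviation filter;
blank assessment deliberately searches *globally* so that the distance from
a target to the nearest background peak in an empty well can be reported on
its natural (tens-to-hundreds of ppm) scale.

**Signal-to-noise.** No standard estimator exists for centroid direct-
infusion data, so S/N is defined as peak intensity over the median intensity
of the other peaks within ±1 Da (`snr_window_da`). With no neighbours the
fallback is the 5th percentile of the remaining peak intensities; with no
other peaks at all, S/N is +∞. The estimator is robust, deterministic and
needs no profile-mode data. The detection rule is strict: S/N must *exceed*
1.5, so a peak at exactly 1.5 fails.

## Sample-level QC

Exclusion order is fixed: failed wells first, then doublets among the
survivors.

*Failed wells.* A single-cell well fails only when **neither** marker lipid
(defaults PC 34:1 and PC 36:2, the two most abundant species) is detected.
Blanks, pooled QCs and curve wells are never classified as failed cells.

*Doublets.* On raw intensities — total-signal normalization would erase the
doubling signature — a well is excluded when ≥ 80% (`doublet_lipid_frac`)
of its *detected* lipids exceed the per-lipid reference mean by more than
2.5 SD (`doublet_sd_multiplier`). The 80% denominator counts only the
well's detected lipids: missing values cannot testify either way. The
reference population is the passing single-cell wells of the same physical
plate (experiment × plate), because raw intensities carry plate batch
effects and cross-plate pooling would inflate the SDs; global pooling is
available by flag.

The reference is made **self-consistent**: wells flagged as doublets are
removed from the reference and the statistics recomputed until the flagged
set stabilises (at most 10 iterations; refinement stops rather than shrink
the reference below 3 wells). Rationale: with ~5% doublets at 2× intensity,
a single-pass reference absorbs the doublets into its own mean and SD, and
plates that randomly receive several doublets raise their cutoff so far that
most of them escape. With refinement the cutoff converges to the clean-cell
distribution and recovery is near-perfect. Single-pass behaviour remains
available (`refine_reference=False`). Monotonicity (raising the SD
multiplier never flags more wells) is enforced by property test rather than
proof.

## Lipid-level QC and tiers

Per experiment, four filters, all of which must pass:
median deviation of detected matches ≤ 10 ppm; median S/N > 1.5 (medians
rather than means for robustness; means available by flag); Pearson r > 0.5
between intensity and cell count in multi-cell "standard curve" wells
(pairwise-dropping missing values, not evaluable — and failing — with fewer
than 3 paired points or a constant vector); and detection in at least 5% of
passing single cells. The 5% is **inclusive** (≥): an entry at exactly 5.0%
passes, which the bundled reference table requires. The source material
states 5% in one place and 10% in another; 5% is the default and the
threshold is configurable.

Tiers across experiments: level 1 = passed every experiment, level 3 =
exactly one, level 2 = anything between (with three experiments: exactly
two). Lipids passing zero experiments are dropped with a count. The bundled
37 × 3 detection-percentage table reproduces the published level-1 panel
(37 lipids: 25 PC / 9 PE / 3 SM) under this rule.

## Normalization and diagnostics

Total-signal normalization divides each sample's detected values by their
sum (missing stays missing), giving unit-sum compositions. It is idempotent,
invariant to per-sample rescaling — which is precisely why it controls for
cell size and removes multiplicative plate batch effects — and it is the
only batch correction applied (no location/scale regression). The
denominator is the sum over detected panel lipids, not total ion current:
normalization operates on processed lipid data.

Batch checking runs a one-way ANOVA (Kruskal–Wallis by flag) per lipid on
the pooled-QC wells across plates, on raw and on normalized values; a lipid
whose raw p < 0.05 becomes ≥ 0.05 after normalization is flagged "batch
effect removed". Degenerate inputs (identical values) map to p = 1 rather
than a numerical failure. The injection-order check computes principal
components of the normalized profiles — missing values imputed as half the
per-lipid observed minimum, a below-LLOD surrogate — and reports the
Spearman correlation of the first two coordinates with injection order,
with permutation p-values (999 permutations, seeded).

## Group statistics

The genotype contrast fits a Gaussian linear model of log-transformed
unit-sum abundance on the group indicator via OLS; the two-sided Wald test
on the coefficient uses the t reference, so with a single binary covariate
it is exactly the equal-variance two-sample t test — which both makes the
closed-form oracle check exact and keeps the null calibration honest at
small n (verified: type-I error within [3.5%, 6.5%] at nominal 5% over
1000 replicates). Fold changes are ratios of natural-scale group means.
Raw p-values are the primary decision quantity (threshold 0.05);
Benjamini–Hochberg q-values are reported alongside. Missing values are
pairwise-deleted: below-LLOD observations are informative but unquantified,
a documented limitation. Replicate adjustment is deliberately not included
by default; the stratification rule and thresholds are recorded in every
output.

Stratification by a lipid (default PC 36:2) is a within-genotype median
split on normalized abundance, ties to the low stratum — balanced strata
with no free parameter. Consequence: when the underlying mixture is not
50/50, the median split misassigns the mass between the median and the
mixture weight *by construction*; the mixture-recovery test therefore runs
at a balanced mixture. The PC/PE ratio is the sum of detected PC values
over the sum of detected PE values; numerator and denominator share the
sample's normalization divisor, so the ratio is invariant to normalization.

## Synthetic data generator

Per single-cell well, each lipid's signal intensity is

    base_abundance × size_factor × plate_factor × genotype_factor × exp(N(0, σ_tech))

with the peak placed at the target m/z perturbed by N(0, σ_ppm) ppm.
Key defaults and why:

| parameter | default | meaning |
|---|---|---|
| `n_plates`, `wells_per_plate` | 7, 96 | the plate design the pipeline targets |
| `qc_per_plate` | 6 | pooled-QC wells per plate |
| `blank_fraction` | 0.10 | extraction blanks among non-QC wells |
| `failed_fraction`, `doublet_fraction` | 0.08, 0.05 | mis-dispensed wells |
| `cell_size_cv` | 0.08 | CV of the lognormal per-cell size factor |
| `abundance_noise_sd` | 0.04 | log-SD of per-signal technical noise |
| `ppm_jitter_sd` | 2.0 ppm | mass error of real signals (mean \|dev\| ≈ 1.6 ppm) |
| `noise_peak_density` | 2.0 /Da | Poisson background peaks, exponential intensities |
| `plate_batch_effect_sd` | 0.30 | multiplicative plate factor, log scale |
| `genotype_effect` | {PC 36:2: 0.40} | low-mode multiplier in the mutant group |
| `bimodality_fraction` | 0.60 | mutant cells drawn from the low mode |
| `abundance_distribution_shape` | 1.0 | panel spans a 100× log-spaced abundance range |

Base abundances are log-spaced across the ranked panel (the abundance
distribution of detectable lipids is strongly non-linear), with the two
marker lipids placed at the top. Doublets draw their size factor from twice
the single-cell distribution, raising all of a well's signals together;
failed wells omit exactly the two marker lipids, which specifically
exercises the "neither marker" rule. Blanks carry background peaks only.
QC pools are an average cell (no size factor, no genotype) with technical
noise. Curve wells scale linearly with cell count before noise. All
randomness flows from the single config seed (`numpy` `SeedSequence`; the
curve generator uses a spawned child so it does not perturb the main
experiment draw); a fixed seed reproduces output bit-for-bit.

**Why the tight size distribution.** The 2.5-SD/80% doublet rule presumes
that a doubling stands far outside normal cell-to-cell variation. Working
the inequality with 5% doublets contaminating the reference shows the rule
reaches sensitivity ≥ 0.9 only when the cell-size CV is ≲ 0.1 and technical
log-SD ≲ 0.05; the defaults (0.08, 0.04) represent a tightly FACS-gated,
single-cell-type population, which is the regime the rule is designed for.
This is a real limitation of the rule, not of the implementation: on a
population with broad size variation (CV ≳ 0.2) the doubling signature
drowns in size scatter and sensitivity degrades sharply.

**What the generator does not emulate.** Isotope envelopes, adducts and
in-source fragments; correlated (structured) chemical noise; intensity-
dependent mass error; LLOD censoring as a hard threshold (weak lipids go
missing through the S/N filter instead, so missingness is less structured
than in real data); drift with injection order (none by default). Passing
recovery tests on this generator therefore shows the pipeline implements
its rules correctly under the stated statistical structure — not that the
rules are optimal for any particular instrument.

## Problem sizes and numerical choices

The test suite and acceptance script run simulations at the default 7 × 96
design (one or two experiments, ~700–1350 wells), 20-seed replication for
the batch check with 6 QCs on each of 7 plates, and 1000 replicates for the
null calibration and for each brute-force oracle comparison. Unit sums hold
to 1e-9 (achieved ~1e-16); idempotence to 1e-12. CSV floats are written via
`repr` and read with round-trip precision, so matrices and manifests
reproduce byte-identically under a fixed seed. mzML support is a minimal
MS1-centroid adapter (64-bit float, base64; zlib accepted on read);
peak-list CSV is the canonical format.

## Known limitations

- Sum-composition annotation only; no adduct disambiguation or isotope
  handling.
- The S/N estimator is implementation-defined (the field has no standard
  for centroid single-cell data); alternatives are configurable.
- Doublet-rule sensitivity depends strongly on the cell-size CV (above).
- Pairwise deletion of missing values in group tests can bias contrasts
  when missingness tracks abundance.
- The median-split stratifier cannot recover an unbalanced mixture's
  component labels beyond the 50% mark; a mixture-model split would be the
  extension.
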