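# Methods

## Design and data model

The experimental design the package analyzes is a cartilage explant
culture: 3 biological replicates (animals), 8 treatment arms composed of
three binary exposures — impact injury (I), inflammatory cytokines (C),
dexamethasone (D) — giving N, I, C, IC, D, ID, CD, ICD, and culture
medium sampled on days 4, 8, 12, 16 and 20. A record is a label-free
summed peak-area intensity for one (protein, animal, treatment, day), or
an explicit missing value. The canonical representation is long (tidy);
wide matrices are in-memory views, so missingness is always explicit per
record. An abundance of exactly 0 in an input file is treated as missing
with a logged warning: label-free intensities are positive, and zeros
are export artifacts.

Seven canonical contrasts are tested: C|N, IC|N, I|N (disease arms vs
control) and D|N, ID|I, CD|C, ICD|IC (each Dex arm vs its matched
non-Dex arm).

## Preprocessing

The chain is fixed in this order and is idempotent on its own output:

1. **All-replicates filter** — keep proteins with ≥ 1 quantified record
   in every animal.
2. **Coverage filter** — keep proteins quantified in ≥ `min_frac`
   (default 5%) of the samples present in the design (120 in the full
   design), with ceiling rounding (ceil(0.05·120) = 6), the conservative
   choice. Whether the source analysis applied this before or after the
   all-replicates filter is not documented; this order is fixed here and
   echoed in the run manifest.
3. **Presence mask** — per (protein, animal, treatment), the count of
   non-missing days, recorded *before* imputation; imputed records never
   count as "present".
4. **Half-minimum imputation** — each missing value is replaced by half
   the protein's smallest observed abundance, globally across all
   samples ("for each protein" read in its plain sense). This is the
   standard treatment of intensities assumed missing because they fell
   below detection.
5. **Summation** — per (protein, animal, treatment), raw-scale abundance
   is summed over the five days and log2-transformed; contrasts are
   tested on this summed matrix. The per-sample log2 table is used only
   for PCA.

## Moderated within-animal contrasts

A contrast reduces to a one-sample problem on the three within-animal
log2 ratios of summed abundance (d_g = 2 residual df per protein). The
design matrix behind the source analysis is not documented; the
one-sample moderated t on within-animal ratios is the simplest model
consistent with a paired n = 3 design, and is what this package fixes.

Per-protein variances s² are shrunk toward a prior (d0, s0²) fitted per
contrast by method of moments on log s²: with
e = log s² − ψ(d_g/2) + log(d_g/2), the model implies
E[e] = log s0² + ψ(d0/2) − log(d0/2) and
Var[e] = ψ′(d_g/2) + ψ′(d0/2). The excess of the empirical spread of e
over the sampling term ψ′(d_g/2) identifies d0 via Newton inversion of
the trigamma function; no excess yields the complete-shrinkage branch
d0 = ∞ with s0² = exp(mean e). The posterior variance is
s̃² = (d0·s0² + d_g·s²)/(d0 + d_g), the statistic
t = mean/√(s̃²/n) is referred to t(d0 + d_g) (standard normal when
d0 = ∞), and p-values are two-sided with direction reported separately.
The test suite cross-checks the fit and the statistics against the
reference empirical-Bayes implementation in R (limma); they agree to
machine precision.

Numerical choices: variances of exactly 0 (possible when imputation
makes all three ratios identical) are floored at 1e-8 inside the
log-moment fit and shrunk normally; one prior is fitted per contrast
rather than globally, because contrasts have different variance
structures and per-contrast fits are self-contained. Benjamini–Hochberg
step-up adjustment is applied within each contrast.

## PCA and heatmap ordering

PCA treats samples as observations and proteins as variables (60 samples
× retained proteins for the non-Dex core N/I/C/IC), standardizes each
variable (SD with denominator n − 1) and decomposes by SVD; at most
min(n − 1, p) components are kept and their percent variances sum
to 100. Zero-variance variables are dropped with a warning before
decomposition.

Heatmap ordering is agglomerative clustering on Euclidean distances of
the z-scored summed matrix over the six conditions N, C, IC, D, CD, ICD;
Ward linkage is used because it recovers compact response-profile
classes most reliably on standardized profiles. The leaf order and the
linkage matrix are returned so callers can cut the tree.

## Response grouping

A protein enters a group only if (a) it is significant vs control in
C|N and/or IC|N and (b) it passes the presence rule: some treatment has
≥ 3 observed timepoints in *every* animal, evaluated on the
pre-imputation mask (this guards the grouping against imputation
artifacts). Rules, with sig/direction taken from the chosen p-value
(raw by default, adjusted optional — both thresholds appear in the
source analysis, raw for grouping and FDR for the differential counts,
so both are exposed):

- **Group III** — significant increase in IC|N (with or without C|N);
  takes precedence over Group II ("C alone").
- **Group II** — significant increase in C|N with IC|N not significant.
- **Group I** — significant decrease in C|N and/or IC|N, with no
  significant increase in either.
- Opposite significant directions across the two contrasts are
  conflicting: the protein is left ungrouped and logged.

Dex calls are made per contrast (increase/decrease when significant with
that sign, else no_change). The consistency verdict uses the three
contrasts D|N, CD|C, ICD|IC (all three agreeing, including
all-no_change); ID|I is computed and reported but excluded from the
verdict, matching how the published consistent-Dex column is defined.
Summary percentages are reported to the nearest integer, with one
decimal below 10%.

## Bootstrap localization enrichment

For a group of k proteins against a background set (an explicit input —
typically the differential proteins; never hard-coded), the observed
proportion annotated to a category is compared with proportions of
10,000 resamples of size k drawn from the background *with replacement*.
The add-one estimator p = (1 + #{resamples ≥ observed})/(n_boot + 1)
(mirrored for the lower tail; the reported tail follows the direction of
departure, both tails are returned) can never be 0; its resolution at
the default repeats is 1/10,001 ≈ 0.0001. Proteins annotated "both"
count toward both categories; "unknown" counts toward neither and its
background share is reported separately — the published background
percentages (42% extracellular, 47% intracellular) do not sum to 100%,
implying exactly such a third stratum.

The calibration suite checks that upper-tail p-values are uniform for
random groups. Because the tie-inclusive add-one estimator is discretely
conservative with bias of order 1/(2√(π·k·p·q)), the null check uses a
group of 400 from a background of 20,000, where that bias (and the
finite-population correction of drawing the group without replacement)
is negligible against the Kolmogorov–Smirnov threshold.

## Synthetic-data generator

The generator exists so that every downstream stage can be tested
against planted ground truth. The latent log2 intensity of protein p,
animal a, treatment t, day d is

x = μ_p + α_{p,a} + τ_p(t) + β·(d − 12) + ε,

with μ_p ~ N(baseline_log2_mean, baseline_log2_sd²), animal offsets
α ~ N(0, animal_sd²), residual ε ~ N(0, residual_sd²), and τ_p(t) the
planted response: Group I proteins shift −effect under any
cytokine-containing arm, Group II only under cytokines without injury,
Group III under any cytokine-containing arm, null proteins not at all.
A configurable fraction of Group III (default 1/3, mirroring the
published 31/92) is Dex-rescued: in the matching Dex arm the cytokine
shift is reduced by `dex_rescue_fraction` (default 1, complete rescue).
An optional small set of "CTGF-like" null proteins (default 0) carries a
constant shift in every Dex arm. Records are censored (missing) with
probability logistic(missing_steepness·(LOD − x)), LOD being the
`lod_quantile` quantile of the realized latent marginal; emitted
abundances are 2^x. Everything is driven by one seed and is exactly
reproducible.

Defaults and why:

| parameter | default | rationale |
|---|---|---|
| n_proteins | 456 | the retained-protein count of the reference design |
| class fractions | 32/64/92/268 of 456 | mirrors the published roster composition |
| effect_log2 | ±1.5 | comfortably detectable at n = 3 with residual SD ~0.3, matching the clearly separated published heatmap |
| baseline_log2_mean, sd | 20, 2.5 | typical label-free log2 intensity scale and spread |
| animal_sd | 0.3 | same order as residual noise; keeps the treatment axis dominant in PCA, matching the clearly separated two-cluster structure reported for the real data and the stated repeatability of the bovine model |
| residual_sd | 0.3 | lower end of the plausible 0.3–0.5 band; within-animal ratios cancel animal offsets, so this drives power |
| day_slope_log2 | 0 | the analysis sums over timepoints, so day trends are not identified; the knob exists for sensitivity studies |
| lod_quantile, missing_steepness | 0.05, 1.5 | mild left-censoring (~7% of records) concentrated in low-abundance proteins |
| frac_extracellular_by_class | 0.67/0.04/0.51/0.42 | the published localization profile of the groups and their background |
| dex_rescue_fraction | 1.0 | "complete rescue" planted so the CD|C and ICD|IC calls have a well-defined target |

What the generator does *not* emulate: peptide-level variation and
shared peptides, identification FDR, correlated proteins (each protein
is independent given its class), day-varying effects, or batch/run
order effects. Passing tests therefore demonstrate that the pipeline's
logic and calibration are correct under the model's assumptions, not
that real cartilage secretome data meets those assumptions.

## Pipeline determinism

A run is fully determined by its configuration and seed: enrichment
seeds are spawned deterministically from the run seed, and the manifest
records configuration, software version and per-stage counts but no
wall-clock timestamps, so re-running a config reproduces every output
byte-identically. All thresholds (alpha, min_frac, n_boot) are
parameters with the reference defaults, never constants.

## Problem sizes in the verification suite

The acceptance checks use the generator's default design (456 proteins,
10 seeds for recovery and calibration means), 5,000 simulated variances
× 10 seeds for the shrinkage-prior recovery, 500 repeats of m = 100
uniform p-values for the FDR check, and 500 random groups at
n_boot = 2,000 for bootstrap calibration; these sizes give Monte-Carlo
error comfortably inside each check's tolerance.

## Known limitations

- Half-minimum imputation before a parametric test is known to distort
  p-value calibration for heavily censored proteins; the filters remove
  the worst cases and the type-I rate on planted nulls stays near
  nominal under the default (mild) censoring, but calibration under
  heavy censoring is not claimed.
- n = 3 animals leaves d_g = 2; inference leans on variance shrinkage,
  and single-protein conclusions should be treated accordingly.
- The presence rule and grouping thresholds reproduce the reference
  analysis; they are heuristics, not optimal decision rules.
- The roster fixture was reconstructed from the published table's
  printed layout; one entry is an unnamed protein (accession G5E6G2)
  whose group placement follows its printed column.
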