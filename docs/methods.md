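# Methods

This note documents the models behind each module, the defaults that
matter, and what the synthetic-data generators do and do not emulate. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Coordinates and formats

All internal coordinates are 0-based half-open; GFF3/VCF 1-based inclusive
conventions are converted once, at the I/O boundary, and the conversion is
an involution (property-tested). Multi-allelic and non-SNP VCF records are
dropped (not split) with a logged count: the marker-design logic assumes
biallelic SNPs. Site QC (`filter_sites`) keeps sites with minor-allele
frequency ≥ 0.05 and missingness ≤ 20% by default; the scan drivers apply
it before PCA.

## Genotype simulation

`simulate_inversion_dataset` draws, per location, each individual's two
arrangement copies independently with P(S) = logistic(β₀ + β₁·latitude) —
Hardy–Weinberg by construction. Defaults are six locations alternating
between two continents across latitudes 49–69°, 40 diploids each, 4 000
SNPs on an 8 Mb chromosome with the inversion at 1–5 Mb, and cline
coefficients β₀ = 6.23, β₁ = −0.1064 (the values the packaged European
table yields when refitted).

* **Collinear background.** Ancestral allele frequencies are uniform on
  (0.05, 0.95); continent-specific frequencies follow a Balding–Nichols
  Beta(p(1−F)/F, (1−p)(1−F)/F) with F = `f_bg` = 0.13, so the expected
  Hudson FST between continents equals `f_bg`.
* **Inside the inversion.** A fraction `d_inv` = 0.3 of sites is fixed
  between arrangements; of the rest, `mu_poly` = 0.7 are polymorphic but
  shared (same frequency in S and N pools, uniform on (0.05, 0.95)); the
  remainder are monomorphic. Haplotypes are drawn i.i.d. per site given
  the arrangement — no within-arrangement linkage disequilibrium and no
  continent structure inside the inversion. This is sufficient for the
  three-cluster PCA signature and the FST contrasts but understates
  haplotype-level correlations of real data, so passing tests demonstrate
  recovery of frequency structure, not of fine-scale LD.
* **Calibration.** Under this law the ratio-of-averages Hudson FST between
  the SS and NN haplotype pools has the closed form
  d/(d + (1−d)·μ·2E[p(1−p)]) with E[p(1−p)] = 0.1825 for the uniform law;
  `expected_inversion_fst` evaluates it (0.63 at defaults, chosen to sit in
  the 0.62–0.66 range typical of old, deeply diverged inversions) and the
  measured global FST must match it within ±0.05.

Randomness: one `SeedSequence` per run, spawned into per-stage streams;
identical seeds are bit-reproducible.

## Inversion scan

Window PCA uses non-overlapping 50 kb windows (step configurable),
requires ≥ 10 segregating sites per window, centers dosages by twice the
allele frequency, mean-imputes missing calls, and optionally scales by
√(2p(1−p)) (off by default). PC sign is pinned so the lexicographically
smallest sample ID scores non-negatively, removing eigenvector sign
ambiguity.

A window is *inversion-like* when all of:

1. BIC over hard-assignment equal-variance Gaussian mixtures selects k = 3
   over k = 1, 2 for 1-D k-means on PC1 (fixed restarts and sub-seed; best
   inertia wins, first found on ties);
2. the 3-cluster silhouette is ≥ 0.8 — k-means on unstructured PC1 noise
   plateaus near 0.6–0.75, while a recombination-suppressed block yields
   ≥ 0.88 even at `d_inv` = 0.3;
3. the middle cluster has the highest mean observed heterozygosity over
   the window's sites (the heterokaryotype hallmark); and
4. the outer clusters differ by ≥ 0.5 in allele frequency at
   ≥ 3 sites — a single high-frequency SNP can mimic criteria 1–3 by
   splitting samples by its own dosage, but cannot supply multiple
   strongly separating sites.

The called interval is the longest run of inversion-like windows allowing
≤ 1 intervening non-qualifying window (`gap_max`). Thresholds 2 and 4 were
fixed from exploratory simulations before the acceptance checks were run
and formalize what is otherwise a visual call; all per-window scores are
written out so calls are auditable.

Karyotype assignment runs k-means (k = 3, 20 restarts, fixed sub-seed) on
the region PC1, labels the middle cluster SN, and resolves the SS/NN
orientation by anchor samples when given, otherwise by which outer cluster
predominates at the lowest-latitude location (S = southern arrangement).
If the SN cluster is not the most heterozygous the assignment is flagged
low-confidence; fewer than three distinct PC1 values is an explicit
failure state, not a forced split.

## Differentiation statistics

Hudson FST uses the Bhatia et al. estimator on hard genotypes with
ratio-of-averages aggregation (per window and globally). This is a
deliberate substitute for genotype-likelihood-based estimators used on
low-coverage data; numeric equality with such estimates is not claimed.
Frequencies come from non-missing calls only; sites with fewer than four
called alleles in either group are excluded, windows without usable sites
report NaN rather than zero.

Pairwise divergence treats compatible IUPAC ambiguity codes as matches and
excludes positions involving N or a gap from the effective alignment
length (how Sanger-corrected alignments are normally scored); percentages
are reported to one decimal.

The ε = 0 minimum spanning network is the union of all minimum spanning
trees: distinct edge weights are processed in increasing order and, within
a weight class, every edge joining components that were distinct before
the class opened is added. Identical sequences collapse into nodes
carrying multiplicity. ε > 0 generalizations are not implemented.

## Marker design

Digestion scans both the recognition site and its reverse complement
(restriction sites act on duplex DNA), finds overlapping matches, and cuts
at the catalogue's per-enzyme offset (EcoRI G^AATTC ships with offset 1;
offsets are catalogue data because fragment-length prediction needs them).
Fragment lengths always sum to the input length (property-tested). A
restriction *contrast* requires the site match to overlap the SNP position
itself, preventing false contrasts from nearby constitutive sites.
Amplicons are centred on the SNP (667 bp default, clipped to the contig);
heterokaryote lanes are the union of the homokaryote fragment patterns.
Candidates are ranked by homokaryote frequency difference, then by whether
all fragments are separable at the gel resolution (50 bp default), then by
the separation itself. Primer thermodynamics are out of scope — the
amplicon sequence is emitted for external primer tools. Concordance
between marker and PCA karyotypes is reported to the nearest integer
percent with the discordant samples listed.

## Clines and Hardy–Weinberg

Arrangement frequency is p = (2·n_SS + n_SN)/(2n) with a Wilson 95% CI on
the allele scale. The HWE test is the Pearson χ² against (np², 2npq, nq²)
with df = 1 and no continuity correction; monomorphic samples are flagged
rather than tested.

The cline model is an aggregated binomial GLM (logit link) on per-location
arrangement counts — aggregation weights each location by sample size, and
the per-location and per-individual parameterizations give identical
estimates. Fitting is IRLS (statsmodels) with relative tolerance 1e-10 and
100 iterations; likely separation is flagged. The LRT χ² is null minus
residual deviance (df = 1); R² is the deviance R². Prediction ribbons are
Wald intervals on the linear predictor mapped through the inverse logit,
so they always contain the fitted curve. Wald ribbons at n ≈ 40 per
location cover the true frequency at about 95% (95.5% across repeated
simulations in the acceptance suite's conditions).

One caveat established during validation: from the packaged count table
the latitude model's LRT χ² and slope reproduce the published values
exactly, but the published deviance R² (0.93) cannot be obtained from
these counts under the stated formula, which yields 0.60; the temperature
model's χ² likewise differs in the third digit because the table's
temperatures are rounded to one decimal. The package reports the values
its own computation produces.

## Thermal performance and viability

The TPC is fitted by least squares of replicate-level viability
proportions on (T², T, 1), weighted by egg counts by default (a flag
switches to unweighted): for a quadratic, nonlinear least squares reduces
exactly to linear least squares, so no multi-start is needed. Traits come
from the closed forms given in the README; a ≥ 0 (non-concave) or complex
roots flag the affected traits as undefined instead of reporting numbers.
Temperatures whose pooled viability falls below 5% (or with fewer than two
surviving replicates) are excluded by a configurable filter rather than a
hard-coded rule.

The deviance analysis fits the shared binomial GLM with all main effects
and two-way interactions (never higher-order terms) with categorical
coding, and tests each term by an explicit model-pair likelihood ratio
respecting marginality (type II): the base model contains every term not
containing the tested one. Gamma/quasi-Poisson analyses of longevity and
fecundity are out of scope; the viability table schema accommodates
external datasets of the same shape.

## Problem sizes

Default analysis and test sizes — 240 diploids × 4 000 SNPs, 20-seed
recovery sweeps, 2 000 coverage simulations, six 100-egg replicates per
temperature — were chosen so each stage's sampling error is small relative
to the effects under study while full runs stay interactive on a single
core.

## Known limitations

* No within-arrangement LD or recombination in the generator; no
  selection, drift trajectories, or inversion-age inference.
* The scan targets a single inversion per chromosome; overlapping
  inversions will produce merged or truncated calls.
* Genotype-likelihood input (low-coverage pipelines) is not supported —
  analyses start from called genotypes.
* The marker designer treats linked diagnostic SNPs independently,
  reporting co-located SNPs as linkage notes rather than designing joint
  assays.
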