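# Methods

This note documents the models, defaults and numerical choices behind the
`staygreen` package, and what the synthetic trials do and do not emulate.

## Synthetic trial generator (`staygreen.synth`)

The generator defines the study conditions under which everything is
tested: 221 wheat cultivars, three nitrogen doses (81 / 110 / 220 kg N/ha,
the lowest being unfertilised mineral soil N), two complete blocks per
main plot, and four imaging dates between late May and early July.

**Senescence trajectories.**  PSRI follows a four-parameter logistic in
thermal time: baseline 0.15, asymptote 1.2, inflection ("onset") at
865 GDD with a cultivar SD of 55 GDD, slope 0.013 per GDD (SD 0.002).
An optional plateau segment (`plateau_gdd`) freezes the curve just after
onset to mimic the mid-season stagnation some high-performing cultivars
show; senescence in the field does not always follow a clean sigmoid, and
the plateau keeps the family flexible while preserving monotonicity.
Onset shifts by N dose (−85 / −35 / 0 GDD at low / intermediate / high N),
so low N senesces earlier and faster — the N gradient every downstream
check relies on.  Gaussian noise (SD 0.03 PSRI units) is added per plot
and date; noisy values are floored at 0.02 so band reflectances stay
positive.

**Causal architecture.**  Three planted loci act additively on onset, per
favourable-allele dose fraction: two favourable-*major* loci effective at
all N doses (+160 and +105 GDD, minor-allele frequency 0.10 each) and one
favourable-*minor* locus effective only at the lowest dose (+140 GDD, MAF
≈ 0.10 overall).  Because most cultivars carry both major favourable
alleles, the low-N locus acts on top of an already delayed onset; the
onset intercept (865 GDD, between the two central imaging dates) keeps
stacked carriers inside the responsive part of the logistic — with a much
later intercept the stacked effect would saturate to nothing.  The first
locus' shift was calibrated once against the generator's own analytic-PVE
helper so that its by-construction PVE on pooled genotype effects is
≈ 25 %; all defaults were frozen afterwards.  The minor favourable allele
follows a per-decade frequency ramp in German cultivars (0 % before 1980
to 24 % from the 2010s), emulating introduction and indirect selection.

Causal carrier counts are pinned to `round(freq · n)` within each
frequency stratum (carriers drawn by permutation), so realized causal MAFs
sit at their planted values; background markers are ordinary Bernoulli
draws.  This removes binomial wobble from the planted signal strength
without touching its composition.

**Genotypes and LD.**  The panel is fully inbred (doses 0/2; heterozygous
draws available via `inbred=False`).  Population structure follows a
Balding–Nichols model: 14 origin-by-decade groups whose allele frequencies
drift around the panel frequency with differentiation F_ST = 0.12.  Around
each causal locus, 8 markers within a 2 Mbp window are copies of the
causal column with per-marker allele flips; the flip rate is solved by
bisection from the exact r²(e, p) relation (the naive (1−2e)² rule badly
overestimates LD at low allele frequency), targeting r² from 1.0 at the
locus down to 0.85 at the window edge — comfortably above the 0.7
block-building threshold.

**Reflectances.**  Band values are obtained by inverting the index
formulas: blue is drawn near 0.045 (kept ≤ 0.055 so green canopies remain
attainable), the 842/740 nm ratio is fixed at 1.05, and red, 740, 842 and
717 nm follow uniquely from the target PSRI, NDVI and NDRE.  NDVI and NDRE
are deterministic functions of the *noisy* PSRI (0.88 − 0.55·s and
0.48 − 0.33·s of the senescence progress s), so the inversion is always
consistent and indices recomputed from bands reproduce the targets to
machine precision.  Rasters for the zonal-statistics path are rendered as
plain float TIFFs with ESRI world files; plot polygons cover the central
1.6 × 4 m (6.4 m²) of each 3 × 7 m plot.

**Yields.**  Grain yield is linear in −(area under the plot's PSRI curve)
with per-dose intercepts; the noise SD is calibrated per N dose so the
*cultivar-mean* PSRI–yield correlation hits −0.80 / −0.70 / −0.68 at
low / intermediate / high N.  Straw yield follows from a harvest index
drawn near 0.45.  These correlation targets are generator settings, not
claims about any field dataset.

**What the generator does not emulate:** radiative-transfer or BRDF
effects, soil background, weather reanalysis, heading-date variation,
spatial field trends, genotype-by-year interaction, or the 2019 vs 2020
camera difference beyond the 740/842 nm NIR band switch.  Passing tests
therefore demonstrate correctness of the statistical machinery under a
known, well-behaved data-generating process — not robustness to every
artefact of real imagery.

## Imaging (`staygreen.imaging`)

Empirical-line calibration fits DN = gain·ρ + offset per band by least
squares (≥ 2 distinct panels required) and inverts it; calibrated
reflectance is clipped to [0, 1.5] with a warning on overshoot.  Zonal
medians use pixel-centre containment (deterministic, standard in raster
zonal statistics); plots with fewer than `min_coverage_px = 50` valid
pixels are flagged and excluded, mirroring the removal of poorly covered
plots — the threshold is this package's choice.  Bands are matched by
exact nominal centre wavelength; rasters and polygons must share a CRS (no
on-the-fly reprojection).  PSRI uses the 740 nm NIR band on the dual
camera and 842 nm on the 5-band MX.

## Thermal time (`staygreen.thermal`)

Daily extremes are clamped into [4, 25] °C *before* averaging — the most
direct reading of "values below the lower or above the upper limit were
set to these threshold values"; clamping the daily mean instead is
available via `clamp_extremes=False`.  Accumulation is end-exclusive by
default (morning flights).  Gaps in the daily series are an error listing
the missing dates, never silently skipped.

## Split-plot analysis (`staygreen.phenostats`)

The response is √(PSRI + 10).  For balanced data, all sums of squares come
from the exact balanced-factorial decomposition (recursive cell-mean
effects), with error strata pooled as: main-plot error = N×B; sub-plot
error = C×B + C×N×B; residual = every time-by-error interaction.  Variance
components solve the expected-mean-squares equations
E[MS_C] = V_R + r·V_C×N + n·r·V_C, E[MS_C×N] = V_R + r·V_C×N,
E[MS_E] = V_R; negative solutions are truncated at zero and flagged.  This
method-of-moments route is exactly checkable against a hand oracle; for
unbalanced data the package falls back to REML (statsmodels `MixedLM` with
a cultivar intercept and a cultivar-by-N variance component).

Genotype effects are centred cultivar means per date and pooled over the
two central senescence dates.  The default is unshrunken (fixed-effect
adjusted means); `effects="shrunken"` multiplies by the reliability
factor, which for balanced data is exactly the BLUP shrinkage of cultivar
means.  Both modes exist because "best linear unbiased estimates modelled
as random effects" is ambiguous between them; neither is asserted to be
the only correct reading.  Reliability uses n = 3 N levels and r = 2
replications (two blocks, one replicate each) by default.

Time-term F-tests are Greenhouse–Geisser corrected: ε is computed from the
double-centred covariance of the per-plot time profiles,
ε = tr(A)²/((t−1)·tr(A²)), clipped to [1/(t−1), 1], and multiplies both
degrees of freedom.  Kenward–Roger degrees of freedom and Mauchly's test
are out of scope; classical stratum df are used instead.  The stay-green
set is the ceil(0.25·N) cultivars with the lowest pooled effects, ties
broken by stable cultivar-id order and flagged.  The relative senescence
rate RSR = 100·(PSRI_later − PSRI_earlier)/PSRI_earlier is computed on the
untransformed index; a negative earlier value flips the sign
interpretation and is flagged rather than rejected.

## GWAS (`staygreen.gwas`)

Filtering keeps MAF ≥ 0.03 and missingness ≤ 0.05 (the discard rules are
"below 3 %" and "more than 5 %", so both boundaries are retained) and
drops monomorphic markers.  Missing doses are mean-imputed (preserves
MAF).  Structure correction uses the first three principal components of
the centred dose matrix (SVD); no kinship matrix, matching the covariate
structure of the modelled analysis.  The single-marker scan residualises
phenotype and doses on the covariates once and fits every marker in one
vectorised pass; collinear markers are flagged with missing p-values.

The multi-locus scan is deliberately a *simplified* iterative-conditioning
procedure in the spirit of FarmCPU/BLINK, not a re-implementation of
either: scan; add the most significant marker passing α/m that is not in
LD (r² > 0.7) with an already selected pseudo-QTN; rescan; stop when no
marker qualifies or at `max_iter` (flagged); finally re-test each selected
pseudo-QTN leave-one-out.  PVE is fixed as 100·2·MAF·(1−MAF)·β²/Var(y),
the Hardy–Weinberg additive-variance convention, capped at 100.  On a
fully inbred panel the realized dose variance is 4p(1−p), twice the
assumed value, so PVE understates the regression R² by up to a factor of
two there; the generator's analytic PVE uses the same convention, so
estimated and by-construction values are always compared on one scale.
Marker effects are reported on the transformed √(PSRI+10) response scale.

## Haplotypes (`staygreen.haplotypes`)

LD is the squared Pearson correlation of dose vectors (composite LD —
appropriate without phase on an essentially inbred panel; whether the 0.7
rule refers to r² or |r| is not fixed in the field, r² is the default and
configurable).  "Adjacent" means physically contiguous markers in map
order, extended per direction until the first r² failure; a gap-tolerant
variant (`max_gap`) is available.

Clustering is k-means (10 restarts, fixed seed) on the block dose matrix;
k is scanned downward from `k_max = 6` and the first k whose smallest
cluster has ≥ 5 members is accepted (k = 1 fallback; k also never exceeds
the number of distinct dose patterns).  This rule favours the finest
admissible partition, so on noisy blocks it yields additional variant
clusters — which is exactly what the `v` suffixes in the naming grammar
(`[Mm][ACGT]v*`) encode; when recovery of a specific planted structure is
being scored, `k_max` should match the expected diversity.  Cluster codes
take the modal focal-marker allele (tie → major allele, flagged); repeated
codes get `v` suffixes in descending size order.

A cluster is *favourable* when its mean genotype effect is significantly
(α = 0.05, one-sample t) below the locus grand mean, defined as the
unweighted mean of cluster means — weighting by members would make a
dominant majority cluster structurally unable to differ from the
reference.  Group comparisons are variance-gated by Levene's test: three
or more groups use ANOVA + Tukey HSD letters under homogeneity and
Kruskal–Wallis + Bonferroni-adjusted pairwise Wilcoxon otherwise; two
groups use Student's or Welch's t-test; a constant group forces the
nonparametric/Welch branch with a note.  Compact letters are the maximal
cliques of the not-significantly-different graph, lettered in group-mean
order.

Stacking classes join the favourable/unfavourable flags over the three
configured loci in fixed order (`F-F-U` etc.).  In the pipeline the two
across-N loci are the strongest across-N pseudo-QTNs and the third is the
low-N pseudo-QTN with the largest excess of low-N over across-N PVE
(accounting for LD with across-N QTNs) — the most N-specific signal.  The
allele-frequency trend reports per-decade frequencies within an origin
group with a Mann–Kendall-type monotone-trend test computed as Kendall's
τ of frequency against decade.

## Problem sizes and determinism

The default demo and the acceptance script use 221 cultivars × 3 doses ×
2 blocks × 4 dates (5 304 plot-dates) and 3 000 markers; the null
calibration uses an independent 200 × 2 000 panel; the variance-component
recovery study uses 500 simulated single-date trials of 200 cultivars.
These sizes give stable statistics while keeping any stage in seconds on
one CPU.  All randomness derives from one master seed through fixed child
streams (`numpy` `SeedSequence`), so identical seeds give byte-identical
outputs; pipeline CSVs carry a provenance header (stage, seed, config
hash).

## Known limitations

- The balanced ANOVA path requires a complete cultivar × N × block × date
  layout; anything else silently routes to REML, which is slower and not
  exactly testable against the hand oracle.
- PVE on inbred panels understates R² (see above); comparisons across
  ploidy/inbreeding regimes should use the regression R² directly.
- The multilocus scan controls the per-scan Bonferroni level but, like its
  inspirations, has no formal FWER guarantee across conditioning
  iterations; occasional extra pseudo-QTNs under strong signals are
  expected.
- Favourable-cluster calling needs enough members for a t-test; clusters
  of fewer than two effect values fall back to a sign-only rule.
- The compact-letter display can assign more letters than the minimal
  covering for pathological significance graphs.
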