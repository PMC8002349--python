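# Methods

## The intra-twin difference procedure

The analysis operates on a genus-level 16S count table from a cohort of
monozygotic twin pairs. Because co-twins share genotype and rearing
environment, a genus that diverges within pairs more than the cohort
average is inferred to be under non-shared environmental control, and one
that diverges less to be genetically (or early-environmentally)
constrained. The pipeline is:

1. **Rarefaction.** Each sample is subsampled to a fixed depth (default
   10,000 reads) *without replacement* — a draw from the sample's existing
   read multiset is a multivariate hypergeometric draw, so every rarefied
   count is bounded by the original and the expected rarefied count of
   taxon *i* is `depth × count_i / total`. Samples with fewer reads than
   the depth are dropped with a warning by default (configurable to an
   error); their co-twins' pairs are removed at reconciliation.
2. **Noise filter.** Genera with mean count < 1 read across retained
   samples are eliminated; a mean of exactly 1.0 is kept (the rule is read
   strictly as "less than"). The order is fixed: rarefy first, then filter,
   so the filter sees equalized sequencing effort.
3. **Standardization.** Per-sample compositions are z-scored per genus
   across all samples (Q values), using the sample SD (n−1). Because
   z-scores are invariant to per-genus positive rescaling, computing Q from
   compositions or from equal-depth counts is identical (asserted by a
   test), and switching to the population SD rescales every genus by the
   same constant and changes no downstream decision (also asserted).
4. **ITD.** Within each pair and genus, Twin1 is the higher-abundance
   member; ITD = Q(Twin1) − Q(Twin2) = |Q_a − Q_b| ≥ 0. Exact ties give
   ITD = 0 and are recorded as ties; for the nutrient screen the tie is
   broken deterministically (lexicographically smaller sample ID acts as
   Twin1) and noted in the run manifest.
5. **Susceptibility extraction.** Each genus's 28 ITD values are compared
   against the pooled ITD cells of all genera (28 × G values) with Welch's
   two-sample *t*-test, two-sided; direction is recovered from the sign of
   mean ITDx − MD. The pooled comparator *includes* the focal genus by
   default because MD is reported as a single cohort-wide grand mean; an
   `exclude_focal` variant is available. Classification: p < α and
   mean ITDx > MD ⇒ environment-susceptible; p < α and mean ITDx < MD ⇒
   genetic-susceptible; otherwise indeterminate.
6. **Nutrient screen.** For each environment-susceptible genus, the
   intra-twin nutrient difference ITND = intake(Twin1) − intake(Twin2) is
   computed with that genus's own twin ordering (a fixed-global-ordering
   mode exists behind a flag, since the difference equation alone does not
   pin the labelling down). Spearman's rs (mid-ranks; p from the *t*
   approximation on n−2 df) is computed between the genus's ITD column and
   each nutrient's ITND column. Two flagging rules are provided: `pvalue`
   (p < α, default) and `threshold` (|rs| ≥ 0.27, the published
   convention); the 0.27 cutoff corresponds to the p < 0.05 critical value
   at roughly n = 56 individuals rather than n = 28 pairs, so both rules
   are always reported rather than guessing its provenance.

### Statistical caveats, mirrored deliberately

The pooled Welch comparator treats all pair × genus cells as one flat
i.i.d. sample although cells share pairs and the focal genus contributes to
its own comparator; no multiple-testing correction is applied across genera
or across the genus × nutrient grid (Benjamini–Hochberg columns/matrices
are emitted for transparency but do not drive any decision). These choices
reproduce the analysis as defined; they are not endorsed as optimal
inference. The null-calibration experiment (below) shows the realized
false-positive rate of the procedure as implemented stays near nominal
under an exchangeable null, which is a property of this pipeline, not a
general guarantee.

## Synthetic cohort generator

The generator exists because no raw twin cohort of this design is publicly
available; it emulates the statistical structure the analysis assumes, with
ground truth exposed.

**Microbiota.** Latent log-abundance for taxon g, pair p, member i:

    L_ipg = mu_g + G_pg + E_ipg,  G ~ N(0, r_g),  E ~ N(0, 1 − r_g)

with unit total latent variance. `r_g` ∈ [0, 1] is the intra-pair
correlation — the variance fraction shared within a pair, a proxy for
genetic plus common-environment control. Per-sample composition is the
softmax of L over taxa; counts are multinomial at the configured depth
(default 10,000). Defaults: 28 pairs, 133 taxa; base log-abundances on a
descending linear grid from +2.5 to −2.5 (≈ 3 decades of relative
abundance, so the rarest taxa sit near the mean-1-read filter boundary);
an r profile with 12 environment-driven taxa (r = 0.05) placed at the
abundant end (real cohorts find their most abundant genera on the
environment-susceptible side), one strongly constrained taxon (r = 0.995),
and a moderately constrained background (r = 0.8).

**Two observation scales.** On the latent Gaussian scale the expected mean
ITD is exactly `2·√((1−r)/π)` (E|N(0, 2(1−r))| after unit standardization).
The softmax/multinomial path destroys this closed form: composition values
of a log-normal latent are heavy-tailed, and the standardized |difference|
of a heavy-tailed variable has a smaller mean relative to its SD (≈ 0.79
vs 1.128 at r = 0) and a much larger per-genus variance. The generator
therefore exposes both the count table and the `latent` matrix
(`read_sampling="none"` skips counts entirely). Calibration and
parameter-recovery experiments that invoke the Gaussian closed form run on
the latent scale; null calibration and the association screen run on the
realistic count scale. A practical consequence worth stating plainly: at
28 pairs, per-genus power on the count scale is modest (a single default
cohort recovers only part of a planted 12-genus environment-driven set),
which is consistent with the reference cohort reporting only its strongest
13 of 133 genera as significant.

**Nutrients.** Intake of nutrient k for member i of pair p is
`nu_k + C_pk + U_ipk` with pair-shared and individual Gaussian components
(default split: half the variance each). The 18-nutrient default panel
matches the published cohort's energy-adjusted means and SDs (e.g. protein
38.5 ± 7.4 g/1000 kcal, vitamin D 7.7 ± 4.6 µg/1000 kcal). Negative draws
are clipped at zero; because vitamin D and B12 have small mean/SD ratios,
naive clipping would shrink their SDs noticeably, so pre-clip parameters
are moment-calibrated (censored-normal moment equations solved numerically)
such that the clipped marginals still match the published mean and SD.
The overall clip rate across the panel is ~0.5% and is logged in the
ground truth.

**Planted diet links.** A link (taxon g, nutrient k, strength s) sets the
individual nutrient component to
`individual_sd × (s·Ê_ipg + √(1−s²)·noise)`, where Ê is the taxon's
unit-variance unique environmental deviation. Ordering co-twins by genus
abundance then makes the genus-ordered ITND stochastically increasing in
the genus's ITD, the monotone structure the Spearman screen detects. The
expected rs sign equals sign(s).

**What the generator does not emulate:** zero inflation and
over-dispersion beyond multinomial noise, phylogenetic correlation between
taxa, enterotype-like clustering, dizygotic twins, within-person temporal
variation, and any systematic diet–microbiota confounding other than the
planted links. Passing recovery tests therefore demonstrates correctness
of the procedure under its own assumptions, not performance on real
cohorts.

## Validation experiments (`twinflux.experiments`)

* **Closed-form recovery.** Empirical mean ITD at r ∈ {0, 0.5, 0.9} with
  5,000 pairs (latent scale) agrees with 2·√((1−r)/π) within 2%.
* **Null calibration.** 200 exchangeable cohorts (all taxa r = 0.5,
  default abundance profile, full count pipeline, 133 × 28): the fraction
  of genera reaching p < 0.05 stays within the binomial 99% band around
  the nominal level (26,600 tests).
* **Parameter recovery.** Planted design (12 taxa at r = 0.05, background
  r = 0.8, one taxon at r = 0.995), chosen by a power analysis before any
  acceptance run was frozen: at 28 pairs on the latent scale, sensitivity
  for the planted environment-driven set is ≈ 0.98 over 100 cohorts and
  the genetic taxon is recovered essentially always. The same design
  through the count pipeline has materially lower sensitivity (heavy-tailed
  ITD; see above) and is reported as such, not hidden.
* **Link sign recovery.** A strength-0.8 link on an abundant low-r taxon
  is recovered with the correct rs sign in ≈ 99% of 500 cohorts through
  the full count pipeline.
* **Oracle equivalence.** The in-package Welch test matches an independent
  reference implementation to 1e−9 in t, df and p over 1,000 random vector
  pairs; Spearman rs reproduces the classic 1 − 6Σd²/(n(n²−1)) formula on
  tie-free inputs; the exact-permutation p at n = 8 agrees with the *t*
  approximation within 0.02 for |rs| ≤ 0.7 under the mid-p convention
  (ties counted at half weight — the appropriate comparator for a
  continuous approximation; the conservative inclusive p, also available,
  deviates by up to 0.024 by exhaustive enumeration).

## Numerical and interface choices

* Rarefaction draws internally in sorted-taxon-label order, making the
  result exactly equivariant under permutation of input rows (the
  underlying sequential sampler is otherwise order-sensitive); each sample
  consumes its own child RNG stream, so dropping one sample does not
  perturb the draws of others.
* TSV is canonical for all tables; a read-only BIOM-JSON (1.0) dialect is
  accepted for count tables and parsed directly (the format is plain
  JSON). The sodium code "NA" forces all readers to disable default
  missing-value tokens; genuinely undefined correlations are written as
  "NA", never as 0.
* Duplicate genus labels across families are disambiguated by prefixing
  the family name; unresolved genus labels ("uncultured" etc.) pass
  through untouched.
* Floats are displayed at 3 decimals (susceptibility) and 2 decimals
  (correlations), matching the conventions of published tables of this
  kind; round-trips are exact to display precision.
* The run manifest records config, library versions, stage dimensions
  (e.g. the genus funnel before/after filtering), tie counts and warnings,
  and contains no timestamps, so identical config + seed reproduces every
  output byte-for-byte.
* Problem sizes in the validation experiments (5,000 pairs for closed
  forms, 200 null replicates, 100/500 recovery seeds) were chosen so
  Monte-Carlo error sits comfortably inside the stated tolerances while
  the full suite runs in well under a minute.

## Known limitations

* MD = grand mean over all cells equals the mean of per-genus means only
  for complete matrices; pairs dropped for low depth remove whole rows, so
  the identity is preserved, but genus-specific missingness is not
  supported.
* The Welch screen's independence caveats above mean reported p-values are
  descriptive, not strictly calibrated, on real (dependent) data.
* The generator's softmax model induces negative correlation between taxa
  via the shared denominator; with 133 taxa this coupling is weak but not
  zero, and it is one reason count-scale behavior is checked empirically
  rather than asserted from the Gaussian theory.
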