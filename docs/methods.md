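# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of `pleioscan`. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## The statistical model

The core of the package is a battery of per-variant, per-phecode logistic
regressions under an additive genetic model: case status is regressed on
the alt-allele dosage (0–2, possibly fractional for imputed genotypes) with
median event age, sex and the first two genotype principal components as
covariates, optionally plus reference-coded site indicators. Inference on
the dosage coefficient is by Wald test (a likelihood-ratio test is
available behind a flag; the two agree closely except in small or sparse
strata). Odds ratios are `exp(beta)` and always refer to the alt allele.

Non-convergence and separation are first-class outcomes: fits are capped at
100 Newton iterations, complete separation (and quasi-separation, detected
as |beta| > 15 or SE > 1e3) yields a flagged row with missing p rather than
a spuriously extreme one, and a failed fit never aborts the scan.

The family-wise threshold is 0.05 divided by the number of *analyzed*
phecodes, recomputed per run rather than hard-coded; for 1232 phecodes this
is 4.06×10⁻⁵ (printed to two significant figures as 4.1×10⁻⁵). Published
analyses of this design also quote a discovery threshold of 5.8×10⁻⁵ whose
implied denominator (~862) does not equal the stated phecode count; both
values can be supplied explicitly to `significant_hits`, and neither is
silently reconciled with the other.

## Phenotype coding

Phecode semantics follow the standard PheWAS-package convention: exclusion
ranges are numeric intervals on decimal phecodes, each phecode's range
containing itself. Status precedence per phecode is: case (≥2 distinct
dates) → excluded-single-instance (exactly 1) → excluded-related-code (a
code elsewhere in the exclusion range) → control. Case status deliberately
takes precedence over the exclusion-range rule for the same phecode, since
a case's own codes always lie inside the range. Single-instance exclusion
is applied before related-code exclusion when both could apply.

The age covariate ("median age at which ICD-9 codes were recorded") is
computed per *person* over all of that person's events, not per phecode;
a per-phecode variant is supported through `median_event_ages`. The adult
filter is strict (`age > 18`), with age taken at the person's last recorded
event.

## Variant selection

The primary cascade applies, in order: gene boundary (1-based inclusive on
both ends, NCBI convention), imputation r² > 0.4, MAF > 1%, LDL-C
association p < 5×10⁻⁸, then greedy LD pruning at r² < 0.3 — survivors are
taken in order of ascending LDL-C p (ties broken lexicographically by
rsid), and a variant is accepted iff its r² with every already-accepted
variant is below the threshold, so each linked group keeps its strongest
LDL-C association. The association filter precedes LD pruning. The
secondary cascade swaps the association criterion for its complement
(p ≥ 5×10⁻⁸, i.e. failure of the primary criterion — no separate threshold
is defined) and additionally requires a "missense" annotation.

LD r² is the squared Pearson correlation of dosages (genotypic r²), not
haplotype r², because phased haplotypes are not available from dosage data.
MAF is recomputed from the dosage matrix (alt frequency folded at 0.5)
rather than trusted from metadata, so that filtering persons cannot leave a
stale frequency. Tight LD groups around an index variant use single-linkage
(connected components) at r² > 0.98 among variants linked to the index at
r² > 0.3.

LDL-C preparation: the median of pre-treatment measurements when any exist,
otherwise the median of on-treatment measurements divided by 0.75;
non-positive values are rejected with a warning. With noiseless synthetic
data the /0.75 back-correction recovers the latent pre-treatment value
exactly.

Principal components use the standard genotype scaling (centre at 2p, scale
by √(2p(1−p))) followed by SVD; sign is fixed by making the
largest-magnitude score positive. Relatedness pruning removes one random
member of each pair with p̂ ≥ 0.5, cascading over the relatedness graph,
with all randomness drawn from the run seed.

## Cross-validation and power

Cross-validation partitions the cohort at random into five folds of
near-equal size (differing by at most one person) and tests the association
within each fold separately; the five p-values are combined by Fisher's
method, χ² = −2Σln p on 2k degrees of freedom. Folds whose fit fails
(e.g. a single-class outcome in a small fold) contribute no p-value and
reduce the degrees of freedom instead of aborting. Zero p-values are
clamped to the smallest positive normal double with a logged warning.

Analytic power for the additive logistic Wald test uses the variance-ratio
normal approximation: with effect ln(OR), predictor variance 2·maf·(1−maf)
under Hardy–Weinberg and case fraction cf, the noncentrality is
|ln OR|·√(n·cf(1−cf)·2·maf(1−maf)) and two-sided power follows from the
normal tails, so power at OR = 1 equals α exactly. This is the same family
of approximations implemented by the logistic-regression functions of the
R package powerMediation. Its accuracy is arbitrated by an independent
Monte-Carlo oracle (`empirical_power`) that simulates genotypes under HWE,
solves the intercept for the target marginal case fraction, and fits each
replicate on genotype-level aggregated counts (sufficient for this model);
the acceptance suite checks agreement within ±0.05 over a 3×3×3 grid of
(n, MAF, OR) at 2000 replicates per cell.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes — it
is the instrument the tests are run on, not a model of real healthcare
data.

* **Genotypes.** Haplotypes are drawn per LD block by latent copying: each
  haplotype copies a shared latent allele with probability c = r²^0.25,
  else draws fresh at its own MAF. For equal within-block frequencies the
  realized dosage r² equals the block target; with unequal frequencies it
  is attenuated ("near" the target). Blocks are mutually independent.
  First-degree pairs are planted by per-locus transmission of one parental
  allele, and emitted with p̂ = 0.5 + N(0, 0.02) — the pruning rule is
  exercised without a full IBD estimator.
* **LDL-C.** Latent pre-treatment LDL-C is intercept (130 mg/dL) + Σβ·dosage
  + N(0, 30), with per-measurement noise of 5 mg/dL; a fraction of persons
  (default 0.237, matching the on-treatment share of the emulated study) is
  measured only on treatment, with values scaled by 0.75.
* **Phecodes.** Disease status per phecode is Bernoulli from a logistic
  liability with the configured baseline prevalence and planted per-variant
  log-odds effects; dosages are mean-centred in the liability so the
  marginal prevalence stays at baseline. Affected persons emit two
  component ICD-9 codes on guaranteed-distinct dates except a configurable
  single-code-noise fraction who emit one (and are correctly excluded
  downstream); a small fraction of unaffected persons emit one code of a
  sibling phecode inside the exclusion range; a small fraction of everyone
  emits an unmapped wellness code.
* **Dates and ages.** Dates are integer day offsets from the year 2000 with
  365-day years — only distinct-date logic and year-scale ages matter.
  Adults-only is *not* enforced at generation (birth years run to 2000), so
  the adult filter has something to remove.
* **Determinism.** Each generator stage draws from its own seeded
  substream, so the same seed reproduces every table byte for byte
  regardless of call order.

Named designs: the *reference* cohort mirrors the published ten-variant
PCSK9/APOB/LDLR panel (MAFs, mg/dL betas and annotations on the published
scale, e.g. −12.97 mg/dL for the PCSK9 missense variant) with lipid-family
phecodes, a planted protective myopia effect and null phenotypes; the
*null* cohort plants no phecode effects at all (for type-I calibration);
the *recovery* cohort plants the −12.97 mg/dL beta on a MAF-0.10 variant
plus a pleiotropic OR of 1.5 on one phecode. The recovery MAF of 0.10 is a
design choice: at n = 5×10⁴ it yields an LDL slope SE of ≈0.3 mg/dL, making
±1.0 a ~3σ recovery criterion, whereas at the published MAF of 1.4% the
same criterion would sit at ~1.2σ of the estimator.

Both the reference and recovery designs add a few dozen LDL-neutral
"marker" variants. This mirrors practice — PCs are computed from large
marker sets, not from the candidate panel — and matters numerically: with
only a handful of variants the leading PCs load heavily on individual
candidates, and conditioning on them both biases single-variant effects and
manufactures spurious LDL-C associations for null variants at large n.

What passing tests do **not** show about real data: the generator has no
healthcare-utilization structure (control under-ascertainment), no code
co-occurrence or trajectory structure, no ICD-10, no cryptic population
stratification (so PC adjustment is exercised but never *needed*), and no
genotyping/imputation error beyond the emitted r² metadata.

## Problem sizes

The test suite runs the scan at n = 5000 with 200 null phecodes (2000
fits), the recovery pipeline at n = 5×10⁴, cross-validation uniformity over
200 seeds, and the power grid at 27 cells × 2000 replicates; these sizes
give stable Monte-Carlo checks (binomial SE ≈ 0.005 on the type-I fraction,
≈ 0.011 on power estimates) at a few minutes of total runtime. On a null
cohort, roughly 0.5 of the 2000 scan p-values are expected below the
200-phecode Bonferroni level in any single realization, so the zero-hit
check is tied to the suite's fixed cohort seed, while the acceptance script
reports the observed count for whatever seed it is given.

## Known limitations

* The Wald test is conservative-to-anticonservative in sparse strata;
  rare-phecode × rare-variant pairs at desk scale rely on the separation
  flags rather than small-sample corrections (no Firth regression).
* Greedy LD pruning is order-dependent by construction; determinism is
  guaranteed by the (p, rsid) sort, but a different tie-break could select
  a different, equally valid panel.
* The analytic power formula ignores covariate adjustment and
  non-collapsibility of the odds ratio; the Monte-Carlo oracle shares the
  no-covariate design, so agreement between them does not certify power
  under heavy covariate adjustment.
* `prepare_ldl` treats a person's LLM status as measurement-level flags;
  time-varying treatment within the pre-treatment window is not modelled.
* VCF support covers biallelic records with DS or GT; multiallelic records
  are rejected rather than split.
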