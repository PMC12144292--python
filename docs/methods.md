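# Methods

This note documents the statistical models, the synthetic-data assumptions,
the numerical choices and the known limitations of `mirseed`.

## Panel QC and normalization

Ct values are abundance on an inverted log₂-like scale (one cycle ≈ one
doubling; lower Ct = more abundant). The QC chain runs in a fixed order:

1. **Validity masking.** Entries with Ct < 15 or Ct > 35 are set to missing
   ("undetermined"). The bounds are strict: 15.0 and 35.0 themselves are
   valid. Defaults are exposed as parameters.
2. **Detection filter.** Features missing in *more than* half of all samples
   (cases and controls pooled, counted after validity masking) are removed.
   A feature missing in exactly half is kept. The filter can only remove
   rows; it never alters values.
3. **Quantile normalization.** All samples are forced onto a common
   reference distribution (the mean of the per-sample quantile functions,
   evaluated on mid-rank plotting positions). On a complete matrix this is
   exactly the classic rank-mean scheme, and ties receive the mean of their
   ranks' reference values (the 2×2 hand example and idempotence hold
   bit-exactly).

   *Incomplete matrices use a smoothed, anchored map.* Simulation audits of
   the realized operating characteristics drove the design, because each
   naive scheme fails in a specific, measurable way:

   - ranking each sample over whatever happens to be observed (map rank r
     of k to quantile (r−½)/k) lets the dropout pattern perturb every
     value through the r/k ratio, roughly doubling the realized
     per-feature SD under scattered missingness;
   - per-sample order statistics as curve knots carry the noise of a
     single feature each, and the slope between adjacent knots is a ratio
     of order-statistic gaps — both inject large, sample-correlated noise
     when the detected panel is sparse;
   - exact rank assignment over a sparse anchor set quantizes a feature's
     value to the local anchor gap, which becomes catastrophic wherever
     the anchor set has a gap.

   The final scheme therefore builds, per sample, a monotone raw→reference
   curve whose nodes are *block means* of the sample's sorted anchor values
   (anchors = features with ≤ 5% missingness; ~12 blocks) paired with block
   means of the reference, with unit-slope extension beyond the anchor
   range; every observed value is mapped through this curve. Block
   averaging removes single-feature noise from the curve, keeps its local
   slope stable, and leaves per-sample technical offsets exactly
   cancelled.

   *Differential features are excluded from the map.* Quantile
   normalization assumes the bulk of features is non-differential; a truly
   shifted feature that helps define the map leaks its group shift into
   its rank-neighbors — the features closest to it in abundance, which
   then read as spuriously differential. The discovery
   pipeline therefore normalizes twice: features called at BH p < 0.05 in
   the first pass are excluded from the second pass's anchors. The
   flagging level matters: flagging liberally (e.g. p < 0.25) removes a
   selection-biased slab of features and can send the refinement into a
   runaway global offset, so the flag set is exactly the DE call set.
   The 20-seed recovery experiment in the test suite (rerun by
   `scripts/acceptance.py`) verifies the resulting operating
   characteristics: planted-feature sensitivity at or above the 96% design
   power, realized FDR inside the 95% binomial band of the nominal 0.05.
4. **Control removal.** Quantile normalization makes endogenous controls
   unnecessary; they are dropped *after* normalization. Unknown control ids
   raise an error (a mislabeled panel should fail loudly).
5. **PCA QC.** Samples-as-observations PCA after feature-mean imputation of
   missing entries. Imputation is used only for this diagnostic view, never
   for inference. Variance-explained fractions are non-increasing and sum
   to 1.

## Differential expression

**Moderated t.** Per feature, the two-group effect is the difference of
group means of observed values; the pooled residual variance s²_g has
d_g = n₁+n₂−2 degrees of freedom. Across features, a scaled-inverse-χ² prior
(d₀, s₀²) is fitted by method-of-moments on z_g = log s²_g: after removing
the known χ² bias (digamma/log terms), the excess of Var(z) over the
expected trigamma term identifies trigamma(d₀/2), solved by Newton
iteration; s₀² follows from the mean. The posterior variance
s̃²_g = (d₀s₀² + d_g s²_g)/(d₀+d_g) yields t_g with d_g+d₀ degrees of
freedom. Two edge policies:

- if the moment equation has no positive root (homogeneous variances),
  d₀ = ∞ and s₀² is set to the *mean* of the s²_g, so the moderated
  statistic coincides exactly with the ordinary pooled t — shrinkage toward
  a common value is a no-op;
- features with fewer than two observations in either group are reported as
  `not_testable` with NaN statistics, never silently dropped.

On heterogeneous random fixtures the implementation reproduces the
Bioconductor empirical-Bayes reference (d₀, s₀², t and p) to ~1e-15; the
suite asserts this through an `Rscript` cross-check.

Sign convention: reported effects are on the **expression** scale (positive
= more abundant in cases). For Ct input the Ct-scale difference is negated;
the plain moderation path is used (no trend or robust variants).

**Multiple testing.** Benjamini–Hochberg step-up,
adj₍ᵢ₎ = min_{j≥i} p₍ⱼ₎·m/j clipped to 1, mapped back to input order;
cross-checked against `statsmodels.multipletests`.

**qPCR quantification.** ΔCt = Ct(target) − Ct(normalizer) per sample
(samples missing either value are excluded with a log entry); group fold
change vs reference = 2^(mean ΔCt_ref − mean ΔCt_group). Tests are Student's
t (pooled by default, Welch by flag, paired supported); the one-tailed p is
half the two-tailed p when the observed direction matches the prespecified
one, else 1 − half. No amplification-efficiency correction beyond the
2^−ΔΔCt model.

**Count contrasts.** The mimic/inhibitor engine is log₂-CPM (prior count
0.5) followed by the same moderated t. This is a deliberate simplification
relative to count-model GLMs: it is accurate for moderately-to-well
expressed genes and slightly conservative for low counts, and its power at
3 replicates/arm is variance-limited (see Limitations).

## Association

Pearson r with p from t = r√((n−2)/(1−r²)); simple least squares whose
slope test is algebraically the same t (asserted to machine tolerance);
diameter-threshold comparisons partition at ≤ cut vs > cut (the convention
follows how diameter strata are reported clinically) and refuse empty
strata by name. The murine aneurysm call is relative diameter ≥ 1.5
(inclusive: the threshold itself is aneurysmal). Cohort expression enters
association on the −ΔCt (abundance-increasing) scale, stated in output
headers.

## Target prioritization

The hypergeometric overlap p is the upper tail P(X ≥ k) for k observed
shared genes between a database of size K and a DE set of size n drawn from
a universe of N — the one-tailed Fisher exact test. The universe is the set
of genes testable in *both* contrasts (a common sampling frame is required
for the test to be valid). A database is *performant* iff its overlap with
down-regulated genes is significant (p < α) while its overlap with
up-regulated genes — which a target database has no reason to contain — is
not (p ≥ α).

Cascade semantics, in order:

1. opposite-direction set: p_adj < α (strict) and log₂FC < 0 under the
   mimic, p_adj < α and log₂FC > 0 under the inhibitor. Strict inequality
   is used here deliberately; the count-based `de_counts` summary uses the
   inclusive thresholds (p_adj ≤ 0.05, |FC| ≥ 1.5) conventional for
   count-model DE reporting — both conventions appear in practice and the
   two call sites document which they use;
2. disease filter: keep genes whose **mean** signed linear fold change
   across the disease-tissue studies in which they were measured is below
   −1.5 (signed convention: |FC| ≥ 1, negative = down in disease). A
   stricter all-studies variant is exposed as an option. Genes absent from
   every study are dropped and logged;
3. tiers: intersection with the **union** of in-silico databases
   (predicted) and of experimentally validated collections (confirmed);
   tiers may overlap. Containment (tiers ⊆ disease-filtered ⊆ opposite set)
   is a hard invariant, enforced at construction.

## Enrichment

Preranked GSEA: genes ranked by signed moderated t (descending; ties broken
lexicographically). For a set S, hits add |stat|^p / Σ_hits |stat|^p and
misses subtract 1/(N−|S|); ES is the signed maximum deviation of the
running sum. Defaults: weight p = 1 (p = 0 available). The null permutes
gene labels (random same-size sets): with 3 replicates per arm a
phenotype-permutation null is degenerate, so the standard preranked
gene-permutation null is the appropriate choice. p = (1 + #{null ≥
obs})/(1 + n_perm) (mirrored for negative ES) — never exactly zero; an
exhaustive enumeration mode exists for small lists. NES divides ES by the
mean |null ES| of matching sign; q-values are BH across sets.

## Power

Two-sample t power uses the noncentral t with ncp = δ/√(sd₁²/n₁+sd₂²/n₂)
and n₁+n₂−2 df; the experiment-wise error rate over m features is
interpreted as Bonferroni (α/m). At the discovery design (200 vs 150,
δ = SD = 0.1) power exceeds 0.96 by a wide margin for any sensible
interpretation of the family-wise control, so the design claim is
insensitive to that choice. Far-tail evaluations fall back to the normal
approximation where scipy's noncentral-t CDF loses accuracy (the
approximation error there is < 1e-6 and the affected term is negligible).
`n_for_power` does monotone doubling + bisection at a fixed allocation
ratio and is exact-minimal by construction.

## Synthetic data: what it emulates, and what it does not

The generator defaults are the discovery-study conditions: 754 panel
features in ~200 cases vs ~190 controls; 12 planted differential miRNAs
with a 0.1 Ct group shift and 0.1 per-feature SD; a mimic/inhibitor/scramble
experiment with 3 replicates per arm, 60 true targets repressed −1.5 log₂
under the mimic and de-repressed +1 under the inhibitor, NB dispersion 0.05.

Choices made where the emulated design is silent:

- **Abundance is bimodal, so detection is too.** A 17% minority of panel
  miRNAs circulates at quantifiable levels (baseline Ct 19–32); the rest
  sits below the detection limit (true Ct 36–45). Dropout is logistic in
  the *true* Ct (midpoint 33, scale 0.7, 1% base rate) — dropout reflects
  underlying abundance, while the batch offset is a downstream shift of
  the measured value. Detected features then carry ~1–2% missingness,
  undetectable ones fail the >50% filter outright, and ~125 of 754
  features survive — the detected-panel size and realized
  post-normalization group SD (~0.1) a plasma panel of this design
  exhibits. The logistic form is a modeling convenience, not a claim
  about instrument chemistry.
- Planted biomarkers are drawn among well-detected features (baseline
  Ct < 30): a biomarker candidate is by construction something the panel
  can measure.
- Batch structure is a per-sample additive Ct offset (SD 0.5) — exactly the
  technical variation quantile normalization exists to remove.
- RNA-seq true targets are planted among genes with base mean ≥ 50, since a
  3-replicate design cannot measure repression of near-silent genes.
- Disease fold-change tables give planted "down" genes FC ≈ −(1.6 + Exp(0.5))
  and all others |FC| ≈ 1; each gene appears in each of 3 studies with
  probability 0.9.

What passing tests therefore show: the pipeline recovers planted signal at
the designed operating point and controls the FDR under the generator's
noise model (independent Gaussian noise, additive batch, Ct-dependent
missingness-at-random given the true Ct). What they do not show: robustness
to correlated miRNA co-regulation, informative missingness beyond the
dropout model, plate/spatial artifacts, pre-amplification chemistry, or
cohort confounding — real-data properties outside the generator.

## Problem sizes used in the shipped experiments

The recovery experiment averages 20 seeds of the full 754 × 390 design
(seconds per seed); the count-contrast recovery uses 2 000-gene panels over
10 seeds; enrichment nulls use 500–1 000 permutations. These sizes give
Monte-Carlo error comfortably below the margins asserted and keep the whole
suite around 15 s.

## Known limitations

- At 3 replicates/arm the +1 log₂ inhibitor effect is variance-limited:
  the infinite-df ideal caps joint opposite-direction recovery near 0.74
  and the log-CPM moderated-t engine realizes ≈ 0.45–0.5. Recovering
  essentially all true targets would need larger effects, more replicates
  or a count-model engine with mean-variance weighting.
- Quantile normalization forces the extremes of every sample toward common
  values, so a genuine group shift in a feature at the very edge of the
  abundance distribution is attenuated.
- The two-pass normalization refinement protects against leakage from
  features strong enough to be called at FDR 0.05 in the first pass; a
  dense block of just-sub-threshold differential features would still bias
  the map slightly.
- The moderated-t prior assumes exchangeable variances; no mean-variance
  trend is fitted, which costs some power on count data.
- The disease filter treats studies symmetrically (unweighted mean of
  signed FCs) and has no notion of study quality or platform.
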