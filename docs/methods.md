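# Methods

## Scope and model

`soiltrace` implements the downstream analysis of a longitudinal
environmental-microbiota-transfer study in homes: repeated seeding of an
entryway rug with forest soil, biweekly passive settled-dust sampling at two
heights (infant breathing zone, IBZ, 30 cm; adult breathing zone, ABZ,
150 cm) in the entrance and living room, living-room floor-dust vacuuming,
and outdoor reference sampling. The analysis asks how far, how strongly and
for how long a soil-derived community signal propagates into house dust.

The pipeline operates on one kingdom at a time (bacterial 16S or fungal ITS
feature tables); bacterial and fungal matrices are never mixed. Sample weeks
lie on a biweekly grid and denote the *end* of each 2-week exposure window;
a window ending exactly at a seeding week closed before the rug was
deployed, so that sample is the "pre" member of the pair for that event.

## Stages

1. **Decontamination.** Prevalence-based flagging against sequencing blanks:
   for each feature, a presence/absence 2x2 table (controls vs experimental
   samples, detected = count > 0) is scored with a one-sided Fisher exact
   test under the alternative "more prevalent in controls"; features with
   p < 0.5 (the conventional probability threshold) are removed. The exact
   hypergeometric score replaces the chi-squared score of the familiar
   prevalence method: it is direction-explicit and stable at the small
   control numbers typical of these studies, and flags in the same
   direction. Samples emptied by feature removal are dropped with a warning.
2. **Rarefaction** to a common depth (default 2000 reads) by multivariate-
   hypergeometric subsampling without replacement; samples below the depth
   are dropped and reported; the draw is deterministic given a seed.
3. **Compositional transform.** CLR with pseudocount 1
   (clr_i = ln(x_i + 1) − mean_j ln(x_j + 1)); Aitchison distance is the
   Euclidean distance between CLR vectors. The pseudocount breaks exact
   scale invariance; at counts large relative to 1 the effect is negligible,
   and the behaviour is asserted in the test suite. Bray–Curtis is computed
   on rarefied counts (equal depth) and never receives a pseudocount.
4. **Diversity.** Chao1 (with the bias-corrected fallback
   S_obs + F1(F1−1)/2 when no doubletons exist, where the classic estimator
   is undefined) and Shannon with natural logarithm, both on rarefied
   counts.
5. **Source indices.**
   - *SSI* (soil source index): the soil signature is the top-N taxa, by
     unweighted mean relative abundance, among taxa detected in **every**
     seeding-soil aliquot (N = 19 bacteria / 28 fungi by default; ties
     broken lexicographically for determinism). A sample's SSI is the sum of
     its relative abundances over the signature taxa. "Most abundant" is
     taken as the unweighted mean across aliquots — pooled-read and median
     rankings are nearly identical on stable soils, and the unweighted mean
     does not privilege deeper-sequenced aliquots. The signature is built
     from all aliquots jointly (one list per kingdom); the per-home
     *averaged baseline* used for beta distances is a separate object.
   - *HSP* (human source proxy): summed relative abundance of
     Staphylococcus and Streptococcus (genus rank) plus
     Propionibacteriaceae, Corynebacteriaceae and Enterobacteriaceae
     (family rank, over member features). A feature counted at genus rank is
     never double-counted under a family entry.
   - *FaRMI*: logistic score 1/(1+exp(−η)), η = intercept + Σ coef·r, where
     r is the per-taxon percentile rank (1-based average rank / n) of
     relative abundance across the samples scored in one call. The ranking
     population is deliberately the full set passed in; score the samples
     you want ranked together in a single call. Coefficients are an external
     CSV input — the published 45-taxon model is not redistributed; tests
     and demonstrations use synthetic coefficients (and say so).
   Indices are fractions internally; the CLI multiplies SSI/HSP by 100.
6. **Convergence to source.** Per home, the aliquot relative-abundance
   profiles are averaged and renormalized; each dust sample is compared to
   its own home's averaged profile by Bray–Curtis.
7. **PERMANOVA.** One-way pseudo-F from the sums-of-squares partition of the
   squared-distance matrix; p by free permutation of sample labels with the
   identity permutation counted in numerator and denominator
   (p ≥ 1/(n_perm+1), never 0), and exhaustive enumeration over distinct
   label arrangements whenever there are no more of them than the requested
   permutation count. Marginal (partial) testing: each term's SS is
   SS(full) − SS(without term) on the Gower-centered matrix, tested against
   the full-model residual mean square; collinear terms raise an error
   naming the aliased terms. No permutation strata (labels are exchanged
   freely); 999 permutations by default.
8. **Ordination.** Classical PCoA (Gower double-centering,
   eigendecomposition, coordinates scaled by √eigenvalue). Negative
   eigenvalues are reported and their axes dropped; each axis is oriented so
   its largest-magnitude coordinate is positive.
9. **Intervention statistics.** For each intervention home x dust stratum x
   seeding event: pre = sample at the event week, post = sample 2 or 4 weeks
   later (pre2w-post2w / pre2w-post4w). The 4-weeks-later sample of one
   event is simultaneously the pre of the next when events are 4 weeks
   apart; the overlap is part of the design and not corrected. Differences
   d = post − pre are gated by Shapiro–Wilk at α = 0.05 (the level and test
   are our choice; only the rule "t when normal, signed-rank otherwise" is
   inherited): pass → two-sided paired t; fail → two-sided Wilcoxon
   signed-rank with zeros dropped and the exact distribution at small
   tie-free n. The gate is decided per metric x stratum x comparison cell.
   Control homes are excluded from pooled paired testing and reported
   descriptively. Raw p-values are reported (no multiplicity correction by
   default; Benjamini–Hochberg is available as an option). Cross-location
   coherence uses Spearman rank correlations between the entrance-IBZ
   anchor and every other stratum, matched on home x week, with an exact
   permutation p at n ≤ 9. Group comparisons use the two-sided rank-sum
   test (2 groups) or Kruskal–Wallis (more).

## Synthetic study generator

The generator produces the full study layout — 5 intervention homes + 1
control, weeks −8…+14 in steps of 2, seedings at weeks 0/4/8, five dust
strata plus an outdoor sampler, soil aliquots sequenced at each event, and
sequencing blanks — together with per-sample ground-truth mixing weights.

Per sample, the expected community is a convex mixture of four pools (soil,
human, outdoor, resident home background) drawn once per study from
symmetric Dirichlets on disjoint feature blocks (a configurable fraction of
soil features is shared with the outdoor pool). The soil weight is

    w_soil(week, stratum, home) = A_home · att(stratum) · exp(−λ·Δt),

with Δt the weeks since the most recent seeding strictly before the sample
week (zero before the first seeding and in control homes); background
weights are rescaled to 1 − w_soil preserving their ratios. Counts are
Dirichlet-multinomial around the mixture (concentration c x composition;
multinomial is the c → ∞ limit) at lognormal read depths. Every sample has
its own RNG stream keyed by a stable hash of (home, stratum, week), so
adding strata or weeks never perturbs existing samples.

Defaults, chosen once to place the default run in the qualitative regime
the pipeline targets (post-seeding SSI increases of roughly 1–10 percentage
points near the rug, decaying spatially and halving every two weeks):

| parameter | default | meaning |
|---|---|---|
| amplitudes | 0.22, 0.14, 0.12, 0.10, 0.08 | per-home deposition fraction at the entrance IBZ right after seeding; the first home mimics a low-competing-influx home with a visibly stronger response |
| attenuation | 1.0 / 0.7 / 0.45 / 0.35 / 0.25 / 0 | entrance IBZ / entrance ABZ / LR IBZ / LR ABZ / floor / outdoor |
| λ | 0.3466 wk⁻¹ | soil signal halves every 2 weeks |
| background weights | human 0.45, outdoor 0.15, home 0.40 | indoor mixture when no soil is present |
| seasonal ramp | +0.01/wk after week 6 | outdoor influx rising toward spring |
| overdispersion c | 2000 | between-sample compositional noise beyond multinomial |
| read depth | lognormal, median 5000, σ=0.25 | comfortably above the 2000-read rarefaction target |
| soil–outdoor overlap | 0.05 | fraction of soil taxa also present outdoors; raising it to ~0.5 reproduces the elevated pre-seeding baseline typical of fungal soil signatures |

A small contaminant pool (3 features) is spiked into blanks (dominant) and
real samples (5x10⁻⁵ weight) so the decontamination stage is exercisable
end to end.

What the generator does **not** emulate: resuspension physics, occupant
behaviour and visitors, additive carry-over across seeding events (only the
most recent event contributes), taxon-specific transport or survival
differences, compositional interactions between sources, and seasonal
community turnover beyond a linear outdoor-weight ramp. Passing tests on
simulated data therefore demonstrate that the pipeline recovers the signal
structure it assumes — not that real dust obeys that structure.

## Numerical choices and degenerate cases

- Signature ties: lexicographic; signature shorter than requested: all
  candidates returned with a warning.
- All-zero paired differences: mean_diff 0, p = 1, test recorded as
  Wilcoxon.
- Constant series in Spearman: error (rho undefined).
- Rarefaction requires integer counts; Chao1 rejects fractional counts.
- Pseudo-F with zero within-group SS is reported as infinite (perfect
  separation); permutation comparisons handle it consistently.
- PCoA eigenvalue positivity tolerance: 1e-10 relative to the leading
  eigenvalue.

## Problem sizes

The test suite and the acceptance script run the default study
(6 homes x 6 strata x 12 weeks ≈ 430 dust samples + 30 aliquots + blanks,
~160 features) with 20 signal replicates, 10–20 null replicates, and 500
null simulations at 199 permutations for permutation-test calibration; the
committed plain-text fixture is a scaled-down study (45 features, 54
samples, one seeding event). These sizes give stable Monte-Carlo estimates
for every asserted quantity while keeping a full run in the tens of
seconds on one CPU.

## Known limitations

- The marginal PERMANOVA permutes raw labels; restricted permutation
  (strata) is not implemented.
- FaRMI scores depend on the ranking population by construction; scores
  from different calls are not comparable unless the populations match.
- The decontamination score is a Fisher exact analogue of the prevalence
  method, not a reimplementation of any specific tool; flagged sets can
  differ near the threshold.
- Only the most recent seeding event contributes to the simulated soil
  weight, so the generator slightly understates late-study accumulation.
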