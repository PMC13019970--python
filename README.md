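# soiltrace

Source-signal tracking for environmental microbiota transfer studies in the
built environment.

When an environmental microbial community — for example sieved forest soil
seeded onto an entryway rug — is deliberately introduced into a home, how
far does its signal spread through house dust, how strong is it, and how
fast does it fade? `soiltrace` answers this for longitudinal amplicon
studies: biweekly settled-dust samples at infant (IBZ, 30 cm) and adult
(ABZ, 150 cm) breathing zones in the entrance and living room, floor dust,
outdoor references, and repeatedly sequenced aliquots of the seeding
material.

The package covers the whole downstream path from a feature (ASV) table:

- **QC** — prevalence-based contaminant flagging against sequencing blanks
  (one-sided Fisher exact on detection prevalence), rarefaction without
  replacement, CLR transform with pseudocount.
- **Source indices** — the *soil source index*
  `SSI = Σ_{t ∈ signature} p_t`, summing a sample's relative abundances over
  the top-N taxa detected in **every** seeding-soil aliquot (N = 19
  bacteria / 28 fungi by default); the *human source proxy* (HSP) over five
  human-associated genera/families; and *FaRMI*, the logistic score
  `1/(1+e^{−η})`, `η = β₀ + Σ β_t r_t`, on percentile-ranked abundances of
  predictor taxa (coefficients supplied as a CSV input).
- **Community analysis** — Bray–Curtis and Aitchison (Euclidean-on-CLR)
  distance matrices, Chao1 and Shannon diversity, PCoA, one-way and
  marginal PERMANOVA with exact enumeration at small n, and per-home
  convergence of dust toward the averaged seeding-soil baseline.
- **Intervention statistics** — pre/post pairing around each seeding event
  (pre2w-post2w, pre2w-post4w), paired t or Wilcoxon signed-rank gated by a
  Shapiro–Wilk normality check, cross-location Spearman correlations
  anchored at the entrance IBZ, and rank-sum/Kruskal–Wallis group
  comparisons.
- **Synthetic studies** — a generator that reproduces the design (5
  intervention homes + 1 control, weeks −8…+14, seedings at 0/4/8) with a
  mixture/decay signal model
  `w_soil = A·att(stratum)·e^{−λΔt}` and Dirichlet-multinomial read noise,
  emitting per-sample ground-truth mixing weights so every stage is
  testable without any external data.

## Worked example

Simulate a default study, run the pipeline and test the paired pre/post
effects (the library works in fractions; multiply by 100 for percent):

```python
import soiltrace as st
from soiltrace.pipeline import analyze_bundle

bundle = st.simulate_study(st.SimulationConfig(), seed=1)
result = analyze_bundle(bundle, depth=2000, rarefy_seed=2)

table = st.intervention_table(
    {"SSI": result.ssi * 100, "HSP": result.hsp * 100},
    bundle.metadata, st.SeedingDesign(), comparisons=["pre2w_post2w"],
)
print(table.to_string(index=False, float_format=lambda v: f"{v:.3g}"))
```

```
metric      stratum   comparison  n_pairs  mean_diff test_used        p
   SSI entrance_IBZ pre2w_post2w       15        4.4         t 1.39e-06
   HSP entrance_IBZ pre2w_post2w       15      -1.31         t   0.0235
   SSI entrance_ABZ pre2w_post2w       15       2.85         t 0.000156
   HSP entrance_ABZ pre2w_post2w       15     -0.233         t    0.574
   SSI       LR_IBZ pre2w_post2w       15       1.74         t 5.57e-05
   HSP       LR_IBZ pre2w_post2w       15      -1.34         t   0.0656
   SSI       LR_ABZ pre2w_post2w       15        1.6         t 1.67e-05
   HSP       LR_ABZ pre2w_post2w       15     -0.643         t    0.179
   SSI     LR_floor pre2w_post2w       15       1.05         t 8.86e-05
   HSP     LR_floor pre2w_post2w       15      0.157         t    0.747
```

Reading it: each row is one dust stratum; `n_pairs` counts home x seeding
event pairs (5 homes x 3 events); `mean_diff` is the mean post-minus-pre
change in percentage points. The soil index rises most in the entrance
infant breathing zone next to the rug (+4.4 pp, paired t, p ≈ 1e-6) and
decays monotonically toward the living-room ABZ and floor, while the
human-source proxy dips close to the rug — the spatial-decay pattern the
pipeline is built to detect. The same machinery runs on real tables via
`load_abundance_table` / `load_metadata` / `load_taxonomy` or the
`soiltrace` CLI (`simulate`, `preprocess`, `signature-build`, `score`,
`distances`, `diversity`, `permanova`, `intervention-test`).

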