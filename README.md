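# dlwsens

Energy-balance sensitivity and exclusion-bias analyses for doubly-labeled-water
(DLW) feeding trials.

## The problem

In parallel-arm feeding trials of macronutrient composition, the primary outcome
— total energy expenditure (TEE) measured by DLW — is open to two recurring
challenges: that participants did not adhere to their assigned diets, and that
discrepancies between reported energy intake (EI) and measured expenditure
("unaccounted energy") identify unreliable participants who should be excluded.
`dlwsens` implements, as a tested and reusable pipeline, the analyses that probe
both challenges:

1. **Nonadherence sensitivity analysis.** DLW measures CO₂ production (rCO₂,
   L/day) and converts it to energy with the Weir factor
   `W(RQ) = 1.106 + 3.941/RQ` kcal per liter of CO₂. During weight and
   body-composition stability the respiratory quotient RQ equals the diet's food
   quotient FQ = Σᵢ fᵢ qᵢ (energy fractions fᵢ, macronutrient quotients
   q_carb = 1.000, q_fat = 0.710, q_protein = 0.810). If a fraction *p* of
   energy was eaten off protocol (assumed to match the moderate 40/40/20
   carb/fat/protein diet), each arm's true FQ shifts toward the moderate diet's
   0.8460, and every participant's TEE rescales by
   `W(FQ(arm, p)) / W(FQ(arm, 0))`. Sweeping *p* over 0–60% and refitting the
   adjusted low-minus-high-carbohydrate contrast gives the sensitivity table,
   including the effect per 10% of energy from carbohydrate,
   `effect / (4·(1−p))` for the 40-point carbohydrate gap.

2. **Unaccounted energy and post-randomization exclusion bias.** UE = EI − TEE −
   (energy-equivalent rate of body-composition change). Excluding participants
   whose UE crosses a threshold selects on a variable linked to the outcome; the
   `elimination_sweep` re-estimates the diet effect at progressively stricter
   thresholds in either direction (low intake relative to TEE, or the converse)
   with a LOESS smooth of effect versus threshold.

3. **Tertile confounding.** Stratifying the per-protocol group by EI/TEE ratio
   and comparing unadjusted with covariate-adjusted per-tertile diet effects,
   plus the odds ratio linking lowest-tertile membership to an
   above-median baseline TEE.

4. **Baseline diagnostics.** Meng's Z-test for dependent correlations compares
   pre- versus post-weight-loss baseline TEE as predictors of the follow-up
   outcome.

A seeded synthetic-cohort generator (`dlwsens.simulate`) emulates the trial
structure — three arms (20/60, 40/40, 60/20 % energy carbohydrate/fat), a true
280 kcal/day low-vs-high effect, correlated baselines, DLW noise on the rCO₂
scale, energy conservation, and flat-slope intake reporting — so every stage is
testable without external data. See `docs/methods.md` for the model, parameter
choices, and limitations.

## Worked example

```sh
dlwsens simulate --seed 7 --out cohort.csv
dlwsens sensitivity --cohort cohort.csv --display --out table1.csv
dlwsens diagnostics --cohort cohort.csv --out corr.json
```

The sensitivity table for this seed (per-protocol group, n = 112; effects in
kcal/day, minimally adjusted for enrollment cohort and post-weight-loss
baseline TEE):

```
  p  fq_low  fq_high  effect_kcal        se  p_value  significant  effect_per_10pct
0.0  0.7880   0.9040          285 50.398573 0.000000         True                71
0.1  0.7938   0.8982          252 50.367236 0.000001         True                70
0.2  0.7996   0.8924          219 50.342039 0.000014         True                68
0.3  0.8054   0.8866          186 50.322961 0.000222         True                66
0.4  0.8112   0.8808          153 50.309981 0.002366         True                64
0.5  0.8170   0.8750          120 50.303085 0.016947         True                60
0.6  0.8228   0.8692           87 50.302263 0.082521        False                55
```

Reading it: at full adherence the arms' food quotients are 0.7880 and 0.9040
and the estimated diet effect is 285 kcal/day; as assumed nonadherence grows,
the FQ gap narrows by a factor (1−p), the re-expressed effect declines, yet it
stays significant through 50% nonadherence and the effect per 10% carbohydrate
stays near 60–70 kcal/day throughout. The diagnostics command prints

```
r_post=0.809 r_pre=0.594 z=4.43 p=9.242e-06
```

— the post-weight-loss baseline predicts the follow-up outcome markedly better
than the pre-weight-loss one (Meng's Z). `dlwsens run --seed 7 --outdir out/`
produces the full bundle (sensitivity table, UE listing, both elimination
sweeps, tertile report, baseline diagnostics, manifest with content hashes).

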