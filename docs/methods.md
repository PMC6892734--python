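# Methods

## Gas-exchange arithmetic

DLW yields a CO₂ production rate rCO₂ (L/day). Energy expenditure follows from
the abridged Weir equation with rO₂ eliminated via rO₂ = rCO₂/RQ:

    TEE = rCO₂ · W(RQ),   W(RQ) = 1.106 + 3.941/RQ  [kcal per L CO₂].

The Weir coefficients (3.941 kcal/L O₂, 1.106 kcal/L CO₂) are fixed constants
of indirect calorimetry, configurable under `weir.{o2,co2}`. During weight and
body-composition stability RQ equals the food quotient of the diet,

    FQ = f_carb·q_carb + f_fat·q_fat + f_prot·q_prot,

with macronutrient quotients q = (1.000, 0.710, 0.810). These are standard
literature values; they are also the unique solution of the 2×2 linear system
forcing the two full-adherence arm FQs to 0.7880 (20/60/20 carb/fat/protein)
and 0.9040 (60/20/20), given that protein is the residual 20% in every arm.
The protein quotient 0.810 is implied rather than independently sourced — a
documented assumption, configurable under `quotients.*`.

Because FQ is linear in composition, a diet eaten as (1−p) of the assigned arm
plus p of the moderate arm has FQ = (1−p)·FQ_arm + p·FQ_mod, so the low/high
arm FQs move symmetrically about the moderate 0.8460 and their gap is
(1−p)·0.1160. Re-expressing a published TEE under a different FQ multiplies it
by W(FQ_new)/W(FQ_old), exactly equivalent to recomputing from rCO₂.

## The sensitivity table

For each nonadherence fraction p in {0, 0.1, …, 0.6}, every participant's
follow-up TEE (mean of the 10- and 20-week measurements) is rescaled to the
arm's FQ(p) and the adjusted low-minus-high contrast is refit. "Minimally
adjusted" is implemented as ANCOVA: outcome = mean follow-up TEE, covariates =
enrollment cohort + post-weight-loss baseline TEE. The trial's primary models
are change-from-post-weight-loss-baseline models with cohort adjustment;
ANCOVA is the standard, at-least-as-efficient equivalent. Cohort-only
adjustment is available by passing `covariates=("cohort",)`.

Display convention: FQ to 4 decimals; effects to whole kcal/day; the
per-10%-carbohydrate column, effect/(4·(1−p)), is computed from the unrounded
effect and rounded half-away-from-zero.

The repeated-measures structure (TEE at 10 and 20 weeks) is collapsed by
averaging before modelling. A full repeated-measures model is deliberately out
of scope; this is the main structural simplification of the inferential
engine.

## Effect models, tertiles, odds ratios

`adjusted_diet_effect` fits OLS of the outcome on arm indicators (reference =
high-carbohydrate) plus covariates, via `statsmodels`; inference is
large-sample Wald (normal) by default, with `use_t=True` for
degrees-of-freedom-corrected intervals. Rank-deficient designs raise an error
naming the first collinear column. No multiplicity adjustment is applied
anywhere.

Tertiles of the EI/TEE ratio are rank-based thirds with ties broken by stable
participant order; lower tertiles absorb the remainder (n = 10 → 4/3/3). The
"above-median baseline TEE" dichotomy uses the lower median (50th percentile
without interpolation) so even-n cohorts are reproducible. The odds ratio is
the Wald estimator with the Haldane–Anscombe 0.5 correction only when a single
cell is zero; a zero margin is an error.

## Unaccounted energy and the elimination sweep

UE = reported intake − TEE − (Δfat·9441 + Δffm·1816)/days, with the energy
densities configurable (`energy_density.{fm,ffm}`) and a 140-day (20-week)
follow-up by default. The threshold form of the sweep uses the difference (UE
in kcal/day) rather than the EI/TEE ratio, because UE is defined in kcal/day;
the ratio is used only for tertile stratification. The sweep grid runs from
the cohort's max |UE| down to 0 in 25 kcal/day steps by default (the original
figure's grid is not published); counts are reported at every threshold so any
cumulative-elimination reading can be recovered. One direction eliminates
UE < −t (low intake relative to TEE), the other UE > +t (low TEE relative to
intake); at any common positive t the two eliminate disjoint sets. A threshold
that leaves fewer than two participants in a contrasted arm flags the estimate
missing rather than raising.

LOESS is local-linear with a tricube kernel, span 0.75, and no robustness
iterations (the conventional defaults; the source analysis names LOESS without
parameters), delegated to `statsmodels.nonparametric.lowess` with degenerate
inputs (identical x, too-small windows) falling back to means.

## Meng's Z

For two predictors sharing an outcome, with Fisher transforms z₁, z₂,
r̄² = (r₁²+r₂²)/2, f = min(1, (1−r_xx)/(2(1−r̄²))) (capped at 1, per the
original recommendation), h = (1−f·r̄²)/(1−r̄²):

    Z = (z₁ − z₂) · √((n−3) / (2(1−r_xx)·h)),

two-sided normal p. The baseline comparison feeds r_post, r_pre and the
pre/post correlation into this statistic; the follow-up outcome is the mean of
the 10- and 20-week TEE, matching the averaging choice above. Type-I error
calibrates to 5% within Monte-Carlo error at n = 100 (verified against direct
null simulation in the test suite).

## The synthetic cohort

Per participant: a latent trivariate-normal (pre-WL, post-WL, follow-up) TEE
trait with correlations (pre↔follow 0.65, post↔follow 0.85, pre↔post 0.70) and
SD 350 kcal/day; additive sex (+250 kcal/day for male) and enrollment-cohort
(+60) shifts entering all three timepoints; a +250 kcal/day pre-weight-loss
offset. Follow-up arm shifts are ±140 kcal/day (low/high) about the moderate
arm, attenuated by (1−p_i) for a participant's real nonadherence fraction.
The actual RQ is FQ(arm, p_i); rCO₂_true = TEE_true/W(RQ); DLW noise (SD 120
kcal/day per measurement, ≈4.5% CV) is added on the rCO₂ scale; the *recorded*
TEE is rCO₂·W(FQ(arm, 0)) — the analyst's full-adherence assumption — so real
nonadherence biases recorded TEE exactly as the sensitivity analysis assumes,
and correcting at the true p recovers the attenuated true effect to machine
precision (a test asserts this).

Energy conservation holds exactly in truth: true intake = true TEE +
body-composition flux (Δ masses ~ N(0, 0.4 kg) over 140 days). Reported intake
follows the flat-slope model of dietary self-report:
reported = μ + κ·(true·(1−p_i) − μ) − 300 + ε, ε ~ N(0, 300), κ = 0.5 by
default. Consequently UE has mean ≈ −300 kcal/day, SD ≈ 350, and is negatively
correlated with true expenditure — roughly 40% of observations fall within
±250 kcal/day. Weight stability (|stored-energy rate| ≤ 50 kcal/day, ~93% of
participants) defines the per-protocol flag. Demographics (age, percent weight
loss) are drawn from simple uniform ranges and exist to exercise the
adjustment code, not to mimic the trial population. One root seed feeds named
substreams (structure, latent TEE, measurement, body composition, intake,
nonadherence), so toggling one noise source leaves the others' draws intact.

Magnitudes not published for the trial — between-person SD, DLW precision,
reporting-error parameters — are set once to realistic literature values
(≈350, ≈120/measurement, slope ≈0.5 with SD 300 and mean underreporting 300
kcal/day) and documented here as placeholders in that sense. Analyses of the
"per-protocol group" at n = 120 use a tightened body-composition SD (0.15 kg)
so the whole generated cohort is weight stable, with arm means 2620/2760/2900
kcal/day.

## What the synthetic cohorts can and cannot show

The generator is arm-exchangeable and Gaussian: both arms share every error
distribution, and individual response heterogeneity beyond the nonadherence
mechanism is absent. Two consequences matter when comparing simulated with
real-data behaviour:

* **One-sided elimination shrinks the contrast in both directions.** For any
  selection score correlated with the outcome and identically distributed
  across arms up to the location shift, truncation at a common threshold
  compresses the between-arm gap — the arm sitting deeper past the cutoff is
  truncated harder. Simulated sweeps therefore show genuine
  post-randomization-exclusion bias (and no bias when UE is independent of
  true TEE), but the *asymmetric* real-data pattern — one direction inflating
  while the other deflates — is not a generic consequence of this structure
  and does not reproduce here; in real data it reflects features outside this
  generator (non-Gaussian tails, response heterogeneity, small-sample
  idiosyncrasy).

* **Tertile adjustment changes the estimate with the opposite generic sign.**
  Selection into the lowest EI/TEE tertile requires higher baselines from
  high-carb-arm members (their TEE is lower), so within that tertile baseline
  imbalance pulls the *unadjusted* contrast down and adjustment raises it. The
  analysis machinery demonstrates confounding-by-selection either way; the
  real data's larger-unadjusted pattern again reflects structure beyond the
  generator.

* **Estimate variability bounds what "stability" can mean.** With coupling
  0.85 and realistic noise the adjusted-contrast SE at n ≈ 120 is ~50
  kcal/day, so per-seed quantities derived from the estimate (the
  per-10%-carbohydrate value, significance at deep nonadherence) fluctuate by
  ±10–30 kcal/day; only their seed-averaged behaviour is stable.

## Numerical choices

Compositions must sum to 1 within 1e-9; RQ/FQ accepted on [0.65, 1.05];
rescaling is exact under round trips to 1e-9. Cohort CSVs round-trip at 1e-6
on energies. The correlation structure is validated by Cholesky factorization
at configuration time. All estimators are deterministic given their inputs;
`run_all` produces byte-identical data products for identical config + seed,
with SHA-256 hashes in the manifest. Plots are optional and headless-safe;
CSV/JSON are canonical.
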