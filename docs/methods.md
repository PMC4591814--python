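# Methods

## The assay and its coordinate system

A translesion-synthesis (TLS) primer-extension assay anneals a short
5′-labelled primer (n0 nt) to the 3′ end of a longer template (here 30 nt)
whose position 17 from the 3′ end is the variable base X — an undamaged T,
a G (for misincorporation experiments), or a (5S)-thymine glycol (Tg).
Products are indexed N0..NK, with K = template length − n0 and product
length n0 + N. Because the template is shared, the lesion's N-index depends
on the primer: N3 for the 14-mer, N2 for the 15-mer, N1 for the 16-mer,
and n0 + lesion_N = 17 always. A 14-mer downstream oligo complementary to
the template's 5′-terminal block converts the X = T substrate into a
nicked substrate in which the advancing primer meets the downstream strand
at its very first insertion (nick_N = 1); synthesis beyond it requires
strand displacement. Sequences are stored 5′→3′; the constructor accepts
the template 3′→5′ behind an explicit orientation flag because protocols
print it in pairing order, and a silent reverse-complement mistake is the
classic failure mode here. Tg is modelled as an annotation on a T and
pairs as T, so damaged and undamaged substrates differ only in the
annotation.

## Generative model of processive extension

Each primer molecule holds a terminus j ∈ {0..K}. One polymerase
*engagement* from terminus j attempts insertions at j+1, j+2, …; each
attempt succeeds with the continuation probability s_i of that position
and the engagement ends at the first failure (dissociation) or at NK.
Engagements are memoryless: a later engagement resumes from the current
terminus with the same probabilities. The engagement count per molecule
over t minutes is Poisson(λt), λ being the engagement rate per molecule
per minute. This is the simplest mechanism consistent with a multi-time-
point design, and it has the property that motivates the assay's
short-incubation ("single-hit") regime: conditional on a single
engagement, the insertion statistic at Ni equals s_i exactly.

The continuation vector s is assembled from an `ExtensionProfile`:
`e_correct[i]` when the Watson–Crick dNTP for position i is present in
the reaction, `e_mis[i]` otherwise (single-dNTP reactions), and a
multiplicative `displacement_factor` ∈ [0,1] at positions at or beyond a
nick. `expected_length_distribution` computes the exact terminus
distribution by dynamic programming over engagements, mixing over the
Poisson count and truncating once the remaining tail mass is below 1e−12
(far below float accumulation error), then renormalising; it serves as
the analytic oracle against which the Monte-Carlo simulator is tested.

`simulate_lanes` draws per-molecule engagement counts, advances each
molecule by the single-engagement rule, tallies termini at unit amplitude
per molecule (absolute scale is irrelevant — every statistic is a ratio),
and applies a densitometry error model: each band is multiplied by
log-normal noise (σ default 0.05) and optionally incremented by
|Normal(background, background/3)|, clamped at zero. The error model is a
modelling choice of this package — published protocols do not specify a
densitometry error distribution — and multiplicative log-normal noise plus
a small additive floor is the standard first approximation for
phosphorimager quantification.

Default study conditions follow the assay design: incubation times 2, 4
and 6 min, two replicate lanes per time point (six lanes per condition),
all four dNTPs. The engagement rate λ is a free synthetic parameter (the
bench protocol fixes enzyme and substrate concentrations, not an
engagement rate); the default λ = 0.05/min keeps λt ≤ 0.3, the near-
single-hit regime the assay's statistics assume. Simulations in the test
suite use 2·10⁴–10⁵ molecules per lane, enough that binomial sampling
error is small against the 5% band noise.

The example profiles ("WT-like", "mutant-like") encode a processive
baseline continuation of 0.9 away from the lesion, misinsertion 0.005,
and lesion-step values chosen so that the single-hit statistics of the
damaged and undamaged arms reproduce the insertion/extension/bypass
pattern of a Tg-competent A-family polymerase and of a primer-grip mutant
whose bypass is about five-fold weaker: WT-like (0.296, 0.418) damaged vs
(0.729, 0.955) undamaged at the lesion and following step; mutant-like
(0.130, 0.190) vs (0.675, 0.959). These give single-hit bypass
efficiencies of ≈17.8% and ≈3.8%.

What the generator does *not* emulate: band-position calling errors and
gel smiling, untemplated terminal additions, intensity saturation,
spatially correlated background, or pipetting differences between time
points. Passing tests therefore validate the statistics and the inference
machinery under the stated noise model, not the robustness of
densitometry itself.

## The statistics and their conventions

All statistics are ratios of cumulative intensities cum(N) = Σ_{M≥N} I(M)
(see README for the definitions). Conventions that required a decision:

- **Bypass's denominator** is cum(N−1), which makes
  byp(N) = ins(N)·ext(N) an exact identity; this is the only reading of
  the definition consistent with its worked values.
- **Evaluation position** for lesion reporting is the lesion's N on both
  the damaged and the undamaged substrate — the only reading under which
  "insertion" means incorporation opposite the lesion.
- **Efficiency is a ratio of replicate means** (not a mean of per-lane
  ratios); its SD is first-order propagation
  eff·√((sd_d/μ_d)² + (sd_u/μ_u)²). A bootstrap alternative is provided
  in `recovery`; the two need not agree exactly at n = 6.
- **Aggregation pooling**: the default treats every lane as one
  observation; `pooling="by_experiment"` first averages time points
  within a replicate, then takes mean/SD across replicates. Both are
  defensible summaries of a 2-experiments × 3-time-points design; the
  pooled version is the default because it uses all lane-level
  variation.
- **Dispersion is the sample SD across lanes** (ddof = 1) and is labelled
  SD in all outputs.
- **Undefined statistics** (zero denominators) are `None`/NaN with a
  reason code, never silently 0. Bands beyond NK are rejected at load
  time rather than folded into the full-length band.
- **Percent formatting** (one decimal, round half up) happens only in
  reports; fractions are used internally.

## Parameter recovery

`estimate_profile` averages the per-lane insertion ratio at each
position; under the single-hit assumption (the default) this is exact on
conditioned single-engagement data. Two departures matter:

- **Position N1 under Poisson engagements.** The denominator cum(0)
  includes molecules never engaged at all, so the raw ratio measures
  P(leaving N0) = 1 − e^(−λt·s₁). With λt supplied, the exact inversion
  ŝ₁ = −ln(1 − f₁)/λt is applied. The inversion amplifies band noise by
  ≈1/λt, so recovering s₁ at λt = 0.1 to ±0.02 needs on the order of 24
  lanes (per-lane SD ≈ 0.04); the recovery simulations use that design.
- **Multi-hit bias at N ≥ 2.** Re-engagement gives dissociated molecules
  further chances, so insertion ratios at N ≥ 2 sit at or above s_i —
  about +0.01 at λt = 0.1, grossly inflated at λt = 5. The bias is
  surfaced (a warning fires when insertion at the lesion drifts upward
  with incubation time by more than 2 SD), not deconvolved: the remedy
  is the assay's own short-incubation design.

Positions whose mean cumulative signal fraction cum(N−1)/total falls
below 0.01 are flagged as unreliable and carry no interval: essentially
no molecules reach them, so their ratios are noise.

`bootstrap_efficiency_ci` resamples lanes with replacement independently
within the damaged and undamaged arms and takes the ratio of mean bypass
probabilities per resample (B default 2000, seed mandatory). The interval
is a *expanded percentile* interval: plain percentile intervals are
systematically too narrow at the lane counts this assay produces (six per
arm), so the quantile levels are widened by the Student-t/normal ratio at
n−1 degrees of freedom together with the √(n/(n−1)) variance inflation.
With six lanes per arm this moves empirical coverage at nominal 95% from
≈86–88% to ≈91–92%. Note the CI's estimand is the population value of the
lane statistic at the simulated engagement level — at λt = 0.1 that value
sits ≈5% (relative) above the single-hit product s_i·s_{i+1} because of
multi-hit bias, and the interval covers the former, not the latter.

`fold_change` reports the reference/variant efficiency ratio and its
nearest-integer fold; reciprocal pairs multiply to 1 on the raw ratio.

## Numerical and interface choices

Poisson-mixture truncation at 1e−12 tail mass; identities
(termination + extension = 1, bypass = insertion·extension, scale
invariance) hold to 1e−12 and are tested as properties. Lane CSVs store
absolute product lengths in nt (gels are read in nt) and are converted to
N-indices at load via the substrate registry; floats round-trip exactly
(`float_precision="round_trip"` on read, `repr` on write). Readers reject
invalid input with the offending row/field named. All randomness flows
through explicit seeds (`numpy.random.default_rng`); identical seeds give
bit-identical lanes and resamples.

## Known limitations

- The model has no nucleotide-level kinetics (k_pol/K_d), no pre-steady-
  state behaviour, and no pH dependence; λ is phenomenological and is not
  derived from enzyme:DNA ratios.
- Single-lesion templates only; multiple lesions per template are
  rejected.
- The N1 engagement correction assumes the Poisson engagement model is
  exact; model misspecification there propagates directly into ŝ₁.
- The bootstrap interval is calibrated for ≈6 lanes per arm; far smaller
  designs (2–3 lanes) remain anti-conservative even with expansion.
- Percent-extension comparisons across lanes assume equal loading; no
  loading normalisation is applied beyond the ratio structure of the
  statistics.
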