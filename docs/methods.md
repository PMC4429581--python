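# Methods

## Model structure and assumptions

The single cell is a two-compartment geometric object: a mother body and,
from START onward, a bud.  Both are treated as separate sphere-like
bodies whose volume scales as surface area to the 3/2 power.  The model
rests on four assumptions: (i) nutrient uptake is proportional to total
surface area; (ii) incorporation into biomass requires the internal
biosynthetic capacity `B_R` and is diluted by volume, so all synthesis
fluxes carry `B_R · A/V`; (iii) transcription of the two cyclin mRNAs is
stochastic (Bernoulli one-molecule bursts per minute) and confined to the
phase whose transition the cyclin drives — `mCLN` to G1, `mCLB` to G2 —
as is translation of the corresponding protein; (iv) phase transitions
are zero-order-ultrasensitive thresholds on cyclin molecule number, with
S phase and mitosis as fixed delays.  There is no explicit CDK network
(no Whi5, Swe1 or APC switches), no spatial bud mechanics and no
resource competition between cells; cells never die.

As a cell enlarges, `A/V = A^{-1/2}` falls, so biosynthesis per unit
volume declines and cyclin accumulation slows.  Since reaching the START
threshold requires `B_R · A/V` to grow into a fixed window set by
`threshold · k_d / (k_p1 · E[mCLN])`, small newborn daughters wait long
in G1 while larger mothers re-enter S quickly: a growth-rate-dependent
sizer emerges without any explicit size set-point.  The two variants
differ in one term of the Clb production flux: model1 integrates the
whole cell's capacity at the G2/M transition, model2 multiplies the flux
by the bud volume fraction `V_d/V`, so that only the bud's share of the
biosynthetic capacity is measured (bud sizer).  A
`clb_localization` fraction `f` interpolates between the two
(`φ = (1−f) + f·V_d/V`); `f = 0` makes the model2 engine bit-identical
to model1, which the test suite uses as an exact cross-check.

## Volume units

Only the proportionality `V ∝ A^{3/2}` is physically meaningful.  The
closure constant `c` in `V = A^{3/2}/c` multiplies every production flux
through `A/V` and is mathematically equivalent to rescaling `growth`,
`k_p1` and `k_p2` by `c`; the calibrated rate constants therefore fix
`c = 1`, and all volumes are reported in the model units `V = A^{3/2}`.
With any other closure (e.g. a literal sphere constant) the published
rate constants would leave their own calibration ranges and the sizer
regime would not be reachable.

## Numerical scheme

Forward Euler with `dt = 1 min`.  Within a step: transcription burst
(applied before the decay of the same step), mRNA decay
`×(1 − k_d·dt)`, cyclin update using the post-transcription mRNA,
biomass update, then the area increments are identified with the
structural biomass increments.  Transitions are checked once per step at
the new time with strict `≥` comparisons, so durations have one-minute
granularity; at most one transition fires per cell per step.  Threshold
crossings record START time and volume; completed mitoses are processed
in cell-id order after the step.  Halving `dt` moves a deterministic G1
duration by well under 2% (test-pinned).  Cyclins are not reset at
transitions or division: they decay with `k_d` (half-life ≈ 7 min) and
are split at division like all soluble species.

The population engine advances every live cell with the same global
clock.  One uniform-random array per step is drawn from a single seeded
generator, with cells in creation (id) order; a numba-compiled kernel
and a pure-Python per-cell reference engine consume the same stream and
produce bit-identical populations (test-pinned), so runs are reproducible
from `(parameters, condition, n_final, seed)` alone.  The progenitor is
a newborn-sized G1 cell (`A_m = 10`, `B_R = 1`, empty mRNA and cyclin
pools); the population attractor is reached within a few generations, so
this choice only shapes the initial transient.  The stop census counts
live cells after divisions are processed.

## Parameters

Best-fit presets (`model1-bestfit`, `model2-bestfit`) carry the published
calibration: `growth` 0.028/0.029 (glucose), `k_p1` 0.452/0.589,
`k_p2` 0.342/1.606, `k_R(G1)` 4.92/4.098, `k_R(S-G2-M)` 1.495/1.04, and
shared structural parameters `k_d = 0.1 min⁻¹`, `P_x = 0.4 min⁻¹`,
threshold 150 molecules, S = 25 min, M = 5 min, `m_BR = m_BA = 1` (any
other constant only rescales `growth`).  Nutrient conditions multiply
`growth`: galactose 0.77, raffinose 0.6, ethanol 0.5.  The *OE-CLN*
mutant doubles the CLN burst probability (0.4 → 0.8 min⁻¹), capped at
one burst per step.

## Statistics conventions

Population standard deviations (`ddof = 0`) throughout.  Cycles starting
at replicative age 0 are daughter cycles, age ≥ 1 mother cycles; phase
means are taken over all completed cycles of a culture.  "Relative
variability" of cell size is the standard deviation of log2-transformed
volumes of the final live population — scale-invariant, and on the
binary-log scale natural for doubling-based size distributions (ratios
and orderings are independent of the base).  Growth rates are volume
differences over phase durations; sizer regressions are ordinary least
squares.

## Fitting

Five parameters (`growth`, `k_p1`, `k_p2`, `k_R(G1)`, `k_R(S-G2-M)`) are
estimated inside their calibration boundaries by minimising
`wRSS = Σ((x−x̂)/σ)²` over per-condition daughter-cell summaries (mean
G1 duration, budded-phase duration, birth volume, budding volume —
means only; σ enters purely as a weight).  `ln L = −(m/2)ln 2π − Σln σ −
wRSS/2` and `AIC = −2 ln L + 2K` (K = 5) rank the variants.  Where an
experimental G1 target is reported as separate time-at-START and
START-to-budding intervals, the two are summed and their uncertainties
combined in quadrature (`combine_g1`), since the model does not resolve
budding separately from START.

The optimiser is a (μ+λ) evolution strategy — population 12, truncation
selection of the best 6, uniform crossover, Gaussian mutation with scale
10% of the boundary width, clipped to the boundaries, multiple uniform
restarts.  The exact operator set is this package's own design; its
validation surface is the convergence of the objective across restarts
and closed-form optimisation checks in the test suite.  Every candidate
is scored with one fixed simulation seed (common random numbers), making
the stochastic objective quasi-deterministic.  Because the reference
experimental tables are not available numerically, fitting is exercised
as parameter recovery against synthetic targets generated by forward
simulation; at desk scale (1,000-cell cultures, 10 restarts, 6
generations) the generating growth rate is recovered within a few
percent and the generating variant wins the AIC ranking.

## Problem sizes

Default study sizes: population statistics on 10,000-cell cultures
averaged over three seeds; mutant and nutrient phenotypes on 5,000-cell
cultures; fitting and recovery on 1,000–2,000-cell cultures.  A
10,000-cell culture takes well under a second after JIT compilation.

## What the simulations do and do not show

The synthetic cultures emulate asynchronous exponential growth from one
progenitor under constant nutrient conditions.  They do not emulate
measurement noise, cell death, replicative ageing beyond pedigree
counting, chemostat dynamics or mother-specific physiology, so passing
tests validate the model's internal logic and its published population
statistics, not agreement with any new experimental data.

Known limitations: with full bud localisation the model2 budded phase
under slow growth (ethanol) runs ≈ 10 min longer than the reference
values (mothers ≈ 113 min vs 103, daughters ≈ 106 vs 98) while model1
matches its reference values to about a minute in both conditions and
model2 matches on glucose; the qualitative structure (equilibrated
mother/daughter budded phase on glucose, a mother-longer trend on
ethanol) is reproduced.  The mother/daughter budded-phase gap in model2
on poor media is sensitive to the assumed 100% localisation; lowering
`clb_localization` to ≈ 0.9 shrinks it, as expected from partial mother
translation.  G1-sizer regressions are stronger (R² ≈ 0.9) than observed
in vivo, reflecting the absence of downstream feedback and measurement
noise.
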