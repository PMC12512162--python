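# Methods

`meatshift` simulates how repeated government campaigns could move a
population's meat consumption towards the UK Climate Change Committee (CCC)
reduction targets (−35% and −50% of mean meat intake), using a
continuous-time Friedkin–Johnsen (FJ) opinion-dynamics model on a synthetic
population calibrated to the marginal structure of the UK National Diet and
Nutrition Survey (NDNS) 2019 adult sample.

## Opinions and agents

Each agent i holds a meat opinion x_i ∈ [0, 1]: the desired fraction of meat
energy within their total daily energy E_i from the four modelled food groups
(meat, meat alternatives, pulses, vegetables).  The baseline opinion is
x_i(0) = (meat kcal)/E_i, so x = 0 identifies vegetarians and x = 1
carnivores.  Stubbornness follows diet class: vegetarians have λ = 0 (no
social susceptibility) and γ = 0 (no external susceptibility) — they keep
their habits throughout; carnivores have λ = 0 but remain exposed to external
influence; omnivores have λ = λ_omnivore.

**λ_omnivore** (default 0.5, configurable per roster): the weight omnivores
put on peer pressure versus their own prejudice.  Published work using this
model family on this survey fixes λ in supplementary material we treat as a
calibration input; 0.5 — an even split between social and inertia forces —
is our declared default, and `read_roster(..., lambda_omnivore=...)` accepts
any other value, including externally supplied heterogeneous values by
editing the roster's `lambda` column after load.

## Social network

Agents are connected in a complete weighted undirected graph with kernel
weights w_ij = exp(−α·|Δage bin| − β·|Δses rank|), α = β = 1 by default,
distances measured on ordinal bin indices (5 age bins, 3 SES ranks).  The
kernel is 1 for identical attributes and exp(−6) at maximal distance.  The
dynamics consume the row-normalized matrix A.  The exact weight function used
with the original survey data is not public; the kernel and its decay rates
are therefore an explicit calibration surface.

## Dynamics and campaigns

Within a campaign, opinions follow the continuous-time FJ equation

    dx_i/dt = λ_i Σ_j A_ij (x_j − x_i) + (1 − λ_i)(u_i − x_i),

with prejudice vector u fixed.  The box [0,1]^n is forward invariant.  A
campaign runs until the sup-norm weekly change drops below `tol` (default
1e−4), the model's operational definition of stationarity.

Between campaigns the external entity (a virtual agent connected to
everyone, exerting effort γ_i ∈ [0, γ̄] on agent i) refreshes prejudices as a
trade-off with the external opinion s_i:

    u ← (1 − γ) ⊙ u_prev + γ ⊙ s,    u_prev(campaign 1) = x(0).

The chain is on prejudices: each campaign blends the *carried prejudice* with
s, so u approaches s geometrically at per-campaign rate γ_i.  We deliberately
do not re-anchor prejudices at the previous campaign's stationary opinions:
doing so makes partially stubborn agents forget their baselines, and the
iterated FJ map then collapses the population onto the fully stubborn agents —
the mean meat intake falls by tens of percent even with γ ≡ 0, every
reduction target is eventually "met" by a government that did nothing, and
the strong dependence of time-to-target on the γ distribution disappears.
With the prejudice chain, γ ≡ 0 leaves the network at its ordinary FJ
equilibrium indefinitely, opinion heterogeneity persists across campaigns,
and halving γ̄ scales the time-to-target by roughly the expected geometric
factor (≈1.7 in our runs).

**External opinion s_i** (default `per_agent_ceiling`): s_i = min(1,
d_kcal/E_i), where d_kcal = (1 − target) × baseline mean meat energy is the
population ceiling (≈131 kcal/d for −35%, ≈101 kcal/d for −50% on a
≈202 kcal/d baseline).  Agents whose total energy is below the ceiling are
simply not asked to reduce.  Note the asymptotic population mean equals the
mean of min(E_i, d_kcal) over externally susceptible agents; the targets are
attainable because vegetarians (γ = 0, anchored at zero) hold the mean
strictly below the ceiling.  A `global_zero` mode (s ≡ 0) is kept for
limit-case testing.

**Integration**: classical fixed-step RK4 with dt = 0.25 week.  Because the
within-campaign dynamics is linear time-invariant, the four RK4 stages
collapse into a fixed affine step, and one week of integration is precomputed
as a dense propagator pair (P_week, S_week) that depends only on (A, λ, dt).
Stepping a week is then a single matrix-vector product, identical to naive
RK4 stepping up to float roundoff (tested to 1e−12), and the propagator is
reused across campaigns, scenarios and sweep cells on the same roster.  This
is what keeps full-population (n = 1841) multi-decade runs to seconds.

**Time accounting**: 1 simulated week is the unit; target attainment is
recorded only at campaign ends (the cadence at which the policymaker observes
the network).  The default horizon is `max_weeks` = 1560 (30 y); slow
scenarios (low broadcast influence at −50%, small-μ sweep cells) are run with
a 3120-week horizon — a run setting, not a model change.

## External-influence scenarios

* `broadcast`: γ_i = γ̄ for all agents; γ̄ = 0.025 (high influence: fiscal
  measures plus information campaigns) and γ̄ = 0.0125 (low influence:
  information only).
* `uniform_random`: γ_i ~ U[0, γ̄].
* `trunc_normal`: γ_i ~ N_[0, γ̄](μ, σ), σ = 0.2 γ̄ by default, sampled by
  inverse CDF on the truncated support so draws are exact and reproducible
  even for means deep in a tail.
* `trunc_normal_sorted`: the same sample, assigned by rank of baseline meat
  opinion — `high_meat_first` gives the largest efforts to the heaviest meat
  eaters, `low_meat_first` the reverse.  Ties in x(0) are broken by ascending
  agent id (the tie rule is otherwise arbitrary and documented here).

Vegetarians' γ is forced to 0 after assignment in every mode.  Carnivores are
sampled like any other agent in heterogeneous modes (nothing distinguishes
them to the sampler); their stubbornness is purely social (λ = 0).

The sensitivity sweep runs a (mode, μ, replicate) grid with per-cell seeds
spawned from a single master seed.  Our default grid is 5 values of
μ/γ̄ ∈ {0.25, 0.4, 0.55, 0.7, 0.85} with 5 replicates per cell (scaled down
from a 19-point × 500-sample design): below μ ≈ 0.25 γ̄ the target is not
reached within the 3120-week horizon under the default calibration, which
would tie cell medians at the not-reached sentinel and void the monotonicity
comparison the sweep exists to make.

## Synthetic population

The generator emulates the NDNS 2019 adult extract: n = 1841; 129
vegetarians, 31 carnivores, and 436 "zero-substitute" agents (meat only, or
meat and vegetables only) as configurable rates; sex-stratified marginal
means/SDs of daily intake in grams for the four groups (male meat
129.9 ± 84.5 g/d, female 91.6 ± 64.9 g/d, etc.).  Diet classes are drawn
first and impose the structural zeros; positive intakes are gamma draws
moment-matched so the zero-inclusive marginals hit the configured targets.
Age (5 bins), SES (3 levels) and sex are drawn independently from configured
marginals — the survey's joint distribution is not public, and the published
histograms do not pin the exact age/SES proportions, so the defaults are
plausible UK adult marginals (documented in `PopulationConfig`).  Energy
densities convert grams to kcal: meat 1.87 kcal/g (the value implied by the
printed target ceilings, 131 kcal = 70 g), alternatives 1.50, pulses 1.10,
vegetables 0.35.  Agents with zero total energy are redrawn (their opinion
would be undefined).

What passing tests on this population do **not** show: fidelity to the
survey's joint attribute–intake distribution, to its exact opinion
distribution (only the marginals are matched), or to the original study's
unpublished λ/kernel/tolerance calibration.  Week counts should therefore be
read as internally consistent model output of the right order of magnitude,
not as a reproduction of the published 270/420/495/765-week figures; those
require the original roster and calibration supplied as inputs
(`read_roster`, `read_impact_table`, `lambda_omnivore`, kernel and tolerance
options — the pathway exercised in the external-data test).

## Consumption allocation

Meat energy is x_i E_i; energy freed by reduction, (x_i(0) − x_i) E_i, is
added to the three substitute groups in fixed per-agent shares, so the
four-group energy E_i is conserved exactly at every time point.  This is the
only closed-form choice consistent with defining the opinion as a fraction of
the four-group energy.  `baseline_strict` shares are proportional to baseline
substitute energy (meat-only agents send everything to vegetables);
`baseline_flexible` (default) additionally lets the zero-substitute agents
adopt some alternatives and pulses, with shares defaulting to the
population-mean substitute composition among agents who reported substitutes
— a 4-day diary can miss foods eaten at weekly cadence.  The two modes agree
exactly for agents with positive baseline alternatives-plus-pulses.  Opinion
*increases* are clamped at baseline and flagged; the modelled campaigns only
push meat downward.  Grams are recovered with each agent's own baseline
kcal-per-gram density, falling back to the population density table for
groups the agent did not consume at baseline.

## Environmental impacts

Impacts are linear: metric = Σ_g grams_g/100 × factor_{g,metric}, for
greenhouse gases (kg CO₂-eq), land (m²), blue water (L) and scarcity-weighted
water (L).  Population changes are percent changes of population totals, not
means of per-agent ratios.  The shipped factor table is synthetic (the
original per-100 g factors are not public): values chosen so a typical adult
diary's baseline daily impacts land in the published range (≈3.2 kg CO₂-eq,
≈6.9 m², ≈203 L, ≈5400 L for males) and so meat dominates per gram on every
metric — most strongly for greenhouse gases and land, least for blue water,
where pulses and vegetables carry sizeable irrigation demand.  Any analysis
that needs defensible impact numbers must supply its own table
(`read_impact_table`).

## Metrics

* **Time-to-target**: smallest campaign-end week with relative mean change
  ≤ −target; the explicit `NOT_REACHED` sentinel otherwise (encoded as `inf`
  in sweep tables so medians stay order-preserving).  A zero target is
  satisfied at week 0.
* **Adopters**: fraction of agents with meat energy strictly below the
  ceiling ("less than" read strictly); vegetarians always count.
* **Relative changes**: population series normalized to baseline; individual
  series exclude zero-baseline agents.
* Reports stratify consumption by sex at baseline and at the target week.

## Numerical choices and degenerate inputs

* `tol` = 1e−4 (sup-norm weekly change) declares stationarity; the
  campaign-end state then sits within a small multiple of tol of the exact
  linear fixed point (verified against a direct solve on hundreds of random
  instances; the bound degrades as max λ → 1, so oracle tests draw λ ≤ 0.85).
* RK4 with dt = 0.25 week on a system whose rate matrix has norm ≤ 2 is far
  inside the stability region; weekly states are clipped to [0,1] to absorb
  roundoff at the box boundary.
* Campaigns that fail to converge within the remaining horizon are flagged in
  `SimulationResult.unconverged_campaigns`, not fatal.
* Zero-degree network rows (impossible with the default complete kernel) get
  zero influence rows rather than NaNs.
* Rosters reject rows with negative or non-numeric intakes and unknown labels
  (hard errors listing rows), and drop rows with missing sex/age/SES or zero
  total energy (warning naming the rows), mirroring survey exclusion rules.

## Known limitations

* The network is static and complete; no rewiring, sparsification, signed or
  antagonistic ties.
* One-dimensional opinions; substitution is confined to the four-group
  basket and total basket energy is held fixed per agent.
* No stochastic opinion noise; all randomness enters through the population
  draw and the γ assignment.
* Budget-constrained campaign planning and health-impact modelling are out of
  scope.
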