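# Model and methods

`ibsem` is an individual-based eco-genetic simulator of a single Atlantic
salmon (*Salmo salar*) river population and its adjoining sea phase.  Every
fish is an explicit individual with sex, life phase, freshwater and sea age,
fork length, weight, maturity state, origin tag, and a diploid multi-locus
genotype.  The model advances in monthly steps through a fixed annual
calendar and is used to study how gene flow from escaped farmed salmon
changes the demography and genetics of a wild population over decades to
centuries.

## Life-history calendar

Time is discrete with a one-month step.  The year divides into a warm growth
season (March–October) and a resting season (November–February).

* **1 January** — oceanic adults gain one sea winter (sea age capped at 3SW).
* **1 April** — eggs hatch and emerge as alevins; the compound egg-to-
  emergence mortality is applied at this moment.
* **1 May** — alevins become young-of-the-year parr (p0), parr ages
  increment (p0→p1→p2, p2 is terminal "older"), and smolts migrate to sea as
  0SW post-smolts.
* **October** — at the start of the month male parr decide maturation
  (maturing parr forgo the month's growth, reflecting gonad investment); at
  the end of the month: adults decide whether to return and enter the river,
  5 % of the returners are exchanged for immigrant strayers, farm escapees
  (if scheduled) join the pool, the spawner census is taken, mature male
  parr suffer pre-spawning mortality, spawning creates the egg cohort,
  spawned adults survive as kelts with probability 0.1 and re-join the sea
  population, and every parr decides whether to smolt next May.
* **1 November** — parr flagged in October enter the smolt sub-phase
  (November–April), growing at a reduced rate through winter.

Within a month the operation order is fixed: begin-month calendar events →
temperature draw → growth → mortality → end-month calendar events.  An
individual-count ledger (births + immigrants − deaths − emigrants) must
balance at every step and is checked in the tests.

## Environment

Two variables describe the physical setting: the river area (default
250 000 m², chosen so the initial 600 000 young-of-the-year correspond to
2.4 fish/m²) and monthly mean water temperatures for the river and the sea,
with optional Gaussian inter-annual noise (on by default).  The shipped
temperature tables are a plausible western-Norway river profile and a
Norwegian-Sea SST climatology; both are plain config entries.  River and sea
draws are independent, as are draws across months and years.

## Genetics

Each fish carries three independent sets of 21 diploid biallelic loci, one
set per main life phase (embryonic, juvenile, marine/adult).  Allele `1` is
the wild variant, `0` the farm variant.  Effects are additive with an
exponentially declining per-locus weight, `w_i ∝ exp(−λ(i−1))` with λ = 0.3
for loci 1–20; locus 21 carries zero weight and serves as a neutral marker
for tracking introgression.  Weights are normalised so the all-wild diploid
genotype scores exactly S = 1 and the all-farm genotype S = 0; consequently
the expected S of a freshly drawn genotype equals its wild-allele frequency,
which makes the headline statistics insensitive to the precise λ.  Wild fish
are initialised at frequency 0.9, farm fish at 0.1, immigrant strayers at
0.8.  Inheritance is Mendelian with free recombination (loci independent);
there is no mutation, dominance or epistasis.  Sex is assigned at birth with
probability ½ and lives on the individual, not the genotype.

Genotype enters the rates through linear modifiers anchored at the wild
endpoint S = 0.9: survival factors `1 + g·scale·(S − 0.9)` (wild survive
better) and growth factors `1 + g·scale·(0.9 − S)` (farm fish grow faster).
The global `fitness_differential_scale` multiplies every genotype gain, so
the wild–farm gap can be halved (0.5), doubled (2.0) or switched off (0 —
used as a neutrality oracle in tests).

The shipped gains (embryonic survival 0.20 one-shot, juvenile survival 0.03
per month, marine survival 0.04 per month, growth 0.15, sea-age-at-return
shift 0.35) deserve comment, because monthly modifiers compound over a
3-6-year life.  A pure-farm founder population is only demographically
viable if its lifetime fitness stays above roughly a tenth of the wild
value (the ceiling set by the density compensation available at low
abundance), which bounds how strong the per-month survival gains can be;
conversely, very strong gains are what would let the doubled-differential
scenario repel heavy escapee gene flow outright.  The shipped values sit on
the viability side of that trade-off: a farm-initialised population
persists and evolves back towards the wild genotype under straying and
selection, at the cost of introgression resistance that saturates under
the heaviest escapee pressure (see limitations).

## Growth

* **Embryonic.** Alevin length at emergence is linear in egg weight plus
  Gaussian noise (defaults calibrated so mean emergence length is 23 mm).
* **Freshwater (parr, smolt).** Monthly weight increment
  `a · W^b · f(T) · g(ED) · h(S) · (1 + ε)` with b = 0.85, multiplicative
  Gaussian noise ε, and a hard temperature window (2–22 °C) combined with a
  linear ramp inside it (parr ramp 7–12 °C, which makes March–April growth
  negligible in the cold early spring, matching the observation that parr
  lengths barely change between November and May).  The density factor
  `g(ED) = 1/(1 + 0.5·ED)` applies to parr only; smolts grow all winter at a
  reduced rate through their own coefficient and a gentler ramp (0–10 °C).
  The coefficients `a` decline with age within the phase.  Length follows
  weight through a condition-factor cubic `W = c·L³` (c = 1.05·10⁻⁵ g/mm³ in
  freshwater, 1.22·10⁻⁵ at sea, fitted from the joint length/weight targets)
  and never decreases.
* **Marine.** Monthly von Bertalanffy length increment
  `κ(sea age) · (L∞ − L) · f(T) · h(S) · (1 + ε)` with L∞ = 1100 mm.  A
  decelerating-in-length form is required here: compounding an unbounded
  allometric weight rule at a monthly step lets long-lived repeat spawners
  grow without limit, whereas the asymptote caps adults near the observed
  maximum (~17 kg).  The κ per sea age are solved analytically from the
  target size-at-age path and then trimmed against simulated censuses
  (size-selective marine survival biases realized means upward).

## Mortality

All mortality is applied as monthly Bernoulli draws (`r < m` kills) on
probabilities clamped to [0, 1] after every modifier.

* **Egg → emergence** (applied once on 1 April):
  `survival = (s₀ + s₁·egg_size) · exp(−k·egg_density) · φ(S_emb)` — linear
  in egg size, exponentially decreasing in egg density (eggs/m², the main
  compensatory mechanism), reduced for farm genotypes.  The alevin month
  carries a small fixed mortality.
* **Juvenile.** Seasonal monthly baselines per parr age (warm > resting,
  decreasing with age), multiplied in the warm season by a density factor
  `exp(−c_age·ED)` where ED is the mass-weighted effective parr density
  `Σ(W/W_ref)^γ / area` (γ = 1, W_ref = 2.9 g ≈ mean autumn p0 weight).  In
  March–April parr are eleven months past emergence and about to be
  promoted, so the next age class's baseline applies — without this the
  over-winter survival of young-of-the-year is roughly halved relative to
  the reference censuses.  Smolts use one baseline in all six months of the
  sub-phase and no density term.
* **Marine.** `m = (m_inf + A·exp(−L/L_s)) · k(sea age)` with a
  deliberately shallow length scale (L_s = 250 mm) and a post-smolt (0SW)
  age multiplier k ≈ 2.7 that carries the heavy first summer at sea;
  survival is scaled by the genotype factor.  The three constants are
  solved jointly against the survivorship targets (first-summer post-smolt
  survival ≈ 4.6 %, first and second full sea-year survivals) along the
  expected growth path, then trimmed iteratively.  The shallow length
  dependence is a deliberate design choice: if the ~95 % first-summer kill
  were steeply size-selective, any heritable growth advantage would
  overwhelm every other fitness difference at sea and farm alleles would
  become net-advantaged, inverting the evolutionary attractor; letting the
  0SW filter act mostly through the age class keeps it demographically
  heavy but only mildly size-selective.

## Maturation, smolting, reproduction, straying

Male parr maturation in October is a logistic in fork length (midpoint
~107 mm, steepness 9 mm — fitted so that at equilibrium sizes roughly 40 %
of p1 and 90 % of p2 males are mature); males that matured the previous
season get twice the probability, capped at one.  Adults return at a fixed
per-sea-age baseline probability (0.50 / 0.88 / 1.0 for 1SW/2SW/3SW —
calibrated so the spawner pool is grilse-dominated with the right sea-age
mix and total egg deposition), shifted down for farm genotypes (delayed
maturation); 0SW fish never return and 3SW fish always do.

The smolting decision at the end of October is zero below the 90 mm
threshold and otherwise logistic in length with exactly 50 % at 103 mm
(steepness 3 mm, set to reproduce the observed smolt/parr split and the
smolt length distribution).

Reproduction: each female's mean fecundity and egg weight are linear in her
body weight (the classic Norwegian regressions; the shipped slope ≈ 1.8
eggs/g emerged from calibrating egg deposition to ~7 eggs/m²), with realized
values Gaussian around the means.  Each female is paired with up to 2 adult
males and up to 5 mature male parr; the parr-fertilised fraction is drawn
per female from a truncated Gaussian (30 % ± 10 %).  Mates are sampled
weight-proportionally without replacement and egg shares within each pool
are proportional to weight; a deterministic largest-male rule was rejected
because with a realistic spawner pool (tens of fish, fewer at desk scale) it
funnels every egg through the same sires and erases the standing genetic
variation the model is supposed to carry.  Farmed escapees compete with
their weight multiplied by 0.33 (reduced spawning success).  Mature male
parr suffer a pre-spawning mortality drawn uniformly from [0.2, 0.4] each
year; spawned adults die with probability 0.9, survivors re-join the sea as
kelts flagged as previous spawners.

Straying exchanges 5 % of the natural returners (round-half-even) for
immigrants that copy the outgoing fish's phenotype and carry a fresh
genotype at wild-allele frequency 0.8 — or, in mirror mode (sensitivity
scenarios), at the outgoing fish's own frequency, which preserves allele
frequencies in expectation while still injecting diversity.  Straying is
applied before escapee injection, and only natural returners stray.

## Scenarios

1. **Wild equilibrium** — 100 years settling + 100 years monitoring,
   10 replicates (3 at desk scale).
2. **Attractor test** — identical, but every founder carries a farm
   genotype (wild-allele frequency 0.1); monitored for all 200 years.
3.–5. **Introgression sensitivity** — 50 years settling, 200 years with
   escapees added to the spawner pool every October (25 / 100 / 250 per year
   at full scale ≈ 5 / 20 / 50 % of the equilibrium spawner pool), then 200
   years of recovery; wild–farm differential at ×1 / ×0.5 / ×2; strayers in
   mirror mode.

Initialisation (May): 600 000 p0 at 23 mm, 30 000 p1 at 65 mm, 30 000 p2 at
100 mm, no smolts, 1 000 adults spread uniformly over 0SW–3SW at
140/560/670/800 mm.

**Desk scale.**  A single scale factor multiplies the river area, all
initial abundances and the escapee numbers, preserving every density.
Because the density-dependent feedbacks operate on densities, the dynamics
are scale-invariant to first order; the tests and the acceptance script run
at 1/25 scale (10 000 m², ~10⁵ individuals peak) with 3 replicates for the
equilibrium scenario and 1 replicate for the long sensitivity scenarios,
which keeps a full 200-year replicate under a minute on one core.  Residual
small-sample effects at this scale are visible mainly in the spawner pool
(~15 fish per year), which widens year-to-year fluctuations but leaves the
pooled 100-year means intact.

## Monitoring and heritability

The sampling calendar follows the field surveys: parr on 1 May and
1 November, smolts on 1 November and at the end of April, oceanic fish at
the end of September, spawners at pool formation in October, eggs right
after spawning.  Summary tables report the within-replicate over-years mean
and SD averaged across replicates, with pooled minima and maxima.

Heritability of fork length is emergent, not prescribed.  Each fish records
its own fork length at its first 1-November census as young-of-the-year;
eggs store the midparent value of that reference length.  Each year h² is
estimated as the slope of offspring-on-midparent regression over that
year's young-of-the-year (minimum 100 complete pairs), clamped to [0, 1]; a
single-parent variant (slope doubled) is available.  With the shipped noise
levels the emergent h² of fork length is of order 0.1: the additive variance
at the equilibrium allele frequencies is small next to the environmental
variance accumulated over a growth season, so the estimate mainly documents
that genetic variance persists, and its magnitude should not be read as a
field-calibrated value.

## Calibration

The supplementary constants behind the reference river statistics are not
part of this implementation's inputs, so defaults are fixed by the shipped
two-stage procedure (`ibsem calibrate`, `src/ibsem/calibrate.py`):

1. *Analytic stage* — marine κ from the size-at-age path; the marine
   mortality floor, size amplitude and post-smolt age multiplier jointly
   from the three survivorship targets along that path; the egg-density
   slope from the target egg-to-emergence survival (0.336) at the target
   egg density (7.3 eggs/m²).
2. *Iterative stage* — short desk-scale runs (45 years, 15-year window)
   drive damped multiplicative updates of the parr growth coefficients,
   seasonal survival baselines, smolt coefficient, maturation midpoint,
   fecundity slope and small marine corrections, each against its own census
   observable; an update that destabilises the population is reverted with a
   smaller step.
3. *Long-run trim* — the slow observables (equilibrium egg deposition, the
   pooled 1-November juvenile density, maturity fractions) settle over
   decades and inherit a few-percent bias from the short windows, so a last
   pass measures 150-200-year equilibrated runs and nudges their dedicated
   knobs (fecundity slope, maturation midpoint, the p1/p2 baselines, the
   egg-density slope and the adult return probabilities) once against those
   long-run values.

The resulting overrides are versioned in
`src/ibsem/data/default_config.yaml` and are what every test and the
acceptance script use; the shipped file is the final state verified against
full 200-year, 3-replicate runs.

## Numerical choices and degenerate inputs

Probabilities are clamped after every modifier; growth increments truncate
at zero; egg counts round to non-negative integers; Gaussian shares truncate
to [0, 1]; straying counts use round-half-even.  Empty mate pools yield zero
eggs (logged condition, not an error).  Random numbers come from independent
`numpy` `SeedSequence`-spawned streams per replicate and per process
(environment, growth, mortality, reproduction, genetics, initialisation), so
a master seed reproduces a run bit-for-bit and replicates are independent.

## Known limitations

No river flow, angling, sea-lice mortality, mutation, linkage, dominance,
spatial habitat structure, or phenology shifts; temperature is the only
fluctuating environmental driver, which understates year-to-year variability
relative to real rivers.  The synthetic environment and the calibrated
constants emulate one well-studied river; transferring conclusions to
another river requires re-running the calibration against that river's
censuses, and passing tests here demonstrate internal consistency with the
reference statistics, not predictive skill for any particular real
population.

Two limitations of the shipped parameterization deserve emphasis.  First,
at desk scale the spawner pool is ~15 fish, so the effective population
size is tiny and the long-run genetic trajectories (for example a
farm-initialised population's return to the wild genotype) are strongly
drift-dominated: individual replicates scatter widely around the mean
trend, the per-gene-set convergence order is not reproducible
replicate-to-replicate, and the approach to the wild attractor is slower
and noisier than the same experiment at full river scale.  Second, the
wild–farm survival gains are bounded above by the viability of a pure-farm
founder population (see the genetics section); as a consequence, under the
heaviest escapee pressure (50 % of the spawner pool, every year, for two
centuries) the gene pool saturates near the farm composition at both the
standard and the doubled differential, and the halved/standard/doubled
ranking of final introgression is then only weakly resolved.  Within a
single simulation the directional effects — depressed native returns
during gene flow, persistent depression afterwards, stronger purging at
larger differentials during recovery — are robust.
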