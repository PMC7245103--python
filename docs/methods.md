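# Methods

`moblue` is a stochastic kinetic model of how giant molybdenum-oxide
clusters — the {Mo36} wheel precursor, the {Mo132} Keplerate ball and the
{Mo154} molybdenum-blue wheel — self-assemble from an acidified, partly
reduced molybdate pot, together with the analysis layer used to
characterize the model's behaviour and a small structural registry. This
note records the model, its assumptions, the shipped parameter values, and
what the synthetic experiments do and do not show.

## Coarse-grained state space

Molecules are tracked by nuclearity (number of Mo centers) only, with two
exceptions that carry structural identity:

* nuclearity 2 splits into the corner-shared dimer {Mo2c} (fully oxidized,
  a wheel constituent) and the edge-shared reduced dimer {Mo2e} (a ball
  constituent);
* intermediates on the assembly path to a giant carry a lineage tag
  (`corner_dimer_path` toward {Mo154}, `edge_dimer_path` toward {Mo132})
  because the two dimers play different structural roles in the two giants.

All other species of a given nuclearity are represented by a single
generic species. Reactions are reversible and elementary: bimolecular
synthesis `A + B -> C` and unimolecular degradation `C -> A + B`. Mo mass
(sum of nuclearity x count) is exactly conserved by every reaction and is
asserted on every sampled trajectory.

## Assembly routes

The species space alone does not determine which of the combinatorially
many aggregation routes exist; the published account gives the building
blocks and the catalytic relationships but no intermediate-level map, so
the route structure below is this package's explicit surrogate. It was
chosen so that the blocks, the templation links, and the qualitative
outcomes match the described chemistry:

* **oxidized condensation chain** — monomers dimerize into {Mo2c}/{Mo2e};
  corner dimers condense into small oligomers (2c+2c -> 4, 4+2c -> 6) and
  hexamers assemble the template (6+6 -> 12 -> 18 -> 24 -> 30 -> 36).
  {Mo36} is therefore an all-hexamer condensate, and {Mo6} is a dedicated
  structural block that amorphous material never absorbs. The reduced
  dimer takes part in no oxidized chemistry.
* **giant paths** — each giant nucleates by capturing a template:
  {Mo36}+{Mo6} opens the wheel path (the wheel grows around its template,
  as in the host–guest {Mo36}⊂{Mo150} structure), and {Mo36}+{Mo2e} opens
  the ball path. Path intermediates follow a canonical build sequence —
  the wheel is hexamer-fed with two corner-dimer closures
  (36 + 6 + 18x6 + 2x2 + 6 = 154), the ball is a pure reduced-dimer ladder
  (36 + 48x2 = 132) — and each intermediate admits exactly the next
  addition of its sequence. The terminal step yields the giant.
* **amorphous aggregates** — seeded by chance collisions of small
  oligomers and growing by monomer accretion (any generic pair may combine
  in the all-pairs mode used for small networks). They model the
  combinatorial background of unstructured polymolybdates.

## Rate model

* Unimolecular (degradation) constants are 1.0 in model units for every
  structured species. Amorphous aggregates shed fragments with a lumped
  constant `n/2 x 1.0`: an amorphous n-mer has of order n/2 distinct ways
  to split, and the accretion-ladder representation merges them into one
  channel. Without this size-proportional fragility amorphous material
  becomes an absorbing mass trap and every flux in the model dies.
* The stable giants {Mo132}/{Mo154} degrade with `k_d = 0.05 << 1`
  (configurable; the template {Mo36} keeps 1.0 by default).
* Bimolecular effective constants are
  `k_eff = base_k * sqrt(T / mu) / V * T_mult * C_mult`, with `mu` the
  reduced mass of the reactants (collision-theory form; masses default to
  nuclearity, k_B = 1, V = 1), applied to propensities by mass action
  (`k N_A N_B`, or `k N (N-1) / 2` for identical reactants).
* The two dimerization channels are in ratio `D` (corner : edge):
  corner = `k_bi_base * D`, edge = `k_bi_base`. `D` is the model's proxy
  for pH / reduction potential.
* **Templation** (`T_mult`): reactions annotated with a template proceed
  `template_factor = 10` times faster while at least one template molecule
  is present (a presence switch; a count-proportional mode is available as
  a configuration option). The default rules make {Mo36} accelerate
  (i) every wheel-path step and (ii) its own assembly route — the
  condensations producing {Mo4}, {Mo6} and the hexamer chain up to
  {Mo36}. Rule (ii) is the embedded autocatalytic loop: a completed
  template coordinates the fragments of the next copy, which is what makes
  {Mo36} a self-replicator in this model. Ablation configurations simply
  pass an empty rule list.
* **Completion bias** (`C_mult`): products with few free bonding sites are
  favoured, `C_mult = 1 + k_nano / (1 + free_sites)` (an exponential form
  is selectable). `free_sites` counts down to the target along a path
  (N - n) and is zero only for completed targets; amorphous species have
  no defined completion and receive no bias. This is the mechanism that
  lets nearly complete structures pull in the last blocks instead of
  dissolving.

## Simulation

The integrator is the exact Gillespie direct method: waiting times are
exponential in the total propensity and reactions fire with probability
proportional to their propensity. The production loop is a numba-compiled
kernel with full propensity recomputation per event (networks here have
a few hundred reactions, so an update graph buys little); a pure-Python
reference stepper implements identical dynamics and backs the unit tests,
including a cross-backend statistical comparison. Trajectories are
sampled onto a fixed time grid; ensembles derive replicate seeds as
`seed_base + r` and report replicate means/variances and time-averaged
abundances over a trailing window (default: the second half of the grid,
discarding burn-in).

Correctness anchors: detailed-balance equilibria of one- and two-species
toys against closed forms, the exact stationary distribution of
`A + A <-> A2` from birth–death state enumeration, agreement of ensemble
means with the deterministic mass-action ODE solution within Monte-Carlo
error, and bit-identical trajectories for identical (configuration, seed).

## Shipped parameters and study conditions

The published model description fixes the unimolecular constant (1.0) and
the template factor (10.0) but not the remaining values, which were
published only in supplementary material; the defaults below are this
package's own operating point, chosen once during model development so
that the default configuration exhibits the described phenomenology, and
then frozen:

| parameter | default | meaning |
|---|---|---|
| `k_uni_default` | 1.0 | unimolecular constant (model units) |
| `k_bi_base` | 5.0 | bimolecular base constant |
| `D` | 1.0 | corner : edge dimerization ratio |
| `k_nano` | 1000.0 | completion-bias strength |
| `template_factor` | 10.0 | templated acceleration |
| `k_d` | 0.05 | giant-cluster degradation constant |
| `temperature`, `volume`, `mass_per_mo` | 1.0 | model units |

Standard experiments (module `moblue.experiments`):

* *reduced synthesis*: 2000 monomers, horizon 8 time units, 201-point
  sampling grid, averaging window = second half;
* *transition sweep*: 21 log-spaced D values in [0.02, 10];
* *giant-growth / seeding runs*: D = 2.5 (inside the wheel-forming regime,
  near the transition);
* *ablation*: the {Mo36} subsystem (nuclearity cap 40, no giants, all-pairs
  enumeration — a model of the giant-free stopped-flow conditions) in the
  dilute regime `k_bi_base = 0.09` with 500 monomers and horizon 40, where
  the uncatalyzed route is slow relative to degradation;
* *forward-rate sweep*: `k_bi_base` in {5, 20, 50, 100, 200, 500} at
  D = 2.5; the documented knee is at the default 5.0 — at this operating
  point the giant yield is already maximal and faster forward rates only
  divert material into amorphous aggregation.

Problem sizes in the test suite and the acceptance script (replicate
counts of 20–100, the masses and horizons above) are the package's
standard scaled-down study sizes; all reported numbers are computed at
run time under exactly these conditions.

## Kinetics layer

Experimental-style traces are analysed with: finite-difference rate curves
(`numpy.gradient`: central differences inside, one-sided at the ends,
non-uniform grids supported); Beer–Lambert conversion (molar
absorptivities must be user-supplied; none are published for these bands);
and a two-step autocatalytic rate law `A -> B` (k1), `A + B -> 2B` (k2)
with the closed-form logistic solution used both as the synthetic-trace
generator and the fit model (`scipy.optimize.curve_fit`, non-negative
bounds, optional fixed parameters such as a known seed concentration B0,
optional 1/sigma^2 weighting). The two-step scheme is a deliberate
surrogate: the measured system shows an uncatalyzed early pathway followed
by autocatalysis, and this is the minimal rate law with that structure —
no claim is made that its two steps are elementary. Precursor
concentration is counted in product units (e.g. [Mo]/36 for {Mo36}) so
A + B is conserved; the divisor is a configuration choice. The lag time is
the maximum-slope tangent's intercept with the initial baseline, clipped
at zero.

## Analysis choices

* Transition detection: midpoint of the steepest change of the (optionally
  moving-average-smoothed) abundance curve; a variance-peak detector is
  also implemented, and the method used is recorded in the result. Curves
  whose total range is below 5% of their magnitude are reported as "no
  transition" rather than a number.
* Scaling exponents: two-sided log–log least squares of abundance against
  |D - D_c|, with fit windows expressed as fractions of D_c (default
  1–25%) and reported alongside the exponents, which are window-sensitive;
  sides with fewer than three usable points are reported as undetermined.
* Coexistence: each giant's curve is normalized by its own sweep maximum
  and the score is the pointwise minimum — 0 if either giant is absent,
  1 where both sit at their maxima. This normalized-minimum form is a
  documented surrogate; the original figure's functional is not specified.

## What the synthetic experiments show — and what they do not

The generator-driven tests demonstrate internal consistency of the model
and the qualitative phenomenology: a transition between a regime with no
wheel and a wheel-forming regime along D; an interior maximum and
coexistence window for the ball; collapse of {Mo36} without its embedded
autocatalytic loop; sigmoidal growth whose induction period is removed by
seeding with preformed template; and the forward-rate paradox. They do
not calibrate the model to measured rate constants, reproduce published
figure values (the parameters behind those figures are not in the main
text), or capture pH/speciation chemistry, spatial effects, or real
photometric noise, so passing tests support the mechanism's coherence,
not quantitative agreement with any particular experiment.

## Known limitations

* The {Mo132} maximum sits about a decade in D below the steepest part of
  the {Mo154} rise rather than immediately adjacent to it: in this
  reservoir-flux formulation the pools self-regulate toward their
  consumption thresholds, which smooths the wheel's onset into a soft
  crossover. A winner-take-all (bistable) template pool would sharpen
  both features onto one point; architectures attempting this
  over-nucleated or gridlocked and were rejected.
* Scaling exponents near the transition are window- and grid-sensitive;
  they are reported with their windows and standard errors and should be
  read as descriptive, not universal.
* The lineage/route structure is a minimal surrogate for an unpublished
  intermediate space; species between {Mo36} and the giants that are off
  the canonical build sequences do not exist in the model.
* Heteropolyanion chemistry ({PMo12}, the {Mo124Ce4} ring) is represented
  only in the structural registry, not in the dynamic network.
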