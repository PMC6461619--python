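# Methods

## Objective, constraints and plausibility

The fitted quantity is a parameter vector of a kinetic model. Its
deviation from reference values is penalized in squared natural-log units,
weighted per uncertainty class: λ_I = 1.0407 for directly measured
references, λ_II = 0.1930 for educated guesses, λ_III = 0 for rough
guesses, and unsearched (US) parameters are held at their reference. The
log-ratio form makes the penalty scale-free and symmetric under inversion
(a parameter at half its reference is penalized exactly like one at twice
its reference); it requires strictly positive parameters and references,
which is enforced at construction.

Each training observation contributes one constraint
`g = mean(((sim − obs)/obs)²) − ε²`. The division by the observation is
kept as-is even though it is asymmetric in sim/obs; observed zeros are
rejected rather than regularized. Allowable errors ε default to 0.1
(high-quality data), 0.2 (medium) and 0.5 (rough), overridable per
constraint; these are relative-error scales typical of metabolomics and
growth measurements. Feasibility is γ = Σ max(0, g)² = 0, with no
exceptions: only feasible fits enter plausibility comparisons. Model
plausibility is MP = exp(−f), reported both raw and rounded to two
significant figures; the MP ratio of two fitted variants quantifies how
much better one mechanism accommodates the same data with less stretching
of its rubber bands.

## Search space and optimizer

Parameters are searched in log10 space, since values span orders of
magnitude and the penalty is itself a log deviation. Default box bounds
are the reference ×/÷ 10 for class I, 10² for class II and 10³ for class
III — generous headroom around the twofold/fivefold deviations one
expects of well-studied parameters.

The optimizer is a real-coded GA with:

* uniform initialization inside the log10 box;
* ensemble crossover: children are the parent centroid plus random
  combinations of parent deviations, ξ ~ N(0, expansion_rate²/n_parents);
  the "star" bias variant (default on) shifts the base point to a
  rank-weighted centroid favouring better parents, with pure unbiased
  crossover available by flag;
* out-of-bounds repair by reflection at the boundary rather than
  clipping, to avoid piling probability mass on the bounds;
* stochastic ranking: adjacent pairs in repeated bubble sweeps are
  compared by f when both are feasible or with probability pf (default
  0.45), by γ otherwise, so the population reduces f and γ in a balanced
  way; at pf = 0 the ordering degenerates to a feasibility-then-violation
  sort and at pf = 1 to a pure objective sort, which the tests assert
  exactly;
* just-generation-gap replacement: n_parents individuals are sampled
  without replacement, n_children children generated, and the best
  children take the parents' slots, conserving population size;
* iterative restart: when neither the best feasible f nor the best γ has
  improved for a stall window the population is reinitialized, while an
  archive keeps the best individual across restarts under the
  lexicographic (γ, f) order.

Hyperparameter defaults scale with dimension d: population 10·d, d+1
parents, 4·d children, stall window 50·d generations — standard values
for this algorithm family. Evaluation failures (e.g. a diverging ODE
solve) map to a γ = +∞ sentinel, never to a silent large number. All
randomness flows through one explicitly passed generator, so equal seeds
give bit-identical runs.

## The demonstration network

The transport thermodynamics are exact: the accumulation factor φ (the
internal/external NH₄⁺ ratio at transporter equilibrium) is
exp(−F·Δψ/(R·T)) for the active (electrogenic) transporter hypothesis and
10^(pH_ext − pH_int) for the facilitated passive NH₃ hypothesis. Around
them sits a reduced network chosen to be the smallest one that preserves
the phenomena of interest — thermodynamic flux reversal, the
ammonium/ammonia futile cycle, and GlnK throttling of AmtB:

* three states (internal total NHx, glutamine, glutamate), in mM, time in
  minutes; membrane potential in mV, temperature in K;
* NH₄⁺/NH₃ speciation treated as instantaneous acid-base equilibrium
  (default pKa 9.25, configurable), since protonation is far faster than
  transport; only total NHx is integrated;
* AmtB flux = vmax · (1 − θ_GlnK) · saturation · (1 − ratio/φ): the
  linear saturation-times-displacement law is the simplest rate form that
  is exactly zero at the equilibrium ratio φ, as the definition of φ
  requires; the passive variant uses the NH₃ gradient analogue;
* GlnK is represented algebraically as a Hill inhibition of AmtB by
  internal NH₄⁺ (half-inhibition k_glnk, coefficient n_glnk), standing in
  for the full uridylylation/2-oxoglutarate cascade; a knockout replaces
  k_glnk by +∞, forcing the inhibition to zero;
* unfacilitated NH₃ diffusion p_diff · (NH₃_ext − NH₃_int); its negative
  (outward) branch is the dissipative half of the futile cycle, whose
  proton cost is converted to an ATP-equivalent rate via 1 H⁺/NH₃ and
  3 H⁺/ATP by default;
* a single saturable assimilation flux (GS-like, vmax_gs, km_gs) feeds
  glutamine, which is drained first-order (k_dil) into glutamate, which
  is drained by a growth-dependent term (mu_max); the growth-rate
  observable is (ln 2/τ₀)·gln/(k_growth+gln) with τ₀ a per-condition
  minimal doubling time proxy.

This toy deliberately omits the uridylylation-state dynamics of
GlnK/GlnB, the ATase/UTase cascade, the GDH/GOGAT split and any gene
expression layer, and its rate constants absorb cytoplasmic volume
scaling; its AmtB and diffusion rate laws are declared stand-ins, not
reconstructions of any published full-network model. Step inputs of
external ammonium are instantaneous concentration changes, and the ODE
integration is split at the step times.

## Steady states and numerics

Time courses use LSODA at rtol 1e−7 / atol 1e−10 by default; halving the
tolerance moves fixture endpoints by far less than 0.1 %. Steady states
are found by a Newton solve from the initial state, accepted only if the
scaled residual is below 1e−8, the state is non-negative and the
finite-difference Jacobian has eigenvalues with negative real parts
(local stability); otherwise the ODEs are integrated toward the attractor
in stages and the endpoint Newton-refined. If neither route converges an
explicit error names the condition and parameter set — never a silent
near-answer. During GA evaluation any such failure becomes the γ = +∞
sentinel.

## Synthetic scenarios

The generator fixes a ground truth and emulates the uncertainty structure
the method assumes: reference values are drawn log-normally around the
truth with a dispersion per class (defaults σ = 0.1, 0.4 and 1.0 for
classes I–III, mirroring informed/educated/rough guesses; US references
equal the truth), and observations are truth simulations with
multiplicative relative noise value·(1 + cv·z), truncated at 1e−9 of the
true value with bounded resampling. The default noise cv is 0.03, well
below the smallest allowable error (0.1), so the ground truth itself is
feasible — a self-consistency gate asserted for every shipped fixture.
Scenarios must carry a seed; unseeded generation is refused.

The shipped default scenario has three conditions echoing the structure
(not the values) of common nitrogen-physiology designs: a 10 mM N-upshift
time course observed at 2–30 min (glutamine, glutamate, internal NHx), a
50 µM low-ammonium steady state (growth rate, net uptake, internal NHx),
and a 1 mM GlnK-knockout steady state (internal NHx, AmtB flux). A
finite-difference rank test at the truth confirms the observation set is
informative enough to constrain all nine searched parameters.

The two-model ranking scenario generates one observation set under the
active-mode truth and hands byte-identical constraints, references and
conditions (differing only in transporter mode) to both variants. The
GlnK-knockout condition is excluded there: its internal-ammonium reading
exceeds the passive variant's thermodynamic ceiling (φ·NH₄⁺_ext) for every
parameter choice, and a fair ranking needs both variants able to reach
feasibility. The low-ammonium condition is the discriminator: the passive
variant can only satisfy the growth/uptake constraints by inflating its
class I assimilation capacity, which stretches the strongest rubber band
and lowers its plausibility — the ranking asserts this direction, not any
particular ratio.

## Replication, comparison, sensitivity

Replicate fits use consecutive seeds and are summarised by per-parameter
coefficients of variation (sample sd / mean over feasible bests). The
representative objective per model is the median over feasible runs
(robust to one bad run; min and mean are available), the MP ratio is
exp(f_B − f_A) of the representatives, and the per-run objective samples
are compared by a two-sided rank-sum test — exact by dynamic-programming
enumeration of the null rank-sum distribution for tie-free samples up to
8 per side (the 5-vs-5 regime is exact; complete separation gives
p = 2/252 ≈ 0.008), normal approximation beyond. Local sensitivities are
normalized central finite differences (default relative step 1e−3) of
steady-state outputs with respect to parameters or physics inputs
(internal/external pH, membrane potential, temperature); a failed steady
state at a perturbed point flags the entry as missing rather than zero.

## Problem sizes used in the shipped tests

The test suite runs the whole pipeline at desk scale as a matter of
design: the default scenario has 9 searched parameters and 17 observation
points over 8 constraints; recovery fits use 4,000 objective evaluations
(population 90, 36 children per generation), and the ranking experiment
five seed pairs at the same budget. These sizes were chosen so a full
fit converges to feasibility with a comfortable margin on a single CPU;
they are configuration, not limits of the method.

## Known limitations

* The demonstration network is a caricature: it preserves transport
  thermodynamics and regulatory throttling but none of the molecular
  detail of ammonium assimilation; conclusions from it are about the
  estimation technology, not about biology.
* Synthetic noise is i.i.d. multiplicative and condition-independent;
  real data have correlated, heteroscedastic errors, so passing recovery
  tests bounds algorithmic correctness, not real-data performance.
* Penalty weights λ are taken as constants; no distributional derivation
  or Bayesian posterior is attempted, and parameter sets with identical
  penalties cannot be distinguished by MP alone.
* The exact "star" crossover coefficients and restart schedule of the
  original algorithm family are exposed as configuration rather than
  hard-coded, and the rank-weighted centroid shift used here is one
  reasonable choice among several.
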