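# Methods

## Thermodynamic model

The receptor is a four-subunit ion channel that interconverts, in a
concerted fashion, between one closed (basal, B) and three open
conformations of increasing conductance (small S, medium M, large L).
Conformation X is characterised by an allosteric constant
`L_X = [B_0]/[X_0]` (dimensionless; by definition `L_B = 1`, and `L > 1`
for every open state of a channel whose opening is agonist-dependent) and
a microscopic dissociation constant `K_X` (molar) identical for all four
sites within a conformation.  A conformation may lack a `K` entirely, in
which case its binding polynomial is 1 — the native-receptor parameter
set uses this for the basal state.

All equilibrium observables follow from the per-conformation statistical
weight `w_X(G) = (1/L_X)(1 + G/K_X)^n`:

* state functions `X̄(G) = w_X / Σ w_Y` (fractions of receptors per
  conformation);
* the saturation function
  `Ȳ(G) = Σ (1/L_X)(G/K_X)(1 + G/K_X)^(n-1) / Σ w_X`;
* within a conformation, ligand occupancy is binomial with per-site
  probability `(G/K)/(1 + G/K)`.

The adjacency chain B⇌S⇌M⇌L carries the affinity ratios
`c = K_higher/K_lower` (< 1 for agonists, so increasing G progressively
stabilises the more-open states).

Two normalizations of the state functions are exposed.  `"all"` divides
by the full partition function.  `"conductive"` drops the basal row and
renormalizes over the open states: this is how conductance frequencies
are reported when only open-channel events are observable, and it is the
mode used for the native parameter set (whose published small-state
frequency of ~0.6 at 1 µM is only reached among open states; under
`"all"` normalization those parameters put most receptors in the basal
state at that concentration).

Numerics: weights are computed as logarithms and fractions formed by
log-sum-exp, because `(1 + G/K_L)^4` overflows double precision once
`G/K` exceeds ~10⁷⁷.  Concentrations are molar throughout; this is the
only reading of the parameter tables that reproduces the published
state-function values.

### Interpretation caveats in the source parameterisation

Two internal inconsistencies in the published account are surfaced rather
than hidden.  (1) The stated relation `L_S = k_SB/k_BS` applied to the
printed fully-liganded kinetic anchors gives 860/3×10⁵ = 2.867×10⁻³,
a factor 10³ from the printed thermodynamic `L_S = 2.867`; which reading
is intended is not resolvable from the text, so both kinetic construction
modes below are exposed and neither is asserted as canonical.  (2) The
native-receptor figure caption places the S/L crossover near 10 µM, while
the printed native parameters put it at 0.1–1 mM; the package reproduces
the parameter-implied curves.

## Fitting

The objective is
`Σ_states Σ_concentrations (log10 X̄(G_j) − log10 y_ij)²`
over the cells present in the dataset; observed frequencies below a floor
ε = 10⁻⁶ (configurable) are clipped to it before the log, since one event
in 10⁶ is below single-channel detection.  Missing rows (e.g. no basal
row in open-channel data) are simply skipped, and such datasets are fitted
in `"conductive"` normalization by default.  The log10 scale gives rare
and common states comparable weight, matching how the curves are read on
a semilog axis.

The search space spans decades (bounds L ∈ [1, 10⁶], K ∈ [10⁻¹⁰, 10⁻³] M)
and the objective is multimodal, so the minimizer is a genetic algorithm
over log10-transformed parameters: population 100, 500 generations,
tournament selection (size 3), uniform crossover at rate 0.8, per-gene
Gaussian mutation at rate 0.05 with σ = 0.3 × (bound width in log10
units), 2 elites, 3 restarts from independent seeded streams.  These
hyperparameters are this package's own defaults; they were chosen for the
decade-spanning log-scale search, not taken from any published
configuration.  A bounded L-BFGS-B refinement of the GA optimum (in the
same log10 coordinates) is appended by default — the memetic combination
converges to curve-level accuracy that the GA alone reaches only with far
larger budgets.  All randomness flows from one integer seed
(`numpy.random.SeedSequence` spawning per-restart streams), so fits are
bit-reproducible; the best-so-far trajectory is non-increasing by
construction (elitism, and the polish only replaces the optimum if it
improves it).

The model is partially sloppy: on few-concentration data, (L, K) pairs
trade off along ridges while the state-function curves barely move.
Curve-space recovery (maximum absolute deviation between generating and
fitted state functions over the data range extended one decade each side)
is therefore the contract checked by the tests; parameter-space deviations
are reported but not asserted.  Goodness of fit is summarised by the
Pearson correlation between observed and predicted frequencies with the
standard two-sided t-transform p-value.

## Kinetic scheme

States are (conformation, i ligands), i = 0..4 — 20 states.  Ligand is an
infinite buffered reservoir (G constant); synaptic depletion is out of
scope.  Binding is per-site with combinatorial multiplicity: propensity
`(n−i)·kon·G` up, `i·koff` down, with `koff = K·kon` per conformation —
the unique choice whose equilibrium reproduces the binomial occupancy of
the thermodynamic model.  `kon = 5×10⁶ M⁻¹s⁻¹` for every conformation by
default (affinity differences live entirely in the off rates), but
per-conformation values are accepted.  Conformational flips exist only
between adjacent conformations, at every shared ligand count; the rate at
i ligands is the fully-liganded anchor scaled by `c^(a(4−i))` (forward)
or `c^(−a(4−i))` (reverse) with transition parameter a = 0.5.  With this
even split, every binding/flip square in the state graph satisfies the
cycle condition exactly, in either mode, because the per-ligand shift of
the flip equilibrium `c^(2a) = c` equals the koff ratio of the pair.

Construction modes:

* `paper_table` — uses the printed fully-liganded anchors verbatim
  (forward 3×10⁵, 2×10⁴, 5×10⁴ s⁻¹; reverse 860, 145, 691 s⁻¹ for B⇌S,
  S⇌M, M⇌L).  Its stationary distribution does **not** match the
  thermodynamic L constants (see caveat above).
* `thermo_consistent` — keeps the printed forward anchors and solves each
  reverse anchor from `k_rev(0)/k_fwd(0) = L_higher/L_lower`, i.e.
  `k_rev4 = k_fwd4 · c^(2an) · L_higher/L_lower`.  The chain then obeys
  detailed balance with the closed-form equilibrium at every G, so its
  stationary distribution equals the MWC distribution exactly — this mode
  anchors all stochastic-vs-closed-form cross-checks.

Schemes require a dissociation constant on every conformation in the
chain (otherwise the ligand-count scaling is undefined); consequently the
native parameter set supports thermodynamics only, and kinetics are run
with the recombinant-receptor parameters, matching how the source model
was exercised.

The master equation `dp/dt = Qᵀp` is integrated with BDF and the exact
Jacobian (rtol 10⁻⁸, atol 10⁻¹²; rates span 1.149 to 3×10⁵ s⁻¹, so the
system is stiff), with a probability-conservation check at 10⁻⁸ and
residual drift renormalised.  Steady states solve `Qᵀp = 0` with a
normalisation row after verifying strong connectivity of the
positive-rate graph (reducible chains — e.g. any scheme at G = 0, where
liganded states cannot be re-entered — raise with the component list).
The SSA is the direct Gillespie method applied to each receptor
independently (receptors do not interact); per-receptor jump paths are
kept for small populations, occupancy is recorded on a uniform grid, and
long-run occupancy averages are accumulated from exact dwell times after
a burn-in.  Summed-conductance traces weight conformations by (B, S, M, L)
= (0, 1, 2, 3) arbitrary units by default — the source model assigns no
numeric conductances to the substates, so only ratios of plateau levels
are meaningful, and the weights are configurable.

Summary statistics: the 20–80% rise time takes the plateau as the mean of
the final 10% of samples (required to sit within a 5% band), with linear
interpolation between samples, so a step resolves to below one sample
interval; `time_to_fraction_of_steady_state` reports the first crossing
of a fraction of the subset's steady-state occupancy (None if not
reached, not an exception).  `time_to_occupancy` is the absolute-level
analogue: the relative measure becomes degenerate at low agonist where
the large state's own steady occupancy is tiny (~6×10⁻⁴ at 1 µM), and is
then non-monotone in G; the absolute measure expresses the claim actually
being made — higher agonist shifts the population to the large state
faster — and is monotone across 1 µM–1 mM.

## Synthetic data

Real inputs are relative frequencies of conductance states deconvolved
from single-channel records.  The generator draws, at each concentration,
`n_events` (default 500, configurable — real per-record event counts are
not published, and identifiability depends on it strongly) from the
multinomial over the generating model's state fractions.  Traces are SSA
runs with optional additive Gaussian observation noise on the summed
conductance, emulating amplifier noise after filtering without modelling
the filter; dwell-time structure is left exact.  What passing tests show
is therefore internal consistency — the fitter recovers models from data
with exactly the assumed sampling structure; they do not probe
deconvolution error, state-misclassification, baseline drift or receptor
heterogeneity, all of which real records contain.

## Problem sizes and tolerances in the test suite

Closed-form checks run on 13–25-point log grids; the
microstate-enumeration oracle (4 conformations × 2⁴ site patterns)
cross-checks state functions at 10⁻¹⁰ relative.  The stochastic
cross-check uses 10⁴ receptors at 1 mM, a 2 ms burn-in (the deterministic
solution is at steady state well inside 1 ms) and 3 ms of averaging, with
agreement asserted at 3 binomial standard errors computed from the
closed-form fractions.  Noiseless curve recovery uses 7 concentrations
spanning 10⁻⁷–10⁻² M, GA population 100 × 200 generations × 2 restarts
plus refinement, asserted at 0.01 maximum curve deviation.  These sizes
were chosen as the smallest that make the statistical assertions sharp.

## Known limitations

* No desensitized states: the parameter sets derive from
  non-desensitizing preparations, and the scheme has no absorbing closed
  branch.
* Constant free ligand; no cleft-diffusion or transient-pulse input.
* Conductance weights are ordinal placeholders, not picosiemens.
* The GA defaults are sensible for the 7-parameter problem shipped here;
  much larger parameterisations would need budget tuning.
* Fitted parameters on sparse data are reported as found, but only the
  curves they imply are defensible (sloppiness; see Fitting).
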