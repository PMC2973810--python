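# Methods

## Model of allosteric regulation

`allonet` models biomolecules as hierarchical *structures*: a tree of
components, some of which are *allosteric* — they fluctuate between two
conformations (a reference and an alternate state, e.g. R/T for a concerted
oligomer, i/a for a receptor's intracellular domain).  Components contain
interaction *sites*: ligand-binding sites, covalently modifiable sites
(phosphorylation and the like, with an ordered state list whose first label
is the unmodified reference) and catalytic sites.

Regulation follows the Monod–Wyman–Changeux independence paradigm.  Every
input to an allosteric component — a bound ligand, a covalent mark, the
conformation of a reciprocally coupled component — is a *modifier* that
multiplies the component's conformational equilibrium constant by a
regulatory factor Γ:

    K_eff = K0 · ∏ᵢ Γᵢ          (product over modifiers out of their reference state)

For a ligand, Γ is not a free parameter: it is the ratio of the ligand's
association constants to the two conformations, Γ = K_alt / K_ref, taken
from the binding rules.  For covalent marks and component–component
couplings Γ is an independent, *intensive* parameter of the structure.
Component–component couplings must be reciprocal with a shared Γ; this is
exactly the condition under which the two-component four-state cycle closes
thermodynamically.

Kinetics extend the same independence assumption to the transition state:

    kf_eff = kf0 · ∏ᵢ Γᵢ^Φᵢ ,   kb_eff = kb0 · ∏ᵢ Γᵢ^(Φᵢ−1)

Each modifier's Φ value splits its equilibrium shift between the forward
and backward transition rates; Φ = 0.5 (the default) is the symmetric
linear free-energy relationship, and equal Φ across modifiers makes log kf
exactly affine in log K_eff (a property test asserts this on compiled
networks).  Because kf_eff/kb_eff = K_eff identically, every cycle composed
of conformational transitions and bimolecular binding steps satisfies
detailed balance *by construction* — and because equilibria depend only on
the ratios, all equilibrium results are Φ-independent (also property
tested).  kT is set to 1 throughout; concentrations and times are in
arbitrary units, and binding constants are association constants
K = kf/kb (units 1/concentration), with K0 = [alternate]/[reference] for
transitions.

## Compilation

`enumerate_network` expands a model into its full reaction network by
fixed-point iteration from the reference-state monomers: at each step every
binding/enzymatic rule is applied to every species (and species pair)
discovered so far, and every allosteric component of every species is given
its conformational transition with rates computed from the modifiers active
*in that species*.  Rules may condition on the joint conformation of
several components (needed when one binding site is coupled to two
allosteric components, as in the quartic receptor); the Γ applied to each
component's transition is then the affinity ratio conditional on the other
component's current state, which keeps all mixed cycles consistent.

Species are deduplicated by a canonical label.  Candidate relabelings
permute identical sibling sites and identical sibling component subtrees;
they are filtered twice: (i) they must preserve the declared
modifier-coupling graph — a ring of four coupled subunits therefore keeps
its dihedral symmetries (8 elements) while all-pairs coupling keeps the
full symmetric group (24) — and (ii) they must commute with the static
pattern matching of every rule and probe, so sites that are identical in
shape but carry distinct rates (the generic N-site protein, the divalent
adaptor) are never wrongly identified.  The canonical form is the
lexicographic minimum of the serialized species over the resulting group.
Statistical factors fall out of embedding counts: the lumped rate of a
reaction is the rule rate times the number of site-level embeddings that
yield the same canonical product, which reproduces the standard MWC
statistical weights (lumped ≡ microstate equilibria is property tested by
recompiling with the symmetry group forced to the identity).

Unimolecular (intra-complex) associations are supported but flagged:
detailed balance is guaranteed only for cycles of conformational and
bimolecular binding steps, and ring-closure cycles are reported rather than
auto-corrected.  Interaction-centric rules (occupancy-conditioned, with ad
hoc cooperativity factors such as the cubic receptor's γ/δ) are parsed and
counted but lie outside the independence paradigm; compiling them cannot
generally balance, which the cycle diagnostics expose.  `validate_model`
additionally warns when rules give a site conformation-dependent affinities
without declaring it a modifier — the one modelling mistake that silently
breaks thermodynamic consistency.

## Equilibria and simulation

Two independent routes compute equilibria, and their agreement is itself a
test:

* **Partition weights** (binding-only networks): propagating
  w(products) = K·w(reactants) over a spanning set of the reversible
  reactions assigns every species a formation weight relative to the free
  monomers (path-independent by detailed balance; the leftover reactions
  yield the cycle residuals used by `detailed_balance_residuals`, tolerance
  1e-9 on |log ∏K|).  Species concentrations are then w·∏xᵢⁿ with
  per-structure activities x solved from the conservation totals by a
  damped Newton iteration in log space.
* **ODE steady state** (any network): stiff integration (LSODA) with the
  integration horizon grown tenfold until ‖dc/dt‖ < 1e-10‖c‖ + 1e-12,
  followed by a Levenberg–Marquardt polish with the per-structure
  conservation rows appended.  Conservation holds along whole trajectories,
  not just at the fixed point.

Dose responses sweep one ligand over a log grid in either *clamped* mode
(free ligand concentration fixed — the dilute-protein convention, used for
all occupancy analyses because per-protein occupancy then depends only on
free ligand activities and not on unstated total concentrations) or
*total* mode (the grid enters the conservation law).  Sweeps auto-widen
until the curve is flat to 0.1% of its span at both ends so that EC points
are genuinely bracketed.  Stimuli (step/ramp waveforms on clamped species)
are supported for time courses.

## Analyses

**Adaptor cooperativity.**  Coarse-graining the divalent adaptor's 8-state
cube over conformations gives the cooperativity parameter

    θ = (1 + K_RT)(1 + K_RT Γ_X Γ_Y) / ((1 + K_RT Γ_X)(1 + K_RT Γ_Y))

(the fold-change of the apparent affinity for one ligand caused by
occupancy of the other site; symmetric in X and Y) and the apparent
affinity K_app = (K_R + K_RT·K_T)/(1 + K_RT).  Both closed forms were
derived from the coarse-graining and are verified against brute-force
partition-sum oracles over random parameter draws; θ is maximal at
K_RT = (Γ_X Γ_Y)^(−1/2), verified against numerical maximization.

**Assembly efficacy.**  The trimer-assembly analysis solves the
coarse-grained 4-species model (A, XA, AY, XAY, with the second binding
scaled by θ) directly in log space, with X_tot = Y_tot = 1 and
K_X = K_Y = 1; this is cross-checked against a compiled full allosteric
adaptor whose microscopic parameters are obtained by inverting the θ and
K_app formulas at the θ-optimal K_RT.  The efficacious range is the width
in decades of the A_tot interval where [XAY] ≥ 50% of its maximum, with
the peak refined by bounded optimization and the crossings by bisection;
the sweep uses 20 points per decade over A_tot ∈ 10⁻⁴–10⁵.

**Hill coefficients.**  `hill_coefficient` defaults to the classical
midpoint estimator: the slope of log(y/(1−y)) against log(input) at the
EC50, evaluated by differentiating a monotone (PCHIP) interpolant of the
logit curve.  It is exact for ideal Hill functions and reproduces the
published cooperativity indices of the tetramer models (≈2.85 concerted,
≈2.17 sequential tetrahedral).  The coarser two-point EC10/EC90 form
log 81 / log(EC90/EC10) is available as `method="ec1090"`; it
systematically underestimates the midpoint slope for non-ideal curves
(≈2.58/1.88 on the same models), which is why it is not the default.  EC
points are interpolated in logit space and refuse curves that are not
saturated at the grid ends.  Competitor analyses express the fixed
competitor concentration in multiples of the EC50 of its own solo
occupancy curve (computed first, on the same compiled network family), and
competitor maxima are reported over a 17-point log grid spanning 0.01×–100×
that EC50.

**Receptor pharmacology.**  Potency is −log10 EC50 of the
fraction-signalling dose response, efficacy its saturating plateau, and a
ligand is an inverse agonist when the plateau falls below the basal
(constitutive) signal.  `rank_order` sorts ligands by potency (ties by
efficacy) per pathway and flags functional selectivity when the orderings
differ — behaviour impossible for a receptor with a single active state.

**Parameter accounting.**  Intensive parameters belong to structures (one
allosteric constant per component, one Γ per covalent coupling and per
reciprocal component pair); extensive parameters belong to rules (one
affinity per conformational rule context; ad hoc factors count once each).
Two levels are exposed because the two published comparisons count at
different granularity: the equilibrium level (no Φ) reproduces the ternary
complex receptor comparison — 59 quartic vs 109 cubic parameters at 4
ligands × 10 G proteins, 11 vs 7 at one of each — while the kinetic level
(one Φ per coupling–partner interaction) reproduces the 3NL+1 = 91
independent rate constants of the generic N = 6-site, L = 5-ligand protein,
against L^N-scaling (233,280) for the context-explicit alternative.  This
convention is reverse-engineered from the printed totals and documented as
such.

## The model library and synthetic fixtures

Builders ship the printed defaults of every worked model: the divalent
adaptor (K_RT = 10⁻³, K_RX = 0.1, K_TX = 10, K_RY = 0.01, K_TY = 100),
the competing-ligand tetramers (concerted K_RT = 10³; sequential K_rt = 0.1
with Γ_S = 10 on tetrahedral or square coupling graphs; ligand affinities
Γᵢ^(±1/2) with Γ₀ = Γ₁ = 0.01, Γ₂ = 1, Γ₃ = 100), the quartic ternary
complex receptor (K_actL = 1, K_actG = 0.05, Γ = 1, the five-ligand /
two-G-protein affinity table) and its cubic counterpart, a
kinase-cascade example with Michaelis–Menten rules, the generic N×L
counting model, and the nested tertiary two-state oligomer.  The tertiary
model reproduces the 252 molecular species of the published reference
scheme when configured with two ligand types (2 quaternary states ×
multisets of 4 subunits over 2 tertiary conformations × 3 site states =
2·C(9,4) = 252); with one ligand it compiles to 70 receptor species.

`random_model(seed, ...)` generates deterministic two-state protein models
(optionally with shared wildcard rules, i.e. symmetric sites, and optional
covalent site + kinase) for property tests: detailed balance, lumping
correctness and enzyme conservation are asserted over a hundred seeds.
These synthetic models emulate the combinatorics of real signalling
proteins but not, e.g., measurement noise, unbalanced energy-consuming
cycles (no GTP/ATP drive), oligomerization of receptors, or more than two
conformations per component — passing tests certify the machinery, not any
particular biological system.

## Numerical choices and limitations

* Cycle-residual tolerance 1e-9; steady-state residual 1e-10·‖c‖ + 1e-12;
  conservation preserved to 1e-9 relative; lumped-vs-microstate and
  coarse-graining identities asserted at 1e-6 relative.
* Species and reactions are emitted in canonical-label lexicographic order;
  all outputs are deterministic for fixed inputs.
* Enumeration is capped (complex size 12, 20 000 species by default) and
  aborts with a diagnostic rather than running away on unbounded
  polymerization.
* Canonicalization enumerates the symmetry group; structures whose
  automorphism group or tied-instance permutations would exceed ~10⁵/5040
  candidates are refused.  This is ample for oligomers up to tetramers with
  several ligand types, the intended regime of full network enumeration.
* SBML Level 3 export is written directly as XML (species, compartment,
  parameters, mass-action kinetic laws; reversible reactions as two-term
  laws).  It is a deliberately small serializer, not a full SBML toolkit:
  no units, annotations or round-trip import.
* The ODE route treats clamped species as fixed parameters; networks driven
  by stimuli are therefore open systems and their steady states need not be
  equilibria (the partition route refuses catalytic networks for the same
  reason).

## Problem sizes

Default test and reproduction runs compile networks of 10–254 species
(adaptor cube → two-ligand tertiary oligomer), sweep dose responses at
12–16 points per decade over auto-widened grids, use a 17-point competitor
grid and 181-point assembly sweeps, and verify properties over 100 random
model seeds — sizes chosen so the full reproduction completes in about a
minute on one CPU while keeping every estimator deep in its converged
regime.
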