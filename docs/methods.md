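# Methods

`qspreduce` implements a reduce-and-link workflow for quantitative systems
pharmacology (QSP): a whole-body pharmacokinetic model and a cellular
reaction-network model are each reduced under declared input–output terms,
then recombined by wiring outputs of one component to inputs of the other.
This note records the models, the numerical choices, and the design
decisions that were genuinely open, together with what the packaged tests
do and do not demonstrate.

## Model representations and simulation

All models are control-affine initial-value problems

    dx/dt = f(x) + Σ_i g_i(x) u_i(t),   y = h(x),   x(0) = x0,

with named states, inputs and outputs. Linear time-invariant systems
(A, B, C) are a distinguished subtype because both the PBPK model and the
balanced-truncation machinery live there.

Dosing semantics: a bolus is an instantaneous state increment through the
input field (`x ← x + g_i(x)·amount`; `B[:,i]·amount` in the linear case),
so a bolus at t = 0 is exactly equivalent to amending the initial state.
Infusions are piecewise-constant rates on `u_i(t)`.

Linear systems are propagated by matrix-exponential stepping with
zero-order hold on the inputs — exact up to machine precision, which
matters because reduction errors of interest reach 10⁻⁸ and must not be
confounded with solver error. Nonlinear systems use a stiff-capable
solver (LSODA) with rtol 10⁻⁸ / atol 10⁻¹⁰ by default (configurable);
integration restarts at every dose event. Stability is eigenvalue-based
with tolerance 10⁻⁹ on real parts; eigenvalues within ±10⁻⁹ of the
imaginary axis are reported as marginal rather than silently classified.

Default reporting grid: 2,000 linearly spaced points over 48 h for
PBPK-driven experiments. No published axis fixes this horizon, so it is a
package default, not a reproduced constant; 48 h covers the absorption
peak and several terminal half-lives for all three packaged compounds.

## Error metric

Reduction fidelity is the maximal relative error

    ε = ‖y − ȳ‖_∞ / ‖y‖_∞,

evaluated per output channel on the discrete simulation grid, with the
headline value the maximum across channels ("in either compartment").
The sup-norm is discretised on the grid; at the default density the
grid-refinement error on smooth PK trajectories is below 1 % of ε
(asserted in the metric tests). ε is invariant to rescaling both
trajectories, so it compares across dose levels. A reference channel that
is identically zero raises an explicit error rather than returning an
infinity.

## The whole-body PBPK model

Sixteen states: thirteen perfusion-limited tissue concentrations
(adipose, bone, brain, gut, heart, kidney, liver, lung, muscle, skin,
spleen, testes, rest-of-body), venous and arterial blood concentrations
(mg/L), and an oral depot amount (mg). Flows are fractions of cardiac
output (QC = 390 L/h), volumes fractions of body weight (70 kg reference
adult). Gut and spleen drain through the liver (splanchnic circulation);
the liver clears drug from its outflow blood at CL_h = CL_bl·BW·60/1000
L/h; the lung sits between venous and arterial blood at full cardiac
output. Oral doses fill the depot, which empties into gut tissue at
first-order rate Ka; IV doses enter venous blood. With clearance disabled
total mass ΣV_t·C_t + depot is conserved to 10⁻⁸ (asserted).

Three design points were genuinely open:

* **Partition-coefficient reference.** The packaged Kp values can be read
  as tissue:blood (outflow C_t/Kp_t) or tissue:plasma (outflow
  C_t·BP/Kp_t). Both conventions exist in the PBPK literature. The
  tissue:blood reading reproduces the published reduction-error tables
  substantially better across compounds (the blood-to-plasma ratio enters
  the discrimination most strongly for midazolam, BP = 0.53), so
  `kp_reference="blood"` is the default and `"plasma"` is available.
* **Residual compartments.** No flow fraction is printed for testes or
  rest-of-body. A zero testes flow would disconnect the compartment and
  destroy asymptotic stability, so the residual cardiac-output fraction
  (1 − Σ printed systemic fractions = 0.115) is split between testes and
  rest-of-body in proportion to their fractional volumes. Their missing
  partition coefficients default to the arithmetic mean of the eleven
  printed tissue Kp values. Both rules are overridable.
* **Hepatic clearance form.** Clearance applies to the liver outflow
  blood concentration. The well-stirred conversion using fu_p and MPPGL
  is *not* applied — those parameters are carried in the types for
  forward compatibility and flagged unused, because no main-text equation
  consumes them.

## Balanced truncation

Standard square-root algorithm: solve AP + PAᵀ + BBᵀ = 0 and
AᵀQ + QA + CᵀC = 0 (`scipy` Lyapunov solvers; residuals checked against
1e−8·‖BBᵀ‖-scale tolerances), factor P = UUᵀ and Q = LLᵀ (Cholesky,
falling back to a symmetric eigenvalue square root for semidefinite
Gramians), SVD of LᵀU = ZΣYᵀ, transformation T = UYΣ^(−1/2). Hankel
singular values beyond the numerical rank of LᵀU cannot be balanced and
are dropped with a warning (the 16-state PBPK model loses one such
direction at machine precision). Truncation keeps the leading k balanced
states, reports the a-priori H∞ bound 2·Σ_{i>k}σ_i, and provides output
recovery through the retained columns of T. Truncating inside a cluster
of numerically equal singular values is refused: the cut moves past the
cluster with a warning, because the split between equal-σ states is
arbitrary. Nonzero initial states are mapped as x̃0 = T_inv[:k]·x0 — exact
for the PBPK experiments, which start from zero.

**Input declaration for the PBPK reduction.** Truncating the full
16-state model with an oral bolus treated as an impulse produces a direct
feedthrough in the reduced system (C̃B̃·dose ≠ 0 at t = 0⁺) that the full
model does not have; this artifact dominates ε at small k and does not
reflect the quality of the reduced distribution dynamics. The package
therefore reduces the PBPK model the same way the framework reduces any
composite: decompose, reduce the component under its declared
input–output terms, relink. The oral depot — a one-state, exactly
solvable absorption process — is kept unreduced; the 15-state
distribution network is truncated with the absorption flux Ka·A(t) as its
input and the compartments of clinical interest as outputs; the depot is
then reattached upstream. The reduced model's output starts at zero like
the full model's (asserted), and `k` counts reduced distribution states.
The generic `reduce_linear` remains available for arbitrary models and
dose regimens.

## Proper lumping

A proper lumping is a 0/1 partition matrix L (each state in exactly one
lump); reduced dynamics are f̃(x̃) = L·f(L̄·x̃) with a generalized inverse
L̄ satisfying L·L̄ = I, and outputs are reconstructed through L̄ so every
original output stays available. The default L̄ is the Moore–Penrose
inverse of the partition — a lumped value split equally over members —
matching the generic lumping literature. For compartmental PK models an
equal split of a *concentration* is unphysical; the PBPK workflow instead
lumps in amount coordinates and distributes a lumped amount over members
in proportion to effective volume V_t·Kp_t (blood pools by plain volume),
which models merged compartments sharing one blood-equivalent
concentration. The inverse is isolated behind two small functions so
other weightings can be swapped in.

The partition search is greedy forward selection: at dimension m,
evaluate all C(m,2) pairwise merges of the current lumps, score each by ε
of the declared outputs against the original model under the test
scenarios (worst case across scenarios), keep the best, recurse. Ties
break on the lowest lexicographic pair index, so reruns are
deterministic. Candidates that fail to simulate score ε = ∞ and are
logged. The search may run on a coarser grid (200 points) than final
reporting (2,000 points) for speed; reported ε always uses the fine grid.
For linear models ε is invariant to input amplitude, so the default
search input is the evaluation dose itself; for nonlinear models,
amplitude variants (10× and 0.1×) should be added via the scenario list
to avoid overfitting the partition to one stimulus level.

Greedy forward selection is path-dependent: a beam search over the same
construction finds 3-lump partitions of the PBPK model with materially
lower ε than the greedy path reaches. The packaged experiments
nevertheless report the plain greedy result, which is the procedure the
reduction literature this package follows actually prescribes.

## Conservation analysis

For a reaction network dx/dt = N·v(x), conservation relations are a basis
of the left null space of N, computed from QR factorisation with column
pivoting of Nᵀ: the pivoting ranks species columns, the first rank(N)
pivots are the independent species, and Γ = [−M I] (in permuted order,
M = N_dep·pinv(N_indep)) satisfies Γ·N = 0. Singular values below
10⁻¹⁰·σ_max count as zero, since SBML models can carry float
stoichiometries. Dependent species are eliminated as affine functions of
the independents and the conserved totals (evaluated from x0 and
re-evaluable for new initial states); elimination is exact — asserted to
ε < 10⁻⁸ against the full model on the packaged fixtures. The reduced
network's stoichiometry has full row rank by construction and is
self-checked.

## Linkage and decomposition

`link` flattens a set of components plus wiring declarations (upstream
output → downstream input, with a unit-conversion coupling, default a
linear gain) into one joint control-affine system — monolithic
co-simulation, so there is no coupling-interval error. Feedback cycles
are allowed; since every component's outputs read only its states,
instantaneous algebraic loops cannot form. The gain between a PK
concentration (mg/L) and a cellular stimulus (µM) requires a molecular
weight that the hypothetical-compound experiments do not fix, so the
default gain is 1 with units documented as nominal.

`decompose_linear_nonlinear` is the inverse operation: given the states
designated nonlinear, it verifies numerically (random sampling around the
initial state) that the remaining block is linear and that the nonlinear
block's dependence on the linear states is affine, promotes the cut arcs
to input/output channels on both blocks, and returns the linkage list
that reassembles the original — round-trip trajectories agree to 10⁻⁸
(asserted). Constant drift offsets in the linear block are rejected
rather than silently absorbed.

## Synthetic fixtures: what they cover and what they do not

`fixtures` generates every test input: random guaranteed-Hurwitz linear
systems (eigenvalues log-uniform in [0.1, 10] h⁻¹, well-conditioned
eigenbasis, dense unit-scale B and C) for the balanced-truncation
property tests; parallel identical compartments with a known exact lump;
isomerisation and Michaelis–Menten networks with known conservation
counts (1 and 2); and a six-state receptor cascade (ligand → receptor
complex → two-step phosphorylation chain) that stands in for a bacterial
chemotaxis-style signalling pathway with one input (extracellular ligand)
and one output (terminal phosphorylated messenger). The default fixture
seed is 20180326. The cascade exercises the same pipeline shape as a real
signalling model — it is not a reimplementation of any published
chemotaxis model, whose equations live in supplementary material we do
not reproduce; users can supply such models via SBML or the JSON schema.
Consequently, passing tests demonstrate correctness of the operations and
the pipeline plumbing, not biological fidelity of any particular cellular
model.

The 99-species ERK activation network is imported from BioModels
(BIOMD0000000049) by `scripts/erk_example.py`; it is not packaged (size
and provenance) and the associated checks run only where the download is
possible.

## Known limitations

* The greedy lumping search reproduces published per-compound lumping
  errors closely at mild reductions (dimensions ≥ 5, within tenths of a
  percentage point) but diverges on the final merges for some compounds;
  see the search discussion above.
* SBML support covers the core constructs of deterministic
  reaction-network models (species, compartments, parameters, reactions,
  kinetic laws, function definitions, initial assignments); events,
  rules, constraints and delays are rejected explicitly.
* Balanced truncation requires asymptotic stability; marginally stable
  systems (conserved moieties included) must go through conservation
  elimination first.
* No SDE/stochastic simulation, no delay equations, no spatial coupling.
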