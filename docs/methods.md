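# Methods

## The design problem

A hexaphyrin NLO switch is a pair of interconvertible macrocycle states with
very different hyper-Rayleigh-scattering first hyperpolarizabilities
(β_HRS): a redox switch (28R → 26R) or a Hückel–Möbius topology switch
(28R → 28M). The design variables are the six meso substituents, grouped by
a substitution pattern; the objective is a switch contrast. This package
implements everything downstream of a β value or β tensor. β tensors
themselves come from coupled-perturbed Kohn–Sham or TD-DFT calculations and
are treated strictly as inputs (fixture tables, tensor files, or
external-evaluator responses).

## HRS invariants

For incoherent second-harmonic scattering from an isotropic ensemble,
observed perpendicular to the propagation plane, the intensity is governed
by two rotational invariants of β, the orientational averages ⟨β²_ZZZ⟩ and
⟨β²_ZXX⟩, and

β_HRS = √(⟨β²_ZZZ⟩ + ⟨β²_ZXX⟩),  DR = ⟨β²_ZZZ⟩ / ⟨β²_ZXX⟩.

The square root is required for β_HRS to carry the dimensions of β;
definitions omitting it appear in the literature as typographical shorthand.
The closed forms implemented in `nlo_tensor.orientational_averages` are the
standard non-Kleinman second-harmonic averages, assuming only the intrinsic
permutation symmetry β_ijk = β_ikj (enforced on read by averaging the last
two indices; a flag disables this). Full Kleinman symmetry is *not* assumed.

Because typeset versions of these 11-term coefficient sums are notoriously
error-prone, the implementation was validated two independent ways:

1. an exact symbolic rotation average (quaternion parametrization of SO(3);
   monomial moments over the unit 3-sphere in closed form), reproduced by
   the implemented coefficients to ~1e-14 on random symmetric tensors;
2. the Monte-Carlo oracle `mc_rotational_average`, which draws Haar-uniform
   rotations from normalized 4D Gaussian quaternions, rotates the tensor,
   and averages (β′_ZZZ)² and (β′_ZXX)². The test suite checks 50 random
   tensors at 10⁶ samples against the closed forms within three standard
   errors.

Spot checks: a single diagonal component gives (β²_zzz/7, β²_zzz/35), hence
β_HRS = |β_zzz|·√(6/35) and DR = 5; the zero tensor of any centrosymmetric
structure gives β_HRS = 0. Units are atomic units throughout; no conversion
is attempted.

## Contrast objectives and the clamp rule

Two figures of merit are supported: the ratio β_HRS(ON)/β_HRS(OFF) and the
difference β_HRS(ON) − β_HRS(OFF). The OFF state is assigned by chemical
role (28R by convention), never by magnitude; when the OFF response exceeds
the ON response the result is flagged `reversed` (negative difference, ratio
below 1) rather than relabelled.

Centrosymmetric OFF states have β_HRS = 0 and would make the ratio infinite,
so a clamp rule applies: if β_HRS(OFF) < 10 a.u., the denominator is
replaced by 0.001 a.u. Both parameters are configurable and default to
these values. Fixture cells printed as "∼0" (zero up to coordinate round-off
in the underlying DFT geometry) are stored as exactly 0, which reproduces
the 10⁶–10⁷ clamped-contrast regime. A consequence used as a test oracle:
for any clamped pair with stored OFF = 0, ratio = 1000 × difference exactly,
so the ratio/difference correlation over centrosymmetric-OFF switches has
R² = 1 by construction. `contrast_correlation` is ordinary least squares
with intercept, as in a standard correlation plot. The clamp is applied
per frequency: dynamic β values are clamped against their own magnitude,
not the static one.

## Chemical space

Six sites R1..R6, 1-based, clockwise. Patterns are ordered partitions of the
sites kept in a packaged YAML config (`data/patterns.yaml`):

* `FULL` — all six sites identical;
* `A2B2C2` — diagonal pairs (R1,R4), (R2,R5), (R3,R6);
* `A3B3` — alternating triples (R1,R3,R5), (R2,R4,R6). The published
  pattern diagram is graphical only; the alternating partition is the one
  consistent with the dipyrromethene + aldehyde condensation route and is
  deliberately stored in config, not code, so it can be corrected without a
  release;
* `A2BC2D` — (R1,R3), (R2), (R4,R6), (R5), reconstructed from explicit
  site mentions in the source data.

The optimization library holds exactly seven fragments (NO₂, CN, F, H, CH₃,
OH, NH₂); PhF₅ is catalogued for fixture joins but excluded from searches.
Canonical keys are `STATE(choice_choice_…)` in group order; they are unique
within any pattern × library space (tested) and serve as fixture join keys.

The formal-centrosymmetry rule marks a 28R structure C_i when its per-site
map is invariant under the diagonal pairing R1↔R4, R2↔R5, R3↔R6. It is a
geometric prediction, not a guarantee: relaxed structures with bulky or
strongly interacting substituents (NO₂ on R1/R4 or R3/R6, NH₂ on R3/R6 in
the pairwise fixture table) break to C2/C1 with β_HRS of order 10³ a.u., and
fixture records always override the formal rule.

## Best-first search

`run_bfs` iterates site groups in a fixed ascending order (configurable);
for each group it scores every library fragment with the other groups
frozen, accepting the strictly best improvement. Sweeps repeat until a full
sweep accepts nothing (convergence) or a cap is reached (default 10 sweeps —
additive landscapes need 1, coupled test landscapes 2–4). Scoring a
candidate evaluates *both* switch states, because the objective is a
contrast; the evaluator contract is `evaluate(state, assignment, frequency)
→ β_HRS`. Design choices that matter:

* *Strict improvement.* Equal-valued candidates never replace the
  incumbent; this guarantees termination and makes the trajectory's
  accepted objective values strictly monotone.
* *Tie-break.* Among equally improving candidates the earliest library
  fragment wins (the source algorithm is silent; a fixed rule keeps runs
  reproducible).
* *Caching.* Objective values are cached by structure key + frequency, so
  no structure is evaluated twice within a run; trajectories serialize to
  JSONL with a config header for resumption and audit.
* *Error policy.* An evaluator failure either aborts (default) or scores
  the candidate −∞ and continues (`neg_inf`), for sparse fixture coverage.

`exhaustive_search` enumerates the space (guard: ≤ 10⁵ points) and is the
oracle: on additive landscapes greedy equals exhaustive for all tested
seeds; with couplings greedy never exceeds it. `random_initial_assignment`
draws each group uniformly (chi-square-tested) from `numpy.random.default_rng`.

## Evaluators and fixtures

The packaged CSVs transcribe published DFT results: the unsubstituted parent
macrocycles (structural descriptors, aromaticity metadata, and β_HRS at
0, 0.653 and 1.165 eV — the static limit and the Nd:YAG/Ho:YAG laser
energies), the fully meso-substituted series with printed contrast columns,
the pairwise-substitution prestudy over the three diagonal site pairs, and
running-text values for the reported optima. Every cell carries a provenance
tag. Descriptor columns (Λ, NICS_zz(1), AV1245, AV_min, Δη, Δ_HL, Φ_p, Π)
are read-only metadata: this package never regenerates wavefunction-derived
quantities.

Load-time validation recomputes every printed ratio/difference column from
its stored ON/OFF betas. The tolerance is 1% relative *or* the slack that
3-significant-figure rounding of the operands propagates into the derived
value, whichever is larger — one difference cell (CN, 26R−28R) deviates
1.08% purely because both printed operands are rounded to three figures, and
the propagated-rounding bound accepts it without loosening anything beyond
printed precision.

The synthetic landscape gives full-space coverage that the tables cannot:
per-(group, fragment, state) base contributions |N(0, base_scale)| with
base_scale = 2000 a.u. (placing single-structure values in the 10²–10⁴ a.u.
range of the tabulated hexaphyrins), optional pairwise couplings
N(0, coupling_scale) (default 0 — the independent-site regime; tests use
500–600 a.u. for coupled landscapes), an absolute value keeping β ≥ 0, and
the centrosymmetry-cancellation rule zeroing formally centrosymmetric 28R
structures unless a symmetry-breaking fragment (default NO₂, mirroring the
fixture exceptions) is present. It reproduces the *structure* of the real
landscape — symmetry dominance of the OFF state, additive-plus-coupling
site effects — but not its chemistry: passing search tests shows the
optimizer is correct, not that it would find the same substituents DFT
would.

The external evaluator writes one JSON request per structure (canonical
key, per-site map, state, frequency) into a job directory and waits for a
response tensor in the `hexanlo-beta-v1` dialect, which it reduces with the
closed-form invariants. Tests exercise the contract with synchronous stub
responders.

## Geometry descriptors

Ring planes are total-least-squares fits (smallest right singular vector of
the centered ring coordinates; degenerate/collinear rings are rejected).
Φ_p is the mean over the six cyclic neighbor pairs of the unsigned
plane–plane angle folded into [0°, 90°]. Π is implemented as the product of
neighbor-normal cosines after propagating a consistent orientation around
the loop, closing against the original first normal: an untwisted loop
closes consistently (Π > 0, Π = 1 for coplanar co-oriented rings) while a
Möbius loop accumulates exactly one reversal (Π < 0), independent of the
starting ring. The published Π definition is cited to prior work that may
use per-atom p-orbital axes along the conjugation path; this plane-normal
variant reproduces the documented sign convention and magnitude range, is
isolated behind one function for replacement, and printed Π values are
therefore treated as fixture metadata, never regeneration targets.
Values above 0.30 are flagged as compatible with macrocyclic aromaticity
(only meaningful for positive Π).

Inversion-center detection inverts every atom through the centroid and
requires a one-to-one match to an atom of the same element within a
tolerance (default 0.1 Å), via greedy nearest-neighbor matching with
consumption — adequate for exact and near-exact C_i candidates, which is
the regime the β_HRS = 0 rule cares about.

The fixture generator places six regular pentagon rings on a circle with
unit normals realizing any feasible sequence of six neighbor plane angles
(colatitude interpolation plus azimuth steps solved from the spherical law
of cosines; infeasible sequences — violating the spherical closure
inequalities — are rejected with an error). A Möbius flag closes the loop
with one orientation reversal. Because the atoms are exactly planar per
ring, Φ_p and Π of generated frames are known in closed form, which is what
the geometry tests assert against. The frames are geometric scaffolds, not
chemical structures: all-carbon rings, no meso bridges, no hydrogens.

## Numerical choices and limitations

* Rotation matrices are validated orthogonal with det +1 to 1e-8 before
  tensor rotation; β_HRS rotation invariance holds to 1e-9 relative.
* Monte-Carlo standard errors use the sample variance of the squared
  rotated components; the 3-SE acceptance band is a statistical check, so
  the 50-tensor test tolerates at most one excursion among 100 bands.
* Problem sizes: search tests use the 343-point A₂B₂C₂ space (exhaustively
  enumerable oracle), 20 seeds additive + 10 coupled; the MC oracle uses
  10⁶ samples per tensor. These sizes were chosen so the full suite runs in
  well under a minute of search and ~25 s of Monte Carlo.
* Fixtures printed to three significant figures bound every
  fixture-derived assertion at roughly the 1% level; nothing downstream
  claims tighter agreement.
* The fixture tables do not cover whole search spaces, so end-to-end BFS
  runs on fixtures are restricted to sub-spaces with complete records (or
  run under the `neg_inf` policy); reported published optima are validated
  as contrast recomputations, not re-derived as search outcomes.
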