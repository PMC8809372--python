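# Methods

`neuroqsp` implements an in-silico discovery workflow for proteasome-inhibitor
neurotoxicity: a Boolean model of intraneuronal signaling is analyzed for the
conditions under which apoptosis commits (continuous simulation, attractor
statistics, minimal intervention search), predictions are qualified against
differential-expression directionality, and a PK/PD layer quantifies drug
interactions in vitro (viability plates) and in vivo (tumor growth inhibition).
This note records the models, the numerical choices, and what the synthetic
data do and do not establish.

## Boolean network model

A network is a set of named nodes with one Boolean update rule each, written
in the BoolNet-style `target, factors` dialect (`!`, `&`, `|`, parentheses,
constants `0`/`1`, `#` comments). Input nodes — ligands, drug exposure
switches — are encoded as self-rules `X, X`, so they hold state under the
synchronous update but can vary across random initial states; clamps override
any rule and model knockouts/inhibitors (`=0`) or constitutive presence
(`=1`). Edges are counted as distinct regulators per rule; input self-rules
contribute no edge, so the count reflects actual interactions.

The bundled fixture (`data/toy_cipn.bnet`, 19 nodes / 19 edges) is a
deliberate simplification of the proteasome-inhibition pathway narrative:
proteasome inhibition releases ROS, driving ER stress (ATF4 → CHOP) and the
intrinsic pro-apoptotic arm; TNFa and NMDA inputs feed the extrinsic caspase-8
and nitric-oxide arms; NGF supports survival through Akt → Bcl2. Apoptosis
fires as `(ProApop & !Bcl2) | Casp8 | NO`: Bcl2 gates only the intrinsic arm.
The gating is deliberate — if Bcl2 vetoed all three arms, restoring Bcl2 (e.g.
by blocking CHOP) would alone silence apoptosis and the fixture would lose the
three-arm combinatorial structure it exists to exercise. The fixture is a test
harness with known exhaustive answers, not a claim of biological completeness.

## Continuous (normalized HillCube) simulation

Each rule's truth table is interpolated multilinearly over the unit hypercube
(the BooleCube `B_i`), and every regulator activity passes first through a
normalized Hill function `h(x) = (x^n/(x^n+k^n))·(1+k^n)`, so `h(0)=0`,
`h(1)=1`. Dynamics follow `dx_i/dt = (B_i(h(x_regs)) - x_i)/tau`. Defaults
`tau = 1`, `k = 0.5`, `n = 3` are the conventional qualitative-modeling
choices. Because `h` fixes the corners, discrete fixed points are continuous
equilibria. Clamped nodes are held constant; unclamped inputs are also held
constant (their self-rule is an experimental condition, not a dynamical
species — passing it through `h` would make intermediate input levels drift).
Integration uses LSODA with rtol 1e-8 / atol 1e-10 on a fixed output grid;
steady state is declared when max |dx/dt| < 1e-6 at `t_end` (default 25 time
units, which the fixture reaches comfortably). Continuous endpoints are
binarized at 0.5 with an indeterminate band [0.45, 0.55] guarding numeric
ties.

## Attractor statistics

Under synchronous updating the network is a deterministic map on a finite
state space; every trajectory ends in a fixed point or cycle. The relative
activation frequency nu of a node is its mean activation over the attractors
reached from sampled start states: each start contributes the node's mean
across its attractor's cycle states (cycle mean; the exact value for fixed
points), averaged over starts. The cycle mean keeps nu in [0, 1]; taking the
canonical first cycle state instead is available as `cycle_stat="first"`.

When the free (unclamped) state space has at most 2^22 states, the engine
builds an explicit successor table (states are bit-packed integers; rules are
evaluated as truth-table lookups on vectorized bit indices), finds all cycles
by pointer doubling — after `n_free` squarings every state has mapped into its
cycle, and the image of the iterated map is exactly the set of reachable cycle
states — and computes exhaustive or sampled frequencies exactly from basin
counts. Larger networks fall back to per-trajectory cycle detection with
basin memoization. Start-state sampling is uniform with replacement over the
free-node hypercube with a recorded seed.

## Minimal intervention analysis

An intervention (clamp set on top of the base clamps) is valid when the goal
node holds its target value in every state of every attractor reachable from
the verified starts — the strictest reading of "retain the goal OFF".
Verification is exhaustive when the free space fits the successor-table cap,
otherwise a seeded sample of starts is used and the result is flagged
`sampled`. Enumeration is breadth-first over sizes with superset pruning:
a candidate containing an already-reported valid set cannot be minimal
regardless of its own validity, so pruning is exact. Both inhibitor-only
(`zero`) and signed (`both`) searches are exposed; results are sorted and
deterministic. If the base clamps alone enforce the goal, the empty set is
reported as the unique minimal intervention.

## Qualification against differential expression

A perturbation is simulated to steady state and each unclamped node's
direction is called from its binarized final activity alone: ON = increasing,
OFF = decreasing, band = indeterminate. Nodes whose call equals their binary
initial value are flagged `no_change_from_initial` but still called — the
direction rule is applied as stated, and the oddity is surfaced rather than
hidden. Probe-level tables are collapsed per gene either by minimum adjusted
p-value (ties: larger |log2fc|, then first occurrence) or by averaging log2
fold-changes; agreement means an increasing call meets log2fc > 0 or a
decreasing call meets log2fc < 0. A log2fc of exactly 0 disagrees with any
directional call (there is no "unchanged" observed category), and
indeterminate calls are excluded from the denominator and listed.
Recomputing differential expression from raw microarray data is out of scope;
the module consumes a probe-level TSV (`probe_id`, `gene_symbol`, `log2fc`,
`adj_p`).

## In vitro pharmacodynamics

Single-agent cytotoxicity: `V = V0·(1 - Imax·C^g/(IC50^g + C^g))`, fit by
weighted least squares (weights proportional to viability, i.e. constant-CV
error), IC50 parametrized on the log scale. The Hill slope defaults to 1 and
is estimable by flag. Two-drug viability uses a competitive combination with
a shared denominator,

    V = V0·(1 - (Imax_B·r_B + Imax_D·r_D)/(1 + r_B + r_D)),
    r_B = (C_B/(psi_vit·IC50_B))^gB,  r_D = (C_D/IC50_D)^gD,

in which `psi_vit` scales the bortezomib IC50: psi > 1 reduces bortezomib
potency (antagonism), psi < 1 increases it (synergy), psi = 1 is additive,
and either single-agent curve is recovered when the partner is absent at
psi = 1. The functional form is this package's canonical choice among
competitive-interaction variants; it satisfies the reduction and sign
conventions above. Estimation is staged: single-agent parameters are fit
first (from single-agent wells) and held fixed while psi is estimated from
combination wells only, with a profile (F-test) confidence interval. Bliss
independence (`E_AB = E_A + E_B - E_A·E_B`) classifies observed combinations
as synergy/additive/antagonism with a ±0.05 excess band.

## Pharmacokinetics and allometric scaling

Dexanabinol disposition is a linear two-compartment model (CL, V1, Q, V2;
first-order `ka` and bioavailability `F` for extravascular doses, `F = 1`
unless configured). Concentrations are evaluated in closed form as sums of
exponentials per dose (eigendecomposition of the rate matrix; superposition
across doses), which also makes the tumor-model drug integrals cheap. The
terminal half-life is `ln2/lambda_z` with lambda_z the slow disposition
eigenvalue. Fits minimize log-scale residuals (constant-CV error). Species
translation uses per-parameter power laws `X = alpha·BW^beta` solved exactly
from two species; predictions reproduce the source species to machine
precision by construction.

## Tumor growth inhibition

    dkg/dt = -kgr·kg,  kg(0) = kg0
    dTV/dt = kg(t)·TV - K_Dex·C_Dex·TV - K_Bort·e^(-psi_viv·k_res·t)·C_Bort·TV

Exponential growth with a decaying rate constant; second-order drug kill; an
exponential resistance onset (`k_res`) on the bortezomib kill term; and an
interaction multiplier `psi_viv` on the resistance rate — psi_viv < 1 means
the partner drug slows resistance onset (synergy). Monotherapy arms use
psi = 1 (there is no interaction partner). Because the state equation is
log-linear given the forcing functions, TV is computed as
`TV0·exp(growth - kill)` with the growth integral in closed form and the kill
integrals by trapezoidal quadrature on a refined grid (default dt = 0.25 h);
the no-drug solution is therefore exactly the closed form
`TV0·exp[(kg0/kgr)(1 - e^(-kgr·t))]`, and the quadrature was checked against
an independent ODE integration.

Fitting is staged and naive-pooled with log residuals: growth (TV0, kg0, kgr)
from the control arm; K_Dex from the dexanabinol arm; K_Bort and k_res from
the bortezomib arm; psi_viv from the combination arm. The confidence interval
for psi_viv is a full profile likelihood: at each candidate psi all other
parameters are re-optimized against all four arms and the F-test threshold is
applied. Profiling only the combination-arm residuals (conditioning on the
earlier stages) is available but materially undercovers (~66% observed for a
95% interval in simulation), because errors in K_Bort/k_res propagate into
psi; re-optimizing the nuisances restores near-nominal coverage.

## Synthetic data: what it emulates, and what it does not

Generators are pure functions of their arguments (seed included) and return
ground-truth sidecars. Defaults encode the study designs the analyses target:
a checkerboard plate spanning the bortezomib IC50 (single-agent wells follow
the plain Hill curves — the interaction acts only when both drugs are
present — with lognormal noise of given CV); rat and human IV plasma profiles
whose two-compartment parameters give terminal half-lives near 4.0 and 4.3 h
(anchoring the near-species-independent disposition reported for this drug);
and a four-arm mouse xenograft study (5 animals/arm, twice-weekly IP dosing
over 28 days, 10% proportional error) with `k_res = 0.0076 1/h` and
`psi_viv = 0.883` as ground truth. Random Boolean networks (≤ 4 regulators,
random truth tables) back the oracle comparisons for the attractor and
intervention engines.

What passing tests show: the engines are exact on spaces small enough to
enumerate, the estimators recover known parameters at realistic noise, and
the intervals have close-to-nominal coverage under the generating model. What
they do not show: anything about mis-specified error models, real microarray
probe behavior, inter-animal growth heterogeneity (the generator pools a
single mean trajectory per arm), or the published 131-node signaling network,
which is distributed only in its paper's supplementary material — analyses of
that model require transcribing it to the `.bnet` dialect, after which every
routine here applies unchanged (the sampled attractor engine and the sampled
intervention verifier exist for exactly that scale).

## Problem sizes used in the shipped checks

Exhaustive attractor analyses run on ≤ 2^18 free states (the fixture);
sampled-versus-exhaustive comparisons use 10^5 starts on 10-node random
networks; intervention-oracle equivalence uses ≤ 7-node networks over all
clamp subsets of size ≤ 2; the psi_viv recovery study uses 100 replicates of
the default four-arm design; the coverage profile uses dt = 1.0 h quadrature
(psi bias from the coarser grid is < 0.1% — far below the sampling noise).
These sizes are the package's chosen desk-scale defaults; all engines accept
larger inputs.

## Known limitations

* Synchronous updating only; asynchronous/probabilistic schemes are out of
  scope, as are SBML-qual import and multi-valued logic.
* The minimal-intervention search is exhaustive over candidate subsets and is
  intended for max_size ≤ 3; it does not use hypergraph/cut-set methods.
* The sampled intervention verifier can accept a set that fails only on
  unsampled basins; results carry the `sampled` flag for this reason.
* Naive pooling ignores animal-level random effects; the psi_viv CI reflects
  residual noise under that assumption.
* The modified competitive-combination form is one of several published
  variants; conclusions about psi's magnitude (not sign) depend on it.
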