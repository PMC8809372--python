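# neuroqsp

Systems-pharmacology toolkit for studying proteasome-inhibitor peripheral
neurotoxicity in silico and for quantifying drug-interaction pharmacology
around it. It is aimed at quantitative systems pharmacology and systems
biology practitioners who want, in one Python package: qualitative signaling
models that can be simulated, perturbed and screened for combinatorial
interventions; a qualification step that confronts model predictions with
differential-expression data; and the PK/PD layer (dose-response interaction,
cross-species scaling, tumor growth inhibition) needed to take a candidate
neuroprotectant through preclinical pharmacology.

## What it computes

**Boolean network core.** Signaling networks are written in the BoolNet-style
`target, factors` rule dialect; input ligands/drug switches are self-rules and
clamps fix nodes to 0/1 (inhibition / constitutive presence). Three analyses
operate on a network:

* *Continuous simulation* — rules are lifted to normalized-HillCube ODEs,
  `dx_i/dt = (B_i(h(x_regs)) − x_i)/τ` with `h(x) = x^n(1+k^n)/(x^n+k^n)`
  (defaults τ=1, k=0.5, n=3), so Boolean fixed points are continuous
  equilibria and trajectories live in [0,1].
* *Attractor statistics* — under synchronous updating, the relative
  activation frequency ν of a node is its mean activation over the attractors
  reached from many (or all) start states; ν_apoptosis summarizes commitment
  to cell death per treatment arm. A bit-packed successor-table engine makes
  exhaustive analysis exact up to 2^22 free states.
* *Minimal intervention analysis* — breadth-first enumeration of all minimal
  clamp sets (size ≤ s) that hold a goal node at a target value in **every**
  reachable attractor under base clamps, with superset pruning and an
  exhaustive or sampled verifier.

**Qualification.** Simulated perturbations yield per-node direction calls
(increasing/decreasing from the binarized steady state); probe-level
differential-expression tables are collapsed per gene and scored for sign
agreement with the calls.

**PK/PD.** Inhibitory Hill viability `V0(1 − Imax·C^γ/(IC50^γ+C^γ))`; a
competitive two-drug combination in which the interaction multiplier Ψ_vit
scales the bortezomib IC50 (Ψ<1 synergy, Ψ=1 additive, Ψ>1 antagonism), with
staged estimation (single-agent parameters fixed, Ψ from combination wells);
Bliss independence classification; a closed-form linear two-compartment model
with per-parameter allometric power laws `X = α·BW^β` solved exactly from two
species; and the tumor growth-inhibition model

    dkg/dt = −kgr·kg
    dTV/dt = kg(t)·TV − K_Dex·C_Dex·TV − K_Bort·e^(−Ψ_viv·k_res·t)·C_Bort·TV

with resistance onset `k_res` and the in-vivo interaction multiplier Ψ_viv on
the resistance rate, fit in stages (control → monotherapies → combination)
with a profile-likelihood CI for Ψ_viv.

A 19-node fixture network encoding the proteasome→ROS/ER-stress, TNFα→caspase-8
and NMDA→NO toxicity arms (plus NGF→Akt→Bcl2 survival) ships with the package;
every analysis also accepts user `.bnet` models, including a transcription of
the published 131-node neuronal signaling model once available
(`neuroqsp.synthetic.full_cipn_network`).

## Worked example

```python
from neuroqsp import (InterventionGoal, enumerate_minimal_interventions,
                      perturbation_panel, toy_cipn_network)

net = toy_cipn_network()
panel = perturbation_panel(
    net,
    [("bort", {"Proteasome": 0}),
     ("bort+triple", {"Proteasome": 0, "TNFa": 0, "NMDA": 0, "ROS": 0})],
    exhaustive=True, goal="Apoptosis",
)
print(panel.nu_goal)
# {'bort': 1.0, 'bort+triple': 0.0}

goal = InterventionGoal("Apoptosis", 0, {"Proteasome": 0, "NGF": 1}, max_size=3)
sets = enumerate_minimal_interventions(net, goal, intervention_values="zero")
print(len(sets), sets[0].members)
# 100 ATF4=0;Casp8=0;NMDA=0
```

Under proteasome inhibition alone every attractor has apoptosis ON
(ν_apoptosis = 1); blocking TNFα, NMDA and ROS together silences it
(ν_apoptosis = 0). The 100 minimal intervention sets are exactly the triples
taking one node from each toxicity arm — no one- or two-node clamp suffices,
which is the model's argument for a triple-target neuroprotectant.

The `examples/` directory has one short script per capability (simulation,
attractor panel, intervention search, qualification, in-vitro interaction,
allometric PK, tumor-study fitting); each prints the numbers it computes and
what they mean. `neuroqsp --help` exposes the same stages as a thin CLI,
including YAML-driven orchestration (`neuroqsp run --config run.yaml --out out/`).

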