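"""Continuous simulation of the toy neurotoxicity network under proteasome inhibition.

Builds the bundled fixture network, clamps the proteasome input OFF (the
bortezomib condition), integrates the normalized-HillCube ODEs for 25 time
units, and prints the steady-state activity of key stress and apoptosis nodes.
Activities near 1 mean the pathway is switched on at steady state.
"""

from neuroqsp import simulate_hillcube, toy_cipn_network

network = toy_cipn_network()
x0 = {node: 0.0 for node in network.nodes}
traj = simulate_hillcube(network, x0, clamps={"Proteasome": 0}, t_end=25.0)

print(f"steady state reached: {traj.steady_state}")
for node in ("ROS", "ATF4", "CHOP", "Bcl2", "Apoptosis"):
    print(f"  {node:10s} final activity = {traj.final[node]:.3f}")
print("Proteasome inhibition turns the oxidative-stress arm ON, suppresses the")
print("pro-survival Bcl2 node, and commits the cell to apoptosis.")
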