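# Toy proteasome-inhibitor neurotoxicity network (version 1).
# A deliberately small signaling fixture: proteasome inhibition releases ROS,
# driving ER stress and the intrinsic apoptotic arm; TNFa and NMDA inputs feed
# the extrinsic caspase-8 and nitric-oxide arms; NGF supports survival via
# Akt -> Bcl2. Inputs are self-rules and are set by clamps/initial conditions.
targets, factors
Proteasome, Proteasome
TNFa, TNFa
NMDA, NMDA
NGF, NGF
ROS, !Proteasome
ERstress, ROS
ATF4, ERstress
CHOP, ATF4
ProApop, CHOP
TNFaR, TNFa
TRADD, TNFaR
FADD, TRADD
Casp8, FADD
NMDAR, NMDA
nNOS, NMDAR
NO, nNOS
Akt, NGF
Bcl2, Akt & !CHOP
Apoptosis, (ProApop & !Bcl2) | Casp8 | NO
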