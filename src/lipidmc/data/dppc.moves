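# Move plan for united-atom DPPC: 88 sampled degrees of freedom.
#   breakage a max_step_A        -> 3 Cartesian DOF, neighbors closed
#   crankshaft a max_deg         -> 1 DOF, rotation about flanking-atom axis
#   torsion a p g max_deg        -> 1 DOF, subtree of a rotated about bond p-g
#   bond_angle a p g max_deg     -> 1 DOF, angle a-p-g driven
crankshaft 2 30
breakage 3 0.10
crankshaft 4 30
crankshaft 5 30
breakage 6 0.10
crankshaft 7 30
crankshaft 8 30
crankshaft 9 30
breakage 10 0.10
crankshaft 11 30
crankshaft 12 30
breakage 13 0.10
crankshaft 14 30
crankshaft 15 30
breakage 16 0.10
crankshaft 17 30
crankshaft 18 30
breakage 19 0.10
crankshaft 20 30
crankshaft 21 30
breakage 22 0.10
crankshaft 23 30
crankshaft 24 30
crankshaft 26 30
breakage 27 0.10
crankshaft 28 30
breakage 29 0.10
crankshaft 30 30
breakage 31 0.10
crankshaft 32 30
breakage 33 0.10
crankshaft 34 30
breakage 35 0.10
crankshaft 36 30
breakage 37 0.10
crankshaft 38 30
breakage 39 0.10
crankshaft 40 30
crankshaft 41 30
crankshaft 42 30
torsion 1 2 3 30
bond_angle 1 2 3 10
torsion 25 24 23 30
bond_angle 25 24 23 10
torsion 43 42 41 30
bond_angle 43 42 41 10
torsion 44 1 2 30
bond_angle 44 1 2 10
torsion 45 1 2 30
bond_angle 45 1 2 10
torsion 46 1 2 30
bond_angle 46 1 2 10
torsion 47 5 4 30
bond_angle 47 5 4 10
torsion 48 5 4 30
bond_angle 48 5 4 10
torsion 49 10 9 30
bond_angle 49 10 9 10
torsion 50 28 27 30
bond_angle 50 28 27 10
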