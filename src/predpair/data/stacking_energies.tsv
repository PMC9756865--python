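# Nearest-neighbor helix stacking free energies, dG37 in kcal/mol.
# Doublet notation: top strand 5'->3' / bottom strand 3'->5'; the first
# column of each strand is the first base pair, e.g. AG/UU stacks an A-U
# pair under a G-U pair.  Watson-Crick values follow the Xia et al. (1998)
# set as tabulated in the Turner 2004 rules; GU wobble values follow the
# Turner/Mathews wobble set.  Each physical doublet is listed once (the
# reverse reading XY/WZ == ZW/YX names the same stack).
doublet	dG37_kcal_mol
AA/UU	-0.93
AU/UA	-1.10
UA/AU	-1.33
CU/GA	-2.08
CA/GU	-2.11
GU/CA	-2.24
GA/CU	-2.35
CG/GC	-2.36
GG/CC	-3.26
GC/CG	-3.42
AG/UU	-0.55
AU/UG	-1.36
UG/AU	-1.00
GA/UU	-1.27
CG/GU	-1.41
CU/GG	-2.11
GG/CU	-1.53
GU/CG	-2.51
GG/UU	0.47
GU/UG	-0.50
UG/GU	0.30
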