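# Built-in torsion library.
# One rule per line: SMARTS<TAB>angle:tolerance[,angle:tolerance...]
# The SMARTS describes a linear path of four atoms; the rotor is the
# central bond and the dihedral is measured over the matched path.
# Rules are tried in file order; the first match wins.  User libraries
# are searched before this file.  Angles in degrees, normalized [0, 360).
#
# amide C-N: planar, trans preferred
[OX1]=[CX3]!@[NX3][!#1]	180:10,0:10
# ester / carbamate C-O: syn (Z) strongly preferred, anti accessible
[OX1]=[CX3]!@[OX2][#6]	0:10,180:10
# aryl-aryl (biaryl): twisted minima
[a][a]!@[a][a]	45:15,135:15,225:15,315:15
# conjugated sp2-sp2 (dienes, enones, aryl-vinyl): s-trans / s-cis
[!#1][CX3,c]!@[CX3,c][!#1]	180:15,0:15
# sp3-aryl / sp3-sp2: perpendicular-staggered pattern
[!#1][CX4]!@[CX3,c][!#1]	0:20,120:20,240:20
# sulfonamide / sulfonyl S-N and S-C rotors
[!#1][SX4]!@[*][!#1]	60:20,180:20,300:20
# generic staggered fallback (always matches any rotor with heavy
# neighbors on both sides)
[!#1][*]!@[*][!#1]	60:20,180:20,300:20
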