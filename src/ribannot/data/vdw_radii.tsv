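# Van der Waals radii (Angstrom), Bondi-style set.
# Elements absent from this table fall back to the 1.80 A default.
element	radius
H	1.20
C	1.70
N	1.55
O	1.52
F	1.47
P	1.80
S	1.80
Cl	1.75
Br	1.85
I	1.98
He	1.40
Ne	1.54
Ar	1.88
Kr	2.02
Xe	2.16
Se	1.90
Si	2.10
B	1.92
Li	1.82
Na	2.27
K	2.75
Rb	3.03
Cs	3.43
Be	1.53
Mg	1.73
Ca	2.31
Sr	2.49
Ba	2.68
Mn	2.05
Fe	2.04
Co	2.00
Ni	1.63
Cu	1.40
Zn	1.39
Cd	1.58
Hg	1.55
Pt	1.75
Pd	1.63
Au	1.66
Ag	1.72
Al	1.84
Ga	1.87
In	1.93
Sn	2.17
Tl	1.96
Pb	2.02
U	1.86
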