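# Elements whose single-atom components are classified as metal ions.
# Alkali, alkaline-earth, transition, post-transition metals, lanthanides,
# actinides and semi-metals. Monoatomic halides are deliberately absent
# (they classify as small molecules).
element
Li
Na
K
Rb
Cs
Fr
Be
Mg
Ca
Sr
Ba
Ra
Sc
Ti
V
Cr
Mn
Fe
Co
Ni
Cu
Zn
Y
Zr
Nb
Mo
Tc
Ru
Rh
Pd
Ag
Cd
Hf
Ta
W
Re
Os
Ir
Pt
Au
Hg
Al
Ga
In
Sn
Tl
Pb
Bi
Po
Ge
Sb
As
La
Ce
Pr
Nd
Pm
Sm
Eu
Gd
Tb
Dy
Ho
Er
Tm
Yb
Lu
Ac
Th
Pa
U
Np
Pu
Am
Cm
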