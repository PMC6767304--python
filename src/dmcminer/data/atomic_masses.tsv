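# Monoisotopic atomic masses (Da), CODATA/IUPAC 2021 values.
# element	monoisotopic_mass
C	12.0
H	1.0078250319
N	14.0030740052
O	15.9949146221
S	31.9720707300
P	30.9737615120
F	18.9984031627
Cl	34.9688527100
Br	78.9183376000
I	126.9044719000
Na	22.9897692820
K	38.9637064864
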