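# Monoisotopic atomic masses (Da) of the most abundant isotope, AME2020/CODATA-2018.
# version: 2020.1 -- pinned; changing any value invalidates recorded sub-ppm errors.
element	mass
C	12.0
H	1.00782503207
N	14.00307400443
O	15.99491461957
S	31.97207117443
P	30.97376199842
Cu	62.92959772
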