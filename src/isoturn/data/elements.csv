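# Natural isotope abundances by nominal mass shift from the monoisotope.
# Values: IUPAC/NIST representative isotopic compositions.
element,mass_shift,abundance
H,0,0.999885
H,1,0.000115
C,0,0.9893
C,1,0.0107
N,0,0.99636
N,1,0.00364
O,0,0.99757
O,1,0.00038
O,2,0.00205
S,0,0.9499
S,1,0.0075
S,2,0.0425
S,4,0.0001
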