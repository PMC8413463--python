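# K-series emission-line energies (keV) and within-element relative
# intensities for the light elements typically fluorescing in wood.
# Energies are the standard weighted Ka1/Ka2 and Kb1 values from published
# X-ray emission-line reference tables (e.g. the X-ray data booklet /
# Bearden compilations), rounded to the meV. Kb/Ka intensity ratios are
# approximate literature values for pure elements.
element,line,energy_kev,relative_intensity
Na,Ka,1.041,1.00
Na,Kb,1.071,0.02
Mg,Ka,1.254,1.00
Mg,Kb,1.302,0.02
Al,Ka,1.487,1.00
Al,Kb,1.557,0.03
Si,Ka,1.740,1.00
Si,Kb,1.836,0.04
P,Ka,2.014,1.00
P,Kb,2.139,0.05
S,Ka,2.308,1.00
S,Kb,2.464,0.06
K,Ka,3.314,1.00
K,Kb,3.590,0.11
Ca,Ka,3.692,1.00
Ca,Kb,4.013,0.13
Fe,Ka,6.404,1.00
Fe,Kb,7.058,0.13
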