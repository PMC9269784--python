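# Published univariate Mann-Whitney p-values for the LUNGx reference cohort,
# as printed.
feature,p_value
max3ddiam,0.029
surfarea,0.012
volume,0.011
ael,0.334
afl,0.015
aco,0.017
kel,0.382
kfl,0.014
mps,0.019
sphericity,0.036
vdn,0.047
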