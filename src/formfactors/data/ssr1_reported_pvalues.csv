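# Published univariate Mann-Whitney p-values for the SSR-1 reference cohort,
# as printed (censored entries kept verbatim as '<0.001').
feature,p_value
max3ddiam,0.001
surfarea,<0.001
volume,<0.001
ael,0.193
afl,0.009
aco,0.008
kel,0.200
kfl,0.010
mps,0.005
sphericity,0.280
vdn,0.274
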