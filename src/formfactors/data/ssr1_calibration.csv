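# Reported per-group feature summaries (mean, SD) and group sizes for the
# SSR-1 reference cohort (PET/CT series, 38 benign / 71 malignant nodules).
# Rows with feature 'n' give the group sizes; 'mean' then holds the count.
feature,class,mean,sd
n,benign,38,
n,malignant,71,
max3ddiam,benign,18.8,7.4
max3ddiam,malignant,23.6,7.7
surfarea,benign,846.7,630.3
surfarea,malignant,1414.4,819.6
volume,benign,2138.1,2369.2
volume,malignant,4209.2,3481.3
ael,benign,0.077,0.056
ael,malignant,0.070,0.059
afl,benign,0.123,0.111
afl,malignant,0.077,0.079
aco,benign,0.800,0.115
aco,malignant,0.853,0.097
kel,benign,0.140,0.096
kel,malignant,0.126,0.099
kfl,benign,0.205,0.163
kfl,malignant,0.136,0.124
mps,benign,0.810,0.117
mps,malignant,0.864,0.092
sphericity,benign,0.774,0.067
sphericity,malignant,0.769,0.061
vdn,benign,0.435,0.112
vdn,malignant,0.431,0.097
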