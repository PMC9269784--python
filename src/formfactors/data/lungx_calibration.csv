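# Reported per-group feature summaries (mean, SD) and group sizes for the
# LUNGx reference cohort (TCIA challenge series, 42 benign / 41 malignant
# nodules). Rows with feature 'n' give the group sizes ('mean' holds the count).
feature,class,mean,sd
n,benign,42,
n,malignant,41,
max3ddiam,benign,23.5,15.1
max3ddiam,malignant,26.1,10.4
surfarea,benign,1457.2,1882.1
surfarea,malignant,1698.9,1252.6
volume,benign,2782.5,4550.9
volume,malignant,3436.0,3432.3
ael,benign,0.070,0.078
ael,malignant,0.069,0.059
afl,benign,0.201,0.139
afl,malignant,0.132,0.096
aco,benign,0.730,0.152
aco,malignant,0.799,0.110
kel,benign,0.127,0.126
kel,malignant,0.126,0.103
kfl,benign,0.315,0.198
kfl,malignant,0.224,0.139
mps,benign,0.734,0.148
mps,malignant,0.803,0.105
sphericity,benign,0.662,0.129
sphericity,malignant,0.625,0.087
vdn,benign,0.359,0.096
vdn,malignant,0.339,0.071
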