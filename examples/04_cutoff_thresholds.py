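"""Accuracy-maximising cutoff thresholds for the discriminative form factors.

For each of AFL, ACO, KFL and MPS the threshold that maximises overall
benign/malignant classification accuracy is computed on each of two
calibrated synthetic cohorts, on their pool, and as the dataset average.
The decision direction is fixed per feature: values above the ACO/MPS
cutoffs indicate malignancy, values below the AFL/KFL cutoffs do.
"""

import formfactors as ff

ds1 = ff.simulate_cohort(ff.load_calibration("SSR1"), seed=0)
ds2 = ff.simulate_cohort(ff.load_calibration("LUNGx"), seed=1)

table = ff.cutoff_table(ds1, ds2)
print(table.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print("\nA lesion with ACO above the pooled threshold (or AFL below its "
      "threshold) would be called malignant by the single-feature rule.")
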