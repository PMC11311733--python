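"""Quality control of a multi-nanoparticle quantification table.

Simulates a small serum cohort, then computes the per-protein %CV report on
linear-scale intensities, flags low-identification samples, and screens
peptide recovery masses against plate medians.
"""

import numpy as np

from coronadx import (
    SimParams,
    compute_cv,
    flag_outlier_samples,
    flag_peptide_recovery,
    generate_cohort,
)

quant, meta, annotations, truth = generate_cohort(
    SimParams(n_subjects=40, n_proteins=60, n_differential=0, seed=1))

strata = meta.set_index("sample_id")["case_status"].map(
    {0: "no_cancer", 1: "cancer"})
cv = compute_cv(quant, strata=strata)
by_np = cv.groupby("np_id")["cv_percent"].median()
print("Median %CV per nanoparticle (biological + technical variation):")
print(by_np.round(1).to_string())

flags = flag_outlier_samples(quant)
print(f"\nLow-identification samples (<25% of mean protein count): "
      f"{sum(flags.values())} of {len(flags)}")

rng = np.random.default_rng(2)
masses = {("PL00", f"S{i:04d}", "NP1"): float(rng.lognormal(np.log(10), 0.2))
          for i in range(15)}
masses[("PL00", "S0003", "NP1")] = 27.0   # 2.7x the plate median
recovery = flag_peptide_recovery(masses)
flagged = [k for k, v in recovery.items() if v]
print(f"Peptide-recovery flags (mass outside 0.5-2x plate median): {flagged}")
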