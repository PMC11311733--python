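"""Fold-change normalization, composition covariate and MNAR imputation.

Shows the per-(sample, NP) shifts removed by normalization, the per-sample
extracellular composition covariate recovered against the simulated truth,
and the down-shifted normal the imputation draws from.
"""

import numpy as np

from coronadx import (
    SimParams,
    composition_covariate,
    detection_filter,
    estimate_imputation_params,
    fold_change_normalize,
    generate_cohort,
    reference_set,
)

quant, meta, annotations, truth = generate_cohort(
    SimParams(n_subjects=60, n_proteins=80, n_differential=0,
              composition_sd=0.5, seed=6))

ref = reference_set(quant, min_detect=0.8)
norm, shifts = fold_change_normalize(quant, ref)
print(f"Reference proteins (>=80% of samples): {len(ref)} of 80")
print(f"Per-(sample, NP) shifts removed: mean |shift| = "
      f"{shifts['shift'].abs().mean():.3f} log2 units")

filt = detection_filter(norm, max_missing=0.6)
kept = filt.groupby(['protein_group', 'np_id']).ngroups
total = norm.groupby(['protein_group', 'np_id']).ngroups
print(f"Detection filter kept {kept}/{total} protein-NP series "
      f"(<60% missing)")

comp = composition_covariate(quant, annotations)
t = truth["samples"].set_index("sample_id")["true_composition"]
r = np.corrcoef(comp.reindex(t.index), t)[0, 1]
print(f"Composition covariate vs simulated truth: Pearson r = {r:.3f}")

params = estimate_imputation_params(filt, value_col="normalized_log2")
print(f"Imputation law: Normal({params.mean:.2f}, {params.sd:.2f}) — "
      f"I0 = {params.I0:.2f}, sigma = {params.sigma:.2f}; missing values are "
      f"drawn 1.8 sigma below the dataset mean with width 0.3 sigma")
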