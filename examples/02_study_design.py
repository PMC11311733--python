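"""Stratified plate randomization and train/validation splitting.

Assigns a cohort to plates of 15 with balanced case/control counts, checks
covariate balance across plates, and draws a stratified 70/30 split.
"""

import pandas as pd

from coronadx import SimParams, assign_plates, generate_cohort, split_train_validation

_, meta, _, _ = generate_cohort(
    SimParams(n_subjects=120, n_proteins=5, n_differential=0, seed=3))

plan = assign_plates(meta, n_per_plate=15, max_attempts=20, seed=4)
plates = pd.Series(plan.plate_assignment)
case = meta.set_index("sample_id")["case_status"]
print("Cases per plate (round-robin keeps these near-equal):")
print(case.groupby(plates).sum().to_string())
print(f"\nRerandomizations needed: {plan.n_rerandomizations}")
print("Balance tests across plates (p > 0.05 = no obvious imbalance):")
print(plan.balance_report.round(3).to_string(index=False))

split = split_train_validation(meta, train_fraction=0.7, seed=5)
counts = pd.Series(split.split).value_counts()
print(f"\nSplit sizes: {counts.to_dict()} "
      f"(train fraction {counts['train'] / len(meta):.2f})")
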