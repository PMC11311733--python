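"""Stratified plate randomization and train/validation splitting.

Plates hold a fixed number of experimental samples; cases and controls are
dealt round-robin within shuffled strata, and the resulting layout is
checked for covariate balance across plates (Kruskal-Wallis for continuous,
chi-squared for categorical variables).  Layouts with any balance p-value
below ``alpha`` are rerandomized, up to a retry budget.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency, kruskal

__all__ = ["DesignPlan", "assign_plates", "split_train_validation"]

CONTINUOUS_BALANCE = ["age", "psa"]
CATEGORICAL_BALANCE = ["cohort", "race_ethnicity"]


@dataclass
class DesignPlan:
    plate_assignment: dict[str, str] = field(default_factory=dict)
    split: dict[str, str] = field(default_factory=dict)
    balance_report: pd.DataFrame | None = None
    n_rerandomizations: int = 0
    balanced: bool = True


def _balance_tests(meta: pd.DataFrame, plates: pd.Series) -> pd.DataFrame:
    rows = []
    groups = meta.groupby(plates, sort=True)
    for var in CONTINUOUS_BALANCE:
        if var not in meta.columns:
            continue
        arrs = [g[var].dropna().to_numpy() for _, g in groups]
        arrs = [a for a in arrs if len(a)]
        if len(arrs) < 2 or all(np.ptp(np.concatenate(arrs)) == 0 for _ in [0]):
            rows.append((var, "kruskal", np.nan, 1.0))
            continue
        try:
            stat, p = kruskal(*arrs)
        except ValueError:  # all values identical
            stat, p = np.nan, 1.0
        rows.append((var, "kruskal", stat, p))
    for var in CATEGORICAL_BALANCE + ["case_status"]:
        if var not in meta.columns:
            continue
        tab = pd.crosstab(plates, meta[var])
        if tab.shape[1] < 2 or tab.shape[0] < 2:
            rows.append((var, "chi2", np.nan, 1.0))
            continue
        try:
            stat, p, *_ = chi2_contingency(tab.to_numpy())
        except ValueError:
            stat, p = np.nan, 1.0
        rows.append((var, "chi2", stat, p))
    return pd.DataFrame(rows, columns=["variable", "test", "statistic", "p"])


def _deal_plates(meta: pd.DataFrame, n_per_plate: int,
                 rng: np.random.Generator) -> pd.Series:
    n = len(meta)
    n_plates = int(np.ceil(n / n_per_plate))
    case = meta["case_status"].to_numpy().astype(int)
    order = np.concatenate([
        rng.permutation(np.flatnonzero(case == 1)),
        rng.permutation(np.flatnonzero(case == 0)),
    ])
    plate_of = np.empty(n, dtype=int)
    # round-robin deal: consecutive samples from each shuffled stratum go to
    # successive plates, forcing near-equal case counts per plate
    for pos, idx in enumerate(order):
        plate_of[idx] = pos % n_plates
    counts = np.bincount(plate_of, minlength=n_plates)
    if counts.max() > n_per_plate:
        # possible when n_plates * n_per_plate barely exceeds n; rebalance by
        # moving overflow to the lightest plates
        for plate in np.flatnonzero(counts > n_per_plate):
            members = np.flatnonzero(plate_of == plate)
            while counts[plate] > n_per_plate:
                target = int(np.argmin(counts))
                mover = members[-1]
                members = members[:-1]
                plate_of[mover] = target
                counts[plate] -= 1
                counts[target] += 1
    return pd.Series([f"PL{i:02d}" for i in plate_of],
                     index=meta["sample_id"].to_numpy())


def assign_plates(
    meta: pd.DataFrame,
    n_per_plate: int = 15,
    max_attempts: int = 50,
    seed: int = 0,
    alpha: float = 0.05,
) -> DesignPlan:
    """Stratified plate randomization with rerandomization on imbalance.

    Cases and controls are shuffled and dealt round-robin across plates.
    Age and PSA balance is tested by Kruskal-Wallis across plates, cohort and
    race/ethnicity by chi-squared on counts; any balance p below ``alpha``
    triggers a rerandomization, up to ``max_attempts``.  If the budget is
    exhausted the best-balanced plan (largest minimum p) is returned with
    ``balanced=False``.
    """
    rng = np.random.default_rng(seed)
    best: tuple[float, pd.Series, pd.DataFrame] | None = None
    for attempt in range(max_attempts):
        plates = _deal_plates(meta, n_per_plate, rng)
        report = _balance_tests(meta.set_index("sample_id").loc[plates.index].reset_index(),
                                plates.reset_index(drop=True))
        min_p = float(report["p"].min()) if len(report) else 1.0
        if best is None or min_p > best[0]:
            best = (min_p, plates, report)
        if min_p >= alpha:
            return DesignPlan(
                plate_assignment=plates.to_dict(),
                balance_report=report,
                n_rerandomizations=attempt,
                balanced=True,
            )
    min_p, plates, report = best
    return DesignPlan(
        plate_assignment=plates.to_dict(),
        balance_report=report,
        n_rerandomizations=max_attempts - 1,
        balanced=False,
    )


def split_train_validation(
    meta: pd.DataFrame,
    train_fraction: float = 0.7,
    seed: int = 0,
) -> DesignPlan:
    """Stratified train/validation split.

    Strata cross case/control status, race/ethnicity and quartile bins of
    age and PSA.  Within each stratum round(f * n) samples go to training;
    singleton strata go to training.
    """
    rng = np.random.default_rng(seed)
    df = meta.copy()
    parts = [df["case_status"].astype(str)]
    if "race_ethnicity" in df.columns:
        parts.append(df["race_ethnicity"].astype(str))
    for var in ("age", "psa"):
        if var in df.columns:
            binned = pd.qcut(df[var], 4, labels=False, duplicates="drop")
            parts.append(binned.astype(str))
    stratum = parts[0]
    for extra in parts[1:]:
        stratum = stratum + "|" + extra
    split: dict[str, str] = {}
    for _, members in df.groupby(stratum, sort=True):
        sids = members["sample_id"].to_numpy()
        if len(sids) == 1:
            split[sids[0]] = "train"
            continue
        k = int(np.rint(train_fraction * len(sids)))
        perm = rng.permutation(len(sids))
        for j, idx in enumerate(perm):
            split[sids[idx]] = "train" if j < k else "validation"
    return DesignPlan(split=split)
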