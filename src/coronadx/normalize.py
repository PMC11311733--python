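"""Fold-change normalization, composition covariate, detection filtering and
left-censored (MNAR) imputation.

Normalization removes one additive shift per (sample, nanoparticle): the
fold change of a record is its log2 intensity minus the per-(protein, NP)
median across samples, and the shift of a (sample, NP) is the median fold
change over a reference set of high-coverage proteins.  Subtracting the
shift from every record of that (sample, NP) centers the sample against the
cohort without letting sparsely observed proteins drive the correction.

Imputation replaces missing values by draws from a down-shifted narrow
normal, Normal(I0 - downshift * sigma, width * sigma), with I0 and sigma the
mean and standard deviation of all observed protein log2 intensities in the
dataset — encoding the assumption that missing values sit below the
detection limit.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ImputationParams",
    "reference_set",
    "protein_np_medians",
    "fold_change_normalize",
    "composition_covariate",
    "detection_filter",
    "select_best_np",
    "impute_mnar",
    "estimate_imputation_params",
    "impute_best_np",
]


@dataclass
class ImputationParams:
    I0: float
    sigma: float
    downshift: float = 1.8
    width: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError("sigma must be positive")

    @property
    def mean(self) -> float:
        return self.I0 - self.downshift * self.sigma

    @property
    def sd(self) -> float:
        return self.width * self.sigma


def estimate_imputation_params(
    q: pd.DataFrame, value_col: str = "log2_intensity",
    downshift: float = 1.8, width: float = 0.3, seed: int = 0,
) -> ImputationParams:
    """Estimate I0 and sigma from every observed intensity in the dataset."""
    vals = q[value_col].to_numpy(dtype=float)
    vals = vals[np.isfinite(vals)]
    return ImputationParams(float(vals.mean()), float(vals.std(ddof=1)),
                            downshift, width, seed)


def reference_set(q: pd.DataFrame, min_detect: float = 0.8) -> set[str]:
    """Protein groups detected (any NP) in at least ``min_detect`` of samples."""
    n_samples = q["sample_id"].nunique()
    if n_samples == 0:
        return set()
    counts = q.groupby("protein_group")["sample_id"].nunique()
    return set(counts.index[counts >= min_detect * n_samples])


def protein_np_medians(
    q: pd.DataFrame, value_col: str = "log2_intensity"
) -> pd.Series:
    """Per-(protein_group, np_id) median intensity across samples."""
    return q.groupby(["protein_group", "np_id"])[value_col].median()


def fold_change_normalize(
    q: pd.DataFrame,
    ref: set[str] | None = None,
    value_col: str = "log2_intensity",
    protein_medians: pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove per-(sample, NP) median fold-change shifts.

    Returns ``(normalized, shifts)``: the input frame with an added
    ``normalized_log2`` column, and a frame of the per-(sample_id, np_id)
    shifts.  Only reference proteins inform the shifts, but every record is
    normalized.  A (sample, NP) with no observed reference protein gets
    shift 0.

    ``protein_medians`` fixes the cohort reference locations (as computed by
    :func:`protein_np_medians`); passing the medians of a reference cohort
    makes the shift fit exactly idempotent and location-equivariant, and is
    how held-out samples are normalized against a training cohort.  When
    omitted the medians of ``q`` itself are used.
    """
    if ref is None:
        ref = reference_set(q)
    out = q.copy()
    if protein_medians is None:
        med = out.groupby(["protein_group", "np_id"])[value_col].transform("median")
    else:
        keys = pd.MultiIndex.from_frame(out[["protein_group", "np_id"]])
        med = pd.Series(protein_medians.reindex(keys).to_numpy(), index=out.index)
    fc = out[value_col] - med
    ref_mask = out["protein_group"].isin(ref) if ref else pd.Series(True, index=out.index)
    shifts = (
        fc[ref_mask]
        .groupby([out.loc[ref_mask, "sample_id"], out.loc[ref_mask, "np_id"]])
        .median()
        .rename("shift")
    )
    keys = pd.MultiIndex.from_frame(out[["sample_id", "np_id"]])
    shift_per_row = shifts.reindex(keys).fillna(0.0).to_numpy()
    out["normalized_log2"] = out[value_col] - shift_per_row
    shift_frame = shifts.reset_index()
    shift_frame.columns = ["sample_id", "np_id", "shift"]
    # report a zero shift for (sample, NP) pairs lacking reference coverage
    all_pairs = out[["sample_id", "np_id"]].drop_duplicates()
    shift_frame = all_pairs.merge(shift_frame, how="left").fillna({"shift": 0.0})
    return out, shift_frame


def composition_covariate(
    q: pd.DataFrame,
    annotations: dict[str, set[str]],
    term: str = "Extracellular",
    value_col: str = "log2_intensity",
) -> pd.Series:
    """Per-sample median fold change of proteins annotated with ``term``.

    The fold change of a record is its intensity minus the per-(protein, NP)
    median across the cohort; (protein, NP) pairs are pooled within each
    sample.  Samples with no annotated observation get NaN (callers
    mean-impute downstream).
    """
    members = annotations.get(term, set())
    if not members:
        raise ValueError(f"annotation term {term!r} has no member proteins")
    med = q.groupby(["protein_group", "np_id"])[value_col].transform("median")
    fc = q[value_col] - med
    mask = q["protein_group"].isin(members)
    cov = fc[mask].groupby(q.loc[mask, "sample_id"]).median()
    return cov.reindex(q["sample_id"].unique()).rename("composition")


def detection_filter(
    q: pd.DataFrame, max_missing: float = 0.6,
    n_samples: int | None = None,
) -> pd.DataFrame:
    """Drop (protein, NP) series absent in ``max_missing`` or more of samples.

    The comparison is strict: a series missing exactly the threshold
    fraction is excluded.  ``n_samples`` defaults to the number of distinct
    samples in the table.
    """
    if q.empty:
        return q.copy()
    if n_samples is None:
        n_samples = q["sample_id"].nunique()
    counts = q.groupby(["protein_group", "np_id"])["sample_id"].nunique()
    missing_frac = 1.0 - counts / n_samples
    keep = counts.index[missing_frac < max_missing]
    idx = pd.MultiIndex.from_frame(q[["protein_group", "np_id"]])
    return q[idx.isin(keep)].reset_index(drop=True)


def select_best_np(q: pd.DataFrame, protein: str) -> str:
    """Nanoparticle with the most non-missing measurements for ``protein``.

    Ties break to the lowest NP identifier.
    """
    sub = q[q["protein_group"] == protein]
    if sub.empty:
        raise KeyError(f"protein {protein!r} not present")
    counts = sub.groupby("np_id")["sample_id"].nunique().sort_index()
    return str(counts.index[np.argmax(counts.to_numpy())])


def _series_rng(params: ImputationParams, key: str) -> np.random.Generator:
    # independent, reproducible stream per series so parallel or reordered
    # execution yields identical draws
    return np.random.default_rng(
        np.random.SeedSequence([params.seed, zlib.crc32(key.encode())])
    )


def impute_mnar(
    series: pd.Series, params: ImputationParams, key: str | None = None
) -> pd.Series:
    """Fill missing entries with draws from the down-shifted normal.

    ``key`` names the series (e.g. "P0001/NP2") and seeds its private
    random stream; observed entries are untouched.
    """
    out = series.astype(float).copy()
    mask = out.isna()
    if mask.any():
        rng = _series_rng(params, key or str(series.name))
        out[mask] = rng.normal(params.mean, params.sd, int(mask.sum()))
    return out


def impute_best_np(
    q: pd.DataFrame,
    samples: np.ndarray | list[str],
    params: ImputationParams,
    value_col: str = "normalized_log2",
) -> pd.DataFrame:
    """Complete each protein's best-covered NP series by MNAR imputation.

    For every protein the NP with the highest non-missing count is filled to
    the full sample list; all other NP series keep only observed values.
    Returns a long frame with columns (sample_id, np_id, protein_group,
    value_col, imputed).
    """
    samples = np.asarray(samples, dtype=object)
    pieces = []
    for protein, sub in q.groupby("protein_group", sort=True):
        counts = sub.groupby("np_id")["sample_id"].nunique().sort_index()
        best = counts.index[np.argmax(counts.to_numpy())]
        best_rows = sub[sub["np_id"] == best]
        series = (
            best_rows.set_index("sample_id")[value_col]
            .reindex(samples)
        )
        was_missing = series.isna().to_numpy()
        filled = impute_mnar(series, params, key=f"{protein}/{best}")
        comp = pd.DataFrame({
            "sample_id": samples,
            "np_id": best,
            "protein_group": protein,
            value_col: filled.to_numpy(),
            "imputed": was_missing,
        })
        others = sub[sub["np_id"] != best].copy()
        others = others[["sample_id", "np_id", "protein_group", value_col]]
        others["imputed"] = False
        pieces.append(comp)
        if len(others):
            pieces.append(others)
    return pd.concat(pieces, ignore_index=True)
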