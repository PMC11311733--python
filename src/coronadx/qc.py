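"""Quality-control computations on quantification tables.

Covers the per-protein %CV report on unnormalized linear-scale intensities,
the low-identification outlier-sample flag, and the plate-wise peptide
recovery flag used during sample preparation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["compute_cv", "flag_outlier_samples", "flag_peptide_recovery"]


def compute_cv(
    q: pd.DataFrame,
    strata: dict[str, str] | pd.Series | None = None,
) -> pd.DataFrame:
    """Percent coefficient of variation per (protein_group, np_id, stratum).

    Intensities in ``q`` are log2; they are un-logged (2**x) before the CV is
    computed, so the report reflects linear-scale, unnormalized variation.
    Uses the sample standard deviation (n-1 denominator).  Combinations with
    fewer than two observations, or zero mean, get a null CV.

    ``strata`` maps sample_id -> stratum label (e.g. cancer status); when
    omitted all samples form a single stratum.
    """
    if q.empty:
        return pd.DataFrame(
            columns=["protein_group", "np_id", "stratum", "cv_percent", "n_obs"]
        )
    df = q.copy()
    if strata is None:
        df["stratum"] = "all"
    else:
        s = pd.Series(strata) if isinstance(strata, dict) else strata
        df["stratum"] = df["sample_id"].map(s).fillna("all")
    df["linear"] = np.exp2(df["log2_intensity"])
    grp = df.groupby(["protein_group", "np_id", "stratum"], sort=True)["linear"]
    out = grp.agg(n_obs="count", mean="mean", sd=lambda v: v.std(ddof=1)).reset_index()
    valid = (out["n_obs"] >= 2) & (out["mean"] != 0)
    out["cv_percent"] = np.where(valid, 100.0 * out["sd"] / out["mean"], np.nan)
    return out[["protein_group", "np_id", "stratum", "cv_percent", "n_obs"]]


def flag_outlier_samples(
    q: pd.DataFrame, *, fraction: float = 0.25, per_np: bool = False
) -> dict[str, bool]:
    """Flag samples identifying < ``fraction`` of the mean protein count.

    A sample's count is the number of distinct protein groups with at least
    one observed intensity in any nanoparticle channel (or per channel when
    ``per_np`` is set, in which case a sample is flagged if any channel is
    low).
    """
    if q.empty:
        return {}
    if per_np:
        counts = q.groupby(["sample_id", "np_id"])["protein_group"].nunique()
        means = counts.groupby("np_id").mean()
        flagged = counts < fraction * counts.index.get_level_values("np_id").map(means)
        out: dict[str, bool] = {}
        for (sid, _), bad in flagged.items():
            out[sid] = out.get(sid, False) or bool(bad)
        return out
    counts = q.groupby("sample_id")["protein_group"].nunique()
    cutoff = fraction * counts.mean()
    return {sid: bool(c < cutoff) for sid, c in counts.items()}


def flag_peptide_recovery(
    masses: dict[tuple[str, str, str], float],
    *,
    high: float = 2.0,
    low: float = 0.5,
) -> dict[tuple[str, str, str], bool]:
    """Flag outlier peptide recovery against the plate/NP median mass.

    ``masses`` maps (plate_id, sample_id, np_id) -> recovered peptide mass in
    micrograms.  A sample is flagged when its mass is more than ``high``-fold
    or less than ``low``-fold the median mass of all samples on the same
    plate for the same nanoparticle.
    """
    for key, m in masses.items():
        if not (m > 0):
            raise ValueError(f"nonpositive peptide mass for {key}")
    medians: dict[tuple[str, str], float] = {}
    groups: dict[tuple[str, str], list[float]] = {}
    for (plate, _sid, npid), m in masses.items():
        groups.setdefault((plate, npid), []).append(m)
    for k, vals in groups.items():
        medians[k] = float(np.median(vals))
    out = {}
    for (plate, sid, npid), m in masses.items():
        ratio = m / medians[(plate, npid)]
        out[(plate, sid, npid)] = bool(ratio > high or ratio < low)
    return out
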