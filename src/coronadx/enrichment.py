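"""Rank-based 1D annotation enrichment.

For each annotation term, member protein values (typically mixed-model log2
fold changes) are compared against non-member values with a two-sided
Mann-Whitney U test.  The enrichment score is the rank-biserial correlation

    s = 2 U / (n1 * n2) - 1,   s in [-1, 1],

positive when member values rank above non-members.  Scores are exact under
monotone transforms of the input values; p-values use exact enumeration for
small terms and the tie-corrected normal approximation otherwise, with
Benjamini-Hochberg correction across the tested terms.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .differential import bh_adjust

__all__ = ["enrich_1d"]


def enrich_1d(
    values: dict[str, float] | pd.Series,
    annotations: dict[str, set[str]],
    min_members: int = 3,
) -> pd.DataFrame:
    """Score every annotation term against a protein -> value mapping.

    Terms with fewer than ``min_members`` scored members (or no
    non-members) are skipped.  Returns a frame with columns term,
    n_members_scored, s, p, q sorted by q then term.
    """
    vals = pd.Series(values, dtype=float)
    if not np.isfinite(vals.to_numpy()).all():
        raise ValueError("values must be finite")
    proteins = vals.index.to_numpy()
    rows = []
    for term in sorted(annotations):
        member_mask = np.isin(proteins, list(annotations[term]))
        n1 = int(member_mask.sum())
        n2 = int(len(vals) - n1)
        if n1 < min_members or n2 == 0:
            continue
        x = vals.to_numpy()[member_mask]
        yv = vals.to_numpy()[~member_mask]
        if np.ptp(vals.to_numpy()) == 0:
            s, p = 0.0, 1.0
        else:
            method = "exact" if n1 * n2 <= 400 and not _has_ties(vals) else "asymptotic"
            res = mannwhitneyu(x, yv, alternative="two-sided", method=method)
            u1 = float(res.statistic)
            s = 2.0 * u1 / (n1 * n2) - 1.0
            p = float(res.pvalue)
        rows.append((term, n1, s, p))
    out = pd.DataFrame(rows, columns=["term", "n_members_scored", "s", "p"])
    out["q"] = bh_adjust(out["p"].to_numpy()) if len(out) else np.nan
    return out.sort_values(["q", "term"]).reset_index(drop=True)


def _has_ties(vals: pd.Series) -> bool:
    arr = vals.to_numpy()
    return len(np.unique(arr)) < len(arr)
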