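"""Greedy maximum-coverage sample selection for spectral-library building.

Given a sample x peptide boolean identification matrix, MaxID repeatedly
picks the sample contributing the most not-yet-covered peptides.  Coverage
is submodular, so the greedy marginal gains are nonincreasing and the
greedy prefix achieves at least (1 - 1/e) of the optimal coverage for any
selection size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SelectionResult", "maxid_select", "saturation_curve"]


@dataclass
class SelectionResult:
    order: list[str]
    marginal_gain: list[int]
    cumulative_unique: list[int]


def maxid_select(
    M: pd.DataFrame,
    k: int | None = None,
    coverage_target: float | None = None,
) -> SelectionResult:
    """Greedy selection of samples maximizing cumulative unique peptides.

    Stops after ``k`` samples, or when ``coverage_target`` (a fraction of
    the total unique peptides in the matrix) is reached, or when no sample
    adds a new peptide.  Ties break to the lexicographically smallest
    sample id.
    """
    if M.empty:
        raise ValueError("identification matrix is empty")
    if k is not None and k > len(M):
        raise ValueError("k exceeds the number of samples")
    if coverage_target is not None and not 0 < coverage_target <= 1:
        raise ValueError("coverage target must lie in (0, 1]")
    A = M.to_numpy(dtype=bool)
    # sort once so np.argmax's first-wins rule realises the lexicographic tie-break
    sample_order = np.argsort(M.index.to_numpy().astype(str), kind="stable")
    A = A[sample_order]
    ids = M.index.to_numpy().astype(str)[sample_order]
    total = int(A.any(axis=0).sum())
    budget = k if k is not None else len(M)
    target = int(np.ceil(coverage_target * total)) if coverage_target else None

    covered = np.zeros(A.shape[1], dtype=bool)
    available = np.ones(len(A), dtype=bool)
    order, gains, cumulative = [], [], []
    for _ in range(budget):
        new = A & ~covered
        counts = new.sum(axis=1)
        counts[~available] = -1
        best = int(np.argmax(counts))
        gain = int(counts[best])
        if gain <= 0:
            break
        covered |= A[best]
        available[best] = False
        order.append(str(ids[best]))
        gains.append(gain)
        cumulative.append(int(covered.sum()))
        if target is not None and covered.sum() >= target:
            break
    return SelectionResult(order, gains, cumulative)


def saturation_curve(M: pd.DataFrame, order: list[str]) -> pd.DataFrame:
    """Cumulative distinct peptides after each prefix of ``order``."""
    unknown = [s for s in order if s not in M.index]
    if unknown:
        raise KeyError(f"samples not in matrix: {unknown[:3]}")
    covered = np.zeros(M.shape[1], dtype=bool)
    rows = []
    for i, sid in enumerate(order, start=1):
        covered |= M.loc[sid].to_numpy(dtype=bool)
        rows.append((i, sid, int(covered.sum())))
    return pd.DataFrame(rows, columns=["n_samples", "sample_id",
                                       "cumulative_unique"])
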