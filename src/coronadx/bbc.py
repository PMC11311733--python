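"""Bootstrapped bias-corrected cross-validation (BBC-CV).

Pooled out-of-fold predictions (one column per pipeline configuration) are
resampled with replacement; on each iteration the best configuration is
selected from the in-bag rows using the composite (summed z-scored
AUC/PPV/NPV) criterion, and the selected configuration — and a clinical
benchmark score, on the identical subjects — is evaluated on the out-of-bag
rows.  The distribution of out-of-bag metrics across iterations corrects
the winner's-curse optimism of reporting the best pooled CV metric, and its
2.5/97.5 percentiles give confidence intervals for the metrics and for the
signature-minus-benchmark differences.

Also provides held-out validation tests (one-sided DeLong for AUC, paired
bootstrap for average PPV/NPV) and the BBC-weighted feature-importance
summary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .classifier import FoldPredictionMatrix, composite_select
from .metrics import MetricTriple, evaluate_metrics

__all__ = [
    "BBCResult",
    "bbc_evaluate",
    "holdout_validate",
    "summarize_importance",
    "delong_auc_test",
]

_METRICS = ("auc", "avg_ppv", "avg_npv")


@dataclass
class BBCResult:
    point: dict[str, float]
    ci: dict[str, tuple[float, float]]
    benchmark_point: dict[str, float] | None
    benchmark_ci: dict[str, tuple[float, float]] | None
    delta_point: dict[str, float] | None
    delta_ci: dict[str, tuple[float, float]] | None
    config_selection_frequency: dict
    oob_metrics: pd.DataFrame = field(repr=False, default=None)
    n_redrawn: int = 0


def _summaries(mat: np.ndarray) -> tuple[dict, dict]:
    point = {m: float(mat[:, i].mean()) for i, m in enumerate(_METRICS)}
    ci = {
        m: (float(np.percentile(mat[:, i], 2.5)),
            float(np.percentile(mat[:, i], 97.5)))
        for i, m in enumerate(_METRICS)
    }
    return point, ci


def bbc_evaluate(
    fp: FoldPredictionMatrix,
    benchmark: pd.Series | np.ndarray | None = None,
    B: int = 500,
    seed: int = 0,
) -> BBCResult:
    """Bootstrapped bias-corrected evaluation of a fold-prediction matrix.

    Scores are averaged over CV repeat seeds per subject before
    bootstrapping.  Degenerate draws whose in-bag or out-of-bag rows hold a
    single class are redrawn, keeping B fixed.
    """
    if B < 50:
        import warnings

        warnings.warn("B < 50 gives unstable percentile intervals")
    pool = fp.pooled()
    y = fp.labels
    n, n_cfg = pool.shape
    if benchmark is not None:
        if isinstance(benchmark, pd.Series):
            bench = benchmark.reindex(fp.subjects).to_numpy(float)
        else:
            bench = np.asarray(benchmark, float)
    else:
        bench = None
    rng = np.random.default_rng(seed)
    sig_rows = np.zeros((B, len(_METRICS)))
    ben_rows = np.zeros((B, len(_METRICS))) if bench is not None else None
    chosen = []
    n_redrawn = 0
    b = 0
    while b < B:
        idx = rng.integers(0, n, n)
        oob = np.setdiff1d(np.arange(n), idx)
        if len(np.unique(y[idx])) < 2 or len(oob) == 0 or len(np.unique(y[oob])) < 2:
            n_redrawn += 1
            continue
        inbag_metrics = {
            cfg: evaluate_metrics(pool[idx, j], y[idx])
            for j, cfg in enumerate(fp.configs)
        }
        best = composite_select(inbag_metrics)
        jbest = fp.configs.index(best)
        chosen.append(best)
        sig_rows[b] = evaluate_metrics(pool[oob, jbest], y[oob]).as_array()
        if bench is not None:
            ben_rows[b] = evaluate_metrics(bench[oob], y[oob]).as_array()
        b += 1

    point, ci = _summaries(sig_rows)
    freq_series = pd.Series(chosen).value_counts(normalize=True)
    freq = {k: float(v) for k, v in freq_series.items()}
    if bench is not None:
        bpoint, bci = _summaries(ben_rows)
        delta = sig_rows - ben_rows
        dpoint, dci = _summaries(delta)
    else:
        bpoint = bci = dpoint = dci = None
    oob_df = pd.DataFrame(sig_rows, columns=list(_METRICS))
    oob_df["selected_config"] = chosen
    return BBCResult(
        point=point, ci=ci,
        benchmark_point=bpoint, benchmark_ci=bci,
        delta_point=dpoint, delta_ci=dci,
        config_selection_frequency=freq,
        oob_metrics=oob_df, n_redrawn=n_redrawn,
    )


def delong_auc_test(
    scores_a: np.ndarray, scores_b: np.ndarray, y: np.ndarray
) -> tuple[float, float]:
    """One-sided paired DeLong test of AUC(a) > AUC(b).

    Returns (delta_auc, p).  The variance of the AUC difference uses the
    DeLong structural-components estimator on the paired score vectors;
    a zero difference with zero variance yields p = 0.5 by continuity.
    """
    y = np.asarray(y, int)
    pos, neg = y == 1, y == 0
    m, k = int(pos.sum()), int(neg.sum())
    if m == 0 or k == 0:
        raise ValueError("both classes required")

    def components(s):
        # midrank placement of each positive among negatives and vice versa
        sp, sn = s[pos], s[neg]
        all_r = rankdata(np.concatenate([sp, sn]))
        rp, rn = all_r[:m], all_r[m:]
        auc = (rp.sum() - m * (m + 1) / 2) / (m * k)
        v10 = (rp - rankdata(sp)) / k          # per-positive components
        v01 = 1.0 - (rn - rankdata(sn)) / m    # per-negative components
        return auc, v10, v01

    auc_a, va10, va01 = components(np.asarray(scores_a, float))
    auc_b, vb10, vb01 = components(np.asarray(scores_b, float))
    delta = auc_a - auc_b
    s10 = np.cov(np.vstack([va10, vb10]), ddof=1)
    s01 = np.cov(np.vstack([va01, vb01]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / k
    if var <= 0:
        p = 0.5 if delta == 0 else (0.0 if delta > 0 else 1.0)
    else:
        p = float(norm.sf(delta / np.sqrt(var)))
    return float(delta), p


def holdout_validate(
    model_scores: np.ndarray,
    benchmark_scores: np.ndarray,
    y: np.ndarray,
    n_boot: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Held-out comparison of signature vs benchmark.

    AUC difference: one-sided paired DeLong test (H1: model > benchmark).
    Average PPV/NPV differences: paired bootstrap one-sided p, with ties at
    zero counted half.
    """
    y = np.asarray(y, int)
    if len(np.unique(y)) < 2:
        raise ValueError("validation labels hold a single class")
    model_scores = np.asarray(model_scores, float)
    benchmark_scores = np.asarray(benchmark_scores, float)
    mm = evaluate_metrics(model_scores, y)
    bb = evaluate_metrics(benchmark_scores, y)
    d_auc, p_auc = delong_auc_test(model_scores, benchmark_scores, y)

    rng = np.random.default_rng(seed)
    n = len(y)
    d_ppv = np.empty(n_boot)
    d_npv = np.empty(n_boot)
    filled = 0
    while filled < n_boot:
        idx = rng.integers(0, n, n)
        if len(np.unique(y[idx])) < 2:
            continue
        mb = evaluate_metrics(model_scores[idx], y[idx])
        bbb = evaluate_metrics(benchmark_scores[idx], y[idx])
        d_ppv[filled] = mb.avg_ppv - bbb.avg_ppv
        d_npv[filled] = mb.avg_npv - bbb.avg_npv
        filled += 1

    def boot_p(d):
        return float((d < 0).mean() + 0.5 * (d == 0).mean())

    rows = [
        ("auc", mm.auc, bb.auc, d_auc, p_auc),
        ("avg_ppv", mm.avg_ppv, bb.avg_ppv, mm.avg_ppv - bb.avg_ppv, boot_p(d_ppv)),
        ("avg_npv", mm.avg_npv, bb.avg_npv, mm.avg_npv - bb.avg_npv, boot_p(d_npv)),
    ]
    return pd.DataFrame(rows, columns=["metric", "model", "benchmark",
                                       "delta", "p_one_sided"])


def summarize_importance(
    fp: FoldPredictionMatrix, bbc: BBCResult
) -> pd.DataFrame:
    """Config-frequency-weighted feature importance summary.

    For each configuration, importances are averaged over its (seed, fold)
    models with absent features contributing zero; configuration averages
    are then combined with the BBC selection frequencies as weights.  The
    inclusion frequency of a feature is the selection-frequency-weighted
    fraction of that configuration's fold models containing it.
    """
    if not bbc.config_selection_frequency:
        raise ValueError("empty configuration selection frequencies")
    if not fp.importance_records:
        raise ValueError("fold-level importances were not recorded")
    by_cfg: dict = {}
    for rec in fp.importance_records:
        by_cfg.setdefault(rec["config"], []).append(rec)
    scores: dict[str, float] = {}
    incl: dict[str, float] = {}
    for cfg, weight in bbc.config_selection_frequency.items():
        recs = by_cfg.get(cfg, [])
        if not recs:
            continue
        feats = sorted({f for r in recs for f in r["features"]})
        fmap = {f: i for i, f in enumerate(feats)}
        acc = np.zeros(len(feats))
        cnt = np.zeros(len(feats))
        for r in recs:
            for f, v in zip(r["features"], r["importance"]):
                acc[fmap[f]] += float(v)
                cnt[fmap[f]] += 1.0
        mean_imp = acc / len(recs)      # absent folds contribute zero
        frac = cnt / len(recs)
        for f in feats:
            scores[f] = scores.get(f, 0.0) + weight * mean_imp[fmap[f]]
            incl[f] = incl.get(f, 0.0) + weight * frac[fmap[f]]
    out = pd.DataFrame({
        "feature": list(scores),
        "score": [scores[f] for f in scores],
        "inclusion_frequency": [incl[f] for f in scores],
    })
    return out.sort_values("score", ascending=False).reset_index(drop=True)
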