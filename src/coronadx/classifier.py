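"""Multimarker classification pipeline with nested cross-validation.

The pipeline turns a quantification table into per-subject case scores:

1.  drop protein-NP features with more than 60% missingness;
2.  fold-change normalize and compute the per-sample composition covariate;
3.  residualize each feature against a plate random intercept plus the
    composition covariate (a per-feature random-intercept model), replacing
    intensities with residuals;
4.  zero-impute remaining missing entries (missing = not present in the
    sample);
5.  rank features by two-sided Wilcoxon rank-sum p in cases vs controls;
6.  among the top-ranked pool, drop features that have a higher-coverage
    correlate above a cutoff rho;
7.  keep the top m surviving features and fit a random forest, tuned by
    inner cross-validation over the mtry grid.

The (m, rho) grid is explored by nested cross-validation: every
preprocessing and selection step is refit inside each outer-training split,
and out-of-fold scores are pooled into a subjects x configurations matrix —
the substrate for bootstrapped bias-corrected evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .lmm import fit_variance_components, random_intercept_blups
from .metrics import MetricTriple, evaluate_metrics
from .normalize import composition_covariate, fold_change_normalize, reference_set

__all__ = [
    "PipelineConfig",
    "FeatureMatrix",
    "FoldPredictionMatrix",
    "FeaturePreprocessor",
    "preprocess_features",
    "rank_features_wilcoxon",
    "correlation_filter",
    "composite_select",
    "nested_cv",
    "default_grid",
]


@dataclass(frozen=True)
class PipelineConfig:
    """One point of the pipeline hyperparameter grid."""

    m: int
    rho: float
    top_pool: int = 1000
    n_trees: int = 500

    def __post_init__(self) -> None:
        if self.m > self.top_pool:
            raise ValueError("m must not exceed top_pool")

    @property
    def key(self) -> tuple[int, float]:
        return (self.m, self.rho)


def default_grid(
    ms=(20, 40, 50, 80, 100, 125, 160, 200),
    rhos=(0.5, 0.6, 0.7, 0.8),
    top_pool: int = 1000,
    n_trees: int = 500,
) -> list[PipelineConfig]:
    return [PipelineConfig(m, r, top_pool, n_trees) for m in ms for r in rhos]


@dataclass
class FeatureMatrix:
    """Residualized subjects x (protein, NP) feature matrix."""

    X: pd.DataFrame                  # rows = sample_id, cols = "protein|np"
    coverage: pd.Series              # pre-imputation non-missing fraction
    constant_flags: pd.Series | None = None

    @property
    def features(self) -> list[str]:
        return list(self.X.columns)


class FeaturePreprocessor:
    """Fit-on-train / apply-anywhere feature preprocessing.

    All dataset-level statistics — missingness filter, per-(protein, NP)
    medians, reference set, composition medians, residualization models —
    are estimated from the fitted (training) samples only.  Transforming
    other samples reuses those statistics, so no validation information
    leaks into feature construction.
    """

    def __init__(self, max_missing: float = 0.6, term: str = "Extracellular",
                 min_detect: float = 0.8):
        self.max_missing = max_missing
        self.term = term
        self.min_detect = min_detect

    def fit(self, quant: pd.DataFrame, meta: pd.DataFrame,
            annotations: dict[str, set[str]]) -> "FeaturePreprocessor":
        samples = meta["sample_id"].to_numpy()
        q = quant[quant["sample_id"].isin(samples)].copy()
        n = len(samples)
        counts = q.groupby(["protein_group", "np_id"])["sample_id"].nunique()
        keep = counts.index[1.0 - counts / n <= self.max_missing]
        idx = pd.MultiIndex.from_frame(q[["protein_group", "np_id"]])
        q = q[idx.isin(keep)]
        self.features_ = [f"{p}|{np_}" for p, np_ in keep]
        self.medians_ = q.groupby(["protein_group", "np_id"])["log2_intensity"].median()
        self.ref_ = reference_set(q, self.min_detect)
        self.annotations_ = annotations
        self.coverage_ = pd.Series(
            (counts.loc[keep] / n).to_numpy(),
            index=self.features_, name="coverage",
        )
        self.plate_of_ = meta.set_index("sample_id")["plate_id"]

        norm, _ = fold_change_normalize(q, self.ref_)
        comp = composition_covariate(q, annotations, self.term)
        comp = comp.reindex(samples).fillna(comp.mean())
        self.comp_mean_ = float(comp.mean())

        self.models_ = {}
        plate = self.plate_of_
        for (p, np_), sub in norm.groupby(["protein_group", "np_id"], sort=True):
            name = f"{p}|{np_}"
            yv = sub["normalized_log2"].to_numpy(float)
            cv = comp.reindex(sub["sample_id"]).to_numpy(float)
            pl = plate.reindex(sub["sample_id"]).to_numpy()
            X = np.column_stack([np.ones(len(yv)), cv])
            fit = fit_variance_components(yv, X, {"plate": pl})
            blups = random_intercept_blups(yv, X, pl, fit, "plate")
            self.models_[name] = (fit.beta.copy(), blups)
        return self

    def _normalize(self, quant: pd.DataFrame, samples: np.ndarray) -> pd.DataFrame:
        q = quant[quant["sample_id"].isin(samples)].copy()
        idx = pd.MultiIndex.from_frame(q[["protein_group", "np_id"]])
        q = q[idx.isin(self.medians_.index)].copy()
        keys = pd.MultiIndex.from_frame(q[["protein_group", "np_id"]])
        fc = q["log2_intensity"].to_numpy() - self.medians_.reindex(keys).to_numpy()
        q["fc"] = fc
        ref_mask = q["protein_group"].isin(self.ref_)
        shifts = (
            q.loc[ref_mask]
            .groupby(["sample_id", "np_id"])["fc"].median()
        )
        pair = pd.MultiIndex.from_frame(q[["sample_id", "np_id"]])
        q["normalized_log2"] = q["log2_intensity"] - shifts.reindex(pair).fillna(0.0).to_numpy()
        return q

    def transform(self, quant: pd.DataFrame, meta: pd.DataFrame) -> FeatureMatrix:
        samples = meta["sample_id"].to_numpy()
        q = self._normalize(quant, samples)
        # per-sample composition against training medians
        members = self.annotations_.get(self.term, set())
        mask = q["protein_group"].isin(members)
        keys = pd.MultiIndex.from_frame(q[["protein_group", "np_id"]])
        fc = q["log2_intensity"].to_numpy() - self.medians_.reindex(keys).to_numpy()
        comp = pd.Series(fc[mask.to_numpy()]).groupby(
            q.loc[mask, "sample_id"].to_numpy()).median()
        comp = comp.reindex(samples).fillna(self.comp_mean_)

        plate = self.plate_of_.reindex(samples)
        X = pd.DataFrame(0.0, index=samples, columns=self.features_)
        key_series = q["protein_group"] + "|" + q["np_id"]
        for name, sub_idx in q.groupby(key_series, sort=False).groups.items():
            if name not in self.models_:
                continue
            beta, blups = self.models_[name]
            sub = q.loc[sub_idx]
            sids = sub["sample_id"].to_numpy()
            cv = comp.reindex(sids).to_numpy(float)
            pred = beta[0] + beta[1] * cv + np.array(
                [blups.get(pl, 0.0) for pl in plate.reindex(sids)]
            )
            X.loc[sids, name] = sub["normalized_log2"].to_numpy(float) - pred
        const = X.std(axis=0) == 0
        return FeatureMatrix(X=X, coverage=self.coverage_.copy(),
                             constant_flags=const)


def preprocess_features(
    quant: pd.DataFrame,
    meta: pd.DataFrame,
    annotations: dict[str, set[str]],
    psa_window: tuple[float, float] | None = None,
    max_missing: float = 0.6,
) -> FeatureMatrix:
    """One-shot preprocessing (fit and transform on the same samples).

    ``psa_window`` restricts subjects to a PSA interval (inclusive), e.g.
    (4, 10) for the reflex-test population, before any statistic is
    estimated.
    """
    if psa_window is not None:
        lo, hi = psa_window
        meta = meta[(meta["psa"] >= lo) & (meta["psa"] <= hi)]
    prep = FeaturePreprocessor(max_missing=max_missing).fit(quant, meta, annotations)
    return prep.transform(quant, meta)


def rank_features_wilcoxon(X: pd.DataFrame, y: np.ndarray) -> pd.DataFrame:
    """Rank features by two-sided Wilcoxon rank-sum p (cases vs controls).

    Ties in p break by descending absolute rank-biserial correlation, then
    by column name.
    """
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes required for ranking")
    A = X.to_numpy(float)
    cases, ctrls = A[y == 1], A[y == 0]
    n1, n2 = len(cases), len(ctrls)
    res = mannwhitneyu(cases, ctrls, alternative="two-sided",
                       method="asymptotic", axis=0)
    u1 = np.atleast_1d(res.statistic)
    p = np.atleast_1d(res.pvalue)
    rb = 2.0 * u1 / (n1 * n2) - 1.0
    out = pd.DataFrame({"feature": X.columns, "p": p, "rank_biserial": rb})
    out["abs_rb"] = out["rank_biserial"].abs()
    out = out.sort_values(["p", "abs_rb", "feature"],
                          ascending=[True, False, True])
    return out.drop(columns="abs_rb").reset_index(drop=True)


def correlation_filter(
    X: pd.DataFrame,
    ranked: list[str],
    rho: float,
    coverage: pd.Series,
    top_pool: int = 1000,
    absolute: bool = False,
) -> list[str]:
    """Coverage-aware redundancy filter over the top-ranked feature pool.

    For each feature F of the pool (visited in rank order), the set of pool
    features whose correlation with F exceeds ``rho`` is found; F is
    excluded when any of them has strictly higher coverage.  Comparisons run
    against the full pool regardless of other features' retention status.
    Correlation is signed Pearson on the residualized entries (absolute
    value behind ``absolute``).
    """
    pool = list(ranked)[:top_pool]
    A = X[pool].to_numpy(float)
    sd = A.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.corrcoef(A, rowvar=False)
    C = np.atleast_2d(np.nan_to_num(C, nan=0.0))
    if absolute:
        C = np.abs(C)
    cov = coverage.reindex(pool).to_numpy(float)
    retained = []
    for i, f in enumerate(pool):
        over = (C[i] > rho) & (np.arange(len(pool)) != i) & (sd > 0)
        if sd[i] == 0:
            over[:] = False
        if not np.any(over & (cov > cov[i])):
            retained.append(f)
    return retained


def composite_select(metrics: dict) -> object:
    """Pick the configuration maximizing summed z-scored AUC/PPV/NPV.

    Metrics are z-scored across configurations (zero when the spread is
    zero); ties break to the smallest configuration key (smaller m, then
    smaller rho for (m, rho) keys).
    """
    if not metrics:
        raise ValueError("no configurations to select from")
    keys = sorted(metrics)
    M = np.array([metrics[k].as_array() for k in keys])
    mean = M.mean(axis=0)
    sd = M.std(axis=0)
    Z = np.where(sd > 0, (M - mean) / np.where(sd == 0, 1.0, sd), 0.0)
    total = Z.sum(axis=1)
    return keys[int(np.argmax(total))]


@dataclass
class FoldPredictionMatrix:
    """Pooled out-of-fold scores: subjects x configurations x seeds."""

    scores: np.ndarray               # (n_subjects, n_configs, n_seeds)
    subjects: np.ndarray
    labels: np.ndarray
    configs: list[tuple[int, float]]
    fold_ids: np.ndarray             # (n_subjects, n_seeds)
    seeds: list[int]
    importance_records: list = field(default_factory=list)

    def pooled(self) -> np.ndarray:
        """Scores averaged over the CV repeat seeds: subjects x configs."""
        return self.scores.mean(axis=2)

    def pooled_metrics(self) -> dict[tuple[int, float], MetricTriple]:
        pool = self.pooled()
        return {
            cfg: evaluate_metrics(pool[:, j], self.labels)
            for j, cfg in enumerate(self.configs)
        }


def _tune_and_fit_rf(
    Xtr: np.ndarray, ytr: np.ndarray, n_trees: int, mtry_grid: list[int],
    n_inner: int, rng_seed: int,
) -> RandomForestClassifier:
    best_mtry, best_auc = mtry_grid[0], -np.inf
    if len(mtry_grid) > 1:
        n_splits = min(n_inner, int(np.bincount(ytr).min()))
        n_splits = max(n_splits, 2)
        inner = StratifiedKFold(n_splits=n_splits, shuffle=True,
                                random_state=rng_seed)
        for mtry in mtry_grid:
            scores = np.zeros(len(ytr))
            for tr, te in inner.split(Xtr, ytr):
                rf = RandomForestClassifier(
                    n_estimators=n_trees, max_features=mtry,
                    random_state=rng_seed, n_jobs=1,
                )
                rf.fit(Xtr[tr], ytr[tr])
                scores[te] = rf.predict_proba(Xtr[te])[:, 1]
            auc = evaluate_metrics(scores, ytr).auc
            if auc > best_auc:
                best_auc, best_mtry = auc, mtry
    rf = RandomForestClassifier(n_estimators=n_trees, max_features=best_mtry,
                                random_state=rng_seed, n_jobs=1)
    rf.fit(Xtr, ytr)
    return rf


def _default_mtry_grid(d: int) -> list[int]:
    r = np.sqrt(d)
    grid = sorted({max(1, int(round(r / 2))), max(1, int(round(r))),
                   max(1, min(d, int(round(2 * r))))})
    return list(grid)


def nested_cv(
    quant: pd.DataFrame,
    meta: pd.DataFrame,
    annotations: dict[str, set[str]],
    grid: list[PipelineConfig] | None = None,
    n_outer: int = 10,
    n_inner: int = 10,
    n_seeds: int = 3,
    base_seed: int = 0,
    label_col: str = "case_status",
    psa_window: tuple[float, float] | None = None,
    mtry_grid: list[int] | None = None,
    compute_importance: bool = False,
) -> FoldPredictionMatrix:
    """Nested cross-validation over the (m, rho) grid.

    Outer folds are stratified; every preprocessing statistic, the Wilcoxon
    ranking, the correlation filter and the random-forest tuning are refit
    inside each outer-training split.  The whole procedure repeats for
    ``n_seeds`` fold seeds, and out-of-fold class-1 probabilities are
    recorded per (subject, configuration, seed).
    """
    grid = grid or default_grid()
    if psa_window is not None:
        lo, hi = psa_window
        meta = meta[(meta["psa"] >= lo) & (meta["psa"] <= hi)].reset_index(drop=True)
    meta = meta.reset_index(drop=True)
    subjects = meta["sample_id"].to_numpy()
    y = meta[label_col].to_numpy(dtype=int)
    if np.bincount(y).min() < n_outer:
        n_outer = max(2, int(np.bincount(y).min()))
    configs = [c.key for c in grid]
    by_key = {c.key: c for c in grid}
    scores = np.zeros((len(subjects), len(configs), n_seeds))
    fold_ids = np.zeros((len(subjects), n_seeds), dtype=int)
    importance_records: list[dict] = []

    for s in range(n_seeds):
        seed = base_seed + 1000 * s
        skf = StratifiedKFold(n_splits=n_outer, shuffle=True, random_state=seed)
        for fold, (tr, te) in enumerate(skf.split(subjects, y)):
            meta_tr, meta_te = meta.iloc[tr], meta.iloc[te]
            prep = FeaturePreprocessor().fit(quant, meta_tr, annotations)
            Ftr = prep.transform(quant, meta_tr)
            Fte = prep.transform(quant, meta_te)
            ranked = rank_features_wilcoxon(Ftr.X, y[tr])["feature"].tolist()
            retained_by_rho: dict[float, list[str]] = {}
            for cfg in grid:
                if cfg.rho not in retained_by_rho:
                    retained_by_rho[cfg.rho] = correlation_filter(
                        Ftr.X, ranked, cfg.rho, Ftr.coverage, cfg.top_pool
                    )
            for j, cfg in enumerate(grid):
                feats = retained_by_rho[cfg.rho][: cfg.m]
                Xtr = Ftr.X[feats].to_numpy(float)
                Xte = Fte.X[feats].to_numpy(float)
                mg = mtry_grid or _default_mtry_grid(len(feats))
                mg = [min(m_, len(feats)) for m_ in mg]
                rf = _tune_and_fit_rf(Xtr, y[tr], cfg.n_trees, sorted(set(mg)),
                                      n_inner, seed + fold)
                scores[te, j, s] = rf.predict_proba(Xte)[:, 1]
                if compute_importance:
                    importance_records.append({
                        "config": cfg.key, "seed": s, "fold": fold,
                        "features": feats,
                        "importance": _heldout_permutation_importance(
                            rf, Xte, y[te], seed + fold),
                    })
            fold_ids[te, s] = fold
    return FoldPredictionMatrix(
        scores=scores, subjects=subjects, labels=y, configs=configs,
        fold_ids=fold_ids, seeds=[base_seed + 1000 * s for s in range(n_seeds)],
        importance_records=importance_records,
    )


def _heldout_permutation_importance(
    rf: RandomForestClassifier, Xte: np.ndarray, yte: np.ndarray,
    seed: int, n_repeats: int = 5,
) -> np.ndarray:
    """Accuracy drop after permuting each feature on the held-out portion,
    standardized by its spread across permutation repeats."""
    rng = np.random.default_rng(seed)
    base = float((rf.predict(Xte) == yte).mean())
    drops = np.zeros((Xte.shape[1], n_repeats))
    for jf in range(Xte.shape[1]):
        Xp = Xte.copy()
        for r in range(n_repeats):
            Xp[:, jf] = rng.permutation(Xte[:, jf])
            drops[jf, r] = base - float((rf.predict(Xp) == yte).mean())
    mean = drops.mean(axis=1)
    sd = drops.std(axis=1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(sd > 0, mean / np.where(sd > 0, sd, 1.0), mean)
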