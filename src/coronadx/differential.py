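"""Per-protein mixed-model differential abundance.

Each protein is fit with a Gaussian linear mixed model of its normalized
log2 intensities pooled across nanoparticle channels:

    Y_ijk = b0 + b1 * CaseStatus_k + (covariates) + u_i + v_j + w_ij + z_k + e_ijk

with random effects for plate (u), nanoparticle (v), plate x nanoparticle
(w) and subject nested within plate (z).  Fixed covariates are age, draw
year, sample-appearance outlier status and the per-sample extracellular
composition covariate.  Proteins observed in a single nanoparticle drop the
v, w and z components and keep the plate intercept.  The case coefficient
is the adjusted log2 fold change; its p-value is a Wald test with a normal
reference on the REML fit, and Benjamini-Hochberg correction is applied
across converged fits within a contrast.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .lmm import fit_variance_components
from .normalize import (
    ImputationParams,
    estimate_imputation_params,
    impute_best_np,
)

__all__ = [
    "LmmSpec",
    "fit_protein_lmm",
    "run_differential",
    "compare_contrasts",
    "bh_adjust",
]

CONTRASTS = ("caseDef1", "caseDef2", "threeLevel")


@dataclass
class LmmSpec:
    """Model specification for the differential stage."""

    contrast: str = "caseDef1"
    fixed: tuple[str, ...] = ("age", "draw_year", "appearance_outlier",
                              "composition")
    reml: bool = True

    def __post_init__(self) -> None:
        if self.contrast not in CONTRASTS:
            raise ValueError(f"unknown contrast {self.contrast!r}")


def _case_variable(meta: pd.DataFrame, contrast: str) -> pd.DataFrame:
    """Case-status indicator column(s) for the requested contrast."""
    if contrast == "caseDef1":
        return pd.DataFrame({"case": meta["case_status"].astype(float)})
    if contrast == "caseDef2":
        sig = (meta.get("grade_group", meta["case_status"]) >= 2).astype(float)
        return pd.DataFrame({"case": sig})
    gg = meta["grade_group"]
    return pd.DataFrame({
        "case_gg1": (gg == 1).astype(float),
        "case_gg2plus": (gg >= 2).astype(float),
    })


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def fit_protein_lmm(
    y: pd.DataFrame,
    meta: pd.DataFrame,
    composition: pd.Series,
    spec: LmmSpec,
    value_col: str = "normalized_log2",
) -> dict:
    """Fit the mixed model for one protein.

    ``y`` is a long frame (sample_id, np_id, value_col) holding the
    protein's observations across channels — the best-covered channel
    already completed by imputation, other channels observed-only.
    Returns a result record (beta, se, p, varcomps, ...), or a skip record
    when fewer than two case levels are present.
    """
    meta_idx = meta.set_index("sample_id")
    df = y.copy()
    caseframe = _case_variable(meta_idx.reset_index(), spec.contrast)
    caseframe.index = meta_idx.index
    case_cols = list(caseframe.columns)
    for c in case_cols:
        df[c] = df["sample_id"].map(caseframe[c])
    if df[case_cols].nunique().min() < 2:
        return {"converged": False, "skipped": True,
                "reason": "single case level"}

    covs = []
    for name in spec.fixed:
        if name == "composition":
            comp = composition.reindex(df["sample_id"])
            comp = comp.fillna(composition.mean())
            df["composition"] = comp.to_numpy()
            covs.append("composition")
        elif name in meta_idx.columns:
            df[name] = df["sample_id"].map(meta_idx[name]).astype(float)
            if df[name].nunique() > 1:
                covs.append(name)

    df["plate"] = df["sample_id"].map(meta_idx["plate_id"])
    n_np = df["np_id"].nunique()
    X = np.column_stack(
        [np.ones(len(df))]
        + [df[c].to_numpy(float) for c in case_cols]
        + [df[c].to_numpy(float) for c in covs]
    )
    names = ["intercept"] + case_cols + covs
    if n_np > 1:
        factors = {
            "plate": df["plate"].to_numpy(),
            "np": df["np_id"].to_numpy(),
            "platenp": (df["plate"].astype(str) + ":" + df["np_id"].astype(str)).to_numpy(),
            "subject": df["sample_id"].to_numpy(),
        }
    else:
        factors = {"plate": df["plate"].to_numpy()}
    fit = fit_variance_components(df[value_col].to_numpy(float), X, factors,
                                  fixed_names=names)
    i = names.index(case_cols[0])
    out = {
        "beta": float(fit.beta[i]),
        "se": float(fit.se[i]),
        "p": fit.wald_p(i),
        "n_np_used": int(n_np),
        "n_obs": fit.n_obs,
        "converged": fit.converged,
        "skipped": False,
        "varcomps": dict(fit.vcomp, residual=fit.sigma2),
    }
    if spec.contrast == "threeLevel":
        j = names.index("case_gg2plus")
        out["beta_gg2plus"] = float(fit.beta[j])
        out["se_gg2plus"] = float(fit.se[j])
        out["p_gg2plus"] = fit.wald_p(j)
    return out


def run_differential(
    normalized: pd.DataFrame,
    meta: pd.DataFrame,
    composition: pd.Series,
    spec: LmmSpec | None = None,
    params: ImputationParams | None = None,
    value_col: str = "normalized_log2",
) -> pd.DataFrame:
    """Differential abundance over all proteins of a normalized table.

    Imputation of each protein's best-covered channel happens once, up
    front, with the seed recorded in ``params``; Benjamini-Hochberg
    correction runs over the converged fits and ``q < 0.05`` defines the
    significant set.
    """
    spec = spec or LmmSpec()
    if params is None:
        params = estimate_imputation_params(normalized, value_col=value_col)
    samples = meta["sample_id"].to_numpy()
    completed = impute_best_np(normalized, samples, params, value_col=value_col)

    rows = []
    for protein, sub in completed.groupby("protein_group", sort=True):
        # canonical row order makes the fit exactly invariant to input order
        sub = sub.sort_values(["np_id", "sample_id"]).reset_index(drop=True)
        res = fit_protein_lmm(sub, meta, composition, spec, value_col=value_col)
        res["protein_group"] = protein
        res["contrast"] = spec.contrast
        rows.append(res)
    de = pd.DataFrame(rows)
    de["q"] = np.nan
    skipped = de["skipped"] if "skipped" in de else pd.Series(False, index=de.index)
    fit_ok = (~skipped.fillna(True).astype(bool)) & de["converged"].fillna(False).astype(bool)
    fit_ok = fit_ok.to_numpy(dtype=bool)
    if fit_ok.any():
        de.loc[fit_ok, "q"] = bh_adjust(de.loc[fit_ok, "p"].to_numpy())
    de["significant"] = de["q"] < 0.05
    front = ["protein_group", "contrast", "beta", "se", "p", "q",
             "significant", "n_np_used", "converged"]
    cols = [c for c in front if c in de.columns]
    return de[cols + [c for c in de.columns if c not in cols]]


def compare_contrasts(
    r1: pd.DataFrame, r2: pd.DataFrame, q_threshold: float = 0.05
) -> tuple[float, pd.DataFrame]:
    """Fold-change agreement between two contrasts.

    Pairs the betas of proteins significant (q below threshold) in either
    contrast and present in both; returns the Pearson correlation and the
    paired table.  Fewer than three pairs yields NaN.
    """
    sig = set(r1.loc[r1["q"] < q_threshold, "protein_group"]) | set(
        r2.loc[r2["q"] < q_threshold, "protein_group"]
    )
    a = r1.set_index("protein_group")["beta"]
    b = r2.set_index("protein_group")["beta"]
    common = sorted(sig & set(a.index) & set(b.index))
    paired = pd.DataFrame({"beta_1": a.loc[common], "beta_2": b.loc[common]})
    if len(paired) < 3:
        return float("nan"), paired
    r = float(np.corrcoef(paired["beta_1"], paired["beta_2"])[0, 1])
    return r, paired
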