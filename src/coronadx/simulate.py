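"""Synthetic cohort generation for nanoparticle-corona serum proteomics.

Emulates the statistical structure the downstream analysis assumes: five
nanoparticle channels per sample, log-normal protein abundance over a wide
(>= 6 log2 units) dynamic range, plate (batch) intercepts, nanoparticle and
plate x nanoparticle effects, subject effects, a per-sample "extracellular
content" composition shift loading only on extracellular-annotated proteins,
intensity-dependent left-censored (MNAR) missingness, a planted set of
case-associated differential proteins, and a clinical benchmark risk score
with tunable discrimination.

Every generated intensity follows

    y[p,k,j] = mu_p + fc_p * case_k + u[p, plate(k)] + v[p,j] + w[p, plate(k), j]
               + z[p,k] + t_k * lambda_p + eps[p,k,j]

with all random effects drawn independently per protein, matching the
per-protein mixed model the differential stage fits.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

__all__ = [
    "SimParams",
    "generate_cohort",
    "generate_id_matrix",
    "generate_benchmark_scores",
]


@dataclass
class SimParams:
    """Generator settings; defaults define the reference study conditions.

    Standard deviations are on the log2-intensity scale.  ``missing_slope``
    is the logistic slope of the missingness probability per log2 unit of
    intensity relative to the grand mean (negative = left-censoring).
    """

    n_subjects: int = 200
    n_proteins: int = 300
    n_np: int = 5
    n_per_plate: int = 15
    case_fraction: float = 0.5
    n_differential: int = 30
    effect_size_log2: float = 1.0
    plate_sd: float = 0.3
    np_sd: float = 0.5
    platenp_sd: float = 0.2
    subject_sd: float = 0.5
    resid_sd: float = 0.3
    composition_sd: float = 0.5
    missing_intercept: float = -3.0
    missing_slope: float = -0.5
    mcar: bool = False
    extracellular_fraction: float = 0.25
    benchmark_auc: float = 0.70
    base_mean_low: float = 14.0
    base_mean_high: float = 22.0
    seed: int = 0

    def validate(self) -> None:
        for f in ("plate_sd", "np_sd", "platenp_sd", "subject_sd",
                  "resid_sd", "composition_sd"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")
        for f in ("case_fraction", "extracellular_fraction"):
            if not 0.0 <= getattr(self, f) <= 1.0:
                raise ValueError(f"{f} must be in [0, 1]")
        if self.n_differential > self.n_proteins:
            raise ValueError("n_differential exceeds n_proteins")
        if self.n_per_plate < 1 or self.n_subjects < 1 or self.n_proteins < 1:
            raise ValueError("infeasible cohort sizes")


def _plate_assignment(case: np.ndarray, n_per_plate: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Block-fill plates with case/control stratification.

    Shuffled cases and controls are interleaved proportionally and then cut
    into consecutive blocks of ``n_per_plate``, so each plate receives an
    approximately equal case fraction.
    """
    n = len(case)
    cases = rng.permutation(np.flatnonzero(case == 1))
    ctrls = rng.permutation(np.flatnonzero(case == 0))
    order = []
    ci = ki = 0
    for pos in range(n):
        # proportional interleave: pick the stream lagging its quota
        want_case = (ci + 1) * len(ctrls) <= (ki + 1) * len(cases)
        if ci < len(cases) and (want_case or ki >= len(ctrls)):
            order.append(cases[ci]); ci += 1
        else:
            order.append(ctrls[ki]); ki += 1
    plates = np.empty(n, dtype=int)
    for pos, subj in enumerate(order):
        plates[subj] = pos // n_per_plate
    return plates


def generate_cohort(params: SimParams):
    """Generate (quant_table, sample_meta, annotation_map, truth).

    Returns
    -------
    quant : long DataFrame of observed records (missing entries absent).
    meta : per-sample metadata frame.
    annotations : dict term -> set of protein groups ("Extracellular" term).
    truth : dict with "proteins" and "samples" DataFrames plus "params".
    """
    p = params
    p.validate()
    rng = np.random.default_rng(p.seed)

    samples = np.array([f"S{i:04d}" for i in range(p.n_subjects)])
    proteins = np.array([f"P{i:04d}" for i in range(p.n_proteins)])
    np_ids = np.array([f"NP{j + 1}" for j in range(p.n_np)])

    n_cases = int(round(p.case_fraction * p.n_subjects))
    case = np.zeros(p.n_subjects, dtype=int)
    case[rng.choice(p.n_subjects, n_cases, replace=False)] = 1
    plates = _plate_assignment(case, p.n_per_plate, rng)
    n_plates = plates.max() + 1

    # clinical covariates
    age = np.clip(rng.normal(65.0, 7.0, p.n_subjects), 45.0, 85.0)
    psa = np.clip(np.exp(rng.normal(np.log(6.0) + 0.15 * case, 0.5)), 0.1, 50.0)
    draw_year = rng.integers(2005, 2017, p.n_subjects)
    race = rng.choice(["W", "B", "H", "O"], p.n_subjects,
                      p=[0.6, 0.15, 0.2, 0.05])
    appearance = (rng.random(p.n_subjects) < 0.02).astype(int)
    grade = np.where(case == 1, rng.integers(1, 3, p.n_subjects), 0)

    # protein-level truth
    mu = rng.uniform(p.base_mean_low, p.base_mean_high, p.n_proteins)
    diff_idx = rng.choice(p.n_proteins, p.n_differential, replace=False)
    fc = np.zeros(p.n_proteins)
    if p.n_differential:
        mag = rng.gamma(4.0, p.effect_size_log2 / 4.0, p.n_differential)
        fc[diff_idx] = rng.choice([-1.0, 1.0], p.n_differential) * mag
    n_extra = int(round(p.extracellular_fraction * p.n_proteins))
    extra_idx = rng.choice(p.n_proteins, n_extra, replace=False)
    loading = np.zeros(p.n_proteins)
    loading[extra_idx] = 1.0
    composition = rng.normal(0.0, p.composition_sd, p.n_subjects)

    # random effects, independently per protein
    shape = (p.n_proteins, p.n_subjects, p.n_np)
    u = rng.normal(0, p.plate_sd, (p.n_proteins, n_plates))
    v = rng.normal(0, p.np_sd, (p.n_proteins, p.n_np))
    w = rng.normal(0, p.platenp_sd, (p.n_proteins, n_plates, p.n_np))
    z = rng.normal(0, p.subject_sd, (p.n_proteins, p.n_subjects))
    eps = rng.normal(0, p.resid_sd, shape)

    y = (
        mu[:, None, None]
        + (fc[:, None] * case[None, :])[:, :, None]
        + u[:, plates, None]
        + v[:, None, :]
        + w[:, plates, :]
        + z[:, :, None]
        + (loading[:, None] * composition[None, :])[:, :, None]
        + eps
    )

    grand = float(y.mean())
    if p.mcar:
        pmiss = np.full(shape, expit(p.missing_intercept))
    else:
        pmiss = expit(p.missing_intercept + p.missing_slope * (y - grand))
    observed = rng.random(shape) >= pmiss

    pi, ki, ji = np.nonzero(observed)
    quant = pd.DataFrame({
        "sample_id": samples[ki],
        "np_id": np_ids[ji],
        "protein_group": proteins[pi],
        "log2_intensity": y[pi, ki, ji],
    })
    quant = quant[["sample_id", "np_id", "protein_group", "log2_intensity"]]

    meta = pd.DataFrame({
        "sample_id": samples,
        "subject_id": samples,
        "cohort": "SYNTH",
        "case_status": case,
        "grade_group": grade,
        "psa": psa,
        "age": age,
        "draw_year": draw_year,
        "race_ethnicity": race,
        "appearance_outlier": appearance,
        "plate_id": np.array([f"PL{i:02d}" for i in plates]),
        "split": "unassigned",
    })
    meta["benchmark_score"] = generate_benchmark_scores(
        meta, p.benchmark_auc, seed=int(rng.integers(0, 2**31 - 1))
    ).to_numpy()

    annotations = {"Extracellular": set(proteins[extra_idx].tolist())}
    truth = {
        "proteins": pd.DataFrame({
            "protein_group": proteins,
            "is_differential": np.isin(np.arange(p.n_proteins), diff_idx),
            "true_log2fc": fc,
            "is_extracellular": loading.astype(bool),
            "base_mean": mu,
        }),
        "samples": pd.DataFrame({
            "sample_id": samples,
            "true_composition": composition,
            "plate_id": meta["plate_id"],
        }),
        "params": asdict(p),
    }
    return quant, meta, annotations, truth


def generate_id_matrix(
    n_samples: int,
    n_peptides: int,
    prevalence_shape: float = 0.2,
    seed: int = 0,
    *,
    prevalence_rate: float = 2.0,
) -> pd.DataFrame:
    """Sample x peptide boolean identification matrix.

    Peptide detection probabilities are drawn from a heavy-tailed
    Beta(``prevalence_shape``, ``prevalence_rate``) law, so that cumulative
    unique-identification curves saturate: a few peptides are near-universal
    while most are rare.
    """
    if n_samples < 1 or n_peptides < 1:
        raise ValueError("matrix dimensions must be >= 1")
    rng = np.random.default_rng(seed)
    probs = rng.beta(prevalence_shape, prevalence_rate, n_peptides)
    mat = rng.random((n_samples, n_peptides)) < probs
    return pd.DataFrame(
        mat,
        index=[f"S{i:04d}" for i in range(n_samples)],
        columns=[f"pep{j:05d}" for j in range(n_peptides)],
    )


def generate_benchmark_scores(
    meta: pd.DataFrame, target_auc: float, seed: int = 0
) -> pd.Series:
    """Binormal risk scores with a target discrimination (AUC).

    Controls score N(0, 1), cases N(sqrt(2) * Phi^-1(AUC), 1); the binormal
    AUC of this pair is exactly ``target_auc``, and the logistic map to
    [0, 1] preserves it.  Targets are clipped just below 1 before the normal
    quantile is taken.
    """
    if not 0.5 <= target_auc < 1.0:
        raise ValueError("target_auc must lie in [0.5, 1)")
    rng = np.random.default_rng(seed)
    case = meta["case_status"].to_numpy().astype(int)
    delta = np.sqrt(2.0) * norm.ppf(min(target_auc, 1.0 - 1e-12))
    x = rng.normal(0.0, 1.0, len(case)) + delta * case
    return pd.Series(expit(x), index=meta["sample_id"].to_numpy(),
                     name="benchmark_score")
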