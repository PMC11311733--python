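import numpy as np
import pandas as pd
import pytest

from coronadx import SimParams, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """60-subject cohort with planted differential proteins."""
    params = SimParams(n_subjects=60, n_proteins=40, n_differential=8,
                       effect_size_log2=1.2, seed=42)
    return generate_cohort(params)


@pytest.fixture()
def toy_quant():
    """Fully observed 3-protein x 3-sample x 1-NP table."""
    rows = []
    values = {
        ("P1", "A"): 10.0, ("P1", "B"): 12.0, ("P1", "C"): 11.0,
        ("P2", "A"): 20.0, ("P2", "B"): 21.0, ("P2", "C"): 19.0,
        ("P3", "A"): 15.0, ("P3", "B"): 18.0, ("P3", "C"): 16.0,
    }
    for (prot, sample), v in values.items():
        rows.append({"sample_id": sample, "np_id": "NP1",
                     "protein_group": prot, "log2_intensity": v})
    return pd.DataFrame(rows)


def random_quant(rng, n_proteins=50, n_samples=30, n_np=2, missing=0.0):
    """Random long quant table used by several property tests."""
    rows = []
    for p in range(n_proteins):
        base = rng.uniform(10, 25)
        for s in range(n_samples):
            for j in range(n_np):
                if rng.random() < missing:
                    continue
                rows.append({
                    "sample_id": f"S{s:03d}",
                    "np_id": f"NP{j + 1}",
                    "protein_group": f"P{p:03d}",
                    "log2_intensity": base + rng.normal(0, 1),
                })
    return pd.DataFrame(rows)
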