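"""Reading and writing the pipeline's tabular formats.

A quantification table ("quant table") is a long-format pandas DataFrame with
columns ``sample_id``, ``np_id``, ``protein_group`` and ``log2_intensity``
(log2 MaxLFQ units), one row per observed measurement.  Missing observations
are represented by *absent* rows; explicit nulls in input files are dropped on
ingest so that both conventions read identically.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

__all__ = [
    "QUANT_COLUMNS",
    "validate_quant",
    "read_quant_table",
    "write_quant_table",
    "read_sample_meta",
    "read_annotations",
    "annotation_map_from_frame",
    "read_id_matrix",
    "write_json_report",
]

QUANT_COLUMNS = ["sample_id", "np_id", "protein_group", "log2_intensity"]

META_REQUIRED = ["sample_id", "case_status"]


class FormatError(ValueError):
    """A required column or structural element is missing."""


class IntegrityError(ValueError):
    """The file parses but violates a table invariant."""


def validate_quant(q: pd.DataFrame) -> pd.DataFrame:
    """Validate and canonicalize a long quant table.

    Drops null-intensity rows, enforces uniqueness of the
    (sample_id, np_id, protein_group) key and finiteness of intensities.
    """
    missing = [c for c in QUANT_COLUMNS if c not in q.columns]
    if missing:
        raise FormatError(f"quant table missing columns: {missing}")
    q = q.loc[:, QUANT_COLUMNS].copy()
    q = q.dropna(subset=["log2_intensity"])
    if not q.empty and not pd.to_numeric(q["log2_intensity"]).map(pd.notna).all():
        raise IntegrityError("non-numeric intensity")
    q["log2_intensity"] = q["log2_intensity"].astype(float)
    import numpy as np

    if not np.isfinite(q["log2_intensity"]).all():
        raise IntegrityError("non-finite log2_intensity")
    key = ["sample_id", "np_id", "protein_group"]
    if q.duplicated(subset=key).any():
        dup = q[q.duplicated(subset=key, keep=False)].iloc[0]
        raise IntegrityError(
            f"duplicate quant key: {tuple(dup[k] for k in key)}"
        )
    for c in key:
        q[c] = q[c].astype(str)
    return q.reset_index(drop=True)


def read_quant_table(
    path: str | Path,
    *,
    sep: str | None = None,
    wide_np_id: str | None = None,
) -> pd.DataFrame:
    """Read a quantification table from a delimited file.

    Long tables must carry the four canonical columns.  A wide matrix
    (rows = protein groups, columns = samples) is accepted when
    ``wide_np_id`` names the nanoparticle channel the matrix belongs to; it
    is melted to long form.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep)
    if wide_np_id is not None:
        first = df.columns[0]
        long = df.melt(id_vars=[first], var_name="sample_id",
                       value_name="log2_intensity")
        long = long.rename(columns={first: "protein_group"})
        long["np_id"] = wide_np_id
        return validate_quant(long)
    return validate_quant(df)


def write_quant_table(q: pd.DataFrame, path: str | Path) -> None:
    validate_quant(q).to_csv(path, sep="\t", index=False)


def read_sample_meta(path: str | Path, *, sep: str | None = None) -> pd.DataFrame:
    """Read per-sample clinical/design metadata (CSV/TSV).

    Enforces the case-definition invariant: grade_group >= 1 implies
    case_status == 1 and grade_group == 0 implies case_status == 0.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    meta = pd.read_csv(path, sep=sep)
    missing = [c for c in META_REQUIRED if c not in meta.columns]
    if missing:
        raise FormatError(f"sample metadata missing columns: {missing}")
    meta["sample_id"] = meta["sample_id"].astype(str)
    if "grade_group" in meta.columns:
        gg = meta["grade_group"].fillna(0).astype(int)
        cs = meta["case_status"].astype(int)
        if ((gg >= 1) & (cs != 1)).any() or ((gg == 0) & (cs != 0)).any():
            raise IntegrityError("grade_group / case_status inconsistency")
    return meta


def annotation_map_from_frame(df: pd.DataFrame) -> dict[str, set[str]]:
    """Build term -> protein-group set mapping from a two-column frame."""
    prot, term = df.columns[:2]
    out: dict[str, set[str]] = {}
    for p, t in zip(df[prot].astype(str), df[term].astype(str)):
        out.setdefault(t, set()).add(p)
    return out


def read_annotations(path: str | Path) -> dict[str, set[str]]:
    """Read protein -> annotation-term mapping.

    Accepts a two-column TSV (protein_group, term) or a GAF 2.x file, from
    which only Cellular Component (aspect ``C``) associations are kept.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("!gaf-version") or first.startswith("!"):
        rows = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("!"):
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 9:
                    continue
                # GAF: col 3 = object symbol, col 5 = GO id, col 9 = aspect
                if parts[8] == "C":
                    rows.append((parts[2], parts[4]))
        return annotation_map_from_frame(
            pd.DataFrame(rows, columns=["protein_group", "term"])
        )
    df = pd.read_csv(path, sep="\t")
    return annotation_map_from_frame(df)


def read_id_matrix(path: str | Path, *, sep: str = "\t") -> pd.DataFrame:
    """Read a sample x peptide boolean identification matrix.

    First column is the sample id; remaining columns are peptides with 0/1
    entries.
    """
    df = pd.read_csv(path, sep=sep)
    df = df.set_index(df.columns[0])
    return df.astype(bool)


def write_json_report(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=float)
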