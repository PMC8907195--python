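"""Cohort manifest: per-subject group, demographics and clinical scores.

The manifest joins subjects to their adjacency-matrix files.  Groups are
AIS (arterial ischemic stroke), PVI (periventricular venous infarction)
and TDC (typically developing controls).  Clinical motor scores: AHA and
MA on 0-100 scales (logit units for the AHA), BBTA/BBTU as block counts;
all optional, with empty CSV cells denoting missing values.
"""

from __future__ import annotations

from pathlib import Path


import pandas as pd

GROUPS = ("AIS", "PVI", "TDC")
STROKE_GROUPS = ("AIS", "PVI")
SCORE_COLUMNS = ("AHA", "MA", "BBTA", "BBTU")
MANIFEST_COLUMNS = (
    "id",
    "group",
    "age",
    "sex",
    "lesion_volume",
    "AHA",
    "MA",
    "BBTA",
    "BBTU",
    "matrix_path",
)


class ManifestError(ValueError):
    pass


def validate_manifest(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ManifestError(f"manifest missing columns: {missing}")
    df = df.loc[:, list(MANIFEST_COLUMNS)].copy()
    if df["id"].duplicated().any():
        raise ManifestError("duplicate subject ids")
    bad = set(df["group"]) - set(GROUPS)
    if bad:
        raise ManifestError(f"unknown group codes: {sorted(bad)}")
    bad_sex = set(df["sex"].dropna()) - {"M", "F"}
    if bad_sex:
        raise ManifestError(f"sex must be M or F, got {sorted(bad_sex)}")
    for col, lo, hi in (("AHA", 0, 100), ("MA", 0, 100)):
        vals = pd.to_numeric(df[col], errors="coerce")
        out = vals.dropna()
        if ((out < lo) | (out > hi)).any():
            raise ManifestError(f"{col} scores outside [{lo}, {hi}]")
        df[col] = vals
    for col in ("BBTA", "BBTU"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if (vals.dropna() < 0).any():
            raise ManifestError(f"{col} counts must be non-negative")
        df[col] = vals
    df["age"] = pd.to_numeric(df["age"], errors="coerce")
    df["lesion_volume"] = pd.to_numeric(df["lesion_volume"], errors="coerce")
    return df


def read_manifest(path) -> pd.DataFrame:
    return validate_manifest(pd.read_csv(path))


def write_manifest(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    validate_manifest(df).to_csv(path, index=False, float_format="%.6g")
    return path


def group_sizes(df: pd.DataFrame) -> dict:
    counts = df["group"].value_counts()
    return {g: int(counts.get(g, 0)) for g in GROUPS}


def split_by_group(df: pd.DataFrame, column: str) -> dict:
    """Per-group numeric vectors for ``column``, NaN dropped."""
    return {
        g: df.loc[df["group"] == g, column].dropna().to_numpy(dtype=float)
        for g in GROUPS
        if (df["group"] == g).any()
    }
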