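"""Reading and writing count matrices, sample metadata, and stage tables.

All files are plain delimited text: tab-separated by default, comma-separated
when the filename ends in ``.csv``. Count matrices have gene identifiers in
the first column and one column per sample; metadata tables have one row per
sample with a fixed set of required columns.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError

__all__ = [
    "METADATA_COLUMNS",
    "VALID_GROUPS",
    "read_counts",
    "write_counts",
    "read_metadata",
    "write_metadata",
    "align_counts_metadata",
    "write_truth",
    "read_truth",
]

#: Required metadata columns, in canonical order.
METADATA_COLUMNS = [
    "sample_id",
    "individual_id",
    "group",
    "freeze_thaw",
    "rin",
    "library_prep",
    "concentration",
]

#: Accepted group labels. "standard" marks industry-standard control samples;
#: "NA" marks samples without a diagnostic assignment.
VALID_GROUPS = {"ASD", "TD", "standard", "NA"}


def _sep_for(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_counts(path) -> pd.DataFrame:
    """Read a gene x sample count matrix from delimited text.

    Validates that counts are non-negative integers, that no cell is missing,
    and that gene and sample identifiers are unique.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "gene_id"
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise DataError(f"duplicated gene ids in {path.name}: {dupes[:5]}")
    if pd.Index(df.columns).duplicated().any():
        raise DataError(f"duplicated sample ids in {path.name}")
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | ~np.isfinite(vals)
        if bad.any():
            gene = df.index[bad.to_numpy()][0]
            raise DataError(
                f"non-numeric or missing count at gene {gene!r}, sample {col!r}"
            )
        if (vals < 0).any():
            gene = df.index[(vals < 0).to_numpy()][0]
            raise DataError(f"negative count at gene {gene!r}, sample {col!r}")
        if not np.allclose(vals, np.round(vals)):
            bad_int = ~np.isclose(np.asarray(vals), np.round(np.asarray(vals)))
            gene = df.index[bad_int][0]
            raise DataError(f"non-integer count at gene {gene!r}, sample {col!r}")
    return df.astype(np.int64)


def write_counts(counts: pd.DataFrame, path) -> None:
    path = Path(path)
    counts.to_csv(path, sep=_sep_for(path), index_label="gene_id")


def read_metadata(path) -> pd.DataFrame:
    """Read and validate a sample metadata table.

    Required columns: sample_id, individual_id, group, freeze_thaw, rin,
    library_prep, concentration. ``freeze_thaw`` must be a non-negative
    integer; ``rin`` must lie in [1, 10] or be missing; ``group`` must be one
    of ASD / TD / standard / NA.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"metadata {path.name} missing columns: {missing}")
    return validate_metadata(df)


def validate_metadata(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["sample_id"] = df["sample_id"].astype(str)
    if df["sample_id"].duplicated().any():
        raise DataError("duplicated sample_id in metadata")
    df["individual_id"] = df["individual_id"].astype(str)
    df["group"] = df["group"].fillna("NA").astype(str)
    bad = sorted(set(df["group"]) - VALID_GROUPS)
    if bad:
        raise DataError(f"unknown group labels: {bad} (expected {sorted(VALID_GROUPS)})")
    ft = pd.to_numeric(df["freeze_thaw"], errors="coerce")
    if ft.isna().any() or (ft < 0).any() or not np.allclose(ft, np.round(ft)):
        raise DataError("freeze_thaw must be a non-negative integer for every sample")
    df["freeze_thaw"] = ft.astype(int)
    rin = pd.to_numeric(df["rin"], errors="coerce")
    present = rin.notna()
    if ((rin[present] < 1) | (rin[present] > 10)).any():
        offender = df.loc[present & ((rin < 1) | (rin > 10)), "sample_id"].iloc[0]
        raise DataError(f"rin out of range [1, 10] for sample {offender!r}")
    df["rin"] = rin
    df["concentration"] = pd.to_numeric(df["concentration"], errors="coerce")
    df["library_prep"] = df["library_prep"].astype(str)
    return df.reset_index(drop=True)


def write_metadata(metadata: pd.DataFrame, path) -> None:
    path = Path(path)
    cols = METADATA_COLUMNS + [c for c in metadata.columns if c not in METADATA_COLUMNS]
    metadata.loc[:, cols].to_csv(path, sep=_sep_for(path), index=False)


def align_counts_metadata(counts: pd.DataFrame, metadata: pd.DataFrame):
    """Check referential integrity and order metadata to match the matrix."""
    meta_ids = set(metadata["sample_id"])
    orphans = [s for s in counts.columns if s not in meta_ids]
    if orphans:
        raise DataError(f"samples in counts but absent from metadata: {orphans[:5]}")
    ordered = (
        metadata.set_index("sample_id").loc[list(counts.columns)].reset_index()
    )
    return counts, ordered


def write_truth(truth: dict, path) -> None:
    """Write a generating-truth record as JSON (arrays become lists)."""

    def _default(o):
        if isinstance(o, (np.ndarray, pd.Series)):
            return np.asarray(o).tolist()
        if isinstance(o, pd.Index):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(f"cannot serialize {type(o)}")

    Path(path).write_text(json.dumps(truth, default=_default, indent=1))


def read_truth(path) -> dict:
    return json.loads(Path(path).read_text())
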