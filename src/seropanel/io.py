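"""Readers and writers for matrices, metadata, tabular results, and manifests.

All tabular artifacts are RFC-4180 CSV (pandas-backed); panel models and run
manifests are JSON. Every writer/reader pair round-trips its domain object.
"""

from __future__ import annotations

import hashlib
import json
import platform
import warnings
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .datatypes import CohortBundle, Marker, MfiMatrix, validate_sample_meta

_FLOAT_FMT = "%.10g"  # fixed formatting so replays are byte-identical


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    return pd.read_csv(path, sep=sep)


def read_mfi_matrix(path: str | Path, dialect: str = "wide") -> MfiMatrix:
    """Read a linear-scale MFI matrix from CSV/TSV.

    ``wide``: first column ``sample_id``, remaining columns named
    ``"SYMBOL|IgG"`` / ``"SYMBOL|IgA"``. ``long``: columns
    (sample_id, marker_id, isotype, mfi), pivoted to wide.

    Duplicate (sample, marker) entries and non-positive MFI are hard errors;
    the offending cell is named.
    """
    df = _read_table(path)
    if dialect == "wide":
        if df.columns[0] != "sample_id":
            raise ValueError(
                f"wide matrix must have 'sample_id' as first column, got {df.columns[0]!r}"
            )
        df = df.set_index("sample_id")
        df.index = df.index.astype(str)
        df.index.name = None
    elif dialect == "long":
        required = ["sample_id", "marker_id", "isotype", "mfi"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"long matrix missing columns: {missing}")
        df = df.copy()
        df["sample_id"] = df["sample_id"].astype(str)
        key = df["marker_id"].astype(str) + "|" + df["isotype"].astype(str)
        dup = df.assign(_key=key).duplicated(subset=["sample_id", "_key"])
        if dup.any():
            row = df.loc[dup.idxmax()]
            raise ValueError(
                "duplicate entry for sample "
                f"{row['sample_id']!r}, marker {row['marker_id']!r} ({row['isotype']})"
            )
        wide = df.assign(_key=key).pivot(index="sample_id", columns="_key", values="mfi")
        if wide.isna().any().any():
            sid = wide.index[wide.isna().any(axis=1)][0]
            mk = wide.columns[wide.isna().any(axis=0)][0]
            raise ValueError(f"long matrix leaves cell empty: sample {sid!r}, marker {mk!r}")
        # deterministic column order: keep first-appearance order from the file
        order = list(dict.fromkeys(key))
        df = wide.loc[:, order]
        df.index.name = None
        df.columns.name = None
    else:
        raise ValueError(f"dialect must be 'wide' or 'long', got {dialect!r}")
    return MfiMatrix(df, scale="linear")


def write_mfi_matrix(m: MfiMatrix, path: str | Path) -> None:
    out = m.data.copy()
    out.insert(0, "sample_id", m.sample_ids)
    out.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_processed_matrix(path: str | Path, scale: str) -> MfiMatrix:
    """Read a matrix written by :func:`write_mfi_matrix` on a declared scale."""
    df = _read_table(path).set_index("sample_id")
    df.index = df.index.astype(str)
    df.index.name = None
    return MfiMatrix(df, scale=scale)


def read_sample_meta(path: str | Path) -> pd.DataFrame:
    df = _read_table(path)
    return validate_sample_meta(df)


def write_sample_meta(meta: pd.DataFrame, path: str | Path) -> None:
    out = meta.copy()
    # nullable booleans -> "True"/"False"/"" cells
    for col in out.columns:
        if str(out[col].dtype) == "boolean":
            out[col] = out[col].map(lambda v: "" if pd.isna(v) else str(bool(v)))
    out.to_csv(path, index=False)


def join_metadata(m: MfiMatrix, meta: pd.DataFrame) -> CohortBundle:
    """Match every matrix sample to exactly one metadata row.

    Samples present in the metadata but not in the matrix are dropped with a
    warning; matrix samples without metadata are a hard error.
    """
    meta = validate_sample_meta(meta.reset_index(drop=True))
    orphans = [s for s in m.sample_ids if s not in meta.index]
    if orphans:
        raise ValueError(f"matrix samples without metadata: {orphans}")
    extra = [s for s in meta.index if s not in set(m.sample_ids)]
    if extra:
        warnings.warn(
            f"{len(extra)} metadata rows without matrix samples dropped: {extra[:5]}...",
            stacklevel=2,
        )
    aligned = meta.loc[m.sample_ids]
    return CohortBundle(matrix=m, meta=aligned)


# --- tabular results ---------------------------------------------------------

def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, index=index, float_format=_FLOAT_FMT)


def write_cutoff_table(cutoffs: pd.DataFrame, path: str | Path) -> None:
    cutoffs.reset_index(names="marker").to_csv(path, index=False, float_format="%.17g")


def read_cutoff_table(path: str | Path) -> pd.DataFrame:
    df = _read_table(path).set_index("marker")
    df.index.name = "marker"
    df["escalated"] = df["escalated"].astype(bool)
    df["n_hc_used"] = df["n_hc_used"].astype(int)
    return df


def write_binary_matrix(calls: pd.DataFrame, path: str | Path) -> None:
    out = calls.astype(int).copy()
    out.insert(0, "sample_id", [str(s) for s in calls.index])
    out.to_csv(path, index=False)


def read_binary_matrix(path: str | Path) -> pd.DataFrame:
    df = _read_table(path).set_index("sample_id")
    df.index = df.index.astype(str)
    df.index.name = None
    return df.astype(bool)


# --- manifest ----------------------------------------------------------------

def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    path: str | Path,
    config: PipelineConfig,
    seed: int | None,
    inputs: dict[str, str | Path] | None = None,
    outputs: dict[str, str | Path] | None = None,
    extra: dict[str, Any] | None = None,
) -> None:
    """Emit a run manifest (config + seed + input digests + versions).

    Re-running the same stage with the manifest's config and seed reproduces
    all outputs byte-identically.
    """
    import seropanel

    manifest = {
        "seropanel_version": seropanel.__version__,
        "python_version": platform.python_version(),
        "config": config.to_dict(),
        "seed": seed,
        "inputs": {k: {"path": str(v), "sha256": file_digest(v)} for k, v in (inputs or {}).items()},
        "outputs": {k: str(v) for k, v in (outputs or {}).items()},
    }
    if extra:
        manifest.update(extra)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_manifest(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
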