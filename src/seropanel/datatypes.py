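"""Domain containers shared by all pipeline stages.

The central object is :class:`MfiMatrix`, a thin wrapper around a pandas
DataFrame of median fluorescence intensities (samples in rows, antigen-isotype
channels in columns) carrying an explicit ``scale`` tag so that scale
transitions (linear -> log2 -> log2, sample-median-centered) only happen
through declared operations.

Marker columns are named ``"SYMBOL|IgG"`` / ``"SYMBOL|IgA"`` — one unambiguous
separator, because each antigen is measured in both isotype channels.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

ISOTYPES = ("IgG", "IgA")
GROUPS = ("SjD", "HC", "NSS", "RA", "SLE", "SSc")
MARKER_SEP = "|"

#: scale tags, in the order they are produced by the pipeline
SCALES = ("linear", "log2", "log2_centered")


@dataclass(frozen=True, order=True)
class Marker:
    """One antigen-isotype channel of the bead array.

    Parameters
    ----------
    marker_id : str
        Antigen symbol, e.g. ``"CCL4"``.
    isotype : str
        ``"IgG"`` or ``"IgA"`` — the detected antibody class.
    source : str
        Provenance of candidacy: ``"discovery"``, ``"literature"`` or
        ``"pathway"``.
    """

    marker_id: str
    isotype: str = "IgG"
    source: str = "discovery"

    def __post_init__(self) -> None:
        if not self.marker_id:
            raise ValueError("marker_id must be non-empty")
        if self.isotype not in ISOTYPES:
            raise ValueError(f"isotype must be one of {ISOTYPES}, got {self.isotype!r}")
        if self.source not in ("discovery", "literature", "pathway"):
            raise ValueError(f"unknown marker source {self.source!r}")

    @property
    def key(self) -> str:
        """Column name used in wide matrices: ``"SYMBOL|IgG"``."""
        return f"{self.marker_id}{MARKER_SEP}{self.isotype}"

    @classmethod
    def from_key(cls, key: str, source: str = "discovery") -> "Marker":
        parts = key.split(MARKER_SEP)
        if len(parts) != 2:
            raise ValueError(
                f"marker column {key!r} is not of the form 'SYMBOL{MARKER_SEP}IgG'"
            )
        return cls(marker_id=parts[0], isotype=parts[1], source=source)


def marker_keys(markers: Iterable[Marker]) -> list[str]:
    return [m.key for m in markers]


class MfiMatrix:
    """Sample x marker intensity matrix with an explicit scale tag.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows indexed by sample id, columns named ``"SYMBOL|isotype"``.
    scale : str
        One of ``"linear"``, ``"log2"``, ``"log2_centered"``.

    Raises
    ------
    ValueError
        On duplicated sample ids or markers, missing cells, or non-positive
        values on the linear scale.
    """

    def __init__(self, data: pd.DataFrame, scale: str = "linear") -> None:
        if scale not in SCALES:
            raise ValueError(f"scale must be one of {SCALES}, got {scale!r}")
        if data.index.duplicated().any():
            dupes = data.index[data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicated sample ids: {dupes}")
        if data.columns.duplicated().any():
            dupes = data.columns[data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicated marker columns: {dupes}")
        values = data.to_numpy(dtype=float)
        if np.isnan(values).any():
            i, j = np.argwhere(np.isnan(values))[0]
            raise ValueError(
                "missing MFI value for sample "
                f"{data.index[i]!r}, marker {data.columns[j]!r}; the assay "
                "yields a value per bead region, so missing cells are not permitted"
            )
        if scale == "linear" and (values <= 0).any():
            i, j = np.argwhere(values <= 0)[0]
            raise ValueError(
                f"non-positive MFI ({values[i, j]!r}) for sample "
                f"{data.index[i]!r}, marker {data.columns[j]!r}"
            )
        # validate marker keys parse
        for col in data.columns:
            Marker.from_key(str(col))
        self.data = data.astype(float)
        self.scale = scale

    # -- convenience accessors -------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.index]

    @property
    def marker_names(self) -> list[str]:
        return [str(c) for c in self.data.columns]

    @property
    def markers(self) -> list[Marker]:
        return [Marker.from_key(str(c)) for c in self.data.columns]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def select_markers(self, names: Iterable[str]) -> "MfiMatrix":
        names = list(names)
        missing = [n for n in names if n not in self.data.columns]
        if missing:
            raise KeyError(f"markers not in matrix: {missing}")
        return MfiMatrix(self.data.loc[:, names].copy(), scale=self.scale)

    def select_samples(self, ids: Iterable[str]) -> "MfiMatrix":
        ids = list(ids)
        missing = [s for s in ids if s not in self.data.index]
        if missing:
            raise KeyError(f"samples not in matrix: {missing}")
        return MfiMatrix(self.data.loc[ids].copy(), scale=self.scale)

    def isotype_markers(self, isotype: str) -> list[str]:
        """Column names of one isotype channel (e.g. IgG-only panel building)."""
        return [m.key for m in self.markers if m.isotype == isotype]

    def with_data(self, data: pd.DataFrame, scale: str) -> "MfiMatrix":
        return MfiMatrix(data, scale=scale)

    def equals(self, other: "MfiMatrix") -> bool:
        return self.scale == other.scale and self.data.equals(other.data)

    def __repr__(self) -> str:  # pragma: no cover
        n, p = self.shape
        return f"MfiMatrix({n} samples x {p} markers, scale={self.scale!r})"


@dataclass
class StandardCurve:
    """ELISA standard ladder: ordered (concentration U/ml, response OD) pairs.

    Exactly five standards spanning 2.5–40 U/ml; concentrations strictly
    increasing, responses strictly monotone (either direction, to cover
    competitive assay formats).
    """

    concentrations: tuple[float, ...]
    responses: tuple[float, ...]

    def __post_init__(self) -> None:
        conc = np.asarray(self.concentrations, dtype=float)
        resp = np.asarray(self.responses, dtype=float)
        if conc.size != 5 or resp.size != 5:
            raise ValueError("standard curve requires exactly 5 ladder points")
        if not (np.diff(conc) > 0).all():
            raise ValueError("ladder concentrations must be strictly increasing")
        d = np.diff(resp)
        if not ((d > 0).all() or (d < 0).all()):
            raise ValueError("ladder responses must be strictly monotone")
        if (conc <= 0).any():
            raise ValueError("ladder concentrations must be positive")

    @property
    def increasing(self) -> bool:
        return self.responses[-1] > self.responses[0]

    @property
    def lower(self) -> float:
        return float(self.concentrations[0])

    @property
    def upper(self) -> float:
        return float(self.concentrations[-1])


def validate_sample_meta(meta: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalize a sample-metadata table.

    Expects columns ``sample_id``, ``group``, ``cohort`` and optionally
    ``ro_ssa_positive`` plus arbitrary binary clinical-flag columns. Flag
    columns are coerced to pandas nullable booleans so that missing clinical
    data survives round-trips (needed for complete-case association analysis).
    """
    required = {"sample_id", "group", "cohort"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata missing required columns: {sorted(missing)}")
    meta = meta.copy()
    meta["sample_id"] = meta["sample_id"].astype(str)
    if meta["sample_id"].duplicated().any():
        dupes = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicated sample ids in metadata: {dupes}")
    bad = set(meta["group"]) - set(GROUPS)
    if bad:
        raise ValueError(f"unknown group labels {sorted(bad)}; expected {GROUPS}")
    for col in meta.columns:
        if col in ("sample_id", "group", "cohort"):
            continue
        meta[col] = _to_nullable_bool(meta[col], col)
    meta = meta.set_index("sample_id", drop=False)
    meta.index.name = None
    return meta


def _to_nullable_bool(s: pd.Series, name: str) -> pd.Series:
    def conv(v):
        if pd.isna(v) or v == "":
            return pd.NA
        if isinstance(v, (bool, np.bool_)):
            return bool(v)
        if isinstance(v, str):
            low = v.strip().lower()
            if low in ("true", "1", "yes"):
                return True
            if low in ("false", "0", "no"):
                return False
            raise ValueError(f"cannot parse boolean flag {name}={v!r}")
        if isinstance(v, (int, float, np.integer, np.floating)):
            if float(v) in (0.0, 1.0):
                return bool(v)
            raise ValueError(f"cannot parse boolean flag {name}={v!r}")
        raise ValueError(f"cannot parse boolean flag {name}={v!r}")

    return s.map(conv).astype("boolean")


def clinical_flag_columns(meta: pd.DataFrame) -> list[str]:
    """Columns of ``meta`` holding nullable binary clinical/laboratory flags."""
    reserved = {"sample_id", "group", "cohort", "ro_ssa_positive"}
    return [c for c in meta.columns if c not in reserved]


@dataclass
class CohortBundle:
    """A validated (matrix, metadata) pair with aligned samples."""

    matrix: MfiMatrix
    meta: pd.DataFrame

    def group_counts(self) -> dict[str, int]:
        return self.meta["group"].value_counts().to_dict()

    def samples_in_group(self, group: str) -> list[str]:
        return self.meta.loc[self.meta["group"] == group, "sample_id"].tolist()
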