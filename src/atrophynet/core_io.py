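"""Spatial data model and I/O for the atrophy-network-mapping pipeline.

Every downstream stage operates on three containers defined here:

``GridSpace``
    A voxel grid (shape + affine) together with a boolean analysis mask.
    The mask induces a fixed linear ordering of in-mask units — row-major
    (C order) over the grid — and every per-unit array in the pipeline uses
    that ordering.  Surface (vertex-wise) data reuse the same container: the
    "grid" is then a 1×1×n_vertices line with an identity affine.

``SubjectMap``
    One scalar per in-mask unit for one subject: cortical thickness (mm),
    a w-score, a Fisher-z connectivity value, or a test statistic.

``PhenotypeTable``
    Per-subject covariates, amyloid measures and clinical scores, backed by
    a pandas DataFrame.

Volumes are NIfTI-1 (via nibabel); phenotype tables are CSV with an
explicit missing-value token set.
"""

from __future__ import annotations

import enum
import json
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

#: CSV tokens mapped to explicit missing values (common CSV dialects).
MISSING_TOKENS: tuple[str, ...] = ("", "NA", "NaN")


class MapKind(str, enum.Enum):
    """What the per-unit values of a :class:`SubjectMap` mean."""

    thickness_mm = "thickness_mm"
    wscore = "wscore"
    connectivity_z = "connectivity_z"
    statistic = "statistic"


# ---------------------------------------------------------------------------
# GridSpace
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GridSpace:
    """A voxel grid with an analysis mask.

    Parameters
    ----------
    shape
        Voxel counts per axis (3-tuple).
    affine
        4×4 voxel-to-world (mm) matrix; must be invertible.
    mask
        Boolean array of ``shape``; True marks in-analysis voxels.  At least
        one voxel must be in-mask.
    """

    shape: tuple[int, int, int]
    affine: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        object.__setattr__(self, "shape", shape)
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError(f"affine must be 4x4, got {affine.shape}")
        if abs(np.linalg.det(affine)) < 1e-12:
            raise ValueError("affine is singular")
        affine.setflags(write=False)
        object.__setattr__(self, "affine", affine)
        mask = np.asarray(self.mask, dtype=bool)
        if mask.shape != shape:
            raise ValueError(
                f"mask shape {mask.shape} does not match grid shape {shape}"
            )
        if not mask.any():
            raise ValueError("mask has no in-analysis voxels")
        mask.setflags(write=False)
        object.__setattr__(self, "mask", mask)

    @property
    def n_units(self) -> int:
        """Number of in-mask units."""
        return int(self.mask.sum())

    def restrict(self, volume: np.ndarray) -> np.ndarray:
        """Extract the in-mask values of a full 3D volume (row-major order)."""
        volume = np.asarray(volume)
        if volume.shape != self.shape:
            raise ValueError(
                f"volume shape {volume.shape} does not match grid shape {self.shape}"
            )
        return volume[self.mask].astype(float, copy=True)

    def embed(self, values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Place per-unit values back into a full 3D volume."""
        values = np.asarray(values, dtype=float)
        if values.shape != (self.n_units,):
            raise ValueError(
                f"expected {self.n_units} in-mask values, got {values.shape}"
            )
        out = np.full(self.shape, fill, dtype=float)
        out[self.mask] = values
        return out

    @classmethod
    def full(cls, shape: Sequence[int], affine: np.ndarray | None = None) -> "GridSpace":
        """A grid with every voxel in-mask (identity affine by default)."""
        shape = tuple(int(s) for s in shape)
        if affine is None:
            affine = np.eye(4)
        return cls(shape=shape, affine=affine, mask=np.ones(shape, dtype=bool))

    # -- serialization ------------------------------------------------------

    def save(self, mask_path: str | os.PathLike, sidecar_path: str | os.PathLike | None = None) -> None:
        """Write the mask as NIfTI plus a JSON provenance sidecar."""
        img = nib.Nifti1Image(self.mask.astype(np.uint8), np.asarray(self.affine))
        nib.save(img, os.fspath(mask_path))
        if sidecar_path is not None:
            meta = {
                "shape": list(self.shape),
                "affine": np.asarray(self.affine).tolist(),
                "n_units": self.n_units,
            }
            with open(sidecar_path, "w") as fh:
                json.dump(meta, fh, indent=2)

    @classmethod
    def load(cls, mask_path: str | os.PathLike) -> "GridSpace":
        img = nib.load(os.fspath(mask_path))
        data = np.asanyarray(img.dataobj)
        return cls(shape=data.shape, affine=img.affine, mask=data > 0)


# ---------------------------------------------------------------------------
# SubjectMap
# ---------------------------------------------------------------------------


@dataclass
class SubjectMap:
    """One scalar per in-mask unit for one subject."""

    space: GridSpace
    values: np.ndarray
    kind: MapKind = MapKind.thickness_mm
    subject_id: str | None = None

    def __post_init__(self) -> None:
        self.kind = MapKind(self.kind)
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.shape[0] != self.space.n_units:
            raise ValueError(
                f"values must be 1-D of length {self.space.n_units} "
                f"(in-mask units), got shape {values.shape}"
            )
        if self.kind is MapKind.thickness_mm:
            if np.any(values[np.isfinite(values)] < 0):
                raise ValueError("thickness values must be >= 0")
        elif self.kind in (MapKind.wscore, MapKind.connectivity_z):
            if not np.all(np.isfinite(values)):
                raise ValueError(f"{self.kind.value} values must be finite")
        self.values = values

    def to_volume(self, fill: float = 0.0) -> np.ndarray:
        return self.space.embed(self.values, fill=fill)


# ---------------------------------------------------------------------------
# Volume I/O
# ---------------------------------------------------------------------------


def read_volume(
    path: str | os.PathLike,
    space: GridSpace | None = None,
    kind: MapKind | str = MapKind.thickness_mm,
    subject_id: str | None = None,
) -> SubjectMap:
    """Read a 3D NIfTI volume as a :class:`SubjectMap`.

    If ``space`` is given, the file's shape must match it and the values are
    restricted to its mask.  Otherwise a full-mask :class:`GridSpace` is
    created from the file's own shape and affine.
    """
    img = nib.load(os.fspath(path))
    data = np.asanyarray(img.dataobj, dtype=float)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {data.shape}")
    if space is None:
        space = GridSpace(shape=data.shape, affine=img.affine,
                          mask=np.ones(data.shape, dtype=bool))
    elif tuple(data.shape) != space.shape:
        raise ValueError(
            f"{path}: volume shape {tuple(data.shape)} does not match "
            f"declared space shape {space.shape}"
        )
    return SubjectMap(space=space, values=space.restrict(data), kind=kind,
                      subject_id=subject_id)


def write_volume(subject_map: SubjectMap, path: str | os.PathLike) -> None:
    """Write a :class:`SubjectMap` as NIfTI; out-of-mask voxels become 0."""
    if not np.all(np.isfinite(subject_map.values)):
        raise ValueError("refusing to write map with non-finite in-mask values")
    vol = subject_map.to_volume(fill=0.0)
    img = nib.Nifti1Image(vol.astype(np.float64), np.asarray(subject_map.space.affine))
    nib.save(img, os.fspath(path))


# ---------------------------------------------------------------------------
# PhenotypeTable
# ---------------------------------------------------------------------------

#: Columns the clinical analyses may consume; only subject_id is mandatory
#: unless the caller asks for more.
KNOWN_COLUMNS = (
    "subject_id", "age", "sex", "education", "suvr", "visual_read",
    "abeta_status", "pacc", "logical_memory", "mmse", "digit_symbol",
    "fcsrt", "cfi_pt", "cfi_sp", "cfi_total", "gds", "ftps",
    "suicide_attempt", "death_wish",
    "hip_l", "hip_r", "ilv_l", "ilv_r",
)


@dataclass
class PhenotypeTable:
    """Per-subject covariates, amyloid measures and clinical scores.

    ``df`` is indexed positionally; ``subject_id`` is a column and must be
    unique.  Missing values are NaN (or pandas NA for booleans).
    """

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if "subject_id" not in self.df.columns:
            raise ValueError("phenotype table requires a subject_id column")
        ids = self.df["subject_id"]
        if ids.duplicated().any():
            dupes = ids[ids.duplicated()].unique().tolist()
            raise ValueError(f"duplicate subject_id values: {dupes}")
        if "suvr" in self.df.columns:
            suvr = pd.to_numeric(self.df["suvr"], errors="coerce")
            if (suvr.dropna() <= 0).any():
                raise ValueError("suvr values must be > 0")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def subject_ids(self) -> list[str]:
        return self.df["subject_id"].astype(str).tolist()

    def column(self, name: str) -> np.ndarray:
        if name not in self.df.columns:
            raise KeyError(
                f"unknown phenotype column {name!r}; available: "
                f"{sorted(self.df.columns)}"
            )
        return self.df[name].to_numpy()

    def covariate_matrix(self, names: Iterable[str]) -> np.ndarray:
        """Stack numeric covariate columns as an (n, q) float array."""
        cols = [pd.to_numeric(self.df[n], errors="coerce").to_numpy(float)
                for n in names]
        return np.column_stack(cols) if cols else np.empty((len(self.df), 0))

    def to_csv(self, path: str | os.PathLike) -> None:
        self.df.to_csv(path, index=False)


def read_phenotypes(
    path: str | os.PathLike,
    required: Sequence[str] = ("subject_id",),
) -> PhenotypeTable:
    """Read a phenotype CSV into a :class:`PhenotypeTable`.

    Missing-value tokens ("", "NA", "NaN") become explicit missing values;
    ``cfi_total`` is computed as ``cfi_pt + cfi_sp`` when absent.
    """
    df = pd.read_csv(
        os.fspath(path),
        na_values=list(MISSING_TOKENS),
        keep_default_na=False,
        dtype={"subject_id": str},
    )
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise ValueError(f"missing required columns: {missing_cols}")
    numeric_like = [c for c in df.columns
                    if c not in ("subject_id",) and df[c].dtype == object]
    for c in numeric_like:
        converted = pd.to_numeric(df[c], errors="coerce")
        # keep text columns (e.g. abeta_status labels) as-is
        if converted.notna().sum() >= df[c].notna().sum():
            df[c] = converted
    if "cfi_total" not in df.columns and {"cfi_pt", "cfi_sp"} <= set(df.columns):
        df["cfi_total"] = df["cfi_pt"] + df["cfi_sp"]
    return PhenotypeTable(df=df)
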