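"""Seed-based connectivity against a normative connectome.

Given a per-subject atrophy seed (a set of voxels, or nonnegative voxel
weights, derived from a w-score map), each normative-connectome subject
contributes one connectivity map: the Pearson correlation between the seed's
mean BOLD time course and every in-mask voxel's time course, Fisher
z-transformed.  Maps are aggregated across connectome subjects either as the
mean Fisher z (default) or as a one-sample t statistic of z.

The connectome itself is a collection of (timepoints × in-mask-voxels)
series matrices over a shared :class:`~atrophynet.core_io.GridSpace`; it can
live in memory or stream from per-subject 4D NIfTI files.  Streaming and
in-memory computation are algebraically identical (a running sum over
subjects), so results agree to machine precision regardless of batching.
"""

from __future__ import annotations

import glob
import os
from dataclasses import dataclass, field
from typing import Iterator, Literal, Mapping, Sequence

import nibabel as nib
import numpy as np

from .core_io import GridSpace, MapKind, SubjectMap

#: |r| is clipped here before atanh so single-voxel seeds stay finite.
R_CLIP = 1.0 - 1e-7


# ---------------------------------------------------------------------------
# Seeds
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Seed:
    """An atrophy seed: in-mask unit indices with optional weights.

    ``weights is None`` means a binary seed (unweighted mean time course);
    otherwise weights are nonnegative and the time course is the
    weight-normalized mean.
    """

    indices: np.ndarray
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=np.intp)
        if idx.ndim != 1 or idx.size == 0:
            raise ValueError("seed must contain at least one voxel")
        object.__setattr__(self, "indices", idx)
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            if w.shape != idx.shape:
                raise ValueError("weights must align with indices")
            if np.any(w < 0) or w.sum() <= 0:
                raise ValueError("weights must be nonnegative with positive sum")
            object.__setattr__(self, "weights", w)

    @property
    def size(self) -> int:
        return int(self.indices.size)


# ---------------------------------------------------------------------------
# Connectome
# ---------------------------------------------------------------------------


class Connectome:
    """Per-subject BOLD time-series over a common masked grid.

    Parameters
    ----------
    space
        Shared grid; series arrays cover its in-mask units in mask order.
    series
        Either a list of (timepoints, n_units) arrays (in-memory) or a list
        of NIfTI paths loaded lazily, one 4D file per connectome subject.
    """

    def __init__(
        self,
        space: GridSpace,
        series: Sequence[np.ndarray] | None = None,
        paths: Sequence[str | os.PathLike] | None = None,
    ) -> None:
        if (series is None) == (paths is None):
            raise ValueError("provide exactly one of series= or paths=")
        self.space = space
        self._series = None
        self._paths = None
        if series is not None:
            checked = []
            for i, s in enumerate(series):
                s = np.asarray(s, dtype=float)
                if s.ndim != 2 or s.shape[1] != space.n_units:
                    raise ValueError(
                        f"subject {i}: series must be (timepoints, {space.n_units})"
                    )
                checked.append(s)
            self._series = checked
            self._n = len(checked)
        else:
            self._paths = [os.fspath(p) for p in paths]
            self._n = len(self._paths)
        if self._n == 0:
            raise ValueError("connectome has no subjects")

    @property
    def n_subjects(self) -> int:
        return self._n

    def subject_series(self, i: int) -> np.ndarray:
        """(timepoints, n_units) series for connectome subject ``i``."""
        if self._series is not None:
            return self._series[i]
        img = nib.load(self._paths[i])
        data = np.asanyarray(img.dataobj, dtype=float)
        if data.ndim != 4:
            raise ValueError(f"{self._paths[i]}: expected 4D NIfTI")
        if data.shape[:3] != self.space.shape:
            raise ValueError(
                f"{self._paths[i]}: shape {data.shape[:3]} does not match "
                f"space {self.space.shape}"
            )
        return data[self.space.mask, :].T

    def iter_series(self) -> Iterator[np.ndarray]:
        for i in range(self._n):
            yield self.subject_series(i)

    def zero_variance_units(self) -> np.ndarray:
        """Indices of units with zero variance in any subject (excluded units)."""
        bad = np.zeros(self.space.n_units, dtype=bool)
        for ts in self.iter_series():
            bad |= ts.std(axis=0) == 0
        return np.flatnonzero(bad)

    @classmethod
    def from_directory(cls, directory: str | os.PathLike,
                       space: GridSpace) -> "Connectome":
        """One 4D NIfTI per connectome subject, sorted by filename."""
        pats = sorted(
            glob.glob(os.path.join(os.fspath(directory), "*.nii"))
            + glob.glob(os.path.join(os.fspath(directory), "*.nii.gz"))
        )
        if not pats:
            raise FileNotFoundError(f"no NIfTI files in {directory}")
        return cls(space=space, paths=pats)

    def save(self, directory: str | os.PathLike) -> None:
        os.makedirs(directory, exist_ok=True)
        for i in range(self._n):
            ts = self.subject_series(i)
            vol = np.zeros(self.space.shape + (ts.shape[0],))
            vol[self.space.mask, :] = ts.T
            img = nib.Nifti1Image(vol, np.asarray(self.space.affine))
            nib.save(img, os.path.join(os.fspath(directory), f"conn_{i:04d}.nii.gz"))


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def resample_to_volume(
    surface_map: SubjectMap,
    lookup: Mapping[int, int] | Sequence[tuple[int, int]],
    target: GridSpace,
) -> SubjectMap:
    """Project a vertex-wise map into a voxel grid via a vertex→voxel lookup.

    Each voxel's value is the mean of the vertex values mapping to it; voxels
    receiving no vertex get NaN (absent from any seed domain built from the
    result).  The lookup abstracts the surface-to-volume registration.
    """
    pairs = list(lookup.items()) if isinstance(lookup, Mapping) else list(lookup)
    if not pairs:
        raise ValueError("empty vertex->voxel lookup")
    n_units = target.n_units
    sums = np.zeros(n_units)
    counts = np.zeros(n_units)
    for vertex, voxel in pairs:
        if not 0 <= voxel < n_units:
            raise ValueError(
                f"lookup maps vertex {vertex} to out-of-mask unit {voxel} "
                f"(target has {n_units} units)"
            )
        sums[voxel] += surface_map.values[vertex]
        counts[voxel] += 1
    out = np.full(n_units, np.nan)
    hit = counts > 0
    out[hit] = sums[hit] / counts[hit]
    return SubjectMap(space=target, values=np.where(hit, out, 0.0),
                      kind=surface_map.kind, subject_id=surface_map.subject_id)


def seed_timecourse(seed: Seed, series: np.ndarray) -> np.ndarray:
    """Mean (or weight-normalized mean) time course over the seed voxels."""
    series = np.asarray(series, dtype=float)
    sub = series[:, seed.indices]
    if seed.weights is None:
        return sub.mean(axis=1)
    w = seed.weights / seed.weights.sum()
    return sub @ w


def _fisher_z_map(seed: Seed, series: np.ndarray) -> np.ndarray:
    """Fisher-z connectivity of the seed course with every voxel, one subject."""
    tc = seed_timecourse(seed, series)
    tc = tc - tc.mean()
    denom_tc = np.sqrt(np.sum(tc**2))
    if denom_tc == 0:
        raise ZeroDivisionError("seed time course has zero variance")
    centered = series - series.mean(axis=0, keepdims=True)
    denom_vox = np.sqrt(np.sum(centered**2, axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (tc @ centered) / (denom_tc * denom_vox)
    r = np.where(denom_vox == 0, 0.0, r)
    r = np.clip(r, -R_CLIP, R_CLIP)
    return np.arctanh(r)


@dataclass
class ConnectivityMap:
    """Aggregated seed connectivity map (Fisher-z units for mean_z)."""

    map: SubjectMap
    aggregation: Literal["mean_z", "t_stat"]
    n_connectome_subjects: int
    degenerate: bool = False
    n_failed: int = 0


def connectivity_map(
    seed: Seed,
    connectome: Connectome,
    aggregation: Literal["mean_z", "t_stat"] = "mean_z",
    subject_id: str | None = None,
) -> ConnectivityMap:
    """Seed-to-whole-brain connectivity aggregated over connectome subjects.

    Per connectome subject: Pearson r between the seed time course and every
    voxel series, clipped to ±(1 − 1e-7), Fisher z = atanh(r).  Aggregation
    is the per-voxel mean of z (default) or the one-sample t of z across
    subjects.  Connectome subjects whose seed course is degenerate are
    skipped; if more than 10% fail the computation aborts.

    Subjects are streamed one at a time with exact running sums, so memory
    stays flat and the result is identical to an all-in-memory computation.
    """
    if aggregation not in ("mean_z", "t_stat"):
        raise ValueError(f"unknown aggregation {aggregation!r}")
    n_units = connectome.space.n_units
    total = np.zeros(n_units)
    total_sq = np.zeros(n_units)
    n_ok = 0
    n_failed = 0
    for series in connectome.iter_series():
        try:
            z = _fisher_z_map(seed, series)
        except ZeroDivisionError:
            n_failed += 1
            continue
        total += z
        total_sq += z**2
        n_ok += 1
    n_total = connectome.n_subjects
    if n_failed > 0.10 * n_total:
        raise RuntimeError(
            f"seed time course degenerate for {n_failed}/{n_total} connectome "
            "subjects (>10%); aborting"
        )
    mean_z = total / n_ok
    degenerate = bool(np.any(np.abs(mean_z) >= np.arctanh(R_CLIP) - 1e-9))
    if aggregation == "mean_z":
        values = mean_z
    else:
        if n_ok < 2:
            raise ValueError("t_stat aggregation needs >= 2 connectome subjects")
        var = (total_sq - n_ok * mean_z**2) / (n_ok - 1)
        var = np.maximum(var, 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            values = mean_z / np.sqrt(var / n_ok)
        values = np.where(var == 0, np.sign(mean_z) * np.inf, values)
        if np.any(~np.isfinite(values)):
            degenerate = True
            values = np.nan_to_num(values, posinf=1e6, neginf=-1e6)
    smap = SubjectMap(space=connectome.space, values=values,
                      kind=MapKind.connectivity_z, subject_id=subject_id)
    return ConnectivityMap(map=smap, aggregation=aggregation,
                           n_connectome_subjects=n_ok, degenerate=degenerate,
                           n_failed=n_failed)


def connectivity_maps(
    seeds: Sequence[Seed],
    connectome: Connectome,
    aggregation: Literal["mean_z", "t_stat"] = "mean_z",
    subject_ids: Sequence[str] | None = None,
) -> list[ConnectivityMap]:
    """Connectivity maps for many seeds in one pass over the connectome.

    Equivalent to calling :func:`connectivity_map` per seed (verified in the
    test suite) but streams each connectome subject once, computing all seed
    time courses and correlations as matrix products — the practical path
    for whole-cohort analyses.
    """
    if aggregation not in ("mean_z", "t_stat"):
        raise ValueError(f"unknown aggregation {aggregation!r}")
    n_units = connectome.space.n_units
    n_seeds = len(seeds)
    if n_seeds == 0:
        raise ValueError("no seeds given")
    W = np.zeros((n_units, n_seeds))
    for j, seed in enumerate(seeds):
        if seed.weights is None:
            W[seed.indices, j] = 1.0 / seed.size
        else:
            W[seed.indices, j] = seed.weights / seed.weights.sum()
    total = np.zeros((n_seeds, n_units))
    total_sq = np.zeros((n_seeds, n_units))
    n_ok = np.zeros(n_seeds, dtype=int)
    n_failed = np.zeros(n_seeds, dtype=int)
    for series in connectome.iter_series():
        tc = series @ W                                  # (T, n_seeds)
        tc = tc - tc.mean(axis=0, keepdims=True)
        denom_tc = np.sqrt(np.sum(tc**2, axis=0))
        ok = denom_tc > 0
        n_failed += ~ok
        n_ok += ok
        centered = series - series.mean(axis=0, keepdims=True)
        denom_vox = np.sqrt(np.sum(centered**2, axis=0))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (tc.T @ centered) / np.outer(denom_tc, denom_vox)
        r[:, denom_vox == 0] = 0.0
        r[~ok, :] = 0.0
        z = np.arctanh(np.clip(r, -R_CLIP, R_CLIP))
        total[ok] += z[ok]
        total_sq[ok] += z[ok] ** 2
    n_total = connectome.n_subjects
    bad = n_failed > 0.10 * n_total
    if np.any(bad):
        raise RuntimeError(
            f"seed time course degenerate for >10% of connectome subjects "
            f"for {int(bad.sum())} seed(s); aborting"
        )
    out: list[ConnectivityMap] = []
    zmax = np.arctanh(R_CLIP)
    for j in range(n_seeds):
        mean_z = total[j] / n_ok[j]
        degenerate = bool(np.any(np.abs(mean_z) >= zmax - 1e-9))
        if aggregation == "mean_z":
            values = mean_z
        else:
            var = (total_sq[j] - n_ok[j] * mean_z**2) / (n_ok[j] - 1)
            var = np.maximum(var, 0.0)
            with np.errstate(invalid="ignore", divide="ignore"):
                values = mean_z / np.sqrt(var / n_ok[j])
            if np.any(~np.isfinite(values)):
                degenerate = True
                values = np.nan_to_num(values, posinf=1e6, neginf=-1e6)
        sid = subject_ids[j] if subject_ids is not None else None
        smap = SubjectMap(space=connectome.space, values=values,
                          kind=MapKind.connectivity_z, subject_id=sid)
        out.append(ConnectivityMap(map=smap, aggregation=aggregation,
                                   n_connectome_subjects=int(n_ok[j]),
                                   degenerate=degenerate,
                                   n_failed=int(n_failed[j])))
    return out
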