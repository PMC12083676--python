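"""Normative thickness model and per-subject w-score atrophy maps.

A per-voxel (or per-vertex) ordinary-least-squares model of cortical
thickness on age and sex is fitted on the amyloid-negative control group.
A subject's w-map is then ``w(u) = (observed(u) - predicted(u)) /
residual_SD(u)`` — a z-score adjusted for covariates, negative where the
cortex is thinner than expected for the subject's age and sex.  Thresholding
the w-map yields the atrophy seed passed to the connectome stage.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .core_io import GridSpace, MapKind, SubjectMap
from .connectome_mapping import Seed

#: Default seed threshold: voxels >= 2 SD thinner than expected.
DEFAULT_SEED_THRESHOLD = -2.0
#: Fallback size when a subject's thresholded seed is empty.
DEFAULT_FALLBACK_K = 50


@dataclass
class NormativeModel:
    """Per-unit OLS coefficients (intercept, age, sex) and residual SD."""

    space: GridSpace
    coefficients: np.ndarray   # (3, n_units)
    residual_sd: np.ndarray    # (n_units,)
    n_controls: int
    covariate_means: np.ndarray  # (age_mean, sex_mean)

    N_PARAMS = 3

    def predict(self, age: float, sex: float) -> np.ndarray:
        x = np.array([1.0, float(age), float(sex)])
        return x @ self.coefficients

    def save(self, directory: str | os.PathLike) -> None:
        """Coefficient/SD volumes as NIfTI plus JSON metadata."""
        from .core_io import write_volume
        os.makedirs(directory, exist_ok=True)
        names = ["intercept", "age", "sex"]
        for i, name in enumerate(names):
            write_volume(
                SubjectMap(space=self.space, values=self.coefficients[i],
                           kind=MapKind.statistic),
                os.path.join(os.fspath(directory), f"coef_{name}.nii.gz"),
            )
        write_volume(
            SubjectMap(space=self.space, values=self.residual_sd,
                       kind=MapKind.statistic),
            os.path.join(os.fspath(directory), "residual_sd.nii.gz"),
        )
        with open(os.path.join(os.fspath(directory), "model.json"), "w") as fh:
            json.dump({"n_controls": self.n_controls,
                       "covariate_means": self.covariate_means.tolist(),
                       "covariates": ["age", "sex"]}, fh, indent=2)


def fit_normative(
    controls: Sequence[SubjectMap],
    age: np.ndarray,
    sex: np.ndarray,
) -> NormativeModel:
    """Fit the control-group normative GLM, one OLS per spatial unit.

    The design is shared across units, so the whole fit is a single least
    squares solve: ``B = pinv(X) @ Y`` with ``Y`` the (n_controls, n_units)
    thickness matrix.  Residual SD uses denominator ``n - p`` (p = 3).
    """
    n = len(controls)
    if n < 10:
        raise ValueError(f"need >= 10 controls, got {n}")
    age = np.asarray(age, dtype=float)
    sex = np.asarray(sex, dtype=float)
    if age.shape != (n,) or sex.shape != (n,):
        raise ValueError("age and sex must align with controls")
    if np.any(~np.isfinite(age)) or np.any(~np.isfinite(sex)):
        raise ValueError("controls must have complete age and sex")
    space = controls[0].space
    Y = np.stack([m.values for m in controls])          # (n, n_units)
    X = np.column_stack([np.ones(n), age, sex])
    p = X.shape[1]
    if n <= p:
        raise ValueError(f"insufficient degrees of freedom: n={n} <= p={p}")
    if np.linalg.matrix_rank(X) < p:
        bad = "sex" if np.ptp(sex) == 0 else "age"
        raise ValueError(f"rank-deficient normative design: column '{bad}' is "
                         "collinear or constant")
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)        # (p, n_units)
    resid = Y - X @ beta
    sd = np.sqrt(np.sum(resid**2, axis=0) / (n - p))
    # an exact fit leaves O(eps) rounding residue; make it an exact zero so
    # degenerate units are detectable downstream
    sd[sd < 1e-10 * max(1.0, float(np.abs(Y).max()))] = 0.0
    return NormativeModel(space=space, coefficients=beta, residual_sd=sd,
                          n_controls=n,
                          covariate_means=np.array([age.mean(), sex.mean()]))


def compute_wmap(
    thickness: SubjectMap,
    age: float,
    sex: float,
    model: NormativeModel,
) -> SubjectMap:
    """Per-unit w-score of a subject's thickness against the normative model."""
    if thickness.space.shape != model.space.shape:
        raise ValueError("subject map and model are on different spaces")
    pred = model.predict(age, sex)
    diff = thickness.values - pred
    sd = model.residual_sd
    zero_sd = sd == 0
    if np.any(zero_sd & (diff != 0)):
        k = int(np.flatnonzero(zero_sd & (diff != 0))[0])
        raise ZeroDivisionError(
            f"degenerate normative model: residual SD is 0 at unit {k} where "
            "observed differs from predicted"
        )
    w = np.zeros_like(diff)
    np.divide(diff, sd, out=w, where=~zero_sd)
    return SubjectMap(space=thickness.space, values=w, kind=MapKind.wscore,
                      subject_id=thickness.subject_id)


def make_seed(
    wmap: SubjectMap,
    threshold: float = DEFAULT_SEED_THRESHOLD,
    weighting: Literal["binary", "magnitude"] = "binary",
    empty_action: Literal["error", "fallback"] = "fallback",
    fallback_k: int = DEFAULT_FALLBACK_K,
) -> Seed:
    """Threshold a w-map into an atrophy seed.

    ``binary``: the voxel set {u : w(u) <= threshold}.  ``magnitude``: the
    same set with weights ``max(0, -w(u) - |threshold|)`` — atrophy severity
    beyond the threshold.  An empty seed either raises or falls back to the
    ``fallback_k`` most-negative voxels (with a warning), per configuration.
    """
    if not threshold < 0:
        raise ValueError(f"seed threshold must be negative, got {threshold}")
    if weighting not in ("binary", "magnitude"):
        raise ValueError(f"unknown weighting {weighting!r}")
    w = wmap.values
    idx = np.flatnonzero(w <= threshold)
    if idx.size == 0:
        if empty_action == "error":
            raise ValueError(
                f"empty seed: no voxels with w <= {threshold} "
                f"(subject {wmap.subject_id})"
            )
        k = min(int(fallback_k), w.size)
        warnings.warn(
            f"empty seed at threshold {threshold} for subject "
            f"{wmap.subject_id}; falling back to the {k} most-negative voxels",
            stacklevel=2,
        )
        idx = np.sort(np.argsort(w)[:k])
    if weighting == "binary":
        return Seed(indices=idx)
    weights = np.maximum(0.0, -w[idx] - abs(threshold))
    if weights.sum() == 0:
        # fallback voxels may all sit above threshold; weight them uniformly
        weights = np.ones_like(weights)
    return Seed(indices=idx, weights=weights)
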