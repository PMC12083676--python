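"""Spatial map similarity and its label-permutation significance test.

Two network maps are compared by Pearson correlation over in-mask units.
Significance is assessed by shuffling the clinical measure across subjects
(each subject's measure is reassigned to a different subject's imaging —
covariates stay attached to their maps), regenerating the unthresholded
t-map, and recomputing the spatial correlation with the reference map; the
one-sided p is the chance of a null correlation at least as large as the
observed one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core_io import SubjectMap
from .perm_inference import Design, _stack_maps, batched_predictor_tstats, fit_glm_map

DEFAULT_N_PERM = 1000


def spatial_corr(
    map_a: SubjectMap | np.ndarray,
    map_b: SubjectMap | np.ndarray,
    mask: np.ndarray | None = None,
) -> float:
    """Pearson correlation between two maps over (optionally masked) units."""
    a = map_a.values if isinstance(map_a, SubjectMap) else np.asarray(map_a, float)
    b = map_b.values if isinstance(map_b, SubjectMap) else np.asarray(map_b, float)
    if a.shape != b.shape:
        raise ValueError(f"maps have different sizes: {a.shape} vs {b.shape}")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        a, b = a[mask], b[mask]
    if a.size < 3:
        raise ValueError("need at least 3 in-mask units")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("a map is constant on the mask; correlation undefined")
    a = a - a.mean()
    b = b - b.mean()
    return float((a @ b) / np.sqrt((a @ a) * (b @ b)))


@dataclass
class SimilarityResult:
    observed_r: float
    null_r: np.ndarray
    p: float
    n_perm: int
    mask_size: int

    def __post_init__(self) -> None:
        assert -1.0 <= self.observed_r <= 1.0


def similarity_permutation_test(
    maps: Sequence[SubjectMap] | np.ndarray,
    measure: np.ndarray,
    covariates: np.ndarray | None,
    reference_map: SubjectMap | np.ndarray,
    n_perm: int = DEFAULT_N_PERM,
    rng_seed: int = 0,
    mask: np.ndarray | None = None,
) -> SimilarityResult:
    """Label-permutation test of network-map similarity to a reference map.

    The observed statistic is the spatial correlation between the
    unthresholded t-map (regression of per-subject connectivity maps on the
    measure, adjusting for covariates) and ``reference_map``.  Each
    permutation shuffles the measure across subjects and rebuilds the t-map.
    p is one-sided (greater), with the (1+b)/(1+m) convention.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    Y = _stack_maps(maps)
    measure = np.asarray(measure, dtype=float)
    design = Design(predictor=measure, covariates=covariates)
    keep = design.complete_rows()
    Y = Y[keep]
    measure = measure[keep]
    cov = covariates[keep] if covariates is not None else None
    ref = (reference_map.values if isinstance(reference_map, SubjectMap)
           else np.asarray(reference_map, float))
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)

    t_obs = fit_glm_map(Y, Design(predictor=measure, covariates=cov)).t
    observed = spatial_corr(t_obs, ref, mask=mask)

    rng = np.random.default_rng(rng_seed)
    n = measure.shape[0]
    perms = np.stack([rng.permutation(n) for _ in range(n_perm)], axis=1)
    t_null = batched_predictor_tstats(Y, cov, measure[perms])  # (n_perm, V)
    refm = ref if mask is None else ref[mask]
    tm = t_null if mask is None else t_null[:, mask]
    tc = tm - tm.mean(axis=1, keepdims=True)
    rc = refm - refm.mean()
    with np.errstate(invalid="ignore", divide="ignore"):
        null_r = (tc @ rc) / np.sqrt(np.sum(tc * tc, axis=1) * (rc @ rc))
    null_r = np.nan_to_num(null_r, nan=0.0)
    p = (1.0 + np.sum(null_r >= observed)) / (1.0 + n_perm)
    return SimilarityResult(observed_r=observed, null_r=null_r, p=float(p),
                            n_perm=n_perm,
                            mask_size=int(refm.size))
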