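"""Mass-univariate GLM with permutation max-statistic FWE correction.

Per spatial unit, the map value is regressed on a predictor of interest
(binary group or a continuous score) plus nuisance covariates (age, sex,
education) and an intercept; the unit's statistic is the predictor's t.
Family-wise error is controlled by referencing each unit's statistic to the
permutation distribution of the maximum statistic over all units.

Two permutation schemes are provided:

* ``freedman_lane`` (default): permute the residuals of the reduced
  nuisance-only model, add back the nuisance fit, refit the full model —
  the covariate-respecting scheme used by PALM-style tools;
* ``manly``: permute the predictor against the (map, covariate) rows.

Both schemes act through a single drawn permutation per iteration, applied
so that they coincide exactly when the nuisance matrix is intercept-only.
When the total number of permutations (n!) is at or below a configured cap,
exhaustive enumeration over all relabelings (identity included) replaces
sampling and p-values become exact: p = b/m.  In sampled mode the valid
convention p = (1+b)/(1+m) is used, so p is never zero.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .core_io import SubjectMap

Sidedness = Literal["two", "greater", "less"]
Scheme = Literal["freedman_lane", "manly"]

DEFAULT_N_PERM = 5000
DEFAULT_EXHAUSTIVE_CAP = 10_000


# ---------------------------------------------------------------------------
# Design
# ---------------------------------------------------------------------------


@dataclass
class Design:
    """Predictor of interest plus nuisance covariates, aligned to maps.

    Rows with any missing value are dropped listwise (the dropped indices
    are recorded on ``dropped``); the surviving design must be full rank
    with a non-constant predictor.
    """

    predictor: np.ndarray
    covariates: np.ndarray | None = None
    subject_ids: Sequence[str] | None = None
    dropped: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        self.predictor = np.asarray(self.predictor, dtype=float)
        if self.predictor.ndim != 1:
            raise ValueError("predictor must be 1-D")
        if self.covariates is not None:
            self.covariates = np.asarray(self.covariates, dtype=float)
            if self.covariates.ndim != 2 or \
                    self.covariates.shape[0] != self.predictor.shape[0]:
                raise ValueError("covariates must be (n_subjects, q)")

    @property
    def n(self) -> int:
        return self.predictor.shape[0]

    def complete_rows(self) -> np.ndarray:
        keep = np.isfinite(self.predictor)
        if self.covariates is not None:
            keep &= np.all(np.isfinite(self.covariates), axis=1)
        return keep

    def matrix(self) -> np.ndarray:
        """Full design [predictor | covariates | intercept]; predictor first."""
        cols = [self.predictor[:, None]]
        if self.covariates is not None and self.covariates.shape[1]:
            cols.append(self.covariates)
        cols.append(np.ones((self.n, 1)))
        return np.concatenate(cols, axis=1)


def _stack_maps(maps: Sequence[SubjectMap] | np.ndarray) -> np.ndarray:
    if isinstance(maps, np.ndarray):
        Y = np.asarray(maps, dtype=float)
        if Y.ndim != 2:
            raise ValueError("map array must be (n_subjects, n_units)")
        return Y
    return np.stack([m.values for m in maps]).astype(float)


# ---------------------------------------------------------------------------
# Core t computation (shared design across units)
# ---------------------------------------------------------------------------


def _tstats(Y: np.ndarray, X: np.ndarray, col: int = 0) -> np.ndarray:
    """t statistic of X[:, col] for each column of Y under OLS."""
    n, p = X.shape
    G = X.T @ X
    try:
        Ginv = np.linalg.inv(G)
    except np.linalg.LinAlgError as exc:
        raise ValueError("rank-deficient design matrix") from exc
    XtY = X.T @ Y
    B = Ginv @ XtY
    rss = np.sum(Y * Y, axis=0) - np.sum(XtY * B, axis=0)
    rss = np.maximum(rss, 0.0)
    dof = n - p
    if dof <= 0:
        raise ValueError(f"no residual degrees of freedom (n={n}, p={p})")
    sigma2 = rss / dof
    denom = np.sqrt(sigma2 * Ginv[col, col])
    with np.errstate(invalid="ignore", divide="ignore"):
        t = B[col] / denom
    t = np.where(denom == 0, np.sign(B[col]) * np.inf, t)
    return t


def batched_predictor_tstats(
    Y: np.ndarray, covariates: np.ndarray | None, predictors: np.ndarray
) -> np.ndarray:
    """t-maps for many candidate predictors sharing one nuisance set.

    ``predictors`` is (n, m); returns (m, n_units).  Uses the
    Frisch-Waugh-Lovell partial-correlation identity, numerically identical
    to refitting the full design for each predictor — the fast path for
    label permutations (checked against :func:`fit_glm_map` in the tests).
    """
    Y = np.asarray(Y, dtype=float)
    n = Y.shape[0]
    Z = np.ones((n, 1)) if covariates is None or covariates.size == 0 \
        else np.column_stack([covariates, np.ones(n)])
    Q, _ = np.linalg.qr(Z)
    Yr = Y - Q @ (Q.T @ Y)
    Pr = predictors - Q @ (Q.T @ predictors)
    ynorm = np.sqrt(np.sum(Yr * Yr, axis=0))
    pnorm = np.sqrt(np.sum(Pr * Pr, axis=0))
    if np.any(pnorm == 0):
        raise ValueError("a permuted predictor is collinear with the covariates")
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Pr.T @ Yr) / np.outer(pnorm, ynorm)
    r = np.where(ynorm[None, :] == 0, 0.0, np.clip(r, -1.0, 1.0))
    dof = n - Z.shape[1] - 1
    if dof <= 0:
        raise ValueError("no residual degrees of freedom")
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt(dof / (1.0 - r**2))
    t = np.where(np.abs(r) >= 1.0, np.sign(r) * np.inf, t)
    return t


# ---------------------------------------------------------------------------
# fit_glm_map
# ---------------------------------------------------------------------------


@dataclass
class GLMResult:
    t: np.ndarray
    n_used: int
    dof: int
    kept: np.ndarray            # boolean row filter after listwise deletion


def fit_glm_map(maps: Sequence[SubjectMap] | np.ndarray, design: Design
                ) -> GLMResult:
    """Per-unit t statistic of the predictor, covariate-adjusted OLS."""
    Y = _stack_maps(maps)
    if Y.shape[0] != design.n:
        raise ValueError("maps and design have different subject counts")
    keep = design.complete_rows()
    Y = Y[keep]
    X = design.matrix()[keep]
    n, p = X.shape
    if n < p + 2:
        raise ValueError(f"need at least {p + 2} complete subjects, got {n}")
    if np.ptp(X[:, 0]) == 0:
        raise ValueError("predictor is constant after listwise deletion")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("rank-deficient design (predictor collinear with "
                         "covariates?)")
    t = _tstats(Y, X, col=0)
    return GLMResult(t=t, n_used=n, dof=n - p, kept=keep)


# ---------------------------------------------------------------------------
# maxt_correct
# ---------------------------------------------------------------------------


@dataclass
class StatMap:
    """Observed t map with permutation p-values (uncorrected and max-t FWE)."""

    t: np.ndarray
    p_uncorrected: np.ndarray
    p_fwe: np.ndarray
    n_perm: int
    sidedness: Sidedness
    scheme: Scheme
    exhaustive: bool
    n_used: int

    def significant(self, alpha: float = 0.05) -> np.ndarray:
        return self.p_fwe <= alpha


def _signed(t: np.ndarray, sidedness: Sidedness) -> np.ndarray:
    if sidedness == "two":
        return np.abs(t)
    if sidedness == "greater":
        return t
    if sidedness == "less":
        return -t
    raise ValueError(f"unknown sidedness {sidedness!r}")


def maxt_correct(
    maps: Sequence[SubjectMap] | np.ndarray,
    design: Design,
    n_perm: int = DEFAULT_N_PERM,
    scheme: Scheme = "freedman_lane",
    sidedness: Sidedness = "two",
    rng_seed: int = 0,
    exhaustive_cap: int = DEFAULT_EXHAUSTIVE_CAP,
    blocks: np.ndarray | None = None,
) -> StatMap:
    """Permutation max-t family-wise-error-corrected statistical map.

    ``p_fwe(u)`` references unit u's statistic to the permutation
    distribution of the maximum statistic over units; ``p_uncorrected(u)``
    uses the unit's own permutation distribution.  Exhaustive enumeration of
    all n! relabelings replaces sampling when n! <= ``exhaustive_cap``.
    """
    if blocks is not None:
        raise NotImplementedError(
            "exchangeability-block permutation is not supported"
        )
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if n_perm < 20:
        warnings.warn(
            f"n_perm={n_perm}: the smallest attainable p is "
            f"{1.0 / (n_perm + 1):.3f}", stacklevel=2,
        )
    if scheme not in ("freedman_lane", "manly"):
        raise ValueError(f"unknown scheme {scheme!r}")

    Y = _stack_maps(maps)
    keep = Design.complete_rows(design)
    Y = Y[keep]
    X = design.matrix()[keep]
    n, p = X.shape
    if n < p + 2:
        raise ValueError(f"need at least {p + 2} complete subjects, got {n}")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("rank-deficient design")

    t_obs = _tstats(Y, X, col=0)
    stat_obs = _signed(t_obs, sidedness)

    exhaustive = math.factorial(n) <= exhaustive_cap
    if exhaustive:
        perm_iter = itertools.permutations(range(n))
        m = math.factorial(n)
    else:
        rng = np.random.default_rng(rng_seed)
        perm_iter = (rng.permutation(n) for _ in range(n_perm))
        m = n_perm

    # reduced (nuisance-only) fit for Freedman-Lane
    Z = X[:, 1:]
    Qz, _ = np.linalg.qr(Z)
    fitted = Qz @ (Qz.T @ Y)
    resid = Y - fitted
    pred = X[:, 0]

    n_units = Y.shape[1]
    count_unit = np.zeros(n_units)
    count_max = np.zeros(n_units)
    # ">=" with a tie tolerance: recomputing the identity permutation leaves
    # O(eps) float residue, which must still count as "as extreme as observed"
    thresh = stat_obs - 1e-8 * (1.0 + np.abs(stat_obs))
    for perm in perm_iter:
        perm = np.asarray(perm, dtype=np.intp)
        if scheme == "freedman_lane":
            Ystar = fitted + resid[perm]
            t_perm = _tstats(Ystar, X, col=0)
        else:
            # inverse permutation of the predictor: pairs (x_{pi^-1(i)}, y_i)
            # match Freedman-Lane's (x_i, y_{pi(i)}) pairing exactly when the
            # nuisance matrix is intercept-only
            Xp = X.copy()
            Xp[np.asarray(perm), 0] = pred
            t_perm = _tstats(Y, Xp, col=0)
        stat_perm = _signed(t_perm, sidedness)
        count_unit += stat_perm >= thresh
        count_max += stat_perm.max() >= thresh

    if exhaustive:
        p_unc = count_unit / m
        p_fwe = count_max / m
    else:
        p_unc = (1.0 + count_unit) / (1.0 + m)
        p_fwe = (1.0 + count_max) / (1.0 + m)
    return StatMap(t=t_obs, p_uncorrected=p_unc, p_fwe=p_fwe, n_perm=m,
                   sidedness=sidedness, scheme=scheme, exhaustive=exhaustive,
                   n_used=n)
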