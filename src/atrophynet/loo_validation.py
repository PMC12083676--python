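"""Leave-one-out validation of the atrophy network map.

For each subject, the network map (unthresholded t-map of connectivity
regressed on SUVr, adjusting for age, sex and education) is rebuilt from
every *other* subject; the held-out subject's own connectivity map is then
compared to that leave-one-out map by spatial correlation.  The resulting
per-subject similarity score is associated with amyloid status, SUVr, and
the clinical/cognitive measures.

Two LOO engines are provided: ``naive`` refits the GLM from scratch per
subject; ``downdate`` removes each subject's rank-one contribution from the
cross-product matrices (X'X, X'Y, Y'Y) and is algebraically identical —
the naive refit is the correctness oracle for the downdating algebra.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import PhenotypeTable, SubjectMap
from .map_similarity import spatial_corr
from .perm_inference import Design, _stack_maps, _tstats, fit_glm_map

#: Outcome -> analysis kind for the standard validation suite.
DEFAULT_OUTCOMES: tuple[tuple[str, str], ...] = (
    ("abeta_status", "binary"),
    ("suvr", "continuous"),
    ("pacc", "continuous"),
    ("digit_symbol", "continuous"),
    ("fcsrt", "continuous"),
    ("mmse", "continuous"),
    ("logical_memory", "continuous"),
    ("cfi_total", "continuous"),
    ("cfi_pt", "continuous"),
    ("cfi_sp", "continuous"),
    ("gds", "continuous"),
    ("ftps", "continuous"),
    ("suicide_attempt", "binary"),
    ("death_wish", "binary"),
)


@dataclass
class LooScores:
    """Per-subject spatial r to the leave-one-out network map."""

    r: np.ndarray                       # (n,), NaN where LOO map was degenerate
    predictor: np.ndarray               # the map-generating predictor (suvr)
    subject_ids: list[str] | None = None
    mode: str = "downdate"
    n_missing: int = 0


def loo_network_scores(
    maps: Sequence[SubjectMap] | np.ndarray,
    suvr: np.ndarray,
    covariates: np.ndarray | None,
    mode: Literal["naive", "downdate"] = "downdate",
    subject_ids: Sequence[str] | None = None,
) -> LooScores:
    """Spatial correlation of each subject's map with their LOO network map."""
    if mode not in ("naive", "downdate"):
        raise ValueError(f"unknown mode {mode!r}")
    Y = _stack_maps(maps)
    suvr = np.asarray(suvr, dtype=float)
    design = Design(predictor=suvr, covariates=covariates)
    keep = design.complete_rows()
    n_all = Y.shape[0]
    X = design.matrix()
    p = X.shape[1]
    if keep.sum() < p + 3:
        raise ValueError(f"need at least {p + 3} complete subjects")
    kidx = np.flatnonzero(keep)
    Yk, Xk = Y[keep], X[keep]
    nk = Yk.shape[0]
    scale = max(1.0, float(np.abs(Yk).max()))
    if np.all(Yk.std(axis=0) <= 1e-12 * scale):
        warnings.warn("all connectivity maps are identical across subjects")
        raise RuntimeError(
            "every leave-one-out network map is degenerate: the connectivity "
            "maps are identical across subjects, so the t-map is undefined"
        )

    r = np.full(n_all, np.nan)
    if mode == "downdate":
        G = Xk.T @ Xk
        A = Xk.T @ Yk
        S = np.sum(Yk * Yk, axis=0)
        for j, i in enumerate(kidx):
            x = Xk[j]
            y = Yk[j]
            Gi = G - np.outer(x, x)
            Ai = A - np.outer(x, y)
            Si = S - y * y
            try:
                Gi_inv = np.linalg.inv(Gi)
            except np.linalg.LinAlgError:
                warnings.warn(f"degenerate design after removing subject {i}")
                continue
            Bi = Gi_inv @ Ai
            rss = np.maximum(Si - np.sum(Ai * Bi, axis=0), 0.0)
            dof = nk - 1 - p
            if dof <= 0:
                raise ValueError("insufficient subjects for leave-one-out")
            with np.errstate(invalid="ignore", divide="ignore"):
                t_map = Bi[0] / np.sqrt(rss / dof * Gi_inv[0, 0])
            t_map = np.nan_to_num(t_map, nan=0.0, posinf=0.0, neginf=0.0)
            r[i] = _safe_corr(Yk[j], t_map, subject=i)
    else:
        sel = np.ones(nk, dtype=bool)
        for j, i in enumerate(kidx):
            sel[j] = False
            try:
                t_map = _tstats(Yk[sel], Xk[sel], col=0)
            except (ValueError, np.linalg.LinAlgError):
                warnings.warn(f"degenerate design after removing subject {i}")
                sel[j] = True
                continue
            t_map = np.nan_to_num(t_map, nan=0.0, posinf=0.0, neginf=0.0)
            r[i] = _safe_corr(Yk[j], t_map, subject=i)
            sel[j] = True

    n_missing = int(np.sum(~np.isfinite(r[kidx])))
    if np.all(~np.isfinite(r)):
        raise RuntimeError(
            "every leave-one-out network map was degenerate (constant t-map); "
            "are all connectivity maps identical?"
        )
    return LooScores(r=r, predictor=suvr,
                     subject_ids=list(subject_ids) if subject_ids else None,
                     mode=mode, n_missing=n_missing)


def _safe_corr(a: np.ndarray, b: np.ndarray, subject: int) -> float:
    try:
        return spatial_corr(a, b)
    except ValueError:
        warnings.warn(f"constant leave-one-out map for subject {subject}; "
                      "r recorded as missing")
        return float("nan")


# ---------------------------------------------------------------------------
# Associations
# ---------------------------------------------------------------------------


@dataclass
class AssociationRecord:
    outcome: str
    kind: str                  # "binary" | "continuous"
    statistic_type: str        # "t" | "pearson_r"
    statistic: float
    p: float
    n: int
    extra: dict = field(default_factory=dict)


def associate(
    scores: LooScores,
    outcome: np.ndarray,
    kind: Literal["binary", "continuous"],
    name: str = "outcome",
) -> AssociationRecord:
    """Associate LOO similarity scores with one outcome.

    Binary outcomes use Welch's two-sample t-test of r between groups;
    continuous outcomes use the Pearson correlation of r with the outcome
    (t-distributed p).  Rows with a missing score or outcome are dropped.
    """
    r = np.asarray(scores.r, dtype=float)
    out = np.asarray(outcome)
    if out.dtype == object or out.dtype.kind in "USb":
        ser = pd.Series(out)
        levels = sorted(ser.dropna().unique().tolist())
        if kind == "binary" and len(levels) == 2:
            # 'positive' codes as 1 against 'negative'; otherwise the
            # lexicographically larger level is the reference group 1
            one = "positive" if set(levels) == {"positive", "negative"} \
                else levels[1]
            out = (ser == one).astype(float).where(ser.notna()).to_numpy(float)
        else:
            out = pd.to_numeric(ser, errors="coerce").to_numpy(float)
    else:
        out = out.astype(float)
    keep = np.isfinite(r) & np.isfinite(out)
    r, out = r[keep], out[keep]
    if r.size < 3:
        raise ValueError(f"{name}: fewer than 3 complete pairs")
    if np.ptp(out) == 0:
        raise ValueError(f"{name}: outcome is constant")
    if kind == "binary":
        levels = np.unique(out)
        if levels.size != 2:
            raise ValueError(f"{name}: binary outcome has {levels.size} levels")
        g1, g0 = r[out == levels.max()], r[out == levels.min()]
        stat, p = stats.ttest_ind(g1, g0, equal_var=False)
        rec = AssociationRecord(outcome=name, kind=kind, statistic_type="t",
                                statistic=float(stat), p=float(p), n=int(r.size))
        # also report the regression-style effect (r of score on 0/1 coding)
        rr, rp = stats.pearsonr(r, out)
        rec.extra = {"pearson_r": float(rr), "pearson_p": float(rp)}
        return rec
    stat, p = stats.pearsonr(r, out)
    return AssociationRecord(outcome=name, kind=kind, statistic_type="pearson_r",
                             statistic=float(stat), p=float(p), n=int(r.size))


def run_validation_suite(
    scores: LooScores,
    phenotypes: PhenotypeTable,
    outcomes: Sequence[tuple[str, str]] = DEFAULT_OUTCOMES,
    on_degenerate: Literal["raise", "record"] = "raise",
) -> pd.DataFrame:
    """Associate the LOO scores with the standard outcome list.

    Returns one row per outcome (statistic, raw p, n used) plus a Bonferroni
    column across the family; raw p-values are the primary output.  With
    ``on_degenerate="record"`` a constant outcome (possible for rare binary
    histories in small cohorts) yields a NaN row instead of aborting.
    """
    records = []
    for name, kind in outcomes:
        values = phenotypes.column(name)   # raises with available columns
        try:
            rec = associate(scores, values, kind, name=name)
        except ValueError as exc:
            if on_degenerate == "record" and "constant" in str(exc):
                warnings.warn(f"outcome {name!r} is constant; recorded as NaN")
                rec = AssociationRecord(outcome=name, kind=kind,
                                        statistic_type="t" if kind == "binary"
                                        else "pearson_r",
                                        statistic=float("nan"), p=float("nan"),
                                        n=0)
            else:
                raise
        records.append(rec)
    m = len(records)
    df = pd.DataFrame([{
        "outcome": rec.outcome,
        "kind": rec.kind,
        "statistic_type": rec.statistic_type,
        "statistic": rec.statistic,
        "p": rec.p,
        "p_bonferroni": min(1.0, rec.p * m),
        "n": rec.n,
        **{f"extra_{k}": v for k, v in rec.extra.items()},
    } for rec in records])
    return df
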