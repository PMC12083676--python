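"""Clinical score construction and amyloid classification.

Implements the study's dual quantitative/qualitative amyloid-status rule
(global florbetapir SUVr with a visual-read tiebreak in the 1.10-1.15 band),
the PACC composite (mean z of four cognitive tests), global cortical
thickness, and the hippocampal occupancy score with optional age/sex
normalization via a control-fitted linear model — the same residual
standardization machinery the w-score pipeline uses.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import MapKind, PhenotypeTable, SubjectMap

SUVR_POSITIVE_THRESHOLD = 1.15
SUVR_VISUAL_BAND_LOW = 1.10


class AbetaBasis(str, enum.Enum):
    suvr_primary = "suvr_primary"
    visual_confirmed = "visual_confirmed"
    below_band = "below_band"


@dataclass(frozen=True)
class AbetaDecision:
    status: str            # "positive" | "negative"
    basis: AbetaBasis


def classify_abeta(suvr: float, visual_read: bool | None = None) -> AbetaDecision:
    """Dual-algorithm amyloid classification.

    SUVr >= 1.15 is the primary positivity criterion; 1.10 <= SUVr < 1.15 is
    positive only if the visual read confirms; below 1.10 is negative.  A
    missing visual read inside the band is an error — the rule cannot be
    evaluated without it.
    """
    if not suvr > 0:
        raise ValueError(f"suvr must be > 0, got {suvr}")
    if suvr >= SUVR_POSITIVE_THRESHOLD:
        return AbetaDecision("positive", AbetaBasis.suvr_primary)
    if suvr >= SUVR_VISUAL_BAND_LOW:
        if visual_read is None or (isinstance(visual_read, float) and math.isnan(visual_read)):
            raise ValueError(
                f"suvr={suvr} lies in the {SUVR_VISUAL_BAND_LOW}-"
                f"{SUVR_POSITIVE_THRESHOLD} band: a visual read is required"
            )
        status = "positive" if bool(visual_read) else "negative"
        return AbetaDecision(status, AbetaBasis.visual_confirmed)
    return AbetaDecision("negative", AbetaBasis.below_band)


def classify_abeta_table(table: PhenotypeTable) -> np.ndarray:
    """Vector of 'positive'/'negative' for every row of a phenotype table."""
    suvr = table.column("suvr")
    visual = table.df["visual_read"] if "visual_read" in table.df.columns else None
    out = []
    for i, s in enumerate(suvr):
        v = None if visual is None or pd.isna(visual.iloc[i]) else bool(visual.iloc[i])
        out.append(classify_abeta(float(s), v).status)
    return np.array(out)


def compute_pacc(z_scores: Sequence[float], allow_missing: bool = False) -> float:
    """PACC composite: arithmetic mean of the four component z-scores.

    Components (Logical Memory Delayed Recall, MMSE, Digit Symbol, FCSRT)
    are expected already standardized against the reference (Aβ−) cohort.
    With ``allow_missing`` the mean runs over the available components; all
    four missing, or any missing without ``allow_missing``, yields NaN.
    """
    z = np.asarray([np.nan if v is None else float(v) for v in z_scores], dtype=float)
    if z.shape != (4,):
        raise ValueError("compute_pacc expects exactly four component scores")
    present = np.isfinite(z)
    if not present.any():
        return float("nan")
    if not allow_missing and not present.all():
        return float("nan")
    return float(z[present].mean())


def standardize_pacc_components(
    components: np.ndarray,
    reference: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """z-score the four PACC components and form the composite.

    ``components`` is (n, 4) raw scores (Logical Memory, MMSE, Digit Symbol,
    FCSRT); ``reference`` is a boolean row mask selecting the normative
    group (the Aβ− controls by convention here; all rows if None).  Returns
    ``(z, pacc)`` where z is (n, 4) and pacc the row mean of available
    components.
    """
    X = np.asarray(components, dtype=float)
    if X.ndim != 2 or X.shape[1] != 4:
        raise ValueError("components must be (n, 4)")
    ref = X if reference is None else X[np.asarray(reference, bool)]
    mu = np.nanmean(ref, axis=0)
    sd = np.nanstd(ref, axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("a reference component has zero variance")
    z = (X - mu) / sd
    with np.errstate(invalid="ignore"):
        pacc = np.nanmean(z, axis=1)
    return z, pacc


def global_thickness(thickness: SubjectMap) -> float:
    """Unweighted mean cortical thickness (mm) over in-mask units."""
    if thickness.kind is not MapKind.thickness_mm:
        raise ValueError(f"expected a thickness map, got kind={thickness.kind.value}")
    return float(np.mean(thickness.values))


@dataclass
class NormativeScalarModel:
    """Age+sex linear norm for a scalar phenotype, fitted on controls.

    Mirrors the per-voxel normative GLM: OLS of the score on (1, age, sex),
    residual SD with denominator n - p.  ``standardize`` returns the w-score
    of a new observation.
    """

    coefficients: np.ndarray   # (3,) intercept, age, sex
    residual_sd: float
    n_controls: int

    @classmethod
    def fit(cls, scores: np.ndarray, age: np.ndarray, sex: np.ndarray
            ) -> "NormativeScalarModel":
        scores = np.asarray(scores, float)
        X = np.column_stack([np.ones_like(scores), np.asarray(age, float),
                             np.asarray(sex, float)])
        n, p = X.shape
        if n <= p:
            raise ValueError(f"need more than {p} controls, got {n}")
        if np.linalg.matrix_rank(X) < p:
            raise ValueError("rank-deficient design (constant age or sex?)")
        beta, *_ = np.linalg.lstsq(X, scores, rcond=None)
        resid = scores - X @ beta
        sd = float(np.sqrt(np.sum(resid**2) / (n - p)))
        return cls(coefficients=beta, residual_sd=sd, n_controls=n)

    def standardize(self, score: float, age: float, sex: float) -> float:
        pred = float(self.coefficients @ np.array([1.0, age, sex]))
        if self.residual_sd == 0:
            if score == pred:
                return 0.0
            raise ZeroDivisionError("degenerate norm: residual SD is zero")
        return (score - pred) / self.residual_sd


def hippocampal_occupancy(
    hip_l: float, ilv_l: float, hip_r: float, ilv_r: float,
    age: float | None = None, sex: float | None = None,
    norm: NormativeScalarModel | None = None,
) -> float:
    """Hippocampal occupancy: hip/(hip + inferior-lateral-ventricle), averaged
    over hemispheres; optionally returned as an age/sex-normalized w-score.
    """
    vols = (hip_l, ilv_l, hip_r, ilv_r)
    if any(not v > 0 for v in vols):
        raise ValueError(f"all volumes must be > 0, got {vols}")
    raw = 0.5 * (hip_l / (hip_l + ilv_l) + hip_r / (hip_r + ilv_r))
    if norm is None:
        return raw
    if age is None or sex is None:
        raise ValueError("age and sex are required for normalized occupancy")
    return norm.standardize(raw, age, sex)


def enrich_phenotypes(table: PhenotypeTable) -> PhenotypeTable:
    """Add derived columns: abeta_status, hoc (raw occupancy), cfi_total.

    PACC is left untouched if present (its component z-standardization is a
    cohort-level choice made upstream).
    """
    df = table.df.copy()
    df["abeta_status"] = classify_abeta_table(table)
    if {"hip_l", "ilv_l", "hip_r", "ilv_r"} <= set(df.columns):
        df["hoc"] = [
            hippocampal_occupancy(r.hip_l, r.ilv_l, r.hip_r, r.ilv_r)
            if np.isfinite([r.hip_l, r.ilv_l, r.hip_r, r.ilv_r]).all() else np.nan
            for r in df.itertuples()
        ]
    if "cfi_total" not in df.columns and {"cfi_pt", "cfi_sp"} <= set(df.columns):
        df["cfi_total"] = df["cfi_pt"] + df["cfi_sp"]
    return PhenotypeTable(df=df)
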