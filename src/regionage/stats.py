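"""Group inference on brain-age gaps.

Region-by-region ANCOVA compares the gap between patients and controls
with chronological age, sex, MMSE and years of education as covariates;
the group F statistic comes from the extra sum of squares of dropping the
group term, and partial eta-squared = SS_group / (SS_group + SS_error) is
the effect size. P values across regions are corrected with the
Benjamini-Hochberg FDR procedure. Within the patient group, region gaps
are regressed on clinical variables (PANSS subscales, illness duration,
onset, nicotine, BMI; and separately antipsychotic dose) controlling for
age and sex, with standardized coefficients.

Model fits go through statsmodels OLS; the F / partial eta-squared
arithmetic is done here from the two model residual sums of squares.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "GroupTestResult", "RegressionResult",
    "ancova_gap", "fdr_adjust", "clinical_regression", "cpz_regression",
    "DEFAULT_ANCOVA_COVARIATES", "DEFAULT_CLINICAL_PREDICTORS",
]

logger = logging.getLogger(__name__)

DEFAULT_ANCOVA_COVARIATES = ("chronological_age", "sex", "mmse", "education")
DEFAULT_CLINICAL_PREDICTORS = (
    "panss_positive", "panss_negative", "panss_general",
    "illness_duration", "age_of_onset", "nicotine_use", "bmi",
)
_BINARY_COLUMNS = {"sex", "nicotine_use", "group"}


@dataclass
class GroupTestResult:
    modality: str
    region_id: int
    f_stat: float
    p_value: float
    partial_eta_sq: float
    group_means: tuple[float, float]     # (HC mean gap, SCZ mean gap), years
    n_per_group: tuple[int, int]
    p_adjusted: float | None = None

    def __post_init__(self):
        if not 0.0 <= self.partial_eta_sq <= 1.0:
            raise ValueError("partial eta-squared must lie in [0, 1]")
        if self.f_stat < 0:
            raise ValueError("F statistic must be non-negative")


@dataclass
class RegressionResult:
    modality: str
    region_id: int
    predictor: str
    beta: float          # standardized coefficient
    t_stat: float
    p_value: float
    n: int
    p_adjusted: float | None = None


def _encode(col: pd.Series, name: str) -> np.ndarray:
    """Numeric design column: binary categoricals -> 0/1, rest as float."""
    if name == "sex":
        vals = col.map({"M": 1.0, "F": 0.0, 1: 1.0, 0: 0.0, True: 1.0, False: 0.0})
        if vals.isna().any():
            raise ValueError("sex column must contain only M/F (or 0/1)")
        return vals.to_numpy(dtype=float)
    if name == "group":
        return (col == "SCZ").to_numpy(dtype=float)
    return col.astype(float).to_numpy()


def _check_full_rank(X: np.ndarray, names: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify columns whose removal restores full rank
        bad = [nm for j, nm in enumerate(names)
               if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank]
        raise ValueError(f"singular design matrix; collinear columns: {bad or names}")


def ancova_gap(
    gaps: np.ndarray,
    subjects: pd.DataFrame,
    covariates: Sequence[str] = DEFAULT_ANCOVA_COVARIATES,
    *,
    modality: str = "GM",
    region_id: int = 0,
) -> GroupTestResult:
    """ANCOVA for the group effect on one region's brain-age gaps.

    Fits gap ~ group + covariates by OLS; the group F statistic is the
    extra-sum-of-squares test of the full model against the group-dropped
    model on (1, n - p - 2) degrees of freedom, and
    partial eta^2 = SS_group / (SS_group + SS_error).
    """
    gaps = np.asarray(gaps, dtype=float)
    if gaps.shape[0] != len(subjects):
        raise ValueError("gaps and subjects must align")
    groups = subjects["group"]
    n_hc = int((groups == "HC").sum())
    n_scz = int((groups == "SCZ").sum())
    p = len(covariates)
    if min(n_hc, n_scz) == 0 or len(subjects) < p + 3:
        raise ValueError("need both groups and n >= number of covariates + 3")

    cols = {"group": _encode(groups, "group")}
    for c in covariates:
        cols[c] = _encode(subjects[c], c)
    names = ["const", "group"] + list(covariates)
    X_full = np.column_stack([np.ones(len(subjects))] + list(cols.values()))
    _check_full_rank(X_full, names)
    X_red = np.delete(X_full, 1, axis=1)

    full = sm.OLS(gaps, X_full).fit()
    reduced = sm.OLS(gaps, X_red).fit()
    ss_group = float(reduced.ssr - full.ssr)
    ss_error = float(full.ssr)
    df_resid = int(full.df_resid)
    if ss_error <= 0:
        f = 0.0 if ss_group <= 0 else np.inf
        pval = 1.0 if ss_group <= 0 else 0.0
        eta = 0.0 if ss_group <= 0 else 1.0
    else:
        f = max(ss_group, 0.0) / (ss_error / df_resid)
        pval = float(sps.f.sf(f, 1, df_resid))
        eta = max(ss_group, 0.0) / (max(ss_group, 0.0) + ss_error)
    g = np.asarray(cols["group"], dtype=bool)
    return GroupTestResult(
        modality=modality, region_id=region_id,
        f_stat=float(f), p_value=pval, partial_eta_sq=float(eta),
        group_means=(float(gaps[~g].mean()), float(gaps[g].mean())),
        n_per_group=(n_hc, n_scz),
    )


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values, in input order.

    Sort ascending, q_(i) = min_{j >= i} p_(j) * m / j capped at 1, then
    undo the sort. Agrees with statsmodels' fdr_bh to float precision
    (cross-checked in the test suite).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or p.min() < 0 or p.max() > 1:
        raise ValueError("p values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    q = p[order] * m / np.arange(1, m + 1)
    q = np.minimum(np.minimum.accumulate(q[::-1])[::-1], 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def _standardized_ols(
    y: np.ndarray,
    design: pd.DataFrame,
    predictors: Sequence[str],
    *,
    modality: str,
    region_id: int,
) -> list[RegressionResult]:
    """Joint OLS of z-scored gap on z-scored continuous terms (binary 0/1),
    returning one RegressionResult per requested predictor."""
    n = len(design)
    zy = (y - y.mean()) / y.std(ddof=0)
    cols, names = [np.ones(n)], ["const"]
    for c in design.columns:
        v = _encode(design[c], c)
        if c not in _BINARY_COLUMNS:
            sd = v.std(ddof=0)
            if sd == 0:
                raise ValueError(f"predictor {c!r} is constant")
            v = (v - v.mean()) / sd
        cols.append(v)
        names.append(c)
    X = np.column_stack(cols)
    _check_full_rank(X, names)
    fit = sm.OLS(zy, X).fit()
    out = []
    for c in predictors:
        j = names.index(c)
        out.append(RegressionResult(
            modality=modality, region_id=region_id, predictor=c,
            beta=float(fit.params[j]), t_stat=float(fit.tvalues[j]),
            p_value=float(fit.pvalues[j]), n=n))
    return out


def clinical_regression(
    gaps: np.ndarray,
    subjects: pd.DataFrame,
    predictors: Sequence[str] = DEFAULT_CLINICAL_PREDICTORS,
    controls: Sequence[str] = ("chronological_age", "sex"),
    *,
    modality: str = "GM",
    region_id: int = 0,
) -> list[RegressionResult]:
    """One joint model per region: gap ~ clinical predictors + age + sex.

    Patient subjects only; rows missing any predictor are dropped listwise
    (logged). Continuous predictors and the gap are z-scored so betas are
    standardized; binary predictors stay 0/1. FDR across regions is the
    caller's responsibility (p_adjusted is left unset here).
    """
    gaps = np.asarray(gaps, dtype=float)
    scz = subjects["group"] == "SCZ"
    if not scz.all():
        raise ValueError("clinical regression is defined on patient subjects only")
    use = list(predictors) + [c for c in controls if c not in predictors]
    sub = subjects[use].copy()
    keep = sub.notna().all(axis=1).to_numpy()
    dropped = int((~keep).sum())
    if dropped:
        logger.info("clinical_regression: listwise deletion of %d subject(s) with "
                    "missing predictors", dropped)
    y = gaps[keep]
    sub = sub.loc[keep]
    if len(sub) <= len(predictors) + 3:
        raise ValueError(f"too few complete cases ({len(sub)}) for "
                         f"{len(predictors)} predictors")
    return _standardized_ols(y, sub, predictors, modality=modality, region_id=region_id)


def cpz_regression(
    gaps: np.ndarray,
    subjects: pd.DataFrame,
    controls: Sequence[str] = ("chronological_age", "sex"),
    *,
    modality: str = "GM",
    region_id: int = 0,
) -> RegressionResult:
    """gap ~ CPZ-equivalent dose + age + sex among dosed patients.

    Subjects without recorded antipsychotic dose are excluded before
    fitting; at least 10 dosed subjects are required.
    """
    gaps = np.asarray(gaps, dtype=float)
    scz = subjects["group"] == "SCZ"
    if not scz.all():
        raise ValueError("cpz regression is defined on patient subjects only")
    dosed = subjects["cpz_dose"].notna().to_numpy()
    if dosed.sum() < 10:
        raise ValueError(f"need at least 10 subjects with antipsychotic dose, "
                         f"got {int(dosed.sum())}")
    sub = subjects.loc[dosed, ["cpz_dose"] + [c for c in controls]]
    return _standardized_ols(gaps[dosed], sub, ["cpz_dose"],
                             modality=modality, region_id=region_id)[0]
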