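"""Score-based stratification, conditional correlation and survival comparison.

Patients are stratified at an activity score of zero (High: score > 0, Low:
score <= 0, the tie going to Low), singly or as the cross of Tumor and
Environmental activity (four groups).  Group survival is compared with
Kaplan-Meier estimates and the (k-1)-df log-rank test; proportional-hazards
modelling is a thin wrapper over lifelines.  First-order partial Spearman
correlation (ranks, then partial Pearson given the conditioning variable)
quantifies associations after removing a confounder.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .errors import ValidationError
from .io import ClinicalTable

logger = logging.getLogger(__name__)

__all__ = [
    "stratify",
    "four_groups",
    "partial_spearman",
    "km_logrank",
    "LogrankResult",
    "cox_hazards",
]

FOUR_GROUP_LABELS = ("T-Hi/E-Hi", "T-Hi/E-Lo", "T-Lo/E-Hi", "T-Lo/E-Lo")


def stratify(scores: pd.Series, cutoff: float = 0.0) -> pd.Series:
    """Binary High/Low labels at ``cutoff``; a score exactly at the cutoff is Low."""
    scores = pd.Series(scores, dtype=float)
    if not np.isfinite(scores.to_numpy()).all():
        raise ValidationError("scores must be finite")
    return pd.Series(
        np.where(scores.to_numpy() > cutoff, "High", "Low"), index=scores.index, name="label"
    )


def four_groups(t_scores: pd.Series, e_scores: pd.Series, cutoff: float = 0.0) -> pd.Series:
    """Cross of T and E binary stratifications: T-Hi/E-Hi ... T-Lo/E-Lo."""
    t_scores = pd.Series(t_scores, dtype=float)
    e_scores = pd.Series(e_scores, dtype=float)
    if set(t_scores.index) != set(e_scores.index):
        raise ValidationError("T and E score vectors cover different samples")
    e_scores = e_scores.loc[t_scores.index]
    t_lab = np.where(t_scores.to_numpy() > cutoff, "T-Hi", "T-Lo")
    e_lab = np.where(e_scores.to_numpy() > cutoff, "E-Hi", "E-Lo")
    return pd.Series(
        [f"{t}/{e}" for t, e in zip(t_lab, e_lab)], index=t_scores.index, name="label"
    )


def partial_spearman(x, y, z) -> tuple[float, float]:
    """First-order partial Spearman correlation of x and y given z.

    Rank-transforms all three vectors, computes the partial Pearson
    correlation of the x/y ranks given the z ranks, and derives a two-sided p
    from the t approximation with n - 3 degrees of freedom.  Symmetric in
    (x, y).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    n = x.size
    if not (y.size == n and z.size == n):
        raise ValidationError("x, y, z must be aligned vectors of equal length")
    if n < 10:
        raise ValidationError(f"partial Spearman needs n >= 10, got {n}")
    if np.isnan(x).any() or np.isnan(y).any() or np.isnan(z).any():
        raise ValidationError("missing values not allowed")
    for name, v in (("x", x), ("y", y), ("z", z)):
        if np.ptp(v) == 0:
            raise ValidationError(f"{name} is constant; partial correlation undefined")
    rx, ry, rz = (stats.rankdata(v) for v in (x, y, z))
    r_xy = np.corrcoef(rx, ry)[0, 1]
    r_xz = np.corrcoef(rx, rz)[0, 1]
    r_yz = np.corrcoef(ry, rz)[0, 1]
    denom = np.sqrt((1 - r_xz**2) * (1 - r_yz**2))
    if denom == 0:
        raise ValidationError("a variable is a perfect monotone function of z")
    rho = (r_xy - r_xz * r_yz) / denom
    rho = float(np.clip(rho, -1.0, 1.0))
    df = n - 3
    if abs(rho) == 1.0:
        return rho, 0.0
    t = rho * np.sqrt(df / (1 - rho**2))
    p = float(2 * stats.t.sf(abs(t), df))
    return rho, p


@dataclass
class LogrankResult:
    chi2: float
    p_value: float
    dof: int
    curves: dict  # label -> DataFrame(time, survival)
    group_sizes: pd.Series

    def summary(self) -> pd.DataFrame:
        df = self.group_sizes.rename("n").to_frame()
        df.attrs.update({"chi2": self.chi2, "p_value": self.p_value, "dof": self.dof})
        return df


def km_logrank(labels: pd.Series, clinical: ClinicalTable) -> LogrankResult:
    """Kaplan-Meier curves per label plus the (k-1)-df log-rank test.

    Samples missing from either table are dropped; labels with zero samples
    after alignment are dropped with a warning.  Requires >= 2 groups and at
    least one event.
    """
    cl = clinical.clinical
    shared = labels.index.intersection(cl.index)
    dropped = len(labels) - len(shared)
    if dropped:
        logger.warning("km_logrank: %d labelled samples lack clinical data", dropped)
    labels = labels.loc[shared]
    cl = cl.loc[shared]
    counts = labels.value_counts()
    if (counts == 0).any():
        logger.warning("km_logrank: dropping empty groups %s", counts[counts == 0].index.tolist())
        counts = counts[counts > 0]
    if len(counts) < 2:
        raise ValidationError("log-rank needs >= 2 non-empty groups")
    if int(cl["event"].sum()) < 1:
        raise ValidationError("log-rank needs at least one event")
    res = multivariate_logrank_test(cl["time"], labels, cl["event"])
    curves = {}
    for lab in counts.index:
        mask = labels == lab
        kmf = KaplanMeierFitter()
        kmf.fit(cl.loc[mask, "time"], cl.loc[mask, "event"], label=str(lab))
        sf = kmf.survival_function_
        curves[lab] = pd.DataFrame(
            {"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()}
        )
    return LogrankResult(
        chi2=float(res.test_statistic),
        p_value=float(res.p_value),
        dof=len(counts) - 1,
        curves=curves,
        group_sizes=counts.sort_index(),
    )


def cox_hazards(
    clinical: ClinicalTable,
    covariates: pd.DataFrame,
) -> pd.DataFrame:
    """Multivariate Cox proportional-hazards fit (delegated to lifelines).

    ``covariates`` is a sample-indexed frame of numeric regressors (e.g. T and
    E activity, age, stage, gender dummies).  Returns hazard ratios with 95%
    CIs and p-values per covariate.
    """
    cl = clinical.clinical
    shared = covariates.index.intersection(cl.index)
    if len(shared) < covariates.shape[1] + 2:
        raise ValidationError("too few samples for the requested covariates")
    df = covariates.loc[shared].astype(float)
    df["time"] = cl.loc[shared, "time"]
    df["event"] = cl.loc[shared, "event"]
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    summary = cph.summary
    out = pd.DataFrame(
        {
            "hazard_ratio": summary["exp(coef)"],
            "hr_lower_95": summary["exp(coef) lower 95%"],
            "hr_upper_95": summary["exp(coef) upper 95%"],
            "p_value": summary["p"],
        }
    )
    out.index.name = "covariate"
    return out
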