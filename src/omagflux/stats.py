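"""Cohort statistics for perfusion metrics.

Group comparisons across normal / glaucoma-suspect / glaucoma eyes (one-way
ANOVA followed by Bonferroni-adjusted pairwise t-tests), univariate linear
regression of flow metrics against clinical measures, diagnostic AROC with
DeLong standard errors and paired comparisons, two-visit reproducibility as
a coefficient of variation, and mean ocular perfusion pressure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

GROUPS = ("normal", "suspect", "glaucoma")


@dataclass
class SubjectRecord:
    """One eye's metrics and clinical covariates."""

    id: str
    group: str  # normal | suspect | glaucoma (optionally glaucoma:POAG / glaucoma:NTG)
    laterality: str = "OD"
    blood_flux_index: dict = field(default_factory=dict)  # global + quadrants
    vessel_area_density: dict = field(default_factory=dict)
    rnfl_thickness_um: float | None = None
    rim_area_mm2: float | None = None
    cdr: float | None = None
    vf_md_db: float | None = None
    vf_psd_db: float | None = None
    iop_mmhg: float | None = None
    systolic_bp_mmhg: float | None = None
    diastolic_bp_mmhg: float | None = None
    signal_strength: int = 10

    def __post_init__(self) -> None:
        base = self.group.split(":")[0]
        if base not in GROUPS:
            raise ValueError(f"unknown group label {self.group!r}")
        if not 0 <= self.signal_strength <= 10:
            raise ValueError("signal strength must lie in 0..10")

    def to_row(self) -> dict:
        row = {
            "id": self.id,
            "group": self.group.split(":")[0],
            "subtype": self.group,
            "laterality": self.laterality,
            "rnfl_thickness_um": self.rnfl_thickness_um,
            "rim_area_mm2": self.rim_area_mm2,
            "cdr": self.cdr,
            "vf_md_db": self.vf_md_db,
            "vf_psd_db": self.vf_psd_db,
            "iop_mmhg": self.iop_mmhg,
            "systolic_bp_mmhg": self.systolic_bp_mmhg,
            "diastolic_bp_mmhg": self.diastolic_bp_mmhg,
            "signal_strength": self.signal_strength,
        }
        for region, v in self.blood_flux_index.items():
            row[f"flux_{region}"] = v
        for region, v in self.vessel_area_density.items():
            row[f"density_{region}"] = v
        return row


def records_to_frame(records: list[SubjectRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.to_row() for r in records])


def qc_filter(records: pd.DataFrame | list, min_ss: int = 6) -> pd.DataFrame | list:
    """Drop eyes whose signal strength falls below the cutoff (SS < min_ss).

    SS equal to the cutoff is retained.  Removals are logged with a reason.
    """
    if isinstance(records, pd.DataFrame):
        keep = records["signal_strength"] >= min_ss
        for _, row in records[~keep].iterrows():
            logger.info("QC removal: subject %s, SS=%s < %s", row.get("id"), row["signal_strength"], min_ss)
        return records[keep].reset_index(drop=True)
    kept = []
    for rec in records:
        if rec.signal_strength >= min_ss:
            kept.append(rec)
        else:
            logger.info("QC removal: subject %s, SS=%s < %s", rec.id, rec.signal_strength, min_ss)
    return kept


def bonferroni_alpha(n_comparisons: int, overall_alpha: float = 0.05) -> float:
    """Per-comparison significance level keeping the family-wise error rate."""
    if n_comparisons < 1:
        raise ValueError("need at least one comparison")
    return overall_alpha / n_comparisons


def group_compare(
    df: pd.DataFrame,
    metric: str,
    group_col: str = "group",
    overall_alpha: float = 0.05,
    welch: bool = False,
) -> dict:
    """One-way ANOVA across groups plus Bonferroni-adjusted pairwise t-tests.

    Pairwise tests are pooled-variance Student t by default (``welch=True``
    for unequal variances); each is judged at ``overall_alpha / n_pairs``.
    """
    groups = [g for g, sub in df.groupby(group_col) if len(sub)]
    samples = {g: df.loc[df[group_col] == g, metric].dropna().to_numpy() for g in groups}
    for g, x in samples.items():
        if x.size < 2:
            raise ValueError(f"group {g!r} needs >= 2 observations for {metric}")
    if len(samples) < 2:
        raise ValueError("need at least two non-empty groups")
    f_stat, p_anova = sps.f_oneway(*samples.values())
    pairs = list(combinations(sorted(samples), 2))
    alpha_per = bonferroni_alpha(len(pairs), overall_alpha)
    pairwise = {}
    for a, b in pairs:
        t, p = sps.ttest_ind(samples[a], samples[b], equal_var=not welch)
        pairwise[f"{a}_vs_{b}"] = {
            "t": float(t),
            "p": float(p),
            "p_bonferroni": float(min(1.0, p * len(pairs))),
            "significant": bool(p < alpha_per),
        }
    return {
        "metric": metric,
        "anova_F": float(f_stat),
        "anova_p": float(p_anova),
        "alpha_per_comparison": alpha_per,
        "pairwise": pairwise,
    }


def univariate_regression(df: pd.DataFrame, x: str, y: str) -> dict:
    """Ordinary least squares of y on x with a two-sided t-test on the slope."""
    sub = df[[x, y]].dropna()
    if len(sub) < 3:
        raise ValueError("need >= 3 complete (x, y) pairs")
    res = sps.linregress(sub[x].to_numpy(), sub[y].to_numpy())
    return {
        "x": x,
        "y": y,
        "n": int(len(sub)),
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r_squared": float(res.rvalue**2),
        "p": float(res.pvalue),
    }


# ---------------------------------------------------------------------------
# AROC (Mann-Whitney construction) and DeLong comparison
# ---------------------------------------------------------------------------


@dataclass
class ROCResult:
    auroc: float
    se: float
    direction: int  # +1: higher metric => disease; -1: lower metric => disease
    n_pos: int
    n_neg: int
    v10: np.ndarray = field(repr=False, default=None)
    v01: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if not 0 <= self.auroc <= 1:
            raise ValueError("AROC must lie in [0, 1]")


def _delong_components(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Placement values of the Mann-Whitney kernel (ties count 1/2)."""
    diff = pos[:, None] - neg[None, :]
    psi = np.where(diff > 0, 1.0, np.where(diff == 0, 0.5, 0.0))
    return psi.mean(axis=1), psi.mean(axis=0), float(psi.mean())


def compute_aroc(
    disease_scores: np.ndarray, control_scores: np.ndarray, orient: bool = True
) -> ROCResult:
    """Area under the ROC curve by exhaustive pair counting.

    AROC is the probability that a diseased eye scores more disease-like than
    a control eye (ties count one half).  With ``orient=True`` the metric
    sign is flipped when needed so that the reported AROC is >= 0.5 (e.g.
    lower flux in disease still yields a discriminative AROC).  The standard
    error is the DeLong variance estimate.
    """
    pos = np.asarray(disease_scores, dtype=float)
    neg = np.asarray(control_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be non-empty")
    direction = 1
    v10, v01, auc = _delong_components(pos, neg)
    if orient and auc < 0.5:
        direction = -1
        v10, v01, auc = _delong_components(-pos, -neg)
    var = 0.0
    if pos.size > 1:
        var += np.var(v10, ddof=1) / pos.size
    if neg.size > 1:
        var += np.var(v01, ddof=1) / neg.size
    return ROCResult(
        auroc=float(auc),
        se=float(np.sqrt(var)),
        direction=direction,
        n_pos=pos.size,
        n_neg=neg.size,
        v10=v10,
        v01=v01,
    )


def compare_arocs(r1: ROCResult, r2: ROCResult) -> dict:
    """Paired DeLong test for two AROCs measured on the same eyes.

    Both ROCResults must come from the same subjects in the same order
    (e.g. flux index vs RNFL thickness on one cohort).
    """
    if r1.n_pos != r2.n_pos or r1.n_neg != r2.n_neg:
        raise ValueError("paired AROC comparison requires identical cohorts")
    m, n = r1.n_pos, r1.n_neg
    var1 = np.var(r1.v10, ddof=1) / m + np.var(r1.v01, ddof=1) / n
    var2 = np.var(r2.v10, ddof=1) / m + np.var(r2.v01, ddof=1) / n
    cov = (
        np.cov(r1.v10, r2.v10, ddof=1)[0, 1] / m
        + np.cov(r1.v01, r2.v01, ddof=1)[0, 1] / n
    )
    var_diff = var1 + var2 - 2 * cov
    if var_diff <= 0:
        return {"delta": float(r1.auroc - r2.auroc), "z": 0.0, "p": 1.0}
    z = (r1.auroc - r2.auroc) / np.sqrt(var_diff)
    p = 2.0 * sps.norm.sf(abs(z))
    return {"delta": float(r1.auroc - r2.auroc), "z": float(z), "p": float(p)}


def aroc_for_metric(
    df: pd.DataFrame, metric: str, positive_group: str, negative_group: str = "normal"
) -> ROCResult:
    pos = df.loc[df["group"] == positive_group, metric].dropna().to_numpy()
    neg = df.loc[df["group"] == negative_group, metric].dropna().to_numpy()
    return compute_aroc(pos, neg)


def reproducibility_cv(visit1: np.ndarray, visit2: np.ndarray) -> dict:
    """Two-visit coefficient of variation per subject, in percent.

    With two measurements the sample SD is |x1 - x2| / sqrt(2); CV is that
    SD over the two-visit mean, times 100.  Summarized as mean and min-max
    across subjects.
    """
    x1 = np.asarray(visit1, dtype=float)
    x2 = np.asarray(visit2, dtype=float)
    if x1.shape != x2.shape:
        raise ValueError("visits must be paired per subject")
    mean = (x1 + x2) / 2.0
    if np.any(mean <= 0):
        raise ValueError("two-visit means must be positive for a CV")
    cv = np.abs(x1 - x2) / np.sqrt(2.0) / mean * 100.0
    return {
        "per_subject": cv,
        "mean": float(cv.mean()),
        "min": float(cv.min()),
        "max": float(cv.max()),
    }


def compute_mopp(
    sbp: float | np.ndarray,
    dbp: float | np.ndarray,
    iop: float | np.ndarray,
    mode: str = "paper",
) -> np.ndarray | float:
    """Mean ocular perfusion pressure (mmHg).

    MAP = dbp + (sbp - dbp) / 3.  Two conventions for the 2/3 posture
    factor are supported: ``"paper"`` applies it to the perfusion pressure,
    MOPP = (2/3) * (MAP - IOP); ``"outside"`` subtracts IOP after scaling,
    MOPP = (2/3) * MAP - IOP.  Negative values are allowed (and logged) when
    IOP exceeds the scaled arterial pressure.
    """
    sbp = np.asarray(sbp, dtype=float)
    dbp = np.asarray(dbp, dtype=float)
    iop = np.asarray(iop, dtype=float)
    if np.any(dbp <= 0) or np.any(sbp < dbp):
        raise ValueError("require sbp >= dbp > 0")
    if np.any(iop < 0):
        raise ValueError("IOP must be non-negative")
    map_ = dbp + (sbp - dbp) / 3.0
    if mode == "paper":
        mopp = (2.0 / 3.0) * (map_ - iop)
    elif mode == "outside":
        mopp = (2.0 / 3.0) * map_ - iop
    else:
        raise ValueError(f"unknown MOPP mode {mode!r}")
    if np.any(mopp < 0):
        logger.warning("negative MOPP encountered (IOP exceeds scaled arterial pressure)")
    if mopp.ndim == 0:
        return float(mopp)
    return mopp
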