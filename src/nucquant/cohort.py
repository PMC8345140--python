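"""Clinical downstream analysis: cell density, concordance, time-dependent
ROC cutoff, Kaplan-Meier curves, log-rank test.

The biomarker score per patient is the density of detected positive cells
(cells/mm^2) over the analysed tissue area.  The density is dichotomized at
the cutoff maximising Youden's J on a time-dependent ROC at a fixed horizon
(default 5 years), and the two groups are compared with the standard
two-group log-rank test after administrative censoring at the horizon.

The time-dependent ROC uses the cumulative-case / dynamic-control
definition with Kaplan-Meier adjustment for right censoring: with overall
survival ``S(t)`` and subgroup survival from separate KM fits,

    sensitivity(c) = P(X > c) * (1 - S_{X>c}(t)) / (1 - S(t))
    specificity(c) = P(X <= c) * S_{X<=c}(t) / S(t)

(Censored-data Bayes-rule estimator; a naive unadjusted variant that drops
censored-before-horizon patients is available behind ``adjust='none'``.)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

__all__ = [
    "CohortRecord",
    "SurvivalSummary",
    "density",
    "concordance",
    "km_curve",
    "td_roc_cutoff",
    "logrank",
    "stratify_cohort",
]


@dataclass(frozen=True)
class CohortRecord:
    patient_id: str
    n_cells: int
    area_mm2: float
    density: float
    time: float
    event: int
    group: int | None = None  # 1 = high density (>= cutoff), 2 = low

    def __post_init__(self) -> None:
        if self.area_mm2 <= 0:
            raise ValueError("area_mm2 must be positive")
        if self.time < 0:
            raise ValueError("time must be >= 0")
        if abs(self.density - self.n_cells / self.area_mm2) > 1e-6 * max(
                1.0, self.density):
            raise ValueError("density must equal n_cells / area_mm2")


@dataclass
class SurvivalSummary:
    cutoff: float
    roc: pd.DataFrame  # cutoff, sensitivity, specificity, youden_j
    auc: float
    km_curves: dict  # group -> DataFrame(time, survival)
    logrank_chi2: float
    logrank_p: float
    horizon: float = 5.0
    group_sizes: dict = field(default_factory=dict)


def density(instances: np.ndarray, microns_per_pixel: float,
            analysed_mask: np.ndarray | None = None):
    """Cell count, analysed area and density from one instance label map.

    ``analysed_mask`` marks the pixels considered tissue (defaults to the
    whole image).  Area in mm^2 is the analysed-pixel count scaled by
    ``(microns_per_pixel / 1000)^2``; density = cells / mm^2.
    """
    if microns_per_pixel <= 0:
        raise ValueError("microns_per_pixel must be positive")
    instances = np.asarray(instances)
    n_cells = int(np.unique(instances[instances > 0]).size)
    if analysed_mask is None:
        n_px = instances.size
    else:
        analysed_mask = np.asarray(analysed_mask, dtype=bool)
        if analysed_mask.shape != instances.shape:
            raise ValueError("analysed_mask shape mismatch")
        n_px = int(analysed_mask.sum())
    area_mm2 = n_px * (microns_per_pixel / 1000.0) ** 2
    if area_mm2 <= 0:
        raise ValueError("analysed area is empty")
    return n_cells, area_mm2, n_cells / area_mm2


def concordance(pred_densities, gt_densities) -> float:
    """Pearson product-moment correlation between predicted and reference
    densities; raises on constant input."""
    x = np.asarray(pred_densities, dtype=float)
    y = np.asarray(gt_densities, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D vectors")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    r, _ = stats.pearsonr(x, y)
    return float(r)


def km_curve(times, events) -> pd.DataFrame:
    """Kaplan-Meier product-limit estimate.

    Returns a step function as a DataFrame ``time, survival`` starting at
    (0, 1); right-censored observations (event == 0) reduce the risk set
    without an event step.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if (times < 0).any():
        raise ValueError("times must be >= 0")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    sf = kmf.survival_function_
    return pd.DataFrame({"time": sf.index.to_numpy(dtype=float),
                         "survival": sf.iloc[:, 0].to_numpy(dtype=float)})


def _km_survival_at(times, events, t: float) -> float:
    """Product-limit survival at ``t`` (direct numpy computation: the
    td-ROC loop evaluates this per candidate cutoff)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        return 1.0
    ts = np.sort(times)
    ev_times = times[(events == 1) & (times <= t)]
    if ev_times.size == 0:
        return 1.0
    uniq, d = np.unique(ev_times, return_counts=True)
    at_risk = ts.size - np.searchsorted(ts, uniq, side="left")
    return float(np.prod(1.0 - d / at_risk))


def td_roc_cutoff(cohort: pd.DataFrame, horizon: float = 5.0,
                  adjust: str = "km"):
    """Time-dependent ROC at ``horizon`` and the Youden-optimal cutoff.

    ``cohort`` needs columns ``density, time_years, event``.  Candidate
    cutoffs are the unique observed densities; with ``adjust='km'``
    sensitivity/specificity use the KM-adjusted cumulative/dynamic
    estimator, with ``adjust='none'`` patients censored before the horizon
    are simply dropped.  Returns ``(roc_df, cutoff, auc)``; the optimal
    cutoff maximises J = sensitivity + specificity - 1 with ties broken
    toward the lower cutoff.  Raises if no events occur before the horizon.
    """
    if adjust not in ("km", "none"):
        raise ValueError("adjust must be 'km' or 'none'")
    x = cohort["density"].to_numpy(dtype=float)
    t = cohort["time_years"].to_numpy(dtype=float)
    e = cohort["event"].to_numpy(dtype=int)
    n = x.size
    if ((e == 1) & (t <= horizon)).sum() < 2:
        raise ValueError("need at least 2 events before the horizon")
    cutoffs = np.unique(x)
    sens = np.empty(cutoffs.size)
    spec = np.empty(cutoffs.size)
    if adjust == "km":
        s_all = _km_survival_at(t, e, horizon)
        for i, c in enumerate(cutoffs):
            hi = x >= c
            p_hi = hi.mean()
            s_hi = _km_survival_at(t[hi], e[hi], horizon) if hi.any() else 1.0
            s_lo = _km_survival_at(t[~hi], e[~hi], horizon) if (~hi).any() else 1.0
            sens[i] = p_hi * (1.0 - s_hi) / max(1.0 - s_all, 1e-12)
            spec[i] = (1.0 - p_hi) * s_lo / max(s_all, 1e-12)
        sens = np.clip(sens, 0.0, 1.0)
        spec = np.clip(spec, 0.0, 1.0)
    else:
        case = (t <= horizon) & (e == 1)
        control = t > horizon
        for i, c in enumerate(cutoffs):
            hi = x >= c
            sens[i] = (hi & case).sum() / max(case.sum(), 1)
            spec[i] = (~hi & control).sum() / max(control.sum(), 1)
    j = sens + spec - 1.0
    best = np.flatnonzero(j == j.max())[0]  # ties -> lower cutoff
    roc = pd.DataFrame({"cutoff": cutoffs, "sensitivity": sens,
                        "specificity": spec, "youden_j": j})
    fpr = 1.0 - spec
    order = np.lexsort((sens, fpr))  # ties in fpr traversed in tpr order
    fpr_s = np.concatenate([[0.0], fpr[order], [1.0]])
    tpr_s = np.concatenate([[0.0], sens[order], [1.0]])
    auc = float(np.trapezoid(tpr_s, fpr_s))
    return roc, float(cutoffs[best]), auc


def logrank(group1: pd.DataFrame, group2: pd.DataFrame,
            horizon: float | None = 5.0):
    """Two-group log-rank test (1 df), optionally restricted to ``horizon``
    years of follow-up by administrative censoring beforehand.

    Each group needs ``time_years`` and ``event`` columns.  Returns
    ``(chi2, p)``.
    """
    if len(group1) == 0 or len(group2) == 0:
        raise ValueError("both groups must be non-empty")

    def _restrict(df):
        t = df["time_years"].to_numpy(dtype=float)
        e = df["event"].to_numpy(dtype=int)
        if horizon is not None:
            e = np.where(t <= horizon, e, 0)
            t = np.minimum(t, horizon)
        return t, e

    t1, e1 = _restrict(group1)
    t2, e2 = _restrict(group2)
    if e1.sum() + e2.sum() == 0:
        return 0.0, 1.0  # no events anywhere: curves identical by definition
    res = logrank_test(t1, t2, event_observed_A=e1, event_observed_B=e2)
    return float(res.test_statistic), float(res.p_value)


def stratify_cohort(cohort: pd.DataFrame, horizon: float = 5.0,
                    adjust: str = "km") -> SurvivalSummary:
    """Full survival chain: td-ROC cutoff -> dichotomize -> KM -> log-rank.

    Group 1 holds patients with density >= cutoff, group 2 the rest; the
    log-rank test runs on follow-up administratively censored at the
    horizon.
    """
    roc, cutoff, auc = td_roc_cutoff(cohort, horizon=horizon, adjust=adjust)
    hi = cohort["density"].to_numpy(dtype=float) >= cutoff
    g1 = cohort.loc[hi]
    g2 = cohort.loc[~hi]
    if len(g1) == 0 or len(g2) == 0:
        raise ValueError("cutoff fails to split the cohort in two")
    chi2, p = logrank(g1, g2, horizon=horizon)
    curves = {
        1: km_curve(g1["time_years"], g1["event"]),
        2: km_curve(g2["time_years"], g2["event"]),
    }
    return SurvivalSummary(cutoff=cutoff, roc=roc, auc=auc, km_curves=curves,
                           logrank_chi2=chi2, logrank_p=p, horizon=horizon,
                           group_sizes={1: int(len(g1)), 2: int(len(g2))})
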