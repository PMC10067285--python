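"""Two-group comparison of mechanical parameters.

The statistical protocol is the standard parametric cascade for two
independent cohorts: per-group Shapiro-Wilk normality checks, an F-test for
homogeneity of variances, then an unpaired two-sided t-test at alpha = 0.05
— Student's pooled t when the F-test does not reject equal variances
(p >= 0.05), Welch's t otherwise.  No multiple-testing correction is applied
across the four parameters.

Input is the tidy per-specimen summary produced by the extraction module
(columns ``specimen_id``, ``group_label``, ``stiffness_N_per_mm``,
``yield_load_N``, ``max_load_N``, ``failure_load_N``) or an in-memory
collection of :class:`~vertmech.extraction.MechanicalSummary`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import StatisticsError
from .extraction import MechanicalSummary

PARAMETERS = ("stiffness", "yield_load", "max_load", "failure_load")
PARAMETER_COLUMNS = {
    "stiffness": "stiffness_N_per_mm",
    "yield_load": "yield_load_N",
    "max_load": "max_load_N",
    "failure_load": "failure_load_N",
}
PARAMETER_UNITS = {"stiffness": "N/mm", "yield_load": "N",
                   "max_load": "N", "failure_load": "N"}


def summaries_to_frame(summaries: Iterable[MechanicalSummary]) -> pd.DataFrame:
    """Tidy per-specimen frame from a collection of mechanical summaries."""
    return pd.DataFrame([s.to_record() for s in summaries])


@dataclass
class GroupSummary:
    """Per-group sample statistics (mean, SD with n-1 denominator, SEM)."""

    group_label: str
    n: int
    mean: dict
    sd: dict
    sem: dict


@dataclass
class GroupComparison:
    """Full test cascade for one parameter between two groups."""

    parameter: str
    group1: str
    group2: str
    n1: int
    n2: int
    mean1: float
    mean2: float
    sd1: float
    sd2: float
    shapiro_p_group1: float
    shapiro_p_group2: float
    f_statistic: float
    f_test_p: float
    t_statistic: float
    t_p: float
    degrees_of_freedom: float
    alpha: float
    significant: bool
    method_note: str

    def __post_init__(self) -> None:
        for p in (self.shapiro_p_group1, self.shapiro_p_group2,
                  self.f_test_p, self.t_p):
            if not 0.0 <= p <= 1.0:
                raise StatisticsError(f"p-value {p} outside [0, 1]")
        if self.significant != (self.t_p < self.alpha):
            raise StatisticsError("significance flag inconsistent with t_p")


def summarize_group(summaries, group_label: str | None = None) -> GroupSummary:
    """Sample mean, SD and SEM per parameter for one group.

    ``summaries`` may be an iterable of :class:`MechanicalSummary` or a tidy
    frame; with a frame, rows are filtered to ``group_label`` when given.
    """
    if isinstance(summaries, pd.DataFrame):
        frame = summaries
    else:
        frame = summaries_to_frame(summaries)
    if group_label is not None and "group_label" in frame.columns:
        sub = frame[frame["group_label"] == group_label]
        frame = sub if len(sub) else frame
    n = len(frame)
    if n < 2:
        raise StatisticsError(
            f"group '{group_label}' has {n} specimens; need at least 2")
    mean, sd, sem = {}, {}, {}
    for param, col in PARAMETER_COLUMNS.items():
        values = frame[col].to_numpy(dtype=float)
        mean[param] = float(np.mean(values))
        sd[param] = float(np.std(values, ddof=1))
        sem[param] = sd[param] / np.sqrt(n)
    return GroupSummary(group_label=group_label or "", n=n,
                        mean=mean, sd=sd, sem=sem)


def test_normality(values) -> tuple[float, float]:
    """Shapiro-Wilk test: (W, p).  Requires 3 <= n <= 5000."""
    values = np.asarray(values, dtype=float)
    if not 3 <= values.size <= 5000:
        raise StatisticsError(
            f"Shapiro-Wilk needs 3..5000 observations, got {values.size}")
    if np.ptp(values) == 0:
        raise StatisticsError("Shapiro-Wilk undefined for a constant sample")
    w, p = sps.shapiro(values)
    return float(w), float(min(max(p, 0.0), 1.0))


def test_variance_homogeneity(a, b) -> tuple[float, float]:
    """Two-sided F-test of equal variances.

    F is the larger sample variance over the smaller, with matching degrees
    of freedom; the two-sided p doubles the upper tail of the F
    distribution.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise StatisticsError("F-test needs at least 2 observations per group")
    va = np.var(a, ddof=1)
    vb = np.var(b, ddof=1)
    if va == 0 and vb == 0:
        raise StatisticsError("F-test undefined: both groups have zero variance")
    if va >= vb:
        num_var, den_var, dfn, dfd = va, vb, a.size - 1, b.size - 1
    else:
        num_var, den_var, dfn, dfd = vb, va, b.size - 1, a.size - 1
    if den_var == 0:
        return float("inf"), 0.0
    f = num_var / den_var
    p = 2.0 * sps.f.sf(f, dfn, dfd)
    return float(f), float(min(p, 1.0))


def compare_groups(a, b, parameter: str = "", *,
                   group1: str = "group1", group2: str = "group2",
                   alpha: float = 0.05,
                   variance_gate_alpha: float = 0.05) -> GroupComparison:
    """Run the full cascade for one parameter on two raw samples.

    Shapiro-Wilk per group (reported, not gating), F-test for variance
    homogeneity, then an unpaired two-sided t-test: pooled when the F-test
    p >= ``variance_gate_alpha``, Welch otherwise.
    """
    if not 0.0 < alpha < 1.0:
        raise StatisticsError("alpha must lie in (0, 1)")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    sw_w1, sw_p1 = test_normality(a)
    sw_w2, sw_p2 = test_normality(b)
    f_stat, f_p = test_variance_homogeneity(a, b)
    pooled = f_p >= variance_gate_alpha
    res = sps.ttest_ind(a, b, equal_var=pooled)
    t_p = float(min(max(res.pvalue, 0.0), 1.0))
    note = (f"Shapiro-Wilk p=({sw_p1:.4f}, {sw_p2:.4f}); "
            f"F-test p={f_p:.4f} -> "
            + ("pooled Student t" if pooled else "Welch t"))
    return GroupComparison(
        parameter=parameter, group1=group1, group2=group2,
        n1=int(a.size), n2=int(b.size),
        mean1=float(np.mean(a)), mean2=float(np.mean(b)),
        sd1=float(np.std(a, ddof=1)), sd2=float(np.std(b, ddof=1)),
        shapiro_p_group1=sw_p1, shapiro_p_group2=sw_p2,
        f_statistic=f_stat, f_test_p=f_p,
        t_statistic=float(res.statistic), t_p=t_p,
        degrees_of_freedom=float(res.df), alpha=alpha,
        significant=bool(t_p < alpha), method_note=note)


# ---------------------------------------------------------------------------
# model/results interface


class TwoGroupStudy:
    """Two-cohort study model over a tidy per-specimen summary frame.

    Parameters
    ----------
    frame : DataFrame
        One row per specimen with a ``group_label`` column and the four
        parameter columns; exactly two distinct group labels are required.
    alpha : float
        Significance level for the t-tests.
    variance_gate_alpha : float
        F-test level gating pooled vs Welch t.
    """

    def __init__(self, frame: pd.DataFrame, *, alpha: float = 0.05,
                 variance_gate_alpha: float = 0.05):
        if "group_label" not in frame.columns:
            raise StatisticsError("frame lacks a 'group_label' column")
        labels = [str(g) for g in pd.unique(frame["group_label"])]
        if len(labels) != 2:
            raise StatisticsError(
                f"expected exactly two groups, found {labels}")
        self.frame = frame
        self.labels = labels
        self.alpha = alpha
        self.variance_gate_alpha = variance_gate_alpha

    @classmethod
    def from_summaries(cls, summaries: Iterable[MechanicalSummary],
                       **kwargs) -> "TwoGroupStudy":
        return cls(summaries_to_frame(summaries), **kwargs)

    def fit(self) -> "TwoGroupStudyResults":
        g1, g2 = self.labels
        sub1 = self.frame[self.frame["group_label"] == g1]
        sub2 = self.frame[self.frame["group_label"] == g2]
        summary1 = summarize_group(sub1, g1)
        summary2 = summarize_group(sub2, g2)
        comparisons = []
        for param, col in PARAMETER_COLUMNS.items():
            comparisons.append(compare_groups(
                sub1[col].to_numpy(dtype=float),
                sub2[col].to_numpy(dtype=float),
                parameter=param, group1=g1, group2=g2, alpha=self.alpha,
                variance_gate_alpha=self.variance_gate_alpha))
        return TwoGroupStudyResults(self, summary1, summary2, comparisons)


class TwoGroupStudyResults:
    """Fitted two-group comparison: group summaries plus one test cascade
    per mechanical parameter."""

    def __init__(self, model: TwoGroupStudy, group1: GroupSummary,
                 group2: GroupSummary,
                 comparisons: Sequence[GroupComparison]):
        self.model = model
        self.group1 = group1
        self.group2 = group2
        self.comparisons = list(comparisons)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.comparisons:
            rows.append({
                "parameter": c.parameter,
                "units": PARAMETER_UNITS[c.parameter],
                f"mean_{c.group1}": c.mean1, f"sd_{c.group1}": c.sd1,
                f"mean_{c.group2}": c.mean2, f"sd_{c.group2}": c.sd2,
                "shapiro_p_group1": c.shapiro_p_group1,
                "shapiro_p_group2": c.shapiro_p_group2,
                "f_statistic": c.f_statistic, "f_test_p": c.f_test_p,
                "t_statistic": c.t_statistic, "t_p": c.t_p,
                "df": c.degrees_of_freedom,
                "significant": c.significant,
                "method": c.method_note,
            })
        return pd.DataFrame(rows)

    def summary(self) -> str:
        g1 = self.group1
        g2 = self.group2
        lines = [
            "Two-group comparison of mechanical parameters",
            "=" * 74,
            f"{g1.group_label}: n={g1.n}    {g2.group_label}: n={g2.n}    "
            f"alpha={self.model.alpha:g}",
            "-" * 74,
            f"{'parameter':<14}{'units':<7}"
            f"{g1.group_label + ' mean+/-sd':>20}"
            f"{g2.group_label + ' mean+/-sd':>20}{'p':>10}",
            "-" * 74,
        ]
        for c in self.comparisons:
            star = " *" if c.significant else ""
            lines.append(
                f"{c.parameter:<14}{PARAMETER_UNITS[c.parameter]:<7}"
                f"{c.mean1:>12.1f} +/- {c.sd1:<5.1f}"
                f"{c.mean2:>10.1f} +/- {c.sd2:<5.1f}"
                f"{c.t_p:>8.4f}{star}")
        lines.append("-" * 74)
        lines.append("* significant at the stated alpha (unpaired t-test; "
                     "pooled or Welch per F-test gate)")
        return "\n".join(lines)
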