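"""Case/control validation statistics for candidate endogenous controls.

Three complementary checks on the validation cohort:

* **difference testing** — per assay, a normality-gated two-sample test on
  Cq (Lilliefors/Kolmogorov-Smirnov gate at alpha = 0.05 per group; Welch
  t when both groups look Gaussian, Mann-Whitney U otherwise);
* **equivalence testing** — the group difference on the log2 expression
  scale (expression = -Cq up to a constant, so a *positive* estimate means
  more abundant in cases) with a symmetric two-sided confidence interval;
  the candidate is equivalent at a fold-change bound F iff the whole
  interval lies inside [-log2 F, +log2 F].  The conventional bounds are
  +-1 (2-fold) and +-1.58 (3-fold, log2 3 to 2 dp);
* **variance homogeneity** — Bartlett's test across the candidates' Cq
  distributions, with per-assay SD confidence intervals at a
  Bonferroni-adjusted chi-square level.
"""

from __future__ import annotations

import math
from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors

from .cq import CqMatrix, SampleSheet
from .errors import InputError, StatisticalError

__all__ = [
    "GroupComparisonResult",
    "EquivalenceResult",
    "VarianceHomogeneityResult",
    "compare_groups",
    "compare_group_values",
    "equivalence_test",
    "variance_homogeneity",
    "TWO_FOLD_BOUND",
    "THREE_FOLD_BOUND",
]

TWO_FOLD_BOUND = 1.0  # log2(2)
THREE_FOLD_BOUND = round(math.log2(3.0), 2)  # 1.58


@dataclass(frozen=True)
class GroupComparisonResult:
    assay: str
    groups: tuple[str, str]
    n: tuple[int, int]
    normality_p: dict[str, float]
    parametric: bool
    test_name: str  # "welch-t" or "mann-whitney"
    statistic: float
    pvalue: float
    estimate: float  # mean(group1) - mean(group2) on the analysed scale
    transform: str | None

    @property
    def significant(self) -> bool:
        return self.pvalue < 0.05

    @property
    def direction(self) -> str:
        if self.estimate > 0:
            return f"higher in {self.groups[0]}"
        if self.estimate < 0:
            return f"higher in {self.groups[1]}"
        return "no difference"


@dataclass(frozen=True)
class EquivalenceResult:
    assay: str
    groups: tuple[str, str]
    estimate: float  # log2 expression difference, group1 - group2
    ci: tuple[float, float]
    confidence: float
    bound: float
    equivalent: bool
    equivalent_2fold: bool
    equivalent_3fold: bool

    def equivalent_at(self, bound: float) -> bool:
        return -bound <= self.ci[0] and self.ci[1] <= bound


@dataclass(frozen=True)
class VarianceHomogeneityResult:
    statistic: float
    pvalue: float
    table: pd.DataFrame  # per assay: n, sd, ci_lower, ci_upper
    alpha: float


def _normality_gate(x: np.ndarray, alpha: float) -> tuple[float, bool]:
    """Lilliefors KS test with estimated parameters; small or degenerate
    groups (n < 5 or zero spread) skip the gate and count as normal."""
    if x.size < 5 or np.ptp(x) == 0.0:
        return float("nan"), True
    _, p = lilliefors(x, dist="norm")
    return float(p), p >= alpha


def compare_group_values(
    x: np.ndarray,
    y: np.ndarray,
    groups: tuple[str, str] = ("group1", "group2"),
    alpha: float = 0.05,
    transform: str | None = None,
    assay: str = "",
) -> GroupComparisonResult:
    """Normality-gated two-sample comparison of raw value vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    if x.size < 2 or y.size < 2:
        raise StatisticalError("need >= 2 values per group")
    if transform == "log10":
        if (x <= 0).any() or (y <= 0).any():
            raise InputError("log10 transform requires positive values")
        x, y = np.log10(x), np.log10(y)
    elif transform is not None:
        raise InputError(f"unknown transform {transform!r}")
    p1, ok1 = _normality_gate(x, alpha)
    p2, ok2 = _normality_gate(y, alpha)
    parametric = ok1 and ok2
    estimate = float(x.mean() - y.mean())
    if np.ptp(np.concatenate([x, y])) == 0.0:
        stat, p = 0.0, 1.0
        test = "welch-t"
    elif parametric:
        stat, p = stats.ttest_ind(x, y, equal_var=False)
        test = "welch-t"
    else:
        stat, p = stats.mannwhitneyu(x, y, alternative="two-sided")
        test = "mann-whitney"
    return GroupComparisonResult(
        assay=assay,
        groups=groups,
        n=(int(x.size), int(y.size)),
        normality_p={groups[0]: p1, groups[1]: p2},
        parametric=parametric,
        test_name=test,
        statistic=float(stat),
        pvalue=float(p),
        estimate=estimate,
        transform=transform,
    )


def _group_values(
    m: CqMatrix, sheet: SampleSheet, assay: str
) -> tuple[tuple[str, str], np.ndarray, np.ndarray]:
    g1, g2 = sheet.require_two_groups(samples=m.sample_ids)
    x = m.values_for(assay, sheet.samples_in(g1, restrict_to=m.sample_ids))
    y = m.values_for(assay, sheet.samples_in(g2, restrict_to=m.sample_ids))
    return (g1, g2), x, y


def compare_groups(
    m: CqMatrix,
    sheet: SampleSheet,
    assay: str,
    alpha: float = 0.05,
    transform: str | None = None,
) -> GroupComparisonResult:
    """Between-group test of an assay's Cq distribution.

    The reported estimate is mean(group1) - mean(group2) *in Cq*, so a
    negative estimate means the assay is more abundant in group1.
    """
    groups, x, y = _group_values(m, sheet, assay)
    return compare_group_values(
        x, y, groups=groups, alpha=alpha, transform=transform, assay=assay
    )


def _welch_ci(
    x: np.ndarray, y: np.ndarray, confidence: float
) -> tuple[float, float, float]:
    est = float(x.mean() - y.mean())
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    se2 = vx / x.size + vy / y.size
    if se2 == 0.0:
        return est, est, est
    se = math.sqrt(se2)
    df = se2**2 / (
        (vx / x.size) ** 2 / (x.size - 1) + (vy / y.size) ** 2 / (y.size - 1)
    )
    tcrit = stats.t.ppf(0.5 + confidence / 2.0, df)
    return est, est - tcrit * se, est + tcrit * se


def equivalence_test(
    m: CqMatrix,
    sheet: SampleSheet,
    assay: str,
    bound: float = THREE_FOLD_BOUND,
    confidence: float = 0.95,
    mode: str = "symmetric-ci",
) -> EquivalenceResult:
    """Equivalence of an assay's expression between groups.

    The estimate is the group1-minus-group2 difference in log2 expression
    (-Cq), with a two-sided Welch confidence interval; equivalence at a
    bound means the whole interval lies within [-bound, +bound].  The
    default reporting interval is the symmetric 95 % CI; ``mode="tost"``
    tightens it to a 90 % interval, which makes the verdict an exact
    two-one-sided-tests procedure at alpha = 0.05.
    """
    if bound <= 0:
        raise InputError("equivalence bound must be > 0")
    groups, x, y = _group_values(m, sheet, assay)
    if x.size < 2 or y.size < 2:
        raise StatisticalError("need >= 2 samples per group")
    if mode == "tost":
        confidence = 0.90
    elif mode != "symmetric-ci":
        raise InputError(f"unknown mode {mode!r}")
    # log2 expression = -Cq: flip the sign of the Cq difference
    est, lo, hi = _welch_ci(-x, -y, confidence)
    res = EquivalenceResult(
        assay=assay,
        groups=groups,
        estimate=est,
        ci=(lo, hi),
        confidence=confidence,
        bound=bound,
        equivalent=(-bound <= lo and hi <= bound),
        equivalent_2fold=(-TWO_FOLD_BOUND <= lo and hi <= TWO_FOLD_BOUND),
        equivalent_3fold=(-THREE_FOLD_BOUND <= lo and hi <= THREE_FOLD_BOUND),
    )
    return res


def variance_homogeneity(
    m: CqMatrix,
    assays: Sequence[str],
    alpha: float = 0.05,
) -> VarianceHomogeneityResult:
    """Bartlett's test of equal Cq variance across assays.

    Also reports each assay's SD with a chi-square confidence interval at
    the Bonferroni-adjusted level alpha/m, the classical multiple-interval
    display for comparing spreads.
    """
    assays = list(assays)
    if len(assays) < 2:
        raise StatisticalError("variance comparison needs >= 2 assays")
    vectors = [m.values_for(a, m.sample_ids) for a in assays]
    for a, v in zip(assays, vectors):
        if v.size < 3:
            raise StatisticalError(f"assay {a!r} has <3 detected samples")
    if all(np.allclose(v.var(ddof=1), vectors[0].var(ddof=1)) for v in vectors):
        stat, p = 0.0, 1.0
    else:
        stat, p = stats.bartlett(*vectors)
    m_tests = len(assays)
    adj = alpha / m_tests
    rows = []
    for a, v in zip(assays, vectors):
        n = v.size
        s2 = v.var(ddof=1)
        lo = math.sqrt((n - 1) * s2 / stats.chi2.ppf(1 - adj / 2, n - 1))
        hi = math.sqrt((n - 1) * s2 / stats.chi2.ppf(adj / 2, n - 1))
        rows.append(
            {"assay": a, "n": n, "sd": math.sqrt(s2), "ci_lower": lo, "ci_upper": hi}
        )
    table = pd.DataFrame(rows).set_index("assay")
    return VarianceHomogeneityResult(
        statistic=float(stat), pvalue=float(p), table=table, alpha=alpha
    )
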