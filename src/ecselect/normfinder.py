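"""Model-based reference-gene stability (NormFinder-style variance decomposition).

Candidate log2 expression is modelled additively as

    y_igj = alpha_ig + beta_gj + eps_igj,   eps_igj ~ N(0, sigma2_ig)

for gene *i*, group *g* (e.g. cancer/control), sample *j*: a gene/group
mean, a shared per-sample effect (RNA loading), and gene-specific noise.
Removing the sample effect by subtracting each sample's mean across the k
candidates gives z_igj, from which the model estimates, per gene and
group, the intra-group variance sigma2_ig and the inter-group difference
d_ig (centred across groups with equal weights, so sum_g d_ig = 0).

Subtracting the sample mean deflates and couples the gene variances:
E[s2_ig] = sigma2_ig (1 - 2/k) + sigma2bar_g / k, where s2_ig is the naive
variance of z and sigma2bar_g the mean of the k gene variances.  Averaging
over genes gives E[s2bar_g] = sigma2bar_g (k-1)/k, hence the finite-gene
correction used here (documented also in result metadata):

    sigma2_ig = ( k * s2_ig - (k/(k-1)) * s2bar_g ) / (k - 2),

truncated at zero (the correction can go negative at small n).  The bias
term is test-then-shrink: a gene's contrast enters only when its own
standardized value max_g |d_ig| / SE(d_ig) clears a Bonferroni-corrected
normal quantile (two-sided alpha = 0.05 / k), and surviving contrasts are
shrunk toward zero by the signal-to-total variance ratio
gamma2 / (gamma2 + Var d_ig), with gamma2 the pooled moment estimate
max(0, mean(d^2) - mean(Var d)).  The hard threshold matters because
sample centring leaks a little of every contrast into every gene: without
it, candidate comparison under homogeneous expression is driven by
sampling noise in d rather than by the variance term.  The per-gene
stability value combines bias and noise:

    rho_i = mean_g( |d~_ig| + sqrt(model Var d_ig) ),

where the model variance charges gene i only its own (corrected)
intra-group variance — the centering noise shared by the whole panel
cancels when any candidate is used as a normalizer, so it does not
discriminate between candidates.  Lower rho is more stable.  With a
single group rho_i reduces to the square root of the estimated gene
variance.  The best two-gene combination treats the pair as the mean of
its members on the log scale: differences average, variance
contributions halve, and the same |bias| + SE composition applies.
"""

from __future__ import annotations

import itertools
from collections.abc import Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from scipy import stats

from .cq import CqMatrix, SampleSheet
from .errors import InputError, StatisticalError

__all__ = ["NormFinderResult", "normfinder_stability", "best_pair", "pair_table"]

_CORRECTION_NOTE = (
    "finite-gene variance correction: sigma2_ig = (k*s2_ig - (k/(k-1))*s2bar_g)/(k-2), "
    "truncated at 0; derived from E[s2_ig] = sigma2_ig*(1-2/k) + sigma2bar_g/k after "
    "per-sample mean removal across k genes; bias terms hard-thresholded at the "
    "Bonferroni-corrected normal quantile (two-sided alpha = 0.05/k) before shrinkage"
)

#: Two-sided familywise level for the per-gene bias threshold.
BIAS_THRESHOLD_ALPHA = 0.05


@dataclass(frozen=True)
class NormFinderResult:
    """Per-gene stability values and the underlying decomposition.

    ``stability`` maps assay -> rho (lower = more stable); ``d`` holds the
    gene x group inter-group differences (log2 units), ``d_kept`` the
    hard-thresholded contrasts and ``d_shrunk`` the thresholded-and-shrunk
    ones entering rho; ``var_d`` their sampling variances (from the raw
    centered spread) and ``var_d_model`` the model-based variances built
    from the corrected gene variances; ``sigma2`` the corrected,
    zero-truncated intra-group variance estimates.
    """

    stability: pd.Series
    d: pd.DataFrame
    d_kept: pd.DataFrame
    d_shrunk: pd.DataFrame
    var_d: pd.DataFrame
    var_d_model: pd.DataFrame
    sigma2: pd.DataFrame
    gamma2: float
    group_sizes: pd.Series
    n_genes: int
    best_single: str
    metadata: dict = field(default_factory=dict)

    @property
    def ranking(self) -> pd.Series:
        return self.stability.sort_values(kind="mergesort")


def _sample_centered(y: pd.DataFrame) -> pd.DataFrame:
    """Remove per-sample means across genes (the shared loading effect)."""
    return y.sub(y.mean(axis=0), axis=1)


def _bias_kept(d: pd.DataFrame, var_d: pd.DataFrame, k: int) -> pd.Series:
    """Per-gene test-then-shrink mask for the bias term.

    A gene's contrast is kept only when max over groups of |d| / SE(d)
    clears the Bonferroni-corrected two-sided normal quantile at
    0.05 / k.  Contrasts that are exact (zero sampling variance, nonzero
    d) are always kept; all-zero contrasts never are.
    """
    zcrit = stats.norm.ppf(1 - BIAS_THRESHOLD_ALPHA / (2 * k))
    d_arr = d.to_numpy(dtype=float)
    v_arr = var_d.to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.abs(d_arr) / np.sqrt(v_arr)
    t[(v_arr == 0.0) & (d_arr != 0.0)] = np.inf
    t[(v_arr == 0.0) & (d_arr == 0.0)] = 0.0
    return pd.Series(np.nanmax(t, axis=1) > zcrit, index=d.index)


def normfinder_stability(
    m: CqMatrix,
    sheet: SampleSheet,
    candidates: Sequence[str],
    min_per_group: int = 2,
) -> NormFinderResult:
    """Estimate stability values for candidate controls.

    Needs >= 3 candidates (the model cannot separate the sample effect
    from gene noise otherwise), complete data on the candidates, and
    >= 2 samples per group.  Groups are weighted equally in the centring
    of d_ig, matching a case/control design intent regardless of group
    size imbalance.
    """
    candidates = list(candidates)
    if len(candidates) < 3:
        raise StatisticalError("NormFinder needs >= 3 candidate assays")
    sub = m.subset(assays=candidates).cq
    known = [s for s in sub.columns if s in sheet.table.index]
    missing = [s for s in sub.columns if s not in sheet.table.index]
    if missing:
        raise InputError(f"samples without group labels: {missing}")
    if sub[known].isna().any().any():
        stacked = sub.stack(future_stack=True)
        bad = stacked[stacked.isna()].index[0]
        raise InputError(
            f"candidate {bad[0]!r} undetected in sample {bad[1]!r}; "
            "candidates must be complete"
        )
    groups = sheet.groups
    for g in groups:
        if len(sheet.samples_in(g, restrict_to=known)) < min_per_group:
            raise StatisticalError(f"group {g!r} has <{min_per_group} samples")

    y = -sub  # log2 expression up to an additive constant
    z = _sample_centered(y)
    k = len(candidates)
    G = len(groups)

    zbar = pd.DataFrame(index=sub.index, columns=groups, dtype=float)
    s2 = pd.DataFrame(index=sub.index, columns=groups, dtype=float)
    n_g = pd.Series(index=groups, dtype=int)
    for g in groups:
        cols = sheet.samples_in(g, restrict_to=known)
        n_g[g] = len(cols)
        zg = z[cols]
        zbar[g] = zg.mean(axis=1)
        s2[g] = zg.var(axis=1, ddof=1) if len(cols) > 1 else 0.0

    # finite-gene correction for the deflation induced by sample centring
    s2bar = s2.mean(axis=0)
    sigma2 = (k * s2 - (k / (k - 1)) * s2bar) / (k - 2)
    sigma2 = sigma2.clip(lower=0.0)

    def _centered_var(spread: pd.DataFrame) -> pd.DataFrame:
        # Var(d_ig) for equal-weight centring:
        # d_ig = (1-1/G) zbar_ig - (1/G) sum_{h!=g} zbar_ih
        per_group = spread.div(n_g, axis=1)
        total = per_group.sum(axis=1)
        return (1 - 1 / G) ** 2 * per_group + (
            total.to_numpy()[:, None] - per_group
        ) / G**2

    if G >= 2:
        d = zbar.sub(zbar.mean(axis=1), axis=0)  # equal group weights
        var_d = _centered_var(s2)  # sampling variance of the observed contrast
        var_d_model = _centered_var(sigma2)  # gene's own (corrected) variance only
        kept = _bias_kept(d, var_d, k)
        d_kept = d.where(kept, 0.0)
        gamma2 = max(0.0, float((d**2).mean().mean() - var_d.mean().mean()))
        with np.errstate(invalid="ignore", divide="ignore"):
            shrink = gamma2 / (gamma2 + var_d) if gamma2 > 0 else var_d * 0.0
        d_shrunk = d_kept * shrink
        rho = (d_shrunk.abs() + np.sqrt(var_d_model)).mean(axis=1)
    else:
        d = pd.DataFrame(0.0, index=sub.index, columns=groups)
        d_kept = d.copy()
        d_shrunk = d.copy()
        var_d = pd.DataFrame(0.0, index=sub.index, columns=groups)
        var_d_model = var_d.copy()
        gamma2 = 0.0
        rho = np.sqrt(sigma2[groups[0]].clip(lower=0.0))

    rho = pd.Series(rho, index=sub.index, name="stability")
    best = rho.sort_values(kind="mergesort").index[0]
    return NormFinderResult(
        stability=rho,
        d=d,
        d_kept=d_kept,
        d_shrunk=d_shrunk,
        var_d=var_d,
        var_d_model=var_d_model,
        sigma2=sigma2,
        gamma2=gamma2,
        group_sizes=n_g,
        n_genes=k,
        best_single=str(best),
        metadata={
            "correction": _CORRECTION_NOTE,
            "group_weighting": "equal",
            "log_base": 2,
        },
    )


def _pair_stability(res: NormFinderResult, i: str, j: str) -> float:
    """Combined stability of two genes used as one normalizer.

    The pair is the mean of its members on the log scale: (thresholded)
    group differences average, variances quarter-sum (i.e. the summed
    contribution halves), and the same shrinkage and |bias| + SE
    composition as for single genes applies.
    """
    d_pair = (res.d_kept.loc[i] + res.d_kept.loc[j]) / 2.0
    var_pair = (res.var_d.loc[i] + res.var_d.loc[j]) / 4.0
    var_pair_model = (res.var_d_model.loc[i] + res.var_d_model.loc[j]) / 4.0
    g2 = res.gamma2
    if g2 > 0:
        d_sh = d_pair * (g2 / (g2 + var_pair))
    else:
        d_sh = d_pair * 0.0
    if (res.group_sizes.size) >= 2:
        return float((d_sh.abs() + np.sqrt(var_pair_model)).mean())
    # single group: rho is sqrt of the averaged-gene variance
    s2_pair = (res.sigma2.iloc[:, 0].loc[i] + res.sigma2.iloc[:, 0].loc[j]) / 4.0
    return float(np.sqrt(s2_pair))


def pair_table(res: NormFinderResult) -> pd.DataFrame:
    """Combined stability for every unordered candidate pair, best first."""
    rows = [
        {"assay_1": i, "assay_2": j, "stability": _pair_stability(res, i, j)}
        for i, j in itertools.combinations(sorted(res.stability.index), 2)
    ]
    return (
        pd.DataFrame(rows)
        .sort_values(["stability", "assay_1", "assay_2"], kind="mergesort")
        .reset_index(drop=True)
    )


def best_pair(res: NormFinderResult) -> tuple[tuple[str, str], float]:
    """Exhaustive search for the most stable two-gene combination."""
    if len(res.stability) < 2:
        raise StatisticalError("best pair needs >= 2 candidates")
    table = pair_table(res)
    top = table.iloc[0]
    return (str(top["assay_1"]), str(top["assay_2"])), float(top["stability"])
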