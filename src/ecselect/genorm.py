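"""geNorm reference-gene stability analysis.

Given relative quantities Q_ij for candidate controls, the pairwise
variation of two candidates is the SD across samples of their log2 ratio,

    V_jk = SD_i( log2(Q_ji / Q_ki) ),

and a candidate's gene-stability measure M_j is the mean of its V_jk over
all other candidates.  Stepwise exclusion of the highest-M candidate
yields a stability ranking ending in an inseparable most-stable pair
(which by construction share the same M).  The optimal number of controls
is judged from V_{n/n+1}, the SD across samples of log2(NF_n / NF_{n+1})
where NF_n is the geometric mean of the n most stable candidates'
quantities: the canonical heuristic accepts the smallest n with
V_{n/n+1} < 0.15, otherwise the n minimizing V.

All outputs are invariant to per-sample scaling of the quantities
(equivalently per-sample additive Cq shifts) — the property that makes
the statistic blind to RNA loading — and to the anchor used when
converting Cq to quantities, since anchors cancel in ratios.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cq import CqMatrix
from .errors import InputError, StatisticalError

__all__ = [
    "GeNormResult",
    "NormalizationFactorSeries",
    "to_relative_quantity",
    "pairwise_variation",
    "pairwise_variation_matrix",
    "stability_m",
    "stepwise_ranking",
    "optimal_ec_count",
]

DEFAULT_V_CUTOFF = 0.15


@dataclass(frozen=True)
class GeNormResult:
    """Stepwise-exclusion ranking.

    ``elimination`` lists (round, assay, M at elimination) for each dropped
    assay; ``final_pair`` are the two surviving assays (equal M, recorded
    in ``final_m``).  ``stability_order`` runs from most to least stable —
    the final pair (alphabetical) followed by eliminations in reverse.
    ``m_by_round`` tabulates every candidate's M at every round;
    ``pairwise_v`` is the initial-round V_jk matrix.
    """

    elimination: tuple[tuple[int, str, float], ...]
    final_pair: tuple[str, str]
    final_m: float
    m_by_round: pd.DataFrame
    pairwise_v: pd.DataFrame
    efficiencies: Mapping[str, float] | None = None
    tie_breaks: tuple[str, ...] = ()

    @property
    def stability_order(self) -> list[str]:
        out = list(self.final_pair)
        out += [assay for _, assay, _ in reversed(self.elimination)]
        return out


@dataclass(frozen=True)
class NormalizationFactorSeries:
    """NF_n per sample for n = 2..N, the V_{n/n+1} series, and the pick."""

    nf: pd.DataFrame  # index: samples; columns: n
    v: pd.Series  # index: n (V between NF_n and NF_{n+1})
    recommended_n: int
    rule: str  # "below_cutoff" or "argmin"
    v_cutoff: float


def to_relative_quantity(
    m: CqMatrix,
    candidates: Sequence[str] | None = None,
    efficiencies: Mapping[str, float] | None = None,
    anchor: str = "min",
) -> pd.DataFrame:
    """Convert Cq to relative quantities Q_ij = (1 + E_i/100)^(anchorCq_i - Cq_ij).

    With the default efficiency of 100 % a one-cycle Cq decrease doubles Q.
    ``anchor="min"`` uses each assay's minimum Cq (so max Q = 1);
    ``anchor="mean"`` its mean.  Candidates must be detected in every
    sample — a missing cell is an error naming the assay and sample.
    """
    assays = list(candidates) if candidates is not None else m.assay_ids
    sub = m.subset(assays=assays).cq
    if sub.isna().any().any():
        where = sub.stack(future_stack=True)
        bad = where[where.isna()].index[0]
        raise InputError(
            f"candidate assay {bad[0]!r} undetected in sample {bad[1]!r}; "
            "candidates must be complete"
        )
    if anchor == "min":
        anchor_cq = sub.min(axis=1)
    elif anchor == "mean":
        anchor_cq = sub.mean(axis=1)
    else:
        raise InputError(f"unknown anchor {anchor!r}; use 'min' or 'mean'")
    eff = pd.Series(100.0, index=sub.index)
    if efficiencies:
        for a, e in efficiencies.items():
            if a in eff.index:
                eff[a] = float(e)
    base = 1.0 + eff / 100.0
    q = pd.DataFrame(
        np.power(base.to_numpy()[:, None], sub.sub(anchor_cq, axis=0).to_numpy() * -1.0),
        index=sub.index,
        columns=sub.columns,
    )
    return q


def _log2_ratio_sd(qj: np.ndarray, qk: np.ndarray) -> float:
    return float(np.std(np.log2(qj / qk), ddof=1))


def pairwise_variation(q: pd.DataFrame, j: str, k: str) -> float:
    """V_jk = SD over samples of log2(Q_j / Q_k); n-1 denominator."""
    if j == k:
        raise InputError("pairwise variation needs two distinct assays")
    if q.shape[1] < 2:
        raise StatisticalError("pairwise variation needs >= 2 samples")
    return _log2_ratio_sd(q.loc[j].to_numpy(), q.loc[k].to_numpy())


def pairwise_variation_matrix(q: pd.DataFrame) -> pd.DataFrame:
    """Symmetric matrix of V_jk with zero diagonal."""
    logq = np.log2(q.to_numpy(dtype=float))
    n = logq.shape[0]
    out = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            v = float(np.std(logq[a] - logq[b], ddof=1))
            out[a, b] = out[b, a] = v
    return pd.DataFrame(out, index=q.index, columns=q.index)


def stability_m(q: pd.DataFrame) -> pd.Series:
    """Gene-stability measure M_j = mean over k != j of V_jk.

    With exactly two candidates both inherit M = V_jk (the pair is
    inseparable).
    """
    if q.shape[0] < 2:
        raise StatisticalError("stability M needs >= 2 assays")
    if q.shape[1] < 2:
        raise StatisticalError("stability M needs >= 2 samples")
    vmat = pairwise_variation_matrix(q)
    k = q.shape[0]
    if k == 2:
        v = vmat.iloc[0, 1]
        return pd.Series([v, v], index=q.index, name="M")
    m = vmat.sum(axis=1) / (k - 1)
    m.name = "M"
    return m


def stepwise_ranking(q: pd.DataFrame) -> GeNormResult:
    """Iteratively drop the highest-M candidate until two remain.

    M is recomputed after every exclusion.  Ties on M are broken by
    dropping the lexicographically last assay; every tie-break is recorded.
    """
    if q.shape[0] < 3:
        raise StatisticalError("stepwise ranking needs >= 3 assays")
    pairwise_v0 = pairwise_variation_matrix(q)
    remaining = q.copy()
    elimination: list[tuple[int, str, float]] = []
    tie_breaks: list[str] = []
    m_rounds: list[pd.Series] = []
    round_no = 1
    while remaining.shape[0] > 2:
        m = stability_m(remaining)
        m_rounds.append(m.rename(round_no))
        worst_m = m.max()
        ties = sorted(m.index[np.isclose(m, worst_m, rtol=0.0, atol=1e-12)])
        drop = ties[-1]
        if len(ties) > 1:
            tie_breaks.append(
                f"round {round_no}: tie on M={worst_m:.6g} among {ties}; dropped {drop!r}"
            )
        elimination.append((round_no, drop, float(m[drop])))
        remaining = remaining.drop(index=drop)
        round_no += 1
    final_m_series = stability_m(remaining)
    m_rounds.append(final_m_series.rename(round_no))
    final_pair = tuple(sorted(remaining.index))
    m_by_round = pd.concat(m_rounds, axis=1)
    m_by_round.columns.name = "round"
    return GeNormResult(
        elimination=tuple(elimination),
        final_pair=final_pair,  # type: ignore[arg-type]
        final_m=float(final_m_series.iloc[0]),
        m_by_round=m_by_round,
        pairwise_v=pairwise_v0,
        tie_breaks=tuple(tie_breaks),
    )


def normalization_factor(q: pd.DataFrame, assays: Sequence[str]) -> pd.Series:
    """NF(sample) = geometric mean of the given assays' relative quantities."""
    sub = q.loc[list(assays)].to_numpy(dtype=float)
    return pd.Series(
        np.exp(np.mean(np.log(sub), axis=0)), index=q.columns, name="NF"
    )


def optimal_ec_count(
    q: pd.DataFrame,
    ranking: GeNormResult,
    v_cutoff: float = DEFAULT_V_CUTOFF,
) -> NormalizationFactorSeries:
    """V_{n/n+1} series and the recommended number of controls.

    NF_n uses the n most stable assays per the ranking; V_{n/n+1} is the
    SD across samples of log2(NF_n / NF_{n+1}).  Recommend the smallest n
    whose V_{n/n+1} falls below the cutoff; when no V does (as in noisy
    clinical panels), fall back to the n minimizing V.
    """
    order = ranking.stability_order
    if len(order) < 3:
        raise StatisticalError("optimal EC count needs >= 3 ranked assays")
    n_max = len(order)
    nf = pd.DataFrame(
        {n: normalization_factor(q, order[:n]) for n in range(2, n_max + 1)}
    )
    nf.columns.name = "n"
    v_vals = {}
    for n in range(2, n_max):
        ratio = np.log2(nf[n].to_numpy() / nf[n + 1].to_numpy())
        v_vals[n] = float(np.std(ratio, ddof=1))
    v = pd.Series(v_vals, name="V")
    v.index.name = "n"
    below = [n for n, val in v.items() if val < v_cutoff]
    if below:
        recommended, rule = min(below), "below_cutoff"
    else:
        recommended, rule = int(v.idxmin()), "argmin"
    return NormalizationFactorSeries(
        nf=nf, v=v, recommended_n=recommended, rule=rule, v_cutoff=v_cutoff
    )
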