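"""Global-mean-expression (GME) stability screening.

For high-density miRNA profiling the mean Cq of all *expressed* miRNAs in
a sample is a robust per-sample normalizer.  Used in reverse, it is also a
screening statistic for candidate endogenous controls: for each assay,
compute its deviation from the per-sample global mean, d_ij = Cq_ij -
GM_j, and score the assay by the SD of that deviation across samples.
Assays riding the global mean (score near 0) are the stability nominees.

Control wells (snoRNAs, negative controls) are excluded from the global
mean itself but are still scored against it; candidate eligibility
requires detection in every sample.
"""

from __future__ import annotations

import logging
from collections.abc import Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cq import CqMatrix
from .errors import InputError, StatisticalError

__all__ = ["GmeRanking", "global_mean_per_sample", "rank_by_gme", "nominate_candidates"]

logger = logging.getLogger(__name__)

DEFAULT_EXPRESSED_CUTOFF = 35.0


@dataclass(frozen=True)
class GmeRanking:
    """Per-assay deviation-SD scores with stability ranks.

    ``table`` is indexed by assay with columns ``score`` (SD of the
    deviation from the per-sample global mean, cycles), ``eligible``
    (detected in all samples and not an excluded control well) and
    ``rank`` (1 = most stable; NaN for ineligible assays).  Ranks are a
    permutation of 1..n_eligible; ties broken lexicographically by name.
    """

    table: pd.DataFrame
    expressed_cutoff: float
    control_assays: tuple[str, ...] = ()
    metadata: dict = field(default_factory=dict)

    def top(self, k: int) -> list[str]:
        ranked = self.table.dropna(subset=["rank"]).sort_values("rank")
        return list(ranked.index[:k])


def _expressed_mask(m: CqMatrix, cutoff: float) -> pd.DataFrame:
    return m.detected & (m.cq < cutoff)


def global_mean_per_sample(
    m: CqMatrix,
    expressed_cutoff: float = DEFAULT_EXPRESSED_CUTOFF,
    control_assays: Sequence[str] = (),
) -> pd.Series:
    """Mean Cq over expressed assays (detected, Cq < cutoff) per sample.

    Control wells are excluded from the mean.  A sample with fewer than
    two expressed assays cannot define a meaningful mean and is an error.
    """
    keep = [a for a in m.assay_ids if a not in set(control_assays)]
    sub = m.cq.loc[keep]
    expressed = sub.notna() & (sub < expressed_cutoff)
    counts = expressed.sum(axis=0)
    low = counts[counts < 2]
    if len(low):
        raise StatisticalError(
            f"samples with <2 expressed assays below Cq {expressed_cutoff}: "
            f"{list(low.index)}"
        )
    return sub.where(expressed).mean(axis=0)


def rank_by_gme(
    m: CqMatrix,
    expressed_cutoff: float = DEFAULT_EXPRESSED_CUTOFF,
    control_assays: Sequence[str] = (),
) -> GmeRanking:
    """Score every assay by the SD of its deviation from the global mean.

    score_i = SD_j(Cq_ij - GM_j), n-1 denominator.  Because the global
    mean absorbs any per-sample additive shift, scores are invariant to
    the shared loading effect.  Assays not detected in all samples, and
    control wells, are scored where possible but marked ineligible.
    """
    if m.n_samples < 2:
        raise StatisticalError("GME ranking needs >= 2 samples")
    gm = global_mean_per_sample(m, expressed_cutoff, control_assays)
    deviations = m.cq.sub(gm, axis=1)
    scores = deviations.std(axis=1, ddof=1, skipna=True)
    controls = set(control_assays)
    eligible = m.detected.all(axis=1) & ~m.cq.index.isin(sorted(controls))
    table = pd.DataFrame(
        {"score": scores, "eligible": eligible}, index=m.cq.index
    ).sort_index()
    order = table[table["eligible"]].sort_values(
        by=["score"], kind="mergesort"
    )  # stable sort on the lexicographically sorted index breaks ties by name
    ranks = pd.Series(np.arange(1, len(order) + 1, dtype=float), index=order.index)
    table["rank"] = ranks.reindex(table.index)
    table = table.sort_values(by=["rank", "score"], na_position="last")
    return GmeRanking(
        table=table,
        expressed_cutoff=expressed_cutoff,
        control_assays=tuple(sorted(controls)),
        metadata={
            "controls_excluded_from_global_mean": True,
            "deviation_sd_ddof": 1,
        },
    )


def nominate_candidates(
    ranking: GmeRanking,
    k: int,
    exclusion_list: Sequence[str] = (),
) -> list[str]:
    """Top-k stability nominees after removing excluded assays.

    The exclusion list is user-supplied configuration (e.g. miRNAs with a
    documented disease association, which disqualifies them as controls).
    If fewer than k eligible assays remain, all are returned with a warning.
    """
    if k < 1:
        raise InputError("k must be >= 1")
    excluded = set(exclusion_list)
    ranked = ranking.table.dropna(subset=["rank"]).sort_values("rank")
    nominees = [a for a in ranked.index if a not in excluded]
    if len(nominees) < k:
        logger.warning(
            "only %d eligible candidates after exclusions (requested %d)",
            len(nominees),
            k,
        )
        return nominees
    return nominees[:k]
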