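"""Amplification efficiency and efficiency-corrected relative quantification.

**Standard curves.**  An assay's amplification efficiency comes from the
semi-log regression of Cq on log10 template input over a dilution series:

    E = (10^(-1/slope) - 1) * 100   [percent],

with slope in cycles per log10 input (-3.3219 at perfect doubling).  The
conventional acceptance band is 90-110 %.

**Relative quantification.**  The comparative cycle-threshold method,

    ddCT = (Cq_target,test - Cq_EC,test) - (Cq_target,calibrator - Cq_EC,calibrator),

gives RQ = 2^(-ddCT) at 100 % efficiency.  With per-assay efficiencies and
K endogenous controls the efficiency-corrected relative quantity is

    RQ_j = (1+E_t/100)^(Cq_t,cal - Cq_t,j) / prod_k [ (1+E_k/100)^(Cq_k,cal - Cq_k,j) ]^(1/K),

i.e. multi-control normalization by the geometric mean of the controls'
linear quantities (equivalently their arithmetic-mean Cq at equal
efficiencies).  The calibrator is a named sample or, by default, a
pseudo-sample holding each assay's control-group mean Cq.
"""

from __future__ import annotations

import logging
import math
from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cq import CqMatrix, SampleSheet
from .errors import InputError
from .validate import GroupComparisonResult, compare_group_values

__all__ = [
    "EfficiencyModel",
    "RelativeQuantity",
    "estimate_efficiency",
    "delta_delta_ct",
    "relative_quantities",
    "ec_sensitivity_experiment",
]

logger = logging.getLogger(__name__)

EFFICIENCY_BAND = (90.0, 110.0)
PERFECT_SLOPE = -1.0 / math.log10(2.0)  # -3.3219 cycles per log10 input


@dataclass(frozen=True)
class EfficiencyModel:
    """Standard-curve fit for one assay."""

    assay_id: str
    slope: float  # cycles per log10 input; < 0 for a functional assay
    intercept: float
    r_squared: float
    efficiency: float  # percent
    accepted: bool
    band: tuple[float, float] = EFFICIENCY_BAND

    @staticmethod
    def from_slope(
        slope: float,
        assay_id: str = "assay",
        intercept: float = float("nan"),
        r_squared: float = float("nan"),
        band: tuple[float, float] = EFFICIENCY_BAND,
    ) -> "EfficiencyModel":
        eff = (10.0 ** (-1.0 / slope) - 1.0) * 100.0
        return EfficiencyModel(
            assay_id=assay_id,
            slope=float(slope),
            intercept=float(intercept),
            r_squared=float(r_squared),
            efficiency=float(eff),
            accepted=bool(band[0] <= eff <= band[1]),
            band=band,
        )


@dataclass(frozen=True)
class RelativeQuantity:
    """One sample's normalized expression of one target."""

    target: str
    sample: str
    ec_strategy: tuple[str, ...]
    calibrator: str
    ddct: float  # cycles (meaningful at equal efficiencies)
    rq: float  # fold vs calibrator; RQ(calibrator) = 1


def estimate_efficiency(
    dilution: pd.DataFrame | Sequence[tuple[float, float]],
    assay_id: str | None = None,
    band: tuple[float, float] = EFFICIENCY_BAND,
) -> EfficiencyModel:
    """Fit the standard curve and derive percent efficiency.

    ``dilution`` is a DataFrame with (case-insensitive) columns
    ``log10_input`` and ``cq`` (optionally ``assay``), or a sequence of
    (log10_input, cq) pairs.  Needs >= 3 points spanning at least two
    distinct input levels.
    """
    if isinstance(dilution, pd.DataFrame):
        cols = {c.strip().lower(): c for c in dilution.columns}
        if "log10_input" not in cols or "cq" not in cols:
            raise InputError("dilution table needs columns 'log10_input' and 'cq'")
        x = dilution[cols["log10_input"]].to_numpy(dtype=float)
        y = dilution[cols["cq"]].to_numpy(dtype=float)
        if assay_id is None and "assay" in cols:
            uniq = dilution[cols["assay"]].unique()
            if len(uniq) > 1:
                raise InputError(
                    f"dilution table mixes assays {list(uniq)}; fit one at a time"
                )
            assay_id = str(uniq[0])
    else:
        arr = np.asarray(list(dilution), dtype=float)
        x, y = arr[:, 0], arr[:, 1]
    if x.size < 3:
        raise InputError("need >= 3 dilution points")
    if np.unique(x).size < 2 or np.ptp(x) == 0.0:
        raise InputError("dilution series has zero variance on the input axis")
    fit = stats.linregress(x, y)
    return EfficiencyModel.from_slope(
        slope=float(fit.slope),
        assay_id=assay_id or "assay",
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        band=band,
    )


def _ec_term(values: Sequence[float]) -> float:
    vals = [float(v) for v in values]
    if any(not math.isfinite(v) for v in vals):
        raise InputError("missing EC Cq value")
    return float(np.mean(vals))


def delta_delta_ct(
    target_test: float,
    ec_test: float | Sequence[float],
    target_calibrator: float,
    ec_calibrator: float | Sequence[float],
) -> float:
    """ddCT = (Cq_tgt,test - Cq_EC,test) - (Cq_tgt,cal - Cq_EC,cal).

    For a multi-control strategy the EC term is the arithmetic mean of the
    controls' Cq (the geometric mean of their linear quantities).  Any
    missing Cq is an error.
    """
    ec_t = _ec_term(np.atleast_1d(ec_test))
    ec_c = _ec_term(np.atleast_1d(ec_calibrator))
    for name, v in (("target test", target_test), ("target calibrator", target_calibrator)):
        if not math.isfinite(float(v)):
            raise InputError(f"missing {name} Cq value")
    return (float(target_test) - ec_t) - (float(target_calibrator) - ec_c)


def _calibrator_cq(
    m: CqMatrix,
    assays: Sequence[str],
    calibrator: str,
    sheet: SampleSheet | None,
    control_group: str | None,
) -> tuple[pd.Series, str]:
    if calibrator == "control_mean":
        if sheet is None:
            raise InputError("calibrator='control_mean' needs a sample sheet")
        group = control_group
        if group is None:
            groups = sheet.groups
            matches = [g for g in groups if g.lower() in {"control", "controls", "healthy"}]
            if len(matches) != 1:
                raise InputError(
                    f"cannot infer the control group from {groups}; pass control_group"
                )
            group = matches[0]
        cols = sheet.samples_in(group, restrict_to=m.sample_ids)
        if not cols:
            raise InputError(f"no samples in control group {group!r}")
        cal = m.cq.loc[list(assays), cols].mean(axis=1)
        return cal, f"mean({group})"
    if calibrator not in m.sample_ids:
        raise InputError(f"calibrator sample {calibrator!r} not in matrix")
    return m.cq.loc[list(assays), calibrator], calibrator


def relative_quantities(
    m: CqMatrix,
    targets: Sequence[str],
    ec_strategy: Sequence[str],
    efficiencies: Mapping[str, float | EfficiencyModel] | None = None,
    calibrator: str = "control_mean",
    sheet: SampleSheet | None = None,
    control_group: str | None = None,
) -> pd.DataFrame:
    """Efficiency-corrected RQ of each target in each sample.

    ``ec_strategy`` lists the endogenous controls (duplicates are
    deduplicated: the geometric mean is idempotent).  ``efficiencies``
    maps assay -> percent efficiency (or an EfficiencyModel); assays
    absent from the map run at 100 % with a logged warning.  Returns a
    samples x targets DataFrame of RQ; RQ at the calibrator equals 1.
    """
    ecs = list(dict.fromkeys(ec_strategy))
    if not ecs:
        raise InputError("EC strategy must list at least one control")
    targets = list(targets)
    involved = targets + ecs
    missing = [a for a in involved if a not in m.assay_ids]
    if missing:
        raise InputError(f"assays not in matrix: {missing}")
    sub = m.cq.loc[involved]
    if sub.loc[ecs].isna().any().any():
        stacked = sub.loc[ecs].stack(future_stack=True)
        bad = stacked[stacked.isna()].index[0]
        raise InputError(f"EC {bad[0]!r} undetected in sample {bad[1]!r}")

    eff = {}
    defaulted = []
    for a in involved:
        e = (efficiencies or {}).get(a)
        if e is None:
            eff[a] = 100.0
            defaulted.append(a)
        else:
            eff[a] = float(e.efficiency if isinstance(e, EfficiencyModel) else e)
    if defaulted and efficiencies is not None:
        logger.warning("no efficiency for %s; defaulting to 100%%", defaulted)

    cal_cq, cal_name = _calibrator_cq(m, involved, calibrator, sheet, control_group)
    out = pd.DataFrame(index=m.sample_ids, columns=targets, dtype=float)
    for t in targets:
        base_t = 1.0 + eff[t] / 100.0
        num = np.power(base_t, cal_cq[t] - m.cq.loc[t])
        denom = np.ones(m.n_samples)
        for k in ecs:
            base_k = 1.0 + eff[k] / 100.0
            denom = denom * np.power(base_k, (cal_cq[k] - m.cq.loc[k]) / len(ecs))
        out[t] = (num / denom).to_numpy()
    out.index.name = "sample"
    out.attrs["ec_strategy"] = tuple(ecs)
    out.attrs["calibrator"] = cal_name
    out.attrs["efficiencies"] = eff
    return out


def ec_sensitivity_experiment(
    m: CqMatrix,
    sheet: SampleSheet,
    targets: Sequence[str],
    strategies: Mapping[str, Sequence[str]] | Sequence[Sequence[str]],
    efficiencies: Mapping[str, float | EfficiencyModel] | None = None,
    calibrator: str = "control_mean",
    control_group: str | None = None,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame], dict[tuple[str, str], GroupComparisonResult]]:
    """Differential expression of each target under each EC strategy.

    For every strategy, compute per-sample RQ, log10-transform, and run
    the normality-gated two-sample test between the groups.  Returns the
    target x strategy p-value matrix, the per-strategy RQ tables and the
    full test results keyed by (target, strategy).
    """
    if isinstance(strategies, Mapping):
        named = {str(k): list(v) for k, v in strategies.items()}
    else:
        named = {"+".join(s): list(s) for s in strategies}
    if not named:
        raise InputError("need at least one EC strategy")
    g1, g2 = sheet.require_two_groups(samples=m.sample_ids)
    pvals = pd.DataFrame(index=list(targets), columns=list(named), dtype=float)
    rq_tables: dict[str, pd.DataFrame] = {}
    details: dict[tuple[str, str], GroupComparisonResult] = {}
    for name, ecs in named.items():
        rq = relative_quantities(
            m,
            targets,
            ecs,
            efficiencies=efficiencies,
            calibrator=calibrator,
            sheet=sheet,
            control_group=control_group,
        )
        rq_tables[name] = rq
        for t in targets:
            x = rq.loc[sheet.samples_in(g1, restrict_to=m.sample_ids), t].to_numpy()
            y = rq.loc[sheet.samples_in(g2, restrict_to=m.sample_ids), t].to_numpy()
            res = compare_group_values(
                x, y, groups=(g1, g2), alpha=alpha, transform="log10", assay=t
            )
            pvals.loc[t, name] = res.pvalue
            details[(t, name)] = res
    pvals.index.name = "target"
    pvals.columns.name = "strategy"
    return pvals, rq_tables, details
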