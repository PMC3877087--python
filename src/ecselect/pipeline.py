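"""End-to-end workflow: screen -> nominate -> validate -> quantify.

Every stage reads/writes delimited text, logs each decision (flag,
disqualification, tie-break), and is a pure function of (inputs, config,
seed).  ``run_demo`` generates both synthetic cohorts and runs the whole
workflow in one call.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import genorm, normfinder
from .cq import (
    CqMatrix,
    SampleSheet,
    calibrations_from_replicates,
    collapse_assay_wells,
    collapse_replicates,
    plates_from_replicates,
    apply_iac_calibration,
    read_cq_table,
    read_replicate_table,
    read_sample_sheet,
    summarize_assays,
    write_cq_table,
    write_replicate_table,
    write_sample_sheet,
    DEFAULT_REPLICATE_SD,
)
from .errors import InputError, StatisticalError
from .gme import DEFAULT_EXPRESSED_CUTOFF, nominate_candidates, rank_by_gme
from .quantify import EFFICIENCY_BAND, ec_sensitivity_experiment
from .simulate import (
    LITERATURE_CANDIDATES,
    NEGATIVE_CONTROL,
    SNORNA_ASSAYS,
    U6_WELLS,
    default_screen_spec,
    default_validation_spec,
    generate_array_screen,
    generate_cohort,
)
from .validate import (
    compare_groups,
    equivalence_test,
    variance_homogeneity,
)

__all__ = [
    "PipelineConfig",
    "run_screen_stage",
    "run_validation_stage",
    "run_quantification_stage",
    "run_demo",
]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All thresholds and file locations in one declarative record.

    Defaults equal the study's printed constants: replicate SD 0.28,
    expressed cutoff Cq 35, geNorm V cutoff 0.15, 3-fold equivalence
    bound, 90-110 % efficiency band, alpha 0.05.
    """

    outdir: str = "ecselect-out"
    screen_cq: str | None = None
    validation_replicates: str | None = None
    sample_sheet: str | None = None
    candidates: list[str] = field(default_factory=lambda: ["miR-16", "miR-425", "U6"])
    targets: list[str] = field(default_factory=lambda: ["miR-93", "miR-181a", "miR-652"])
    exclusion_list: list[str] = field(default_factory=list)
    top_k: int = 10
    expressed_cutoff: float = DEFAULT_EXPRESSED_CUTOFF
    replicate_sd: float = DEFAULT_REPLICATE_SD
    v_cutoff: float = genorm.DEFAULT_V_CUTOFF
    fold_change_bound: float = 3.0
    efficiency_band: tuple[float, float] = EFFICIENCY_BAND
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("expressed_cutoff", "replicate_sd", "v_cutoff", "fold_change_bound", "alpha"):
            if getattr(self, name) <= 0:
                raise InputError(f"threshold {name} must be positive")
        self.efficiency_band = tuple(self.efficiency_band)  # type: ignore[assignment]

    # -- round trip through YAML -----------------------------------------
    def to_yaml(self, path: str) -> None:
        data = dataclasses.asdict(self)
        data["efficiency_band"] = list(self.efficiency_band)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @property
    def log2_bound(self) -> float:
        import math

        b = math.log2(self.fold_change_bound)
        return round(b, 2)


def _outdir(config: PipelineConfig) -> Path:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def _log_thresholds(config: PipelineConfig) -> None:
    logger.info(
        "thresholds: expressed_cutoff=%s replicate_sd=%s v_cutoff=%s "
        "fold_change_bound=%s efficiency_band=%s alpha=%s seed=%s",
        config.expressed_cutoff,
        config.replicate_sd,
        config.v_cutoff,
        config.fold_change_bound,
        config.efficiency_band,
        config.alpha,
        config.seed,
    )


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def run_screen_stage(config: PipelineConfig, matrix: CqMatrix | None = None) -> dict:
    """GME screening: rank the profiling panel, nominate candidates.

    Replicate control wells (the four U6 wells) are collapsed first;
    snoRNA/negative control wells are excluded from the global mean but
    scored.  Writes the ranked table and the nominee list; nominees are
    merged with the configured literature candidates.
    """
    out = _outdir(config)
    _log_thresholds(config)
    if matrix is None:
        if config.screen_cq is None:
            raise InputError("no screen Cq table configured")
        matrix = read_cq_table(config.screen_cq)
    wells_present = [w for w in U6_WELLS if w in matrix.assay_ids]
    if wells_present:
        matrix = collapse_assay_wells(matrix, {w: "U6" for w in wells_present})
        logger.info("collapsed %d U6 wells into one assay", len(wells_present))
    controls = [a for a in ("U6", *SNORNA_ASSAYS, NEGATIVE_CONTROL) if a in matrix.assay_ids]
    ranking = rank_by_gme(
        matrix, expressed_cutoff=config.expressed_cutoff, control_assays=controls
    )
    for a, row in ranking.table.iterrows():
        if not row["eligible"]:
            logger.info("screen: %s ineligible (control well or dropout)", a)
    nominees = nominate_candidates(ranking, config.top_k, config.exclusion_list)
    merged = list(dict.fromkeys([*nominees, *[c for c in LITERATURE_CANDIDATES if c in matrix.assay_ids or c == "U6"]]))
    ranking.table.to_csv(out / "screen_gme_ranking.csv")
    pd.Series(nominees, name="nominee").to_csv(out / "screen_nominees.csv", index=False)
    pd.Series(merged, name="candidate").to_csv(out / "screen_candidates_merged.csv", index=False)
    logger.info("screen: %d nominees after %d exclusions", len(nominees), len(config.exclusion_list))
    return {"ranking": ranking, "nominees": nominees, "candidates": merged}


def run_validation_stage(
    config: PipelineConfig,
    replicates=None,
    sheet: SampleSheet | None = None,
) -> dict:
    """Replicate QC, IAC calibration, and the full stability battery.

    Produces the per-assay Cq summary, geNorm M/V tables, NormFinder
    stability values, group comparisons, equivalence verdicts, the
    Bartlett variance report, and a combined recommendation (best single
    control and best pair from both algorithms).
    """
    out = _outdir(config)
    _log_thresholds(config)
    if replicates is None:
        if config.validation_replicates is None:
            raise InputError("no validation replicate table configured")
        replicates = read_replicate_table(config.validation_replicates, max_sd=config.replicate_sd)
    if sheet is None:
        if config.sample_sheet is None:
            raise InputError("no sample sheet configured")
        sheet = read_sample_sheet(config.sample_sheet)

    matrix, qc = collapse_replicates(replicates)
    qc.to_csv(out / "validation_replicate_qc.csv", index=False)
    for _, row in qc[~qc["passed"]].iterrows():
        logger.info(
            "replicate QC: excluded (%s, %s) SD %.3f > %.2f",
            row["sample"], row["assay"], row["sd"], row["threshold"],
        )
    has_iac = any(r.sample_id == "IAC" for r in replicates)
    if has_iac:
        cals = calibrations_from_replicates(replicates)
        plates = plates_from_replicates(replicates)
        matrix = apply_iac_calibration(matrix, cals, plates)
        for c in cals:
            logger.info("IAC: plate %s offset %+.3f cycles", c.plate_id, c.offset)

    candidates = [c for c in config.candidates if c in matrix.assay_ids]
    disqualified = []
    for c in list(candidates):
        if matrix.cq.loc[c].isna().any():
            disqualified.append(c)
            candidates.remove(c)
            logger.info("candidate %s disqualified: undetected in some sample", c)

    summary = summarize_assays(matrix.subset(assays=candidates), sheet)
    summary.to_csv(out / "validation_cq_summary.csv")

    # geNorm
    q = genorm.to_relative_quantity(matrix, candidates=candidates)
    genorm_tables: dict = {}
    if len(candidates) >= 3:
        ranking = genorm.stepwise_ranking(q)
        for note in ranking.tie_breaks:
            logger.info("geNorm %s", note)
        nf_series = genorm.optimal_ec_count(q, ranking, v_cutoff=config.v_cutoff)
        ranking.m_by_round.to_csv(out / "genorm_m_by_round.csv")
        nf_series.v.to_csv(out / "genorm_v_series.csv")
        genorm_tables = {"ranking": ranking, "nf": nf_series}
        logger.info(
            "geNorm: final pair %s (M=%.3f); recommended n=%d by %s",
            ranking.final_pair, ranking.final_m, nf_series.recommended_n, nf_series.rule,
        )
    elif len(candidates) == 2:
        m_vals = genorm.stability_m(q)
        m_vals.to_csv(out / "genorm_m_by_round.csv")
        genorm_tables = {"pair_m": m_vals}
        logger.info("geNorm: only 2 candidates; both carry M=%.3f", float(m_vals.iloc[0]))
    else:
        raise StatisticalError("geNorm needs >= 2 complete candidates")

    # NormFinder
    nf_result = None
    if len(candidates) >= 3:
        nf_result = normfinder.normfinder_stability(matrix, sheet, candidates)
        pair, pair_val = normfinder.best_pair(nf_result)
        nf_table = pd.DataFrame(
            {
                "stability": nf_result.stability,
                **{f"d_{g}": nf_result.d[g] for g in nf_result.d.columns},
                **{f"sigma2_{g}": nf_result.sigma2[g] for g in nf_result.sigma2.columns},
            }
        )
        nf_table.to_csv(out / "normfinder_stability.csv")
        normfinder.pair_table(nf_result).to_csv(out / "normfinder_pairs.csv", index=False)
        logger.info(
            "NormFinder: best single %s; best pair %s (%.3f); %s",
            nf_result.best_single, pair, pair_val, nf_result.metadata["correction"],
        )
    else:
        logger.info("NormFinder skipped: needs >= 3 candidates, have %d", len(candidates))

    # group comparison / equivalence / variance homogeneity
    comp_rows, eq_rows = [], []
    for c in candidates:
        comp = compare_groups(matrix, sheet, c, alpha=config.alpha)
        eq = equivalence_test(matrix, sheet, c, bound=config.log2_bound)
        comp_rows.append(
            {
                "assay": c, "test": comp.test_name, "parametric": comp.parametric,
                "statistic": comp.statistic, "pvalue": comp.pvalue,
                "estimate_cq": comp.estimate, "direction": comp.direction,
            }
        )
        eq_rows.append(
            {
                "assay": c, "estimate_log2": eq.estimate,
                "ci_lower": eq.ci[0], "ci_upper": eq.ci[1],
                "equivalent_2fold": eq.equivalent_2fold,
                "equivalent_3fold": eq.equivalent_3fold,
            }
        )
        if comp.pvalue < config.alpha:
            logger.info("group comparison: %s differs between groups (p=%.4g)", c, comp.pvalue)
    comparisons = pd.DataFrame(comp_rows).set_index("assay")
    equivalences = pd.DataFrame(eq_rows).set_index("assay")
    comparisons.to_csv(out / "validation_group_comparison.csv")
    equivalences.to_csv(out / "validation_equivalence.csv")
    var_report = variance_homogeneity(matrix, candidates, alpha=config.alpha)
    var_report.table.to_csv(out / "validation_variance_homogeneity.csv")

    recommendation = _recommend(genorm_tables, nf_result, comparisons, config)
    (out / "recommendation.json").write_text(json.dumps(recommendation, indent=2))
    logger.info("recommendation: %s", recommendation)
    return {
        "matrix": matrix,
        "summary": summary,
        "genorm": genorm_tables,
        "normfinder": nf_result,
        "comparisons": comparisons,
        "equivalences": equivalences,
        "variance": var_report,
        "recommendation": recommendation,
        "disqualified": disqualified,
        "candidates": candidates,
    }


def _recommend(genorm_tables, nf_result, comparisons, config) -> dict:
    rec: dict = {"flagged_by_group_test": comparisons.index[comparisons["pvalue"] < config.alpha].tolist()}
    if "ranking" in genorm_tables:
        rec["genorm_pair"] = list(genorm_tables["ranking"].final_pair)
        rec["genorm_recommended_n"] = genorm_tables["nf"].recommended_n
        rec["genorm_rule"] = genorm_tables["nf"].rule
    if nf_result is not None:
        pair, val = normfinder.best_pair(nf_result)
        rec["normfinder_best_single"] = nf_result.best_single
        rec["normfinder_pair"] = list(pair)
        rec["normfinder_pair_stability"] = val
    if "ranking" in genorm_tables and nf_result is not None:
        overlap = sorted(set(genorm_tables["ranking"].final_pair) & set(nf_result.stability.index))
        rec["consensus_pair"] = list(genorm_tables["ranking"].final_pair)
    return rec


def run_quantification_stage(
    config: PipelineConfig,
    matrix: CqMatrix,
    sheet: SampleSheet,
    strategies: dict[str, list[str]] | None = None,
    efficiencies=None,
) -> dict:
    """Relative quantification of targets under alternative EC strategies.

    Emits per-strategy RQ tables, the target x strategy p-value matrix,
    and a discordance summary (targets whose significance verdict flips
    between strategies).  An empty target list yields an empty report.
    """
    out = _outdir(config)
    _log_thresholds(config)
    targets = [t for t in config.targets if t in matrix.assay_ids]
    if not targets:
        pd.DataFrame().to_csv(out / "quantification_pvalues.csv")
        logger.info("quantification: no targets; empty report")
        return {"pvalues": pd.DataFrame(), "discordant": []}
    if strategies is None:
        singles = {c: [c] for c in config.candidates if c in matrix.assay_ids}
        pair = [c for c in ("miR-16", "miR-425") if c in matrix.assay_ids]
        strategies = dict(singles)
        if len(pair) == 2:
            strategies["+".join(pair)] = pair
    pvals, rq_tables, _ = ec_sensitivity_experiment(
        matrix, sheet, targets, strategies, efficiencies=efficiencies,
        alpha=config.alpha,
    )
    pvals.to_csv(out / "quantification_pvalues.csv")
    for name, rq in rq_tables.items():
        rq.to_csv(out / f"quantification_rq_{name.replace('/', '-')}.csv")
    sig = pvals < config.alpha
    discordant = [t for t in targets if sig.loc[t].nunique() > 1]
    for t in discordant:
        logger.info(
            "quantification: %s verdict flips across strategies (p: %s)",
            t, {k: round(v, 4) for k, v in pvals.loc[t].items()},
        )
    pd.Series(discordant, name="discordant_target").to_csv(
        out / "quantification_discordant.csv", index=False
    )
    return {"pvalues": pvals, "rq": rq_tables, "discordant": discordant}


# ---------------------------------------------------------------------------
# demo
# ---------------------------------------------------------------------------


def run_demo(seed: int = 0, outdir: str = "ecselect-demo", make_figures: bool = True) -> dict:
    """Generate both synthetic cohorts and run the full workflow.

    Writes the simulated inputs (screen matrix, validation replicate
    wells, sample sheets, ground-truth sidecars, a dilution series), all
    stage outputs and a plain-text log under ``outdir``.  Deterministic
    for a fixed seed.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    config = PipelineConfig(outdir=str(out), seed=seed)
    config.to_yaml(out / "config.yaml")

    log_path = out / "demo.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(name)s: %(message)s"))
    root = logging.getLogger("ecselect")
    root.addHandler(handler)
    old_level = root.level
    root.setLevel(logging.INFO)
    try:
        screen = generate_array_screen(default_screen_spec(), seed=seed)
        write_cq_table(screen.matrix, str(out / "screen_cq.csv"))
        write_sample_sheet(screen.sheet, str(out / "screen_samples.csv"))
        (out / "screen_truth.json").write_text(json.dumps(screen.truth, indent=2))

        validation = generate_cohort(default_validation_spec(), seed=seed + 1)
        write_replicate_table(validation.replicates, str(out / "validation_replicates.csv"))
        write_sample_sheet(validation.sheet, str(out / "validation_samples.csv"))
        (out / "validation_truth.json").write_text(json.dumps(validation.truth, indent=2))

        screen_result = run_screen_stage(config, matrix=screen.matrix)
        validation_result = run_validation_stage(
            config, replicates=validation.replicates, sheet=validation.sheet
        )
        quant_result = run_quantification_stage(
            config, validation_result["matrix"], validation.sheet
        )
        if make_figures:
            _demo_figures(out, validation_result)
    finally:
        root.removeHandler(handler)
        handler.close()
        root.setLevel(old_level)
    return {
        "screen": screen_result,
        "validation": validation_result,
        "quantification": quant_result,
        "outdir": str(out),
    }


def _demo_figures(out: Path, validation_result: dict) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    tables = validation_result["genorm"]
    if "ranking" in tables:
        ranking = tables["ranking"]
        order = ranking.stability_order
        m_first = ranking.m_by_round.iloc[:, 0]
        fig, ax = plt.subplots(figsize=(5, 3))
        ax.bar([str(a) for a in order], [m_first[a] for a in order])
        ax.set_ylabel("geNorm M (round 1)")
        ax.set_title("Candidate stability (most stable left)")
        fig.tight_layout()
        fig.savefig(out / "genorm_m.png", dpi=120)
        plt.close(fig)

        v = tables["nf"].v
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.plot(v.index, v.values, marker="o")
        ax.axhline(0.15, linestyle="--", linewidth=1)
        ax.set_xlabel("n controls")
        ax.set_ylabel("V(n/n+1)")
        fig.tight_layout()
        fig.savefig(out / "genorm_v.png", dpi=120)
        plt.close(fig)
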