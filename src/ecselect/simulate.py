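"""Synthetic Cq cohorts with known ground truth.

The generative model for a well of assay *i*, sample *j*, replicate *r* is

    Cq_ijr = B_i + S_j + delta_i * 1[group(j) = case] + pi_plate(j) + eps_ij + eta_ijr

with a per-sample RNA-loading effect ``S_j ~ N(0, tau^2)`` shared by every
assay in the sample (exactly the nuisance that endogenous controls and
global-mean normalization exist to remove), per-assay biological/technical
noise ``eps_ij ~ N(0, sigma_i^2)``, an optional between-run plate effect
``pi_p ~ N(0, plate_sd^2)`` and replicate-well jitter
``eta ~ N(0, sigma_rep^2)``.  All noise is Gaussian on the Cq (log2) scale.

Two study designs are emulated:

* a profiling *screen* — 377 miRNA assays plus U6 in quadruplicate, RNU44,
  RNU48 and one never-detected negative-control assay, over 10 cancer and
  10 control samples;
* a *validation* cohort — 40 cancer / 20 control samples, triplicate wells,
  per-plate inter-assay calibrators, with candidate-control location and
  scale chosen to match the published validation summaries (miR-16-like
  mean Cq ~= 15.46, miR-425-like ~= 20.74, U6-like ~= 21.04 with a
  +0.57-cycle case-control shift, the control group being the more
  abundant).

Generation is a pure function of (spec, seed).
"""

from __future__ import annotations

import math
from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cq import CqMatrix, ReplicateSet, SampleSheet
from .errors import InputError

__all__ = [
    "AssayModel",
    "CohortSpec",
    "SimulatedCohort",
    "generate_cohort",
    "generate_array_screen",
    "generate_dilution_series",
    "default_validation_spec",
    "default_screen_spec",
]

#: log2(10): cycles per 10-fold dilution step at 100 % efficiency.
CYCLES_PER_LOG10_AT_E100 = 1.0 / math.log10(2.0)


@dataclass(frozen=True)
class AssayModel:
    """One assay's generating parameters.

    ``delta`` is the case-minus-control shift in cycles (a *positive* delta
    means higher Cq, i.e. *lower* abundance, in the case group; 0 for a
    non-differential assay).  ``role`` is free-text bookkeeping
    ("stable", "unstable", "target", "snoRNA", "negative", ...).
    """

    name: str
    baseline: float
    sigma: float
    delta: float = 0.0
    role: str = "mirna"

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise InputError(f"assay {self.name!r}: sigma must be >= 0")


@dataclass(frozen=True)
class CohortSpec:
    """Design of a simulated cohort; generation is deterministic given a seed."""

    n_case: int
    n_control: int
    assays: tuple[AssayModel, ...]
    tau: float = 0.5  # SD of the shared per-sample loading effect, cycles
    sigma_rep: float = 0.10  # replicate-well jitter SD, cycles
    n_replicates: int = 3
    samples_per_plate: int = 20
    plate_sd: float = 0.0  # between-run shift SD, cycles
    iac_sample: str = "IAC"
    include_iac: bool = False
    case_label: str = "cancer"
    control_label: str = "control"
    cohort_label: str = "validation"
    max_cycles: float = 40.0

    def __post_init__(self) -> None:
        if self.n_case < 1 or self.n_control < 1:
            raise InputError("need at least one sample per group")
        if self.tau < 0 or self.sigma_rep < 0 or self.plate_sd < 0:
            raise InputError("variance-component SDs must be >= 0")
        if self.n_replicates < 1:
            raise InputError("n_replicates must be >= 1")
        if self.samples_per_plate < 1:
            raise InputError("samples_per_plate must be >= 1")
        if len(self.assays) < 1:
            raise InputError("need at least one assay")
        names = [a.name for a in self.assays]
        if len(set(names)) != len(names):
            raise InputError("assay names must be unique")
        object.__setattr__(self, "assays", tuple(self.assays))

    @property
    def designated_stable(self) -> tuple[str, ...]:
        return tuple(a.name for a in self.assays if a.role == "stable")

    @property
    def designated_unstable(self) -> tuple[str, ...]:
        return tuple(a.name for a in self.assays if a.role == "unstable")


@dataclass(frozen=True)
class SimulatedCohort:
    """Generated cohort: replicate wells, collapsed matrix, labels, ground truth.

    ``truth`` records every parameter and realized random effect, so each
    sample's *expected* Cq (baseline + loading + group effect + plate
    effect) can be recomputed exactly via :meth:`expected_cq`.
    """

    replicates: tuple[ReplicateSet, ...]
    matrix: CqMatrix  # replicate means per (assay, sample), IAC excluded
    sheet: SampleSheet
    truth: dict

    def expected_cq(self, assay: str, sample: str) -> float:
        t = self.truth
        a = t["assays"][assay]
        mean = a["baseline"] + t["loading"][sample] + t["plate_effects"][t["plates"][sample]]
        if t["group"][sample] == t["case_label"]:
            mean += a["delta"]
        return mean

    def sample_plates(self) -> dict[str, str]:
        return dict(self.truth["plates"])


def _clip_cq(values: np.ndarray, max_cycles: float) -> np.ndarray:
    return np.clip(values, 0.0, max_cycles)


def generate_cohort(spec: CohortSpec, seed: int) -> SimulatedCohort:
    """Draw one cohort from the generative model.

    Returns replicate-level wells (including IAC wells when
    ``spec.include_iac``), the collapsed matrix of replicate means, the
    sample sheet and the ground-truth record.
    """
    rng = np.random.default_rng(seed)
    samples = [f"{spec.case_label}_{i + 1:03d}" for i in range(spec.n_case)]
    samples += [f"{spec.control_label}_{i + 1:03d}" for i in range(spec.n_control)]
    groups = [spec.case_label] * spec.n_case + [spec.control_label] * spec.n_control

    n_plates = max(1, math.ceil(len(samples) / spec.samples_per_plate))
    plate_ids = [f"plate{p + 1}" for p in range(n_plates)]
    # round-robin so each plate carries both groups (no plate/group confound)
    plates = {s: plate_ids[i % n_plates] for i, s in enumerate(samples)}

    loading = rng.normal(0.0, spec.tau, size=len(samples))
    plate_eff = rng.normal(0.0, spec.plate_sd, size=n_plates) if spec.plate_sd > 0 else np.zeros(n_plates)
    plate_eff_map = dict(zip(plate_ids, plate_eff.tolist()))

    reps: list[ReplicateSet] = []
    collapsed = pd.DataFrame(
        np.nan,
        index=pd.Index([a.name for a in spec.assays], name="assay"),
        columns=samples,
    )
    for a in spec.assays:
        eps = rng.normal(0.0, a.sigma, size=len(samples)) if a.sigma > 0 else np.zeros(len(samples))
        for j, s in enumerate(samples):
            mean = a.baseline + loading[j] + plate_eff_map[plates[s]] + eps[j]
            if groups[j] == spec.case_label:
                mean += a.delta
            jitter = (
                rng.normal(0.0, spec.sigma_rep, size=spec.n_replicates)
                if spec.sigma_rep > 0
                else np.zeros(spec.n_replicates)
            )
            wells = _clip_cq(mean + jitter, spec.max_cycles)
            reps.append(
                ReplicateSet(
                    sample_id=s,
                    assay_id=a.name,
                    plate_id=plates[s],
                    values=tuple(wells.tolist()),
                )
            )
            collapsed.loc[a.name, s] = float(wells.mean())

    if spec.include_iac:
        # the IAC is one common physical sample re-run on every plate
        iac_loading = rng.normal(0.0, spec.tau)
        for a in spec.assays:
            iac_eps = rng.normal(0.0, a.sigma) if a.sigma > 0 else 0.0
            for p in plate_ids:
                jitter = (
                    rng.normal(0.0, spec.sigma_rep, size=spec.n_replicates)
                    if spec.sigma_rep > 0
                    else np.zeros(spec.n_replicates)
                )
                mean = a.baseline + iac_loading + plate_eff_map[p] + iac_eps
                wells = _clip_cq(mean + jitter, spec.max_cycles)
                reps.append(
                    ReplicateSet(
                        sample_id=spec.iac_sample,
                        assay_id=a.name,
                        plate_id=p,
                        values=tuple(wells.tolist()),
                    )
                )

    sheet = SampleSheet(
        pd.DataFrame(
            {"group": groups, "cohort": spec.cohort_label},
            index=pd.Index(samples, name="sample"),
        )
    )
    truth = {
        "seed": int(seed),
        "tau": spec.tau,
        "sigma_rep": spec.sigma_rep,
        "n_replicates": spec.n_replicates,
        "plate_sd": spec.plate_sd,
        "case_label": spec.case_label,
        "control_label": spec.control_label,
        "assays": {
            a.name: {"baseline": a.baseline, "sigma": a.sigma, "delta": a.delta, "role": a.role}
            for a in spec.assays
        },
        "designated_stable": list(spec.designated_stable),
        "designated_unstable": list(spec.designated_unstable),
        "loading": dict(zip(samples, loading.tolist())),
        "plate_effects": plate_eff_map,
        "plates": plates,
        "group": dict(zip(samples, groups)),
    }
    return SimulatedCohort(
        replicates=tuple(reps),
        matrix=CqMatrix(collapsed, max_cycles=spec.max_cycles),
        sheet=sheet,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# default designs
# ---------------------------------------------------------------------------


def default_validation_spec() -> CohortSpec:
    """Validation-cohort design: 40 cancer / 20 control, triplicates, IAC.

    Candidate-control baselines are the published control-group mean Cq
    values; per-assay sigmas are set so that sqrt(tau^2 + sigma^2) matches
    the published total SDs with tau = 0.5.  The U6-like snoRNA carries the
    published +0.57-cycle case-control shift (more abundant in controls).
    Three targets mimic the quantification experiment: a true-null miRNA
    (miR-93-like), a modestly shifted one (miR-181a-like) and a strongly
    under-expressed one (miR-652-like, +2 cycles in cases).
    """
    assays = (
        AssayModel("miR-16", baseline=15.460, sigma=1.246, delta=0.0, role="stable"),
        AssayModel("miR-425", baseline=20.740, sigma=1.324, delta=0.0, role="stable"),
        AssayModel("U6", baseline=20.661, sigma=0.60, delta=0.569, role="unstable"),
        AssayModel("miR-93", baseline=23.0, sigma=0.5, delta=0.0, role="target"),
        AssayModel("miR-181a", baseline=22.0, sigma=0.7, delta=0.4, role="target"),
        AssayModel("miR-652", baseline=26.0, sigma=0.8, delta=2.0, role="target"),
    )
    return CohortSpec(
        n_case=40,
        n_control=20,
        assays=assays,
        tau=0.5,
        sigma_rep=0.10,
        n_replicates=3,
        samples_per_plate=20,
        plate_sd=0.20,
        include_iac=True,
        cohort_label="validation",
    )


#: Screen panel: the ten near-global-mean miRNAs reported by the profiling
#: arm, in their published stability order (tightest first).
SCREEN_TOP10 = (
    "miR-103",
    "miR-185",
    "miR-532",
    "miR-194",
    "miR-126",
    "miR-155",
    "let-7c",
    "miR-345",
    "miR-425",
    "miR-15b",
)

U6_WELLS = ("U6_w1", "U6_w2", "U6_w3", "U6_w4")
SNORNA_ASSAYS = ("RNU44", "RNU48")
NEGATIVE_CONTROL = "ath-miR-159a"
#: Literature candidates profiled alongside the panel.
LITERATURE_CANDIDATES = ("miR-16", "miR-425", "miR-484", "miR-142-3p", "U6", "RNU44", "RNU48")


def default_screen_spec(panel_seed: int = 2013) -> CohortSpec:
    """Profiling-screen design: 377 miRNAs + U6 x4 + RNU44/RNU48 + negative control.

    10 cancer / 10 control samples, one well per assay.  The ten
    near-global-mean candidates get small, slightly increasing sigmas so a
    clear stability ordering exists; remaining panel miRNAs draw baselines
    from N(28, 3^2) (clipped to [18, 36]) and sigmas from U(0.25, 1.2),
    with ~15 % carrying a disease effect.  ``panel_seed`` fixes the panel's
    *parameters* (it is part of the design, not of the sampling noise).
    """
    rng = np.random.default_rng(panel_seed)
    assays: list[AssayModel] = []
    for i, name in enumerate(SCREEN_TOP10):
        assays.append(
            AssayModel(
                name,
                baseline=float(rng.uniform(20, 26)),
                sigma=0.08 + 0.012 * i,
                delta=0.0,
                role="stable",
            )
        )
    extra_lit = {
        "miR-16": AssayModel("miR-16", baseline=16.0, sigma=0.30, delta=0.0, role="mirna"),
        "miR-484": AssayModel("miR-484", baseline=22.5, sigma=0.45, delta=0.0, role="mirna"),
        "miR-142-3p": AssayModel("miR-142-3p", baseline=19.5, sigma=0.55, delta=0.0, role="mirna"),
    }
    assays.extend(extra_lit.values())
    n_filler = 377 - len(assays)
    for i in range(n_filler):
        delta = float(rng.choice([0.0, rng.normal(0.0, 0.8)], p=[0.85, 0.15]))
        assays.append(
            AssayModel(
                f"miR-sim-{i + 1:03d}",
                baseline=float(np.clip(rng.normal(28.0, 3.0), 18.0, 36.0)),
                sigma=float(rng.uniform(0.25, 1.2)),
                delta=delta,
                role="mirna",
            )
        )
    for w in U6_WELLS:
        assays.append(AssayModel(w, baseline=21.0, sigma=0.55, delta=0.3, role="snoRNA"))
    assays.append(AssayModel("RNU44", baseline=24.5, sigma=0.9, delta=0.0, role="snoRNA"))
    assays.append(AssayModel("RNU48", baseline=23.5, sigma=1.1, delta=0.0, role="snoRNA"))
    assays.append(AssayModel(NEGATIVE_CONTROL, baseline=40.0, sigma=0.0, delta=0.0, role="negative"))
    return CohortSpec(
        n_case=10,
        n_control=10,
        assays=tuple(assays),
        tau=0.5,
        sigma_rep=0.0,
        n_replicates=1,
        samples_per_plate=20,
        plate_sd=0.0,
        include_iac=False,
        cohort_label="screen",
    )


def generate_array_screen(
    spec: CohortSpec | None = None,
    seed: int = 0,
    undetected_fraction: float = 0.10,
) -> SimulatedCohort:
    """Generate the profiling screen (one well per assay; 384 wells per sample).

    ``undetected_fraction`` of the filler panel assays become dropout-prone:
    in those assays each sample is undetected with probability 0.3.  The
    negative-control assay is never detected; designated-stable candidates,
    literature candidates and control RNAs are always detected.
    """
    if spec is None:
        spec = default_screen_spec()
    if len(spec.assays) < 10:
        raise InputError("screen spec needs >= 10 assays")
    if not 0.0 <= undetected_fraction <= 1.0:
        raise InputError("undetected_fraction must be in [0, 1]")
    cohort = generate_cohort(spec, seed)
    cq = cohort.matrix.cq.copy()

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xD10]))
    protected = set(SCREEN_TOP10) | set(U6_WELLS) | set(SNORNA_ASSAYS)
    protected |= set(LITERATURE_CANDIDATES)
    fillers = [
        a.name for a in spec.assays if a.role == "mirna" and a.name not in protected
    ]
    n_dropout = int(round(undetected_fraction * len(fillers)))
    dropout_assays = list(rng.choice(fillers, size=n_dropout, replace=False)) if n_dropout else []
    for a in dropout_assays:
        mask = rng.random(cq.shape[1]) < 0.3
        cq.loc[a, mask] = np.nan
    if NEGATIVE_CONTROL in cq.index:
        cq.loc[NEGATIVE_CONTROL] = np.nan

    truth = dict(cohort.truth)
    truth["dropout_assays"] = sorted(map(str, dropout_assays))
    truth["undetected_fraction"] = undetected_fraction
    return SimulatedCohort(
        replicates=cohort.replicates,
        matrix=CqMatrix(cq, max_cycles=spec.max_cycles),
        sheet=cohort.sheet,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# dilution series
# ---------------------------------------------------------------------------


def generate_dilution_series(
    true_efficiency: float,
    anchor_cq: float = 20.0,
    n_points: int = 5,
    fold: float = 10.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    assay: str = "assay",
) -> pd.DataFrame:
    """Standard-curve input: Cq along a ``fold``-dilution series.

    The exact line is ``Cq = anchor_cq + slope * log10(input)`` with
    ``slope = -1 / log10(1 + E/100)``; successive points are spaced by
    ``log(fold) / log(1 + E/100)`` cycles (log2(10) ~= 3.3219 per 10-fold
    step at 100 % efficiency).  Gaussian noise of SD ``noise_sd`` is added
    per point.  Columns: assay, log10_input, cq.
    """
    if n_points < 3:
        raise InputError("need >= 3 dilution points")
    if fold <= 1:
        raise InputError("fold must be > 1")
    if not 0 < true_efficiency <= 120:
        raise InputError("true_efficiency must be in (0, 120] percent")
    slope = -1.0 / math.log10(1.0 + true_efficiency / 100.0)
    log10_input = -np.arange(n_points) * math.log10(fold)  # neat: starts at undiluted
    cq = anchor_cq + slope * log10_input
    if noise_sd > 0:
        cq = cq + np.random.default_rng(seed).normal(0.0, noise_sd, size=n_points)
    return pd.DataFrame({"assay": assay, "log10_input": log10_input, "cq": cq})
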