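"""Quantification-cycle (Cq / C_T) data structures and I/O.

The central measurement object is :class:`CqMatrix`, an assays x samples
table of quantification cycles.  The quantification cycle is the PCR cycle
at which a well's fluorescence crosses the detection threshold; it is
inversely proportional to the log of the initial template abundance, so one
cycle corresponds to a two-fold change at perfect amplification efficiency.

Undetected wells ("Undetermined" in instrument exports) carry no numeric
Cq; they are stored as NaN and exposed through the ``detected`` mask.

This module also handles the plate-level bookkeeping that precedes any
stability analysis: collapsing replicate wells under a replicate-SD policy,
and inter-assay calibrator (IAC) correction for between-run shifts.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError

__all__ = [
    "CqMatrix",
    "SampleSheet",
    "ReplicateSet",
    "PlateCalibration",
    "read_cq_table",
    "write_cq_table",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_replicate_table",
    "write_replicate_table",
    "collapse_replicates",
    "collapse_assay_wells",
    "calibrations_from_replicates",
    "plates_from_replicates",
    "apply_iac_calibration",
    "summarize_assays",
]

#: Tokens in delimited files that mean "well not called above background".
UNDETERMINED_TOKENS = frozenset({"undetermined", "undet", "na", "nan", ""})

#: Replicate-set standard-deviation policy: sets whose sample SD (cycles)
#: exceeds this are flagged and excluded.
DEFAULT_REPLICATE_SD = 0.28


@dataclass(frozen=True)
class CqMatrix:
    """Assays x samples matrix of quantification-cycle values.

    Parameters
    ----------
    cq
        DataFrame indexed by assay id with sample ids as columns.  NaN
        marks an undetected well; all other values must be finite and lie
        within ``[0, max_cycles]``.
    max_cycles
        Number of PCR cycles run (upper bound on any detected Cq).
    """

    cq: pd.DataFrame
    max_cycles: float = 40.0

    def __post_init__(self) -> None:
        cq = self.cq
        if not isinstance(cq, pd.DataFrame):
            raise InputError("cq must be a pandas DataFrame (assays x samples)")
        if cq.index.has_duplicates:
            dups = cq.index[cq.index.duplicated()].unique().tolist()
            raise InputError(f"duplicate assay ids: {dups}")
        if cq.columns.has_duplicates:
            dups = cq.columns[cq.columns.duplicated()].unique().tolist()
            raise InputError(f"duplicate sample ids: {dups}")
        values = cq.to_numpy(dtype=float)
        finite = np.isfinite(values)
        bad = finite & ((values < 0) | (values > self.max_cycles))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise InputError(
                f"Cq out of range [0, {self.max_cycles}] for assay "
                f"{cq.index[i]!r}, sample {cq.columns[j]!r}: {values[i, j]}"
            )
        if np.isinf(values).any():
            raise InputError("infinite Cq values are not allowed")
        object.__setattr__(self, "cq", cq.astype(float))

    # -- basic views -------------------------------------------------------
    @property
    def assay_ids(self) -> list[str]:
        return list(self.cq.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.cq.columns)

    @property
    def detected(self) -> pd.DataFrame:
        """Boolean mask of wells called above background."""
        return self.cq.notna()

    @property
    def n_assays(self) -> int:
        return self.cq.shape[0]

    @property
    def n_samples(self) -> int:
        return self.cq.shape[1]

    def subset(
        self,
        assays: Sequence[str] | None = None,
        samples: Sequence[str] | None = None,
    ) -> "CqMatrix":
        cq = self.cq
        if assays is not None:
            missing = [a for a in assays if a not in cq.index]
            if missing:
                raise InputError(f"assays not in matrix: {missing}")
            cq = cq.loc[list(assays)]
        if samples is not None:
            missing = [s for s in samples if s not in cq.columns]
            if missing:
                raise InputError(f"samples not in matrix: {missing}")
            cq = cq[list(samples)]
        return CqMatrix(cq, max_cycles=self.max_cycles)

    def values_for(self, assay: str, samples: Sequence[str]) -> np.ndarray:
        """Detected Cq values of one assay over the given samples."""
        if assay not in self.cq.index:
            raise InputError(f"assay {assay!r} not in matrix")
        vals = self.cq.loc[assay, list(samples)].to_numpy(dtype=float)
        return vals[np.isfinite(vals)]

    def equals(self, other: "CqMatrix") -> bool:
        """Equality up to row/column order."""
        if set(self.assay_ids) != set(other.assay_ids):
            return False
        if set(self.sample_ids) != set(other.sample_ids):
            return False
        a = self.cq.sort_index(axis=0).sort_index(axis=1)
        b = other.cq.sort_index(axis=0).sort_index(axis=1)
        return bool(((a == b) | (a.isna() & b.isna())).all().all())


@dataclass(frozen=True)
class SampleSheet:
    """Per-sample group (e.g. cancer/control) and cohort (screen/validation) labels."""

    table: pd.DataFrame  # index: sample_id; columns: group [, cohort]

    def __post_init__(self) -> None:
        t = self.table
        if "group" not in t.columns:
            raise InputError("sample sheet needs a 'group' column")
        if t.index.has_duplicates:
            dups = t.index[t.index.duplicated()].unique().tolist()
            raise InputError(f"duplicate sample ids in sample sheet: {dups}")
        if "cohort" not in t.columns:
            t = t.assign(cohort="default")
        object.__setattr__(self, "table", t)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def groups(self) -> list[str]:
        """Group labels in order of first appearance."""
        return list(dict.fromkeys(self.table["group"]))

    def samples_in(self, group: str, restrict_to: Sequence[str] | None = None) -> list[str]:
        ids = [s for s, g in self.table["group"].items() if g == group]
        if restrict_to is not None:
            allowed = set(restrict_to)
            ids = [s for s in ids if s in allowed]
        return ids

    def group_of(self, sample: str) -> str:
        try:
            return str(self.table.loc[sample, "group"])
        except KeyError:
            raise InputError(f"sample {sample!r} not in sample sheet") from None

    def require_two_groups(
        self, samples: Sequence[str] | None = None, min_per_group: int = 2
    ) -> tuple[str, str]:
        """Return the two group labels, checking minimum sizes."""
        groups = self.groups
        if len(groups) != 2:
            raise InputError(f"expected exactly 2 groups, found {groups}")
        for g in groups:
            n = len(self.samples_in(g, restrict_to=samples))
            if n < min_per_group:
                raise InputError(
                    f"group {g!r} has {n} samples; need >= {min_per_group}"
                )
        return groups[0], groups[1]


@dataclass(frozen=True)
class ReplicateSet:
    """Replicate wells for one (sample, assay) on one plate.

    ``values`` may contain NaN for undetected wells; at least one replicate
    must be detected.  ``max_sd`` is the replicate-SD policy threshold in
    cycles (sample SD, n-1 denominator).
    """

    sample_id: str
    assay_id: str
    values: tuple[float, ...]
    plate_id: str = "plate1"
    max_sd: float = DEFAULT_REPLICATE_SD

    def __post_init__(self) -> None:
        if self.max_sd <= 0:
            raise InputError("replicate SD policy threshold must be > 0")
        if len(self.values) == 0:
            raise InputError(
                f"empty replicate set for ({self.sample_id}, {self.assay_id})"
            )
        object.__setattr__(self, "values", tuple(float(v) for v in self.values))

    @property
    def detected_values(self) -> np.ndarray:
        vals = np.asarray(self.values, dtype=float)
        return vals[np.isfinite(vals)]

    @property
    def mean(self) -> float:
        vals = self.detected_values
        if vals.size == 0:
            raise InputError(
                f"no detected replicate for ({self.sample_id}, {self.assay_id})"
            )
        return float(vals.mean())

    @property
    def sd(self) -> float:
        vals = self.detected_values
        if vals.size <= 1:
            return 0.0
        return float(vals.std(ddof=1))


@dataclass(frozen=True)
class PlateCalibration:
    """Additive between-run correction anchored on the inter-assay calibrator.

    ``offset = plate_mean - global_mean`` is subtracted from every Cq on the
    plate, so within-plate contrasts are untouched and, with the global mean
    defined as the well-count-weighted mean of the plate means, the weighted
    offsets sum to zero.
    """

    plate_id: str
    iac_assay_id: str
    plate_mean: float
    global_mean: float
    n_wells: int = 1

    @property
    def offset(self) -> float:
        return self.plate_mean - self.global_mean


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------

_LONG_REQUIRED = {"sample", "assay", "cq"}


def _parse_cq_token(token: object, where: str) -> float:
    s = str(token).strip()
    if s.lower() in UNDETERMINED_TOKENS:
        return math.nan
    try:
        return float(s)
    except ValueError:
        raise InputError(f"non-numeric Cq value {s!r} at {where}") from None


def _sep_for(path: str) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def read_cq_table(path: str, layout: str = "auto", max_cycles: float = 40.0) -> CqMatrix:
    """Read a delimited Cq table (CSV/TSV).

    Two layouts are supported.  *Wide*: assays as rows (first column holds
    assay ids), samples as columns — the shape instrument exports use.
    *Long*: tidy records with case-insensitive columns
    ``sample, assay, cq`` and optionally ``replicate, plate``; at most one
    record per (sample, assay, replicate).  With ``layout="auto"`` a header
    containing the three long-format column names selects the long reader.

    "Undetermined" (any case) and empty cells map to not-detected.
    """
    raw = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    lowered = [c.strip().lower() for c in raw.columns]
    if layout == "auto":
        layout = "long" if _LONG_REQUIRED.issubset(lowered) else "wide"
    if layout == "long":
        return _long_to_matrix(raw, path, max_cycles)
    if layout != "wide":
        raise InputError(f"unknown layout {layout!r}; use 'wide', 'long' or 'auto'")
    return _wide_to_matrix(raw, path, max_cycles)


def _wide_to_matrix(raw: pd.DataFrame, path: str, max_cycles: float) -> CqMatrix:
    if raw.shape[1] < 2:
        raise InputError(f"{path}: wide layout needs an assay column plus >=1 sample")
    assay_col = raw.columns[0]
    assays = raw[assay_col].astype(str).str.strip()
    if assays.duplicated().any():
        dups = assays[assays.duplicated()].unique().tolist()
        raise InputError(f"{path}: duplicate assay rows {dups}")
    data = {}
    for col in raw.columns[1:]:
        parsed = []
        for row_i, token in enumerate(raw[col], start=2):  # header is line 1
            parsed.append(_parse_cq_token(token, f"{path}:{row_i} (sample {col!r})"))
        data[str(col).strip()] = parsed
    cq = pd.DataFrame(data, index=pd.Index(assays, name="assay"))
    return CqMatrix(cq, max_cycles=max_cycles)


def _long_to_matrix(raw: pd.DataFrame, path: str, max_cycles: float) -> CqMatrix:
    cols = {c.strip().lower(): c for c in raw.columns}
    missing = _LONG_REQUIRED - set(cols)
    if missing:
        raise InputError(f"{path}: long layout missing columns {sorted(missing)}")
    sample = raw[cols["sample"]].astype(str).str.strip()
    assay = raw[cols["assay"]].astype(str).str.strip()
    rep = (
        raw[cols["replicate"]].astype(str).str.strip()
        if "replicate" in cols
        else pd.Series(["1"] * len(raw))
    )
    key = pd.DataFrame({"sample": sample, "assay": assay, "replicate": rep})
    if key.duplicated().any():
        first = key[key.duplicated()].iloc[0]
        raise InputError(
            f"{path}: duplicate record for sample={first['sample']!r}, "
            f"assay={first['assay']!r}, replicate={first['replicate']!r}"
        )
    multi = key.duplicated(subset=["sample", "assay"]).any()
    if multi:
        raise InputError(
            f"{path}: multiple replicates per (sample, assay); read with "
            "read_replicate_table() and collapse_replicates() first"
        )
    cq_vals = [
        _parse_cq_token(token, f"{path}:{row_i}")
        for row_i, token in enumerate(raw[cols["cq"]], start=2)
    ]
    frame = pd.DataFrame({"sample": sample, "assay": assay, "cq": cq_vals})
    wide = frame.pivot(index="assay", columns="sample", values="cq")
    wide.index.name = "assay"
    wide.columns.name = None
    return CqMatrix(wide, max_cycles=max_cycles)


def write_cq_table(m: CqMatrix, path: str, layout: str = "wide") -> None:
    """Write a CqMatrix; undetected wells become "Undetermined"."""
    if layout == "wide":
        out = m.cq.copy().astype(object)
        out[m.cq.isna()] = "Undetermined"
        out.index.name = "assay"
        out.to_csv(path, sep=_sep_for(path))
    elif layout == "long":
        long = (
            m.cq.rename_axis("assay")
            .reset_index()
            .melt(id_vars="assay", var_name="sample", value_name="cq")
        )
        long["cq"] = long["cq"].map(lambda v: "Undetermined" if pd.isna(v) else v)
        long[["sample", "assay", "cq"]].to_csv(path, sep=_sep_for(path), index=False)
    else:
        raise InputError(f"unknown layout {layout!r}")


def read_sample_sheet(path: str) -> SampleSheet:
    raw = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    raw.columns = [c.strip().lower() for c in raw.columns]
    if "sample" not in raw.columns:
        raise InputError(f"{path}: sample sheet needs a 'sample' column")
    table = raw.set_index("sample")
    return SampleSheet(table)


def write_sample_sheet(sheet: SampleSheet, path: str) -> None:
    sheet.table.rename_axis("sample").to_csv(path, sep=_sep_for(path))


def read_replicate_table(path: str, max_sd: float = DEFAULT_REPLICATE_SD) -> list[ReplicateSet]:
    """Read a long table with replicate wells into ReplicateSets.

    Expects case-insensitive columns ``sample, assay, cq`` and optionally
    ``replicate, plate``.  Wells sharing (sample, assay, plate) form one set.
    """
    raw = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    cols = {c.strip().lower(): c for c in raw.columns}
    missing = _LONG_REQUIRED - set(cols)
    if missing:
        raise InputError(f"{path}: replicate table missing columns {sorted(missing)}")
    frame = pd.DataFrame(
        {
            "sample": raw[cols["sample"]].astype(str).str.strip(),
            "assay": raw[cols["assay"]].astype(str).str.strip(),
            "plate": (
                raw[cols["plate"]].astype(str).str.strip()
                if "plate" in cols
                else "plate1"
            ),
            "cq": [
                _parse_cq_token(token, f"{path}:{row_i}")
                for row_i, token in enumerate(raw[cols["cq"]], start=2)
            ],
        }
    )
    sets = []
    for (sample, assay, plate), grp in frame.groupby(
        ["sample", "assay", "plate"], sort=True
    ):
        sets.append(
            ReplicateSet(
                sample_id=sample,
                assay_id=assay,
                plate_id=plate,
                values=tuple(grp["cq"]),
                max_sd=max_sd,
            )
        )
    return sets


def write_replicate_table(reps: Iterable[ReplicateSet], path: str) -> None:
    rows = []
    for r in reps:
        for i, v in enumerate(r.values, start=1):
            rows.append(
                {
                    "sample": r.sample_id,
                    "assay": r.assay_id,
                    "plate": r.plate_id,
                    "replicate": i,
                    "cq": "Undetermined" if not math.isfinite(v) else v,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep=_sep_for(path), index=False)


# ---------------------------------------------------------------------------
# replicate collapsing & calibration
# ---------------------------------------------------------------------------


def collapse_replicates(
    reps: Iterable[ReplicateSet],
    max_cycles: float = 40.0,
) -> tuple[CqMatrix, pd.DataFrame]:
    """Collapse replicate wells to one Cq per (sample, assay).

    Wells sharing a (sample, assay) key — including inter-assay repeats
    across plates — are pooled; the collapsed value is the arithmetic mean
    of the detected replicates (Cq is already a log-scale quantity).  Sets
    whose replicate SD exceeds the policy threshold are flagged and
    *excluded* from the output matrix (no best-2-of-3 rescue).

    Returns the collapsed matrix and a QC report with one row per
    (sample, assay): n wells, mean, SD, threshold and pass flag.
    """
    pooled: dict[tuple[str, str], list[ReplicateSet]] = {}
    for r in reps:
        pooled.setdefault((r.sample_id, r.assay_id), []).append(r)
    if not pooled:
        raise InputError("no replicate sets given")

    qc_rows = []
    cells: dict[tuple[str, str], float] = {}
    for (sample, assay), group in sorted(pooled.items()):
        values = np.concatenate([g.detected_values for g in group])
        if values.size == 0:
            raise InputError(f"no detected replicate for ({sample}, {assay})")
        threshold = min(g.max_sd for g in group)
        mean = float(values.mean())
        sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
        passed = sd <= threshold
        qc_rows.append(
            {
                "sample": sample,
                "assay": assay,
                "plates": ";".join(sorted({g.plate_id for g in group})),
                "n_detected": int(values.size),
                "mean_cq": mean,
                "sd": sd,
                "threshold": threshold,
                "passed": passed,
            }
        )
        if passed:
            cells[(sample, assay)] = mean

    assays = sorted({a for _, a in pooled})
    samples = sorted({s for s, _ in pooled})
    cq = pd.DataFrame(np.nan, index=pd.Index(assays, name="assay"), columns=samples)
    for (sample, assay), v in cells.items():
        cq.loc[assay, sample] = v
    qc = pd.DataFrame(qc_rows)
    return CqMatrix(cq, max_cycles=max_cycles), qc


def collapse_assay_wells(m: CqMatrix, well_to_assay: Mapping[str, str]) -> CqMatrix:
    """Merge replicate assay wells (e.g. four U6 wells) into single assays.

    Wells listed in ``well_to_assay`` are averaged (mean of detected wells)
    into their target assay name; all other rows pass through unchanged.
    """
    cq = m.cq
    keep = cq.loc[[a for a in cq.index if a not in well_to_assay]].copy()
    targets: dict[str, list[str]] = {}
    for well, target in well_to_assay.items():
        if well not in cq.index:
            raise InputError(f"well {well!r} not in matrix")
        targets.setdefault(target, []).append(well)
    merged = {}
    for target, wells in targets.items():
        if target in keep.index:
            raise InputError(f"target assay {target!r} collides with an existing row")
        merged[target] = cq.loc[wells].mean(axis=0, skipna=True)
    out = pd.concat([keep, pd.DataFrame(merged).T])
    out.index.name = "assay"
    return CqMatrix(out, max_cycles=m.max_cycles)


def calibrations_from_replicates(
    reps: Iterable[ReplicateSet], iac_sample: str = "IAC"
) -> list[PlateCalibration]:
    """Derive per-plate calibrations from the inter-assay calibrator wells.

    The IAC is the same physical sample run on every plate; its per-plate
    mean Cq, against the well-count-weighted global mean, gives each
    plate's additive offset.
    """
    per_plate: dict[str, list[float]] = {}
    assay_ids: set[str] = set()
    for r in reps:
        if r.sample_id == iac_sample:
            per_plate.setdefault(r.plate_id, []).extend(r.detected_values.tolist())
            assay_ids.add(r.assay_id)
    if not per_plate:
        raise InputError(f"no wells found for IAC sample {iac_sample!r}")
    weights = {p: len(v) for p, v in per_plate.items()}
    means = {p: float(np.mean(v)) for p, v in per_plate.items()}
    total = sum(weights.values())
    global_mean = sum(means[p] * weights[p] for p in means) / total
    iac_assay = ";".join(sorted(assay_ids))
    return [
        PlateCalibration(
            plate_id=p,
            iac_assay_id=iac_assay,
            plate_mean=means[p],
            global_mean=global_mean,
            n_wells=weights[p],
        )
        for p in sorted(per_plate)
    ]


def plates_from_replicates(
    reps: Iterable[ReplicateSet], iac_sample: str = "IAC"
) -> dict[str, str]:
    """Map each (non-IAC) sample to its plate; a sample on two plates is an error."""
    plates: dict[str, str] = {}
    for r in reps:
        if r.sample_id == iac_sample:
            continue
        known = plates.get(r.sample_id)
        if known is not None and known != r.plate_id:
            raise InputError(
                f"sample {r.sample_id!r} appears on plates {known!r} and {r.plate_id!r}"
            )
        plates[r.sample_id] = r.plate_id
    return plates


def apply_iac_calibration(
    m: CqMatrix,
    calibrations: Sequence[PlateCalibration],
    sample_plates: Mapping[str, str],
    iac_sample: str = "IAC",
) -> CqMatrix:
    """Subtract each plate's IAC offset from its samples' Cq values.

    Cq' = Cq - (plate IAC mean - global IAC mean).  Within-plate contrasts
    are unchanged.  The IAC sample's own column, if present, is removed
    from the output.
    """
    by_plate = {c.plate_id: c for c in calibrations}
    out = m.cq.drop(columns=[iac_sample], errors="ignore").copy()
    for sample in out.columns:
        plate = sample_plates.get(sample)
        if plate is None:
            raise InputError(f"sample {sample!r} has no plate assignment")
        cal = by_plate.get(plate)
        if cal is None:
            raise InputError(f"plate {plate!r} for sample {sample!r} lacks an IAC")
        out[sample] = out[sample] - cal.offset
    return CqMatrix(out, max_cycles=m.max_cycles)


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------


def summarize_assays(
    m: CqMatrix,
    sheet: SampleSheet | None = None,
    decimals: int = 3,
) -> pd.DataFrame:
    """Per-assay Cq summary (mean, SD, min, max, range = max - min).

    With a sample sheet, per-group rows are added below each assay's
    overall row.  Values are reported rounded to ``decimals`` (internal
    computation is at full precision); SD uses the n-1 denominator.
    """
    scopes: list[tuple[str, list[str]]] = [("all", m.sample_ids)]
    if sheet is not None:
        for g in sheet.groups:
            scopes.append((g, sheet.samples_in(g, restrict_to=m.sample_ids)))
    rows = []
    for assay in m.assay_ids:
        for scope, samples in scopes:
            vals = m.values_for(assay, samples)
            if vals.size == 0:
                if scope == "all":
                    raise InputError(f"assay {assay!r} has no detected value")
                continue
            rows.append(
                {
                    "assay": assay,
                    "scope": scope,
                    "n_detected": int(vals.size),
                    "mean": vals.mean(),
                    "sd": vals.std(ddof=1) if vals.size > 1 else 0.0,
                    "min": vals.min(),
                    "max": vals.max(),
                    "range": vals.max() - vals.min(),
                }
            )
    out = pd.DataFrame(rows).set_index(["assay", "scope"])
    return out.round(decimals)
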