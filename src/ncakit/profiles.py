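"""Concentration–time data model, units discipline, BLQ handling and CSV IO.

The central container is :class:`ConcentrationTimeProfile`: the mean
concentration–time course of one analyte in one matrix (plasma or a solid
tissue) for one study arm.  Profiles from serial-sacrifice (destructive
sampling) designs are *mean* profiles — each time point is the average over
``n_animals`` different animals — so a profile carries one concentration per
time, not per subject.

Units are fixed by matrix: ng/mL for fluids (plasma), ng/g for solid
tissues.  Times are hours post (first) dose.  Concentrations below the
assay's lower limit of quantitation (LLOQ) are flagged BLQ and carry no
numeric value until a censoring policy is applied.
"""

from __future__ import annotations

import csv
import io
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DegenerateProfileError,
    DuplicateRecordError,
    SchemaError,
    ValidationError,
)

__all__ = [
    "AnalyteSpec",
    "DoseRegimen",
    "ConcentrationRecord",
    "ConcentrationTimeProfile",
    "FoldChangeRecord",
    "PncCellCounts",
    "METARRESTIN",
    "MATRIX_UNITS",
    "read_profiles",
    "write_profiles",
    "read_fold_changes",
    "read_pnc_counts",
    "censor_blq",
    "to_molar",
    "BLQ_POLICIES",
]

#: Reporting unit per sampling matrix.  Solid tissues are assayed from
#: homogenate and reported per gram of tissue.
MATRIX_UNITS: Mapping[str, str] = {
    "plasma": "ng/mL",
    "tumor": "ng/g",
    "spleen": "ng/g",
    "liver": "ng/g",
}

ROUTES = ("IV", "PO_gavage", "PO_chow")

BLQ_POLICIES = ("pre_tmax_zero_post_tmax_drop", "drop_all", "zero_all")


@dataclass(frozen=True)
class AnalyteSpec:
    """Analyte identity, molar mass and per-matrix assay LLOQs.

    ``lloq_by_matrix`` maps matrix name to the lower limit of quantitation
    in the matrix unit (ng/mL for fluids, ng/g for solids).
    """

    name: str
    molecular_weight: float  # g/mol
    lloq_by_matrix: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.molecular_weight > 0:
            raise ValidationError("molecular_weight must be > 0")
        for matrix, lloq in self.lloq_by_matrix.items():
            if not lloq > 0:
                raise ValidationError(f"LLOQ for {matrix!r} must be > 0")

    def lloq(self, matrix: str) -> float | None:
        return self.lloq_by_matrix.get(matrix)


#: Metarrestin (ML-246).  The bioanalytical method was validated in plasma
#: (LLOQ 1.0 ng/mL) and liver homogenate (5.0 ng/g); the liver LLOQ is
#: applied to the other solid tissues assayed from homogenate.
METARRESTIN = AnalyteSpec(
    name="metarrestin",
    molecular_weight=474.6,
    lloq_by_matrix={"plasma": 1.0, "liver": 5.0, "tumor": 5.0, "spleen": 5.0},
)


@dataclass(frozen=True)
class DoseRegimen:
    """Dosing route, level and schedule.

    ``dose_level`` is mg/kg per administration for IV and gavage; for chow
    dosing it is the nominal daily-equivalent dose (the study formulated
    chow at 70 ppm ≡ 10 mg/kg/day and 170 ppm ≡ 25 mg/kg/day).
    """

    route: str
    dose_level: float  # mg/kg (per dose; daily-equivalent for chow)
    n_doses: int = 1
    dose_interval: float = 24.0  # h

    def __post_init__(self) -> None:
        if self.route not in ROUTES:
            raise ValidationError(f"route must be one of {ROUTES}, got {self.route!r}")
        if self.dose_level < 0:
            raise ValidationError("dose_level must be >= 0")
        if self.n_doses < 1:
            raise ValidationError("n_doses must be >= 1")
        if self.n_doses > 1 and not self.dose_interval > 0:
            raise ValidationError("dose_interval must be > 0 for multiple dosing")

    @property
    def schedule(self) -> str:
        return "single" if self.n_doses == 1 else f"daily×{self.n_doses}"

    @property
    def is_multiple(self) -> bool:
        return self.n_doses > 1


@dataclass(frozen=True)
class ConcentrationRecord:
    """One time point of a mean profile.

    BLQ records carry ``concentration=None``; quantifiable records carry a
    non-negative concentration in the profile's matrix unit.
    """

    time: float  # h since reference dose
    concentration: float | None
    blq: bool = False
    n_animals: int = 1

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValidationError(f"time must be >= 0, got {self.time}")
        if self.blq:
            if self.concentration is not None:
                raise ValidationError("BLQ records carry no numeric concentration")
        else:
            if self.concentration is None:
                raise ValidationError("non-BLQ record needs a concentration")
            if self.concentration < 0:
                raise ValidationError(
                    f"concentration must be >= 0, got {self.concentration}"
                )
        if self.n_animals < 1:
            raise ValidationError("n_animals must be >= 1")


@dataclass(frozen=True)
class ConcentrationTimeProfile:
    """Mean concentration vs time for one (arm, matrix, regimen)."""

    arm_id: str
    matrix: str
    regimen: DoseRegimen
    analyte: AnalyteSpec
    records: tuple[ConcentrationRecord, ...]

    def __post_init__(self) -> None:
        if self.matrix not in MATRIX_UNITS:
            raise ValidationError(
                f"unknown matrix {self.matrix!r}; expected one of {sorted(MATRIX_UNITS)}"
            )
        if not self.records:
            raise ValidationError("profile needs at least one record")
        object.__setattr__(self, "records", tuple(self.records))
        times = [r.time for r in self.records]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValidationError("records must be strictly increasing in time")

    # -- convenience accessors -------------------------------------------

    @property
    def unit(self) -> str:
        return MATRIX_UNITS[self.matrix]

    @property
    def times(self) -> np.ndarray:
        """Times of quantifiable (non-BLQ) records, hours."""
        return np.array([r.time for r in self.records if not r.blq], dtype=float)

    @property
    def concentrations(self) -> np.ndarray:
        """Concentrations of quantifiable records, matrix units."""
        return np.array(
            [r.concentration for r in self.records if not r.blq], dtype=float
        )

    @property
    def n_blq(self) -> int:
        return sum(r.blq for r in self.records)

    def scaled(self, k: float) -> "ConcentrationTimeProfile":
        """Profile with every quantifiable concentration multiplied by ``k``."""
        recs = tuple(
            r if r.blq else replace(r, concentration=r.concentration * k)
            for r in self.records
        )
        return replace(self, records=recs)


# ---------------------------------------------------------------------------
# PD-side record types (consumed by ncakit.markers)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FoldChangeRecord:
    """Per-gene signed fold changes for the marker-selection filter.

    Signed convention: an x-fold *down*-regulation is encoded as −x, never
    as 1/x, so |fc| ≥ 1 always and direction concordance between two
    contrasts is the sign of their product.  Contrasts: ``fc_tm_tv``
    treated tumor vs vehicle tumor, ``fc_pm_pv`` treated pancreas vs
    vehicle pancreas, ``fc_pv_tv`` vehicle pancreas vs vehicle tumor.
    """

    gene_id: str
    fc_tm_tv: float
    fc_pm_pv: float
    fc_pv_tv: float
    p_value: float

    def __post_init__(self) -> None:
        for name in ("fc_tm_tv", "fc_pm_pv", "fc_pv_tv"):
            v = getattr(self, name)
            if abs(v) < 1.0:
                raise ValidationError(
                    f"{name}={v} violates the signed fold-change convention "
                    "(magnitudes < 1 are ratio-encoded)"
                )
        if not 0.0 <= self.p_value <= 1.0:
            raise ValidationError(f"p_value must be in [0, 1], got {self.p_value}")


@dataclass(frozen=True)
class PncCellCounts:
    """Per-sample perinucleolar-compartment (PNC) cell counts.

    ``cells_with_pnc`` counts cells containing at least one PNC among
    ``cells_total`` scored tumor cells.
    """

    sample_id: str
    group: str
    cells_total: int
    cells_with_pnc: int

    def __post_init__(self) -> None:
        if self.cells_total <= 0:
            raise ValidationError("cells_total must be > 0")
        if not 0 <= self.cells_with_pnc <= self.cells_total:
            raise ValidationError("need 0 <= cells_with_pnc <= cells_total")

    @property
    def prevalence(self) -> float:
        return self.cells_with_pnc / self.cells_total


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

REQUIRED_COLUMNS = (
    "arm",
    "matrix",
    "route",
    "dose_mg_per_kg",
    "time_h",
    "conc",
    "blq",
    "n",
)

_OPTIONAL_COLUMNS = ("n_doses", "dose_interval_h", "time_unit")


def _parse_blq(value) -> bool:
    if isinstance(value, str):
        return value.strip() in ("1", "true", "True", "yes")
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return False
    return bool(int(value))


def read_profiles(
    source,
    analyte: AnalyteSpec = METARRESTIN,
    on_unflagged_blq: str = "flag",
) -> list[ConcentrationTimeProfile]:
    """Read concentration–time profiles from a delimited text table.

    ``source`` is a path or file-like object holding a CSV with columns
    ``arm, matrix, route, dose_mg_per_kg, time_h, conc, blq, n`` (optional:
    ``n_doses``, ``dose_interval_h``, ``time_unit`` — minutes are converted
    to hours on read).  Rows are grouped into one profile per
    (arm, matrix), time-sorted and validated.

    A quantifiable concentration below the analyte's matrix LLOQ with the
    BLQ flag unset is a data-entry inconsistency: with
    ``on_unflagged_blq="flag"`` (default) it is auto-flagged BLQ with a
    warning; ``"error"`` raises; ``"keep"`` keeps the value.
    """
    if on_unflagged_blq not in ("flag", "error", "keep"):
        raise ValueError("on_unflagged_blq must be 'flag', 'error' or 'keep'")
    df = pd.read_csv(
        source,
        dtype={"arm": str, "matrix": str, "route": str},
        float_precision="round_trip",
    )
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    # canonicalize time to hours
    if "time_unit" in df.columns:
        unit = df["time_unit"].fillna("h").str.strip().str.lower()
        bad = ~unit.isin(["h", "hr", "hour", "min", "minute"])
        if bad.any():
            raise ValidationError(
                f"unknown time_unit at row(s) {list(df.index[bad])}"
            )
        factor = np.where(unit.str.startswith("min"), 1.0 / 60.0, 1.0)
        df = df.assign(time_h=df["time_h"].astype(float) * factor)

    dup = df.duplicated(subset=["arm", "matrix", "time_h"], keep=False)
    if dup.any():
        keys = df.loc[dup, ["arm", "matrix", "time_h"]].drop_duplicates()
        raise DuplicateRecordError(
            "duplicate (arm, matrix, time) rows: "
            + "; ".join(f"{a}/{m}@{t}h" for a, m, t in keys.itertuples(index=False))
        )

    for idx, row in df.iterrows():
        if float(row["time_h"]) < 0:
            raise ValidationError(f"row {idx}: negative time {row['time_h']}")
        if not _parse_blq(row["blq"]) and not pd.isna(row["conc"]):
            if float(row["conc"]) < 0:
                raise ValidationError(f"row {idx}: negative concentration {row['conc']}")

    profiles: list[ConcentrationTimeProfile] = []
    for (arm, matrix), grp in df.groupby(["arm", "matrix"], sort=True):
        grp = grp.sort_values("time_h")
        route = grp["route"].iloc[0]
        regimen = DoseRegimen(
            route=route,
            dose_level=float(grp["dose_mg_per_kg"].iloc[0]),
            n_doses=int(grp["n_doses"].iloc[0]) if "n_doses" in grp.columns else 1,
            dose_interval=(
                float(grp["dose_interval_h"].iloc[0])
                if "dose_interval_h" in grp.columns
                else 24.0
            ),
        )
        lloq = analyte.lloq(matrix)
        records = []
        for idx, row in grp.iterrows():
            blq = _parse_blq(row["blq"])
            conc = None if blq or pd.isna(row["conc"]) else float(row["conc"])
            if conc is None and not blq:
                raise ValidationError(
                    f"row {idx}: empty concentration without BLQ flag"
                )
            if (
                conc is not None
                and lloq is not None
                and conc < lloq
                and on_unflagged_blq != "keep"
            ):
                msg = (
                    f"row {idx}: concentration {conc} {MATRIX_UNITS[matrix]} is below "
                    f"the {matrix} LLOQ ({lloq}) but not flagged BLQ"
                )
                if on_unflagged_blq == "error":
                    raise ValidationError(msg)
                warnings.warn(msg + "; auto-flagging", UserWarning, stacklevel=2)
                blq, conc = True, None
            records.append(
                ConcentrationRecord(
                    time=float(row["time_h"]),
                    concentration=conc,
                    blq=blq,
                    n_animals=int(row["n"]),
                )
            )
        profiles.append(
            ConcentrationTimeProfile(
                arm_id=str(arm),
                matrix=str(matrix),
                regimen=regimen,
                analyte=analyte,
                records=tuple(records),
            )
        )
    return profiles


def write_profiles(profiles: Iterable[ConcentrationTimeProfile], target) -> None:
    """Write profiles in the same CSV dialect ``read_profiles`` accepts.

    Floats are written with ``repr`` so a read/write round trip preserves
    every value bit-exactly.  BLQ records are written as an empty ``conc``
    field with ``blq=1``.
    """

    def _fmt(x: float) -> str:
        return repr(float(x))

    close = False
    if isinstance(target, (str, bytes)) or hasattr(target, "__fspath__"):
        fh = open(target, "w", newline="")
        close = True
    else:
        fh = target
    try:
        writer = csv.writer(fh)
        writer.writerow(list(REQUIRED_COLUMNS) + ["n_doses", "dose_interval_h"])
        for p in profiles:
            for r in p.records:
                writer.writerow(
                    [
                        p.arm_id,
                        p.matrix,
                        p.regimen.route,
                        _fmt(p.regimen.dose_level),
                        _fmt(r.time),
                        "" if r.blq else _fmt(r.concentration),
                        int(r.blq),
                        r.n_animals,
                        p.regimen.n_doses,
                        _fmt(p.regimen.dose_interval),
                    ]
                )
    finally:
        if close:
            fh.close()


def read_fold_changes(source) -> list[FoldChangeRecord]:
    """Read a fold-change table (gene_id, fc_tm_tv, fc_pm_pv, fc_pv_tv, p_value)."""
    df = pd.read_csv(source)
    required = ("gene_id", "fc_tm_tv", "fc_pm_pv", "fc_pv_tv", "p_value")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    return [
        FoldChangeRecord(
            gene_id=str(row.gene_id),
            fc_tm_tv=float(row.fc_tm_tv),
            fc_pm_pv=float(row.fc_pm_pv),
            fc_pv_tv=float(row.fc_pv_tv),
            p_value=float(row.p_value),
        )
        for row in df.itertuples(index=False)
    ]


def read_pnc_counts(source) -> list[PncCellCounts]:
    """Read a PNC cell-count table (sample_id, group, cells_total, cells_with_pnc)."""
    df = pd.read_csv(source)
    required = ("sample_id", "group", "cells_total", "cells_with_pnc")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    return [
        PncCellCounts(
            sample_id=str(row.sample_id),
            group=str(row.group),
            cells_total=int(row.cells_total),
            cells_with_pnc=int(row.cells_with_pnc),
        )
        for row in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# BLQ censoring and molar conversion
# ---------------------------------------------------------------------------


def censor_blq(
    profile: ConcentrationTimeProfile,
    policy: str = "pre_tmax_zero_post_tmax_drop",
) -> ConcentrationTimeProfile:
    """Resolve BLQ records into a fully numeric profile.

    Policies:

    ``pre_tmax_zero_post_tmax_drop`` (default)
        BLQ records at or before the observed Tmax are set to 0 (absorption
        phase, true value between 0 and LLOQ, zero biases AUC least);
        BLQ records after Tmax are dropped (common NCA practice — a zero on
        the log-linear tail would distort the terminal fit).
    ``drop_all`` / ``zero_all``
        Drop, or zero, every BLQ record.

    Idempotent: applying the same policy twice is a no-op.  Raises
    :class:`DegenerateProfileError` when nothing quantifiable remains.
    """
    if policy not in BLQ_POLICIES:
        raise ValueError(f"policy must be one of {BLQ_POLICIES}, got {policy!r}")
    observed = [(r.time, r.concentration) for r in profile.records if not r.blq]
    if not observed:
        raise DegenerateProfileError(
            f"profile {profile.arm_id}/{profile.matrix}: all records are BLQ"
        )
    out: list[ConcentrationRecord] = []
    if policy == "pre_tmax_zero_post_tmax_drop":
        t_max = max(observed, key=lambda tc: (tc[1], -tc[0]))[0]
    for r in profile.records:
        if not r.blq:
            out.append(r)
            continue
        if policy == "zero_all" or (
            policy == "pre_tmax_zero_post_tmax_drop" and r.time <= t_max
        ):
            out.append(replace(r, blq=False, concentration=0.0))
        # else: drop
    if not any(r.concentration > 0 for r in out):
        raise DegenerateProfileError(
            f"profile {profile.arm_id}/{profile.matrix}: no positive "
            "concentrations after BLQ censoring"
        )
    return replace(profile, records=tuple(out))


def to_molar(conc, analyte: AnalyteSpec = METARRESTIN):
    """Convert a mass concentration (ng/mL or ng/g) to µM.

    ng/mL equals µg/L, so dividing by the molar mass in g/mol gives µmol/L
    directly.  Solid-tissue concentrations (ng/g) are converted assuming a
    tissue density of 1 g/mL; e.g. 6200 ng/g of metarrestin (474.6 g/mol)
    is 13.1 µM.
    """
    arr = np.asarray(conc, dtype=float)
    if np.any(arr < 0):
        raise ValidationError("concentration must be >= 0")
    out = arr / analyte.molecular_weight
    return float(out) if np.isscalar(conc) or arr.ndim == 0 else out
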