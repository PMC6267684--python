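"""Study orchestration and report generation.

Turns a set of concentration–time profiles plus a study configuration into
the two tables a PK study report prints: a parameter table (rows =
NCA parameters, columns = arm/matrix, with "NA" marking parameters not
applicable to a route and "NC" marking parameters that could not be
calculated) and a comparisons table (tissue/plasma ratios, multiple-dose
accumulation ratios, bioavailability, dose-proportionality fits).

Report generation is pure — the same inputs give byte-identical output —
and every number is traceable: the audit log records, per profile, the
BLQ policy, the chosen λz window and the extrapolated AUC fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .errors import NcaKitError, ValidationError
from .nca import (
    NcaOptions,
    NcaResult,
    bioavailability,
    dose_proportionality,
    exposure_ratio,
    run_nca,
)
from .profiles import METARRESTIN, AnalyteSpec, ConcentrationTimeProfile

__all__ = [
    "ComparisonRequest",
    "StudyConfig",
    "ReportBundle",
    "build_report",
    "parameter_table",
    "comparison_table",
    "format_ratio",
]

#: Display precision by comparison kind, matching how such tables are
#: conventionally printed: partitioning ratios to the nearest integer,
#: accumulation ratios to one decimal, bioavailability to two.
RATIO_PRECISION = {"tissue_plasma": 0, "accumulation": 1, "bioavailability": 2}

_PARAM_LABELS = {
    "auc_0_24": "AUC0-24h",
    "auc_0_48": "AUC0-48h",
    "auc_0_inf": "AUC0-inf",
    "t_half": "t1/2 (h)",
    "t_max": "Tmax (h)",
    "c_max": "Cmax",
    "c_mean": "Cmean",
    "cl_p": "CLp (mL/min/kg)",
    "vd_ss": "Vdss (L/kg)",
    "extrapolated_fraction": "AUC extrapolated fraction",
}


@dataclass(frozen=True)
class ComparisonRequest:
    """One cross-profile metric: ``kind`` in {tissue_plasma, accumulation,
    bioavailability}; numerator/denominator are (arm_id, matrix) pairs."""

    kind: str
    numerator: tuple[str, str]
    denominator: tuple[str, str]
    metric: str = "auc_0_24"

    def __post_init__(self) -> None:
        if self.kind not in RATIO_PRECISION:
            raise ValidationError(
                f"kind must be one of {sorted(RATIO_PRECISION)}, got {self.kind!r}"
            )

    @property
    def label(self) -> str:
        n, d = self.numerator, self.denominator
        return f"{self.kind}[{self.metric}] {n[0]}/{n[1]} : {d[0]}/{d[1]}"


@dataclass(frozen=True)
class StudyConfig:
    """Analysis configuration: analyte, NCA options, requested comparisons
    and dose-proportionality sets (each a list of arm_ids whose plasma
    metric is regressed on dose)."""

    analyte: AnalyteSpec = METARRESTIN
    options: NcaOptions = NcaOptions()
    comparisons: tuple[ComparisonRequest, ...] = ()
    dose_proportionality: tuple[tuple[str, tuple[str, ...]], ...] = ()

    @classmethod
    def from_yaml(cls, source) -> "StudyConfig":
        """Load from YAML.  Schema::

            analyte:
              name: metarrestin
              molecular_weight: 474.6
              lloq: {plasma: 1.0, liver: 5.0}
            options:
              blq_policy: pre_tmax_zero_post_tmax_drop
              lambda_selection: best_fit
            comparisons:
              - kind: tissue_plasma
                metric: auc_0_inf
                numerator: {arm: c57_po_3, matrix: liver}
                denominator: {arm: c57_po_3, matrix: plasma}
            dose_proportionality:
              - metric: auc_0_inf
                arms: [c57_po_3, c57_po_10, kpc_sd_25]
        """
        if hasattr(source, "read"):
            raw = yaml.safe_load(source)
        else:
            with open(source) as fh:
                raw = yaml.safe_load(fh)
        raw = raw or {}
        analyte = METARRESTIN
        if "analyte" in raw:
            a = raw["analyte"]
            analyte = AnalyteSpec(
                name=a.get("name", "analyte"),
                molecular_weight=float(a["molecular_weight"]),
                lloq_by_matrix={k: float(v) for k, v in a.get("lloq", {}).items()},
            )
        opts = NcaOptions(**raw.get("options", {}))
        comparisons = tuple(
            ComparisonRequest(
                kind=c["kind"],
                metric=c.get("metric", "auc_0_24"),
                numerator=(c["numerator"]["arm"], c["numerator"].get("matrix", "plasma")),
                denominator=(
                    c["denominator"]["arm"],
                    c["denominator"].get("matrix", "plasma"),
                ),
            )
            for c in raw.get("comparisons", [])
        )
        dp = tuple(
            (d.get("metric", "auc_0_inf"), tuple(d["arms"]))
            for d in raw.get("dose_proportionality", [])
        )
        return cls(
            analyte=analyte, options=opts, comparisons=comparisons,
            dose_proportionality=dp,
        )


def format_ratio(value: float, kind: str) -> str:
    """Render a comparison value at its reporting precision ("5.0", "79")."""
    digits = RATIO_PRECISION[kind]
    if digits == 0:
        return str(int(round(value)))
    return f"{value:.{digits}f}"


def _sig(value, figs: int = 3) -> str:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return ""
    if value == 0:
        return "0"
    return f"{value:.{figs}g}"


def parameter_table(results: Sequence[NcaResult], sig_figs: int = 3) -> pd.DataFrame:
    """Parameter table: rows = NCA parameters, columns = arm/matrix.

    Cells hold the value at ``sig_figs`` significant figures, or "NA"
    (not applicable to the route/design) / "NC" (not calculated, e.g. λz
    unreliable) exactly as flagged by the analysis."""
    table: dict[str, dict[str, str]] = {}
    for res in results:
        col = f"{res.arm_id}/{res.matrix}"
        cells: dict[str, str] = {}
        for param, label in _PARAM_LABELS.items():
            value = getattr(res, param)
            if value is None or (isinstance(value, float) and math.isnan(value)):
                cells[label] = res.flags.get(param, res.flags.get("lambda_z", "NC"))
            else:
                cells[label] = _sig(value, sig_figs)
        table[col] = cells
    return pd.DataFrame(table).reindex([_PARAM_LABELS[p] for p in _PARAM_LABELS])


def comparison_table(
    results: Sequence[NcaResult], config: StudyConfig
) -> pd.DataFrame:
    """Evaluate every requested comparison; unresolvable requests are
    listed with value "NC" and the reason, and the run continues."""
    index = {(r.arm_id, r.matrix): r for r in results}
    rows = []
    for req in config.comparisons:
        row = {"comparison": req.label, "kind": req.kind, "metric": req.metric}
        try:
            num = index.get(req.numerator)
            den = index.get(req.denominator)
            if num is None or den is None:
                missing = req.numerator if num is None else req.denominator
                raise NcaKitError(f"profile {missing[0]}/{missing[1]} not in study")
            if req.kind == "bioavailability":
                f = bioavailability(
                    getattr(num, req.metric), num.dose_level,
                    getattr(den, req.metric), den.dose_level,
                )
                row["value"] = f.value
                row["display"] = format_ratio(f.value, req.kind) + (
                    " (>1)" if f.exceeds_unity else ""
                )
            else:
                value = exposure_ratio(num, den, req.metric)
                row["value"] = value
                row["display"] = format_ratio(value, req.kind)
            row["note"] = ""
        except (NcaKitError, TypeError) as exc:
            row["value"] = float("nan")
            row["display"] = "NC"
            row["note"] = str(exc)
        rows.append(row)

    by_arm = {}
    for r in results:
        if r.matrix == "plasma":
            by_arm[r.arm_id] = r
    for metric, arms in config.dose_proportionality:
        points, missing = [], []
        for arm in arms:
            res = by_arm.get(arm)
            v = getattr(res, metric, None) if res is not None else None
            if v is None:
                missing.append(arm)
            else:
                points.append((res.dose_level, v))
        row = {
            "comparison": f"dose_proportionality[{metric}] {'+'.join(arms)}",
            "kind": "dose_proportionality",
            "metric": metric,
        }
        if missing or len(points) < 2:
            row.update(value=float("nan"), display="NC",
                       note=f"missing arms: {', '.join(missing)}")
        else:
            fit = dose_proportionality(points, metric)
            row.update(
                value=fit.r_squared,
                display=f"R2={fit.r_squared:.3f}, slope={_sig(fit.slope)}",
                note="degenerate (2 doses)" if fit.degenerate else "",
            )
        rows.append(row)
    return pd.DataFrame(rows, columns=["comparison", "kind", "metric", "value", "display", "note"])


@dataclass(frozen=True)
class ReportBundle:
    parameters: pd.DataFrame
    comparisons: pd.DataFrame
    audit: tuple[str, ...]

    def to_markdown(self) -> str:
        lines = ["# NCA report", "", "## Parameters", "", "```"]
        lines.append(self.parameters.to_string())
        lines += ["```", "", "## Comparisons", "", "```"]
        lines.append(
            self.comparisons[["comparison", "display", "note"]].to_string(index=False)
        )
        lines.append("```")
        lines += ["", "## Audit log", ""]
        lines += [f"- {entry}" for entry in self.audit]
        return "\n".join(lines) + "\n"

    def write(self, out_dir) -> None:
        import pathlib

        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.parameters.to_csv(out / "parameters.csv")
        self.comparisons.to_csv(out / "comparisons.csv", index=False)
        (out / "report.md").write_text(self.to_markdown())


def build_report(
    profiles: Sequence[ConcentrationTimeProfile],
    config: StudyConfig = StudyConfig(),
    results: Sequence[NcaResult] | None = None,
) -> ReportBundle:
    """Run NCA on every profile (unless precomputed ``results`` are
    supplied) and assemble the parameter and comparison tables."""
    audit = []
    if results is None:
        results = []
        for p in profiles:
            res = run_nca(p, config.options)
            results.append(res)
            win = (
                f"lambda window {res.lambda_window[0]:g}-{res.lambda_window[1]:g} h "
                f"({res.lambda_points} pts, adjR2={res.lambda_r2_adj:.4f})"
                if res.lambda_window is not None
                else "lambda not estimated"
            )
            extrap = (
                f", extrapolated fraction {res.extrapolated_fraction:.3f}"
                if res.extrapolated_fraction is not None
                else ""
            )
            audit.append(
                f"{p.arm_id}/{p.matrix}: blq_policy={config.options.blq_policy}, "
                f"{win}{extrap}"
            )
    else:
        results = list(results)
        audit.append("comparisons computed from precomputed NCA results")
    return ReportBundle(
        parameters=parameter_table(results),
        comparisons=comparison_table(results, config),
        audit=tuple(audit),
    )
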