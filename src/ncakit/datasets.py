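"""Packaged example data: published summary PK parameters for metarrestin
in mice.

These are the reported exposure parameters (mean-profile NCA, n=3 animals
per time point) for the single/multiple-dose metarrestin mouse studies:
wild-type C57BL/6 mice after a single 3 mg/kg IV bolus or 3/10 mg/kg oral
gavage, and tumor-bearing KPC mice after 25 mg/kg oral gavage (single dose,
and day 14 of daily dosing) plus a 10 mg/kg/day drug-in-chow steady-state
arm.  Raw concentration–time measurements were not published, but every
derived quantity (clearance, bioavailability, tissue/plasma partitioning,
accumulation, molar conversions, dose proportionality) is recomputable
from these summaries; that is what :mod:`ncakit` demonstrations and checks
use them for.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .nca import NcaResult

__all__ = [
    "summary_parameters",
    "results_from_summary",
    "exposure_response_cohorts",
    "TUMOR_CONC_24H_SD25_NG_PER_G",
    "PNC_PREVALENCE_VEHICLE",
    "PNC_PREVALENCE_TREATED",
    "CHOW_PLASMA_AUC_0_24",
]

#: Mean intratumor metarrestin concentration 24 h after a single 25 mg/kg
#: oral dose (ng/g; 6.2 µg/g ≈ 13 µM at MW 474.6 and density 1 g/mL).
TUMOR_CONC_24H_SD25_NG_PER_G = 6200.0

#: Observed PNC prevalence (fraction of tumor cells with ≥1 PNC) in
#: vehicle- and metarrestin-treated tumors (14 days, 25 mg/kg/day PO).
PNC_PREVALENCE_VEHICLE = 0.382
PNC_PREVALENCE_TREATED = 0.098

#: Steady-state plasma AUC0–24h on drug-in-chow dosing at 10 mg/kg/day
#: (ng·h/mL), comparable to the 4520 ng·h/mL single-gavage value.
CHOW_PLASMA_AUC_0_24 = 4160.0

# One row per reported (arm, matrix) column; None where the source table
# shows NA (not available) or NC (not calculated).
_ROWS = [
    # arm, matrix, route, dose, n_doses, auc_0_24, auc_0_48, auc_0_inf, t_half, t_max, c_max
    ("c57_iv_3", "plasma", "IV", 3.0, 1, 1010.0, None, 1040.0, 5.0, None, None),
    ("c57_po_3", "plasma", "PO_gavage", 3.0, 1, 823.0, None, 871.0, 5.4, 2.0, 55.7),
    ("c57_po_3", "liver", "PO_gavage", 3.0, 1, 66100.0, None, 68600.0, 4.7, 1.0, 5420.0),
    ("c57_po_10", "plasma", "PO_gavage", 10.0, 1, 4520.0, None, 4790.0, 5.6, 2.0, 349.0),
    ("c57_po_10", "liver", "PO_gavage", 10.0, 1, 276000.0, None, 281000.0, 4.1, 2.0, 21400.0),
    ("kpc_sd_25", "plasma", "PO_gavage", 25.0, 1, 12100.0, None, 14400.0, 8.5, 6.0, 810.0),
    ("kpc_sd_25", "tumor", "PO_gavage", 25.0, 1, 232000.0, None, None, None, 6.0, 14000.0),
    ("kpc_sd_25", "spleen", "PO_gavage", 25.0, 1, 396000.0, None, 495000.0, 9.7, 6.0, 25000.0),
    ("kpc_sd_25", "liver", "PO_gavage", 25.0, 1, 536000.0, None, 653000.0, 9.0, 6.0, 34200.0),
    ("kpc_md_25", "plasma", "PO_gavage", 25.0, 14, 31500.0, 38400.0, 39300.0, 8.2, 3.0, 2000.0),
    ("kpc_md_25", "tumor", "PO_gavage", 25.0, 14, 1150000.0, 1810000.0, 2090000.0, 18.0, 6.0, 65000.0),
    ("kpc_md_25", "spleen", "PO_gavage", 25.0, 14, 959000.0, 1220000.0, 1250000.0, 8.2, 6.0, 62400.0),
    ("kpc_md_25", "liver", "PO_gavage", 25.0, 14, 987050.0, 1290000.0, 1350000.0, 9.6, 6.0, 59500.0),
    ("chow_10", "plasma", "PO_chow", 10.0, 10, 4160.0, None, None, None, None, None),
]

_COLUMNS = [
    "arm_id",
    "matrix",
    "route",
    "dose_mg_per_kg",
    "n_doses",
    "auc_0_24",
    "auc_0_48",
    "auc_0_inf",
    "t_half",
    "t_max",
    "c_max",
]


def summary_parameters() -> pd.DataFrame:
    """Published summary exposure parameters, one row per (arm, matrix).

    AUCs in ng·h/mL (plasma) or ng·h/g (solids), times in hours,
    concentrations in ng/mL or ng/g.  NaN marks parameters the source
    reported as NA/NC.
    """
    return pd.DataFrame(_ROWS, columns=_COLUMNS).astype(
        {c: float for c in _COLUMNS[3:4] + _COLUMNS[5:]}
    )


def results_from_summary() -> list[NcaResult]:
    """The summary parameters repackaged as :class:`~ncakit.nca.NcaResult`
    objects, so cross-profile comparisons (tissue/plasma ratios,
    accumulation, bioavailability) run on the published values exactly as
    they would on freshly computed ones.  Cmean is AUC0–24h/24."""
    out = []
    for row in _ROWS:
        arm, matrix, route, dose, n_doses, a24, a48, ainf, th, tmax, cmax = row
        out.append(
            NcaResult(
                arm_id=arm,
                matrix=matrix,
                route=route,
                dose_level=dose,
                n_doses=n_doses,
                auc_0_t=a24 if a24 is not None else np.nan,
                t_last=24.0,
                c_last=np.nan,
                c_max=cmax if cmax is not None else np.nan,
                t_max=tmax if tmax is not None else np.nan,
                auc_0_24=a24,
                auc_0_48=a48,
                auc_0_inf=ainf,
                t_half=th,
                lambda_z=None if th is None else 0.693 / th,
                c_mean=None if a24 is None else a24 / 24.0,
            )
        )
    return out


def exposure_response_cohorts() -> dict[str, list[tuple[str, float]]]:
    """Cohorts of the intratumor exposure–response comparison: marker →
    [(cohort id, intratumor AUC0–24h ng·h/mL)].  Vehicle cohorts carry
    zero exposure."""
    return {
        "FOXA1": [
            ("vehicle", 0.0),
            ("chow_25", 396000.0),
            ("gavage_md_25", 1150000.0),
        ],
        "FOXO6": [
            ("vehicle", 0.0),
            ("chow_10", 80600.0),
            ("chow_10_ss", 96100.0),
        ],
    }
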