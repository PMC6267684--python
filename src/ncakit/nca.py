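"""Non-compartmental PK parameter estimation.

Implements the standard NCA toolbox for mean concentration–time profiles:
linear-trapezoidal AUC (with partial AUCs by boundary interpolation),
terminal-slope (λz) estimation by best-fit log-linear regression,
extrapolation to infinity, Cmax/Tmax, plasma clearance and steady-state
volume of distribution for IV bolus data, oral bioavailability, exposure
ratios across profiles, and dose-proportionality regression.

Conventions follow common practice for rodent serial-sacrifice studies:
profiles are naive-pooled means (n animals per time point), AUC uses the
linear trapezoidal rule, λz comes from an ordinary least-squares fit of
ln C vs t over a "best fit" suffix window (maximum adjusted R², ties broken
toward more points), and t½ = 0.693/λz.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import (
    DegenerateProfileError,
    ExtrapolationError,
    InsufficientDataError,
    NcaKitError,
    RouteError,
    ValidationError,
)
from .profiles import ConcentrationTimeProfile, censor_blq

__all__ = [
    "LambdaZFit",
    "NcaOptions",
    "NcaResult",
    "BioavailabilityResult",
    "DoseProportionalityFit",
    "auc_linear_trapezoid",
    "aumc_linear_trapezoid",
    "estimate_lambda_z",
    "half_life",
    "auc_to_infinity",
    "cmax_tmax",
    "clearance_iv",
    "vdss_iv",
    "bioavailability",
    "exposure_ratio",
    "dose_proportionality",
    "run_nca",
]

#: Numerator of the half-life formula.  The conventional rounded constant
#: 0.693 is used rather than ln 2 (difference < 0.03%), matching how the
#: derived half-lives in the source tables were computed.
HALF_LIFE_NUMERATOR = 0.693

#: Two best-fit λz windows whose adjusted R² differ by less than this are
#: treated as tied; the tie goes to the window with more points.
LAMBDA_R2_TIE_TOL = 1e-4


def _profile_arrays(profile: ConcentrationTimeProfile) -> tuple[np.ndarray, np.ndarray]:
    if profile.n_blq:
        raise ValidationError(
            "profile still contains BLQ records; apply censor_blq first"
        )
    return profile.times, profile.concentrations


# ---------------------------------------------------------------------------
# AUC / AUMC
# ---------------------------------------------------------------------------


def _trapezoid_clipped(
    t: np.ndarray, y: np.ndarray, t_start: float, t_end: float
) -> float:
    if t_start >= t_end:
        raise ValidationError(f"need t_start < t_end, got [{t_start}, {t_end}]")
    if t_start < t[0] - 1e-12 or t_end > t[-1] + 1e-12:
        raise ExtrapolationError(
            f"interval [{t_start}, {t_end}] h outside sampled range "
            f"[{t[0]}, {t[-1]}] h; partial AUCs are never extrapolated"
        )
    t_start, t_end = max(t_start, t[0]), min(t_end, t[-1])
    y_start = float(np.interp(t_start, t, y))
    y_end = float(np.interp(t_end, t, y))
    inside = (t > t_start) & (t < t_end)
    tt = np.concatenate(([t_start], t[inside], [t_end]))
    yy = np.concatenate(([y_start], y[inside], [y_end]))
    return float(np.trapezoid(yy, tt))


def auc_linear_trapezoid(
    profile: ConcentrationTimeProfile,
    t_start: float | None = None,
    t_end: float | None = None,
) -> float:
    """Linear-trapezoidal AUC over ``[t_start, t_end]`` (ng·h/mL or ng·h/g).

    Defaults to the full sampled span.  Interval endpoints falling between
    samples are obtained by linear interpolation between the bracketing
    samples; intervals outside the sampled range raise
    :class:`ExtrapolationError`.  Additive over adjacent subintervals.
    """
    t, c = _profile_arrays(profile)
    if t.size < 2:
        raise InsufficientDataError("AUC needs at least two records")
    t_start = float(t[0]) if t_start is None else float(t_start)
    t_end = float(t[-1]) if t_end is None else float(t_end)
    return _trapezoid_clipped(t, c, t_start, t_end)


def aumc_linear_trapezoid(
    profile: ConcentrationTimeProfile,
    t_start: float | None = None,
    t_end: float | None = None,
) -> float:
    """Linear-trapezoidal area under the first-moment curve t·C(t)."""
    t, c = _profile_arrays(profile)
    if t.size < 2:
        raise InsufficientDataError("AUMC needs at least two records")
    t_start = float(t[0]) if t_start is None else float(t_start)
    t_end = float(t[-1]) if t_end is None else float(t_end)
    return _trapezoid_clipped(t, t * c, t_start, t_end)


# ---------------------------------------------------------------------------
# Terminal slope
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LambdaZFit:
    """Terminal-phase log-linear regression result.

    ``lambda_z`` is None when no acceptable (negative-slope) window exists;
    downstream extrapolation is then disabled.
    """

    lambda_z: float | None
    n_points: int
    r2_adj: float
    window: tuple[float, float]  # (first, last) time in the fitted window, h
    intercept: float  # ln-concentration intercept at t=0

    @property
    def estimable(self) -> bool:
        return self.lambda_z is not None


def _loglinear_ols(t: np.ndarray, lnc: np.ndarray) -> tuple[float, float, float]:
    """OLS of ln C on t: returns (slope, intercept, adjusted R²)."""
    n = t.size
    tbar, ybar = t.mean(), lnc.mean()
    sxx = float(((t - tbar) ** 2).sum())
    sxy = float(((t - tbar) * (lnc - ybar)).sum())
    slope = sxy / sxx
    intercept = ybar - slope * tbar
    ss_tot = float(((lnc - ybar) ** 2).sum())
    ss_res = float(((lnc - (intercept + slope * t)) ** 2).sum())
    r2 = 1.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return slope, intercept, r2_adj


def estimate_lambda_z(
    profile: ConcentrationTimeProfile,
    selection: str = "best_fit",
    min_points: int = 3,
    window: tuple[float, float] | None = None,
) -> LambdaZFit:
    """Estimate the terminal rate constant λz by log-linear regression.

    ``selection="best_fit"`` scans every suffix window of ≥ ``min_points``
    positive-concentration records (the Cmax record itself is excluded for
    extravascular routes, included for IV bolus) and returns the window
    maximizing adjusted R²; near-ties (ΔR²adj < 1e-4) are broken toward the
    window with more points.  ``selection="manual"`` fits the caller-given
    ``window=(t_lo, t_hi)`` as-is.

    λz is the negated slope and must be positive; windows with nonpositive
    slope are unacceptable.  If no window qualifies, the fit is returned
    flagged not-estimable rather than raising.
    """
    t, c = _profile_arrays(profile)
    pos = c > 0
    t, c = t[pos], c[pos]
    if selection == "manual":
        if window is None:
            raise ValueError("manual selection needs window=(t_lo, t_hi)")
        mask = (t >= window[0] - 1e-12) & (t <= window[1] + 1e-12)
        cand_t, cand_c = t[mask], c[mask]
        if cand_t.size < min_points:
            raise InsufficientDataError(
                f"only {cand_t.size} positive records inside window {window}"
            )
        slope, intercept, r2_adj = _loglinear_ols(cand_t, np.log(cand_c))
        lam = -slope if slope < 0 else None
        return LambdaZFit(lam, cand_t.size, r2_adj,
                          (float(cand_t[0]), float(cand_t[-1])), intercept)
    if selection != "best_fit":
        raise ValueError(f"selection must be 'best_fit' or 'manual', got {selection!r}")

    i_max = int(np.argmax(c))  # earliest maximum
    start = i_max if profile.regimen.route == "IV" else i_max + 1
    cand_t, cand_c = t[start:], c[start:]
    if cand_t.size < min_points:
        raise InsufficientDataError(
            f"only {cand_t.size} usable terminal records "
            f"(need >= {min_points} after Tmax)"
        )
    lnc = np.log(cand_c)
    fits = []
    for j in range(cand_t.size - min_points + 1):
        slope, intercept, r2_adj = _loglinear_ols(cand_t[j:], lnc[j:])
        if slope < 0:
            fits.append((r2_adj, cand_t.size - j, slope, intercept, j))
    if not fits:
        # e.g. still-rising profile: λ not estimable, extrapolation disabled
        return LambdaZFit(None, 0, math.nan, (math.nan, math.nan), math.nan)
    best_r2 = max(f[0] for f in fits)
    acceptable = [f for f in fits if f[0] >= best_r2 - LAMBDA_R2_TIE_TOL]
    r2_adj, n_pts, slope, intercept, j = max(acceptable, key=lambda f: f[1])
    return LambdaZFit(
        -slope, n_pts, r2_adj, (float(cand_t[j]), float(cand_t[-1])), intercept
    )


def half_life(lambda_z: float) -> float:
    """Apparent terminal half-life, 0.693/λz (hours)."""
    if not lambda_z > 0:
        raise ValidationError(f"lambda_z must be > 0, got {lambda_z}")
    return HALF_LIFE_NUMERATOR / lambda_z


def auc_to_infinity(
    auc_0_t: float, c_last: float, lambda_z: float
) -> tuple[float, float]:
    """AUC extrapolated to infinity and the extrapolated fraction.

    AUC0–∞ = AUC0–t + C_last/λz; the second return value is the fraction of
    AUC0–∞ contributed by the extrapolated tail.
    """
    if not lambda_z > 0:
        raise ValidationError(f"lambda_z must be > 0, got {lambda_z}")
    if c_last < 0:
        raise ValidationError("c_last must be >= 0")
    tail = c_last / lambda_z
    auc_inf = auc_0_t + tail
    return auc_inf, (tail / auc_inf if auc_inf > 0 else 0.0)


def cmax_tmax(profile: ConcentrationTimeProfile) -> tuple[float, float]:
    """Maximum observed concentration and its time; ties go to the earliest."""
    t, c = _profile_arrays(profile)
    if t.size == 0:
        raise DegenerateProfileError("no quantifiable records")
    i = int(np.argmax(c))  # argmax returns the first (earliest) maximum
    return float(c[i]), float(t[i])


# ---------------------------------------------------------------------------
# Dose-normalized parameters
# ---------------------------------------------------------------------------


def clearance_iv(dose_mg_per_kg: float, auc_0_inf: float, route: str = "IV") -> float:
    """Plasma clearance after IV bolus, mL/min/kg.

    CL = dose/AUC0–∞; with dose in ng/kg (mg/kg × 10⁶) and AUC in ng·h/mL
    this yields mL/h/kg, divided by 60 for mL/min/kg.
    """
    if route != "IV":
        raise RouteError(f"clearance is an IV-only parameter (route={route!r})")
    if not auc_0_inf > 0:
        raise ValidationError("auc_0_inf must be > 0")
    return dose_mg_per_kg * 1e6 / auc_0_inf / 60.0


def vdss_iv(
    dose_mg_per_kg: float,
    profile: ConcentrationTimeProfile,
    lambda_z: float,
    route: str = "IV",
) -> float:
    """Steady-state volume of distribution after IV bolus, L/kg.

    Vdss = CL × MRT with MRT = AUMC0–∞/AUC0–∞.  Both moments use the
    linear trapezoid over the sampled span plus the analytic tail
    corrections C_last/λ (AUC) and C_last·(t_last/λ + 1/λ²) (AUMC).
    The profile should include its t=0 anchor (back-extrapolated C0).
    """
    if route != "IV":
        raise RouteError(f"Vdss is an IV-only parameter (route={route!r})")
    if not lambda_z > 0:
        raise ValidationError("lambda_z must be > 0")
    t, c = _profile_arrays(profile)
    pos = np.nonzero(c > 0)[0]
    if pos.size == 0:
        raise DegenerateProfileError("no positive concentrations")
    t_last, c_last = float(t[pos[-1]]), float(c[pos[-1]])
    auc_inf = auc_linear_trapezoid(profile) + c_last / lambda_z
    aumc_inf = aumc_linear_trapezoid(profile) + c_last * (
        t_last / lambda_z + 1.0 / lambda_z**2
    )
    mrt = aumc_inf / auc_inf
    cl = clearance_iv(dose_mg_per_kg, auc_inf)  # mL/min/kg
    return cl * 60.0 * mrt / 1000.0  # L/kg


@dataclass(frozen=True)
class BioavailabilityResult:
    """Dose-normalized oral/IV AUC ratio; flagged when it exceeds unity."""

    value: float

    @property
    def exceeds_unity(self) -> bool:
        return self.value > 1.0


def bioavailability(
    auc_po: float, dose_po: float, auc_iv: float, dose_iv: float
) -> BioavailabilityResult:
    """Absolute oral bioavailability F = (AUC_PO/dose_PO)/(AUC_IV/dose_IV).

    Values above 1 (possible with dose-dependent absorption or clearance)
    are reported as-is and flagged via ``exceeds_unity``.
    """
    if not (auc_iv > 0 and dose_iv > 0 and dose_po > 0):
        raise ValidationError("IV AUC and both doses must be > 0")
    return BioavailabilityResult((auc_po / dose_po) / (auc_iv / dose_iv))


def exposure_ratio(numerator: "NcaResult", denominator: "NcaResult", metric: str) -> float:
    """Ratio of one exposure metric across two NCA results.

    ``metric`` is an :class:`NcaResult` field name (``auc_0_24``,
    ``auc_0_inf``, ``c_mean`` ...).  Used for tissue/plasma partitioning
    ratios and multiple-dose:single-dose accumulation ratios.
    """
    num = getattr(numerator, metric, None)
    den = getattr(denominator, metric, None)
    if num is None or den is None:
        raise NcaKitError(
            f"metric {metric!r} missing on "
            f"{'numerator' if num is None else 'denominator'}"
        )
    if not den > 0:
        raise ValidationError(f"denominator {metric} must be > 0")
    return num / den


@dataclass(frozen=True)
class DoseProportionalityFit:
    """OLS line of an exposure metric against dose."""

    metric: str
    points: tuple[tuple[float, float], ...]
    slope: float
    intercept: float
    r_squared: float

    @property
    def degenerate(self) -> bool:
        """True when only two distinct doses support the fit (R²=1 trivially)."""
        return len({d for d, _ in self.points}) < 3


def dose_proportionality(
    points: Sequence[tuple[float, float]], metric: str = "auc_0_inf"
) -> DoseProportionalityFit:
    """Fit metric = slope·dose + intercept by ordinary least squares."""
    doses = np.array([p[0] for p in points], dtype=float)
    values = np.array([p[1] for p in points], dtype=float)
    if np.unique(doses).size < 2:
        raise ValidationError("dose proportionality needs >= 2 distinct doses")
    slope, intercept = np.polyfit(doses, values, 1)
    fitted = slope * doses + intercept
    ss_tot = float(((values - values.mean()) ** 2).sum())
    ss_res = float(((values - fitted) ** 2).sum())
    r2 = 1.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    return DoseProportionalityFit(
        metric=metric,
        points=tuple((float(d), float(v)) for d, v in points),
        slope=float(slope),
        intercept=float(intercept),
        r_squared=float(r2),
    )


# ---------------------------------------------------------------------------
# Full NCA
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NcaOptions:
    """Knobs for :func:`run_nca`.

    ``estimate_lambda=None`` means route-dependent: λz is attempted for IV
    and gavage profiles but skipped for chow steady-state windows, where
    the quasi-continuous intake leaves no terminal phase to fit.
    """

    blq_policy: str = "pre_tmax_zero_post_tmax_drop"
    lambda_selection: str = "best_fit"
    lambda_min_points: int = 3
    lambda_window: tuple[float, float] | None = None
    partial_aucs: tuple[float, ...] = (24.0, 48.0)
    estimate_lambda: bool | None = None


@dataclass(frozen=True)
class NcaResult:
    """The full NCA parameter set for one profile.

    Optional parameters are ``None`` when not computed; ``flags`` maps the
    parameter name to "NA" (not applicable, e.g. CL for an oral arm) or
    "NC" (not calculated, e.g. t½ when λz was not estimable).
    """

    arm_id: str
    matrix: str
    route: str
    dose_level: float
    n_doses: int

    auc_0_t: float
    t_last: float
    c_last: float
    c_max: float
    t_max: float

    auc_0_24: float | None = None
    auc_0_48: float | None = None
    auc_0_inf: float | None = None
    extrapolated_fraction: float | None = None
    lambda_z: float | None = None
    lambda_points: int | None = None
    lambda_r2_adj: float | None = None
    lambda_window: tuple[float, float] | None = None
    t_half: float | None = None
    c_mean: float | None = None
    cl_p: float | None = None
    vd_ss: float | None = None
    flags: dict = field(default_factory=dict)

    PARAMETER_ORDER = (
        "auc_0_24",
        "auc_0_48",
        "auc_0_inf",
        "t_half",
        "t_max",
        "c_max",
        "c_mean",
        "cl_p",
        "vd_ss",
        "auc_0_t",
        "extrapolated_fraction",
        "lambda_z",
        "lambda_r2_adj",
    )


def _back_extrapolate_c0(t: np.ndarray, c: np.ndarray) -> float:
    """C(0) for IV bolus, log-linear through the first two positive samples.

    Falls back to the first observed concentration when the profile starts
    flat or rising (back-extrapolation would be meaningless).
    """
    pos = np.nonzero(c > 0)[0]
    if pos.size < 2:
        return float(c[pos[0]]) if pos.size else 0.0
    i, j = pos[0], pos[1]
    if c[j] >= c[i]:
        return float(c[i])
    slope = (math.log(c[j]) - math.log(c[i])) / (t[j] - t[i])
    return float(math.exp(math.log(c[i]) - slope * t[i]))


def run_nca(
    profile: ConcentrationTimeProfile, options: NcaOptions = NcaOptions()
) -> NcaResult:
    """Full non-compartmental analysis of one profile.

    Composes BLQ censoring, C(0) handling (log-linear back-extrapolation
    for single-dose IV bolus, zero for single-dose extravascular), AUC0–t,
    partial AUCs with interpolated boundaries, best-fit λz, t½, AUC0–∞,
    Cmean = AUC0–24h/24, and — for single-dose IV — CLp and Vdss.  Partial
    results are returned with per-parameter flags rather than failing.
    """
    regimen = profile.regimen
    clean = censor_blq(profile, options.blq_policy)
    c_max, t_max = cmax_tmax(clean)
    t, c = _profile_arrays(clean)

    flags: dict[str, str] = {}
    # anchor the profile at t=0 for single-dose AUC
    if t[0] > 0 and regimen.n_doses == 1:
        if regimen.route == "IV":
            c0 = _back_extrapolate_c0(t, c)
        else:
            c0 = 0.0
        t = np.concatenate(([0.0], t))
        c = np.concatenate(([c0], c))

    pos = np.nonzero(c > 0)[0]
    t_last, c_last = float(t[pos[-1]]), float(c[pos[-1]])
    auc_0_t = float(np.trapezoid(c, t))

    # terminal slope
    estimate_lambda = options.estimate_lambda
    if estimate_lambda is None:
        estimate_lambda = regimen.route != "PO_chow"
    lam_fit = None
    if estimate_lambda:
        try:
            lam_fit = estimate_lambda_z(
                clean,
                selection=options.lambda_selection,
                min_points=options.lambda_min_points,
                window=options.lambda_window,
            )
        except InsufficientDataError:
            flags["lambda_z"] = "NC"
    else:
        flags["lambda_z"] = "NA"

    lambda_z = lam_fit.lambda_z if lam_fit is not None else None
    if lam_fit is not None and not lam_fit.estimable:
        flags["lambda_z"] = "NC"

    t_half_v = auc_inf = extrap = None
    if lambda_z is not None:
        t_half_v = half_life(lambda_z)
        auc_inf, extrap = auc_to_infinity(auc_0_t, c_last, lambda_z)
    else:
        flags.setdefault("t_half", flags.get("lambda_z", "NC"))
        flags.setdefault("auc_0_inf", flags.get("lambda_z", "NC"))

    # partial AUCs (no extrapolation beyond t_last)
    partial: dict[float, float | None] = {}
    for t_end in options.partial_aucs:
        if t[0] <= 0.0 and t[-1] >= t_end:
            partial[t_end] = _trapezoid_clipped(t, c, 0.0, t_end)
        else:
            partial[t_end] = None
            flags[f"auc_0_{int(t_end)}"] = "NA"
    auc_0_24 = partial.get(24.0)
    c_mean = auc_0_24 / 24.0 if auc_0_24 is not None else None

    cl_p = vd_ss = None
    if regimen.route == "IV" and regimen.n_doses == 1:
        if auc_inf is not None:
            cl_p = clearance_iv(regimen.dose_level, auc_inf)
            aumc_tail = c_last * (t_last / lambda_z + 1.0 / lambda_z**2)
            aumc_inf = float(np.trapezoid(t * c, t)) + aumc_tail
            mrt = aumc_inf / auc_inf
            vd_ss = cl_p * 60.0 * mrt / 1000.0
        else:
            flags["cl_p"] = flags["vd_ss"] = "NC"
    else:
        flags["cl_p"] = flags["vd_ss"] = "NA"

    return NcaResult(
        arm_id=profile.arm_id,
        matrix=profile.matrix,
        route=regimen.route,
        dose_level=regimen.dose_level,
        n_doses=regimen.n_doses,
        auc_0_t=auc_0_t,
        t_last=t_last,
        c_last=c_last,
        c_max=c_max,
        t_max=t_max,
        auc_0_24=auc_0_24,
        auc_0_48=partial.get(48.0),
        auc_0_inf=auc_inf,
        extrapolated_fraction=extrap,
        lambda_z=lambda_z,
        lambda_points=lam_fit.n_points if lam_fit is not None else None,
        lambda_r2_adj=lam_fit.r2_adj if (lam_fit and lam_fit.estimable) else None,
        lambda_window=lam_fit.window if (lam_fit and lam_fit.estimable) else None,
        t_half=t_half_v,
        c_mean=c_mean,
        cl_p=cl_p,
        vd_ss=vd_ss,
        flags=flags,
    )
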