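"""Plate-level statistics: control pooling, LOD, cytotoxicity gating,
4PL dose-response fitting, EC interpolation, and activity calling.

The limit of detection for each endpoint and experiment is the pooled
control mean plus three control standard deviations (z = 3).  A dose is
cytotoxic when its mean nuclei count falls more than 20% below the vehicle
mean; the highest noncytotoxic concentration (HNC) is the largest tested
dose with no cytotoxicity at it or below.  A sample is called adipogenic
when at least two endpoints respond above their LOD at a noncytotoxic
dose; across independent experiments a majority rule applies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

ENDPOINTS = (
    "nuclei_count",
    "droplet_count",
    "total_area",
    "total_intensity",
    "n_adipocytes",
    "n_mature",
)

WELL_VOLUME_UL = 200.0
MG_PLASTIC_PER_UL_EXTRACT = 15.0
CYTOTOX_FRACTION = 0.20
MIN_ACTIVE_ENDPOINTS = 2


class DoseUnitError(ValueError):
    pass


# ---------------------------------------------------------------------------
# controls and LOD
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ControlPool:
    values: np.ndarray
    pooled: bool
    p_value: float
    statistic: float


@dataclass(frozen=True)
class LodResult:
    endpoint: str
    control_mean: float
    control_sd: float
    lod_threshold: float
    experiment_id: str = ""
    degenerate: bool = False


def pool_controls(
    negative: np.ndarray | list,
    vehicle: np.ndarray | list,
    alpha: float = 0.05,
) -> ControlPool:
    """Pool negative and vehicle controls unless Welch's t rejects equality.

    With p >= alpha the groups are concatenated; otherwise a warning is
    emitted and only the vehicle controls are used.
    """
    neg = np.asarray(negative, dtype=float)
    veh = np.asarray(vehicle, dtype=float)
    if neg.size < 2 or veh.size < 2:
        raise ValueError("need at least two values per control group")
    if np.ptp(neg) == 0 and np.ptp(veh) == 0 and neg[0] == veh[0]:
        # identical constants: t is 0/0; treat as indistinguishable
        t_stat, p = 0.0, 1.0
    else:
        t_stat, p = stats.ttest_ind(neg, veh, equal_var=False)
    if p >= alpha:
        return ControlPool(np.concatenate([neg, veh]), True, float(p), float(t_stat))
    warnings.warn(
        f"negative and vehicle controls differ (Welch p={p:.3g}); using vehicle only",
        stacklevel=2,
    )
    return ControlPool(veh, False, float(p), float(t_stat))


def compute_lod(
    pooled_controls: np.ndarray | list,
    endpoint: str,
    experiment_id: str = "",
) -> LodResult:
    """LOD = control mean + 3 x sample SD (n-1 denominator).

    All-identical controls give SD 0 and a threshold equal to the mean,
    flagged degenerate.
    """
    vals = np.asarray(pooled_controls, dtype=float)
    if vals.size < 3:
        raise ValueError("need >= 3 pooled control values for an LOD")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1))
    return LodResult(
        endpoint=endpoint,
        control_mean=mean,
        control_sd=sd,
        lod_threshold=mean + 3.0 * sd,
        experiment_id=experiment_id,
        degenerate=(sd == 0.0),
    )


# ---------------------------------------------------------------------------
# cytotoxicity
# ---------------------------------------------------------------------------


def assess_cytotoxicity(
    nuclei_by_dose: dict[float, np.ndarray | list],
    vehicle_nuclei: np.ndarray | list,
    fraction: float = CYTOTOX_FRACTION,
) -> float | None:
    """Highest noncytotoxic concentration under the strict >20% loss rule.

    A dose is cytotoxic iff its mean nuclei count is strictly below
    ``(1 - fraction)`` of the vehicle mean.  The HNC is the highest dose
    with no cytotoxicity at it or any lower dose; None when even the lowest
    dose is cytotoxic.
    """
    veh_mean = float(np.mean(np.asarray(vehicle_nuclei, dtype=float)))
    if veh_mean <= 0:
        raise ValueError("vehicle mean nuclei count must be positive")
    cutoff = (1.0 - fraction) * veh_mean
    hnc: float | None = None
    for dose in sorted(nuclei_by_dose):
        mean = float(np.mean(np.asarray(nuclei_by_dose[dose], dtype=float)))
        if mean < cutoff:
            break
        hnc = float(dose)
    return hnc


def cytotoxic_doses(
    nuclei_by_dose: dict[float, np.ndarray | list],
    vehicle_nuclei: np.ndarray | list,
    fraction: float = CYTOTOX_FRACTION,
) -> set[float]:
    veh_mean = float(np.mean(np.asarray(vehicle_nuclei, dtype=float)))
    cutoff = (1.0 - fraction) * veh_mean
    return {
        float(d)
        for d, v in nuclei_by_dose.items()
        if float(np.mean(np.asarray(v, dtype=float))) < cutoff
    }


# ---------------------------------------------------------------------------
# 4PL dose-response
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FourPLFit:
    bottom: float
    top: float
    ec50: float
    hill: float
    rss: float
    converged: bool
    degenerate: bool = False

    def predict(self, dose: np.ndarray | float) -> np.ndarray | float:
        return four_pl(np.asarray(dose, dtype=float), self.bottom, self.top, self.ec50, self.hill)


def four_pl(dose: np.ndarray, bottom: float, top: float, ec50: float, hill: float) -> np.ndarray:
    """y = bottom + (top - bottom) * d^h / (d^h + ec50^h); y(0) = bottom."""
    dose = np.asarray(dose, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        ratio = np.where(dose > 0, (ec50 / np.maximum(dose, 1e-300)) ** hill, np.inf)
        y = bottom + (top - bottom) / (1.0 + ratio)
    return np.where(dose > 0, y, bottom)


def fit_4pl(
    doses: np.ndarray | list,
    responses: np.ndarray | list,
    *,
    n_starts: int = 6,
    max_hill: float = 10.0,
) -> FourPLFit:
    """Least-squares 4PL fit with multi-start initialization.

    Replicates are passed as repeated (dose, response) pairs; the fit is
    invariant to their order.  Flat data returns a degenerate fit with
    top == bottom.  Non-convergence keeps the best start's parameters with
    ``converged`` False.
    """
    d = np.asarray(doses, dtype=float)
    y = np.asarray(responses, dtype=float)
    if d.shape != y.shape:
        raise ValueError("doses and responses must align")
    if not np.all(np.isfinite(d)) or not np.all(np.isfinite(y)):
        raise ValueError("doses and responses must be finite")
    if d.size < 2 or np.unique(d[d > 0]).size < 2:
        raise ValueError("need >= 2 positive dose levels to fit")

    y_lo, y_hi = float(y.min()), float(y.max())
    span = y_hi - y_lo
    if span == 0.0:
        return FourPLFit(y_lo, y_lo, float(np.median(d[d > 0])), 1.0, 0.0, True, degenerate=True)

    pos = np.sort(np.unique(d[d > 0]))
    ec50_grid = np.geomspace(pos[0], pos[-1], num=max(n_starts - 2, 1))
    starts = [(y_lo, y_hi, ec, 1.0) for ec in ec50_grid]
    starts += [(y_lo, y_hi, float(np.sqrt(pos[0] * pos[-1])), h) for h in (0.5, 3.0)]

    lower = [y_lo - 2 * span, y_lo - 2 * span, pos[0] / 1e3, 1.0 / max_hill]
    upper = [y_hi + 2 * span, y_hi + 2 * span, pos[-1] * 1e3, max_hill]

    best: tuple[float, np.ndarray] | None = None
    converged = False
    for p0 in starts[:n_starts]:
        try:
            popt, _ = optimize.curve_fit(
                four_pl, d, y, p0=p0, bounds=(lower, upper), maxfev=20_000
            )
        except (RuntimeError, optimize.OptimizeWarning, ValueError):
            continue
        rss = float(np.sum((four_pl(d, *popt) - y) ** 2))
        if best is None or rss < best[0]:
            best = (rss, popt)
        converged = True
    if best is None:
        # fall back to the raw initial guess, flagged unconverged
        p0 = starts[0]
        rss = float(np.sum((four_pl(d, *p0) - y) ** 2))
        return FourPLFit(*[float(v) for v in p0], rss=rss, converged=False)

    rss, (bottom, top, ec50, hill) = best[0], best[1]
    if top < bottom:  # canonical orientation
        bottom, top = top, bottom
    degenerate = abs(top - bottom) < 1e-9 * max(abs(top), abs(bottom), 1.0)
    return FourPLFit(
        float(bottom), float(top), float(ec50), float(hill), float(rss),
        converged=converged, degenerate=degenerate,
    )


def interpolate_ec(fit: FourPLFit, level: float) -> float | None:
    """Dose producing ``level`` percent of the fitted effect span.

    Closed form ``ec50 * (f / (100 - f))^(1/hill)``.  Degenerate or
    unconverged fits return None.
    """
    if not (0.0 < level < 100.0):
        raise ValueError("level must be in (0, 100)")
    if fit.degenerate or not fit.converged or fit.top <= fit.bottom:
        return None
    return float(fit.ec50 * (level / (100.0 - level)) ** (1.0 / fit.hill))


# ---------------------------------------------------------------------------
# activity calling
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ActivityCall:
    sample_id: str
    hnc: float | None
    per_endpoint_active: dict[str, bool] = field(default_factory=dict)
    active: bool = False
    ec10: float | None = None
    ec20: float | None = None
    experiment_id: str = ""


def call_activity(
    sample_id: str,
    series_by_endpoint: dict[str, dict[float, np.ndarray | list]],
    lods: dict[str, LodResult],
    hnc: float | None,
    *,
    fits: dict[str, FourPLFit] | None = None,
    min_active_endpoints: int = MIN_ACTIVE_ENDPOINTS,
    experiment_id: str = "",
) -> ActivityCall:
    """Per-endpoint LOD exceedance at noncytotoxic doses, >= 2-endpoint rule.

    An endpoint is active when the mean response at any noncytotoxic dose
    (dose <= hnc) reaches its LOD threshold.  Endpoints without data or
    without an LOD are skipped with a warning, never counted active.
    EC10/EC20 come from the first active endpoint with a usable fit.
    """
    per_endpoint: dict[str, bool] = {}
    for ep, by_dose in series_by_endpoint.items():
        if ep == "nuclei_count":
            continue  # cytotoxicity endpoint, gated separately
        if ep not in lods:
            warnings.warn(f"{sample_id}: no LOD for endpoint {ep}; skipped", stacklevel=2)
            continue
        usable = {
            d: v for d, v in by_dose.items() if hnc is not None and d <= hnc and len(v) > 0
        }
        if not usable:
            per_endpoint[ep] = False
            continue
        threshold = lods[ep].lod_threshold
        per_endpoint[ep] = any(
            float(np.mean(np.asarray(v, dtype=float))) >= threshold for v in usable.values()
        )
    active = sum(per_endpoint.values()) >= min_active_endpoints

    ec10 = ec20 = None
    if active and fits:
        for ep, is_active in per_endpoint.items():
            if not is_active or ep not in fits:
                continue
            f = fits[ep]
            e10, e20 = interpolate_ec(f, 10.0), interpolate_ec(f, 20.0)
            if e10 is not None:
                ec10, ec20 = e10, e20
                break
    return ActivityCall(
        sample_id=sample_id,
        hnc=hnc,
        per_endpoint_active=per_endpoint,
        active=active,
        ec10=ec10,
        ec20=ec20,
        experiment_id=experiment_id,
    )


def combine_experiment_calls(calls: list[ActivityCall]) -> bool:
    """Majority rule across independent experiments (>= half active)."""
    if not calls:
        return False
    n_active = sum(c.active for c in calls)
    return n_active * 2 > len(calls)


# ---------------------------------------------------------------------------
# dose units
# ---------------------------------------------------------------------------


def convert_dose(
    value: float,
    from_unit: str,
    to_unit: str,
    *,
    well_volume_ul: float = WELL_VOLUME_UL,
    mg_per_ul_extract: float = MG_PLASTIC_PER_UL_EXTRACT,
) -> float:
    """Convert between mg plastic/well, mg plastic/mL and uL of extract.

    The default calibration: a 200 uL well, and 1 uL of concentrated
    extract equivalent to 15 mg of plastic.
    """
    units = {"mg_per_well", "mg_per_mL", "uL_extract"}
    if from_unit not in units or to_unit not in units:
        raise DoseUnitError(f"units must be one of {sorted(units)}")
    # normalize to mg plastic per well
    if from_unit == "mg_per_well":
        mg_per_well = value
    elif from_unit == "mg_per_mL":
        mg_per_well = value * (well_volume_ul / 1000.0)
    else:
        mg_per_well = value * mg_per_ul_extract
    if to_unit == "mg_per_well":
        return mg_per_well
    if to_unit == "mg_per_mL":
        return mg_per_well / (well_volume_ul / 1000.0)
    return mg_per_well / mg_per_ul_extract


def solvent_percent(dilution_factor: float) -> float:
    """Final solvent percentage (v/v) after diluting the extract ``factor``-fold."""
    if dilution_factor <= 0:
        raise ValueError("dilution factor must be positive")
    return 100.0 / dilution_factor
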