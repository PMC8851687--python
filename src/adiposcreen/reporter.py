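"""Reporter-gene (receptor-activation) plate analysis.

Tabular only: each well carries a raw luminescence-style signal and a
nuclei count from a single low-magnification image.  The signal is
normalized per nucleus, zero-nuclei wells are flagged cytotoxic and
dropped, cytotoxicity gating reuses the same >20% nuclei-loss rule as the
adipogenesis plates, and sample activity is expressed as percent of the
reference compound's fitted maximum.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from adiposcreen.plate_stats import FourPLFit, assess_cytotoxicity, fit_4pl

REQUIRED_COLUMNS = ["well_id", "treatment", "dose", "raw_signal", "nuclei_count"]


class ReporterDataError(ValueError):
    pass


def normalize_reporter(wells: pd.DataFrame) -> pd.DataFrame:
    """Add ``normalized_signal`` = raw_signal / nuclei_count per well.

    Wells with zero nuclei are flagged ``cytotoxic_excluded`` and get NA; a
    dataset where every well has zero nuclei is an error.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in wells.columns]
    if missing:
        raise ReporterDataError(f"missing columns: {missing}")
    if (wells["nuclei_count"] <= 0).all():
        raise ReporterDataError("all wells have zero nuclei; nothing to normalize")
    if (wells["raw_signal"] < 0).any() or (wells["nuclei_count"] < 0).any():
        raise ReporterDataError("raw_signal and nuclei_count must be non-negative")
    out = wells.copy()
    ok = out["nuclei_count"] > 0
    out["cytotoxic_excluded"] = ~ok
    out["normalized_signal"] = np.where(ok, out["raw_signal"] / out["nuclei_count"], np.nan)
    return out


def fit_reference_curve(wells: pd.DataFrame) -> FourPLFit:
    """4PL fit of the normalized reference-compound dose series."""
    ref = wells[(wells["treatment"] == "reference") & ~wells["cytotoxic_excluded"]]
    if ref.empty:
        raise ReporterDataError("no usable reference wells")
    return fit_4pl(ref["dose"].to_numpy(float), ref["normalized_signal"].to_numpy(float))


def percent_of_max(
    values: np.ndarray | list | float,
    reference: FourPLFit,
) -> np.ndarray | float:
    """Normalized signal as percent of the reference span.

    ``100 * (value - bottom) / (top - bottom)`` with the reference fit's
    bottom and top.  A degenerate reference is an error.
    """
    if reference.degenerate or reference.top <= reference.bottom:
        raise ReporterDataError("degenerate reference curve; cannot express percent of max")
    vals = np.asarray(values, dtype=float)
    pct = 100.0 * (vals - reference.bottom) / (reference.top - reference.bottom)
    return float(pct) if np.isscalar(values) else pct


def sample_activity(
    wells_by_experiment: dict[str, pd.DataFrame],
    sample_id: str,
) -> dict:
    """Median-across-experiments percent-of-max activity at the sample HNC.

    Per experiment: normalize, gate cytotoxicity on nuclei counts, refit
    the reference curve, take the mean normalized signal at the HNC and
    express it as percent of the reference maximum.  Returns the median and
    the per-experiment values.
    """
    per_exp: dict[str, float] = {}
    for exp_id, wells in wells_by_experiment.items():
        norm = normalize_reporter(wells)
        ref_fit = fit_reference_curve(norm)
        sample = norm[(norm["treatment"] == "sample") & (norm["sample_id"] == sample_id)]
        if sample.empty:
            continue
        veh = norm[norm["treatment"].isin(["vehicle", "negative"])]
        nuclei_by_dose = {
            float(d): g["nuclei_count"].to_numpy(float)
            for d, g in sample.groupby("dose")
        }
        hnc = assess_cytotoxicity(nuclei_by_dose, veh["nuclei_count"].to_numpy(float))
        if hnc is None:
            continue
        at_hnc = sample[(sample["dose"] == hnc) & ~sample["cytotoxic_excluded"]]
        if at_hnc.empty:
            continue
        per_exp[exp_id] = float(
            percent_of_max(float(at_hnc["normalized_signal"].mean()), ref_fit)
        )
    return {
        "sample_id": sample_id,
        "median_percent_activity": float(np.median(list(per_exp.values()))) if per_exp else None,
        "per_experiment": per_exp,
    }
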