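"""Single-cell adipocyte classification and per-well population summaries.

A cell is an adipocyte when at least one lipid droplet is assigned to it;
a mature adipocyte when its summed droplet area reaches the maturity
threshold (default 1000 px, i.e. eight average-sized droplets).  Average
intensity is the per-lipid-pixel mean over a cell's assigned droplets and
is normalized to the pooled mean of the reference-compound adipocytes on
the same plate.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

MATURE_AREA_THRESHOLD_PX = 1000.0

RECORD_COLUMNS = [
    "cell_id",
    "droplet_count",
    "lipid_area",
    "avg_intensity",
    "is_adipocyte",
    "is_mature",
    "norm_intensity",
]


class NormalizationError(ValueError):
    """No reference adipocytes available on the plate."""


class ConsistencyError(ValueError):
    """Droplet table references a cell that does not exist."""


@dataclass(frozen=True)
class PopulationSummary:
    well_id: str
    n_cells: int
    n_preadipocytes: int
    n_adipocytes: int
    n_mature: int
    median_lipid_area: float | None
    median_norm_intensity: float | None


def classify_adipocytes(
    cell_ids: pd.Series | np.ndarray | list,
    droplets: pd.DataFrame,
) -> pd.DataFrame:
    """One record per cell with droplet count, lipid area and mean intensity.

    ``droplets`` must carry ``cell_id``, ``area`` and
    ``integrated_intensity``; droplets with NA ``cell_id`` (unassigned) are
    ignored here — they only feed image-level endpoints.
    """
    ids = pd.Index(pd.unique(pd.Series(cell_ids))).dropna()
    assigned = droplets.dropna(subset=["cell_id"]) if len(droplets) else droplets
    if len(assigned):
        unknown = set(assigned["cell_id"].astype(int)) - set(int(i) for i in ids)
        if unknown:
            raise ConsistencyError(f"droplets reference unknown cells: {sorted(unknown)}")
        grouped = assigned.groupby(assigned["cell_id"].astype(int)).agg(
            droplet_count=("area", "size"),
            lipid_area=("area", "sum"),
            total_intensity=("integrated_intensity", "sum"),
        )
    else:
        grouped = pd.DataFrame(columns=["droplet_count", "lipid_area", "total_intensity"])

    rows = []
    for cid in ids:
        cid = int(cid)
        if cid in grouped.index:
            g = grouped.loc[cid]
            count = int(g["droplet_count"])
            area = float(g["lipid_area"])
            avg = float(g["total_intensity"]) / area if area > 0 else 0.0
        else:
            count, area, avg = 0, 0.0, 0.0
        rows.append(
            {
                "cell_id": cid,
                "droplet_count": count,
                "lipid_area": area,
                "avg_intensity": avg if count else np.nan,
                "is_adipocyte": count >= 1,
                "is_mature": False,
                "norm_intensity": np.nan,
            }
        )
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def flag_mature(
    records: pd.DataFrame,
    mature_area_threshold: float = MATURE_AREA_THRESHOLD_PX,
) -> pd.DataFrame:
    """Set ``is_mature`` = adipocyte with ``lipid_area >= threshold`` (inclusive)."""
    out = records.copy()
    out["is_mature"] = out["is_adipocyte"] & (out["lipid_area"] >= mature_area_threshold)
    return out


def normalize_intensity(
    records: pd.DataFrame,
    plate_reference_records: pd.DataFrame,
    *,
    plate_id: str = "?",
) -> pd.DataFrame:
    """Divide each adipocyte's ``avg_intensity`` by the pooled reference mean.

    The reference is every adipocyte in the plate's reference-compound wells
    pooled together.  Preadipocytes keep NA.
    """
    ref = plate_reference_records[plate_reference_records["is_adipocyte"]]
    if ref.empty:
        raise NormalizationError(f"plate {plate_id}: no reference adipocytes to normalize against")
    ref_mean = float(ref["avg_intensity"].mean())
    if not np.isfinite(ref_mean) or ref_mean <= 0:
        raise NormalizationError(f"plate {plate_id}: degenerate reference mean {ref_mean}")
    out = records.copy()
    out["norm_intensity"] = np.where(
        out["is_adipocyte"], out["avg_intensity"] / ref_mean, np.nan
    )
    return out


def summarize_population(records: pd.DataFrame, well_id: str) -> PopulationSummary:
    """Counts and adipocyte-only medians for one well.

    Medians are over adipocytes; wells without adipocytes report None so
    downstream fitting can drop them explicitly rather than seeing zeros.
    """
    adipo = records[records["is_adipocyte"]]
    n_cells = int(len(records))
    n_adipo = int(len(adipo))

    def _median(series: pd.Series) -> float | None:
        vals = series.dropna()
        return float(np.median(vals)) if len(vals) else None

    return PopulationSummary(
        well_id=well_id,
        n_cells=n_cells,
        n_preadipocytes=n_cells - n_adipo,
        n_adipocytes=n_adipo,
        n_mature=int(adipo["is_mature"].sum()),
        median_lipid_area=_median(adipo["lipid_area"]) if n_adipo else None,
        median_norm_intensity=_median(adipo["norm_intensity"]) if n_adipo else None,
    )


def summaries_to_frame(summaries: list[PopulationSummary]) -> pd.DataFrame:
    return pd.DataFrame([asdict(s) for s in summaries])
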