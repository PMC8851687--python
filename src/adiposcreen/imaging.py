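"""Segmentation of nuclei, cell regions and lipid droplets, plus per-image endpoints.

The pipeline is the classic sequence: smooth, automatic global threshold,
distance-transform watershed declumping, size gates.  Cell regions grow
outward from each nucleus up to a maximum expansion radius and partition
the claimed area (each region contains exactly its seed nucleus).  Droplets
are detected on the background-corrected lipid channel and assigned to the
cell with maximal pixel overlap, falling back to the nearest cell within a
distance cap; ties break toward the lower cell id.

The four per-image endpoints are nuclei count (proliferation), droplet
count, total droplet area and total background-subtracted droplet
intensity (adipogenesis).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import regionprops
from skimage.segmentation import expand_labels, watershed

NUCLEI_COLUMNS = ["nucleus_id", "centroid_row", "centroid_col", "area"]
DROPLET_COLUMNS = [
    "droplet_id",
    "centroid_row",
    "centroid_col",
    "area",
    "integrated_intensity",
    "cell_id",
]


class FieldMismatchError(ValueError):
    """Tables passed together do not come from the same field."""


@dataclass(frozen=True)
class SegmentationParams:
    smooth_sigma: float = 1.0
    threshold_method: str = "otsu"
    min_area: int = 20
    max_area: int = 10_000
    declump_min_distance: int = 5
    min_threshold_snr: float = 5.0


@dataclass(frozen=True)
class DropletParams:
    smooth_sigma: float = 0.5
    threshold_method: str = "otsu"
    min_droplet_area: int = 9
    declump: bool = False
    declump_min_distance: int = 4
    background_subtract: bool = True
    min_threshold_snr: float = 5.0


def _threshold_above_noise_floor(image: np.ndarray, threshold: float, snr: float) -> bool:
    """Guard against thresholding pure noise: the automatic threshold must
    clear the robust background level (median + snr * 1.4826 * MAD)."""
    med = float(np.median(image))
    mad = float(np.median(np.abs(image - med)))
    return threshold >= med + snr * 1.4826 * mad


@dataclass
class ObjectTables:
    field_id: tuple[str, int]
    nuclei: pd.DataFrame
    cells: np.ndarray  # label map, 0 = background, labels = nucleus ids
    droplets: pd.DataFrame


@dataclass(frozen=True)
class ImageEndpoints:
    field_id: tuple[str, int]
    nuclei_count: int
    droplet_count: int
    total_area: float
    total_intensity: float


def _threshold(image: np.ndarray, method: str) -> float:
    if method == "otsu":
        return float(threshold_otsu(image))
    raise ValueError(f"unknown threshold method {method!r}")


def _is_flat(image: np.ndarray) -> bool:
    return bool(np.ptp(image) == 0)


def _declump(mask: np.ndarray, min_distance: int) -> np.ndarray:
    """Split touching objects by watershed on the distance transform."""
    distance = ndimage.distance_transform_edt(mask)
    coords = peak_local_max(
        distance, min_distance=min_distance, labels=mask, exclude_border=False
    )
    if len(coords) == 0:
        labels, _ = ndimage.label(mask)
        return labels
    markers = np.zeros(mask.shape, dtype=np.int32)
    markers[tuple(coords.T)] = np.arange(1, len(coords) + 1)
    return watershed(-distance, markers=markers, mask=mask)


def segment_nuclei(
    nuclei_channel: np.ndarray,
    params: SegmentationParams | None = None,
) -> pd.DataFrame:
    """Nuclei table (id, intensity-weighted centroid, area) from the nuclei channel.

    A uniform image yields an empty table, not an error.
    """
    params = params or SegmentationParams()
    img = np.asarray(nuclei_channel, dtype=np.float64)
    if img.size == 0:
        raise ValueError("empty image")
    if _is_flat(img):
        return pd.DataFrame(columns=NUCLEI_COLUMNS)
    smooth = ndimage.gaussian_filter(img, params.smooth_sigma) if params.smooth_sigma > 0 else img
    thresh = _threshold(smooth, params.threshold_method)
    if not _threshold_above_noise_floor(smooth, thresh, params.min_threshold_snr):
        return pd.DataFrame(columns=NUCLEI_COLUMNS)
    mask = smooth > thresh
    if not mask.any():
        return pd.DataFrame(columns=NUCLEI_COLUMNS)
    labels = _declump(mask, params.declump_min_distance)

    rows = []
    nucleus_id = 0
    for prop in regionprops(labels, intensity_image=img):
        if not (params.min_area <= prop.area <= params.max_area):
            continue
        nucleus_id += 1
        wr, wc = prop.centroid_weighted
        rows.append(
            {
                "nucleus_id": nucleus_id,
                "centroid_row": float(wr),
                "centroid_col": float(wc),
                "area": int(prop.area),
            }
        )
    return pd.DataFrame(rows, columns=NUCLEI_COLUMNS)


def delineate_cells(
    nuclei: pd.DataFrame,
    lipid_channel: np.ndarray,
    *,
    max_expansion_radius: float = 30.0,
) -> np.ndarray:
    """Cell label map seeded at nucleus centroids.

    Every nucleus yields exactly one region labelled with its nucleus id;
    regions are the nearest-seed partition truncated at
    ``max_expansion_radius``; pixels beyond stay background (0).
    """
    shape = np.asarray(lipid_channel).shape
    seeds = np.zeros(shape, dtype=np.int32)
    for _, row in nuclei.iterrows():
        r = int(np.clip(round(row["centroid_row"]), 0, shape[0] - 1))
        c = int(np.clip(round(row["centroid_col"]), 0, shape[1] - 1))
        seeds[r, c] = int(row["nucleus_id"])
    return expand_labels(seeds, distance=max_expansion_radius)


def detect_droplets(
    lipid_channel: np.ndarray,
    params: DropletParams | None = None,
) -> pd.DataFrame:
    """Droplet table from the lipid channel.

    Intensity is integrated after per-image median background subtraction
    (the default; toggle with ``params.background_subtract``).  The
    ``cell_id`` column starts out as NA; :func:`assign_droplets` fills it.
    """
    params = params or DropletParams()
    img = np.asarray(lipid_channel, dtype=np.float64)
    if img.size == 0:
        raise ValueError("empty image")
    empty = pd.DataFrame(columns=DROPLET_COLUMNS).astype({"cell_id": "Int64"})
    if _is_flat(img):
        return empty
    background = float(np.median(img)) if params.background_subtract else 0.0
    corrected = np.clip(img - background, 0.0, None)
    smooth = (
        ndimage.gaussian_filter(corrected, params.smooth_sigma)
        if params.smooth_sigma > 0
        else corrected
    )
    if _is_flat(smooth):
        return empty
    thresh = _threshold(smooth, params.threshold_method)
    if not _threshold_above_noise_floor(smooth, thresh, params.min_threshold_snr):
        return empty
    mask = smooth > thresh
    if not mask.any():
        return empty
    if params.declump:
        labels = _declump(mask, params.declump_min_distance)
    else:
        labels, _ = ndimage.label(mask)

    rows = []
    droplet_id = 0
    for prop in regionprops(labels, intensity_image=corrected):
        if prop.area < params.min_droplet_area:
            continue
        droplet_id += 1
        rows.append(
            {
                "droplet_id": droplet_id,
                "centroid_row": float(prop.centroid[0]),
                "centroid_col": float(prop.centroid[1]),
                "area": int(prop.area),
                "integrated_intensity": float(prop.image_intensity.sum()),
                "cell_id": pd.NA,
            }
        )
    # keep the label map around for overlap-based assignment
    out = pd.DataFrame(rows, columns=DROPLET_COLUMNS).astype({"cell_id": "Int64"})
    out.attrs["label_map"] = labels
    out.attrs["kept_labels"] = {
        row["droplet_id"]: lbl
        for row, lbl in zip(rows, _kept_labels(labels, params.min_droplet_area))
    }
    return out


def _kept_labels(labels: np.ndarray, min_area: int) -> list[int]:
    return [p.label for p in regionprops(labels) if p.area >= min_area]


def assign_droplets(
    droplets: pd.DataFrame,
    cell_labels: np.ndarray,
    *,
    max_assign_distance: float = 15.0,
) -> pd.DataFrame:
    """Fill ``cell_id`` by maximal pixel overlap with the cell label map.

    Droplets with zero overlap go to the nearest cell within
    ``max_assign_distance`` of their centroid; otherwise they stay
    unassigned (NA) but remain in the table so image totals are unaffected.
    Ties break toward the lowest cell id.
    """
    droplets = droplets.copy()
    if droplets.empty:
        return droplets
    label_map = droplets.attrs.get("label_map")
    kept = droplets.attrs.get("kept_labels", {})
    has_cells = bool((np.asarray(cell_labels) > 0).any())

    assigned = []
    for _, row in droplets.iterrows():
        cell = pd.NA
        if label_map is not None and row["droplet_id"] in kept:
            pix = cell_labels[label_map == kept[row["droplet_id"]]]
            pix = pix[pix > 0]
            if pix.size:
                counts = np.bincount(pix)
                best = counts.max()
                cell = int(np.flatnonzero(counts == best)[0])  # lowest id on tie
        if cell is pd.NA and has_cells:
            cell = _nearest_cell(
                cell_labels,
                (float(row["centroid_row"]), float(row["centroid_col"])),
                max_assign_distance,
            )
        assigned.append(cell)
    droplets["cell_id"] = pd.array(assigned, dtype="Int64")
    droplets.attrs.clear()  # label-map hand-off is consumed; keeps frames concat-safe
    return droplets


def _nearest_cell(
    cell_labels: np.ndarray, centroid: tuple[float, float], max_distance: float
):
    """Lowest-id cell whose nearest pixel is within ``max_distance`` of
    ``centroid``; exact-distance ties break toward the lower id."""
    pad = int(math.ceil(max_distance)) + 1
    r0 = max(int(centroid[0]) - pad, 0)
    r1 = min(int(centroid[0]) + pad + 1, cell_labels.shape[0])
    c0 = max(int(centroid[1]) - pad, 0)
    c1 = min(int(centroid[1]) + pad + 1, cell_labels.shape[1])
    window = cell_labels[r0:r1, c0:c1]
    if not (window > 0).any():
        return pd.NA
    rr, cc = np.mgrid[r0:r1, c0:c1]
    dist = np.hypot(rr - centroid[0], cc - centroid[1])
    dist = np.where(window > 0, dist, np.inf)
    dmin = dist.min()
    if dmin > max_distance:
        return pd.NA
    candidates = np.unique(window[np.isclose(dist, dmin)])
    return int(candidates.min())


def segment_field(
    nuclei_channel: np.ndarray,
    lipid_channel: np.ndarray,
    field_id: tuple[str, int],
    *,
    nuclei_params: SegmentationParams | None = None,
    droplet_params: DropletParams | None = None,
    max_expansion_radius: float = 30.0,
    max_assign_distance: float = 15.0,
) -> ObjectTables:
    """Full segmentation of one field: nuclei, cells, assigned droplets."""
    if np.asarray(nuclei_channel).shape != np.asarray(lipid_channel).shape:
        raise ValueError("channel shapes differ")
    nuclei = segment_nuclei(nuclei_channel, nuclei_params)
    cells = delineate_cells(nuclei, lipid_channel, max_expansion_radius=max_expansion_radius)
    droplets = detect_droplets(lipid_channel, droplet_params)
    droplets = assign_droplets(droplets, cells, max_assign_distance=max_assign_distance)
    return ObjectTables(field_id=field_id, nuclei=nuclei, cells=cells, droplets=droplets)


def compute_image_endpoints(tables: ObjectTables) -> ImageEndpoints:
    """Per-image endpoint quadruple; unassigned droplets count toward totals."""
    return ImageEndpoints(
        field_id=tables.field_id,
        nuclei_count=int(len(tables.nuclei)),
        droplet_count=int(len(tables.droplets)),
        total_area=float(tables.droplets["area"].sum()) if len(tables.droplets) else 0.0,
        total_intensity=(
            float(tables.droplets["integrated_intensity"].sum())
            if len(tables.droplets)
            else 0.0
        ),
    )


def endpoints_to_frame(endpoints: list[ImageEndpoints]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "well_id": e.field_id[0],
                "field_index": e.field_id[1],
                "nuclei_count": e.nuclei_count,
                "droplet_count": e.droplet_count,
                "total_area": e.total_area,
                "total_intensity": e.total_intensity,
            }
            for e in endpoints
        ]
    )
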