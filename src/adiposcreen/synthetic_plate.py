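"""Synthetic plate layouts, ground-truth cell populations, and rendered fields.

Everything downstream of the microscope is testable against the objects
generated here: a plate design maps wells to treatments and doses, a
dose-effect model turns doses into differentiation fractions and droplet
size distributions, and the renderer turns ground-truth object lists into
two-channel field images (nuclei stain, lipid stain).

All randomness flows from a single integer seed through
:class:`numpy.random.SeedSequence`, so re-runs are bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import math
import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml
from scipy import ndimage

PLATE_ROWS = string.ascii_uppercase[:8]
PLATE_COLS = range(1, 13)

TREATMENTS = (
    "vehicle",
    "negative",
    "reference",
    "sample",
    "preadipocyte_control",
    "blank",
)


class PlateSizingError(ValueError):
    """Requested layout does not fit on the plate."""


class PlacementError(RuntimeError):
    """Could not place the requested objects at the configured density."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WellAssignment:
    well_id: str
    treatment: str
    sample_id: str | None
    dose: float
    replicate_index: int

    def __post_init__(self) -> None:
        if self.treatment not in TREATMENTS:
            raise ValueError(f"unknown treatment {self.treatment!r}")
        if self.dose < 0:
            raise ValueError("dose must be non-negative")
        if self.replicate_index < 1:
            raise ValueError("replicate_index must be >= 1")


@dataclass
class PlateDesign:
    plate_id: str
    wells: list[WellAssignment]

    def wells_by_treatment(self, treatment: str) -> list[WellAssignment]:
        return [w for w in self.wells if w.treatment == treatment]

    def sample_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for w in self.wells:
            if w.treatment == "sample" and w.sample_id is not None:
                seen.setdefault(w.sample_id)
        return list(seen)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "plate_id": self.plate_id,
                    "well_id": w.well_id,
                    "treatment": w.treatment,
                    "sample_id": w.sample_id,
                    "dose": w.dose,
                    "replicate_index": w.replicate_index,
                }
                for w in self.wells
            ]
        )


@dataclass(frozen=True)
class EffectModel:
    """Dose-dependent differentiation and droplet-size ground truth.

    ``base_frac``/``max_frac`` bound the adipocyte fraction at zero and
    saturating dose; the transition follows a Hill curve with midpoint
    ``ec50`` and slope ``hill``.  Droplet pixel areas are log-normal;
    ``maturity_boost`` scales per-adipocyte droplet areas up with dose so
    high doses produce more mature (large-area) adipocytes.
    """

    ec50: float
    hill: float
    base_frac: float
    max_frac: float
    droplet_count_mean: float = 6.0
    droplet_area_log_mean: float = math.log(125.0)
    droplet_area_log_sd: float = 0.45
    intensity_per_area: float = 40.0
    maturity_boost: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.base_frac <= self.max_frac <= 1.0):
            raise ValueError(
                "need 0 <= base_frac <= max_frac <= 1, got "
                f"base_frac={self.base_frac}, max_frac={self.max_frac}"
            )
        if self.ec50 <= 0:
            raise ValueError("ec50 must be positive")
        if self.hill <= 0:
            raise ValueError("hill must be positive")
        if self.droplet_count_mean < 1:
            raise ValueError("droplet_count_mean must be >= 1")
        if self.maturity_boost < 0:
            raise ValueError("maturity_boost must be >= 0")

    def response(self, dose: float) -> float:
        """Hill-curve occupancy in [0, 1] at ``dose``."""
        if dose <= 0:
            return 0.0
        dh = dose**self.hill
        return dh / (dh + self.ec50**self.hill)

    def adipocyte_fraction(self, dose: float) -> float:
        return self.base_frac + (self.max_frac - self.base_frac) * self.response(dose)


@dataclass(frozen=True)
class ImagingConfig:
    field_shape: tuple[int, int] = (512, 512)
    bit_depth: int = 16
    background_level: float = 100.0
    blur_sigma: float = 1.0
    noise_model: str = "none"  # none | gaussian | poisson_gaussian
    noise_params: dict = field(default_factory=dict)
    fields_per_well: int = 9
    nucleus_intensity: float = 3000.0

    def __post_init__(self) -> None:
        if self.field_shape[0] <= 0 or self.field_shape[1] <= 0:
            raise ValueError("field_shape must be positive")
        if self.noise_model not in ("none", "gaussian", "poisson_gaussian"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")
        if self.fields_per_well < 1:
            raise ValueError("fields_per_well must be >= 1")

    @property
    def max_value(self) -> int:
        return 2**self.bit_depth - 1

    @property
    def dtype(self) -> np.dtype:
        return np.dtype(np.uint8 if self.bit_depth <= 8 else np.uint16)


@dataclass(frozen=True)
class Droplet:
    centroid: tuple[float, float]  # (row, col), 0-based px
    radius: float
    peak_intensity: float


@dataclass(frozen=True)
class CellTruth:
    cell_id: int
    nucleus_centroid: tuple[float, float]
    nucleus_radius: float
    is_adipocyte: bool
    droplets: tuple[Droplet, ...] = ()

    def __post_init__(self) -> None:
        if not self.is_adipocyte and self.droplets:
            raise ValueError("non-adipocyte cells must have no droplets")


@dataclass
class FieldTruth:
    well_id: str
    field_index: int
    cells: list[CellTruth]

    @property
    def field_id(self) -> tuple[str, int]:
        return (self.well_id, self.field_index)

    @property
    def n_nuclei(self) -> int:
        return len(self.cells)

    @property
    def n_droplets(self) -> int:
        return sum(len(c.droplets) for c in self.cells)

    def all_droplets(self) -> list[Droplet]:
        return [d for c in self.cells for d in c.droplets]


@dataclass
class FieldImages:
    field_id: tuple[str, int]
    nuclei_channel: np.ndarray
    lipid_channel: np.ndarray

    def __post_init__(self) -> None:
        if self.nuclei_channel.shape != self.lipid_channel.shape:
            raise ValueError("channel shapes differ")


# ---------------------------------------------------------------------------
# plate design
# ---------------------------------------------------------------------------


def dilution_series(top_dose: float, n_concentrations: int, dilution_factor: float) -> list[float]:
    """Doses ``top_dose / dilution_factor**k`` for ``k = 0 .. n-1`` (descending)."""
    if n_concentrations < 1:
        raise ValueError("n_concentrations must be >= 1")
    if dilution_factor <= 1:
        raise ValueError("dilution_factor must be > 1")
    if top_dose <= 0:
        raise ValueError("top_dose must be positive")
    return [top_dose / dilution_factor**k for k in range(n_concentrations)]


def all_well_ids() -> list[str]:
    return [f"{r}{c}" for r in PLATE_ROWS for c in PLATE_COLS]


def design_plate(
    samples: Sequence[str],
    top_dose: float,
    n_concentrations: int,
    dilution_factor: float = 2.0,
    replicates: int = 4,
    seed: int = 0,
    *,
    plate_id: str = "P1",
    n_vehicle: int = 4,
    n_negative: int = 4,
    n_reference: int = 4,
    reference_dose: float = 300.0,
    n_preadipocyte: int = 1,
    n_blank: int = 0,
) -> PlateDesign:
    """Lay out samples plus controls on a 96-well plate, seed-randomized.

    Each sample occupies ``n_concentrations x replicates`` wells on a 1:2-style
    serial dilution from ``top_dose``.  Control wells (vehicle, negative,
    reference compound at ``reference_dose``, undifferentiated-cell control,
    optional blanks) are always present.  Well positions are a deterministic
    permutation of the full layout driven by ``seed``.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if n_vehicle < 1 or n_reference < 1:
        raise ValueError("need at least one vehicle and one reference well")
    doses = dilution_series(top_dose, n_concentrations, dilution_factor)

    assignments: list[tuple[str, str | None, float, int]] = []
    for i in range(n_vehicle):
        assignments.append(("vehicle", None, 0.0, i + 1))
    for i in range(n_negative):
        assignments.append(("negative", None, 0.0, i + 1))
    for i in range(n_reference):
        assignments.append(("reference", None, reference_dose, i + 1))
    for i in range(n_preadipocyte):
        assignments.append(("preadipocyte_control", None, 0.0, i + 1))
    for i in range(n_blank):
        assignments.append(("blank", None, 0.0, i + 1))
    for sample_id in samples:
        for dose in doses:
            for rep in range(1, replicates + 1):
                assignments.append(("sample", str(sample_id), dose, rep))

    capacity = len(PLATE_ROWS) * len(PLATE_COLS)
    if len(assignments) > capacity:
        raise PlateSizingError(
            f"layout needs {len(assignments)} wells but the plate has "
            f"{capacity}; reduce by {len(assignments) - capacity} wells"
        )

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    positions = sorted(int(p) for p in rng.permutation(capacity)[: len(assignments)])
    shuffled = [assignments[int(i)] for i in rng.permutation(len(assignments))]
    ids = all_well_ids()
    wells = [
        WellAssignment(ids[pos], trt, sid, dose, rep)
        for pos, (trt, sid, dose, rep) in zip(positions, shuffled)
    ]
    return PlateDesign(plate_id=plate_id, wells=wells)


# ---------------------------------------------------------------------------
# ground-truth simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlacementConfig:
    """Geometry knobs for rejection-sampled object placement."""

    nucleus_radius: float = 6.0
    cell_min_distance: float = 40.0
    cell_max_radius: float = 18.0
    droplet_min_gap: float = 2.0
    border_margin: float = 16.0
    max_attempts: int = 2000
    droplet_max_attempts: int = 40


def _place_points(
    rng: np.random.Generator,
    n: int,
    shape: tuple[int, int],
    margin: float,
    min_distance: float,
    max_attempts: int,
) -> list[tuple[float, float]]:
    lo_r, hi_r = margin, shape[0] - 1 - margin
    lo_c, hi_c = margin, shape[1] - 1 - margin
    if hi_r <= lo_r or hi_c <= lo_c:
        raise PlacementError("border_margin leaves no interior to place objects in")
    placed = np.empty((0, 2), dtype=float)
    attempts = 0
    while len(placed) < n:
        if attempts >= max_attempts * max(n, 1):
            raise PlacementError(
                f"placed only {len(placed)}/{n} cells at min_distance={min_distance}"
            )
        attempts += 1
        cand = np.array([rng.uniform(lo_r, hi_r), rng.uniform(lo_c, hi_c)])
        if not len(placed) or (np.hypot(*(placed - cand).T) >= min_distance).all():
            placed = np.vstack([placed, cand])
    return [tuple(p) for p in placed]


def _field_rng(seed: int, well_index: int, field_index: int) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(well_index, field_index))
    return np.random.default_rng(ss)


def simulate_field_truth(
    rng: np.random.Generator,
    well_id: str,
    field_index: int,
    adipocyte_fraction: float,
    n_cells: int,
    model: EffectModel,
    config: ImagingConfig,
    placement: PlacementConfig,
    area_scale: float = 1.0,
) -> FieldTruth:
    """One field: place nuclei, draw per-cell adipocyte status and droplets."""
    centers = _place_points(
        rng,
        n_cells,
        config.field_shape,
        placement.border_margin,
        placement.cell_min_distance,
        placement.max_attempts,
    )
    disc_pos = np.empty((0, 2), dtype=float)  # placed droplet centres (all cells)
    disc_rad = np.empty(0, dtype=float)
    cells: list[CellTruth] = []
    for cid, center in enumerate(centers, start=1):
        is_adipo = bool(rng.random() < adipocyte_fraction)
        droplets: tuple[Droplet, ...] = ()
        if is_adipo:
            n_drop = 1 + int(rng.poisson(max(model.droplet_count_mean - 1.0, 0.0)))
            placed: list[Droplet] = []
            for _ in range(n_drop):
                area = area_scale * float(
                    rng.lognormal(model.droplet_area_log_mean, model.droplet_area_log_sd)
                )
                radius = math.sqrt(area / math.pi)
                for _attempt in range(placement.droplet_max_attempts):
                    ang = rng.uniform(0, 2 * math.pi)
                    dist = rng.uniform(
                        placement.nucleus_radius + radius + 1.0,
                        max(
                            placement.cell_max_radius,
                            placement.nucleus_radius + radius + 2.0,
                        ),
                    )
                    pos = (
                        center[0] + dist * math.sin(ang),
                        center[1] + dist * math.cos(ang),
                    )
                    m = placement.border_margin
                    if not (
                        m <= pos[0] <= config.field_shape[0] - 1 - m
                        and m <= pos[1] <= config.field_shape[1] - 1 - m
                    ):
                        continue
                    ok = not len(disc_pos) or (
                        np.hypot(disc_pos[:, 0] - pos[0], disc_pos[:, 1] - pos[1])
                        >= radius + disc_rad + placement.droplet_min_gap
                    ).all()
                    if ok:
                        peak = model.intensity_per_area * float(rng.uniform(0.8, 1.2))
                        placed.append(Droplet(pos, radius, peak))
                        disc_pos = np.vstack([disc_pos, pos])
                        disc_rad = np.append(disc_rad, radius)
                        break
                # droplet silently skipped when it cannot be placed; truth
                # records only what was placed, so counts stay consistent
            if not placed:
                is_adipo = False
            droplets = tuple(placed)
        cells.append(
            CellTruth(
                cell_id=cid,
                nucleus_centroid=center,
                nucleus_radius=placement.nucleus_radius,
                is_adipocyte=is_adipo,
                droplets=droplets,
            )
        )
    return FieldTruth(well_id=well_id, field_index=field_index, cells=cells)


def simulate_truth(
    design: PlateDesign,
    model: EffectModel,
    cells_per_field: int,
    config: ImagingConfig,
    seed: int,
    *,
    placement: PlacementConfig | None = None,
    reference_fraction: float | None = None,
) -> list[FieldTruth]:
    """Ground truth for every field of every well in ``design``.

    The expected adipocyte fraction for sample wells follows the model's
    Hill curve; vehicle/negative wells sit at ``base_frac``; reference wells
    at ``reference_fraction`` (default ``max_frac``); preadipocyte-control
    wells at zero; blank wells contain no cells.  Per-cell status is an
    independent Bernoulli draw.
    """
    if cells_per_field < 0:
        raise ValueError("cells_per_field must be >= 0")
    placement = placement or PlacementConfig()
    ref_frac = model.max_frac if reference_fraction is None else reference_fraction
    truths: list[FieldTruth] = []
    for wi, well in enumerate(design.wells):
        if well.treatment == "sample":
            frac = model.adipocyte_fraction(well.dose)
        elif well.treatment in ("vehicle", "negative"):
            frac = model.base_frac
        elif well.treatment == "reference":
            frac = ref_frac
        else:  # preadipocyte_control, blank
            frac = 0.0
        n_cells = 0 if well.treatment == "blank" else cells_per_field
        area_scale = 1.0
        if model.maturity_boost > 0 and well.treatment == "sample":
            area_scale = 1.0 + model.maturity_boost * model.response(well.dose)
        elif model.maturity_boost > 0 and well.treatment == "reference":
            area_scale = 1.0 + model.maturity_boost
        for fi in range(config.fields_per_well):
            rng = _field_rng(seed, wi, fi)
            truths.append(
                simulate_field_truth(
                    rng, well.well_id, fi, frac, n_cells, model, config, placement,
                    area_scale=area_scale,
                )
            )
    return truths


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def _add_disc(canvas: np.ndarray, center: tuple[float, float], radius: float, amplitude: float) -> None:
    """Accumulate an anti-aliased disc: per-pixel coverage ramps linearly
    over one pixel at the rim."""
    r0 = max(int(math.floor(center[0] - radius - 2)), 0)
    r1 = min(int(math.ceil(center[0] + radius + 2)) + 1, canvas.shape[0])
    c0 = max(int(math.floor(center[1] - radius - 2)), 0)
    c1 = min(int(math.ceil(center[1] + radius + 2)) + 1, canvas.shape[1])
    if r0 >= r1 or c0 >= c1:
        return
    rr, cc = np.mgrid[r0:r1, c0:c1]
    dist = np.hypot(rr - center[0], cc - center[1])
    coverage = np.clip(radius - dist + 0.5, 0.0, 1.0)
    canvas[r0:r1, c0:c1] += amplitude * coverage


def _check_in_bounds(truth: FieldTruth, shape: tuple[int, int]) -> None:
    for cell in truth.cells:
        r, c = cell.nucleus_centroid
        if not (0 <= r < shape[0] and 0 <= c < shape[1]):
            raise ValueError(f"nucleus of cell {cell.cell_id} out of bounds")
        for d in cell.droplets:
            if not (
                d.centroid[0] - d.radius >= 0
                and d.centroid[0] + d.radius <= shape[0] - 1
                and d.centroid[1] - d.radius >= 0
                and d.centroid[1] + d.radius <= shape[1] - 1
            ):
                raise ValueError(f"droplet of cell {cell.cell_id} out of bounds")


def render_field(truth: FieldTruth, config: ImagingConfig, seed: int = 0) -> FieldImages:
    """Render nuclei and lipid channels from ground truth.

    Discs are drawn anti-aliased, blurred with a normalized Gaussian kernel
    (flux-conserving away from borders), offset by the background level,
    noised per ``config.noise_model`` and quantized to the configured bit
    depth.
    """
    _check_in_bounds(truth, config.field_shape)
    nuc = np.zeros(config.field_shape, dtype=np.float64)
    lip = np.zeros(config.field_shape, dtype=np.float64)
    for cell in truth.cells:
        _add_disc(nuc, cell.nucleus_centroid, cell.nucleus_radius, config.nucleus_intensity)
        for d in cell.droplets:
            _add_disc(lip, d.centroid, d.radius, d.peak_intensity)
    if config.blur_sigma > 0:
        nuc = ndimage.gaussian_filter(nuc, config.blur_sigma, mode="constant")
        lip = ndimage.gaussian_filter(lip, config.blur_sigma, mode="constant")
    nuc += config.background_level
    lip += config.background_level

    if config.noise_model != "none":
        well_key = int.from_bytes(
            hashlib.sha256(truth.well_id.encode()).digest()[:4], "big"
        )
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(well_key, truth.field_index))
        )
        if config.noise_model == "gaussian":
            sd = float(config.noise_params.get("sd", 10.0))
            nuc = nuc + rng.normal(0.0, sd, nuc.shape)
            lip = lip + rng.normal(0.0, sd, lip.shape)
        else:  # poisson_gaussian
            gain = float(config.noise_params.get("gain", 1.0))
            read_sd = float(config.noise_params.get("read_sd", 2.0))
            nuc = rng.poisson(np.maximum(nuc / gain, 0.0)) * gain + rng.normal(0, read_sd, nuc.shape)
            lip = rng.poisson(np.maximum(lip / gain, 0.0)) * gain + rng.normal(0, read_sd, lip.shape)

    def _quantize(a: np.ndarray) -> np.ndarray:
        return np.clip(np.rint(a), 0, config.max_value).astype(config.dtype)

    return FieldImages(
        field_id=truth.field_id,
        nuclei_channel=_quantize(nuc),
        lipid_channel=_quantize(lip),
    )


def render_plate(
    truths: Sequence[FieldTruth], config: ImagingConfig, seed: int = 0
) -> list[FieldImages]:
    return [render_field(t, config, seed=seed) for t in truths]


# ---------------------------------------------------------------------------
# well-level endpoint simulation (fast path for screen-scale statistics)
# ---------------------------------------------------------------------------

ENDPOINTS = (
    "nuclei_count",
    "droplet_count",
    "total_area",
    "total_intensity",
    "n_adipocytes",
    "n_mature",
)


def simulate_endpoint_screen(
    samples: Sequence[str],
    doses: Sequence[float],
    replicates: int,
    control_means: dict[str, float],
    control_sds: dict[str, float],
    effect_sizes: dict[str, float],
    cytotoxic_doses: dict[str, Sequence[float]] | None = None,
    *,
    n_controls: int = 8,
    cytotoxic_drop: float = 0.35,
    affected_endpoints: Sequence[str] = ENDPOINTS[1:],
    seed: int = 0,
    experiment_id: str = "E1",
) -> pd.DataFrame:
    """Well-level endpoint table with planted effects, bypassing rendering.

    Active samples get their adipogenic endpoints shifted by
    ``effect_sizes[sample] * control_sd`` at the top dose, scaled down the
    dilution series proportionally to dose.  Cytotoxic doses depress the
    nuclei count by ``cytotoxic_drop`` (fractional).  Gaussian noise at the
    control SD is added everywhere.  Returns a tidy frame with one row per
    (well, endpoint is a column).
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    cytotoxic_doses = cytotoxic_doses or {}
    top = max(doses)
    rows: list[dict] = []

    for trt in ("negative", "vehicle"):
        for rep in range(1, n_controls // 2 + 1):
            row = {
                "experiment_id": experiment_id,
                "treatment": trt,
                "sample_id": None,
                "dose": 0.0,
                "replicate_index": rep,
            }
            for ep in ENDPOINTS:
                row[ep] = control_means[ep] + rng.normal(0.0, control_sds[ep])
            rows.append(row)

    for sample in samples:
        eff = float(effect_sizes.get(sample, 0.0))
        toxic = set(float(d) for d in cytotoxic_doses.get(sample, ()))
        for dose in doses:
            for rep in range(1, replicates + 1):
                row = {
                    "experiment_id": experiment_id,
                    "treatment": "sample",
                    "sample_id": sample,
                    "dose": float(dose),
                    "replicate_index": rep,
                }
                scale = dose / top
                for ep in ENDPOINTS:
                    mu = control_means[ep]
                    if ep in affected_endpoints:
                        mu = mu + eff * scale * control_sds[ep]
                    if ep == "nuclei_count" and float(dose) in toxic:
                        mu = control_means[ep] * (1.0 - cytotoxic_drop)
                    row[ep] = mu + rng.normal(0.0, control_sds[ep])
                rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# plate I/O
# ---------------------------------------------------------------------------


def truth_to_frames(truths: Sequence[FieldTruth]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flatten truths into a cells table and a droplets table."""
    cell_rows, droplet_rows = [], []
    for t in truths:
        for cell in t.cells:
            cell_rows.append(
                {
                    "well_id": t.well_id,
                    "field_index": t.field_index,
                    "cell_id": cell.cell_id,
                    "nucleus_row": cell.nucleus_centroid[0],
                    "nucleus_col": cell.nucleus_centroid[1],
                    "nucleus_radius": cell.nucleus_radius,
                    "is_adipocyte": cell.is_adipocyte,
                    "n_droplets": len(cell.droplets),
                }
            )
            for di, d in enumerate(cell.droplets):
                droplet_rows.append(
                    {
                        "well_id": t.well_id,
                        "field_index": t.field_index,
                        "cell_id": cell.cell_id,
                        "droplet_index": di,
                        "row": d.centroid[0],
                        "col": d.centroid[1],
                        "radius": d.radius,
                        "peak_intensity": d.peak_intensity,
                    }
                )
    cell_cols = [
        "well_id", "field_index", "cell_id", "nucleus_row", "nucleus_col",
        "nucleus_radius", "is_adipocyte", "n_droplets",
    ]
    droplet_cols = [
        "well_id", "field_index", "cell_id", "droplet_index", "row", "col",
        "radius", "peak_intensity",
    ]
    return (
        pd.DataFrame(cell_rows, columns=cell_cols),
        pd.DataFrame(droplet_rows, columns=droplet_cols),
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_plate(
    design: PlateDesign,
    truths: Sequence[FieldTruth],
    images: Sequence[FieldImages],
    out_dir: str | Path,
) -> Path:
    """Write TIFFs, truth CSVs, the design YAML and a checksum manifest.

    Filenames follow ``{plate}_{well}_{field}_{channel}.tiff``.  Returns the
    manifest path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth_ids = {t.field_id for t in truths}
    image_ids = {im.field_id for im in images}
    if truth_ids != image_ids:
        raise ValueError("truths and images cover different fields")

    entries = []
    for im in images:
        well, fi = im.field_id
        for channel, arr in (("nuclei", im.nuclei_channel), ("lipid", im.lipid_channel)):
            name = f"{design.plate_id}_{well}_{fi}_{channel}.tiff"
            tifffile.imwrite(out / name, arr)
            entries.append({"file": name, "kind": "image", "sha256": _sha256(out / name)})

    cells, droplets = truth_to_frames(truths)
    cells.to_csv(out / "truth_cells.csv", index=False)
    droplets.to_csv(out / "truth_droplets.csv", index=False)
    for name in ("truth_cells.csv", "truth_droplets.csv"):
        entries.append({"file": name, "kind": "truth", "sha256": _sha256(out / name)})

    layout = {
        "plate_id": design.plate_id,
        "coordinate_convention": "0-based (row, col); areas in pixel counts; intensities a.u.",
        "wells": [
            {
                "well_id": w.well_id,
                "treatment": w.treatment,
                "sample_id": w.sample_id,
                "dose": w.dose,
                "replicate_index": w.replicate_index,
            }
            for w in design.wells
        ],
    }
    with open(out / "plate_layout.yaml", "w") as fh:
        yaml.safe_dump(layout, fh, sort_keys=False)
    entries.append(
        {"file": "plate_layout.yaml", "kind": "design", "sha256": _sha256(out / "plate_layout.yaml")}
    )

    manifest_path = out / "manifest.json"
    manifest = {"plate_id": design.plate_id, "n_fields": len(images), "files": entries}
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest_path


def load_plate_layout(path: str | Path) -> PlateDesign:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    wells = [
        WellAssignment(
            w["well_id"], w["treatment"], w.get("sample_id"), float(w["dose"]),
            int(w["replicate_index"]),
        )
        for w in data["wells"]
    ]
    return PlateDesign(plate_id=data["plate_id"], wells=wells)
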