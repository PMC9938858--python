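"""Shared data model, image I/O, calibration and plate-layout handling.

Conventions used throughout the package:

* pixel coordinates are 0-based ``(row, col)``;
* areas are kept in px^2 internally and converted to µm^2 via
  ``pixel_size ** 2`` only when features are reported;
* raw camera units are preserved through I/O — each algorithm states
  whether it works on raw or [0, 1]-rescaled intensities.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

#: channel roles understood by the pipelines
ROLES = ("nuclei", "neuron", "oligodendrocyte")


class DimensionalError(ValueError):
    """Channel planes do not share a common shape."""


class ConfigError(ValueError):
    """Invalid channel-role or calibration configuration."""


@dataclass
class MultiChannelImage:
    """A single imaged field: one 2-D intensity grid per channel role.

    Parameters
    ----------
    channels
        Mapping from role (``nuclei`` / ``neuron`` / ``oligodendrocyte``)
        to a 2-D array of intensities.
    bit_depth_max
        Raw-unit ceiling of the camera (65535 for 16-bit data). After
        contrast stretching this becomes 1.0.
    pixel_size
        Physical calibration in µm per pixel.
    """

    channels: dict
    bit_depth_max: float = 65535.0
    pixel_size: float = 0.6
    field_id: str = ""
    well_id: str = ""

    def __post_init__(self) -> None:
        if not self.channels:
            raise ConfigError("at least one channel is required")
        shapes = {np.asarray(g).shape for g in self.channels.values()}
        if len(shapes) != 1:
            raise DimensionalError(f"channel shapes differ: {sorted(shapes)}")
        (shape,) = shapes
        if len(shape) != 2:
            raise DimensionalError(f"channels must be 2-D, got shape {shape}")
        for role, grid in self.channels.items():
            if role not in ROLES:
                raise ConfigError(f"unknown channel role {role!r}; expected one of {ROLES}")
            g = np.asarray(grid)
            if g.size and (float(g.min()) < 0 or float(g.max()) > self.bit_depth_max):
                raise ValueError(
                    f"channel {role!r} intensities outside [0, {self.bit_depth_max}]"
                )
        if self.pixel_size <= 0:
            raise ConfigError("pixel_size must be > 0")

    @property
    def shape(self) -> tuple:
        return next(iter(self.channels.values())).shape

    def require(self, *roles: str) -> None:
        missing = [r for r in roles if r not in self.channels]
        if missing:
            raise ConfigError(f"missing required channel(s): {missing}")


@dataclass
class PlateLayout:
    """Well → condition/dose assignment for one plate.

    ``table`` has columns ``well_id``, ``condition``, ``dose`` (ng/ml, 0 for
    vehicle) and ``is_control``.
    """

    table: pd.DataFrame

    REQUIRED = ("well_id", "condition", "dose", "is_control")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ConfigError(f"layout missing columns: {missing}")
        if self.table["well_id"].duplicated().any():
            dups = self.table.loc[self.table["well_id"].duplicated(), "well_id"].tolist()
            raise ConfigError(f"duplicate well ids in layout: {dups}")
        self.table = self.table.reset_index(drop=True)

    @classmethod
    def from_records(cls, records: Sequence[tuple]) -> "PlateLayout":
        """Build a layout from ``(well_id, condition, dose, is_control)`` tuples."""
        df = pd.DataFrame(records, columns=list(cls.REQUIRED))
        df["is_control"] = df["is_control"].astype(bool)
        return cls(df)

    @classmethod
    def from_csv(cls, path) -> "PlateLayout":
        df = pd.read_csv(path)
        df["is_control"] = df["is_control"].astype(bool)
        return cls(df)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @property
    def control_wells(self) -> list:
        return self.table.loc[self.table["is_control"], "well_id"].tolist()

    def require_control(self) -> None:
        if not self.control_wells:
            raise ConfigError("layout has no control wells but normalization was requested")

    def condition_of(self, well_id: str) -> str:
        row = self.table.loc[self.table["well_id"] == well_id]
        if row.empty:
            raise ConfigError(f"well {well_id!r} not in layout")
        return str(row["condition"].iloc[0])


@dataclass
class CalibrationConfig:
    """All physical calibration and algorithm tunables in one place.

    Every value can be overridden from YAML; the defaults encode a typical
    20x high-content objective (0.6 µm/px) and the per-step tunables
    described in the docs. Raw-unit thresholds (`common_threshold`,
    `mbp_intensity_window`, `mbp_diff_threshold`) are instrument-specific.
    """

    # physical calibration
    pixel_size: float = 0.6  # µm / px
    expected_ol_diameter: float = 30.0  # µm, footprint of an averaged OL

    # preprocessing
    saturate_frac: float = 0.01
    noise_max_fraction: float = 0.05
    noise_mad_k: float = 6.0
    leak_alpha: float = 1.0
    leak_beta: float = 0.5
    leak_tile_px: int = 64
    leak_exclude_threshold: float = 0.6
    leak_floor: float = 0.05

    # myelination index
    threshold_count: int = 13
    threshold_mode: str = "range"  # "range" | "percentile"
    size_floor_frac: float = 0.20
    neuron_threshold: float = 0.2
    neuron_threshold_mode: str = "range"  # "range" | "percentile"
    aggregate_diameter_px: int = 60
    aggregate_intensity_min: float = 0.9
    aggregate_overlap_frac: float = 0.5
    dust_circularity: float = 0.9
    exclude_border_cells: bool = False

    # differentiation
    nucleus_diameter: float = 10.0  # µm
    detection_sensitivity: float = 0.1
    splitting_sensitivity: float = 0.5
    common_threshold: float = 30.0  # raw units (DAPI)
    cytoplasm_threshold_frac: float = 0.3
    cytoplasm_max_radius_factor: float = 2.0
    mbp_intensity_window: tuple = (100.0, 150.0)  # raw units
    mbp_area_window: tuple = (200.0, 300.0)  # µm^2

    # myelinated segment length
    ridge_scale_px: float = 1.0
    ridge_norm_sigma: float = 5.0
    ridge_norm_floor: float = 1.0  # raw units, division guard
    smoothing_sigma: float = 1.0
    linear_window_px: int = 11
    contrast: float | None = None  # absolute response; None -> percentile
    contrast_percentile: float = 95.0
    min_support_frac: float = 0.1
    min_diameter_px: float = 6.0
    max_gap_px: int = 3
    background_border_px: int = 3
    mbp_diff_threshold: float = 100.0  # raw units, A - B
    axon_intensity_min: float | None = None  # None -> median of segment means

    def __post_init__(self) -> None:
        for name in ("pixel_size", "expected_ol_diameter", "nucleus_diameter"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        self.mbp_intensity_window = tuple(float(v) for v in self.mbp_intensity_window)
        self.mbp_area_window = tuple(float(v) for v in self.mbp_area_window)

    # -- derived quantities ------------------------------------------------
    @property
    def expected_ol_diameter_px(self) -> float:
        return self.expected_ol_diameter / self.pixel_size

    @property
    def expected_ol_area_px(self) -> float:
        """Area of the averaged OL footprint, π (d/2)^2, in px^2."""
        return np.pi * (self.expected_ol_diameter_px / 2.0) ** 2

    @property
    def nucleus_diameter_px(self) -> float:
        return self.nucleus_diameter / self.pixel_size

    # -- serialization -----------------------------------------------------
    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["mbp_intensity_window"] = list(self.mbp_intensity_window)
        data["mbp_area_window"] = list(self.mbp_area_window)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "CalibrationConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown calibration keys: {sorted(unknown)}")
        return cls(**data)


# ---------------------------------------------------------------------------
# image I/O


def _bit_depth_max(dtype: np.dtype) -> float:
    dtype = np.dtype(dtype)
    if dtype.kind == "u" or dtype.kind == "i":
        return float(np.iinfo(dtype).max)
    if dtype.kind == "f":
        return 1.0
    raise ConfigError(f"unsupported TIFF dtype {dtype}")


def read_field(
    source,
    role_map: Mapping[str, object] | None = None,
    calibration: CalibrationConfig | None = None,
    field_id: str = "",
    well_id: str = "",
) -> MultiChannelImage:
    """Read one imaged field from TIFF file(s).

    ``source`` is either a mapping role → single-plane TIFF path, or a single
    multi-page TIFF path together with ``role_map`` mapping role → page index.
    Raw intensities are preserved untouched; ``bit_depth_max`` is taken from
    the file dtype (255 / 65535 for 8-/16-bit).
    """
    calibration = calibration or CalibrationConfig()
    planes: dict = {}
    if isinstance(source, Mapping):
        for role, path in source.items():
            if role not in ROLES:
                raise ConfigError(f"unknown channel role {role!r}")
            planes[role] = tifffile.imread(path)
    else:
        if role_map is None:
            raise ConfigError("role_map (role -> page index) required for multi-page TIFF")
        stack = tifffile.imread(source)
        if stack.ndim == 2:
            stack = stack[None]
        for role, page in role_map.items():
            if role not in ROLES:
                raise ConfigError(f"unknown channel role {role!r}")
            page = int(page)
            if page >= len(stack):
                raise ConfigError(f"page {page} out of range for {source}")
            planes[role] = stack[page]
    if not planes:
        raise ConfigError("no channels requested")
    dtypes = {np.asarray(p).dtype for p in planes.values()}
    bit_max = max(_bit_depth_max(d) for d in dtypes)
    return MultiChannelImage(
        channels={r: np.asarray(p) for r, p in planes.items()},
        bit_depth_max=bit_max,
        pixel_size=calibration.pixel_size,
        field_id=field_id,
        well_id=well_id,
    )


def write_field(img: MultiChannelImage, directory, stem: str | None = None) -> dict:
    """Write one 16-bit single-plane TIFF per channel; returns role → path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = stem or f"{img.well_id or 'well'}_{img.field_id or 'f0'}"
    paths = {}
    for role, grid in img.channels.items():
        path = directory / f"{stem}_{role}.tif"
        tifffile.imwrite(path, np.asarray(grid).astype(np.uint16))
        paths[role] = path
    return paths


def write_results(table: pd.DataFrame, path) -> None:
    """Write a results table to CSV with a stable column order.

    Numeric columns round-trip at full precision (pandas writes ``repr``
    of floats, which is exact in Python 3).
    """
    if table is None or len(table) == 0:
        raise ValueError("refusing to write an empty results table")
    # %.17g guarantees bit-exact float round-trips through the CSV
    table.to_csv(path, index=False, float_format=lambda v: format(v, ".17g"))


def read_results(path) -> pd.DataFrame:
    # round_trip parsing pairs with the %.17g writer for bit-exact floats
    return pd.read_csv(path, float_precision="round_trip")
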