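"""Per-oligodendrocyte myelination-index scoring.

The index of one OL is the fraction of its segmented area covered by high
neuron (axonal) signal: ``high_neuron_area_px / cell_area_px`` ∈ [0, 1].
Detection picks, from a scan across the 20–80% middle intensity band, the
threshold at which the most cells appear; artefacts are removed by two
rules — saturated neuron aggregates that survive erosion with a 60 px
circle become exclusion zones, and near-circular objects (circularity
4πA/P² > 0.9) are dropped as dust.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure, morphology

from .io_types import CalibrationConfig, MultiChannelImage
from . import preprocessing

logger = logging.getLogger(__name__)

#: 8-connectivity structuring element for component labeling
_STRUCT8 = np.ones((3, 3), dtype=bool)

CELL_COLUMNS = [
    "label",
    "cell_area_px",
    "high_neuron_area_px",
    "myelination_index",
    "centroid_row",
    "centroid_col",
    "area_um2",
    "excluded_reason",
]


@dataclass
class ThresholdScanResult:
    """Outcome of the cell-count-maximizing threshold scan."""

    thresholds: np.ndarray  # ascending candidates
    counts: np.ndarray  # cells detected at each candidate
    selected: float  # lowest threshold attaining the max count

    @property
    def selected_index(self) -> int:
        return int(np.argmax(self.counts))


@dataclass
class FieldResult:
    """Full per-field scoring output, kept for QC overlays and debugging."""

    cells: pd.DataFrame
    noise: "preprocessing.NoiseReport | None" = None
    leak: "preprocessing.LeakReport | None" = None
    scan: ThresholdScanResult | None = None
    labels: np.ndarray | None = None
    high_neuron: np.ndarray | None = None
    aggregate_zones: np.ndarray | None = None


def _candidate_thresholds(grid: np.ndarray, cal: CalibrationConfig) -> np.ndarray:
    g = np.asarray(grid, dtype=float)
    lo_r = g.min() + 0.2 * (g.max() - g.min())
    hi_r = g.min() + 0.8 * (g.max() - g.min())
    if cal.threshold_mode == "percentile":
        lo, hi = np.percentile(g, [20.0, 80.0])
        if hi <= lo:  # sparse field: percentiles collapse onto background
            lo, hi = lo_r, hi_r
    else:
        lo, hi = lo_r, hi_r
    return np.linspace(lo, hi, cal.threshold_count)


def _count_cells(grid: np.ndarray, threshold: float, min_area: float) -> int:
    labels, n = ndimage.label(grid > threshold, structure=_STRUCT8)
    if n == 0:
        return 0
    areas = np.bincount(labels.ravel())[1:]
    return int(np.sum(areas >= min_area))


def detect_oligodendrocytes(
    ol_channel: np.ndarray, cal: CalibrationConfig
) -> tuple[np.ndarray, ThresholdScanResult]:
    """Segment OL cells by scanning thresholds across the middle band.

    Candidate thresholds span the 20–80% middle of the intensity range (or
    of the 20th–80th percentiles in percentile mode). At each candidate the
    8-connected components larger than the size floor — 20% of the averaged
    OL area — are counted; the *lowest* threshold attaining the maximum
    count wins (ties broken toward sensitivity). Returns the label grid at
    the winning threshold (background 0, labels 1..n) and the scan record.
    """
    g = np.asarray(ol_channel, dtype=float)
    min_area = cal.size_floor_frac * cal.expected_ol_area_px
    thresholds = _candidate_thresholds(g, cal)
    counts = np.array([_count_cells(g, t, min_area) for t in thresholds])
    selected = float(thresholds[int(np.argmax(counts))])
    scan = ThresholdScanResult(thresholds=thresholds, counts=counts, selected=selected)

    labels, n = ndimage.label(g > selected, structure=_STRUCT8)
    if n:
        areas = np.bincount(labels.ravel())
        keep = np.flatnonzero(areas >= min_area)
        keep = keep[keep > 0]
        remap = np.zeros(areas.size, dtype=np.int32)
        remap[keep] = np.arange(1, keep.size + 1)
        labels = remap[labels]
    if counts.max() == 0:
        logger.warning("no threshold in the scan band yielded any cell")
        labels = np.zeros_like(g, dtype=np.int32)
    return labels.astype(np.int32), scan


def detect_high_neuron(
    neuron_channel: np.ndarray, cell_labels: np.ndarray, cal: CalibrationConfig
) -> np.ndarray:
    """Mask of high neuron signal inside detected cells.

    "Highest 80%, i.e. above 20%": on the stretched [0, 1] scale the default
    is simply intensity > 0.2 (range mode); percentile mode instead anchors
    at the 20th within-image percentile.
    """
    g = np.asarray(neuron_channel, dtype=float)
    if cal.neuron_threshold_mode == "percentile":
        thr = float(np.percentile(g, 100.0 * cal.neuron_threshold))
    else:
        thr = float(cal.neuron_threshold)
    return (g > thr) & (np.asarray(cell_labels) > 0)


def aggregate_zones(
    neuron_channel: np.ndarray, cal: CalibrationConfig
) -> np.ndarray:
    """Exclusion zones from saturated neuron aggregates.

    Seed pixels are near-saturated neuron signal (≥ 99th percentile and
    ≥ ``aggregate_intensity_min``). Regions that survive erosion with a
    circle of the configured diameter (60 px) are reconstructed back to
    their full extent and become exclusion zones; thin axonal structures
    erode away entirely and create none.
    """
    g = np.asarray(neuron_channel, dtype=float)
    seed_thr = max(float(np.percentile(g, 99.0)), cal.aggregate_intensity_min)
    seed = g >= seed_thr
    if not seed.any():
        return np.zeros(g.shape, dtype=bool)
    # pepper impulses punch pinholes that a wide erosion would amplify
    seed = morphology.remove_small_holes(seed, max_size=64)
    radius = max(1, cal.aggregate_diameter_px // 2)
    eroded = morphology.erosion(seed, morphology.disk(radius))
    if not eroded.any():
        return np.zeros(g.shape, dtype=bool)
    recon = morphology.reconstruction(eroded.astype(np.uint8), seed.astype(np.uint8))
    return recon.astype(bool)


def exclude_aggregates(
    neuron_channel: np.ndarray,
    cell_labels: np.ndarray,
    cal: CalibrationConfig,
) -> tuple[np.ndarray, set]:
    """Find aggregate exclusion zones and the cells they swallow.

    Returns the zone mask and the set of cell labels whose overlap with a
    zone exceeds ``aggregate_overlap_frac`` of the cell area.
    """
    zones = aggregate_zones(neuron_channel, cal)
    excluded: set = set()
    labels = np.asarray(cell_labels)
    if zones.any() and labels.max() > 0:
        areas = np.bincount(labels.ravel())
        overlap = np.bincount(labels[zones].ravel(), minlength=areas.size)
        for lab in range(1, areas.size):
            if areas[lab] and overlap[lab] / areas[lab] > cal.aggregate_overlap_frac:
                excluded.add(lab)
    return zones, excluded


def circularity_of(mask: np.ndarray) -> float:
    """4πA/P² of a binary object (1.0 for an ideal disk)."""
    props = measure.regionprops(mask.astype(np.uint8))
    if not props:
        raise ValueError("empty mask")
    p = props[0]
    if p.perimeter == 0:
        return 1.0
    return float(4.0 * np.pi * p.area / p.perimeter**2)


def exclude_dust(cell_labels: np.ndarray, circ_threshold: float = 0.9) -> set:
    """Labels of near-circular objects (likely dust specks).

    Circularity is 4πA/P² with the standard border-chain perimeter
    estimator; objects above ``circ_threshold`` are flagged.
    """
    dust: set = set()
    for p in measure.regionprops(np.asarray(cell_labels)):
        if p.perimeter == 0:
            circ = 1.0
        else:
            circ = 4.0 * np.pi * p.area / p.perimeter**2
        if circ > circ_threshold:
            dust.add(int(p.label))
    return dust


def _border_labels(labels: np.ndarray) -> set:
    edge = np.concatenate([labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]])
    return set(int(v) for v in np.unique(edge) if v > 0)


def score_field(img: MultiChannelImage, cal: CalibrationConfig) -> FieldResult:
    """Run the full index pipeline on one field, keeping intermediates.

    Steps: impulse-noise QC gate → contrast stretch of both channels →
    leak correction and exclusion gate → OL detection (threshold scan) →
    high-neuron mapping → aggregate and dust exclusion → per-cell index.
    A gated-out field returns an empty table with ``attrs['excluded_reason']``
    set to ``"noise"`` or ``"leak"``.
    """
    img.require("neuron", "oligodendrocyte")

    def empty(reason: str, noise=None, leak=None) -> FieldResult:
        df = pd.DataFrame(columns=CELL_COLUMNS)
        df.attrs["excluded_reason"] = reason
        df.attrs["well_id"] = img.well_id
        df.attrs["field_id"] = img.field_id
        return FieldResult(cells=df, noise=noise, leak=leak)

    noise = preprocessing.noise_report(img, cal)
    if not noise.passed:
        return empty("noise", noise=noise)

    stretched = MultiChannelImage(
        channels={
            role: preprocessing.contrast_stretch(grid, cal.saturate_frac)
            for role, grid in img.channels.items()
        },
        bit_depth_max=1.0,
        pixel_size=img.pixel_size,
        field_id=img.field_id,
        well_id=img.well_id,
    )
    cleaned, leak = preprocessing.clean_channel_leak(stretched, cal)
    if leak.excluded:
        return empty("leak", noise=noise, leak=leak)

    neuron = cleaned.channels["neuron"]
    ol = cleaned.channels["oligodendrocyte"]

    labels, scan = detect_oligodendrocytes(ol, cal)
    high = detect_high_neuron(neuron, labels, cal)
    # aggregates are a raw-image phenomenon: the leak correction deliberately
    # dims them, so zones are sought on the stretched pre-clean channel
    zones, agg_excluded = exclude_aggregates(
        stretched.channels["neuron"], labels, cal
    )
    high = high & ~zones  # aggregate zones never count as myelin
    dust = exclude_dust(labels, cal.dust_circularity)
    border = _border_labels(labels) if cal.exclude_border_cells else set()

    areas = np.bincount(labels.ravel())
    high_areas = np.bincount(labels[high].ravel(), minlength=areas.size)
    rows = []
    for p in measure.regionprops(labels):
        lab = int(p.label)
        if lab in agg_excluded:
            reason = "aggregate"
        elif lab in dust:
            reason = "dust"
        elif lab in border:
            reason = "border"
        else:
            reason = None
        area = int(areas[lab])
        high_area = int(high_areas[lab])
        rows.append(
            {
                "label": lab,
                "cell_area_px": area,
                "high_neuron_area_px": high_area if reason is None else np.nan,
                "myelination_index": (high_area / area) if reason is None else np.nan,
                "centroid_row": float(p.centroid[0]),
                "centroid_col": float(p.centroid[1]),
                "area_um2": area * cal.pixel_size**2,
                "excluded_reason": reason,
            }
        )
    cells = pd.DataFrame(rows, columns=CELL_COLUMNS)
    cells.attrs["well_id"] = img.well_id
    cells.attrs["field_id"] = img.field_id
    return FieldResult(
        cells=cells,
        noise=noise,
        leak=leak,
        scan=scan,
        labels=labels,
        high_neuron=high,
        aggregate_zones=zones,
    )


def score_cells(img: MultiChannelImage, cal: CalibrationConfig) -> pd.DataFrame:
    """Per-cell myelination indices for one field (see :func:`score_field`).

    Returns one row per detected OL with ``well``/``field`` identifiers;
    excluded cells carry ``excluded_reason`` and no index.
    """
    result = score_field(img, cal)
    cells = result.cells.copy()
    cells.insert(0, "well", img.well_id)
    cells.insert(1, "field", img.field_id)
    cells.attrs = dict(result.cells.attrs)
    return cells
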