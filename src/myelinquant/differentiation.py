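"""OPC-monoculture differentiation readout: fraction of MBP+ cells.

Nuclei are detected in the DAPI channel (smoothing, thresholding, seeded
watershed splitting), a cytoplasm region is grown around each nucleus in
the MBP channel with a per-object threshold, and a region is MBP+ when its
mean intensity and area fall inside the configured windows (defaults
100–150 raw units and 200–300 µm², closed intervals). The readout is the
ratio a/b of MBP+ cells to all nuclei.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import feature, measure, segmentation

from .io_types import CalibrationConfig, MultiChannelImage

_STRUCT8 = np.ones((3, 3), dtype=bool)

REGION_COLUMNS = [
    "label",
    "area_px",
    "area_um2",
    "mean_intensity",
    "roundness",
    "width_um",
    "length_um",
]


@dataclass
class NucleusSet:
    """Labeled nuclei: label grid plus a per-nucleus feature table."""

    labels: np.ndarray
    table: pd.DataFrame  # label, centroid_row, centroid_col, area_px

    def __len__(self) -> int:
        return len(self.table)


def detect_nuclei(dapi_channel: np.ndarray, cal: CalibrationConfig) -> NucleusSet:
    """Detect nuclei as locally bright DAPI regions.

    Smoothing at σ = diameter/4 → absolute threshold (``common_threshold``,
    raw units) → local-maximum markers spaced by ``splitting_sensitivity ×
    diameter`` → watershed splitting of touching nuclei. Detections whose
    equivalent diameter is outside [0.5, 2] × the configured diameter are
    dropped. An empty image yields an empty set.
    """
    g = np.asarray(dapi_channel, dtype=float)
    d_px = cal.nucleus_diameter_px
    sm = ndimage.gaussian_filter(g, sigma=max(0.5, d_px / 4.0))
    thr = max(cal.common_threshold, cal.detection_sensitivity * float(sm.max()))
    fg = sm > thr

    def _empty() -> NucleusSet:
        return NucleusSet(
            labels=np.zeros(g.shape, dtype=np.int32),
            table=pd.DataFrame(columns=["label", "centroid_row", "centroid_col", "area_px"]),
        )

    if not fg.any():
        return _empty()
    min_distance = max(1, int(round(cal.splitting_sensitivity * d_px)))
    peaks = feature.peak_local_max(sm, min_distance=min_distance, threshold_abs=thr, labels=ndimage.label(fg, structure=_STRUCT8)[0])
    if peaks.size == 0:
        return _empty()
    markers = np.zeros(g.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    labels = segmentation.watershed(-sm, markers=markers, mask=fg, connectivity=2)

    rows = []
    keep_map = np.zeros(int(labels.max()) + 1, dtype=np.int32)
    next_label = 1
    for p in measure.regionprops(labels):
        ed = p.equivalent_diameter_area
        if 0.5 * d_px <= ed <= 2.0 * d_px:
            keep_map[p.label] = next_label
            rows.append(
                {
                    "label": next_label,
                    "centroid_row": float(p.centroid[0]),
                    "centroid_col": float(p.centroid[1]),
                    "area_px": int(p.area),
                }
            )
            next_label += 1
    labels = keep_map[labels]
    return NucleusSet(labels=labels.astype(np.int32), table=pd.DataFrame(rows))


def segment_cytoplasm(
    mbp_channel: np.ndarray, nuclei: NucleusSet, cal: CalibrationConfig
) -> tuple[pd.DataFrame, np.ndarray]:
    """Grow one cytoplasm region per nucleus in the MBP channel.

    Each pixel is admitted when its MBP intensity reaches the per-object
    threshold (``cytoplasm_threshold_frac`` × the mean MBP over the nucleus
    footprint) and lies within ``cytoplasm_max_radius_factor`` × nucleus
    diameter of its nearest nucleus; regions must stay geodesically
    connected to their seed. The nucleus footprint always belongs to its
    region, so a nucleus with no surrounding MBP yields a region of roughly
    the footprint with mean MBP ≈ 0.

    Returns the per-region feature table (mean raw intensity, area in µm²,
    roundness 4πA/P², best-fit-ellipse width/length in µm) and the region
    label grid.
    """
    g = np.asarray(mbp_channel, dtype=float)
    labels = np.asarray(nuclei.labels)
    n = int(labels.max())
    out_labels = np.zeros(g.shape, dtype=np.int32)
    if n == 0:
        return pd.DataFrame(columns=REGION_COLUMNS), out_labels

    # per-seed threshold from the nucleus-footprint mean
    seed_means = ndimage.mean(g, labels=labels, index=np.arange(1, n + 1))
    thresholds = cal.cytoplasm_threshold_frac * np.asarray(seed_means)

    # nearest-nucleus partition of the field
    dist, (ir, ic) = ndimage.distance_transform_edt(labels == 0, return_indices=True)
    nearest = labels[ir, ic]
    max_r = cal.cytoplasm_max_radius_factor * cal.nucleus_diameter_px

    thr_map = np.concatenate([[np.inf], thresholds])[nearest]
    allowed = ((g >= thr_map) & (thr_map > 0) & (dist <= max_r)) | (labels > 0)

    rows = []
    for lab in range(1, n + 1):
        cand = allowed & (nearest == lab)
        # keep only the component geodesically connected to the nucleus
        comp, _ = ndimage.label(cand, structure=_STRUCT8)
        seed_ids = np.unique(comp[labels == lab])
        seed_ids = seed_ids[seed_ids > 0]
        region = np.isin(comp, seed_ids) if seed_ids.size else (labels == lab)
        region |= labels == lab
        out_labels[region] = lab
        props = measure.regionprops(region.astype(np.uint8))[0]
        perim = props.perimeter
        rows.append(
            {
                "label": lab,
                "area_px": int(props.area),
                "area_um2": props.area * cal.pixel_size**2,
                "mean_intensity": float(g[region].mean()),
                "roundness": float(4.0 * np.pi * props.area / perim**2) if perim else 1.0,
                "width_um": float(props.axis_minor_length * cal.pixel_size),
                "length_um": float(props.axis_major_length * cal.pixel_size),
            }
        )
    return pd.DataFrame(rows, columns=REGION_COLUMNS), out_labels


def filter_mbp_positive(
    regions: pd.DataFrame,
    intensity_window: tuple = (100.0, 150.0),
    area_window: tuple = (200.0, 300.0),
) -> pd.DataFrame:
    """MBP+ subset: mean intensity AND area inside the closed windows."""
    if regions.empty:
        return regions.copy()
    ilo, ihi = intensity_window
    alo, ahi = area_window
    mask = (
        regions["mean_intensity"].between(ilo, ihi, inclusive="both")
        & regions["area_um2"].between(alo, ahi, inclusive="both")
    )
    return regions.loc[mask].copy()


def differentiation_ratio(positives: int, nuclei: int) -> float:
    """Ratio a/b of MBP+ cells to total nuclei."""
    if nuclei <= 0:
        raise ValueError("differentiation ratio undefined: no nuclei (b = 0)")
    return positives / nuclei


def analyze_field(img: MultiChannelImage, cal: CalibrationConfig) -> dict:
    """Run the full differentiation readout on one monoculture field.

    Returns counts ``a`` (MBP+), ``b`` (nuclei), the ratio, and the
    per-region feature table.
    """
    img.require("nuclei", "oligodendrocyte")
    nuclei = detect_nuclei(img.channels["nuclei"], cal)
    regions, _ = segment_cytoplasm(img.channels["oligodendrocyte"], nuclei, cal)
    positives = filter_mbp_positive(regions, cal.mbp_intensity_window, cal.mbp_area_window)
    b = len(nuclei)
    a = len(positives)
    return {
        "well": img.well_id,
        "field": img.field_id,
        "a": a,
        "b": b,
        "ratio": differentiation_ratio(a, b) if b else np.nan,
        "regions": regions,
        "positives": positives,
    }


def summarize_differentiation(field_results: list) -> pd.DataFrame:
    """Per-well a, b and ratio; counts are summed before dividing."""
    df = pd.DataFrame(
        [{"well": r["well"], "a": r["a"], "b": r["b"]} for r in field_results]
    )
    grouped = df.groupby("well", as_index=False)[["a", "b"]].sum()
    grouped["ratio"] = grouped["a"] / grouped["b"]
    return grouped
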