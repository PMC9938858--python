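"""Total myelinated-axon length per well.

Pipeline: Hessian ridge enhancement of the neuron channel with kernel
normalization (pixel-wise division by the smoothed original), oriented
line-integral detection of linear features, gap closing, small-object
removal and skeletonization; per-segment MBP foreground mean A and local
background mean B (3 px surrounding band); a traced segment is an axon when
its neuron intensity is high enough, and a myelinated axon when
A − B exceeds the raw-unit difference threshold (default 100).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import filters, morphology

from .io_types import CalibrationConfig, MultiChannelImage, PlateLayout

_STRUCT8 = np.ones((3, 3), dtype=bool)

SEGMENT_COLUMNS = [
    "segment_id",
    "length_um",
    "mbp_mean",  # A
    "background_mean",  # B
    "mbp_difference",  # A - B
    "neuron_mean",
    "touches_border",
    "segment_class",
    "myelinated",
]


@dataclass
class NeuriteSegment:
    """One traced linear segment (geometry; intensities filled in later)."""

    segment_id: int
    skeleton_rc: np.ndarray  # (n, 2) skeleton pixel coordinates
    mask: np.ndarray  # boolean region of the traced feature
    length_um: float
    touches_border: bool


@dataclass
class WellLengthSummary:
    well_id: str
    myelinated_um: float
    unmyelinated_um: float
    normalized: float = np.nan


def ridge_enhance(grid: np.ndarray, cal: CalibrationConfig) -> np.ndarray:
    """Line-enhancing ridge response with kernel normalization.

    Hessian-based tubeness (Sato filter) at σ = ``ridge_scale_px`` responds
    to thin bright curvilinear structures; the response is divided
    pixel-wise by the Gaussian-smoothed original (σ = ``ridge_norm_sigma``,
    floored at ``ridge_norm_floor`` raw units) to flatten the
    illumination-dependent response. A flat image maps to ≈ 0 everywhere.
    """
    g = np.asarray(grid, dtype=float)
    if g.max() == g.min():
        return np.zeros_like(g)
    tube = filters.sato(g, sigmas=[cal.ridge_scale_px], black_ridges=False)
    denom = np.maximum(ndimage.gaussian_filter(g, cal.ridge_norm_sigma), cal.ridge_norm_floor)
    return tube / denom


def _line_kernels(length: int, n_orientations: int = 8) -> list:
    kernels = []
    half = length // 2
    for k in range(n_orientations):
        theta = np.pi * k / n_orientations
        dr, dc = -np.sin(theta), np.cos(theta)
        rr = np.round(np.arange(-half, half + 1) * dr).astype(int)
        cc = np.round(np.arange(-half, half + 1) * dc).astype(int)
        size = 2 * half + 1
        kern = np.zeros((size, size))
        kern[rr + half, cc + half] = 1.0
        kernels.append(kern / kern.sum())
    return kernels


def _skeleton_length_px(skel: np.ndarray) -> float:
    """Length of a skeleton in px: axial links + √2 × diagonal links.

    A diagonal link is skipped when either of its two bridging axial pixels
    is itself on the skeleton (the path then runs through that pixel).
    """
    s = np.asarray(skel, dtype=bool)
    axial = np.count_nonzero(s[:, :-1] & s[:, 1:]) + np.count_nonzero(s[:-1, :] & s[1:, :])
    # down-right diagonals: bridges are (r, c+1) and (r+1, c)
    dr_pair = s[:-1, :-1] & s[1:, 1:]
    dr_bridge = s[:-1, 1:] | s[1:, :-1]
    # down-left diagonals: bridges are (r, c-1) and (r+1, c)
    dl_pair = s[:-1, 1:] & s[1:, :-1]
    dl_bridge = s[:-1, :-1] | s[1:, 1:]
    diag = np.count_nonzero(dr_pair & ~dr_bridge) + np.count_nonzero(dl_pair & ~dl_bridge)
    return axial + np.sqrt(2.0) * diag


def trace_segments(
    enhanced: np.ndarray, cal: CalibrationConfig
) -> list:
    """Trace linear features in a ridge-enhanced grid.

    Gaussian smoothing → oriented line-integral detector over 8
    orientations of a window of ``linear_window_px``; the response is the
    *anisotropy* (best minus worst orientation), which is high along thin
    lines and ≈ 0 on isotropic blobs and flats → binarize at the contrast
    threshold (absolute if configured, else the configured percentile of
    the response) → morphological closing with a disk of radius
    ``max_gap_px`` → drop objects with equivalent diameter below
    ``min_diameter_px`` → skeletonize. Each 8-connected skeleton component
    becomes one :class:`NeuriteSegment`; length is the axial + √2·diagonal
    step count times the pixel size.
    """
    g = np.asarray(enhanced, dtype=float)
    sm = ndimage.gaussian_filter(g, cal.smoothing_sigma)
    best = np.full_like(sm, -np.inf)
    worst = np.full_like(sm, np.inf)
    for kern in _line_kernels(int(cal.linear_window_px)):
        resp = ndimage.correlate(sm, kern, mode="nearest")
        np.maximum(best, resp, out=best)
        np.minimum(worst, resp, out=worst)
    response = best - worst
    if cal.contrast is not None:
        thr = float(cal.contrast)
    else:
        thr = float(np.percentile(response, cal.contrast_percentile))
    binary = response > max(thr, 0.0)
    # restrict to the ridge's own support: the oriented windows smear an
    # object's response over the window length, which would let isotropic
    # specks masquerade as >window-sized objects
    if g.max() > 0:
        binary &= g > cal.min_support_frac * g.max()
    if cal.max_gap_px > 0:
        binary = morphology.closing(binary, morphology.disk(cal.max_gap_px))
    labels, n = ndimage.label(binary, structure=_STRUCT8)
    if n:
        areas = np.bincount(labels.ravel())
        eq_diam = np.sqrt(4.0 * areas / np.pi)
        drop = eq_diam < cal.min_diameter_px
        drop[0] = True
        binary[drop[labels]] = False

    skeleton = morphology.skeletonize(binary)
    seg_labels, n_seg = ndimage.label(skeleton, structure=_STRUCT8)
    mask_labels, _ = ndimage.label(binary, structure=_STRUCT8)
    segments = []
    h, w = binary.shape
    for sid in range(1, n_seg + 1):
        skel = seg_labels == sid
        coords = np.argwhere(skel)
        mask_label = mask_labels[coords[0, 0], coords[0, 1]]
        mask = mask_labels == mask_label if mask_label else skel
        touches = bool(
            mask[0, :].any() or mask[-1, :].any() or mask[:, 0].any() or mask[:, -1].any()
        )
        segments.append(
            NeuriteSegment(
                segment_id=sid,
                skeleton_rc=coords,
                mask=mask,
                length_um=_skeleton_length_px(skel) * cal.pixel_size,
                touches_border=touches,
            )
        )
    return segments


def measure_background(
    segment_mask: np.ndarray, mbp_channel: np.ndarray, border_px: int = 3
) -> float:
    """Local background mean B in the ``border_px`` band around a segment.

    The band is the dilation of the segment minus the segment itself; at
    field edges the band is simply clipped at the image border (pixels
    beyond the border are not invented). If the band is empty the mean over
    all remaining non-segment pixels is used.
    """
    mask = np.asarray(segment_mask, dtype=bool)
    g = np.asarray(mbp_channel, dtype=float)
    band = morphology.dilation(mask, morphology.disk(border_px)) & ~mask
    if band.any():
        return float(g[band].mean())
    rest = ~mask
    if rest.any():
        return float(g[rest].mean())
    return 0.0


def measure_segments(
    segments: list,
    mbp_channel: np.ndarray,
    neuron_channel: np.ndarray,
    cal: CalibrationConfig,
) -> pd.DataFrame:
    """Per-segment intensity features on RAW channels: A, B, A−B, neuron mean."""
    mbp = np.asarray(mbp_channel, dtype=float)
    neuron = np.asarray(neuron_channel, dtype=float)
    rows = []
    for seg in segments:
        a = float(mbp[seg.mask].mean())
        b = measure_background(seg.mask, mbp, cal.background_border_px)
        rows.append(
            {
                "segment_id": seg.segment_id,
                "length_um": seg.length_um,
                "mbp_mean": a,
                "background_mean": b,
                "mbp_difference": a - b,
                "neuron_mean": float(neuron[seg.mask].mean()),
                "touches_border": seg.touches_border,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[c for c in SEGMENT_COLUMNS if c not in ("segment_class", "myelinated")],
    )


def classify_segments(
    measured: pd.DataFrame,
    axon_intensity_min: float | None = None,
    mbp_diff_threshold: float = 100.0,
) -> pd.DataFrame:
    """Label segments as (un)myelinated axons.

    Border-touching segments are dropped first. Remaining segments with
    neuron mean ≥ ``axon_intensity_min`` (default: the median neuron mean,
    a data-driven stand-in for the manually adjusted intensity) are axons;
    an axon is myelinated iff A − B > ``mbp_diff_threshold``. Myelinated and
    unmyelinated axons partition the axon set.
    """
    df = measured.loc[~measured["touches_border"]].copy()
    if df.empty:
        df["segment_class"] = pd.Series(dtype=object)
        df["myelinated"] = pd.Series(dtype=bool)
        return df
    if axon_intensity_min is None:
        axon_intensity_min = float(df["neuron_mean"].median())
    is_axon = df["neuron_mean"] >= axon_intensity_min
    df["segment_class"] = np.where(is_axon, "axon", "non-axon")
    df["myelinated"] = is_axon & (df["mbp_difference"] > mbp_diff_threshold)
    return df


def measure_field_lengths(img: MultiChannelImage, cal: CalibrationConfig) -> pd.DataFrame:
    """Full per-field pipeline: trace on the neuron channel, classify by MBP."""
    img.require("neuron", "oligodendrocyte")
    enhanced = ridge_enhance(img.channels["neuron"], cal)
    segments = trace_segments(enhanced, cal)
    measured = measure_segments(
        segments, img.channels["oligodendrocyte"], img.channels["neuron"], cal
    )
    classified = classify_segments(
        measured, cal.axon_intensity_min, cal.mbp_diff_threshold
    )
    classified.insert(0, "well", img.well_id)
    classified.insert(1, "field", img.field_id)
    return classified


def summarize_well(
    segments: pd.DataFrame, layout: PlateLayout | None = None
) -> pd.DataFrame:
    """Sum (un)myelinated axon lengths per well; normalize to control mean.

    ``segments`` must carry a ``well`` column (fields of a well are summed
    together). With a layout, totals are divided by the mean myelinated
    total of the control wells; the mean of control wells maps to 1.0.
    """
    ax = segments.loc[segments["segment_class"] == "axon"]
    summary = []
    for well, grp in ax.groupby("well"):
        summary.append(
            {
                "well": well,
                "myelinated_um": float(grp.loc[grp["myelinated"], "length_um"].sum()),
                "unmyelinated_um": float(grp.loc[~grp["myelinated"], "length_um"].sum()),
            }
        )
    out = pd.DataFrame(summary, columns=["well", "myelinated_um", "unmyelinated_um"])
    if layout is not None:
        layout.require_control()
        controls = out.loc[out["well"].isin(layout.control_wells), "myelinated_um"]
        if controls.empty or controls.mean() == 0:
            raise ValueError("control wells have zero myelinated length; cannot normalize")
        out["normalized"] = out["myelinated_um"] / controls.mean()
    return out
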