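"""Image conditioning ahead of myelination-index scoring.

Four steps: impulse ("salt and pepper") noise estimation for image QC,
percentile contrast stretching to a common [0, 1] scale, bidirectional
channel bleed-through ("leak") correction by Gaussian reweighting, and a
tile-correlation gate that excludes fields whose leak is beyond repair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io_types import CalibrationConfig, MultiChannelImage


@dataclass
class NoiseReport:
    """Per-channel impulse-noise fractions and the pass/fail QC verdict."""

    fractions: dict
    max_fraction: float
    passed: bool


@dataclass
class LeakReport:
    """Summary tile-wise spatial correlation between neuron and OL channels.

    ``excluded`` is True iff ``leak_score`` exceeds the configured ceiling —
    such a field is dominated by bleed-through and is dropped from scoring.
    """

    leak_score: float
    threshold: float
    excluded: bool


def _min_neighbor_diff(g: np.ndarray) -> np.ndarray:
    """Per-pixel minimum |difference| to its 8 neighbors (reflect-padded)."""
    p = np.pad(g, 1, mode="reflect")
    h, w = g.shape
    out = np.full(g.shape, np.inf)
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            np.minimum(out, np.abs(g - p[1 + dr : 1 + dr + h, 1 + dc : 1 + dc + w]), out=out)
    return out


def estimate_noise(grid: np.ndarray, mad_k: float = 6.0) -> float:
    """Estimate the fraction of impulse-noise ("salt and pepper") pixels.

    The residual is each pixel's *minimum* absolute difference to its 8
    neighbors: a genuine impulse is isolated and differs from every
    neighbor, while pixels on thin curvilinear structures (axons, OL
    processes — the dominant content of these fields) always have a similar
    neighbor along the structure and score ≈ 0. A pixel is an impulse when
    its residual exceeds ``mad_k`` times the robust spread (1.4826·MAD) of
    the residual over the image. On mostly-flat images the MAD collapses to
    zero; then, if the zero-residual part of the image is itself perfectly
    flat, every deviating pixel is an impulse by definition, and otherwise
    the spread is re-estimated from the non-zero residuals. Deterministic;
    a constant image yields 0. Only visible impulses count (pepper on black
    background is undetectable in principle).
    """
    g = np.asarray(grid, dtype=float)
    if g.size == 0:
        raise ValueError("empty image")
    ptp = float(g.max() - g.min())
    if ptp == 0:
        return 0.0
    resid = _min_neighbor_diff(g)
    sigma = 1.4826 * float(np.median(np.abs(resid - np.median(resid))))
    if sigma > 0:
        return float(np.mean(resid > mad_k * sigma))
    nonzero = resid > 1e-6 * ptp
    frac_nonzero = float(np.mean(nonzero))
    if frac_nonzero == 0:
        return 0.0
    background = g[~nonzero]
    if background.size:
        # flat-background shortcut: on an otherwise constant image every
        # *isolated* deviator is an impulse by definition. Judge flatness on
        # the central 99% of the background (paired impulses leak into it),
        # and require the deviators to be mostly isolated — contiguous
        # deviating blobs are structure, not noise.
        lo, hi = np.percentile(background, [0.5, 99.5])
        neighbor_counts = ndimage.convolve(
            nonzero.astype(np.uint8), np.ones((3, 3), dtype=np.uint8), mode="constant"
        )
        isolated_frac = float(np.mean(neighbor_counts[nonzero] == 1))
        if float(hi - lo) <= 1e-9 * ptp and isolated_frac > 0.5:
            return frac_nonzero
    med_nonzero = float(np.median(resid[nonzero]))
    if med_nonzero > 0.2 * ptp:
        # the typical deviation spans a fifth of the dynamic range: that is
        # impulse-dominated, not texture — count the deviators outright
        return frac_nonzero
    sigma = 1.4826 * med_nonzero
    return float(np.mean(resid > mad_k * sigma))


def noise_report(img: MultiChannelImage, cal: CalibrationConfig) -> NoiseReport:
    fractions = {
        role: estimate_noise(grid, cal.noise_mad_k) for role, grid in img.channels.items()
    }
    passed = all(f <= cal.noise_max_fraction for f in fractions.values())
    return NoiseReport(fractions=fractions, max_fraction=cal.noise_max_fraction, passed=passed)


def contrast_stretch(grid: np.ndarray, saturate_frac: float = 0.01) -> np.ndarray:
    """Linearly rescale to [0, 1], saturating ``saturate_frac`` at each end.

    The lowest and highest percentiles map to 0 and 1 respectively, with
    values beyond them clipped; a constant image maps to all zeros. The
    mapping is monotone non-decreasing.
    """
    g = np.asarray(grid, dtype=float)
    if g.size == 0:
        raise ValueError("empty image")
    lo, hi = np.percentile(g, [100.0 * saturate_frac, 100.0 * (1.0 - saturate_frac)])
    if hi <= lo:
        return np.zeros_like(g)
    return np.clip((g - lo) / (hi - lo), 0.0, 1.0)


def tile_leak_score(neuron: np.ndarray, ol: np.ndarray, tile_px: int = 64) -> float:
    """Median Pearson correlation over non-overlapping tiles.

    Tiles where both channels vary contribute their Pearson coefficient.
    A tile where one channel varies while the other stays flat is maximal
    evidence *against* bleed-through (leak would copy the variation across)
    and contributes 0; tiles flat in both channels are uninformative and
    are skipped. Returns 0.0 when no tile is informative. High values mean
    the two channels carry the same spatial structure, i.e. bleed-through.
    """
    n = np.asarray(neuron, dtype=float)
    o = np.asarray(ol, dtype=float)
    if n.shape != o.shape:
        raise ValueError("channel shapes differ")
    h, w = n.shape
    cors = []
    for r0 in range(0, h - tile_px + 1, tile_px):
        for c0 in range(0, w - tile_px + 1, tile_px):
            tn = n[r0 : r0 + tile_px, c0 : c0 + tile_px].ravel()
            to = o[r0 : r0 + tile_px, c0 : c0 + tile_px].ravel()
            n_varies, o_varies = tn.std() > 0, to.std() > 0
            if n_varies and o_varies:
                cors.append(float(np.corrcoef(tn, to)[0, 1]))
            elif n_varies or o_varies:
                cors.append(0.0)
    if not cors:
        # tiny images: fall back to a single whole-image tile
        if h < tile_px or w < tile_px:
            if n.std() > 0 and o.std() > 0:
                return float(np.corrcoef(n.ravel(), o.ravel())[0, 1])
        return 0.0
    return float(np.median(cors))


def clean_channel_leak(
    img: MultiChannelImage, cal: CalibrationConfig
) -> tuple[MultiChannelImage, LeakReport]:
    """Suppress bleed-through between the neuron and OL channels.

    Both channels must already be contrast-stretched to [0, 1]. A wide
    Gaussian (σ = expected OL diameter / 2, in px) estimates where each
    channel's own cellular signal lives:

    * the OL channel is multiplied by a factor *proportional to* its blurred
      self (blended by ``leak_alpha``: multiplier = (1−α) + α·Ĝ/max Ĝ) —
      genuine OL somata/arbours keep their weight while thin, far-from-soma
      leak traces of axons are scaled down toward zero;
    * the neuron channel is reweighted *downward* proportionally to its
      blurred self (multiplier = 1 − β·Ĝ/max Ĝ), suppressing blobby
      OL-shaped leak.

    After reweighting, residue below ``leak_floor`` carries no evidence of
    cellular structure and is zeroed — this is what actually removes leak
    support (a smooth multiplicative factor alone leaves the tile-wise
    Pearson correlation essentially unchanged). A correction is only
    applied when the leak's source channel carries any signal (an empty OL
    channel cannot leak into the neuron image). Outputs stay in [0, 1]. The
    returned ``LeakReport`` carries the tile-correlation score of the
    *input* pair; fields above the configured ceiling are flagged excluded.
    """
    img.require("neuron", "oligodendrocyte")
    neuron = np.asarray(img.channels["neuron"], dtype=float)
    ol = np.asarray(img.channels["oligodendrocyte"], dtype=float)

    score = tile_leak_score(neuron, ol, cal.leak_tile_px)
    report = LeakReport(
        leak_score=score,
        threshold=cal.leak_exclude_threshold,
        excluded=bool(score > cal.leak_exclude_threshold),
    )

    sigma = cal.expected_ol_diameter_px / 2.0
    ol_out = ol.copy()
    neuron_out = neuron.copy()
    if neuron.max() > 0 and ol.max() > 0:
        g_ol = ndimage.gaussian_filter(ol, sigma)
        if g_ol.max() > 0:
            mult = (1.0 - cal.leak_alpha) + cal.leak_alpha * g_ol / g_ol.max()
            ol_out = np.clip(ol * mult, 0.0, 1.0)
            ol_out[ol_out < cal.leak_floor] = 0.0
        g_n = ndimage.gaussian_filter(neuron, sigma)
        if g_n.max() > 0:
            neuron_out = np.clip(
                neuron * (1.0 - cal.leak_beta * g_n / g_n.max()), 0.0, 1.0
            )
            neuron_out[neuron_out < cal.leak_floor] = 0.0

    channels = dict(img.channels)
    channels["neuron"] = neuron_out
    channels["oligodendrocyte"] = ol_out
    cleaned = MultiChannelImage(
        channels=channels,
        bit_depth_max=max(1.0, float(img.bit_depth_max)),
        pixel_size=img.pixel_size,
        field_id=img.field_id,
        well_id=img.well_id,
    )
    return cleaned, report
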