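"""Ground-truthed synthetic fluorescence fields for co- and monocultures.

The generator states an idealized but recognizable world: dense beds of
thin bright axon lines with optional saturated round RGC aggregates in the
neuron channel; oligodendrocytes as a soma plus radial processes in the OL
channel, with a *planted* fraction of each OL's pixels co-localizing with
high neuron signal (the quantity the index pipeline must recover);
optional additive cross-channel leak, bright hard-edged dust disks, and
salt-and-pepper impulse noise applied last. Rendering is quantized to
16-bit integers so a fixed seed reproduces images bit-exactly.

Deliberate idealizations (see docs/methods.md): background axon lines are
not drawn inside OL ground-truth masks, so the planted per-cell overlap
fraction is exact by construction; bleed-through and aggregates default to
off and are explicit dials.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from skimage import draw, morphology

from .io_types import CalibrationConfig, MultiChannelImage, PlateLayout


class SpecError(ValueError):
    """Invalid scene specification."""


@dataclass
class SceneSpec:
    """Declarative description of one synthetic field.

    Intensities are on a [0, 1] scale before 16-bit quantization; lengths
    and diameters are in pixels unless suffixed ``_um``.
    """

    size: int = 512
    pixel_size: float = 0.6  # µm/px
    bit_depth_max: int = 65535
    seed: int = 0

    # neuron channel
    n_neuron_lines: int = 30
    line_width_px: float = 2.0
    line_intensity: float = 0.55
    n_aggregates: int = 0
    aggregate_diameter_px: float = 100.0
    aggregate_centers: tuple | None = None  # explicit (row, col) centers

    # oligodendrocyte channel
    n_ols: int = 4
    ol_soma_diameter_px: float = 20.0
    n_processes: int = 8
    process_length_px: float = 24.0
    process_width_px: float = 3.0
    ol_intensity: float = 0.8
    myelin_intensity: float = 0.9
    planted_fractions: tuple | None = None  # per OL; None -> uniform random

    # contaminants
    leak_neuron_to_ol: float = 0.0
    leak_ol_to_neuron: float = 0.0
    impulse_fraction: float = 0.002
    n_dust: int = 0
    dust_diameter_px: tuple = (10.0, 20.0)

    # axon-field mode (myelinated segment-length pipeline)
    n_axons: int = 8
    axon_myelinated_fraction: float = 0.5
    axon_mbp_intensity: float = 400.0  # raw units on myelinated sheaths
    mbp_background: float = 20.0  # raw units
    axon_margin_px: int = 12

    # monoculture mode
    n_cells: int = 100
    positive_fraction: float = 0.4
    nucleus_diameter_um: float = 10.0
    dapi_peak: float = 200.0  # raw units after quantization scale (see render)
    mbp_positive_intensity: float = 125.0  # raw units
    mbp_positive_area_um2: float = 250.0
    mbp_negative_intensity: float = 40.0
    mbp_negative_area_um2: float = 80.0
    mono_impulse_fraction: float = 0.0

    def __post_init__(self) -> None:
        for name in ("impulse_fraction", "positive_fraction", "mono_impulse_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SpecError(f"{name} must be in [0, 1], got {v}")
        if self.planted_fractions is not None:
            fr = tuple(float(f) for f in self.planted_fractions)
            if any(not 0.0 <= f <= 1.0 for f in fr):
                raise SpecError("planted_fractions must be in [0, 1]")
            if len(fr) != self.n_ols:
                raise SpecError("planted_fractions length must equal n_ols")
            self.planted_fractions = fr
        for name in ("leak_neuron_to_ol", "leak_ol_to_neuron"):
            if getattr(self, name) < 0:
                raise SpecError(f"{name} must be >= 0")

    def replace(self, **kw) -> "SceneSpec":
        return dataclasses.replace(self, **kw)


@dataclass
class GroundTruth:
    """Everything a test oracle needs, independent of the pipelines."""

    ol_masks: list = field(default_factory=list)  # boolean per OL
    myelin_masks: list = field(default_factory=list)  # planted high-neuron per OL
    planted_fractions: np.ndarray = field(default_factory=lambda: np.zeros(0))
    aggregate_mask: np.ndarray | None = None
    dust_masks: list = field(default_factory=list)
    neuron_line_mask: np.ndarray | None = None
    # monoculture
    nucleus_centers: np.ndarray | None = None
    positive_flags: np.ndarray | None = None
    positive_fraction: float = np.nan
    # axon fields
    axon_lengths_um: np.ndarray | None = None
    axon_myelinated: np.ndarray | None = None


@dataclass
class PlateGroundTruth:
    fields: dict  # well_id -> list of (MultiChannelImage, GroundTruth)
    planted_mean: dict  # well_id -> mean planted myelination fraction
    layout: PlateLayout


def _thick_line(shape: tuple, p0: tuple, p1: tuple, width: float) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    rr, cc = draw.line(int(p0[0]), int(p0[1]), int(p1[0]), int(p1[1]))
    ok = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
    mask[rr[ok], cc[ok]] = True
    r = max(0, int(round((width - 1) / 2)))
    if r:
        mask = morphology.dilation(mask, morphology.disk(r))
    return mask


def _disk_mask(shape: tuple, center: tuple, radius: float) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    rr, cc = draw.disk(center, radius, shape=shape)
    mask[rr, cc] = True
    return mask


def _ol_mask(spec: SceneSpec, center: tuple, rng: np.random.Generator) -> np.ndarray:
    """Soma disk plus radial processes: a star shape (circularity << 0.9)."""
    shape = (spec.size, spec.size)
    soma_r = spec.ol_soma_diameter_px / 2.0
    mask = _disk_mask(shape, center, soma_r)
    for k in range(spec.n_processes):
        theta = 2.0 * np.pi * k / spec.n_processes + rng.uniform(-0.15, 0.15)
        end = (
            center[0] + (soma_r + spec.process_length_px) * np.sin(theta),
            center[1] + (soma_r + spec.process_length_px) * np.cos(theta),
        )
        mask |= _thick_line(shape, center, end, spec.process_width_px)
    return mask


def _plant_myelin(
    mask: np.ndarray, center: tuple, fraction: float
) -> tuple[np.ndarray, float]:
    """Choose the planted high-neuron subset of an OL mask.

    Pixels are taken in order of decreasing distance from the soma center —
    myelinating processes first, soma last — until the requested fraction
    of the mask is covered. Returns the subset mask and the exact fraction.
    """
    coords = np.argwhere(mask)
    d2 = (coords[:, 0] - center[0]) ** 2 + (coords[:, 1] - center[1]) ** 2
    order = np.argsort(-d2, kind="stable")
    n_high = int(round(fraction * len(coords)))
    chosen = coords[order[:n_high]]
    s = np.zeros_like(mask)
    s[chosen[:, 0], chosen[:, 1]] = True
    return s, n_high / len(coords)


def _apply_impulse(
    grid: np.ndarray, fraction: float, rng: np.random.Generator
) -> np.ndarray:
    if fraction <= 0:
        return grid
    n = grid.size
    k = int(round(fraction * n))
    if k == 0:
        return grid
    idx = rng.choice(n, size=k, replace=False)
    flat = grid.ravel()
    flat[idx[: k // 2]] = 0.0
    flat[idx[k // 2 :]] = 1.0
    return flat.reshape(grid.shape)


def _quantize(grid: np.ndarray, bit_max: int) -> np.ndarray:
    return np.round(np.clip(grid, 0.0, 1.0) * bit_max).astype(np.uint16)


def _grid_centers(
    size: int, n: int, margin: float, rng: np.random.Generator, jitter: float
) -> np.ndarray:
    """Jittered grid placement guaranteeing non-overlapping footprints."""
    per_side = int(np.ceil(np.sqrt(n)))
    usable = size - 2 * margin
    if usable <= 0:
        raise SpecError("field too small for the requested objects")
    step = usable / max(per_side - 1, 1) if per_side > 1 else 0.0
    slots = [
        (margin + i * step, margin + j * step)
        for i in range(per_side)
        for j in range(per_side)
    ]
    order = rng.permutation(len(slots))[:n]
    centers = np.array([slots[i] for i in order], dtype=float)
    centers += rng.uniform(-jitter, jitter, size=centers.shape)
    return np.clip(centers, margin * 0.5, size - margin * 0.5)


def generate_coculture_field(
    spec: SceneSpec, field_id: str = "f0", well_id: str = "W0"
) -> tuple[MultiChannelImage, GroundTruth]:
    """Render one RGC–OPC co-culture field with exact per-OL ground truth."""
    rng = np.random.default_rng(spec.seed)
    shape = (spec.size, spec.size)
    neuron = np.zeros(shape)
    ol = np.zeros(shape)
    gt = GroundTruth()

    # --- oligodendrocytes -------------------------------------------------
    extent = spec.ol_soma_diameter_px / 2.0 + spec.process_length_px
    if spec.n_ols:
        centers = _grid_centers(spec.size, spec.n_ols, extent + 8, rng, jitter=6.0)
        if spec.planted_fractions is not None:
            fractions = np.asarray(spec.planted_fractions, dtype=float)
        else:
            fractions = rng.uniform(0.0, 1.0, size=spec.n_ols)
        for center, f in zip(centers, fractions):
            mask = _ol_mask(spec, tuple(center), rng)
            texture = rng.normal(0.0, 0.03, size=int(mask.sum()))
            vals = np.clip(spec.ol_intensity * (1.0 + texture), 0.6, 0.95)
            ol[mask] = np.maximum(ol[mask], vals)
            s, f_exact = _plant_myelin(mask, tuple(center), f)
            gt.ol_masks.append(mask)
            gt.myelin_masks.append(s)
            gt.planted_fractions = np.append(gt.planted_fractions, f_exact)
    ol_union = np.zeros(shape, dtype=bool)
    for m in gt.ol_masks:
        ol_union |= m

    # --- neuron lines (kept out of OL footprints: exact ground truth) -----
    line_mask = np.zeros(shape, dtype=bool)
    for _ in range(spec.n_neuron_lines):
        edge0, edge1 = rng.choice(4, size=2, replace=False)

        def _edge_point(e: int) -> tuple:
            t = rng.uniform(0, spec.size - 1)
            return [(0, t), (spec.size - 1, t), (t, 0), (t, spec.size - 1)][e]

        line_mask |= _thick_line(shape, _edge_point(edge0), _edge_point(edge1), spec.line_width_px)
    line_mask &= ~ol_union
    vals = np.clip(
        spec.line_intensity * (1.0 + rng.normal(0.0, 0.05, size=int(line_mask.sum()))),
        0.3,
        0.8,
    )
    neuron[line_mask] = vals
    gt.neuron_line_mask = line_mask

    # planted myelin: high neuron signal on the chosen OL pixels
    for s in gt.myelin_masks:
        neuron[s] = np.maximum(neuron[s], spec.myelin_intensity)

    # --- aggregates: saturated flat-top blobs with a soft skirt -----------
    agg_mask = np.zeros(shape, dtype=bool)
    if spec.n_aggregates:
        if spec.aggregate_centers is not None:
            agg_centers = np.asarray(spec.aggregate_centers, dtype=float)
        else:
            agg_centers = rng.uniform(
                spec.aggregate_diameter_px, spec.size - spec.aggregate_diameter_px,
                size=(spec.n_aggregates, 2),
            )
        yy, xx = np.mgrid[0 : spec.size, 0 : spec.size]
        for center in agg_centers[: spec.n_aggregates]:
            r = np.hypot(yy - center[0], xx - center[1])
            core = 0.35 * spec.aggregate_diameter_px
            sigma = 0.15 * spec.aggregate_diameter_px
            profile = np.where(r <= core, 1.0, np.exp(-((r - core) ** 2) / (2 * sigma**2)))
            neuron = np.maximum(neuron, profile)
            agg_mask |= r <= spec.aggregate_diameter_px / 2.0
    gt.aggregate_mask = agg_mask

    # --- dust: hard-edged bright disks in the OL channel ------------------
    for _ in range(spec.n_dust):
        d = rng.uniform(*spec.dust_diameter_px)
        for _attempt in range(50):
            c = rng.uniform(d, spec.size - d, size=2)
            dm = _disk_mask(shape, tuple(c), d / 2.0)
            if not (dm & morphology.dilation(ol_union, morphology.disk(3))).any():
                ol[dm] = 0.95
                gt.dust_masks.append(dm)
                break

    # --- cross-channel leak ----------------------------------------------
    ol_leaked = np.clip(ol + spec.leak_neuron_to_ol * neuron, 0.0, 1.0)
    neuron_leaked = np.clip(neuron + spec.leak_ol_to_neuron * ol, 0.0, 1.0)

    # --- impulse noise last so the noise estimator sees the planted rate --
    neuron_leaked = _apply_impulse(neuron_leaked, spec.impulse_fraction, rng)
    ol_leaked = _apply_impulse(ol_leaked, spec.impulse_fraction, rng)

    img = MultiChannelImage(
        channels={
            "neuron": _quantize(neuron_leaked, spec.bit_depth_max),
            "oligodendrocyte": _quantize(ol_leaked, spec.bit_depth_max),
        },
        bit_depth_max=float(spec.bit_depth_max),
        pixel_size=spec.pixel_size,
        field_id=field_id,
        well_id=well_id,
    )
    return img, gt


def generate_monoculture_field(
    spec: SceneSpec, field_id: str = "f0", well_id: str = "W0"
) -> tuple[MultiChannelImage, GroundTruth]:
    """Render one OPC-monoculture field (DAPI nuclei + MBP cytoplasm).

    A planted fraction of the cells carries a uniform MBP disk whose mean
    intensity and area sit inside the default MBP+ windows (125 raw units,
    250 µm²); the rest fail one window each — half by area (small bright
    disk), half by intensity (dim full-size disk).
    """
    rng = np.random.default_rng(spec.seed)
    shape = (spec.size, spec.size)
    d_px = spec.nucleus_diameter_um / spec.pixel_size
    pos_r = np.sqrt(spec.mbp_positive_area_um2 / np.pi) / spec.pixel_size
    neg_r = np.sqrt(spec.mbp_negative_area_um2 / np.pi) / spec.pixel_size

    margin = 2.5 * pos_r
    centers = _grid_centers(spec.size, spec.n_cells, margin, rng, jitter=3.0)

    dapi = np.full(shape, 2.0 / spec.bit_depth_max)
    mbp = np.zeros(shape)
    yy, xx = np.mgrid[0 : spec.size, 0 : spec.size]
    sigma = d_px / 3.0
    n_pos = int(round(spec.positive_fraction * spec.n_cells))
    order = rng.permutation(spec.n_cells)
    positive = np.zeros(spec.n_cells, dtype=bool)
    positive[order[:n_pos]] = True

    for i, center in enumerate(centers):
        r2 = (yy - center[0]) ** 2 + (xx - center[1]) ** 2
        blob = (spec.dapi_peak / spec.bit_depth_max) * np.exp(-r2 / (2 * sigma**2))
        dapi = np.maximum(dapi, blob)
        if positive[i]:
            dm = _disk_mask(shape, tuple(center), pos_r)
            mbp[dm] = spec.mbp_positive_intensity / spec.bit_depth_max
        elif i % 2 == 0:  # area-window failure: small but bright
            dm = _disk_mask(shape, tuple(center), neg_r)
            mbp[dm] = spec.mbp_positive_intensity / spec.bit_depth_max
        else:  # intensity-window failure: full size but dim
            dm = _disk_mask(shape, tuple(center), pos_r)
            mbp[dm] = spec.mbp_negative_intensity / spec.bit_depth_max

    dapi = _apply_impulse(dapi, spec.mono_impulse_fraction, rng)
    mbp = _apply_impulse(mbp, spec.mono_impulse_fraction, rng)

    img = MultiChannelImage(
        channels={
            "nuclei": _quantize(dapi, spec.bit_depth_max),
            "oligodendrocyte": _quantize(mbp, spec.bit_depth_max),
        },
        bit_depth_max=float(spec.bit_depth_max),
        pixel_size=spec.pixel_size,
        field_id=field_id,
        well_id=well_id,
    )
    gt = GroundTruth(
        nucleus_centers=centers,
        positive_flags=positive,
        positive_fraction=n_pos / spec.n_cells,
    )
    return img, gt


def generate_axon_field(
    spec: SceneSpec, field_id: str = "f0", well_id: str = "W0"
) -> tuple[MultiChannelImage, GroundTruth]:
    """Render straight, well-separated axons with known myelinated lengths.

    Horizontal axons (kept clear of the image border so the border-object
    rule does not fire) populate the neuron channel; a planted subset
    carries an MBP sheath — a widened overlay at ``axon_mbp_intensity`` raw
    units over a flat ``mbp_background`` — so the A−B classification has an
    exact oracle. ``GroundTruth.axon_lengths_um`` and ``axon_myelinated``
    record the planted lengths and flags.
    """
    rng = np.random.default_rng(spec.seed)
    shape = (spec.size, spec.size)
    neuron = np.zeros(shape)
    mbp = np.full(shape, spec.mbp_background / spec.bit_depth_max)
    m = spec.axon_margin_px
    n = spec.n_axons
    rows = np.linspace(m + 10, spec.size - m - 10, n)
    n_my = int(round(spec.axon_myelinated_fraction * n))
    myelinated = np.zeros(n, dtype=bool)
    myelinated[rng.permutation(n)[:n_my]] = True
    lengths = []
    for i, r0 in enumerate(rows):
        r = float(r0) + rng.uniform(-3, 3)
        p0, p1 = (r, m), (r, spec.size - 1 - m)
        line = _thick_line(shape, p0, p1, spec.line_width_px)
        neuron[line] = spec.line_intensity
        lengths.append(np.hypot(p1[0] - p0[0], p1[1] - p0[1]) * spec.pixel_size)
        if myelinated[i]:
            sheath = morphology.dilation(line, morphology.disk(2))
            mbp[sheath] = spec.axon_mbp_intensity / spec.bit_depth_max
    img = MultiChannelImage(
        channels={
            "neuron": _quantize(neuron, spec.bit_depth_max),
            "oligodendrocyte": _quantize(mbp, spec.bit_depth_max),
        },
        bit_depth_max=float(spec.bit_depth_max),
        pixel_size=spec.pixel_size,
        field_id=field_id,
        well_id=well_id,
    )
    gt = GroundTruth()
    gt.axon_lengths_um = np.asarray(lengths)
    gt.axon_myelinated = myelinated
    return img, gt


def hill_curve(dose, floor: float, ceiling: float, ec50: float, slope: float):
    """Hill dose–response: floor + (ceiling − floor) · d^h / (d^h + EC50^h)."""
    d = np.asarray(dose, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(d > 0, d**slope / (d**slope + ec50**slope), 0.0)
    return floor + (ceiling - floor) * frac


def generate_dose_plate(
    layout: PlateLayout,
    ec50: float = 100.0,
    slope: float = 1.5,
    floor: float = 0.1,
    ceiling: float = 0.7,
    seed: int = 0,
    base_spec: SceneSpec | None = None,
    fields_per_well: int = 1,
    fraction_sd: float = 0.03,
) -> PlateGroundTruth:
    """Co-culture plate whose planted per-well myelination follows a Hill curve.

    Each well's planted mean fraction is the Hill curve at its dose (vehicle
    dose 0 sits at the floor); per-OL fractions scatter around it with SD
    ``fraction_sd``. Per-well/field seeds derive deterministically from
    ``seed`` and stay below 2^31.
    """
    layout.require_control()
    base = base_spec or SceneSpec()
    master = np.random.default_rng(seed)
    fields: dict = {}
    planted_mean: dict = {}
    for _, row in layout.table.iterrows():
        well = row["well_id"]
        target = float(hill_curve(row["dose"], floor, ceiling, ec50, slope))
        well_fields = []
        realized = []
        for f in range(fields_per_well):
            sub_seed = int(master.integers(0, 2**31 - 1))
            sub_rng = np.random.default_rng(sub_seed)
            fr = np.clip(
                target + fraction_sd * sub_rng.standard_normal(base.n_ols), 0.0, 1.0
            )
            spec = base.replace(seed=sub_seed, planted_fractions=tuple(fr))
            img, gt = generate_coculture_field(spec, field_id=f"f{f}", well_id=well)
            well_fields.append((img, gt))
            realized.extend(gt.planted_fractions.tolist())
        fields[well] = well_fields
        planted_mean[well] = float(np.mean(realized)) if realized else np.nan
    return PlateGroundTruth(fields=fields, planted_mean=planted_mean, layout=layout)
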