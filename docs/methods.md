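# Methods

`myelinquant` quantifies in vitro myelination from multi-channel
high-content fluorescence images of RGC–OPC co-cultures and OPC
monocultures. Three readouts are implemented: a per-oligodendrocyte
**myelination index**, an OPC-**differentiation ratio**, and the total
**myelinated segment length** per well. A synthetic field generator with
exact ground truth backs every test. This note records the models, the
tunables that matter, the numerical choices, and what a green test does
and does not establish.

## 1. Myelination index

The index of one oligodendrocyte (OL) is

```
index = area of high neuron signal inside the OL region / total OL region area ∈ [0, 1]
```

computed from a neuron channel (axonal marker, e.g. Smi31) and an OL
channel (MBP). The per-field pipeline:

1. **Impulse-noise QC.** The salt-and-pepper fraction of each channel is
   estimated and the field is dropped when any channel exceeds
   `noise_max_fraction` (default 0.05). The residual used is each pixel's
   *minimum* absolute difference to its 8 neighbours: a genuine impulse is
   isolated and differs from every neighbour, while a pixel on a thin
   curvilinear structure (axon, OL process — the dominant content of these
   fields) always has a similar neighbour along the structure. The impulse
   threshold is `k·1.4826·MAD` of that residual (k = 6). Sparse fields
   collapse the MAD to zero; two fallbacks handle them: on an otherwise
   perfectly flat background, isolated deviators are counted outright, and
   when the typical deviation spans ≥ 20 % of the dynamic range the
   deviators are impulse-dominated by construction. *Limitations:* pepper
   on black background is undetectable in principle, and at impulse
   densities ≳ 10 % the isolation assumption saturates, so the estimate
   under-reports dense noise (it still crosses the 0.05 gate by ~20 %
   density).
2. **Contrast stretch.** Each channel is mapped linearly to [0, 1] with the
   lowest and highest 1 % of pixels saturated (`saturate_frac`); a constant
   channel maps to zero. The mapping is monotone and idempotent up to one
   intensity quantum.
3. **Bleed-through ("leak") correction.** A wide Gaussian at
   σ = expected OL diameter / 2 (in px) estimates where each channel's own
   cellular mass lives. The OL channel is multiplied by
   `(1 − α) + α·Ĝ(OL)/max Ĝ(OL)` (α = `leak_alpha` = 1): far-from-soma
   axon traces leaked into the OL channel scale toward zero while somata
   and arbours keep their weight. The neuron channel is multiplied by
   `1 − β·Ĝ(neuron)/max Ĝ(neuron)` (β = `leak_beta` = 0.5), suppressing
   blobby OL-shaped leak. β must stay below 0.8: a full-strength
   suppression would push legitimately saturated myelin below the fixed
   0.2 high-neuron cut (step 5). After reweighting, residue below
   `leak_floor` (0.05) is zeroed — a smooth multiplicative factor alone
   cannot reduce tile-wise Pearson correlation (Pearson is affine-
   invariant), so the floor is what actually removes leak support.
   Corrections only apply when the leak's source channel carries signal.
4. **Leak gate.** The leak score is the median Pearson correlation between
   the two channels over non-overlapping 64-px tiles of the *input* pair.
   Tiles where one channel varies while the other is flat contribute 0 —
   leak copies variation across channels, so a flat-vs-varying tile is
   maximal evidence against it; tiles flat in both are uninformative.
   Fields scoring above `leak_exclude_threshold` (0.6) are excluded.
5. **OL detection.** 13 candidate thresholds span the 20–80 % middle of the
   intensity range (configurable to percentile anchoring; the range mode is
   the default because on sparse fields the 20th/80th percentiles collapse
   onto the background). At each candidate, 8-connected components with
   area ≥ 20 % of the averaged OL footprint (π·(`expected_ol_diameter`/2)²,
   default 30 µm at 0.6 µm/px) are counted; the *lowest* candidate
   attaining the maximum count wins, favouring sensitivity.
6. **High-neuron mapping.** Inside detected cells, neuron pixels above 0.2
   of the stretched range count as myelin-apposed ("highest 80 %, i.e.
   above 20 %"); a percentile mode is available.
7. **Artefact exclusion.** (a) Aggregates: near-saturated neuron regions
   (≥ 99th percentile and ≥ 0.9) that survive erosion with a 60-px circle
   are reconstructed to full extent and become exclusion zones; cells
   overlapping a zone by > 50 % are dropped, and zone pixels never count as
   myelin for the rest. Zones are sought on the *pre-correction* stretched
   neuron channel, because step 3 deliberately dims them. Pinholes from
   pepper noise are filled before the erosion (a single hole would
   otherwise void a 30-px radius). (b) Dust: objects with circularity
   4πA/P² > 0.9 (perimeter from the standard border-chain estimator) are
   dropped; OLs are star-shaped and score far lower.
8. **Scoring.** One record per retained cell; excluded cells carry a reason
   and no index. Border-touching cells are retained by default
   (`exclude_border_cells` flips this).

## 2. Differentiation ratio (OPC monocultures)

DAPI nuclei are detected by Gaussian smoothing (σ = diameter/4), an
absolute threshold (`common_threshold`, raw units), local-maximum markers
spaced by `splitting_sensitivity × diameter`, and watershed splitting;
detections outside [0.5, 2] × the configured diameter are dropped. A
cytoplasm region grows from each nucleus in the MBP channel, admitting
pixels above `0.3 ×` the nucleus-footprint mean within `2 ×` diameter of
the nucleus, geodesically connected to it (open stand-ins for the
proprietary building blocks of commercial high-content software, matching
the described behaviour that intensity falls with distance from the
nucleus). A region is MBP⁺ iff its mean raw intensity lies in
`mbp_intensity_window` (default 100–150) **and** its area lies in
`mbp_area_window` (default 200–300 µm²), both closed intervals. Those
windows are instrument-specific raw-unit settings and must be recalibrated
per imaging setup. The readout is a/b — MBP⁺ cells over nuclei — with
counts summed per well before dividing.

## 3. Myelinated segment length

Neurites are traced on the neuron channel: Hessian tubeness (Sato) at
σ = 1 px, kernel-normalized by pixel-wise division by the Gaussian-smoothed
original (σ = 5 px, floored at 1 raw unit); then an oriented line-integral
detector (8 orientations, window `linear_window_px` = 11) whose response is
the **anisotropy** — best minus worst orientation — so thin lines score
high while isotropic blobs and flats score ≈ 0. The binary mask (response
above the 95th percentile or an absolute `contrast`, intersected with the
ridge's own support at `min_support_frac` of its maximum) is gap-closed
with a disk of radius `max_gap_px` = 3, cleared of objects with equivalent
diameter < `min_diameter_px` = 6, and skeletonized. Length counts axial
steps plus √2 × diagonal steps (diagonals bridged by an axial skeleton
pixel are not double-counted), times the pixel size; planted straight lines
at 0°/45°/90° measure within 1 %.

Per segment, the MBP foreground mean `A` and the local background mean `B`
(mean over the 3-px band around the segment, clipped at the image border —
never shrunk inward, so A − B stays meaningful) are computed on **raw**
intensities. Border-touching segments are dropped; remaining segments with
neuron mean ≥ `axon_intensity_min` (default: their median, a data-driven
stand-in for a manually tuned cut) are axons; an axon is myelinated iff
`A − B > mbp_diff_threshold` (default 100 raw units). Myelinated and
unmyelinated axons partition the axon set. Well totals sum member segments
and are normalized to the mean myelinated total of the vehicle-control
wells. Tracing is not anchored to nuclei: neuron somata sit in aggregates
outside most fields, so requiring nucleus contact would discard valid
sheaths.

## 4. Synthetic fields and what a green test establishes

The generator renders 512² 16-bit fields at 0.6 µm/px. Co-culture mode:
~30 thin axon lines (width 2 px, intensity 0.55 of range), 4 OLs (20-px
soma, 8 radial processes of 24 px), per-OL planted myelination fraction
realized by painting high neuron signal (0.9) on the planted subset of OL
pixels, processes before soma; optional saturated aggregates (flat-top
radius 35 px inside a 100-px footprint — large enough to survive the 60-px
erosion rule), hard-edged dust disks, additive cross-channel leak, and
salt-and-pepper noise applied last (so the noise estimator sees the
planted rate). Monoculture mode plants an exact count of MBP⁺ cells whose
rendered disks sit inside the default windows (125 raw units, 250 µm²)
and negatives that each fail exactly one window. The axon-field mode draws
straight, border-clear axons with known myelinated lengths. A dose plate
maps each well's planted mean fraction through a Hill curve
`floor + (ceiling − floor)·d^h/(d^h + EC50^h)`.

Stated-world choices, made once: **leak coefficients default to 0** —
bleed-through is an explicit dial, because with the tile-median score any
global leak drives soma-free tiles to correlation ≈ 1 and would exclude
every field; with well-matched filter sets real bleed is small, and the
leak tests set the dial explicitly. **Aggregates default to 0** (neuron
somata cluster in aggregates that sit outside most imaged fields).
**Background axon lines are not drawn inside OL masks**, which makes the
planted per-cell overlap fraction exact by construction. Consequently a
green recovery test establishes that the pipeline reads out planted
colocalization accurately under impulse noise, texture, dust and optional
leak/aggregates — not that it handles out-of-focus fields, uneven
illumination, overlapping OLs, or genuinely ambiguous partial sheath
contact, none of which the generator emulates.

Determinism: all randomness flows from one `numpy` Generator per field;
rendering is quantized to integers, so a fixed seed reproduces images and
all downstream CSVs bit-exactly.

## 5. Validation surrogate

The published workflow was validated by correlating algorithm indices with
a blinded expert's ordinal 1–5 myelination scores. Desk-scale builds have
no expert, so the rank-fidelity surrogate correlates computed indices with
planted fractions across ≥ 30 synthetic cells spanning 0–1 and requires
Pearson r ≥ 0.9 (measured ≈ 1.0); `correlate_with_reference` accepts
ordinal references and reports Spearman ρ alongside for real use.

## 6. Degenerate inputs and tie-breaks

Constant channels stretch to zero; a scan with no object above the size
floor returns an empty labelling with a warning; threshold-scan ties go to
the lowest threshold; nuclei with zero surrounding MBP keep a region equal
to their footprint; an empty background band falls back to all non-segment
pixels; b = 0 nuclei or a zero/absent control mean raise explicit errors
rather than propagating NaN.
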