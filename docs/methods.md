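# Methods

## The measurement

Retinal vascular tortuosity is quantified per vessel as the arc-to-chord
ratio

    T = L_curve / L_straight,

where `L_curve` is the length of the vessel's centerline path from the
optic disc (OD) to a terminal endpoint and `L_straight` the straight-line
distance between the two path ends.  A perfectly straight vessel gives
T = 1; twisting raises T.  The package computes T separately for arteries
and veins, because the two vessel types have different wall composition
and baseline geometry and are compared statistically per eye.

The chain, per image:

1. **Normalization** — 8-bit RGB to double precision in [0, 1]
   (`I / 255`).
2. **Resize policy** — native images with a dimension above 1,000 px are
   halved; if pixels-per-degree (`ppd = height / FOV`) still exceeds 50,
   the image is halved again.  This standardizes spatial resolution across
   datasets acquired at 30–45° fields of view.  The size rule fires only
   for native-scale images (cumulative `resize_factor == 1`), so applying
   the policy to its own output is a no-op.
3. **Segmentation** — the LAB b (blue–yellow) channel is extracted and
   min–max normalized, thresholded with ISODATA (iterative intermeans),
   and cleaned by removing 8-connected components below 20 px.  A config
   flag `invert_b` selects polarity; vessels can be either side of the
   threshold depending on the coloring of the source (dark-red vessels on
   an orange fundus sit *below* the b threshold, so phantom runs use
   `invert_b: true`).
4. **Enhancement** — a pluggable tube-enhancement stage; the default is a
   multiscale Sato vesselness filter (scales 1–3 px, normalized response
   threshold 0.15) whose super-threshold pixels are unioned into the mask.
   The stage is monotone: it can only add foreground.
5. **GT-guided restoration** — annotated artery/vein/overlap pixels from
   the RGB ground-truth map are unioned in and the result closed with a
   disk, restoring continuity of thin vessels the thresholding missed.
6. **OD detection** — CLAHE followed by a circular Hough transform over
   radii 0.5–2.5 × the nominal OD radius (the disc subtends ≈ 5° of visual
   angle, so nominal radius = `ppd · 5/2` px); candidate circles must lie
   inside the visible vascular region.  A manual circle always wins;
   cross-dataset OD detection is the least reproducible stage, so manual
   specification is first-class (CLI flag, JSON sidecar).
7. **Artery–vein separation** — the RGB label map (red = artery, blue =
   vein, green = artery-vein crossing) is classified in HSV space with
   disjoint hue bands (artery H ∈ [0, 0.1] ∪ [0.9, 1], vein H ∈
   [0.55, 0.75], overlap H ∈ [0.2, 0.45], with saturation/value guards).
   Each class mask is `segmentation AND (class OR overlap)`: crossing
   pixels are deliberately included in *both* masks so each class remains
   topologically connected through crossings.  Masks are closed with
   disk(2).
8. **Skeletonization** — each class mask is thinned to a one-pixel
   centerline by iterative thinning to a fixed point.  Lee's variant is
   used rather than the classic two-subiteration (Zhang-style) scheme: on
   a battery of 100 random masks the classic scheme left a stable 2×2
   foreground block in one case (a 2×2 square is a fixed point of it),
   which violates the 1-px-wide contract the tracer relies on; Lee's
   variant was block-free and equally topology-preserving.
9. **Tracing** — skeleton pixels form an undirected graph with
   8-connected edges.  *Start candidates* are skeleton pixels in the
   annulus `r_OD < d ≤ r_OD + δ` (δ = 5 px).  *Endpoints* are skeleton
   pixels with exactly one foreground neighbor; endpoints at `d ≤ r_OD + δ`
   are dropped — inside the disc they are clinically meaningless, and
   inside the start band they are vessel origins, not distal termini (the
   band exclusion is this package's tie-break; keeping band endpoints
   would pair each origin with itself at zero chord).  Each surviving
   endpoint is validated by a breadth-first search that must reach a start
   while avoiding the closed disc `{p : d ≤ r_OD}`; the first start
   reached is paired with the endpoint.  A second BFS traces the validated
   pair start-to-end; the FIFO queue and fixed row-major neighbor order
   make the path deterministic, and BFS on a unit-weight graph is a
   shortest path (verified against an independent unit-weight Dijkstra).

## Arc length: two modes

**Pixel-count mode (default).**  `L_curve` = number of pixels on the BFS
path, `L_straight` = `round(√((x_e−x_s)² + (y_e−y_s)²))`.  This is the
reference behavior and explains why measured tortuosity can fall *below*
1: a diagonal step advances √2 toward the chord but counts as one pixel,
so a near-diagonal straight vessel has T → 1/√2 ≈ 0.707 from above.  The
lower bound T > 0.707 is enforced as an invariant over 1,000 phantom
traces.

**Geometric mode (`arc_mode: geometric`).**  For users needing T ≥ 1
semantics and quantitative agreement with continuous arc length.  Summing
raw per-step lengths (1 axial, √2 diagonal) is *not* used: on digitized
smooth curves that estimator carries a staircase-quantization bias of up
to +8.2% (worst at 22.5° to the pixel grid, ~+5.5% averaged over
orientations), which we measured directly on rasterized lines, circular
arcs and sinusoids.  Instead the traced path is measured as a polyline
subsampled every `polyline_stride` = 5 pixels (last point always kept),
and divided by the *exact* (unrounded) chord.  Measured bias on the same
shapes is below 1.6%, and T ≥ 1 holds exactly by the triangle inequality.
The stride trades staircase smoothing against corner clipping: 5 px keeps
the underestimate below 0.3% for curvature radii above ~15 px, which
covers retinal vessels at the working resolutions.

## Statistics

The unit of analysis is the per-image mean tortuosity per vessel class
(n = number of eyes); a back-solve of a published Pearson p-value against
its r at n = 20 paired image means motivates this reconstruction, and
per-segment pooling is reported alongside but not tested.  For an
artery/vein comparison: Shapiro–Wilk on each sample gates the branch at
α = 0.05 — both p > α selects the parametric set (Pearson r with two-sided
p, single-predictor regression R² = r², Cohen's d with pooled SD, sign =
mean(artery) − mean(vein), hence negative when veins are more tortuous);
otherwise the nonparametric set (Spearman ρ, Mann–Whitney U, Wilcoxon
signed-rank on image-paired means — a paired test is impossible at segment
level when the classes have unequal segment counts).  All statistics the
sample sizes permit are computed regardless of branch; the report renders
only the branch-appropriate cells, leaving the rest blank.  No
multiple-testing correction is applied.

## The phantom generator

`make_radial_spec` emulates one eye: a bright circular OD at the image
center (radius 35 px in a 420×420 frame, FOV 45°), and 20 vessels
radiating at evenly spaced, jittered angles, alternating artery/vein, with
curve kinds cycling line / sinusoid / quadratic Bézier at width 3 px.
Inner termini sit 2 px outside the disc (inside the start annulus).  Veins
are drawn with larger sinusoid amplitudes (3–5 px vs 1.5–3 px) and Bézier
offsets (10–16 px vs 6–10 px) than arteries, reproducing the
vein-more-tortuous pattern of healthy retinas, and the last slot is a vein
chord crossing the first artery so the label map carries a genuine green
crossing.  The intensity image is a fundus-like orange background with
smooth seeded noise, dark-red vessels and a bright-yellow disc, so the
full segmentation path (LAB-b, ISODATA, vesselness) is exercised, not
bypassed.

Truth tables hold analytic arc lengths (closed form for lines/arcs,
adaptive quadrature at tolerance 1e-8 for sinusoids/Béziers — negligible
against the few-percent recovery bands), exact chords, their ratio, and
rounded endpoint pixels.  `degrade` stresses the restoration stage with
seeded Poisson gaps and 1–3 px spurs.

What the phantom does **not** emulate: vessel width variation and central
reflex, branching trees (vessels are unbranched OD-to-periphery paths),
lesions and pigmentation, capture noise/blur, annotation errors in the
label map, or off-center/nasal OD placement.  Passing the phantom battery
therefore demonstrates the geometry and plumbing of the measurement — not
segmentation robustness on clinical images.

## Numerical choices and degenerate inputs

- ISODATA: initialized at the global mean, |ΔT| < 1e-6, ≤ 100 iterations;
  constant grids are rejected as degenerate.
- A constant b channel min–max-normalizes to all zeros.
- Masks and label maps are resized nearest-neighbor (preserves binarity);
  intensity images bilinear.
- `straight_length` rounds half away from zero (`floor(x + 0.5)`).
- Zero chords (coincident start/end) flag the record invalid and exclude
  it with a warning, as do unreachable pairs (`L_curve` missing).
- Ties in BFS are broken by the fixed row-major neighbor order; identical
  inputs give byte-identical outputs end to end.
- Constant samples make correlation undefined; those cells are reported
  missing rather than zero.

## Problem sizes used in the test and acceptance batteries

Desk-scale batteries run on 420×420 phantoms: 50 seeded 20-vessel
phantoms (≈1,000 traces) for the tortuosity lower bounds, 50 random
≤500-px skeletons for the BFS/Dijkstra cross-check, 100 random masks for
the thinning invariants, and a 12-eye cohort for the end-to-end
statistical workflow.  These sizes give stable minima and rates while
keeping the full battery under a minute on one CPU.

## Known limitations

- Artery–vein separation requires an RGB ground-truth label map; no
  automatic artery–vein classifier is included.
- One pair per endpoint: the first start reached wins; alternative
  anatomical origins are not enumerated, and vessels are not subdivided at
  bifurcations.
- OD detection is tuned for a bright disc within the vascular region;
  images where the disc is dark or clipped need a manual circle.
- Pixel-count tortuosity is resolution- and orientation-dependent by
  construction; cross-dataset comparisons should fix the resize policy
  and prefer geometric mode when absolute values matter.
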