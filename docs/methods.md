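# Methods

## Problem setting

A potted tomato plant is imaged indoors by a consumer structured-light
RGB-D camera at 0.9–1.0 m. The goal is twofold: (1) automatically detect
and segment the *main stems* in the registered depth/color frame, harvesting
texture patches of real stems and leaves into a database; and (2) grow
virtual 3D tomato plants of two varieties (cherry and ordinary) with a
parametric L-system, mapping the harvested textures onto the virtual organs.
A synthetic RGB-D renderer closes the loop so the detection pipeline can be
exercised and scored with no camera and no external data.

## Stem digitization

**Depth-window masking.** Foreground is defined purely by range: pixels with
a valid reading (depth ≠ 0) inside a closed window, default 800–1500 mm.
Color never participates, so masking is independent of illumination. Sensor
dropout holes inside the plant are left as-is (no in-fill): the later steps
are explicitly designed around sparse, fragmented masks.

**Skeletonization.** The mask is thinned to a one-pixel skeleton with
Zhang's 2D thinning (scikit-image's default 2D `skeletonize`), chosen for
speed and for its tolerance of fragmented input; each mask component thins
to one skeleton component.

**Line detection.** Candidate stems are straight runs found by the
Progressive Probabilistic Hough Transform over the skeleton. Parameters
(defaults: ρ = 1 px, θ = 1°, 20 votes, minimum length 20 px, maximum gap
5 px at 640×480) deliberately over-detect — canopy and pot clutter is
removed geometrically afterwards, not by tuning the detector. The PPHT
samples points at random; the generator is owned by a seed parameter, so a
fixed seed gives a byte-identical, canonically ordered segment list.

**Breadth histogram and the valley.** A uniform square grid (default 8 px
cells) is laid over the image; a cell is *valid* when ≥ 20 % of its pixels
are foreground. The plant axis is the vertical through the centroid column
of the bottom 15 % of foreground rows (the pot band), falling back to the
whole-mask centroid. For each grid row i (i = 1 at the top of the plant,
increasing downward), the breadth nᵢ is the cell distance from the axis to
the farthest valid cell, floored at 1 for rows that contain any valid cell;
0 is reserved for empty rows, which inherit the nearest non-zero row above
(else below). The resulting top-to-bottom profile of a potted plant is
bimodal — wide canopy, thin bare-stem waist, wide pot ("fat-thin-fat") — and
after a running median (window 5, replicate edges) the waist appears as the
valley between the two modes.

With pᵢ = nᵢ/N, Σpᵢ = 1, a threshold k splits rows into C₀ = {1..k} and
C₁ = {k+1..L} with weights ω₀, ω₁ and means μ₀, μ₁; the between-class
variance is σ_B²(k) = ω₀ω₁(μ₁−μ₀)², maximized by a full scan (smallest k on
ties, compared at 12 significant digits so exact ties are not decided by
float noise). When the two classes are unbalanced — mass ratio above 1.5 —
the threshold is biased toward the heavier mode, so Otsu is re-applied on
the weaker side's sub-histogram and that sub-threshold becomes the final k*
(two passes at most). σ₀ and σ₁ are the within-class standard deviations of
row positions (weights nᵢ, computed on the smoothed histogram) on each side
of the final k*, and the stem region is the row interval
[⌊k*−σ₀⌋, ⌈k*+σ₁⌉], clamped to [1, L]; flooring/ceiling never shrinks it.

**False-positive removal.** A candidate segment survives iff (a) its
grid-row span intersects the stem interval (a segment partially inside is
kept), and (b) if its midpoint lies below k*, the mean full valid-cell width
of its rows is ≤ 4 cells — pot cross-sections are far wider than any stem.

**Texture harvesting.** Stem patches are axis-aligned crops of each
surviving segment's bounding box dilated by 6 px, with the foreground mask
as alpha. Leaf cutouts come from photos on a uniform background via
excess-green thresholding (2G−R−B > 20) and a largest-component rule —
deterministic and training-free. Patches are stored as RGBA PNGs under
`root/<variety>/<organ>/<phase>/` with an atomic JSON index; sampling is
uniform and seeded.

## Evaluation protocol

Counting is per image, against manually annotated (here: rendered) main-stem
polylines, restricted to stems and segments intersecting the valley
interval. A detected segment *on* a stem is an SD, otherwise an FP; a stem
covered by ≥ 1 segment is a TP, otherwise an FN. "On" is operationalized as
mean point-to-polyline distance ≤ 5 px (≈ one stem width at 0.95 m), using
32 samples along the segment. Batch rates divide summed counts:
TPR + FNR = 1 over stems, Ac + ER = 1 over detections. Reported percentages
round half-up to one decimal. The per-phase counts of the original two-variety
study are embedded as a worked example; all of its printed rates reproduce
from the raw counts except one entry (cherry phase-3 ER, printed 3.1 % where
1/33 = 3.0 %), which the tests flag rather than match.

## Parametric L-systems

The grammar G = (V, ω, P, Θ) couples organ symbols (L, l, F, S, G, P, H, Y,
y, h, f) with rotation operators (+ − & # /), brackets, and control
characters A/B/C/D that never become geometry. Each organ carries an integer
age, incremented once per stage until the organ's maturity (defaults: stem
internodes 5, leaves 4, fruit 6, flowers 3), after which it holds the stable
state r — except leaves, where r triggers bifurcation: the rule rewrites
L(r) so that the fragment `[+L(r)]` becomes exactly `[+L(3)][-L(0)]` (the
rule body intentionally closes and reopens a bracket; the full string stays
balanced). A production `pred : cond -> succ` holds iff letter, arity and
condition all match; two productions holding for one symbol is an error —
the system is deterministic given parameters. Symbols with no holding
production age in place.

The branching plan is fixed before growth by a *choice string* of
lateral-branch form codes (1 short branch/compound leaf, 2 leafy branch,
3 flowering branch, 4/5 terminal leafy/flowering branch, terminal codes only
in last position). The main-stem control A(i, j) emits one internode per
stage, spawns a branch of form choice(i), and recurses with i+1, j+1 — so
later codes sprout strictly higher on the stem; j counts internodes
produced. The two shipped grammars (plain-text data files users can replace)
differ only in the flowering branch: the cherry variety carries leaves and
flower stalks on the same branch, the ordinary variety on separate branches.
Flowers that reach maturity are replaced by young fruit at the same spot.

## Geometry and rendering

Turtle interpretation maintains an orthonormal heading/left/up frame:
+/− yaw (default 25°), & pitches branches (40°), # pitches leaves (30°),
/ rolls by 137.5° so successive branches spiral phyllotactically. Internodes
are 12-sided tapered frustums (radius 0.6 cm, ×0.92 per branching depth,
×0.95 taper per internode); leaves are bicubic Bézier patches (4×4 control
grid, mid-rib lowered so blades are never flat) sampled 8×8; fruit are
spheres whose color interpolates linearly on the HSV hue circle from green
(120°) at age 0 to red (0°) at maturity; organ sizes scale 0.3 → 1.0 with
age. After interpretation, every lateral branch is bent toward gravity with
cumulative pitch min(1.5°/cm × length, 85°) — longer branches droop strictly
more — and each main-stem internode gets a small random deflection (uniform
in [0°, 3°]).

Structural diversity comes from exactly four seeded perturbations: leaf- and
flower-stalk insertion angles (±10°), branch attachment positions along the
stem (±0.3 internode), branch length scales (±20 %), and leaf count per
branch (±1). Zero-width ranges reproduce the unperturbed scene bit-for-bit;
one seed drives the whole axiom→grow→render path, and exports are
byte-deterministic OBJ + MTL bundles (textures copied alongside; re-import
preserves vertex and face counts).

## Synthetic scenes

The renderer is a pinhole z-buffer projection (640×480, focal 575 px, plant
at 950 mm) rasterizing stem cylinders as depth-interpolated thick lines,
leaves as polygons, fruit as discs. Noise reproduces the fragmented look of
structured-light depth: 2 mm quantization, 1 px silhouette erosion, and
seeded per-pixel dropout (5 % easy, 20 % hard). Ground truth is the
projected main-stem polyline(s). Benchmark scenes use a randomized
parametric potted plant — 1–2 slightly tilted stems of 42–52 cm (36–44 cm
cherry), a dense canopy of 34–46 leaf blades over the top 40 % (12–20 on
hard scenes, i.e. a partial canopy), and a 17 cm-wide pot — sized so a plant
fills the frame at the working distance and the breadth profile is strongly
bimodal. The generator does **not** emulate background clutter, sunlight
interference, wire-trained (non-potted) growth habits, or physically
accurate disparity noise, so passing the closed loop demonstrates the
geometric logic of the pipeline, not robustness to every greenhouse
condition.

## Operating point

Recall and precision trade off through the removal constraints: relaxing
them (keeping every candidate and scoring the whole frame) raises TPR and
collapses Ac. Following the original tuning rule — push accuracy as high as
possible while keeping TPR above 70 % — the closed-loop evaluation uses a
minimum PPHT line length of 50 px (module defaults are unchanged), which
suppresses the short canopy fragments that otherwise dangle into the top of
the valley interval. On 20-scene easy benchmarks this yields TPR ≈ 0.97–1.0
and Ac ≈ 0.93–1.0 across seeds; problem sizes throughout (20 scenes per
batch, 1000 histograms for the threshold oracle, 10–14 growth stages) keep
the whole validation suite inside a few minutes on one core.

## Known limitations

* The grammars are reconstructions constrained by the published alphabet,
  control-character roles, branch forms and the leaf-bifurcation rule; the
  original production tables are not public, so rule bodies (and all
  maturity ages and default angles) are this package's own choices, exposed
  as data and configuration.
* The breadth definition floors occupied rows at 1 cell so an axis-hugging
  stem never reads as an empty row; genuinely empty rows inherit a neighbor.
* Whether σ₀/σ₁ should be computed before or after median smoothing is
  unspecified upstream; they are computed on the smoothed histogram.
* Plants trained along vertical wires violate the fat-thin-fat assumption;
  the split-image workaround (running the pipeline per height band) is not
  implemented.
* The valley interval is recomputed per image, not fixed per batch.
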