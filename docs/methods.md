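# Methods

## Model and assumptions

A *digital region* is a set of cells on the square grid, held here as a
boolean mask (`BinaryRegion`). Coordinates are 0-based `(row, col)`, row 0
at top. Adjacency is 8-connectivity, which admits exactly four axes
through a point (0°, 45°, 90°, 135°); drawn through the centroid they cut
the foreground into eight angular sectors. The asymmetry statistic is the
sum over the four vertex-opposite sector pairs of the squared difference
in Normalized E-Factor, `NEF = P/(4√n)`.

Assumptions: the mask is a meaningful segmentation (segmentation quality
is out of scope); foreground is white unless `--invert`; holes are part of
the shape and are never filled, since the measure applies to non-convex
regions with holes; multi-component masks are scored as given, with
largest-component filtering strictly opt-in (`--largest-component`),
because the measure itself is defined for any cell set.

## Definitions and numerical choices

**Perimeter** is the count of exposed unit cell edges (foreground cell
abutting background or the grid border), computed as
`4A − 2·(4-adjacent foreground pairs)`. The alternative — border *pixel*
count — was rejected because the edge count makes the s×s square's NEF
exactly 1 (`P = 4s = 4√n`), anchoring NEF's normalization at the grid
isoperimetric minimum. With this choice `NEF ≥ 1` for every non-empty cell
set (by grid isoperimetry and concavity of √, the bound also holds for
disconnected sets, which sectors of a non-convex region can be).

**Centroid** is the pixel mean `(Σr/A, Σc/A)`, kept at full floating
precision; rounding it to a pixel would destroy the exact-zero property
for symmetric shapes. Moment-based orientation is used only by the
reflection comparator.

**Sector membership** uses exact integer arithmetic: with integer sums
`Sr, Sc` and area `A`, the offsets `dy = Sr − A·r`, `dx = A·c − Sc` are
integer multiples of the true centroid offsets, and the octant of
`atan2(dy, dx)` is decided by sign comparisons and `|dy|` vs `|dx|` — no
trigonometry, no rounding. Bins are half-open `[i·45°, (i+1)·45°)`, so a
cell exactly on an axis goes deterministically to the higher-angle sector,
and a 180°-rotated partner (whose offsets are exact negations) lands in
the opposite bin. Consequences, all exact rather than approximate:
integer translation and quarter-turn rotation leave the score bit-identical
(the pair terms permute; `math.fsum` makes the total order-independent),
and any region with 180° rotational symmetry about a lattice-symmetric
point scores exactly 0.

**The centroid-coincident cell.** A cell whose center falls exactly on
the centroid lies on all four axes and belongs to no wedge. Assigning it
to any one sector would inflate that sector by one cell and give every
odd symmetric shape (odd-diameter discs, odd-centered polygons) a spurious
nonzero score of order 1/n. It is therefore excluded from the eight
sectors and reported as `axis_cell` on the decomposition; sector areas sum
to the parent area minus at most one. A single-pixel region consequently
has an all-empty (degenerate) profile and scores 0 — consistent with a
single cell being perfectly symmetric.

**Empty sectors** score NEF 0 and set a degeneracy flag instead of
raising, keeping the asymmetry formula total; the CLI warns. Which sector
is labeled "R1" is a convention (sector 0 starts at 0°, measured with the
row axis pointing up); any fixed convention preserves the measure because
only opposite pairing enters the formula.

**Reflection comparator (`asymmetry_ref`).** Orientation is
`θ = ½·atan2(2μ₁₁, μ₂₀ − μ₀₂)` from central second moments; isotropic
regions (|signal| < 1e-9·A) get `θ = 0` plus a flag. The mask is
resampled into the principal frame by nearest-neighbor rotation
(`scipy.ndimage.rotate`, order 0), then reflected across each centroidal
grid axis; each one-sided difference is half the symmetric-difference
area, so a mirror-symmetric shape scores 0, and the reported value is
`100·min(ΔA₁, ΔA₂)/A` with `A` the resampled area (differences and
normalizer live on the same grid). Nearest-neighbor resampling is exact
for multiples of 90° and introduces boundary raggedness otherwise; for
thin structures (a few cells wide) that raggedness can dominate the
score. This is intrinsic to the comparator class, not to this
implementation, and is one reason the octant measure avoids rotation
altogether.

**Feature ratios** use the thinness ratio `P²/(4πA)` as the "classic
compactness" descriptor. **TDV** implements the weighted sum only; no
malignancy threshold is applied.

## Synthetic shape generator

`shapes` emulates the geometric study conditions: squares and discs on a
resolution ladder, a disc whose eight 45° arcs are successively replaced
by their chords (circle→octagon morph, diameter 512 in a 563×545 frame),
and a 12-gon with triangular peaks on consecutive edges (star→dodecagon
morph, 300 px peak-to-peak in a 331×331 frame). Rasterization is
cell-center-inside with closed boundaries; generators are pure functions
of their spec. Even-sided polygons and discs are tested through
absolute-value half-plane predicates, so a centered even-symmetric spec
digitizes to an *exactly* 180°-symmetric mask — the main end-to-end
symmetry oracle. Star peaks have base = polygon edge and apex on the
peak-to-peak circle at the edge-midpoint bearing; the base polygon's
circumradius defaults to 2/3 of the apex radius; retained peaks are
consecutive, making intermediate morph shapes maximally one-sided.
Exact parity matters: central symmetry of the digitization requires twice
the shape center to be integer in both coordinates (and side/frame parity
to match for squares).

The generator emulates ideal geometry only: no segmentation noise, no
border fuzz, no holes, no annotator variability. Passing tests on these
fixtures establish the measure's algebraic and asymptotic properties, not
its clinical performance on real lesion masks, which requires the external
expert-labeled databases (see README).

**Resolution sweep.** A disc centered on a lattice-symmetric point
digitizes to an exactly symmetric mask and scores 0 at every diameter,
which would make a resolution sweep vacuous. The sweep fixtures therefore
center the disc a quarter cell off-lattice (+0.25, +0.25), the canonical
worst-case digitization offset; the measured score is then pure
digitization asymmetry, which decays toward 0 as the diameter grows
(32 → 512), the asymptotic behavior of interest. Scale-stability uses a
6-peak star (peak-to-peak 120, frame 141×141) under integer
nearest-neighbor upscaling ×1–×4, sizes chosen so the whole suite runs in
seconds.

## Evaluation harness

Rank mode: Spearman ρ with average-rank ties; the two-sided p-value is an
exact full permutation enumeration for n ≤ 10 (an iterative numpy
permutation-matrix construction; 10! ≈ 3.6M rows evaluated in chunks) and
the t-approximation with n−2 df above. Binary mode: classes 0–1 negative
vs class 2 positive; `score > threshold` predicts positive; the default
threshold maximizes Youden's J with ties broken toward the lowest
threshold (the published operating point is not stated, so the optimum is
the reproducible default and `--threshold` overrides); ROC area is
threshold-free via the rank-sum identity (ties count ½); Fisher's exact
test is the two-sided within-table association test on the confusion
table — the alternative reading (method's table vs dermatologists' table)
would instead compare two tables and is not implemented; the Wilcoxon
rank-sum test is exact (full enumeration, ties handled by permutation)
when both groups are below 10 and the assignment count is enumerable,
otherwise the tie-corrected normal approximation; Cohen's d pools
variances by degrees of freedom. All reject flags use α = 0.05 with raw
p-values and no multiple-testing correction, matching the reporting style
the harness mirrors.

## Known limitations

- The measure compares opposite-sector compactness only; shapes whose
  opposite octants differ in form but tie in NEF score 0 despite being
  visually asymmetric (NEF is a many-to-one descriptor).
- Scores at very low resolution (diameters of a few cells) are dominated
  by digitization noise; the resolution experiments quantify this.
- `asymmetry_ref` inherits the discretization fragility of
  rotate-and-reflect methods for thin regions (see above).
- The generator's fixture magnitudes are not comparable to published
  morph-table values shape-for-shape: the published intermediate morph
  geometry is not fully specified, so only the qualitative profile (low
  ends, interior maximum) is reproducible.
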