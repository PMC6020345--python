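# nefasym

Quantitative asymmetry scoring of binary digital regions — typically
segmented skin-lesion masks — from the shape alone, with no major-axis
search and no region rotation.

Asymmetry is the most heavily weighted component of the clinical ABCD
dermoscopy rule (Total Dermatoscopic Value `TDV = 1.3A + 0.1B + 0.5C +
0.5D`), but most computational asymmetry indices first estimate a symmetry
axis and rotate the lesion onto it — a step that is ill-posed for the
non-convex, ragged shapes melanomas actually have, and that itself perturbs
the digitized region. This package implements an axis-free alternative
aimed at researchers in dermoscopic image analysis and, more generally, at
anyone who needs a scale-, rotation- and translation-robust asymmetry
descriptor for binary masks.

## The measure

For a digital region `R` with area `A`, centroid `(r̂, ĉ) = (Σr/A, Σc/A)`,
the four axes available under 8-connectivity (0°, 45°, 90°, 135°) are drawn
through the centroid, partitioning the foreground into eight angular
sectors `R1 … R8`. Each sector is scored with the Normalized E-Factor, a
discrete compactness descriptor

```
NEF(R) = P / (4 √n)
```

where `P` is the discrete perimeter (exposed unit cell edges, hole
boundaries included) and `n` the cell count; a perfect square — the most
compact shape on the square grid — scores exactly 1. The asymmetry value is
the sum of squared differences between vertex-opposite sectors:

```
Asymmetry_NEF = Σ_{i=1..4} (NEF_Ri − NEF_R(i+4))²
```

A region with 180° rotational symmetry about its centroid scores exactly 0
(this package decides sector membership with exact integer arithmetic, so
the zero is exact, not approximate); the score grows as opposite sectors
diverge in compactness.

Comparator formulas are included for benchmarking: the reflection-based
percentage score about the centroidal principal axes
(`Asymmetry_Ref = 100·ΔA_min/A_total`), the 24-component sector
feature-ratio vector `R_i = Q_i / Σ_{j≠i} Q_j` over perimeter, area and
thinness ratio `P²/(4πA)`, and the clinical `TDV`.

## Worked example

Generate a half-star — a 12-gon with triangular peaks on six consecutive
edges, 300 px peak-to-peak in a 331×331 frame — and score it:

```
$ python -c "from nefasym import save_mask; from nefasym.shapes import *; \
    save_mask(rasterize(ShapeSpec('peaked_star', 300, (331,331), k=12, present=6)), 'half_star.png')"
$ nefasym score half_star.png --ref
mask:           half_star.png
area:           38278
centroid:       (149.035, 165.000)
nef sectors:    1.6982 1.6662 1.6651 1.6982 1.4684 1.3629 1.3611 1.4684
pair terms:     0.052808 0.092008 0.092415 0.052808
asymmetry_nef:  0.290039
asymmetry_ref:  0.0000%
```

The peaked half faces the smooth half, so all four opposite-sector NEF
differences are large and `Asymmetry_NEF ≈ 0.29` — while the
reflection-based comparator reports 0%, because the half-star still has one
mirror axis and `Asymmetry_Ref` takes the minimum over the two principal
axes. This is precisely the failure mode of axis-based measures that the
octant decomposition avoids. A full 12-peak star or the plain dodecagon
(`present=12` / `present=0`) scores ≈ 0 on both.

Other entry points: `nefasym batch DIR` ranks every mask in a directory by
score (the ranking used against clinical assessments), `nefasym shapes
--out-dir DIR` regenerates the full synthetic fixture suite (resolution
ladders, circle→octagon and star→dodecagon morphs), and `nefasym evaluate
scores.csv` runs the statistical harness (Spearman rank mode for ordinal
expert labels; sensitivity/specificity/ROC-area/Fisher/Wilcoxon/Cohen's d
for binary or 0/1/2 class labels).

## Evaluating against expert-labeled databases

The published benchmarks use two external image sets that are not bundled
here: a 40-region lesion set ranked by fourteen dermatologists, and the
PH² dermoscopy database (200 images with expert asymmetry classes 0/1/2
and hand-made segmentations). To reproduce that style of analysis on data
you have obtained: export each lesion's binary mask (white foreground);
write a CSV with columns `mask_path,label` where `label` is the expert
rank or the 0/1/2 class; run `nefasym evaluate masks.csv`. Class 0–1 is
treated as the negative group and class 2 as positive; the classification
threshold defaults to the Youden-optimal point (`--threshold` overrides).
External asymmetry indices can be compared by supplying their values in a
`score` column instead.

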