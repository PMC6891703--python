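# Methods

This note records the models, conventions and numerical choices behind
`pigmount`, the defaults and why they were chosen, and what the synthetic
experiments do and do not demonstrate.

## Problem setting and pipeline

The task is per-frame binary recognition of mounting behaviour in a pen of
group-housed pigs filmed from above. The pipeline deliberately starts
*after* instance segmentation: its input contract is a `FrameRecord` — an
image size, a behaviour label, and one `PigInstance` (binary mask + bounding
box + optional detection score) per animal. Any segmenter satisfying that
contract can feed it; the repository ships file-based backends (Labelme
polygon JSON, PNG label masks, CSV box tables) and a synthetic generator.
The classifier never sees pixels, only mask/box geometry, which is what
makes mounting detectable even when pig and floor colours are similar: the
geometry of the *segmentation*, not the photometry, carries the signal.

## Coordinate and rasterization conventions

Pixels are 0-based; pixel `(row i, col j)` has centre `(x=j+0.5, y=i+0.5)`.
A polygon rasterizes to the pixels whose centres lie strictly inside it
(even-odd rule; polygons must be simple — self-intersection is an error,
never silently repaired). Integral boxes are half-open
`[x_min, x_max) × [y_min, y_max)`. Consequences: an axis-aligned `w × h`
rectangle has mask area exactly `w·h`, and a mask's tight box has integral
corners within 1 px of the polygon's coordinate extremes. These conventions
make areas exact and every rasterization reproducible.

Round-tripping: PNG label masks and CSV tables are exact inverses of their
readers. Labelme JSON written by the package carries sub-pixel
marching-squares outlines; those are for annotation-tool interoperability,
and re-rasterizing them approximates (does not exactly rebuild) the source
mask — dataset export/import therefore goes through the PNG channel.

## Geometric features

For `P` expected pigs the frame vector has `3P + C(P,2)` slots
(18 at the default `P = 4`): per pig `(perimeter, S_small, S_large)`, then
all pairwise box-centre distances in canonical `i<j` order.

**Perimeter** is the polyline length of the marching-squares iso-contour at
level 0.5 of the zero-padded binary mask, summed over connected components.
It is sub-pixel, additive over components, and stable under resolution
changes. Known bias: the staircase cannot cut corners shallower than 45°,
so smooth boundaries are overestimated by roughly 5–10% (a digitized disk
of radius 8 measures ≈ 55.1 px against the ideal 2πr ≈ 50.3); axis-aligned
shapes are nearly exact (a 10 × 20 rectangle measures ≈ 58.8 px against
60). The bias is systematic and scale-stable, so it is harmless to a
classifier fed consistent features; smoother estimators (boundary
pre-smoothing, Crofton) trade it for rounding error on the axis-aligned
shapes that dominate box-aligned pig bodies and were rejected for that
reason.

**Half-body areas**: the splitting segment joins the midpoints of the
bounding box's two *long* sides (so it crosses the box at half-length,
perpendicular to the long axis). Every foreground pixel goes to exactly one
half by centre position; centres exactly on the line go to the half nearer
the box origin, making `S_small + S_large` equal the mask area exactly, for
every mask including multi-component ones. A square box is a measure-zero
tie broken by calling the x-parallel sides "long". Both halves enter the
feature vector, sorted `(S_small, S_large)`, which removes any ambiguity
about which anatomical half is which.

**Assembly**: instances are sorted into raster order (centre y, then x), so
the vector is invariant to segmentation output order. Count mismatches keep
the dimension fixed: extra detections are dropped lowest-score-first
(missing scores count as 1.0), absent pigs contribute zero
perimeter/areas and image-diagonal "far away" sentinel distances. Optional
normalization (off by default) divides lengths by the image diagonal and
areas by the image area; it is unnecessary downstream because the
classifier z-scores features anyway, but useful when comparing feature
tables across image resolutions.

## Classifier

The extreme learning machine draws hidden weights and biases uniformly on
`[−1, 1]` (seeded; sigmoid activation by default) and fits only the output
weights by minimum-norm least squares `β = H⁺T`, with `T` the `N × 2`
one-hot `±1` target matrix (positive class first). The kernel variant
replaces the explicit hidden layer with a Gram matrix and solves

    (I/C + Ω) A = T,   Ω_ij = K(x_i, x_j)

once, by a symmetric positive-definite solve (`scipy.linalg.solve`,
`assume_a="pos"`); an explicit inverse is never formed and KELM training is
fully deterministic. Predictions are `K(x, X_train) A`, class = argmax of
the two outputs, exact ties resolved to the negative class (a fixed,
documented convention; with the symmetric ±1 coding argmax equals the sign
of the decision difference).

Features are z-scored per dimension from the training set before any
kernel (stored in the model, re-applied at prediction): perimeters (px),
areas (px²) and distances (px) differ by orders of magnitude, which an RBF
kernel would otherwise conflate into the largest-scale features.
Zero-variance dimensions (e.g. padding slots on fully-detected datasets)
keep unit scale.

Default kernel: RBF with `γ` and `C` tuned by fivefold cross-validated grid
search over `γ ∈ {10⁻³, 10⁻², 10⁻¹, 1}` × `C ∈ {1, 10, 10², 10³}` —
logarithmic grids spanning under- to over-fitting on z-scored features.
Selection score is mean fold accuracy (MCC available by flag); ties prefer
smaller `C`, then smaller `γ` (weaker model wins). The best cell is refit
once per outer fold and the five models' held-out metrics are averaged for
reporting. The linear kernel is retained because linear-kernel KELM is
algebraically identical to ridge regression on raw features, which the test
suite uses as an independent oracle.

Metric conventions: SP = TN/(TN+FP), SN = TP/(TP+FN), ACC, and MCC from the
confusion matrix; MPA is the mean over classes (background included) of
per-class pixel recall. Any zero denominator evaluates to 0 with a logged
warning (for MCC: any zero factor under the root gives 0), keeping batch
evaluation total on degenerate folds.

## Synthetic scene generator

The generator emulates the *statistical situations* of overhead pen footage
of four young minipigs, not its photometry. Defaults: 640 × 480 canvas
(≈ 290 px/m for a ~2.2 m pen), four pigs, each an ellipse body with
semi-axes 55–75 px × 20–28 px plus a head disc (0.6 × semi-minor radius) at
one tip — about the pen coverage of ~25 kg animals. Three regimes:

* **separated** — all masks pairwise clear by ≥ 3 px (dilation-checked);
* **adhering** — two pigs in contact (gap ≤ 1 px) without overlap, found by
  bisecting the approach distance along a random direction; the designated
  hard-negative regime;
* **mounting** — one pig laid across another's midsection, roughly
  perpendicular (± 0.25 rad) to its spine. The occluded fraction of the
  mounted body is steered to a target drawn from `overlap_range` (default
  0.25–0.45) by bisection on how far the mounting pig slides along its own
  axis. Occlusion semantics: the occluder wins contested pixels; the
  mounted instance's ground-truth mask is its *visible* remainder. For
  overlap ≥ 0.15 the covering band crosses the body end to end and
  candidates are rejected until the visible remnant has exactly two
  components of ≥ 25 px — the fragmented-mask signature a real segmenter
  produces under mounting; below 0.15 no split is demanded (the band cannot
  reliably cross), which is what lets the degenerate-overlap control
  experiments run.

Frame labels are positive iff a mounting event was planted. Datasets fix
the exact positive count (`round(n · fraction)`, default fraction 0.5,
mirroring a class-balanced training regime); negatives draw
adhering-vs-separated from the adhesion probability (default 0.3).
Reproducibility: frame `i` of a dataset uses child seed `[seed, i]`, so
generation is order-independent and a manifest (config + child seeds +
regimes) regenerates a dataset bit-for-bit. The grayscale rendering
(gradient-lit floor, pig tone close to floor tone, mild noise) exists for
demos and figures; no pipeline stage reads it.

What passing synthetic tests shows — and does not. They show the geometric
features separate the mounting regime from separated *and* adhering
negatives when the occlusion signature is present, that the whole pipeline
is wired correctly, and that recovery degrades to chance when the planted
effect is removed (overlap → 0). They do not show field performance: real
segmentation masks carry boundary noise, missed and spurious detections,
and mounting postures vary more than a perpendicular-ellipse model; late-
stage mounting with near-total occlusion is explicitly harder for any
segmenter and is not emulated. The defaults are engineering choices tuned
for realistic pen coverage, not measurements of pigs.

## Problem sizes and numerics

The shipped experiments use a 300-frame synthetic study (200 training
frames under fivefold cross-validation, 100 held-out) — large enough that
binomial noise on held-out accuracy is ~5% at 3σ, small enough to run
end-to-end in tens of seconds on one CPU. The permuted-label control
repeats the *entire* tuning procedure on shuffled training labels and must
land within 3σ of chance on the held-out frames.

Numerical details worth knowing: the KELM system is PSD + `I/C` and hence
always solvable for `C > 0`; the training-system residual is checked to
1e−8 relative in tests. ELM interpolation tests use minimum-norm `lstsq`
(rcond=None). Confusion-matrix metrics are computed in floating point to
avoid integer overflow in the MCC product. Placement uses rejection
sampling with a 400-try cap and raises a diagnostic error (suggesting
smaller pigs or a larger pen) rather than looping forever.

## Known limitations

* The half-body split uses the axis-aligned bounding box, not the pig's
  principal axis; for pigs oriented near 45° the "long side" is less
  anatomically meaningful. The classifier compensates in practice, but the
  feature is coarser there.
* Perimeter carries the marching-squares staircase bias on smooth
  boundaries (see above); comparisons with perimeter values from other
  conventions need a calibration factor.
* The pipeline is strictly per-frame: no temporal smoothing, no tracking,
  no event-duration logic.
* Two-class only; `expected_pigs` is fixed per run, and scenes with wildly
  varying animal counts need the padding/truncation policy documented
  above, which was designed for occasional detector failure, not for
  variable group sizes.
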