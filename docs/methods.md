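# Methods

This note records the models implemented, the conventions and parameter
choices that were genuinely open, and what the synthetic test bed does and
does not establish.

## Pipeline

Every image passes through the same chain: grayscale conversion (Rec. 601
luminance 0.299R + 0.587G + 0.114B), bilinear resize to the working grid
(default 56 × 56), a 3 × 3 median filter with reflective padding, and a
linear contrast stretch that maps the 1% and 99% intensity quantiles to 0
and 255 with saturation beyond them.  Lesions are darker than skin in
dermoscopy, so "foreground" means `pixel ≤ th` throughout ("dark" polarity;
configurable).  Five candidate segmenters then run on the preprocessed
grid, the objective below picks one winner, and the winner's largest
component is eroded (disc radius 1), closed (disc radius 2) and reduced to
its largest remaining component.

## Threshold selectors

**Otsu** minimizes σ²_w(th) = w₁σ₁² + w₂σ₂² over th ∈ [0, 255];
**Kapur** maximizes H(≤th) + H(>th), with empty histogram bins contributing
nothing.  Both consider only thresholds that leave two nonempty classes:
an empty class would make Kapur's sum degenerate to the full-image entropy
and always win, which contradicts the method's intent.  Ties — including
floating-point near-ties, resolved within 1e-9 (relative) of the optimum —
break to the smallest threshold.  Consequence worth knowing: when the two
intensity clusters are separated by an empty histogram gap, every threshold
in the gap ties and the selector returns the gap's left edge, not its
middle.  Both selectors are verified against independent exhaustive
searches computed from raw pixel values.

**Grey feature-histogram**: for every candidate threshold the image is
binarised and the mean area of the 8-connected foreground components is
recorded; a genuine image structure stays stable over a long threshold
range, so the midpoint of the longest run whose feature varies by < 5%
(relative) is returned.  Masks that are empty or cover the whole frame
carry no object feature and score 0, which keeps degenerate plateaus out of
the search; when no plateau longer than one threshold exists the selector
falls back to Otsu.

**Cross-entropy (information) distance.** The fitness driving the
Harris-hawks search is the pixelwise generalized Kullback–Leibler
divergence Dist(I, S) = Σⱼ Iⱼ ln(Iⱼ/Sⱼ), where S replaces each pixel by its
class-mean — the classic minimum-cross-entropy thresholding criterion.
Because class means preserve class sums, Dist ≥ 0 with equality exactly
when the reconstruction reproduces the image.  Zero-intensity pixels
contribute 0; a zero class mean is smoothed with ε = 1e-12; masks with an
empty class score +∞.  An alternative reading — the KL divergence between
the *histograms* of image and reconstruction — was implemented and
rejected: its own exhaustive optimum lands at thresholds ≈ 230–247 with
Dice 0.3–0.7 on hairy and low-contrast fixtures, because concentrating
histogram mass near the class-mean bins is not the same thing as separating
the classes.  Natural logarithms are used wherever an entropy or divergence
appears.

**Harris-hawks optimization** follows the standard formulation: escape
energy E = 2E₀(1 − t/T) switches hawks between exploration and the four
besiege moves (soft/hard, with or without Levy-flight rapid dives,
β = 1.5), greedy acceptance per hawk.  Defaults: population 20, 50
iterations — common values in the metaheuristic literature; with fitness
values cached per integer threshold a run costs at most 256 distinct
evaluations.  Positions are clamped to [0, 255] and rounded for evaluation.
The initial population is spread over the image's own intensity range: any
threshold outside it produces an empty or full mask with infinite fitness,
and on images whose grey levels span a narrow band a [0, 255]-uniform
population can miss the feasible sliver entirely.  Identical seeds give
bit-identical results.

## Chan-Vese active contour

The two-phase model minimizes μ·Length(C) + ∫_in (u₀−c₁)² + ∫_out (u₀−c₂)².
Intensities are scaled to [0, 1] for the evolution so μ (default 0.2) is
comparable across images.  The level set starts as a centred circle of
radius min(H, W)/3 — the selection objective itself assumes lesions near
the centre, and the evaluation harness never places them outside the
frame's middle two-thirds.  The evolution engine is the standard
semi-implicit scheme (scikit-image's implementation) driven in warm-started
250-iteration chunks; it stops when fewer than a fraction `cv_tol = 1e-3`
of pixels switch side over a whole chunk, with a cap of 12 000 iterations
at dt = 2.  The cap matters: at 56 × 56 the front creeps roughly a pixel
per few hundred iterations, and stopping early leaves a halo of the initial
circle that both degrades the mask and — being large and centred — can
steal the ensemble decision.  Two safeguards make the stage predictable:
the returned state never has higher total energy than the initial circle
(otherwise the initial state is returned with a warning), and the reported
foreground is always the darker side of the partition.  The stage contains
no randomness.

## Selection objective

Candidates are scored as `norm_area − norm_distance − penalty` on their
largest 8-connected component: area is normalized by the frame area A·B
and the centroid-to-centre distance by half the frame diagonal, so both
terms live in [0, 1]; entirely black or white masks get an infinite penalty
and can never win while any non-degenerate candidate exists (if *all*
candidates are degenerate, the raw Otsu mask is returned with a warning).
Exact ties break by the fixed order otsu > acm > kapur > hho > gray.

The objective is a prior, not an oracle: among several good masks it
prefers the largest centred one, so a moderately over-segmenting candidate
can outrank a slightly better one, and a *centred* failure — e.g. a
half-frame blob produced by mis-thresholding a strong one-sided
illumination gradient — defeats it by construction.  Its robustness relies
on realistic failure geometry: degenerate masks are excluded, and
off-centre or border-hugging failures lose on the distance term.

## Synthetic test bed

Fixtures are elliptical lesions (mean intensity 60, sd 6) on skin (mean
190, sd 6) with Gaussian sensor noise (sd 4), rendered at 4× the working
grid; the pipeline's own resize brings them down.  Rendering at native
scale is what keeps artefact geometry honest: a 2-px hair or a thin marker
rim on the rendered frame stays thin after downsizing, as in real
dermoscopic frames (∼1000 px across), instead of becoming a rope several
working-pixels wide.  The ground truth is the analytic ellipse indicator
sampled at working-grid pixel centres — exact by construction, unaffected
by artefacts, always a single component.

The default 50-image suite stratifies five conditions (10 each): clean;
hairy (15 dark anti-aliased strokes, thickness 2); inhomogeneous (radial
multiplicative vignette, amplitude 0.35 at the corners — ring-lit
dermoscopes darken the borders, not one side); low contrast (lesion 120 on
skin 165 with a 1.5-px boundary blur); marker (bright circular rim).
Lesion centres are jittered within the frame's middle region and semi-axes
drawn from 7–16 px.  Everything is seeded and bit-reproducible.

What passing on this suite shows: the selectors agree with their exhaustive
definitions, the contour descends in energy, and the selection step adds
value over any fixed method under the modelled artefacts.  What it does not
show: performance on real dermoscopy — the generator has no skin texture,
color information, gel bubbles, ruler overlays or lesion substructure, its
artefact severities are single points in a wide real-world range, and the
margin by which the ensemble beats the best single method is small when
all five candidates are healthy (a few hundredths of Dice; on some suite
seeds the best individual method ties or edges ahead).

## Evaluation conventions

Foreground (lesion) is the positive class.  Dice of two empty masks is 1
(perfect agreement on absence); a rate with zero denominator is reported as
missing (NaN), never as 0.  Jaccard is computed as DSC/(2−DSC) and
cross-checked against |A∩G|/|A∪G|.  Method comparisons use Welch's
unequal-variance two-sample t-test, two-sided, α = 0.05; two identical
zero-variance samples score p = 1 by convention.  When individual
segmenters are compared against the ensemble (acceptance script, test
suite), each receives the same largest-component extraction and
morphological cleanup as the ensemble winner: the comparison then isolates
the selection step, rather than mixing it with the cleanup's systematic
one-pixel shrink, which at these lesion sizes (∼300–700 px) costs several
Dice points on every method alike.
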