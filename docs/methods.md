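# Methods

## Scalar field construction

The analysis object is a standardized 2D scalar field.  From a 3D volume the
central axial slice is taken at index ⌊n/2⌋ (0-based); published pipelines
rarely fix this convention, so it is pinned here for reproducibility.  The slice is resampled to 256×256 by bilinear
interpolation (multichannel input is averaged to one channel first).  Within
the brain mask the intensities are z-scored with the **population** (divide
by N) standard deviation and then shifted so the in-mask minimum is exactly
0; pixels outside the mask are set to 0.  Two consequences matter
downstream:

* the field is invariant to affine rescaling of the scanner units, so
  features are comparable across acquisitions;
* the background sits at the filtration floor together with the darkest
  in-brain pixel, so persistence is computed on the full rectangle rather
  than a cropped region.

"Minimum set to zero" is implemented as a *shift* of the standardized
values, not clipping of negatives: clipping would merge every sub-mean
structure into one plateau and erase the dim-0 diagram's low end, which
contradicts the intent of standardizing before the filtration.

Skull stripping is out of scope: a user-supplied mask is the primary path,
and the built-in fallback (Otsu threshold → largest connected component →
hole filling) is a stand-in suitable for phantoms and quick looks only.

## Persistence

The field is triangulated Freudenthal-style (vertices = pixels; horizontal,
vertical and one (i,j)→(i+1,j+1) diagonal edge per cell; two triangles per
cell), and every simplex enters the filtration at the maximum of its vertex
values (lower-star).  The connectivity convention matters on plateaus and is
fixed to this triangulation; ties are ordered by (value, dimension, index)
and merges follow the elder rule.

* **dim 0** is computed by a Kruskal-style union-find sweep over edges in
  increasing filtration order.  A component is born at a local minimum; at a
  merge the younger component dies at the edge value.
* **dim 1** is computed by Alexander duality instead of boundary-matrix
  reduction: a hole of the sublevel complex is a bounded connected component
  of its complement, so a union-find sweep over the dual graph (triangles
  plus the outer face, joined across shared edges, in decreasing value
  order) yields the (birth, death) pairs directly.  A hole is born at the
  edge value that cuts its last dual path to the outer face and dies at its
  largest triangle value — a local maximum of the field, as expected.

Zero-persistence pairs (birth = death), which lower-star filtrations produce
in abundance and which carry no homological information, are dropped.  The
essential dim-0 class (the component born at the global minimum, which never
dies) is excluded from feature computation; on a full rectangular grid dim 1
has no essential classes.

Correctness is enforced by an independent oracle: for any threshold t the
number of diagram intervals containing t must equal the Betti numbers of the
sublevel complex, with b0 from connected components of the sublevel vertex
set and b1 = b0 − χ from the Euler characteristic.  This check runs on
hundreds of random small fields in the test suite and determines the
diagrams uniquely.  A useful corollary validated there: for distinct-valued
fields, dim-0 classes = local minima and dim-1 points = *interior* local
maxima — a maximum on the image border drains into the unbounded region at
zero persistence instead of filling a hole.

The union-find sweeps are numba-compiled; a 256×256 field takes a few
milliseconds, which makes the Monte-Carlo studies below cheap.

## Convex-peel features

The 100α% convex peel (α = 0.95 by default) strips whole convex-hull layers
while at least ⌈αn⌉ points would remain, then takes the hull of the
survivors.  Whole-layer stripping matches the "peeling successive hulls"
construction; a layer is the set of *extreme* points of the current cloud,
so collinear points interior to a hull edge are not removed with it.
Degenerate clouds are defined explicitly: a segment has area 0, perimeter
twice its length and filamentarity 1 (the line limit); a single point has
all geometry 0 and filamentarity 0.

Seven features summarize a diagram: the count of finite points `npoints`
and mean `lifetime` are computed on the full diagram (not the peel), and
the peel polygon contributes its area centroid (x, y), perimeter P, area A,
and filamentarity F = (P² − 4πA)/(P² + 4πA), the standard shape-finder
index (0 for a disk, → 1 for a filament).  The area centroid (rather than
the mean of retained points) is used because the peel is meant to describe
the diagram's *shape*; both conventions agree for symmetric clouds.

## Statistical workflow

All inferential primitives are implemented in-package and cross-checked
against scipy/statsmodels in the tests:

* **Wilcoxon rank-sum**, two-sided: exact enumeration when n₁+n₂ ≤ 10
  without ties, otherwise the normal approximation with midranks, tie
  correction and a 0.5 continuity correction (the default behavior of the
  common analysis packages).
* **Cohen's d** with pooled (n−1) variance, and **post-hoc power** of the
  two-sided two-sample t-test via the noncentral t with noncentrality
  d·√(n₁n₂/(n₁+n₂)).  At d = 0.55 and n = 30+30 this evaluates to ≈ 0.56;
  power tools differ at the second decimal depending on approximation, so
  small discrepancies with other software are expected and not chased.
* **Logistic regression** by Newton–Raphson, converging on a small step or
  a log-likelihood plateau; Wald 95% CIs exp(β ± 1.96·SE); apparent AUC of
  the fitted probabilities by the rank (Mann–Whitney) formula.  *Complete*
  separation by a single covariate raises an error naming it; quasi-complete
  separation (e.g. a zero cell in a binary covariate) is fitted like
  standard GLM software, yielding a large OR with an enormous CI rather
  than an abort — bootstrap resamples of small cohorts hit this routinely,
  and it is why percentile upper bounds can be very large.
* **Benjamini–Hochberg** step-up adjustment, capped at 1.
* **Percentile bootstrap**: subject-level case resampling, unstratified;
  failed refits (separation, rank deficiency, non-convergence) are redrawn
  and counted, and more than 50% failures aborts.
* Missing covariates are handled by listwise deletion with a logged count;
  no imputation.

The analyze stage mirrors the biomarker evaluation design: per-feature
Wilcoxon/d/power, then two 4-covariate models — {dim1 perimeter, CVD
history, age, CH50} and {dim1 area, CVD history, age, CH50} — with optional
reduced ({feature, age, CH50}) and extended (+ disease duration,
prednisolone dose) variants.

## Synthetic phantoms

The generator emulates the statistical structure the analysis assumes, not
anatomy.  A slice is an elliptical mask (semi-axes 0.42H × 0.36W) on a zero
background containing:

* a smooth background field (white noise blurred with σ = 8 px, scaled to
  unit SD in the mask) playing the role of tissue contrast — it dominates
  the in-mask variance the way anatomy does in a real slice;
* Poisson-many lesions (rate λ = 6 control / 12 case), each a compactly
  supported Gaussian bump (support 1.5r, continuous at the cutoff) with
  log-normal radius (median 2.5 px control / 3.75 case, log-SD 0.2) and
  peak height 2.0·r/2.5 standardized units — larger lesions are brighter,
  as less partial-volume-diluted hyperintensities are;
* correlated pixel noise (white noise blurred with σ = 2.5 px, scaled to
  SD 0.1).

Each bump contributes exactly one local maximum, so the hole-diagram ground
truth is countable: mean dim-1 `npoints` rises monotonically with λ.  Two
generator properties were deliberately designed around the z-scoring step:
lesion intensity must stay a modest share of the in-mask variance (else
case images are *compressed* by their own larger SD and the group contrast
inverts), and pixel noise must be spatially correlated (white noise floods
the diagram with thousands of single-pixel holes that drown the lesion
signal in the 95% peel).  Neither issue arises in real FLAIR data, where
tissue contrast dominates the variance; the design simply restores that
regime.

Clinical covariates are sampled per group to match the reported cohort
margins: age normal (medians 39.5 case / 44.5 control, SD from IQR/1.349),
cerebrovascular-disease prevalence 0.30 / 0.10, CH50 log-normal (medians
30.6 / 24.4), disease duration exponential, prednisolone log-normal.
Covariates are mutually independent by default.  Scenario presets: `null`
(no group difference anywhere, for type-I-error checks), `paperlike` (the
defaults above), `strong` (tripled rate, doubled radius).

What passing synthetic tests show — and what they do not: they demonstrate
that the pipeline detects a lesion-burden contrast of plausible effect size
(hole-feature Cohen's d ≈ 0.5–0.7 at the default settings) through the full
stack with correct type-I error under the null.  They do not show anything
about real FLAIR contrast, scanner effects, registration, or skull-strip
quality, and phantom feature values are not on the scale of real-image
features (a real 256×256 slice yields far more diagram points than a
phantom).

## Problem sizes and numerical choices

Monte-Carlo studies in the tests and acceptance script use 128×128 phantoms
with 30+30 subjects per cohort and 25–50 replicate seeds, and 48–64 px
grids for level-calibration loops; these sizes give stable Monte-Carlo
estimates for the quantities asserted.  Newton iterations stop at step
< 1e-8 (or a likelihood plateau) with a 100-iteration cap; peeling
tolerances are exact (integer/rational geometry is handled by qhull); all
randomness flows from explicit seeds through `numpy.random.SeedSequence`
spawning, so every result in the test suite and acceptance report is
bit-reproducible.

## Known limitations

* 2D only: a single central slice per subject, no volumetric persistence.
* No deep-learning skull stripping, bias-field correction or registration.
* The threshold fallback mask is not a substitute for real skull stripping
  on clinical images.
* Filamentarity's degenerate-case conventions (segment → 1, point → 0) are
  a definition, not a limit derived from data.
* Apparent (resubstitution) AUC is reported, as no held-out data exists in
  the design; it is optimistic relative to external validation.
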