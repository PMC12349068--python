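# topobrain

Topological biomarkers for 2D brain MRI slices.

`topobrain` implements an image-analysis pipeline for case/control studies
that quantify white-matter pathology — e.g. distinguishing neuropsychiatric
systemic lupus erythematosus (NPSLE) from SLE without neuropsychiatric
involvement — by the *shape* of a slice's persistence diagrams rather than
by lesion segmentation:

1. **Preprocess** — take the central axial slice of a FLAIR volume, resample
   to a 256×256 grayscale grid, mask the brain (user-supplied mask, or an
   Otsu-threshold fallback), z-score the in-brain intensities and shift the
   in-brain minimum to 0, with everything outside the brain set to 0.
2. **Persistence** — compute the sublevel-set (lower-star) persistent
   homology of the standardized field z(x) on a Freudenthal triangulation.
   Sublevel sets F_t = {x : z(x) ≤ t} grow with the threshold t; connected
   components (dim 0) are born at local minima, and holes (dim 1) die at
   local maxima — bright lesions therefore leave long-lived holes.
3. **Convex-peel features** — summarize each diagram by its 95% convex peel
   (strip convex-hull layers until ≥95% of points remain) and report seven
   numbers per diagram: `npoints`, mean `lifetime` (death − birth), peel
   `centroidx`/`centroidy`, `perimeter`, `area`, and the filamentarity
   F = (P² − 4πA)/(P² + 4πA) — 14 features per image.
4. **Statistics** — Wilcoxon rank-sum group comparisons with Cohen's d and
   post-hoc power; multivariable logistic regression (Newton MLE, Wald 95%
   CIs, Benjamini–Hochberg FDR adjustment); subject-level percentile
   bootstrap of odds ratios; rank-based ROC AUC.
5. **Synthetic data** — a phantom generator (elliptical brain, smooth
   background field, truncated-Gaussian lesions whose rate and size differ
   by group, correlated pixel noise) plus clinical-covariate simulation, so
   the whole pipeline is testable end to end without any imaging data.

## Worked example

```python
import numpy as np
from topobrain import (compute_diagrams, diagram_features, standardize,
                       generate_phantom)
from topobrain.synthetic_data import PhantomSpec

spec = PhantomSpec(shape=(128, 128))
image, mask = generate_phantom(spec, group=1, seed=7)   # NPSLE-like slice
field = standardize(image, mask)
dgm0, dgm1 = compute_diagrams(field)
f = diagram_features(dgm1, alpha=0.95)
print(f"holes: n={f.npoints}, lifetime={f.lifetime:.3f}, "
      f"perimeter={f.perimeter:.3f}, area={f.area:.3f}, "
      f"filamentarity={f.filamentarity:.3f}")
```

prints

```
holes: n=32, lifetime=0.821, perimeter=14.266, area=10.362, filamentarity=0.220
```

i.e. this phantom's hole diagram has 32 points whose 95% convex peel is a
moderately round polygon (filamentarity 0.220) with perimeter ≈ 14.3 and
area ≈ 10.4 in squared standardized-intensity units; lesion-driven holes
live ≈ 0.82 intensity units on average.  In a cohort the case group's larger/more
numerous lesions push the peel perimeter and area up, which is what the
logistic models test.

The same pipeline is available from the shell:

```bash
topobrain simulate --scenario paperlike --n 30 --size 128 --seed 1 --out run/
topobrain extract  --manifest run/manifest.csv --alpha 0.95 --out run/feat/
topobrain analyze  --features run/feat/features.csv --bootstrap 2000 \
                   --seed 1 --out run/results/
```

`analyze` writes `results.json` (Wilcoxon/d/power per feature; odds ratios,
Wald and bootstrap CIs, raw and BH-adjusted p-values, AUC for the
perimeter- and area-based 4-covariate models) and a plain-text report.

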