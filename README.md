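# sarcoshg — sarcomere morphometry from SHG striation images

Second-harmonic-generation (SHG) microscopy images unstained striated muscle
label-free: the signal comes from the myosin thick filaments, so each
sarcomere appears as a pair of bright A-band segments split by the dark
M-band and bounded by dark Z-discs.  This package measures three distances
from such images — and is aimed at groups quantifying sarcomere remodelling
in cohorts (e.g. control vs growth-restricted hearts) from striation images:

* **SL** — sarcomere length, Z-disc to Z-disc;
* **ABL** — intra-sarcomeric A-band length, the distance between the two
  A-band segments around the M-band;
* **TTIL** — thick–thin filament interaction length, the width (FWHM) of
  the A-band-related intensity peak.

## The model

Along a fiber the SHG intensity is modelled as a periodic train of Gaussian
peak pairs: peaks of standard deviation σ = TTIL / (2√(2 ln 2)) sit at
kSL ± ABL/2 for integer k.  The mean-subtracted, normalized autocorrelation
function (ACF) of this profile has the closed form

    m(τ) = (w(τ) − dc) / (w(0) − dc),   h(x) = exp(−x² / 4σ²),
    w(τ) = Σₖ [ 2·h(τ − kSL) + h(τ − kSL − ABL) + h(τ − kSL + ABL) ],
    dc   = 8√π σ / SL.

The pipeline estimates the per-pixel fiber orientation with a structure
tensor, traces each fiber along the orientation field, extracts its axial
intensity profile (transversely averaged), computes the empirical ACF, and
recovers (SL, ABL, TTIL) by bounded nonlinear least squares of m(τ) against
it (plus an amplitude/offset nuisance pair).  Fibers whose fitted SL/ABL
ratio is strictly above 2.25 are excluded: near ratio 2 the pattern
degenerates to period SL/2 and the typical cardiac striation signature is
lost.  Heart-level means feed paired t-tests and one-way ANOVA.

A second, independent arm implements the ranked-list gene-set scan used for
microarray data: GO annotations are propagated up the ontology, every term
is tested with Fisher's exact test at a series of sliding rank cuts, and all
term × cut p-values are Benjamini–Hochberg adjusted jointly.

A fully ground-truthed simulator generates biperiodic striation images
(fibers at ≈45°, 40 nm/pixel, Poisson photon + read noise), paired
control/IUGR cohorts at the configured group distributions, and ranked gene
lists with an embedded enriched block — so every stage is testable without
any external data.

## Worked example

```python
import numpy as np
from sarcoshg import (SarcomereParams, parallel_fiber_layout,
                      simulate_fiber_image, measure_image)

truth = SarcomereParams(sl_um=1.658, abl_um=0.772, ttil_um=0.104)
layout = parallel_fiber_layout([truth] * 5, rng=np.random.default_rng(0))
image, gt = simulate_fiber_image(layout, noise=1.0, seed=1000)
fits, traces = measure_image(image)
for f in fits:
    e = f.estimate
    print(f"fiber {f.fiber_id}: SL {e.sl_um:.4f}  ABL {e.abl_um:.4f} "
          f"TTIL {e.ttil_um:.4f}  ratio {e.ratio:.3f}")
```

prints (one line per traced fiber; every fiber here shares the same truth):

```
fiber 0: SL 1.6577  ABL 0.7702 TTIL 0.1021  ratio 2.152
fiber 1: SL 1.6576  ABL 0.7738 TTIL 0.0991  ratio 2.142
fiber 2: SL 1.6578  ABL 0.7734 TTIL 0.0990  ratio 2.144
fiber 3: SL 1.6575  ABL 0.7730 TTIL 0.1031  ratio 2.144
fiber 4: SL 1.6577  ABL 0.7734 TTIL 0.1020  ratio 2.143
```

Estimates land within a few nanometres of the 1.658 / 0.772 / 0.104 µm
ground truth — well inside the ~20 nm accuracy reported for the imaging
technique itself.

The cohort-scale analysis lives in `analysis/` as numbered drivers:

```bash
python analysis/01_simulate_cohorts.py --seed 1   # 4 cohorts -> scratch/cohorts
python analysis/02_measure_sarcomeres.py          # fits -> results/
python analysis/03_cohort_statistics.py           # paired t / ANOVA tables
python analysis/04_geneset_scan.py --seed 1       # enrichment scan -> results/
```

On the seed-1 cohorts this measures (7 hearts × 3 images per group):

```
fetal control: SL 1.655 um, ABL 0.771 um, TTIL 0.1030 um
fetal iugr   : SL 1.532 um, ABL 0.706 um, TTIL 0.0955 um
SL  : control 1.655 ± 0.078 vs IUGR 1.532 ± 0.094 um, paired t p = 0.022 *
```

and the gene-set arm flags the M-band (GO:0031430) block — annotated on
1.61% of genes above the best rank cut vs 0.65% below — as up-regulated with
raw p ≈ 1e-10.

There is also a thin CLI (`sarcoshg sim-image | sim-cohort | measure |
cohort | geneset-scan`) over the same library calls.

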