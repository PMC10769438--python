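# bitescape

Feeding-strike kinematics and bite performance landscapes from landmark
tracking.

## The problem

Scale-eating (lepidophagous) pupfish remove scales and tissue from prey
with fast biting strikes. In the laboratory this is measured by filming
strikes on standardized gelatin cubes at 1,100 fps, landmarking five
craniofacial points per frame with a pose-estimation model (e.g. SLEAP),
and measuring the length, width, and depth of each bite divot with
calipers. The scientific question is how strike kinematics map onto bite
performance — in particular whether the map is a simple ridge or a
multi-peaked landscape that could isolate a trophic specialist from its
generalist relatives.

`bitescape` implements that full analysis as a tested Python library:

- **landmark I/O** — read/write five-landmark track files (HDF5:
  `tracks`, `point_scores`, `node_names`), calibrate pixels to mm with a
  ruler scale, bridge short detector dropouts, and load bite-dimension
  CSV tables (volume = length x width x depth).
- **kinematics** — per strike, inside the window from strike start to
  gel impact: peak gape *g* (premaxilla tip to dentary tip, mm), peak
  jaw protrusion *jp* (pupil to premaxilla tip, mm), minimum lower-jaw
  angle *ja* (dentary–quadrate–preopercle, degrees, over the
  onset-to-peak window), time to peak gape *TTPG* (first frame at 20% of
  peak gape to the peak-gape frame; 0.909 ms per frame at 1,100 fps),
  and ram speed *rs* (pupil displacement over that interval divided by
  TTPG; mm/ms = m/s).
- **multivariate statistics** — correlation-matrix PCA and Fisher LDA
  (classification accuracy by species or strike type).
- **mixed models** — repeated strikes per fish are handled with
  `response ~ species + strike_type + (1 | individual)` fit by REML
  (statsmodels), with ML-refit AIC comparison of interactions and
  random slopes.
- **performance landscape** — Gaussian GAMs with low-rank thin-plate
  regression splines, including the 2-D interaction surface `s(g, jp)`,
  smoothness chosen by REML, optional double-penalty shrinkage, AIC
  model selection over the standard candidate set, surface prediction
  on a convex-hull-masked grid, and prominence-filtered interior peak
  counting.
- **synthetic strikes** — a generator that renders landmark tracks and
  bite tables from a known two-peak performance surface, providing
  ground truth for every stage.

The GAM core is

```
y = X beta + f(g, jp) + eps,    f penalized by lambda * integral of squared curvature
```

with `f` a rank-30 thin-plate regression spline (radial kernel
r^2 log r, affine null space), lambda selected by restricted maximum
likelihood, and AIC = -2 logLik + 2 (edf + 1).

## Worked example

`examples/05_performance_landscape.py` generates the default synthetic
study (4 species groups x 5 fish x 8 strikes, 5 px landmark jitter at
10 px/mm), extracts kinematics from the rendered tracks, runs AIC model
selection for bite length, and counts peaks on the best surface:

```
AIC model selection for bite length:
                                                             model  deviance_explained   edf    aic  delta_aic
      length_mm ~ species + strike_type + ja + rs + ttpg + s(g,jp)                0.78 28.59 325.12       0.00
             length_mm ~ species + strike_type + ja + rs + s(g,jp)                0.78 27.73 325.21       0.09
                length_mm ~ strike_type + ja + ttpg + rs + s(g,jp)                0.77 25.78 325.90       0.78
 length_mm ~ species + strike_type + ja + ttpg + rs + s(g) + s(jp)                0.74 22.67 345.25      20.13
       length_mm ~ species + strike_type + g + jp + ja + ttpg + rs                0.47 12.00 434.16     109.04
...
interior performance peaks: 2
  peak at g=2.95 mm, jp=2.81 mm (predicted length 3.55 mm, prominence 3.04)
  peak at g=5.28 mm, jp=7.60 mm (predicted length 2.83 mm, prominence 1.60)

true generator optima: (g=3.0, jp=2.8), (g=5.5, jp=7.5)
```

Models containing the bivariate `s(g, jp)` surface beat the additive
`s(g) + s(jp)` alternatives by ~20 AIC, and the fitted surface recovers
both injected performance optima — one at small gape/protrusion
(generalist-like strikes) and one at large gape/protrusion (scale-eater
strikes) — to within ~0.2 mm, with a valley between them. The other
examples walk through generation (`01`), kinematic extraction and its
accuracy against ground truth (`02`, peak-gape bias +0.06 mm under 5 px
jitter), multivariate overlap (`03`, PC1 = 59% of variance, loaded on
gape and protrusion), and mixed models (`04`, scale-eater gape effect
+2.78 mm, Wald z = 10.9, controlling for repeated measures).

A thin CLI wraps the same pipeline:

```bash
bitescape all --seed 1 --out results/demo          # simulate -> extract -> analyze
bitescape peaks --config config.yaml --out results # just the landscape stage
```

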