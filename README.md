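# coatfit

Quantitative geometry of clathrin-coated endocytic sites from 3D
single-molecule localization microscopy (SMLM), and kinetic modelling
of how the clathrin coat grows and bends during endocytosis.

During clathrin-mediated endocytosis a protein coat assembles on the
plasma membrane and remodels it into a spherical vesicle.  Whether the
coat first assembles flat and then bends (constant-area model, CAM),
or grows at its final curvature (constant-curvature model, CCM), is a
long-standing question.  `coatfit` implements the analysis that
resolves it from static 3D SMLM snapshots:

1. **Spherical-cap geometry** — every coat is described by a sphere
   radius *r* and closing angle *θ* (0° flat → 180° closed), with
   surface area *A* = 2π*r*²(1−cos θ), curvature *H* = 1/*r*, rim
   length *ε* = 2π*r* sin θ and projected (rim-disc) area
   *A*ₚ = π*r*² sin²θ.
2. **Maximum-likelihood cap fitting** — the cap surface, discretized
   into quasi-uniform model points, defines a Gaussian-mixture +
   uniform-background probability density over the localization point
   cloud (using each localization's own precision); nine parameters
   (size, closing angle, position, orientation, background weight,
   extra blur) are fitted by multi-start simplex optimization.
3. **Growth models** — CAM, CCM, a linear-curvature variant, and the
   *cooperative curvature model* (CoopCM), in which coat area grows at
   the rim, d*A*/d*t* = *k*ₒₙ *ε*, while curvature relaxes
   cooperatively toward a preferred value *H*₀:
   d*H*/d*θ* = γ(1 − *H*²/*H*₀²), giving *H*(θ) = *H*₀ tanh(γθ/*H*₀).
   Models are fitted to (θ, observable) site populations by nonlinear
   least squares and compared by BIC.  Derived quantities: preferred
   radius *R*₀ = 1/*H*₀ and the flat-preassembly fraction
   *A*₀ = *A*(θ=0.01 rad)/*A*(θ=π) — the fraction of the final coat
   area already present when bending starts.
4. **Pseudotime** — sites sorted by θ give a rank-normalized timeline;
   the CoopCM predicts θ(t) ≈ √(24 γ *k*ₒₙ t / (8 γ²*H*₀⁻² − 1)), a
   square-root law fitted for the rim growth rate *k*ₒₙ.
5. **Particle averaging** — per pseudotime bin, sites are aligned by
   their fitted pose, rescaled to the bin median radius, rotationally
   averaged (72 × 5°) and rendered as 3D volumes (movie frames via a
   sliding window).
6. **Simulator** — a full SMLM photophysics generator (labeling
   probability 0.6, 5 nm linkage error, exponential on-times,
   reactivation, Poisson photons, CRLB localization noise) that
   produces localization tables for caps or hemisphere+cylinder
   ("U-shaped") ground-truth coats, used to validate the estimator.

## Worked example

```python
import math
from coatfit import (GroundTruthShape, SimulationConfig, simulate_site,
                     fit_cap, compute_A0)

shape = GroundTruthShape(kind="cap", r=100.0, theta=math.radians(120))
table = simulate_site(shape, SimulationConfig(), seed=1)   # 140 localizations
fit = fit_cap(table)
print(f"theta = {math.degrees(fit.theta):.1f} deg, r = {fit.r:.1f} nm")
print(f"A0 (SK-MEL-2 parameters) = {compute_A0(9.4e-3, 13.9e-3):.3f}")
```

prints

```
theta = 115.1 deg, r = 100.2 nm
A0 (SK-MEL-2 parameters) = 0.516
```

i.e. the fit recovers the generating closing angle of 120° to a few
degrees and the radius to well under a percent, and the cooperative-curvature
parameters fitted in SK-MEL-2 cells imply that ~52 % of the final coat
surface is already assembled when curvature generation begins.

The end-to-end pipeline (simulate or read a field → detect sites →
crop → cap fits → QC flags → growth-model fits + BIC → pseudotime →
*k*ₒₙ → averages) runs from a YAML config:

```bash
coatfit run config.yaml
coatfit report <output_dir>
```

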