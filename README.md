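# chemoguide

Quantification of extracellular-matrix (ECM) fiber alignment and 3D
cancer-cell motility under combined chemotactic and contact-guidance
cues.

Cells migrating inside a collagen matrix respond simultaneously to a
soluble attractant gradient (chemotaxis) and to the local orientation of
the fibers around them (contact guidance). In a radial assay — an inner
reservoir releasing attractant into an annular collagen gel — the two
cues can be placed in the same direction (radially aligned fibers) or at
an angle (vortex-aligned fibers), and their combined effect read out
from time-lapse fluorescence microscopy. `chemoguide` implements the
full quantification pipeline for such experiments, plus a synthetic
microenvironment generator so every stage can be validated against known
ground truth without microscopy data.

## What it computes

**Fiber alignment** — from the structure tensor (windowed gradient
matrix) of a fiber image:

- the local principal direction θ_p (axis of minimal intensity
  variation, i.e. the fiber direction; axial, mod 180°), and
- the coherence c = (λ_max − λ_min)/(λ_max + λ_min) ∈ [0, 1], which is 1
  for perfectly parallel texture and → 0 for isotropic texture; fibers
  with c > 0.2 are conventionally called well aligned,

binned radially into profiles of mean c and mean Δθ, the angle between
the fiber direction and the radial (gradient) direction, folded to
[0°, 90°].

**Cell morphology** — per segmented cell: area, traced-contour
perimeter, circularity 4π·A/P², moment-equivalent aspect ratio, and the
"strongly protrusive" classification (circularity below 80% of an ideal
ellipse with the same aspect ratio).

**Motility** — detections linked into trajectories; per step the
chemotaxis index

```
CI = v̂ · (−r̂)
```

(unit velocity dotted with the inward radial unit vector; 1 = straight
up-gradient, −1 = straight down-gradient), pooled mean CI, mean
instantaneous speed, and net radial displacement per cell.

**Chemical gradient** — azimuthally averaged radial intensity profiles
of a dye channel, linear-fit diagnostics, and a radial diffusion solver
for the annulus (steady state a + b·ln r).

**Synthetic microenvironment** — fiber images following radial / vortex
/ parallel / isotropic direction fields with controllable disorder, cell
masks with controlled aspect ratio and protrusions, biased persistent
random-walk trajectories with tunable chemotactic bias and
fiber-guidance coupling, and rendered two-channel time-lapse stacks.

## Worked example

Simulate a radial microenvironment with a chemotactic bias calibrated to
an expected step CI of 0.3, then run the full pipeline back over the
rendered images:

```sh
cat > cfg.yaml <<EOF
geometry: {center_px: [256, 256], inner_radius_um: 100.0, pixel_size_um: 4.0}
simulate: {n_cells: 30, chemo_bias_kappa: 0.63, seed_annulus_um: [350, 900],
           size_px: [512, 512], wobble_deg: 10, n_fibers: 4000}
EOF
chemoguide simulate  --config cfg.yaml --seed 3 --out sim/
chemoguide orient    --fibers sim/fibers.tif --config cfg.yaml \
                     --r-min 150 --r-max 900 --n-bins 8 --seed 3 --out profile.csv
chemoguide segment   --cells sim/cells.tif --config cfg.yaml --seed 3 --out cells.csv
chemoguide track     --detections cells.csv --config cfg.yaml --seed 3 --out traj.csv
chemoguide summarize --trajectories traj.csv --cells cells.csv \
                     --config cfg.yaml --seed 3 --out summary.json
```

`summarize` prints:

```json
{
  "n_cells": 31,
  "n_steps": 529,
  "mean_speed_um_per_h": 9.671480767658384,
  "mean_ci": 0.26314816521786866,
  "mean_ci_per_cell": 0.2539188145064249,
  "mean_net_radial_displacement_um": 41.95941939662325,
  "morphology": {
    "n_observations": 561,
    "frac_ar_gt3": 0.44919786096256686,
    "frac_ar_gt6": 0.09982174688057041,
    "frac_protrusive": 0.0
  }
}
```

The recovered pooled mean CI (0.26) sits within sampling error of the
simulator's calibrated expectation (0.30 at κ = 0.63, attenuated
slightly by segmentation jitter), the mean speed matches the generator's
9.5 µm/h step law, and the net radial displacement is positive (toward
the attractant source). The first lines of `profile.csv`,

```
r_um,mean_coherence,mean_delta_theta_deg,mean_cos_delta_theta,n_pixels
196.875,0.75957608,2.6909822,0.99835321,2652
290.625,0.77927813,3.0370995,0.9977346,6057
```

show a strongly aligned (c ≈ 0.76), near-radial (Δθ ≈ 3°) fiber field,
as prescribed for this simulation.

## Documentation

See `docs/methods.md` for the models, estimators, numerical choices,
default parameters, and the limitations of the synthetic generator.
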