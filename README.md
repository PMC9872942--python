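# stenoflow

Point-cloud deep-learning surrogate for carotid-artery-stenosis (CAS)
hemodynamics, before and after surgical cavity restoration.

Carotid stenosis — atherosclerotic narrowing of the common or internal
carotid artery (CCA/ICA) — is a major cause of ischemic stroke, and
revascularization surgery is assessed through the pressure and velocity
fields it restores.  Computing those fields with CFD takes hours per
vessel; a learned surrogate produces them in a forward pass.  `stenoflow`
is a self-contained implementation of that surrogate strategy for
researchers in computational hemodynamics and scientific ML: a parametric
generator of stenotic carotid bifurcations (and their "postoperative"
stenosis-removed twins), a reduced-physics flow oracle standing in for the
CFD stage, the dual-channel point-cloud network, and the field-error
metrics used to judge it.  Everything runs from scratch on one CPU with no
external data.

## The model

Each vessel is represented by two point clouds: a **cavity cloud**
{N₁ × P₁} of lumen-surface coordinates (geometry) and a **fluid cloud**
{N₂ × P₂} of interior points carrying the systolic-peak pressure p (Pa) and
velocity **v** (m/s).  The network maps (cavity cloud, fluid coordinates) →
per-fluid-point field:

- a shared per-point stem FC1–FC2 feeds both channels (one weight storage);
- the cavity channel ends in 512 features per surface point and is
  max-pooled into a single 512-d global geometry code (order-invariant);
- the fluid channel ends in 128 features per interior point;
- the code is tiled and concatenated (512 + 128 = 640) and decoded by
  FC5–FC6 into 1 (pressure) or 3 (velocity) values per fluid point.

Training: MSE on normalized fields, Adam (lr 10⁻³, β₁ 0.9, β₂ 0.999,
ε 10⁻⁸), batch size 1, best held-out weights retained.  Four independent
networks cover {preoperative, postoperative} × {velocity, pressure}, all
built from the same vessels with a shared 9:1 train/test split.

Prediction error is scored per sample by

- MRE = (100/N₂) Σᵢ |yᵢ − ŷᵢ| / |yᵢ|  (near-zero truth values are
  guard-excluded and counted), and
- NMAE = (100/N₂) Σᵢ |yᵢ − ŷᵢ| / (max|y| − min|y|),

on the whole model, the stenotic windows and the bifurcation region, with
velocity scored on speed.  A consistency analysis correlates predicted and
oracle mean speeds in a thin slab at each stenosis throat (Pearson r),
evaluating postoperative twins at the paired station of the removed lesion.

## Worked example

```python
import stenoflow as sf

# one synthetic stenotic bifurcation and its flow field
spec = sf.sample_vessel_spec(seed=0)
print(spec.stenoses)
cavity = sf.build_cavity_cloud(spec, 2000, seed=1)
fluid = sf.sample_fluid_points(spec, 10000, seed=2)
field = sf.compute_field(spec, fluid)
print(f"peak speed {field.speed.max():.2f} m/s, "
      f"pressure range {field.pressure.min():.0f}-{field.pressure.max():.0f} Pa")
```

prints

```
(StenosisSpec(branch='ICA', center_s=25.9945975410637, length=18.691333659165828, severity=0.4853086206137439),)
peak speed 10.92 m/s, pressure range 16000-26630 Pa
```

— a 48.5% ICA stenosis.  Continuity raises the mean speed at the throat by
1/(1−σ)² ≈ 3.8×, so the centreline jet reaches ~11 m/s, and the viscous
plus lesion expansion losses stack ~10.6 kPa on top of the 16 kPa systolic
outlet reference.  The fixed-inflow oracle deliberately lets severe lesions
produce supraphysiological jets; see `docs/methods.md`.

An end-to-end run (generate → simulate → four datasets → four networks →
error report) at smoke scale:

```bash
stenoflow run-all --profile smoke --seed 2 --out runs/smoke
stenoflow report --run-dir runs/smoke
```

The `desk` profile (100 vessels + twins, 2,000/10,000-point clouds,
100 epochs) is the package's benchmark configuration and takes roughly a
quarter hour on one CPU.

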