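# Methods

## Problem

Carotid artery stenosis (CAS) narrows the common or internal carotid artery
(CCA/ICA) and is a leading cause of ischemic stroke; revascularization
surgery restores the flow cavity.  Pressure and velocity fields in the
bifurcation guide both diagnosis and postoperative assessment, but a
transient CFD solve per vessel is far too slow for interactive use.
`stenoflow` implements a surrogate strategy: learn the mapping from vessel
*geometry* (a surface point cloud of the lumen) to the *flow field*
(pressure or velocity at interior points) so that, once trained, a field
prediction costs one forward pass.

The package is fully self-contained: a parametric generator replaces
clinical image-derived anatomies and a reduced-physics oracle replaces the
CFD stage, so every experiment here runs from scratch on one CPU.  What the
pipeline demonstrates is therefore the *methodology* — point-cloud datasets,
the dual-channel network, the error metrics — under controlled synthetic
conditions, not clinical accuracy.

## Synthetic vessel generator

A vessel is the union of three straight circular tubes meeting at an apex:
CCA (inlet at the origin, axis +z, default length 40 mm), ICA (40 mm) and
ECA (35 mm), with the daughters in the x–z plane deviating from the CCA
axis by angles that sum to the bifurcation angle, split proportionally to
branch diameters.  Seven parameters are drawn uniformly and independently
per vessel:

| parameter | default range | units |
|---|---|---|
| CCA diameter | 6.7–9.0 | mm |
| ICA diameter | 4.6–6.3 | mm |
| ECA diameter | 3.8–5.2 | mm |
| ICA–ECA bifurcation angle | 20–120 | degrees |
| number of stenoses | 1–2 | — |
| stenosis severity σ | 0–80 | % diameter |
| stenosis length L | 5–20 | mm |

Stenoses sit on the CCA or ICA at uniform feasible positions; two lesions
are redrawn until their windows are disjoint.  Lesions are axisymmetric
cosine constrictions, r(s) = r0·(1 − σ·c(s)) with
c(s) = ½(1 + cos(2π(s − s0)/L)) inside the window and 0 outside; severity is
diameter-based (NASCET-style), so the throat diameter is (1 − σ) times
baseline.  Windows are kept clear of the junction transition zone (one CCA
radius around the apex) so the junction geometry is stage-invariant.

The *postoperative twin* of a vessel zeroes every severity while keeping the
lesion records, so the original throat stations remain addressable for
paired pre/post comparisons.

Two clouds are sampled per vessel, both deterministic given a seed:

* the **cavity cloud** (surface): branch and arc-length draws follow the
  *baseline* (lesion-free) area measure and each point is then placed at the
  stenosed radius.  This makes a vessel and its twin emit identical points
  outside the lesion windows for the same seed (exact pre/post pairing) at
  the cost of mildly non-uniform surface density inside the windows.
* the **fluid cloud** (interior): volume-uniform over the tube union via
  per-branch draws with first-containing-branch de-duplication; points are
  strictly interior.

Features of real data the generator does not emulate: curved and tapering
centerlines, non-circular and eccentric lumens, asymmetric or multi-lobed
plaque, the saddle-shaped apex fillet of a real bifurcation (our union of
tubes has a sharp junction shoulder), and anatomical correlations between
parameters.  Passing tests therefore validate the pipeline's mechanics and
learnability on idealized anatomy only.

## Reduced-physics flow oracle

The oracle produces a steady field at the systolic-peak instant (the single
time point the datasets represent):

* blood: Newtonian, density ρ = 1060 kg/m³, viscosity μ = 0.0035 Pa·s;
  rigid walls.
* inlet: systolic-peak mass flow at the CCA, default 0.0476 kg/s
  (configurable).  The default is chosen to be self-consistent with a
  cycle-mean Reynolds number of ~346 and a peak Reynolds number of ~2,200
  in a 7.318 mm CCA — i.e. physiological carotid flow at the top of the
  laminar regime the Poiseuille profile assumes.  Quoted peak carotid mass
  flows in the literature vary and are sometimes internally inconsistent
  with their companion Reynolds numbers; the Reynolds anchors are the
  physically meaningful constraint for a laminar oracle, so they define the
  default here.
* outflow split by Murray's law: q_ica/q_eca = (d_ica/d_eca)³, exact
  conservation.
* velocity: Poiseuille profile per branch, v = 2·V̄(s)·(1 − (r/R(s))²) along
  the local tangent with V̄ = Q/(πR²); inside the junction transition zone
  the direction blends linearly from the CCA tangent to the daughter
  tangent.
* pressure: outlet reference plus the integrated Poiseuille gradient
  8μQ/(πR⁴) from the point to its outlet (CCA points route through the ICA
  path), plus a lumped Young–Tsai-type expansion loss per traversed
  stenosis, ΔP = Kt·(ρ/2)·V̄_up²·(A_up/A_throat − 1)², applied at the distal
  window edge (Kt = 1 by default, toggleable).  The upstream-velocity form
  is the standard one and keeps severe-stenosis drops within a numerically
  usable range while preserving the severity–pressure-drop coupling.
* the outlet reference pressure defaults to 16 kPa (~120 mmHg), emulating a
  physiological pressure-waveform outlet at the systolic instant, so the
  stored pressures are absolute, as in a clinically configured CFD run.

The oracle is exact for a straight tube (closed-form Poiseuille) and
mass-conservative at the bifurcation to machine precision.  It has no
secondary or recirculating flow, no transient effects, and its pressure is
uniform over each cross-section; these are deliberate reductions — the
surrogate-learning problem, not the flow solver, is the object of study.
Geometry is handled in mm, all flow formulas in SI; fields are stored in Pa
and m/s.

## Datasets

Four datasets — {preoperative, postoperative} × {velocity, pressure} — are
derived from one family of geometry draws, so the four networks see the
same vessels; each is split 9:1 (test count = ⌊n/10⌋) by a seeded
permutation shared by all four.  Default desk-scale clouds are 2,000 cavity
and 10,000 fluid points per vessel (one-tenth of the full-resolution
40,000/220,000 profile), stored float64 for coordinates and float32 for
fields in one HDF5 archive per dataset with a JSON manifest.

Coordinates are normalized per sample (centred on the cavity centroid,
scaled by its bounding-sphere radius).  The target field undergoes one
per-dataset affine: pressure — which rides on a ~16 kPa constant
physiological background — is first recentred by the midrange of the
training values (velocity components are naturally centred and use offset
zero), then divided by the maximum absolute centred value over training
samples.  Without the recentering the per-dataset max-abs scale reduces the
pressure signal to sub-percent wiggles around 1.0, which measurably
cripples training.  Both transforms are exactly invertible.

## Network

Per-point fully connected stacks in pure NumPy (float32), with manual
backpropagation and a from-scratch Adam optimizer:

* shared stem FC1 (3→64), FC2 (64→64) applied to both clouds — a single
  parameter storage, so weight sharing is structural;
* cavity head FC3 (64→128→512), max-pooled over points into a 512-d global
  geometry code (order-invariant by construction);
* fluid head FC4 (64→128→128) per fluid point;
* stitching to 512 + 128 = 640 features per fluid point;
* decoder FC5 (640→256), FC6 (256→128), linear head to 1 (pressure) or
  3 (velocity) outputs; ReLU activations, no normalization layers (batch
  size 1 makes batch statistics degenerate).

Training: MSE loss on the normalized field (MAE available by config), Adam
with learning rate 0.001, β1 = 0.9, β2 = 0.999, ε = 1e−8, one sample per
step, reference schedule 1,000 epochs; the weights with the lowest held-out
loss are retained.  For desk-scale runs, random per-step subsets of the
clouds (512 cavity / 512 fluid points) keep an optimization step cheap;
evaluation always uses full clouds.  Model selection during training uses a fixed
random subset of the held-out clouds purely for speed.

## Error metrics and evaluation

* MRE (%) = (100/N)·Σ |y_i − ŷ_i| / |y_i|.  The definition is singular at
  y_i = 0, so points with |y_i| < 10⁻³·max|y| over the region are excluded
  and their count reported (walls for velocity; relevant to pressure only
  in gauge-zero configurations).
* NMAE (%) = (100/N)·Σ |y_i − ŷ_i| / (max|y| − min|y|), range taken from
  the truth magnitudes over the region.
* Velocity metrics act on the speed (magnitude); per-component values are
  obtainable by applying the same functions componentwise.
* Regions: whole model; stenotic windows (effective lesions only, hence
  empty postoperatively); a ball of 1.5 CCA radii around the apex for the
  bifurcation.  Metrics are computed per sample and aggregated as
  mean ± s.d. (population s.d.), matching a per-sample-then-average
  convention.
* Consistency analysis: per held-out vessel, the mean speed in a thin slab
  (5% of the lesion length, widened once if empty) at each stenosis throat,
  compared between oracle and prediction via Pearson r (two-sided p).
  Postoperative twins are evaluated at the paired stations of their removed
  lesions.

## Run profiles and problem sizes

| profile | vessels | cavity/fluid points | epochs | purpose |
|---|---|---|---|---|
| smoke | 10 | 300 / 1,200 | 3 | plumbing checks, seconds |
| desk | 100 | 2,000 / 10,000 | 100 | the package's study scale |
| full | 1,000 | 40,000 / 220,000 | 1,000 | full-resolution reference |

The desk profile is the package's own benchmark configuration: it trains
the four networks in roughly a quarter hour on one CPU and is the scale at
which the repository's end-to-end numbers are produced.

## Numerical choices

* Quadrature for areas/volumes/pressure integrals: trapezoid on a 0.02 mm
  arc-length grid (exact for constant-radius segments).
* Cloud sampling tops up in rounds and then subsamples exactly to the
  target count; counts are within the ±5% contract by construction.
* Junction ownership: a fluid point inside a daughter tube follows the
  daughter's flow; remaining points follow the CCA.  Ties between daughters
  resolve in ICA, ECA order.
* Max-pool backward routes gradients to argmax rows (first index on ties).
* He initialisation seeded from the network config; every stochastic step
  (init, shuffling, subsetting) derives from explicit seeds, so training is
  bit-reproducible on fixed hardware.
* Degenerate inputs raise typed errors: closed lumen (GeometryError),
  off-branch arc lengths and out-of-lumen queries (DomainError), zero metric
  ranges and all-excluded MRE (UndefinedMetricError), min > max ranges
  (ConfigurationError).

## Known limitations

* The oracle's fixed-flow boundary condition produces very high throat
  speeds and pressure drops at severe stenosis: the Murray's-law split is
  independent of severity, so flow does not redistribute away from a tight
  lesion as it would in a pressure-driven transient solve.  Fields are
  internally consistent but supraphysiological at high severity.
* As a consequence, preoperative pressure ranges vary over roughly four
  orders of magnitude across the severity envelope (the lumped loss grows
  like (1 − σ)⁻⁴).  Combined with the single per-dataset field scale, the
  mild-lesion pressure samples occupy a tiny fraction of the normalized
  scale, and their range-normalized NMAE remains very large at desk scale;
  an MAE-loss configuration (available via `NetworkConfig(loss="mae")`)
  reduces this by roughly an order of magnitude but does not eliminate it.
  Velocity NMAE and postoperative pressure MRE do not suffer from this and
  come out small in the desk benchmark.
* MRE divides by the local field magnitude, and a Poiseuille profile
  sampled volume-uniformly contains points of arbitrarily small speed, so
  velocity MRE is dominated by near-wall relative accuracy.  Driving it
  down requires far more data and training than the desk profile performs
  (single-sample overfitting does reach sub-percent MRE, and held-out MRE
  falls both with epochs and with training-set size, so the gap is one of
  scale, not mechanism).
* The surrogate interpolates within the generator's parameter envelope
  only; nothing here supports extrapolation claims to real anatomies.
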