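# Methods

`gradose` implements a beam-arrangement-free dose-prediction workflow for
passively scattered proton therapy of liver tumours: a 3D encoder–decoder
network maps CT and structure masks to a relative dose distribution, and is
trained with composite losses that optionally include differentiable
dose–volume-histogram (DVH) terms and a dose-gradient term targeting the
steep lateral and distal fall-off produced by the Bragg peak.  Because no
clinical cohort is distributed with the package, a seeded analytic phantom
generator supplies training and evaluation cases with the same structural
conventions.

## Conventions and normalization

All volumes live on regular grids with physical spacing in mm; axes are
(Right–Left, Anterior–Posterior, Superior–Inferior).  CT values are min–max
normalized to [0, 1] over a configurable window, default (−1000, 2000) HU
with clipping; the window spans air to dense bone and the clipping guards
CT artifacts.  Dose is kept in relative units: every reference dose and
every model prediction is scaled so that the dose covering 50% of the CTV
(the voxel-wise median) equals 1.0.  D50% is interpreted as the median of
CTV voxel doses, and all D_p% quantiles use the linear-interpolation
convention; the normalization is idempotent to float precision.  Two
prescription protocols are carried per case — 66 Gy(RBE)/10 fx and
64 Gy(RBE)/8 fx, mixed ≈3:1 by the generator — and affect only the
conversion of absolute thresholds (e.g. 30 Gy(RBE)) into relative dose.

## Loss functions

Four components combine into four composites (Loss1 = MSE; Loss2 = MSE +
wMSE; Loss3 = Loss2 + w_dvh·DVH_total; Loss4 = Loss2 + w_g·gradient):

* **MSE** — mean squared voxel error over the volume.
* **wMSE** — Σ_ROI w²_ROI · mean squared error inside the ROI, with weights
  CTV 1.0, PTV 0.8, liver 0.5, spinal cord 0.2, intestines 0.2 (dose-
  constraint priority).  Overlapping ROIs each contribute their own term,
  exactly as the squared-weight formula reads.
* **DVH loss** — |ΔD98%| + |ΔD2%| on the CTV (relative dose), |ΔV30| +
  |ΔV15| (percent) + |ΔDmean| on the normal liver (liver minus GTV; liver
  minus CTV with a provenance flag when no GTV exists), and |ΔV10%| of the
  out-of-ROI body in cm³.  The mixed units are intentional; the composite
  weight absorbs scale.
* **Dose-gradient loss** — mean squared difference of the voxel-wise
  gradient magnitude G(D) = √((∂D/∂x)² + (∂D/∂y)² + (∂D/∂z)²), derivatives
  per physical mm.  G uses central differences in the interior and
  one-sided differences at faces, so it is exact on linear fields and
  defined everywhere; computing in mm keeps G comparable across grids.

**Differentiable surrogates.**  The DVH quantities are order statistics and
hard counts; for training, D_p% is the linear-interpolated percentile
(differentiable a.e. through the two adjacent order statistics) and V_t is
a temperature-τ sigmoid relaxation, mean σ((d − t)/τ), with τ in relative
dose (default 0.01; at τ = 0.005 the surrogate sits within 0.5 percentage
points of the hard count on phantom cohorts).  Evaluation always uses the
hard definitions.  V_t uses the ≥ t convention and V_<t the strict
complement, so the pair partitions the volume.

**Component weights.**  The composite weights are MSE 1, wMSE 1, DVH 1e-4,
gradient 0.1; they were chosen (for clinical-scale dose grids) so that each
term contributes a similar order of magnitude and none dominates.  All
weights are exposed through `LossSpec` for other regimes.  A scale caveat:
on the coarse desk phantoms the logged training magnitudes are MSE ≈ 1e-2
versus gradient ≈ 3e-4, so with weight 0.1 the gradient term contributes
only ≈0.3% of Loss4 — at desk scale Loss4 behaves closely to Loss2 during
optimization, and users studying the gradient term there may wish to raise
its weight toward magnitude parity (≈30) via `LossSpec`.

All training gradients (including the DVH surrogates and the exact adjoint
of the finite-difference operator inside the gradient loss) are analytic
and validated against central finite differences in the test suite.

## Synthetic phantom generator

Each case is an elliptic soft-tissue body (axial ellipse, full SI extent)
containing a lateralized liver ellipsoid, a posterior spinal-cord cylinder,
an anterior intestinal blob, and a spherical GTV placed uniformly among
liver voxels deep enough that (i) the sphere fits inside the liver and
(ii) the body surface is at least r + 18 mm away, so an entrance path
always exists (the modelled treatment protocols impose comparable
clearances).  Margins follow clinical practice: CTV = GTV + 5 mm
isotropic; PTV = CTV + 5 mm (RL, AP) and 7 mm (SI).  The default grid is
48³ voxels at 2 mm isotropic spacing.

Dose is an analytic SOBP surrogate per beam: along the beam axis the
profile is a reduced entrance plateau (fraction 0.7 of the SOBP dose)
ramping linearly to a flat spread-out-Bragg-peak region that covers the
PTV's depth extent plus a 3 mm margin, then a half-Gaussian distal fall-off
(σ = 3 mm, truncated at 4σ); transversely the beam is the PTV projection
dilated by a 7 mm aperture margin with Gaussian-smoothed edges (penumbra
σ = 4 mm).  Two beam angles per case are chosen by a planner surrogate
rather than drawn blindly: every candidate on the 5° grid inside the
clinically used sectors (60–145° excluded) is scored by the mean tissue
path length from body entry to the PTV, plus penalties when the corridor
traverses the spinal cord or intestines, plus a prior favouring the
clinically frequent sectors; the beams are near-optimal candidates at
least 30° apart, with a seeded tie-break.  This matters: beam placement is
then a (noisy) function of the anatomy the network sees, which is the
premise that makes beam paths learnable from masks alone — with
anatomy-independent angle sampling the corridors are unpredictable in
principle and gradient-aware training cannot show its effect.  The sector
frequencies of the clinical cohort emerge from the anatomy and the prior
instead of being imposed.  The two beams are averaged and normalized to
the CTV median.  Depth is geometric from the body entry point, not
water-equivalent; heterogeneity, range uncertainty and motion are out of
scope.  The generator guarantees, and the tests assert, the property the
gradient loss is designed to learn: the mean |∇D| in a 6 mm shell just
distal to the PTV exceeds that in the entrance-plateau region by ≥ 2×.
The contrast regions exclude the lateral penumbra band, the other beam's
fall-off zones, and the one-voxel body surface (the dose-to-air step is
not plateau structure).

What passing tests on phantoms do **not** show: performance on real CT
heterogeneity, scattered-dose tails, TPS optimizer trade-offs, or clinical
anatomical variability; the phantom study demonstrates that the losses,
metrics and training machinery behave as designed, not clinical accuracy.

## Network and training

The predictor is a plain 3D U-Net: per level two 3×3×3 convolutions (He
init) with ReLU, 2× max pooling down, nearest-neighbour upsampling with
channel concatenation up, a 1×1×1 head, and a softplus output enforcing
dose non-negativity.  Input channels, fixed order: normalized CT plus the
CTV, PTV, spinal-cord, liver, intestines and body masks (no beam
information).  The head is initialized near the relative-dose scale
(weights ×0.1, bias softplus⁻¹(0.1)); with a generic init the first
optimizer steps can drive the logits into softplus saturation, where
gradients vanish and the network dies at zero output.  Forward and
backward passes are written in numpy (per-offset matrix products; float32)
and checked against finite differences.  Only `normalization='none'` is
implemented — the desk-scale nets train stably without norm layers — and
the activation may be relu or leaky_relu.

Training uses Adam on the composite loss with early stopping: stop after
`patience` epochs (default 30) without a relative validation-loss
improvement > 1e-6 (the tolerance guards float jitter), restore the
parameters at the minimum validation loss.  Full-scale defaults follow the
clinical recipe: lr 1e-4, up to 300 epochs, stratified 124/30/18-style
split by protocol, grid search over lr {1e-5, 1e-4, 1e-3} × batch
{2, 4, 8} ranked by best validation loss.  The stratified splitter uses
per-stratum largest-remainder allocation plus a repair pass so the global
split sizes are met exactly while every stratum stays within one case of
its proportional share.

**Desk-scale preset** (what the experiment harness and the acceptance
script run): 24³ voxels at 4 mm spacing (the same 96 mm field of view as
the default grid), depth-3 U-Net with 4 base features, batch 4, lr 1e-3,
40 epochs, 32 cases split 24/4/4.  These sizes make a full two-arm,
five-seed comparison feasible on one CPU; they change problem size only.

## Evaluation

Hard metrics per case, for reference and predicted dose: CTV/PTV D98% and
D2% (percent of prescription), Paddick conformity index CI = TV²_PIV /
(TV · PIV) with the prescription isodose volume taken anywhere in the body
(standard Paddick scoping; CI := 0 when PIV is empty), normal-liver Dmean
(%), V30 Gy(RBE) (%), V<15 Gy(RBE) (cm³), the 10% isodose volume (cm³),
and the Dice coefficient of the 10% dose region (DSC := 1 for two empty
masks).  Cohort reports add mean ± SD, MAE/RMSE of 10%-isodose volumes,
DVH curves, and two-sided Wilcoxon signed-rank tests (zeros dropped, exact
p-values for n ≤ 25 without ties; all-zero differences report p = 1 with a
flag); independent groups use the Mann–Whitney U test.  Spinal cord and
intestines are excluded from quantitative metrics — their doses sit below
10% of the prescription — but still feed the wMSE and the out-of-ROI body
region.  Absolute thresholds (30/15 Gy(RBE)) are converted per case via
the prescription, so V30 means 30/66 or 30/64 in relative dose.

## Numerical choices and degenerate inputs

Empty CTV, all-zero CTV dose, empty masks in metrics, missing structures,
non-finite losses, and beams that miss the PTV all raise immediately with
named diagnostics.  Empty ROIs contribute zero to wMSE with a warning.
Ties in max pooling split the gradient evenly.  Margin expansion uses a
voxel-center-in-ellipsoid test in physical mm, which is grid-independent
and handles anisotropic margins; zero margins are the identity.

## What the desk-scale loss comparison shows

The experiment harness trains Loss1 and Loss4 arms that differ only in the
loss.  At desk scale the phantom corridors are geometrically simple and
anatomy-predictable, so MSE-only training already reproduces them well;
the wMSE component inside Loss2/Loss4 concentrates capacity on the target
ROIs and measurably degrades out-of-ROI corridor fidelity, and the
0.1-weighted gradient term is too small at desk dose-grid magnitudes to
compensate.  The gradient term's designed effect is still visible exactly
where the clinical motivation predicts: whenever an MSE-trained model
fails to learn the corridors, the Loss4 arm recovers fall-off fidelity
(sharply lower test gradient loss, higher 10%-isodose Dice).  Whether
Loss4 beats Loss1 overall is therefore a property of problem scale and
task difficulty, not of the implementation; desk-scale runs should be read
as machinery validation, not as a reproduction of clinical-scale loss
rankings.

## Known limitations

* The SOBP surrogate is geometric; no water-equivalent depth, scatter,
  nuclear halo, or heterogeneity corrections.
* Only the basic U-Net family is provided; densely connected, hierarchical,
  self-configuring and transformer variants are out of scope.
* The numpy implementation targets desk-scale volumes; clinical-resolution
  training would need a GPU framework behind the same interfaces.
* Phantom fall-off widths (distal σ, penumbra σ) are free parameters of
  the generator, not fitted to a commissioned beam model.
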