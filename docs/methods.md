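# Methods

## The model

Brain age is regressed from a preprocessed T1-weighted volume by a 3D
convolutional network that interleaves residual and self-attention blocks,
followed by a fused fully-connected head and a support-vector-regression
(SVR) refinement stage. The brain-age gap (BAG) — predicted brain age minus
chronological age — is then used as the sole biomarker for
Alzheimer's-vs-normal classification.

### Network architecture

The default block stack is R(8), A(16), R(32), A(64), R(128) on a
64×64×32 input; every block halves each spatial dimension with a
2×2×2/stride-2 max-pool, so five blocks leave a 2×2×1×128 map (512 values
after flattening).

**Residual block.** Two 3×3×3 convolutions (stride 1, zero "same"
padding) with batch normalisation and an ELU (α = 1) between them form the
residual branch F(x); a 1×1×1 projection of the input forms the shortcut.
The two meet by pointwise sum, H(x) = shortcut(x) + F(x), followed by ELU
and max-pooling. The projection exists precisely so the sum is well-typed
when the channel count changes.

**Attention block.** Queries Q and values V are two independent 3×3×3
convolutions of the block input. Spatial positions are flattened to a
sequence of length N = D·H·W with C channels; scores S<sub>ij</sub> =
Q<sub>i</sub>·V<sub>j</sub> (optionally scaled by 1/√C, off by default) are
row-softmaxed and the output at position i is the resulting convex
combination of value rows — the values act as their own keys, as no
separate key embedding exists in this design. Q and the attention output
are concatenated and a third 3×3×3 convolution projects the concatenation
back to the block's nominal width (keeping the stated widths 16 and 64
meaningful as output channel counts) before batch norm, ELU and pooling.
The N×N weight matrix makes attention O(N²) in memory; inference uses a
chunked row-wise computation with identical results, and training places
attention where the grid is small enough to materialise the matrix.

**Head.** Flatten → dense(128, l2 = 1e-4) → ELU → dropout(0.2) →
concatenate the subject's sex code G ∈ {0, 1} → a final linear unit
emitting the age estimate. The post-ELU dense activation with dropout
disabled is the penultimate feature vector F<sub>l</sub>.

### Implementation

No deep-learning framework is used: convolution (im2col), batch
normalisation, pooling, attention, dense layers, dropout, backpropagation
and Adam are implemented directly on numpy arrays. Backward passes are
verified against central-difference numerical gradients in the unit tests,
and the attention layer against an independent dense softmax-attention
reference. All computation is single-threaded CPU float32 (optimiser
moments in float64), which makes every forward/backward pass — and hence
training — bit-reproducible for a fixed seed.

Batch normalisation uses exponential running statistics (momentum 0.99,
ε = 1e-3) at inference, so the inference forward pass is a pure function
of parameters and input. Max-pool ties break toward the first element in
window order, deterministically.

### Training

Adam (lr = 7e-4, β = 0.9/0.999, ε = 1e-7) minimises mean squared error
for a fixed number of epochs with batch size 8; there is no early
stopping, but the parameters with the best validation loss are
checkpointed and restored at the end. The final linear unit's bias is
warm-started at the mean training age (switchable), so early epochs refine
structure rather than crawl out of a ~50-year offset. A non-finite loss
aborts with a diagnostic rather than silently continuing.

### SVR head

Per y = SVR(F_l ⊕ G), the penultimate features fused with sex are
regressed onto age with ε-insensitive RBF-kernel SVR (C = 1, ε = 0.1,
γ = "scale"). Feature columns **and the age target** are standardised by
training-set statistics stored with the head (zero-variance columns pass
through unscaled); predictions are mapped back to years. Target
standardisation is this package's own choice: with ages in raw years the
conventional C = 1 box constraint caps the fit far below the 20–80-year
spread, while on a unit-variance target the conventional defaults behave
conventionally. Statistics come from training rows only — the tests
assert there is no leakage from evaluation rows.

### BAG-based Alzheimer's detection

BAG = brain_age − chronological_age, computed per scan. Four binary
classifiers — logistic regression, SVM (RBF, Platt-calibrated
probabilities), AdaBoost and XGBoost — are fitted on the 1-D BAG feature
of a stratified 85% training split and combined by majority vote on the
15% holdout. A 2–2 tie goes to AD iff the mean of the four predicted AD
probabilities exceeds 0.5; that mean probability is also the ensemble's
ROC score. AD is the positive class. Precision, recall, F1 and accuracy
come directly from the confusion tally; the ROC is a descending threshold
sweep with trapezoid-rule AUC (cross-checked against the Mann–Whitney U
normalisation and sklearn in the tests).

### Grad-CAM

Saliency for the scalar age output: channel weights are the spatial mean
of ∂age/∂A for the chosen block's pre-pool activation A (default: the last
residual block), the map is the rectified channel-weighted sum,
trilinearly upsampled to the input grid and min–max normalised to [0, 1].
Normalisation makes the map invariant to uniform rescaling of the head
weights; a model with vanishing gradients at the source yields an all-zero
map with a warning.

## Preprocessing

Fixed order, each stage switchable: brain extraction → bias-field
correction → resize → intensity normalisation.

* **Brain extraction** is a pluggable interface: a supplied mask wins,
  then an external-tool hook, then a fallback that thresholds (Otsu),
  takes the largest connected component with filled holes as the head,
  removes the bright skull/scalp shell by a robust median/99.5-percentile
  intensity rule (plain Otsu degenerates on near-discrete histograms), and
  keeps the largest remaining component after closing and hole-filling.
* **Bias correction** estimates a smooth multiplicative field by
  least-squares fitting a polynomial (default total degree 2) to
  log-intensities inside the mask and divides it out, preserving the mean
  in-mask intensity. Voxels dimmer than half the in-mask median are
  excluded from the fit so dark CSF-like structures (ventricles) do not
  drag the field into fitting anatomy — the same robustness that
  histogram-based N4 achieves. An `n4_hook` substitutes a full external N4
  implementation. Non-positive in-mask intensities are shifted before the
  log, with a log message.
* **Resize** uses trilinear interpolation at pixel centres for
  intensities and nearest-neighbour for masks; axes are stretched
  independently (anisotropic inputs are distorted onto the common grid —
  deliberate, and noted). A Gaussian prefilter (σ = √((f²−1)/12)) is
  applied automatically to axes downsampled by more than 2×, so
  256-voxel scanner grids reach 64×64×32 without aliasing while small
  integer-factor resizes remain exactly trilinear.
* **Normalisation** z-scores inside the mask (outside stays 0); a
  zero-variance region yields zeros with a warning.

## The synthetic cohort generator

A phantom is a concentric ellipsoidal "head": zero background, a bright
shell (intensity 1.5) for skull/scalp, uniform brain tissue (1.0), and a
central low-intensity "ventricle" (0.2) whose radius grows linearly with
age — r = 2.0 + 0.075·age voxels on the 32×32×16 grid, anisotropically
scaled in z. Sex scales whole-brain volume by ±sex_scale/2 (default 10%
volume difference, males larger). Nuisance processes: additive Gaussian
noise (σ = 0.05 against brain intensity 1.0) and a multiplicative bias
field exp(a·p(x,y,z)) for a random quadratic p with unit max amplitude
(a = 0.1 by default) — the same model family the correction stage assumes,
mirroring how N4-style methods model scanner inhomogeneity.

Alzheimer's disease is modelled as accelerated aging: an AD subject's
morphology is rendered at chronological age + Δ with Δ ~ N(5, 2) years
truncated at zero by default, while the manifest keeps the chronological
age. The default Δ creates a recoverable but non-trivial CN/AD
separation; it is a free simulation parameter, not an empirical claim.
Cohort ages are uniform on the requested range (default 20–80).

What the phantoms deliberately do **not** model: anatomy (the geometry is
ellipsoidal), MRI physics (no Rician noise, no partial-volume mixing),
scanner/site effects, and registration error. Passing tests therefore
demonstrate that the implementation recovers a known monotone
structure–age mapping under noise and bias at desk scale — they say
nothing about accuracy on clinical data, and the headline numbers of
full-scale multi-dataset studies are out of reach by construction.

## Desk-scale study sizes

The bundled experiments run on one CPU in minutes, with sizes chosen as
the package's defaults:

* **Regression study**: 240 single-scan CN subjects, 32×32×16 phantoms,
  subject-level 25%/10% test/val split, reduced network R(4), A(8), R(16)
  with 64 dense units, 15 epochs. With the generator's default noise this
  lands the held-out MAE near 2 years (against a ~15-year mean-predictor
  baseline), so the gap experiment probes the biomarker at a realistic
  error level.
* **BAG study**: an independent 120-subject cohort, half rendered with a
  fixed Δ = 8 years, ages capped at 70 so accelerated phantoms stay within
  the geometry; brain ages from the trained network + SVR head; ensemble
  evaluated on the stratified 15% BAG holdout.
* **Demo** (`brainage demo`): 36 subjects on 16×16×8 grids with a
  two-block network — small enough to run end to end in seconds.

## Numerical and design choices

* Sex coding: female = 0, male = 1; aliases F/M, female/male, 0/1.
* Repeated scans of one subject always share a split partition; metrics
  are reported per scan (the weighting of multi-scan subjects in
  evaluation is a free choice; per-scan is the simplest defensible one).
* The 95% CI reported with regression metrics is the t-based interval of
  the mean signed error — one defensible reading among several.
* The gender covariate enters twice by design: fused into the network head
  and again as the G column of the SVR input.
* F_l is the 128-dim dense activation (not the 512-dim flattened map);
  the extraction point is the last feature map before the output unit.
* Attention defaults to unscaled scores; `use_scale` enables the 1/√C
  variant.
* Adam ε = 1e-7 and BN ε = 1e-3 follow common framework defaults; the
  dense l2 weight (1e-4) is configurable and otherwise unstated.
* The ensemble committee has four members, hence even; the
  mean-probability tie-break is deterministic and uses information the
  committee already produces.

## Known limitations

* The attention training path materialises the N×N weight matrix; on the
  full 64×64×32 architecture the first attention block has N = 16384,
  which is why training at that scale wants a GPU-class budget while
  inference (chunked) runs on modest memory.
* The bias-field surrogate is a global polynomial fit; genuinely
  non-polynomial inhomogeneity profiles are only approximated (the hook
  accepts a full N4 implementation where needed).
* The fallback brain extractor assumes a bright shell enclosing the
  tissue; it is a phantom-shaped stand-in for a learned skull-stripper,
  not a clinical tool.
* Training determinism is guaranteed on a single CPU; multi-threaded BLAS
  reductions may reorder sums and break bit-identity.
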