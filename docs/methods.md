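# Methods

## Problem and data model

A patient case is a set of co-registered volumes on one regular voxel grid
(default 128×128×128, spacing 3.5×3.5×2.0 mm): a CT volume in scanner
counts 0–4095 with 0 marking non-body voxels, up to seven binary OAR masks
and three binary PTV masks (PTV56/63/70 carrying 56/63/70 Gy
prescriptions), a possible-dose mask (the body), and — for training and
evaluation — a reference dose in [0, 70] Gy that vanishes outside the
possible-dose mask. A clinically absent structure is an *absent key* in the
mask map, never an all-zero mask, so the number of DVH criteria per patient
(99 per present structure, at most 990) is unambiguous.

On disk each quantity is a two-column CSV of (flattened C-order voxel
index, value); mask files store indices only. This mirrors the public
OpenKBP layout so real archives drop in; the reader tolerates one header
line and treats an empty structure file as a missing structure. Doses
round-trip to ≤1e-6 Gy (`%.9g` formatting); integer volumes round-trip
exactly.

## Synthetic phantoms

The generator emulates the *structure* of a head-and-neck planning case,
not its anatomy: an ellipsoidal body covering ≈61% of the grid; ten
ellipsoidal structures at fixed normalized positions (jittered ±1.2% of the
extent per case) chosen to be pairwise disjoint, inside the body, and
roughly anatomical (brainstem above cord, lateral parotids, an anterior
bone-intensity mandible bar); CT = 900 counts soft tissue / 2500 counts
mandible + N(0, 60²) noise clipped to [1, 4095] inside the body. The
reference dose is an analytic surrogate, not beam physics: the per-voxel
maximum over present PTVs of `prescription · exp(−d²/2σ²)` with `d` the
Euclidean mm distance to the PTV (0 inside) and σ = 15 mm, clipped to
[0, 70] Gy and zeroed outside the body. Consequences used by tests: dose
inside each PTV equals its prescription; dose falls monotonically along
rays away from a PTV; mean dose in PTV70 exceeds mean dose in PTV56.

Each optional structure is dropped independently with probability 0.2 by
default (all ten are optional). Every case draws from its own RNG stream
keyed by `(seed, case_index)`, so cohorts are order-independent and
bit-reproducible.

What the phantoms do **not** model: realistic CT texture and anatomy
boundaries, beam directions, scatter, build-up, or inter-structure dose
trade-offs. Passing tests therefore demonstrate that the pipeline is
correct and that the cascade can learn a smooth mask-driven dose field —
they say nothing about clinical accuracy on real patients.

## Preprocessing and augmentation

Standardization is `z = (x − μ)/σ` with μ, σ the *population* mean and
standard deviation pooled over all CT voxels (zeros included) of the
training cases only. Pooling over all voxels rather than body voxels is a
deliberate reading — nothing in the method's description restricts the
pool, and the reference training-set values (μ≈919, σ≈396) are consistent
with zeros included; anyone trying to match those numbers on the real
archive should be aware of this choice.

The two augmentations are integer-voxel and exact: axis flips (each axis
with probability 0.5) and translations drawn uniformly from the per-axis
range that keeps the body bounding box on-grid (`−lo .. extent−1−hi`), so
masks stay binary, dose values are untouched, and every structure's voxel
count is conserved. The countable offline enumeration per case is
{identity, random flip, random translation, flip∘translation}, quadrupling
a cohort (200 → 800). The trainer applies this enumeration once per run
and reshuffles case order each epoch.

## DVH machinery

`D_k` (dose received by ≥k% of a structure) is the (100−k)-th percentile
of the voxel doses, estimated by linear interpolation between adjacent
order statistics at fractional rank `(100−k)/100·(N−1)` — numpy's default
convention, chosen because it is continuous in the dose values (required
for a differentiable loss) and the most common estimator. `D0.1cc` is the
m-th largest voxel dose with `m = max(1, floor(0.1 cm³ / voxel volume))`,
i.e. a nearest-order-statistic reading of "highest dose covering at least
0.1 cm³"; no interpolation between order statistics is applied, and m is
clamped to the structure size for very small structures.

The per-patient DVH-score is implemented as the **mean** of absolute
differences over the ≤23 (structure, metric) entries, although the
metric's defining formula is often written as an L1 norm: the per-RoI and
overall magnitudes reported for this metric in the literature (~1.2–2.1 Gy
per structure, ~1.44 overall) are only consistent with a mean. A
`strict_sum=True` flag provides the unnormalized L1 variant. Cohort score
= mean of per-patient scores; `per_roi_scores` pools entries across
patients by default with a `per_patient=True` variant (whose Overall
equals the cohort DVH-score exactly).

## Losses

* Masked MAE: `(1/V_p) Σ |pred − true|` over the possible-dose mask.
  Voxels outside the mask are unpenalized (and predictions are zeroed
  there at evaluation time). Gradient: `sign(pred − true)/V_p` inside the
  mask.
* DVH loss: mean absolute criteria difference over the `n_p = 99 ×
  (#present structures)` criteria. Its gradient is sparse: each criterion
  touches at most the two voxels defining the interpolated percentile,
  with the interpolation weights; ties are broken by stable sort order so
  the gradient lands on the selected stored element. Finite-difference
  checks at differentiable points agree to 1e-4.
* Total: `0.5·MAE(A) + L_DVH(B)` — the coarse head is auxiliary, hence
  half weight.

## Network

See the README for the channel plan. Discrete choices the textual
architecture description leaves open were fixed as follows: instance
normalization carries learnable affine parameters and convolutions carry
biases; encoder levels 4 and 5 are pure transitions (2×2×2 max-pool;
stride-2 3×3×3 conv 15W→31W) with no extra conv blocks — the only reading
consistent with the printed level-start widths; decoder up-blocks are
trilinear ×2 up-sampling followed by a 3×3×3 conv to widths 8W/4W/2W/W,
and the two conv blocks after each skip concatenation keep that level's
up-sampled width, so the final decoder width is W (Model A's 16-channel
feature output). Model A's dose head output is *not* forwarded to Model B
— "output" is read as the 16 feature channels. Absent structures enter as
all-zero channels so the 11/27-channel contract is unconditional.

Under these choices the default cascade has 42,690,290 trainable
parameters (8,539,217 in A + 34,151,073 in B). A smaller total is
sometimes quoted for this architecture family; no combination of the open
discrete choices reproduces it — every architecture whose widths scale
with the base width, as the printed channel plans do, has a parameter
total ≡ 2 (mod 48), which excludes that figure (≡ 34 mod 48). The package
treats its own literal construction as definitive and reports the count it
computes.

Weights are initialized from a zero-mean normal with He scaling
(sd = √(2/fan-in)), biases zero, affine gains one, deterministically from
`init_seed`.

### Numerical backbone

No deep-learning framework is used: `dosecast.nn` is a small reverse-mode
autodiff over `(C, D, H, W)` float32 numpy arrays. Convolutions run as
im2col GEMMs; the input gradient of a stride-1 convolution is computed as
a convolution with the spatially flipped, channel-transposed kernel, so
forward and both gradients are single BLAS calls. Above a 256 MiB patch-
matrix threshold the forward pass switches to z-slab processing, keeping
full-resolution (128³) inference within a few hundred MB. Max-pool ties
route the gradient to a single argmax voxel. Trilinear ×2 up-sampling uses
half-pixel-centered sampling with edge clamping, applied as dense per-axis
interpolation matrices whose transpose is the exact gradient operator.
Instance norm uses ε = 1e-5. All ops are finite-difference verified.

## Training

Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-8), batch size 1 (one optimizer step
per case; larger batches average gradients). The learning rate follows
`α_t = α_min + ½(α_max − α_min)(1 + cos(π·t/T))` stepped per epoch, with
α_max = 1e-3 and α_min = 0 — the standard one-cycle choice, since only the
initial rate is prescribed. Modes: `dual_dvh` (headline), `dual_mae`
(0.5·MAE(A)+MAE(B)), `single_mae` (Model B alone on the 11-channel input —
in this ablation no Model A is built, matching the single-model
comparison). Early stopping is replaced by best-validation checkpointing
within a fixed epoch budget, since "stop when no longer improving" is not
operational. Runs are bit-reproducible given the seed under
single-threaded BLAS.

## Scaled-down study sizes

Full-scale training (128³, widths 16/32, 800 augmented cases, 100 epochs)
is a GPU-scale workload. The test suite's end-to-end learning check
instead uses 20 phantoms (→ 80 augmented cases) on a 16³ grid with widths
2/4 for 30 epochs — the smallest 16-divisible grid, chosen so the run
keeps the full optimizer-step count (2400 steps, the quantity that governs
how far the output scale can travel under Adam) at about three minutes of
CPU time. Under seed 1 this run drives the validation total loss to 32% of
its first-epoch value (71.7 Gy → 23.1 Gy) and beats an untrained network's
phantom DVH-score by a factor of ~4.5 (12.2 Gy vs 54.3 Gy). Because instance normalization decouples internal
weight scale from output scale, output magnitude is controlled mainly by
the last affine gain and the head weights; very short runs (few hundred
steps) therefore barely move the loss, which is expected behavior, not a
defect.

## Known limitations

* The phantom dose model is analytic; no beam physics.
* No DICOM ingestion, resampling, or world coordinates — voxel grids only.
* `D0.1cc` uses the nearest order statistic (no interpolation).
* Training at full 128³ scale is impractical on CPU; the package is
  correctness-oriented at desk scale and architecture-faithful at full
  scale.
* The numpy backbone holds the forward graph of one case in memory;
  training memory grows with grid size and width (≈250 MB at 32³ with
  widths 2/4).
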