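# Methods

## The model family

The classifier is a MobileNetV2 backbone specialized for surface-defect
recognition on dried jujube fruit. Defects of interest are small and often
low-contrast (early mold is a faint gray-green tint; cracks are 1–3-pixel
dark lines at working resolution), so the design adds attention at three
levels while keeping the parameter and compute budget of an edge-deployable
model.

**Backbone.** A stride-2 3×3 stem (3→32 channels), then seven stages of
inverted residual blocks (1×1 expansion → 3×3 depthwise → 1×1 linear
projection, identity skip when shapes match), with block counts
1/2/3/4/3/3/1, expansion 1 then 6, and output channels
16/24/32/64/96/160/320. Strides follow the canonical layout, giving 7×7×320
features at a 224×224 input.

**CoordAtt** (channel→spatial attention, residual). Channel weights come
from an SE bottleneck on globally pooled features,
`s = σ(W₂ ReLU(W₁ ḡ(F)))`; the spatial gate is a grouped K×K convolution of
`s⊙F`, reduced to one channel by a mean over channels and squashed by a
sigmoid. Output: `gate ⊙ (s⊙F) + F`. The "mean over channels" reading of the
gate's pooling is the only one that produces a spatial map, which is the
block's stated purpose (localizing direction-sensitive structure such as
cracks along the fruit axis). Blocks are embedded *selectively*: after the
final block of stages 1–6 only (embedding mode "a"). Mode "b" — after the
stem, inside every inverted residual after its depthwise conv, and after the
tail — is supported for comparison and is strictly heavier.

**Zero-initialized gate.** The gate convolution (weights and bias) starts at
zero, so the gate is exactly 0.5 everywhere and the block reduces to
`F + 0.5·(s⊙F)` — a mild, well-conditioned residual amplifier — until
training moves it. Only the gate conv is zero-initialized; SE layers use
standard fan-in initialization.

**EfficientRCAM** applies a depthwise convolution `D = DW(F)` (default 3×3)
followed by the same attention cascade computed *from D*, with the residual
to D: `gate ⊙ (s⊙D) + D`. An optional 1×1 squeeze (`internal_compression`)
thins the gate pathway. **CascadedRCAM** is the network tail:
`ConvBNHSwish(F + EfficientRCAM(F); K_adapt, C/2)`, i.e. residual fusion of
original and enhanced features then 2× channel compression (320→160) by a
pointwise conv. It replaces the standard 320→1280 head; the classifier is a
linear map from the pooled 160-dim feature. H-Swish
(`x·ReLU6(x+3)/6`) is the activation in the stem, the tail and all
ConvBNHSwish blocks; inverted residuals keep ReLU6.

## Calibration of the free attention hyperparameters

The architecture's published budget is 2.16 M parameters and 0.32 GMACs at
224×224, but the attention hyperparameters behind that budget (SE ratio r,
gate groups g, kernel sizes, the compression pathway) are free. We searched
the grid r ∈ {2,4,8} × group width {4,8,16} × K ∈ {3,5,7} ×
K_depth, K_g ∈ {3,5,7} × tail r ∈ {2,4,8} × internal compression
{off,2,4,8} with closed-form parameter/MAC counts and froze the combination
most consistent with the block descriptions (3×3 depthwise in the tail, a
lightweight compression pathway present):

| knob | value |
|---|---|
| stage CoordAtt: SE ratio r | 4 |
| stage CoordAtt: gate group width (channels/group) | 8 |
| stage CoordAtt: gate kernel K | 5 |
| tail EfficientRCAM: depthwise kernel | 3 |
| tail EfficientRCAM: gate kernel / group width | 3 / 8 |
| tail EfficientRCAM: SE ratio | 8 |
| tail EfficientRCAM: internal compression | 2 |
| tail adaptation kernel K_adapt | 1 (pointwise) |

This yields 2,162,700 trainable parameters (2.16 M) and 0.316 GMACs (0.32 G
at two decimals); the width-1.0 MobileNetV2 reference is 3,504,872
parameters at 1000 classes and 2,231,558 (2.23 M) with the 6-class head.
"FLOPs (G)" is counted as multiply-accumulates: K²·(C_in/g)·C_out·H·W per
convolution and in·out per linear layer, the convention of the
lightweight-CNN literature.

## Data pipeline

**Corpus expansion is static and strategy-structured.** The training split
is expanded once: every base image yields itself (clean standardized
resize) plus `multiplicity − 1` augmented variants, each generated from a
stored seed (default multiplicity 4: 12,000 base images → 48,000, of which
33,600 train / 9,600 test / 4,800 validation at the 0.7/0.2/0.1 stratified
split). Variants are therefore deterministic, cacheable arrays, and all
variants of one base image stay in one split (no leakage). Each variant
applies one of the three expansion strategies, cycled per base image:

1. *random cropping* — random resized crop, area 70–100 %, aspect
   0.8–1.25, bicubic;
2. *flipping* — random horizontal/vertical flips (at least one applied);
3. *comprehensive* — rotation ±15°, shear ≤10°, one rectangular occlusion
   covering 2–20 % of the image filled with mid-gray (128,128,128, also the
   affine border fill), and ±20 % brightness/contrast/saturation jitter.

Treating these as separate strategies (rather than stacking every transform
onto every copy) keeps most variants anchored to the intact defect
signature, which matters at small working resolutions where a crop plus an
occlusion can jointly erase a 3-pixel crack. `train_transform` still
exposes the fully stacked stochastic transform for pipelines that want it.
Evaluation resizes the shorter side to 256·S/224 and center-crops S (S = 224
by default). Standardization uses per-channel mean/std computed on the
training split at generation time and stored in the manifest header.

**Synthetic generator.** Each image is a pure function of
(label, seed, config): a soft-gradient grainy background, an ellipsoidal
red-brown fruit with radial shading and a specular highlight, and a
class-specific overlay — dark random-walk polylines (cracked), blurred
gray-green blobs (mold), small dark punctures with exposed-flesh rims
(bird_pecked), sinusoidal ridge shading (wrinkled), a 3–5-lobed boundary
warp (deformed), nothing (normal). The base fruit and background consume an
RNG stream independent of the label, so images of different classes at the
same seed differ only in the defect overlay (and boundary warp). The `easy`
difficulty uses high-contrast, large defects; `hard` shrinks and fades them.
The generator emulates class-conditional structure, not photography: there
is no camera noise model, no specular clutter, no inter-variety texture
variation, and backgrounds are near-uniform. Passing tests on this corpus
demonstrates that the pipeline learns the intended class signatures
end-to-end; it says nothing about accuracy on real fruit photographs.

## Training

AdamW with β₁ = 0.9 (the recipe's "momentum"), β₂ = 0.999, decoupled weight
decay 5e-2 applied to convolution/linear weights only; initial learning rate
5e-4 with one linear warm-up epoch then cosine decay to zero, resolved per
step; cross-entropy without label smoothing; batch size 32; training from
scratch. The best-validation-accuracy epoch is checkpointed. The 4,800-image
"verification" split serves as the model-selection (validation) set and the
9,600-image split as the held-out test set. The full-scale recipe (200
epochs on the 48,000-image corpus at 224 px) is documented but not executed
by the test suite; desk-scale runs use the same loop on the synthetic corpus
at 64 px — 200 base images per class, multiplicity 4 (3,360 training
arrays), a width-0.5 model (`width_multiplier`, channels rounded to
multiples of 8) and 6 epochs — sizes chosen so a run completes on one CPU
core in minutes while still exercising every component. For such short
schedules the desk runs raise the initial learning rate to 1e-3: the 5e-4
default is tuned to a 200-epoch horizon, and a 6-epoch cosine at that rate
spends too few steps at a useful magnitude to converge. The full-scale
default is unchanged. On the balanced easy synthetic corpus this
configuration reaches validation macro-F1 ≈ 0.89 (best epoch of the
6-epoch run).

## Numerical and engineering choices

The package ships its own small reverse-mode autograd engine over NumPy
(`julite.nn`): grouped/depthwise convolution via im2col + GEMM with an
explicit backward pass, fused batch-norm and hard-swish primitives, AdamW,
and a module system with state-dict (de)serialization. float64 is the
default for oracle-level exactness in tests; training casts the model to
float32. Backward-pass closures are released as each node is processed, so a
graph can be backpropagated once; Grad-CAM reads the retained gradient of
the chosen layer's activation. BN uses eps 1e-5, momentum 0.1, biased
variance for normalization and unbiased running variance; in eval mode the
running statistics are folded into a constant affine map. Degenerate
metric denominators (a class never predicted or absent) score 0 and the
class is flagged in the report. Heatmaps are min-max normalized; a constant
map is returned as all zeros.

## Known limitations

- The synthetic corpus is far easier than real photographs; reported
  desk-scale metrics are pipeline-health indicators, not accuracy claims.
- The engine is CPU-only and optimized for small batches; full-scale
  224 px training is possible but slow (hours per epoch), so the published
  recipe at full scale is a documented procedure, not a test.
- Grouped-conv group counts are clamped to divisors of the channel count,
  so exotic width multipliers can shift the effective group width.
- FPS measurements depend entirely on the host; they are reported but never
  asserted against any reference value.
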