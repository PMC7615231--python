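# Methods

## The guidance problem

During an obstetric ultrasound examination a sonographer simultaneously
reads the image, moves their eyes between anatomical structures, and rotates
the handheld probe toward a clinically defined *standard plane* (e.g. the
trans-ventricular, abdominal-circumference, or femur view). `guidenet`
models the next-step statistics of those two motor signals jointly: given
the synchronized streams of frame features, gaze points and probe
orientations up to time *t−1*, it predicts a probability distribution over
the gaze movement and the probe rotation at time *t*. All streams are
sampled at 6 Hz.

Four guidance policies are supported, in three combinations (the policy
with no local imitation signal on either task, SP+MG, is rejected at
configuration time):

* **OG** — the next gaze shift `s_t = g_t − g_{t−1}` as a bivariate
  Gaussian, decoded from a 5-vector (means through `sigmoid − 0.5` so they
  stay on the normalized screen, standard deviations through `exp`,
  correlation through `tanh`);
* **MG** — displacements of 1–3 gaze *fixation centers* over a 5-frame lag
  as an L-component bivariate Gaussian mixture (6L-vector; weights by
  softmax). Centers come from k-means over a sliding 5-frame window, seeded
  from the previous window's centers so cluster indices correspond across
  windows;
* **OP** — the next probe rotation `r_t = q*_{t−1} q_t` as a 4-D Gaussian
  over quaternion components (14-vector: 4 mean + 10 Cholesky entries);
* **SP** — the rotation straight to the standard plane, `q*_{t−1} q_T`,
  with the same density family.

## Quaternion conventions

Scalar-first Hamilton quaternions `(w, x, y, z)`. Because `q` and `−q`
encode the same rotation, every quaternion is sign-canonicalized (`w ≥ 0`,
ties resolved by the first nonzero component) before entering a loss or a
target stream, so the double cover never flips regression targets
mid-sequence. Angles are measured as `2·arccos(|⟨q1, q2⟩|)` and reported in
degrees. Scan stages are *coarse* (angle to the plane > 10°) and *fine*
(≤ 10°).

## Architecture

Each frame contributes three signals — image representation (1,920-dim,
from a pluggable encoder that must emit a 640×7×9 map pooled to 640×1×3),
gaze shift (2-dim) and probe rotation (4-dim) — each embedded to 128
channels by FC → BatchNorm → ReLU. The three embeddings are the nodes of a
graph whose 3×3 adjacency is `A = softmax_rows(θ(f) φ(f)ᵀ) + M`, with θ, φ
linear maps to 256 dimensions and `M` an unconstrained learnable mask
initialized at zero (so training starts from the pure feature-similarity
graph). Messages into the gaze and probe streams are one-layer graph
convolutions with the sigmoid applied *inside* the sum over source nodes —
this exact form is implemented even though the sigmoid-outside variant is
more common — so each message channel lies in (0, 3).

Each stream runs a GRU whose per-gate input transforms are these graph
messages. The two hidden states then mix through channel-wise adaptive
weights α (gaze) and β (probe), each a free 128-vector squashed by a
sigmoid and initialized at 0.5:

    h^s_t = α(1−z^s)h^s_{t−1} + αz^s h̃^s + (1−α)z^r h^s_{t−1} + (1−α)(1−z^r)h̃^s

and the probe update is the exact mirror (roles of the streams and of α/β
exchanged). For every channel the coefficients on `(h_{t−1}, h̃)` sum to 1,
α → 1 recovers the standard GRU, and disabling the pathway
(`bidirectional=False`) pins both weights at 1, giving two independent
graph-convolutional GRUs — the ablation switch. A final linear head per
stream emits the raw density parameters (5 / 6L / 14).

Conditioning is strictly one-step-ahead under teacher forcing: inputs at
index *t−1* produce the distribution for step *t*; a one-second warm-up
(t₀ = 6 frames) precedes the first prediction.

### Rotation decode centering

The probe head decodes its mean as `μ = (1,0,0,0) + s·raw` and its Cholesky
factor as `s·(softplus-diagonal, free off-diagonal)` with `s = 0.02`, and
the rotation *input* is standardized by the inverse transform before
embedding. The scale corresponds to a nominal per-frame rotation of ~1–2°
at 6 Hz (quaternion components of a few 10⁻²). This centering is essential
in practice: per-frame rotations deviate from the identity by ~10⁻³–10⁻²,
three orders of magnitude below the initialization scale of an unconstrained
head, and a control experiment with a plain MLP confirmed that neither it
nor the full model can learn the rotation mapping without it, while both
learn it readily with it. Unit norm of μ is enforced only softly, by the
training prior below; normalization to an exact rotation happens only when a
decoded mean or sampled average is composed with quaternions.

## Training objective

    L = Σ_{t=t₀}^{T} ( −λ_s log P_s − λ_r log P_r + η(1 − ‖μ^r_t‖)² )

with λ_s = λ_r = 1 (the two log-likelihoods share a range) and η = 50 — the
quaternion prior is a hard constraint in spirit and outweighs the guidance
losses. The prior (and the probe NLL) are active only when λ_r > 0, so a
gaze-only configuration leaves the probe head untouched. NLLs are computed
with numerically stable forms: log-sum-exp for the mixture, an unrolled
forward substitution on the 4-D Cholesky factor for the rotation density, a
floor of 1e−6 on (1 − ρ²), and scale floors σ ≥ 1e−3 (≈0.3 px) and Cholesky
diagonal ≥ 1e−3 (≈0.11°) that keep the NLLs bounded below when targets are
(near-)deterministic, as in noiseless simulations.

Optimization is AdamW at lr 1e−3, multiplied by 0.01 every 8 epochs (the
reading of "decayed by 0.01" as a multiplicative factor is a judgment call;
subtractive and 0.99-multiplicative readings are possible). Training clips
are 32 contiguous frames sampled per sequence per epoch
(`windows_per_sequence` can draw several, which desk-scale datasets need to
reach sane optimizer-step counts); augmentation of image frames jitters
brightness/contrast within 10% and crops within 20% per side, training only.
Two optional stabilizers, off by default: global gradient-norm clipping, and
a mean warm-up phase (`warmup_epochs`) that regresses the distribution means
with squared error before switching to the NLL — at the switch the heads'
scale slots are re-initialized to the empirical residual scale and the
optimizer moments are reset. The warm-up mirrors, at desk scale, the
original two-phase (pretrain, fine-tune) regime.

## Evaluation protocol

At each predicted step the decoded distribution is sampled 100 times and
the samples averaged into a point prediction (rotation averages are
renormalized and sign-canonicalized). A probe prediction is *correct* when
applying it rotates the probe no farther from the target orientation — the
actual next orientation `q_t` under OP, the plane `q_T` under SP — a
non-strict criterion under which the identity rotation counts as toward.
Accuracy is averaged within stage per sequence, then across sequences, and
also reported in 10°-wide bins over [0°, 30°]. Gaze is scored in pixels
after denormalization (ℓ2 error of the sampled mean; best-of-N over the raw
samples), and through saliency metrics: the predicted density is rendered
on the 224×288 raster anchored at the previous gaze point (OG) or the
lagged window centers (MG) and compared with an empirical map (8-px
Gaussians at the recorded gaze points; σ ≈ 1° of visual angle at typical
viewing geometry) via SIM, CC, KLD (KL(empirical ‖ predicted), ε = 1e−7)
and with the recorded fixations via AUC-Judd (thresholds at fixation
saliency values, all pixels as the negative pool; constant maps score 0.5)
and NSS. The continuation baselines replay the previous true rotation or
gaze shift. A seed-sensitivity harness retrains under several seeds on
fixed data and logs the spread of direction accuracy and gaze error.

## The scan simulator

Clinical scan recordings are not publicly deposited, so the package ships a
simulator that generates synchronized streams with the statistical
structure the model assumes:

* **Probe**: starts 30° (default) from a random target orientation; each
  coarse step closes a fixed geodesic fraction (default 0.1) of the
  remaining angle, optionally perturbed by rotation noise (default 0.5° per
  step); within 10° a fine phase superposes forward/backward oscillations
  (default 2°) on the drift, mimicking end-of-acquisition refinement. The
  last four frames settle with fraction 0.5 — capped at 1/2 so that
  replaying the previous rotation can never overshoot, keeping the
  continuation baseline exactly toward-target on noiseless runs. Noiseless
  runs end within 1° of the target.
* **Gaze**: a hidden fixation index over 1–3 plane-specific anchor centers
  (two structures for TVP/ACP, the two femur ends for FSP) switches with a
  per-frame saccade probability (default 0.1); gaze is the current center
  plus isotropic jitter (default 0.01 normalized units), clamped on-screen;
  centers drift as the probe approaches.
* **Features**: a fixed random linear embedding of the scan state (angle
  encodings, plane one-hot, gaze position) plus Gaussian noise — dependent
  on the probe's angular error the way encoder features are, and exactly
  recoverable by a linear probe when noiseless. An image mode renders
  geometric pseudo-anatomy (ellipses, a femur line) for end-to-end encoder
  tests.

One global seed fans out to per-sequence seeds through a counter, so any
sequence is reproducible in isolation. What the simulator does *not*
emulate: real ultrasound image content and its artifacts, fetal movement,
sonographer-specific scanning styles, freeze/annotation events, and the
many-plane (14-class) taxonomy. Passing tests on simulation therefore
demonstrate that the implementation is internally correct and that the
model class can learn guidance structure of this kind — not clinical
performance.

## Problem sizes and numerical choices

The shipped experiments run on one CPU core at desk scale: parameter
recovery trains on 200 sequences of 32 frames (feature dimension 64) for 10
epochs with three sampled windows per sequence per epoch; probe-guidance
behavior trains on 150 noiseless sequences under the same window sampling; the seed harness uses a reduced-width
model (32 channels) over three seeds. Training sequences match the 32-frame
window so the coarse phase (which occupies only the first ~12 frames of an
approach from 30°) appears in every clip. Structural checks always
instantiate the full-width model (128/256 channels, 1,920-dim features).
K-means windows use many restarts (cheap at 5 points per window) so the
partition matches exhaustive search; near-antipodal slerp falls back to a
fixed orthogonal waypoint; batch normalization uses running statistics in
evaluation so single-sequence inference is deterministic.

## Known limitations

The network is trained and evaluated with numpy on CPU through a small
tape-based autodiff engine; throughput limits experiments to reduced widths
and short schedules, and the pretrained ultrasound encoder of the original
system is replaced by the encoder *interface* plus a lightweight
random-init backbone. The MG policy's cross-window center correspondence by
seeded k-means is a design decision (sorting or optimal assignment are
alternatives); degenerate windows (fewer distinct points than components)
are masked out of the loss rather than imputed. Rollout is teacher-forced
everywhere, including evaluation; free-running rollout (feeding predictions
back as inputs) is not implemented.
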