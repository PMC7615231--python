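"""Multi-task training: objective, targets, augmentation, optimizer schedule.

The objective jointly minimizes the negative log-likelihoods of the gaze and
probe tasks over the predicted steps t0..T, plus a soft unit-norm prior on
the predicted rotation mean:

    L = sum_t ( -lambda_s log P_s - lambda_r log P_r + eta (1 - ||mu_r||)^2 )

with lambda_s = lambda_r = 1 (the two log-likelihoods share a range) and
eta = 50 — the prior is a hard constraint in spirit, so it outweighs the
two guidance losses; it keeps the rotation mean on the unit sphere without
hard normalization. Training is teacher-forced on windows of 32 contiguous
frames with a one-second warm-up (t0 = 6 at 6 Hz), optimized by AdamW with
the initial learning rate 1e-3 multiplied by 0.01 every 8 epochs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .gaze import sliding_center_windows
from .heads import ROT_CENTER, ROT_SCALE, nll_mg_raw, nll_og_raw, nll_quat_raw, quaternion_prior_raw
from .model import GuideNet, PolicyPair
from .nn import AdamW, Tensor, stack
from .quat import _angle_arr, _conj_arr, _mul_arr, canonicalize
from .simulate import SimSequence

__all__ = ["TrainConfig", "make_targets", "multitask_loss", "augment_frame", "train", "window_slice"]


@dataclass(frozen=True)
class TrainConfig:
    policy_pair: PolicyPair = field(default_factory=lambda: PolicyPair("OP", "OG"))
    lambda_s: float = 1.0
    lambda_r: float = 1.0
    eta: float = 50.0
    window: int = 32
    t0: int = 6
    F: int = 5
    L: int = 3
    lr: float = 1e-3
    decay: float = 0.01  # multiplicative lr factor ...
    decay_every: int = 8  # ... applied every this many epochs
    weight_decay: float = 1e-4
    epochs: int = 10
    batch_size: int = 16
    windows_per_sequence: int = 1  # random training windows drawn per sequence per epoch
    grad_clip: float | None = 5.0  # global gradient-norm clip (None disables)
    warmup_epochs: int = 0  # initial epochs regressing the means (squared error)
    # before switching to the full NLL; avoids the plateau where an inflated
    # covariance absorbs the mean bias early in training
    embed: int = 128
    hidden: int = 128
    proj: int = 256
    bidirectional: bool = True
    use_variance: bool = True  # False: plain regression on the means (ablation)
    seed: int = 0

    def __post_init__(self):
        if min(self.lambda_s, self.lambda_r, self.eta) < 0:
            raise ValueError("loss weights must be non-negative")
        if self.window <= self.t0 + 1:
            raise ValueError("window must exceed t0 + 1")


@dataclass
class SequenceTargets:
    """Per-step regression targets aligned with a sequence's frames."""

    gaze_shifts: np.ndarray  # (T, 2): s_t = g_t - g_{t-1} (s_0 = 0)
    rotations: np.ndarray  # (T, 4): canonical r_t (policy-dependent)
    center_disp: np.ndarray | None  # (T, L, 2) for MG, else None
    center_mask: np.ndarray | None  # (T,) bool: steps with a valid MG target


def make_targets(seq: SimSequence, policy_pair: PolicyPair, L: int = 3, F: int = 5, t0: int = 6) -> SequenceTargets:
    """Build aligned target streams for one sequence.

    OP targets are the actual per-step rotations ``conj(q_{t-1}) q_t``; SP
    targets are recomputed each step against the fixed plane orientation,
    ``conj(q_{t-1}) q_T``. MG targets are the displacements of the seeded
    k-means centers over an F-frame lag and exist only once a full window
    and its lagged counterpart fit after the warm-up (mask).
    """
    T = seq.T
    g = seq.gaze
    q = seq.quats
    shifts = np.zeros((T, 2))
    shifts[1:] = g[1:] - g[:-1]

    rotations = np.zeros((T, 4))
    rotations[:, 0] = 1.0
    if policy_pair.probe == "OP":
        rotations[1:] = canonicalize(_mul_arr(_conj_arr(q[:-1]), q[1:]))
    else:  # SP: rotation from q_{t-1} to the standard plane
        if seq.q_target is None:
            raise ValueError("SP policy requires a target plane quaternion")
        qT = seq.q_target.to_array()
        rotations[1:] = canonicalize(_mul_arr(_conj_arr(q[:-1]), np.broadcast_to(qT, (T - 1, 4))))

    center_disp = center_mask = None
    if policy_pair.gaze == "MG":
        windows = sliding_center_windows(g, F=F, L=L, seed=0)
        center_disp = np.zeros((T, L, 2))
        center_mask = np.zeros(T, dtype=bool)
        for t in range(t0 + F, T):
            w_now, w_prev = windows[t], windows[t - F]
            if w_now is None or w_prev is None:
                continue
            if w_now.n_centers != L or w_prev.n_centers != L:
                continue  # degenerate window: masked out
            center_disp[t] = w_now.centers - w_prev.centers
            center_mask[t] = True
    return SequenceTargets(shifts, rotations, center_disp, center_mask)


def window_slice(seq: SimSequence, start: int, length: int) -> SimSequence:
    """Contiguous sub-sequence (targets are rebuilt on the slice)."""
    sl = slice(start, start + length)
    return replace(
        seq,
        features=None if seq.features is None else seq.features[sl],
        frames=None if seq.frames is None else seq.frames[sl],
        gaze=seq.gaze[sl],
        quats=seq.quats[sl],
        angle_to_target=seq.angle_to_target[sl],
        true_centers=seq.true_centers[sl],
        fixation_index=seq.fixation_index[sl],
    )


def multitask_loss(
    raw_s_list: list[Tensor],
    raw_r_list: list[Tensor],
    targets: list[SequenceTargets],
    cfg: TrainConfig,
    t0: int | None = None,
) -> tuple[Tensor, dict[str, float]]:
    """Objective summed over predicted steps, averaged over the batch.

    Returns the scalar loss tensor and a float breakdown
    (gaze_nll / probe_nll / prior). Non-finite step terms are a hard error
    naming the step and term.
    """
    t0 = cfg.t0 if t0 is None else t0
    n_steps = len(raw_s_list)
    gaze_terms, probe_terms, prior_terms = [], [], []
    gaze_tgt = np.stack([tg.gaze_shifts for tg in targets])  # (B, T, 2)
    rot_tgt = np.stack([tg.rotations for tg in targets])
    if cfg.policy_pair.gaze == "MG":
        disp_tgt = np.stack([tg.center_disp for tg in targets])
        mask = np.stack([tg.center_mask for tg in targets])

    for i in range(n_steps):
        t = t0 + i
        raw_s, raw_r = raw_s_list[i], raw_r_list[i]
        if cfg.lambda_s > 0:
            if cfg.policy_pair.gaze == "OG":
                term = (
                    nll_og_raw(raw_s, gaze_tgt[:, t]).mean()
                    if cfg.use_variance
                    else (((raw_s[:, 0:2].sigmoid() - 0.5) - Tensor(gaze_tgt[:, t])) ** 2).sum(axis=1).mean()
                )
            else:
                m = mask[:, t].astype(float)
                if cfg.use_variance:
                    term = (nll_mg_raw(raw_s, disp_tgt[:, t], cfg.L) * m).sum() * (1.0 / max(m.sum(), 1.0))
                else:
                    mu = (raw_s[:, 0 : 5 * cfg.L].reshape(-1, cfg.L, 5)[:, :, 0:2].sigmoid() - 0.5)
                    sq = ((mu - Tensor(disp_tgt[:, t])) ** 2).sum(axis=2).mean(axis=1)
                    term = (sq * m).sum() * (1.0 / max(m.sum(), 1.0))
            _check_finite(term, t, "gaze")
            gaze_terms.append(term)
        if cfg.lambda_r > 0:
            if cfg.use_variance:
                term = nll_quat_raw(raw_r, rot_tgt[:, t]).mean()
            else:
                # regression on the raw (pre-decode) scale for conditioning
                raw_tgt = (rot_tgt[:, t] - ROT_CENTER) / ROT_SCALE
                term = ((raw_r[:, 0:4] - Tensor(raw_tgt)) ** 2).sum(axis=1).mean() * ROT_SCALE**2
            _check_finite(term, t, "probe")
            probe_terms.append(term)
            prior = quaternion_prior_raw(raw_r, cfg.eta).mean()
            _check_finite(prior, t, "prior")
            prior_terms.append(prior)

    zero = Tensor(0.0)
    gaze_sum = stack(gaze_terms).sum() if gaze_terms else zero
    probe_sum = stack(probe_terms).sum() if probe_terms else zero
    prior_sum = stack(prior_terms).sum() if prior_terms else zero
    total = cfg.lambda_s * gaze_sum + cfg.lambda_r * probe_sum + prior_sum
    parts = {
        "gaze_nll": float(gaze_sum.data),
        "probe_nll": float(probe_sum.data),
        "prior": float(prior_sum.data),
    }
    return total, parts


def _check_finite(term: Tensor, t: int, name: str) -> None:
    if not np.all(np.isfinite(term.data)):
        raise FloatingPointError(f"non-finite {name} loss term at step t={t}")


def augment_frame(image: np.ndarray, seed: int) -> np.ndarray:
    """Training-time frame augmentation: brightness and contrast jitter
    within 10% and a random crop retaining at least 80% per side, resized
    back to the model input shape. Deterministic under the seed; never
    applied at evaluation."""
    from skimage.transform import resize

    rng = np.random.default_rng(seed)
    img = np.asarray(image, dtype=float)
    h, w = img.shape
    b = rng.uniform(0.9, 1.1)
    c = rng.uniform(0.9, 1.1)
    img = (img - 0.5) * c + 0.5
    img = img * b
    ch = int(round(h * rng.uniform(0.8, 1.0)))
    cw = int(round(w * rng.uniform(0.8, 1.0)))
    top = rng.integers(0, h - ch + 1)
    left = rng.integers(0, w - cw + 1)
    img = img[top : top + ch, left : left + cw]
    img = resize(img, (h, w), order=1, anti_aliasing=False)
    return np.clip(img, 0.0, 1.0)


def _softplus_inv(y: np.ndarray) -> np.ndarray:
    return np.log(np.expm1(np.maximum(y, 1e-6)))


def _recalibrate_scale_slots(model: GuideNet, dataset: list[SimSequence], cfg: TrainConfig, rng) -> None:
    """At the warm-up -> NLL switch, re-initialize the heads' scale slots to
    the empirical residual scale of the warmed-up mean predictions.

    During mean warm-up the covariance outputs receive no direct gradient but
    drift with the shared trunk; starting the NLL phase from arbitrary scales
    destabilizes it. Zeroing the corresponding head columns and setting the
    biases from measured residuals gives the NLL phase a calibrated start.
    """
    from .nn import no_grad

    idx = rng.permutation(len(dataset))[: min(len(dataset), 2 * cfg.batch_size)]
    T = dataset[0].T
    starts = rng.integers(0, T - cfg.window + 1, size=len(idx))
    windows = [window_slice(dataset[k], s, cfg.window) for k, s in zip(idx, starts)]
    feats = np.stack([w.features for w in windows])
    gaze = np.stack([w.gaze for w in windows])
    quats = np.stack([w.quats for w in windows])
    targets = [make_targets(w, cfg.policy_pair, L=cfg.L, F=cfg.F, t0=cfg.t0) for w in windows]
    # train mode on purpose: residuals must reflect the batch statistics the
    # NLL phase will actually see
    with no_grad():
        raw_s_list, raw_r_list = model.rollout(feats, gaze, quats, t0=cfg.t0)

    rot_tgt = np.stack([tg.rotations for tg in targets])
    res_r = np.concatenate(
        [(ROT_CENTER + ROT_SCALE * raw_r.data[:, 0:4]) - rot_tgt[:, cfg.t0 + i] for i, raw_r in enumerate(raw_r_list)]
    )
    scale_r = np.maximum(res_r.std(axis=0), 2e-3)
    model.head_r.W.data[:, 4:] = 0.0
    model.head_r.b.data[4:8] = _softplus_inv(scale_r / ROT_SCALE)
    model.head_r.b.data[8:] = 0.0

    if cfg.policy_pair.gaze == "OG":
        gaze_tgt = np.stack([tg.gaze_shifts for tg in targets])
        res_s = np.concatenate(
            [
                (0.5 * (1 + np.tanh(0.5 * raw_s.data[:, 0:2])) - 0.5) - gaze_tgt[:, cfg.t0 + i]
                for i, raw_s in enumerate(raw_s_list)
            ]
        )
        scale_s = np.maximum(res_s.std(axis=0), 2e-3)
        model.head_s.W.data[:, 2:] = 0.0
        model.head_s.b.data[2:4] = np.log(scale_s)
        model.head_s.b.data[4] = 0.0
    else:  # MG: per-component scale slots share the pooled residual scale
        disp_tgt = np.stack([tg.center_disp for tg in targets])
        mask = np.stack([tg.center_mask for tg in targets])
        res = []
        for i, raw_s in enumerate(raw_s_list):
            t = cfg.t0 + i
            m = mask[:, t]
            if not m.any():
                continue
            for l in range(cfg.L):
                mu_l = 0.5 * (1 + np.tanh(0.5 * raw_s.data[m, 5 * l : 5 * l + 2])) - 0.5
                res.append(mu_l - disp_tgt[m, t, l])
        scale = np.maximum(np.concatenate(res).std(axis=0), 2e-3) if res else np.array([0.05, 0.05])
        for l in range(cfg.L):
            model.head_s.W.data[:, 5 * l + 2 : 5 * l + 5] = 0.0
            model.head_s.b.data[5 * l + 2 : 5 * l + 4] = np.log(scale)
            model.head_s.b.data[5 * l + 4] = 0.0


def train(dataset: list[SimSequence], cfg: TrainConfig) -> tuple[GuideNet, pd.DataFrame]:
    """Train a guidance model on a dataset of sequences.

    Each optimizer step samples a random contiguous window of ``cfg.window``
    frames per sequence in the batch (teacher forcing throughout). Loss
    history is recorded per epoch; training aborts with diagnostics if the
    loss diverges. Fully reproducible under ``cfg.seed``.
    """
    if not dataset:
        raise ValueError("empty dataset")
    feature_dim = dataset[0].features.shape[1]
    rng = np.random.default_rng(cfg.seed)
    model = GuideNet(
        cfg.policy_pair,
        feature_dim=feature_dim,
        embed=cfg.embed,
        hidden=cfg.hidden,
        proj=cfg.proj,
        L=cfg.L,
        bidirectional=cfg.bidirectional,
        seed=cfg.seed,
    )
    opt = AdamW(model.parameters(), lr=cfg.lr, weight_decay=cfg.weight_decay)
    history: list[dict[str, float]] = []
    n = len(dataset)
    T = dataset[0].T
    if T < cfg.window:
        raise ValueError(f"sequences of length {T} are shorter than the training window {cfg.window}")

    model.train()
    for epoch in range(cfg.epochs):
        opt.lr = cfg.lr * (cfg.decay ** (epoch // cfg.decay_every))
        loss_cfg = replace(cfg, use_variance=False) if epoch < cfg.warmup_epochs else cfg
        if cfg.warmup_epochs > 0 and epoch == cfg.warmup_epochs and cfg.use_variance:
            _recalibrate_scale_slots(model, dataset, cfg, rng)
            # fresh optimizer state: the moment estimates of the regression
            # phase are mis-scaled for NLL gradients
            opt = AdamW(model.parameters(), lr=opt.lr, weight_decay=cfg.weight_decay)
        order = np.concatenate([rng.permutation(n) for _ in range(cfg.windows_per_sequence)])
        ep_loss, ep_parts = 0.0, {"gaze_nll": 0.0, "probe_nll": 0.0, "prior": 0.0}
        n_batches = 0
        for lo in range(0, len(order), cfg.batch_size):
            idx = order[lo : lo + cfg.batch_size]
            starts = rng.integers(0, T - cfg.window + 1, size=len(idx))
            windows = [window_slice(dataset[k], s, cfg.window) for k, s in zip(idx, starts)]
            feats = np.stack([w.features for w in windows])
            gaze = np.stack([w.gaze for w in windows])
            quats = np.stack([w.quats for w in windows])
            targets = [make_targets(w, cfg.policy_pair, L=cfg.L, F=cfg.F, t0=cfg.t0) for w in windows]
            raw_s, raw_r = model.rollout(feats, gaze, quats, t0=cfg.t0)
            loss, parts = multitask_loss(raw_s, raw_r, targets, loss_cfg)
            if not np.isfinite(loss.data):
                raise FloatingPointError(f"training diverged at epoch {epoch}: loss={loss.data}")
            opt.zero_grad()
            loss.backward()
            if cfg.grad_clip is not None:
                total_sq = sum(float((p.grad**2).sum()) for p in model.parameters() if p.grad is not None)
                scale = cfg.grad_clip / max(np.sqrt(total_sq), cfg.grad_clip)
                if scale < 1.0:
                    for p in model.parameters():
                        if p.grad is not None:
                            p.grad *= scale
            opt.step()
            ep_loss += float(loss.data)
            for k in ep_parts:
                ep_parts[k] += parts[k]
            n_batches += 1
        history.append(
            {
                "epoch": epoch,
                "loss": ep_loss / n_batches,
                **{k: v / n_batches for k, v in ep_parts.items()},
            }
        )
    model.eval()
    return model, pd.DataFrame(history)
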