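"""Twin graph-convolutional GRU streams with a bidirectional inverse pathway.

Each of the gaze (s) and probe (r) streams runs a GRU whose input transforms
are graph-convolution messages over the 3-node modality graph (one message
per gate). The two hidden states are then mixed by channel-wise adaptive
weights alpha (gaze) and beta (probe):

    h^s_t = a(1-z^s) h^s_{t-1} + a z^s hs~ + (1-a) z^r h^s_{t-1} + (1-a)(1-z^r) hs~
    h^r_t = b(1-z^r) h^r_{t-1} + b z^r hr~ + (1-b) z^s h^r_{t-1} + (1-b)(1-z^s) hr~

(elementwise; the probe update mirrors the gaze one with the roles of the
streams and of alpha/beta exchanged). For every channel the coefficients on
(h_{t-1}, h~) sum to exactly 1, and alpha -> 1 (resp. beta -> 1) recovers the
standard GRU update; disabling the pathway pins both at 1, giving two
independent GCGRUs. alpha and beta are free 128-vectors squashed by a
sigmoid, initialized at 0 pre-squash so both streams start half-coupled.

Rollout is strictly one-step-ahead under teacher forcing: the distribution
for step t is produced from inputs up to t-1 only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .graph import AdjacencyModule, EmbeddingBlock, graph_message
from .nn import Linear, Module, Parameter, Tensor

__all__ = ["GuideState", "PolicyPair", "GuideNet", "head_dim"]

GAZE, PROBE = 1, 2  # node indices in the (I, s, r) order

VALID_PAIRS = {("OP", "OG"), ("SP", "OG"), ("OP", "MG")}


@dataclass(frozen=True)
class PolicyPair:
    """A probe policy (OP: next rotation; SP: rotation-to-plane) combined
    with a gaze policy (OG: next shift; MG: multi-step center mixture).

    The SP+MG combination has no local imitation signal on either task and
    is rejected.
    """

    probe: Literal["OP", "SP"]
    gaze: Literal["OG", "MG"]

    def __post_init__(self):
        if (self.probe, self.gaze) not in VALID_PAIRS:
            raise ValueError(f"unsupported policy pair {self.probe}+{self.gaze} (supported: OP+OG, SP+OG, OP+MG)")


def head_dim(policy: str, L: int = 3) -> int:
    """Raw output dimensionality of a policy head."""
    if policy == "OG":
        return 5
    if policy == "MG":
        return 6 * L
    if policy in ("OP", "SP"):
        return 14
    raise ValueError(f"unknown policy {policy!r}")


@dataclass
class GuideState:
    h_s: Tensor  # (B, H) gaze-stream hidden state
    h_r: Tensor  # (B, H) probe-stream hidden state

    @classmethod
    def zeros(cls, batch: int, hidden: int) -> "GuideState":
        return cls(Tensor(np.zeros((batch, hidden))), Tensor(np.zeros((batch, hidden))))


class _StreamGates(Module):
    """Per-stream GRU parameters: one graph kernel W, recurrent kernel U and
    bias b for each of the update (z), reset (gamma) and candidate (h) gates."""

    def __init__(self, embed: int, hidden: int, rng: np.random.Generator):
        def k(n_in, n_out):
            bound = np.sqrt(6.0 / (n_in + n_out))
            return Parameter(rng.uniform(-bound, bound, size=(n_in, n_out)))

        self.W = {g: k(embed, hidden) for g in ("z", "gamma", "h")}
        self.U = {g: k(hidden, hidden) for g in ("z", "gamma", "h")}
        self.b = {g: Parameter(np.zeros(hidden)) for g in ("z", "gamma", "h")}


class GuideNet(Module):
    """The full multi-task guidance model (feature-input form).

    Parameters
    ----------
    feature_dim : length of the per-frame image representation (1,920 for the
        encoder contract; smaller values are accepted for reduced studies).
    embed, hidden, proj : channel sizes (defaults 128, 128, 256).
    policy_pair : which probe/gaze policy heads to train.
    L : mixture components for the MG head (<= 3).
    bidirectional : enable the cross-stream pathway (ablation switch).
    """

    def __init__(
        self,
        policy_pair: PolicyPair,
        feature_dim: int = 1920,
        embed: int = 128,
        hidden: int = 128,
        proj: int = 256,
        L: int = 3,
        bidirectional: bool = True,
        seed: int = 0,
    ):
        if not (1 <= L <= 3):
            raise ValueError("L must be in {1, 2, 3}")
        rng = np.random.default_rng(seed)
        self.policy_pair = policy_pair
        self.feature_dim = feature_dim
        self.embed = embed
        self.hidden = hidden
        self.proj = proj
        self.L = L
        self.bidirectional = bidirectional

        self.embed_I = EmbeddingBlock(feature_dim, embed, rng)
        self.embed_s = EmbeddingBlock(2, embed, rng)
        self.embed_r = EmbeddingBlock(4, embed, rng)
        self.adjacency = AdjacencyModule(embed, proj, rng)
        self.gates_s = _StreamGates(embed, hidden, rng)
        self.gates_r = _StreamGates(embed, hidden, rng)
        self.alpha_raw = Parameter(np.zeros(hidden))  # sigmoid -> 0.5: half-coupled start
        self.beta_raw = Parameter(np.zeros(hidden))
        self.head_s = Linear(hidden, head_dim(policy_pair.gaze, L), rng)
        self.head_r = Linear(hidden, head_dim(policy_pair.probe), rng)

    # -- single step ----------------------------------------------------------

    def step(
        self,
        features: np.ndarray | Tensor,
        s_prev: np.ndarray | Tensor,
        r_prev: np.ndarray | Tensor,
        state: GuideState,
    ) -> tuple[GuideState, Tensor, Tensor]:
        """One guidance step. Inputs are the frame feature, gaze shift and
        probe rotation observed at t-1; returns the new state and the raw
        head vectors parametrizing the step-t distributions."""
        from .heads import ROT_CENTER, ROT_SCALE

        f_I = self.embed_I(features)
        f_s = self.embed_s(s_prev)
        # rotation inputs are centered at the identity and scaled by the
        # nominal per-frame rotation amplitude so their informative (vector)
        # components enter the embedding at O(1)
        r_in = (r_prev - ROT_CENTER) * (1.0 / ROT_SCALE) if isinstance(r_prev, np.ndarray) else (
            (r_prev - Tensor(ROT_CENTER)) * (1.0 / ROT_SCALE)
        )
        f_r = self.embed_r(r_in)
        from .graph import ModalityEmbedding

        emb = ModalityEmbedding(f_I, f_s, f_r).stacked()  # (B, 3, C)
        A, _ = self.adjacency(emb)

        def gates_for(stream: _StreamGates, j: int, h_prev: Tensor):
            msg = {g: graph_message(A, emb, stream.W[g], j) for g in ("z", "gamma", "h")}
            z = (msg["z"] + h_prev @ stream.U["z"] + stream.b["z"]).sigmoid()
            gamma = (msg["gamma"] + h_prev @ stream.U["gamma"] + stream.b["gamma"]).sigmoid()
            cand = (msg["h"] + (gamma * h_prev) @ stream.U["h"] + stream.b["h"]).tanh()
            return z, cand

        z_s, cand_s = gates_for(self.gates_s, GAZE, state.h_s)
        z_r, cand_r = gates_for(self.gates_r, PROBE, state.h_r)

        if self.bidirectional:
            alpha = self.alpha_raw.sigmoid()
            beta = self.beta_raw.sigmoid()
            h_s = pathway_update(state.h_s, cand_s, z_s, z_r, alpha)
            h_r = pathway_update(state.h_r, cand_r, z_r, z_s, beta)
        else:
            h_s = (1.0 - z_s) * state.h_s + z_s * cand_s
            h_r = (1.0 - z_r) * state.h_r + z_r * cand_r

        return GuideState(h_s, h_r), self.head_s(h_s), self.head_r(h_r)

    # -- sequence rollout ------------------------------------------------------

    def rollout(
        self,
        features: np.ndarray,
        gaze: np.ndarray,
        quats: np.ndarray,
        t0: int = 6,
    ) -> tuple[list[Tensor], list[Tensor]]:
        """Teacher-forced one-step-ahead rollout over a (batched) sequence.

        ``features`` (B, T, D); ``gaze`` (B, T, 2) normalized points;
        ``quats`` (B, T, 4) canonical unit quaternions. Returns raw head
        outputs for steps t0 .. T-1 (inputs at t-1 produce the prediction
        for t, so nothing at step t leaks into its own prediction).
        """
        from .quat import _conj_arr, _mul_arr, canonicalize

        features = np.asarray(features, dtype=float)
        gaze = np.asarray(gaze, dtype=float)
        quats = np.asarray(quats, dtype=float)
        if features.ndim == 2:
            features, gaze, quats = features[None], gaze[None], quats[None]
        B, T = features.shape[:2]
        if T < t0 + 2:
            raise ValueError(f"sequence length {T} too short for warm-up t0={t0}")

        shifts = np.zeros((B, T, 2))
        shifts[:, 1:] = gaze[:, 1:] - gaze[:, :-1]
        rots = np.zeros((B, T, 4))
        rots[:, 0, 0] = 1.0  # identity at the first frame
        rots[:, 1:] = canonicalize(_mul_arr(_conj_arr(quats[:, :-1]), quats[:, 1:]))

        state = GuideState.zeros(B, self.hidden)
        raw_s_list: list[Tensor] = []
        raw_r_list: list[Tensor] = []
        for i in range(T - 1):
            state, raw_s, raw_r = self.step(features[:, i], shifts[:, i], rots[:, i], state)
            if i + 1 >= t0:
                raw_s_list.append(raw_s)
                raw_r_list.append(raw_r)
        return raw_s_list, raw_r_list


def pathway_update(h_prev: Tensor, cand: Tensor, z_own: Tensor, z_other: Tensor, w: Tensor) -> Tensor:
    """Bidirectional pathway hidden-state update.

    Convex per-channel combination of (h_prev, cand): the own-stream GRU
    update weighted by w plus the inverse update driven by the other
    stream's gate weighted by (1 - w).
    """
    own = (1.0 - z_own) * h_prev + z_own * cand
    inverse = z_other * h_prev + (1.0 - z_other) * cand
    return w * own + (1.0 - w) * inverse
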