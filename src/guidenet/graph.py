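"""Modality graph: frame encoder, per-modality embeddings, adaptive adjacency.

The three per-frame signals — image representation, gaze shift, probe
rotation — form the nodes (I, s, r) of a 3-node graph. Each signal is
embedded into a 128-channel vector by an FC + BatchNorm + ReLU block; the
edge strengths are an adaptive 3x3 adjacency ``A = A_soft + M`` where
``A_soft(j, k) = softmax_k( theta(f_j)^T phi(f_k) )`` is row-stochastic
feature similarity (theta, phi project 128 -> 256) and ``M`` is an
unconstrained learnable mask shared across time, initialized at zero.

Messages into the gaze and probe streams are one-layer spatial graph
convolutions with the sigmoid applied inside the sum over source nodes:
``m_j = sum_k sigmoid( A(j, k) * f_k W )``, so each output channel lies in
(0, 3).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import BatchNorm1d, Linear, Module, Parameter, Tensor, stack

__all__ = [
    "NODE_ORDER",
    "EncoderOutput",
    "FrameEncoder",
    "LightweightEncoder",
    "ModalityEmbedding",
    "EmbeddingBlock",
    "AdjacencyState",
    "AdjacencyModule",
    "graph_message",
    "FRAME_SHAPE",
    "FEATURE_DIM",
]

NODE_ORDER = ("I", "s", "r")  # fixed node indexing of the modality graph
FRAME_SHAPE = (224, 288)  # (height, width) of a model-input frame
FEATURE_DIM = 1920  # pooled image representation length (640 * 1 * 3)


@dataclass(frozen=True)
class EncoderOutput:
    feature_map: np.ndarray  # (B, 640, 7, 9)
    pooled: np.ndarray  # (B, 1920)


@dataclass(frozen=True)
class ModalityEmbedding:
    image_vec: Tensor
    gaze_vec: Tensor
    probe_vec: Tensor

    def stacked(self) -> Tensor:
        """(B, 3, C) in the fixed (I, s, r) node order."""
        return stack([self.image_vec, self.gaze_vec, self.probe_vec], axis=1)


@dataclass(frozen=True)
class AdjacencyState:
    A_soft: np.ndarray  # (3, 3) row-stochastic similarity term
    M: np.ndarray  # (3, 3) learnable mask
    A: np.ndarray  # their sum


class FrameEncoder:
    """Contract for pluggable image backbones.

    Any encoder must map (B, 224, 288) grayscale frames in [0, 1] to a
    (B, 640, 7, 9) feature map; pooling/flattening to the 1,920-vector is
    shared and fixed.
    """

    def feature_map(self, images: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def __call__(self, images: np.ndarray) -> EncoderOutput:
        images = np.asarray(images, dtype=float)
        if images.ndim == 2:
            images = images[None]
        if images.shape[1:] != FRAME_SHAPE:
            raise ValueError(f"expected frames of shape {FRAME_SHAPE}, got {images.shape[1:]}")
        fmap = self.feature_map(images)
        if fmap.shape[1:] != (640, 7, 9):
            raise ValueError(f"backbone produced {fmap.shape[1:]}, contract is (640, 7, 9)")
        return EncoderOutput(feature_map=fmap, pooled=pool_and_flatten(fmap))


def pool_and_flatten(fmap: np.ndarray) -> np.ndarray:
    """Adaptive average pooling of a (B, 640, 7, 9) map to (640, 1, 3), then
    flattening to the 1,920-channel image representation."""
    pooled = fmap.reshape(fmap.shape[0], 640, 7, 3, 3).mean(axis=(2, 4))  # (B, 640, 3)
    return pooled.reshape(fmap.shape[0], FEATURE_DIM)


def _conv2d(x: np.ndarray, w: np.ndarray, b: np.ndarray, stride: int) -> np.ndarray:
    """Plain strided 3x3 (or 1x1) convolution with 'same'-style padding,
    forward only (the lightweight backbone is not trained)."""
    B, C, H, W = x.shape
    Co, Ci, kh, kw = w.shape
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    Ho = (H + 2 * ph - kh) // stride + 1
    Wo = (W + 2 * pw - kw) // stride + 1
    patches = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    patches = patches[:, :, ::stride, ::stride]  # (B, C, Ho, Wo, kh, kw)
    cols = patches.transpose(0, 2, 3, 1, 4, 5).reshape(B, Ho * Wo, Ci * kh * kw)
    out = cols @ w.reshape(Co, -1).T + b
    return out.reshape(B, Ho, Wo, Co).transpose(0, 3, 1, 2)


class LightweightEncoder(FrameEncoder):
    """Small random-init convolutional backbone satisfying the shape contract.

    Five stride-2 3x3 conv+ReLU stages (224x288 -> 7x9) followed by a 1x1
    conv to 640 channels. Intended for shape/e2e tests and the image mode of
    the simulator; a pretrained backbone can be plugged in via the same
    :class:`FrameEncoder` contract.
    """

    def __init__(self, seed: int = 0, zero_bias: bool = False):
        rng = np.random.default_rng(seed)
        chans = [1, 8, 16, 32, 64, 64]
        self.layers = []
        for ci, co in zip(chans[:-1], chans[1:]):
            w = rng.normal(scale=np.sqrt(2.0 / (ci * 9)), size=(co, ci, 3, 3))
            b = np.zeros(co) if zero_bias else rng.normal(scale=0.01, size=co)
            self.layers.append((w, b))
        w = rng.normal(scale=np.sqrt(2.0 / 64), size=(640, 64, 1, 1))
        b = np.zeros(640) if zero_bias else rng.normal(scale=0.01, size=640)
        self.head = (w, b)

    def feature_map(self, images: np.ndarray) -> np.ndarray:
        x = images[:, None, :, :]
        for w, b in self.layers:
            x = np.maximum(_conv2d(x, w, b, stride=2), 0.0)
        w, b = self.head
        return np.maximum(_conv2d(x, w, b, stride=1), 0.0)


class EmbeddingBlock(Module):
    """FC -> BatchNorm -> ReLU mapping one raw modality vector to 128 channels."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.n_in = n_in
        self.fc = Linear(n_in, n_out, rng)
        self.bn = BatchNorm1d(n_out)

    def __call__(self, x: Tensor | np.ndarray) -> Tensor:
        x = x if isinstance(x, Tensor) else Tensor(x)
        if x.shape[-1] != self.n_in:
            raise ValueError(f"embedding block expects {self.n_in}-dim input, got {x.shape[-1]}")
        return self.bn(self.fc(x)).relu()


class AdjacencyModule(Module):
    """Adaptive adjacency ``A = softmax_rows(theta(f) phi(f)^T) + M``."""

    def __init__(self, embed_dim: int, proj_dim: int, rng: np.random.Generator):
        self.theta = Linear(embed_dim, proj_dim, rng)
        self.phi = Linear(embed_dim, proj_dim, rng)
        self.M = Parameter(np.zeros((3, 3)))  # zero init: start from pure similarity

    def __call__(self, emb_stacked: Tensor) -> tuple[Tensor, Tensor]:
        """emb_stacked: (B, 3, C). Returns (A, A_soft), each (B, 3, 3)."""
        th = self.theta(emb_stacked)  # (B, 3, P)
        ph = self.phi(emb_stacked)
        scores = th @ ph.T  # (B, 3, 3): scores[j, k] = theta(f_j) . phi(f_k)
        a_soft = scores.softmax(axis=-1)
        return a_soft + self.M, a_soft

    def state(self, emb_stacked: Tensor) -> AdjacencyState:
        """Numpy snapshot (batch-averaged) for inspection and JSON dumps."""
        A, a_soft = self(emb_stacked)
        return AdjacencyState(
            A_soft=a_soft.data.mean(axis=0),
            M=self.M.data.copy(),
            A=A.data.mean(axis=0),
        )


def graph_message(A: Tensor, emb_stacked: Tensor, W: Parameter, j: int) -> Tensor:
    """One-layer graph convolution message into node j (1 = gaze, 2 = probe).

    ``sum_k sigmoid( A(j, k) * f_k W )`` with the sigmoid inside the sum, so
    every output channel lies in (0, 3).
    """
    if j not in (1, 2):
        raise ValueError("messages are defined for the gaze (1) and probe (2) nodes")
    transformed = emb_stacked @ W  # (B, 3, C)
    B = A.shape[0]
    scale = A[:, j, :].reshape(B, 3, 1)
    return (scale * transformed).sigmoid().sum(axis=1)  # (B, C)
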