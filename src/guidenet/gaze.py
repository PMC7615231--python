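"""Gaze-point normalization, step shifts, and sliding-window fixation clustering.

Screen gaze is normalized to ``(-0.5, 0.5)`` per axis with the image center at
the origin (x rightward, y downward); all file I/O stores raw pixels and
normalization happens on load. The one-step signal is the shift
``s_t = g_t - g_{t-1}``; the multi-step signal clusters the gaze points of a
sliding window of ``F`` frames into ``L <= 3`` fixation centers and tracks the
per-center displacement ``s^l_t = c^l_t - c^l_{t-F}``.

Cross-window center correspondence is supplied by seeding each window's
k-means from the previous window's centers (k-means++ on the first window).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

__all__ = [
    "GazeSample",
    "GazeShift",
    "CenterWindow",
    "normalize_gaze",
    "denormalize_gaze",
    "gaze_shift",
    "reconstruct_gaze",
    "cluster_window",
    "center_displacement",
    "sliding_center_windows",
]

_BOUND = 0.5 - 1e-9


def _clamp(v: float) -> float:
    return float(np.clip(v, -_BOUND, _BOUND))


@dataclass(frozen=True)
class GazeSample:
    """Normalized gaze point; |x|, |y| < 0.5 with the image center at (0,0)."""

    x: float
    y: float
    t: int = 0

    def to_array(self) -> np.ndarray:
        return np.array([self.x, self.y])


@dataclass(frozen=True)
class GazeShift:
    dx: float
    dy: float

    def to_array(self) -> np.ndarray:
        return np.array([self.dx, self.dy])


@dataclass(frozen=True)
class CenterWindow:
    """Fixation centers of one F-frame window, with per-center member weights."""

    centers: np.ndarray  # (L, 2)
    weights: np.ndarray  # (L,), sums to 1
    window_start: int
    window_end: int
    degenerate: bool = False  # True when L had to be reduced

    @property
    def n_centers(self) -> int:
        return len(self.centers)


def normalize_gaze(raw_xy, image_size) -> GazeSample:
    """Map raw pixel coordinates to (-0.5, 0.5) with the center invariant.

    ``image_size`` is (width, height) in pixels. Points outside the image are
    clamped to the boundary.
    """
    w, h = image_size
    if w <= 0 or h <= 0:
        raise ValueError("image_size must be positive")
    x = float(raw_xy[0]) / w - 0.5
    y = float(raw_xy[1]) / h - 0.5
    return GazeSample(_clamp(x), _clamp(y))


def denormalize_gaze(g: GazeSample, image_size) -> np.ndarray:
    """Inverse of :func:`normalize_gaze`; returns pixel coordinates."""
    w, h = image_size
    return np.array([(g.x + 0.5) * w, (g.y + 0.5) * h])


def gaze_shift(g_prev: GazeSample, g_curr: GazeSample) -> GazeShift:
    """Per-step gaze displacement ``s_t = g_t - g_{t-1}``."""
    return GazeShift(g_curr.x - g_prev.x, g_curr.y - g_prev.y)


def reconstruct_gaze(g_prev: GazeSample, s_hat: GazeShift) -> GazeSample:
    """Predicted absolute gaze ``g_hat = g_{t-1} + s_hat``, clamped on-screen."""
    return GazeSample(_clamp(g_prev.x + s_hat.dx), _clamp(g_prev.y + s_hat.dy), g_prev.t + 1)


def cluster_window(
    points: list[GazeSample] | np.ndarray,
    L: int,
    init_centers: CenterWindow | None = None,
    seed: int = 0,
    window_start: int = 0,
) -> CenterWindow:
    """K-means partition of one window's gaze points into L fixation centers.

    When ``init_centers`` is given, k-means is seeded from them so that
    cluster index l corresponds across consecutive windows. If the window has
    fewer distinct points than L, duplicate centers are merged, L is reduced
    and the window is flagged degenerate.
    """
    pts = np.asarray([p.to_array() if isinstance(p, GazeSample) else p for p in points], dtype=float)
    if L < 1:
        raise ValueError("L must be >= 1")
    if L > len(pts):
        raise ValueError(f"L={L} exceeds window size {len(pts)}")

    distinct = np.unique(pts, axis=0)
    k = min(L, len(distinct))
    degenerate = k < L

    if k == 1:
        centers = distinct.mean(axis=0, keepdims=True) if len(distinct) == 1 else pts.mean(axis=0, keepdims=True)
        labels = np.zeros(len(pts), dtype=int)
    else:
        if init_centers is not None and init_centers.n_centers == k:
            init = np.asarray(init_centers.centers, dtype=float)
            km = KMeans(n_clusters=k, init=init, n_init=1, random_state=seed)
        else:
            # windows are tiny (F ~ 5 points): many restarts are cheap and
            # reliably reach the globally best partition
            km = KMeans(n_clusters=k, init="k-means++", n_init=max(10, 8 * len(pts)), random_state=seed)
        labels = km.fit_predict(pts)
        centers = np.array([pts[labels == i].mean(axis=0) for i in range(k)])

    weights = np.bincount(labels, minlength=len(centers)).astype(float) / len(pts)
    return CenterWindow(
        centers=centers,
        weights=weights,
        window_start=window_start,
        window_end=window_start + len(pts) - 1,
        degenerate=degenerate,
    )


def center_displacement(window_t: CenterWindow, window_prev: CenterWindow) -> list[GazeShift]:
    """Per-center displacement ``s^l_t = c^l_t - c^l_{t-F}`` under the seeded
    index correspondence. A center-count mismatch means correspondence is
    broken and is a hard error."""
    if window_t.n_centers != window_prev.n_centers:
        raise ValueError(
            f"center-count mismatch ({window_t.n_centers} vs {window_prev.n_centers}): correspondence broken"
        )
    diff = window_t.centers - window_prev.centers
    return [GazeShift(float(d[0]), float(d[1])) for d in diff]


def sliding_center_windows(
    gaze: np.ndarray, F: int = 5, L: int = 3, seed: int = 0
) -> list[CenterWindow | None]:
    """Cluster every length-F window ending at each frame t (None for t < F-1).

    Returns one entry per frame; entry t covers frames [t-F+1, t]. Windows are
    chained: each is seeded from the previous one's centers.
    """
    gaze = np.asarray(gaze, dtype=float)
    out: list[CenterWindow | None] = [None] * len(gaze)
    prev: CenterWindow | None = None
    for t in range(F - 1, len(gaze)):
        win = cluster_window(gaze[t - F + 1 : t + 1], L, init_centers=prev, seed=seed, window_start=t - F + 1)
        out[t] = win
        prev = None if win.degenerate else win
    return out
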