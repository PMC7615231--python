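"""Evaluation machinery: rotation-direction accuracy with coarse/fine
staging, gaze pixel error, best-of-N, saliency rendering and the five
saliency metrics (SIM, CC, KLD, AUC-Judd, NSS).

A probe prediction counts as correct when applying it rotates the probe no
farther from the target orientation (non-strict); accuracy is reported per
scanning stage — coarse (> 10 deg to the plane) and fine (<= 10 deg) — and
per 10-degree angle bin over [0, 30] deg. Gaze is scored in pixels after
denormalization. Saliency maps live on the 224x288 image raster and are
normalized to sum 1 unless a metric requires z-scoring.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.stats import multivariate_normal

from .gaze import CenterWindow, GazeSample, denormalize_gaze
from .graph import FRAME_SHAPE
from .heads import BivariateGaussianParams, GazeMixtureParams
from .quat import _angle_arr, _mul_arr, canonicalize

__all__ = [
    "StageMask",
    "SaliencyMap",
    "stage_split",
    "direction_accuracy",
    "DirectionAccuracy",
    "gaze_l2_error",
    "best_of_n_error",
    "render_saliency",
    "empirical_saliency",
    "sim",
    "cc",
    "kld",
    "auc_judd",
    "nss",
]

FINE_THRESHOLD_DEG = 10.0
ANGLE_BINS = [(0.0, 10.0), (10.0, 20.0), (20.0, 30.0)]
_DEFAULT_SIZE = (FRAME_SHAPE[1], FRAME_SHAPE[0])  # (width, height)


@dataclass(frozen=True)
class StageMask:
    """Per-frame scanning-stage labels from the angle to the target plane."""

    angles_deg: np.ndarray
    labels: np.ndarray  # "coarse" / "fine"

    def is_fine(self) -> np.ndarray:
        return self.labels == "fine"


def stage_split(quats: np.ndarray, q_target) -> StageMask:
    """Label every frame coarse (> 10 deg to the plane) or fine (<= 10 deg)."""
    qt = q_target.to_array() if hasattr(q_target, "to_array") else np.asarray(q_target)
    angles = _angle_arr(np.asarray(quats, dtype=float), qt)
    labels = np.where(angles > FINE_THRESHOLD_DEG, "coarse", "fine")
    return StageMask(angles_deg=angles, labels=labels)


@dataclass(frozen=True)
class DirectionAccuracy:
    overall: float
    coarse: float  # NaN when the stage has no frames
    fine: float
    bins: dict[tuple[float, float], float]
    n_frames: int


def direction_accuracy(
    pred_rotations: np.ndarray,
    quats: np.ndarray,
    q_target,
    frame_indices: np.ndarray | None = None,
    policy: str = "OP",
) -> DirectionAccuracy:
    """Fraction of predicted rotations that rotate toward the target.

    ``pred_rotations`` (N, 4) are sampled-mean unit rotations for frames
    ``frame_indices`` (defaults to 1..N). For the OP policy the per-step
    target is the actual next orientation ``q_t``; for SP it is the plane
    orientation ``q_T``. Staging and binning use the angle from ``q_{t-1}``
    to the plane.
    """
    pred = canonicalize(np.asarray(pred_rotations, dtype=float))
    quats = np.asarray(quats, dtype=float)
    qt_plane = q_target.to_array() if hasattr(q_target, "to_array") else np.asarray(q_target)
    if frame_indices is None:
        frame_indices = np.arange(1, len(pred) + 1)
    frame_indices = np.asarray(frame_indices)

    q_prev = quats[frame_indices - 1]
    target = quats[frame_indices] if policy == "OP" else np.broadcast_to(qt_plane, (len(pred), 4))
    moved = _mul_arr(q_prev, pred)
    toward = _angle_arr(moved, target) <= _angle_arr(q_prev, target) + 1e-9
    stage_angle = _angle_arr(q_prev, qt_plane)

    def frac(mask):
        return float(toward[mask].mean()) if mask.any() else float("nan")

    coarse_m = stage_angle > FINE_THRESHOLD_DEG
    bins = {b: frac((stage_angle > b[0]) & (stage_angle <= b[1])) for b in ANGLE_BINS}
    return DirectionAccuracy(
        overall=float(toward.mean()),
        coarse=frac(coarse_m),
        fine=frac(~coarse_m),
        bins=bins,
        n_frames=len(pred),
    )


def gaze_l2_error(pred: GazeSample, truth: GazeSample, image_size=_DEFAULT_SIZE) -> float:
    """Euclidean gaze error in pixels."""
    return float(np.linalg.norm(denormalize_gaze(pred, image_size) - denormalize_gaze(truth, image_size)))


def best_of_n_error(samples: np.ndarray, truth: GazeSample, image_size=_DEFAULT_SIZE) -> float:
    """Minimum pixel error over sampled gaze predictions (the starred
    best-of-N evaluation of sampling-based predictors)."""
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    if len(samples) == 0:
        raise ValueError("no samples")
    errs = [gaze_l2_error(GazeSample(float(s[0]), float(s[1])), truth, image_size) for s in samples]
    return float(min(errs))


# -- saliency ------------------------------------------------------------------


@dataclass(frozen=True)
class SaliencyMap:
    values: np.ndarray  # (H, W), non-negative
    normalization: str  # "density" | "sum1" | "zscore"
    off_screen_flag: bool = False

    @property
    def shape(self):
        return self.values.shape


def _pixel_grid(image_size) -> tuple[np.ndarray, np.ndarray]:
    w, h = image_size
    xs = (np.arange(w) + 0.5) / w - 0.5
    ys = (np.arange(h) + 0.5) / h - 0.5
    return np.meshgrid(xs, ys)  # each (H, W)


def render_saliency(
    dist: BivariateGaussianParams | GazeMixtureParams,
    anchor: GazeSample | CenterWindow,
    image_size=_DEFAULT_SIZE,
) -> SaliencyMap:
    """Saliency map of a predicted gaze distribution on the image raster.

    The shift distribution is translated to absolute screen position via the
    anchor (previous gaze point for the one-step policy; the lagged window's
    centers for the multi-step mixture), evaluated per pixel and normalized
    to sum 1. If more than half the probability mass falls off-screen the
    map is flagged (and still rendered on the clamped domain).
    """
    X, Y = _pixel_grid(image_size)
    pos = np.dstack([X, Y])
    if isinstance(dist, BivariateGaussianParams):
        comps = [(1.0, dist)]
        anchors = [np.asarray(anchor.to_array() if isinstance(anchor, GazeSample) else anchor)]
    else:
        comps = list(zip(dist.pi, dist.components))
        if not isinstance(anchor, CenterWindow) or anchor.n_centers != dist.n_components:
            raise ValueError("mixture rendering needs a CenterWindow anchor with matching center count")
        anchors = list(anchor.centers)

    density = np.zeros(X.shape)
    for (w_l, comp), a in zip(comps, anchors):
        mean = np.asarray(a, dtype=float) + comp.mu
        density += w_l * multivariate_normal(mean=mean, cov=comp.covariance()).pdf(pos)
    pixel_area = 1.0 / (image_size[0] * image_size[1])
    mass_on_screen = density.sum() * pixel_area
    flag = mass_on_screen < 0.5
    if flag:
        warnings.warn("more than 50% of predicted gaze mass falls off-screen", stacklevel=2)
    total = density.sum()
    values = density / total if total > 0 else np.full_like(density, 1.0 / density.size)
    return SaliencyMap(values=values, normalization="sum1", off_screen_flag=flag)


def empirical_saliency(points: list[GazeSample], blur_sigma_px: float = 8.0, image_size=_DEFAULT_SIZE) -> SaliencyMap:
    """Empirical gaze map: a sum of isotropic Gaussians (sigma in pixels)
    at the recorded gaze points, normalized to sum 1."""
    if not points:
        raise ValueError("no gaze points")
    w, h = image_size
    impulses = np.zeros((h, w))
    for p in points:
        px, py = denormalize_gaze(p, image_size)
        impulses[int(np.clip(py, 0, h - 1)), int(np.clip(px, 0, w - 1))] += 1.0
    blurred = gaussian_filter(impulses, sigma=blur_sigma_px, mode="constant")
    return SaliencyMap(values=blurred / blurred.sum(), normalization="sum1")


def _as_sum1(m: SaliencyMap) -> np.ndarray:
    v = np.asarray(m.values, dtype=float)
    s = v.sum()
    if not np.isclose(s, 1.0, atol=1e-6):
        warnings.warn("saliency map not sum-normalized; normalizing", stacklevel=3)
        v = v / s
    return v


def sim(p: SaliencyMap, q: SaliencyMap) -> float:
    """Histogram intersection: the pixel-wise minimum of two sum-1 maps."""
    return float(np.minimum(_as_sum1(p), _as_sum1(q)).sum())


def cc(p: SaliencyMap, q: SaliencyMap) -> float:
    """Pearson linear correlation of the flattened maps (0 for a
    zero-variance map, with a warning)."""
    a, b = p.values.ravel(), q.values.ravel()
    if np.std(a) == 0 or np.std(b) == 0:
        warnings.warn("zero-variance saliency map: CC defined as 0", stacklevel=2)
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def kld(p: SaliencyMap, q: SaliencyMap, eps: float = 1e-7) -> float:
    """KL(p || q) with the empirical map as p and the prediction as q (the
    saliency-benchmark convention), eps-stabilized."""
    pv, qv = _as_sum1(p), _as_sum1(q)
    return float(np.sum(pv * np.log(pv / (qv + eps) + eps)))


def _fixation_values(m: SaliencyMap, fixations: list[GazeSample], image_size) -> np.ndarray:
    w, h = image_size
    vals = []
    for f in fixations:
        px, py = denormalize_gaze(f, image_size)
        vals.append(m.values[int(np.clip(py, 0, h - 1)), int(np.clip(px, 0, w - 1))])
    return np.asarray(vals)


def auc_judd(p: SaliencyMap, fixations: list[GazeSample], image_size=_DEFAULT_SIZE) -> float:
    """ROC area with fixated pixels as positives and all pixels as the
    negative pool; thresholds are taken at each fixation's saliency value.
    A constant map scores 0.5 by convention."""
    if not fixations:
        raise ValueError("need at least one fixation")
    v = p.values
    if np.ptp(v) == 0:
        return 0.5
    fvals = _fixation_values(p, fixations, image_size)
    allv = v.ravel()
    thresholds = np.sort(fvals)[::-1]
    tpr = [0.0]
    fpr = [0.0]
    for th in thresholds:
        tpr.append(float((fvals >= th).mean()))
        fpr.append(float((allv >= th).mean()))
    tpr.append(1.0)
    fpr.append(1.0)
    return float(np.trapezoid(tpr, fpr))


def nss(p: SaliencyMap, fixations: list[GazeSample], image_size=_DEFAULT_SIZE) -> float:
    """Mean z-scored saliency at the fixation pixels (0 for a constant map)."""
    if not fixations:
        raise ValueError("need at least one fixation")
    v = p.values
    sd = v.std()
    if sd == 0:
        return 0.0
    z = SaliencyMap(values=(v - v.mean()) / sd, normalization="zscore")
    return float(_fixation_values(z, fixations, image_size).mean())
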