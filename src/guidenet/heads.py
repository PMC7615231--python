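"""Probability heads for the guidance policies.

Three output densities are used, one per policy family:

* one-step gaze shift (OG) — bivariate Gaussian, decoded from a 5-vector
  ``(mu_x, mu_y, log sigma_x, log sigma_y, rho_raw)``: the means pass through
  ``sigmoid(.) - 0.5`` so they live in (-0.5, 0.5), the standard deviations
  through ``exp``, and the correlation through ``tanh``;
* multi-step gaze centers (MG) — an L-component bivariate Gaussian mixture
  decoded from a 6L-vector (L blocks of 5 as above followed by L weight
  logits softmaxed to the simplex);
* probe rotation (OP/SP) — a 4-D multivariate Gaussian over quaternion
  components decoded from a 14-vector: 4 for the mean, decoded as the
  identity quaternion plus a small-rotation scale times the raw output
  (unit norm is encouraged only by the training prior
  ``eta * (1 - ||mu||)^2``), and 10 for a lower-triangular Cholesky factor
  with softplus-positive diagonal at the same scale.

Every decode has two routes: a numpy route producing parameter dataclasses
for sampling/evaluation, and an autodiff route (``*_raw`` functions on
:class:`~guidenet.nn.Tensor`) used inside the training loss.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Tensor
from .quat import canonicalize

__all__ = [
    "BivariateGaussianParams",
    "GazeMixtureParams",
    "QuatGaussianParams",
    "decode_og",
    "decode_mg",
    "decode_op",
    "nll_bivariate",
    "nll_mixture",
    "nll_quat",
    "quaternion_prior",
    "sample",
    "point_prediction",
    "nll_og_raw",
    "nll_mg_raw",
    "nll_quat_raw",
    "quaternion_prior_raw",
    "TRIL_ROWS",
    "TRIL_COLS",
]

_RHO_FLOOR = 1e-6  # floor on (1 - rho^2)
# scale floors keep the NLLs bounded below on (near-)deterministic targets,
# where the unconstrained optimum sigma -> 0 would explode the gradients;
# 1e-3 normalized units is ~0.3 px on the screen raster
SIGMA_FLOOR = 1e-3
CHOL_DIAG_FLOOR = 1e-3
# the rotation head decodes around the identity rotation at the scale of a
# nominal per-frame probe rotation (~1-2 deg at 6 Hz, i.e. quaternion
# components of a few 1e-2); without this centering the raw outputs would
# have to span three orders of magnitude below their initialization scale
ROT_CENTER = np.array([1.0, 0.0, 0.0, 0.0])
ROT_SCALE = 0.02

# fixed order of the 6 strict lower-triangle entries of the 4x4 Cholesky factor
TRIL_ROWS = np.array([1, 2, 2, 3, 3, 3])
TRIL_COLS = np.array([0, 0, 1, 0, 1, 2])


def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def _softplus(x):
    return np.logaddexp(0.0, x)


@dataclass(frozen=True)
class BivariateGaussianParams:
    mu: np.ndarray  # (2,), each in (-0.5, 0.5)
    sigma: np.ndarray  # (2,), > 0
    rho: float  # in (-1, 1)

    def covariance(self) -> np.ndarray:
        sx, sy = self.sigma
        c = self.rho * sx * sy
        return np.array([[sx**2, c], [c, sy**2]])


@dataclass(frozen=True)
class GazeMixtureParams:
    components: tuple[BivariateGaussianParams, ...]
    pi: np.ndarray  # (L,), simplex

    @property
    def n_components(self) -> int:
        return len(self.components)


@dataclass(frozen=True)
class QuatGaussianParams:
    mu: np.ndarray  # (4,), unconstrained mean
    chol: np.ndarray  # (4, 4) lower-triangular, positive diagonal

    def covariance(self) -> np.ndarray:
        return self.chol @ self.chol.T


# -- numpy decodes -------------------------------------------------------------


def decode_og(raw) -> BivariateGaussianParams:
    raw = np.asarray(raw, dtype=float)
    if raw.shape != (5,) or not np.all(np.isfinite(raw)):
        raise ValueError("OG head expects a finite 5-vector")
    return BivariateGaussianParams(
        mu=_sigmoid(raw[:2]) - 0.5,
        sigma=np.maximum(np.exp(raw[2:4]), SIGMA_FLOOR),
        rho=float(np.tanh(raw[4])),
    )


def decode_mg(raw, L: int) -> GazeMixtureParams:
    raw = np.asarray(raw, dtype=float)
    if L < 1:
        raise ValueError("mixture needs at least one component")
    if raw.shape != (6 * L,):
        raise ValueError(f"MG head with L={L} expects a {6 * L}-vector, got {raw.shape}")
    comps = tuple(decode_og(raw[5 * l : 5 * l + 5]) for l in range(L))
    logits = raw[5 * L :]
    e = np.exp(logits - logits.max())
    return GazeMixtureParams(components=comps, pi=e / e.sum())


def decode_op(raw) -> QuatGaussianParams:
    raw = np.asarray(raw, dtype=float)
    if raw.shape != (14,) or not np.all(np.isfinite(raw)):
        raise ValueError("probe head expects a finite 14-vector")
    chol = np.zeros((4, 4))
    chol[np.arange(4), np.arange(4)] = np.maximum(ROT_SCALE * _softplus(raw[4:8]), CHOL_DIAG_FLOOR)
    chol[TRIL_ROWS, TRIL_COLS] = ROT_SCALE * raw[8:14]
    return QuatGaussianParams(mu=ROT_CENTER + ROT_SCALE * raw[:4], chol=chol)


# -- numpy log-densities -------------------------------------------------------


def nll_bivariate(params: BivariateGaussianParams, s) -> float:
    """Negative log density of the bivariate normal at shift s."""
    s = np.asarray(s, dtype=float).reshape(2)
    dx, dy = s - params.mu
    sx, sy = params.sigma
    omr = max(1.0 - params.rho**2, _RHO_FLOOR)
    z = (dx / sx) ** 2 - 2.0 * params.rho * dx * dy / (sx * sy) + (dy / sy) ** 2
    return float(np.log(2 * np.pi) + np.log(sx) + np.log(sy) + 0.5 * np.log(omr) + z / (2.0 * omr))


def nll_mixture(params: GazeMixtureParams, s) -> float:
    """Negative log of the mixture density, via log-sum-exp."""
    logs = np.array([-nll_bivariate(c, s) for c in params.components])
    with np.errstate(divide="ignore"):
        logw = np.where(params.pi > 0, np.log(np.maximum(params.pi, 1e-300)), -np.inf)
    m = np.max(logs + logw)
    return float(-(m + np.log(np.exp(logs + logw - m).sum())))


def nll_quat(params: QuatGaussianParams, r) -> float:
    """Negative log density of the 4-D normal at rotation components r."""
    from scipy.linalg import solve_triangular

    r = np.asarray(r, dtype=float).reshape(4)
    d = r - params.mu
    y = solve_triangular(params.chol, d, lower=True)
    logdet = 2.0 * np.sum(np.log(np.diag(params.chol)))
    return float(2.0 * np.log(2 * np.pi) + 0.5 * logdet + 0.5 * y @ y)


def quaternion_prior(mu, eta: float) -> float:
    """Soft unit-norm prior ``eta * (1 - ||mu||_2)^2`` on the rotation mean."""
    mu = np.asarray(mu, dtype=float)
    return float(eta * (1.0 - np.linalg.norm(mu)) ** 2)


# -- sampling ------------------------------------------------------------------


def sample(params, n: int, seed: int) -> np.ndarray:
    """Draw n i.i.d. samples from a decoded policy distribution.

    Returns (n, 2) for gaze densities and (n, 4) for the rotation density.
    Mixture draws pick a component by its weight, then sample it.
    """
    if n < 1:
        raise ValueError("need n >= 1 draws")
    rng = np.random.default_rng(seed)
    if isinstance(params, BivariateGaussianParams):
        return rng.multivariate_normal(params.mu, params.covariance(), size=n)
    if isinstance(params, GazeMixtureParams):
        idx = rng.choice(params.n_components, size=n, p=params.pi)
        out = np.empty((n, 2))
        for l, comp in enumerate(params.components):
            m = idx == l
            if m.any():
                out[m] = rng.multivariate_normal(comp.mu, comp.covariance(), size=int(m.sum()))
        return out
    if isinstance(params, QuatGaussianParams):
        eps = rng.normal(size=(n, 4))
        return params.mu + eps @ params.chol.T
    raise TypeError(f"unknown distribution parameters: {type(params)!r}")


def point_prediction(draws, kind: str = "shift") -> np.ndarray:
    """Average sampled trajectories into one prediction.

    ``kind='rotation'`` renormalizes the mean to a unit quaternion and
    canonicalizes its sign before use.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.size == 0:
        raise ValueError("no draws")
    mean = draws.mean(axis=0)
    if kind == "rotation":
        n = np.linalg.norm(mean)
        if n == 0:
            return np.array([1.0, 0.0, 0.0, 0.0])
        return canonicalize(mean / n)
    return mean


# -- autodiff (training) routes ------------------------------------------------


def nll_og_raw(raw: Tensor, target: np.ndarray) -> Tensor:
    """Per-sample OG NLL from the raw (B, 5) head output."""
    t = np.asarray(target, dtype=float)
    mu = raw[:, 0:2].sigmoid() - 0.5
    sigma = raw[:, 2:4].exp().maximum(SIGMA_FLOOR)
    log_sigma = sigma.log()
    rho = raw[:, 4].tanh()
    d = (Tensor(t) - mu) / sigma
    dx, dy = d[:, 0], d[:, 1]
    omr = (1.0 - rho**2).maximum(_RHO_FLOOR)
    z = dx**2 - 2.0 * rho * dx * dy + dy**2
    return log_sigma.sum(axis=1) + 0.5 * omr.log() + z / (2.0 * omr) + float(np.log(2 * np.pi))


def nll_mg_raw(raw: Tensor, target: np.ndarray, L: int) -> Tensor:
    """Per-sample, per-center MG NLL from the raw (B, 6L) head output.

    The mixture models the displacement of each gaze center; the NLL of each
    target center displacement is computed against the full mixture and
    averaged over the L target centers.
    """
    from .nn import stack as tstack

    t = np.asarray(target, dtype=float)  # (B, L, 2)
    log_pi = raw[:, 5 * L :].softmax(axis=-1).maximum(1e-300).log()  # (B, L)
    per_center = []
    for lc in range(t.shape[1]):  # over target centers
        comp_ll = []
        for l in range(L):  # over mixture components
            block = raw[:, 5 * l : 5 * l + 5]
            comp_ll.append(-nll_og_raw(block, t[:, lc, :]))
        ll = tstack(comp_ll, axis=1) + log_pi  # (B, L)
        per_center.append(-ll.logsumexp(axis=1))
    return tstack(per_center, axis=1).mean(axis=1)


def nll_quat_raw(raw: Tensor, target: np.ndarray) -> Tensor:
    """Per-sample 4-D Gaussian NLL from the raw (B, 14) probe head output.

    The quadratic form is computed by an unrolled forward substitution on the
    Cholesky factor (fixed 4-D case), keeping the whole path differentiable.
    """
    t = np.asarray(target, dtype=float)
    mu = raw[:, 0:4] * ROT_SCALE + ROT_CENTER
    diag = [(raw[:, 4 + i].softplus() * ROT_SCALE).maximum(CHOL_DIAG_FLOOR) for i in range(4)]
    off = {(int(r), int(c)): raw[:, 8 + k] * ROT_SCALE for k, (r, c) in enumerate(zip(TRIL_ROWS, TRIL_COLS))}
    d = Tensor(t) - mu
    y0 = d[:, 0] / diag[0]
    y1 = (d[:, 1] - off[(1, 0)] * y0) / diag[1]
    y2 = (d[:, 2] - off[(2, 0)] * y0 - off[(2, 1)] * y1) / diag[2]
    y3 = (d[:, 3] - off[(3, 0)] * y0 - off[(3, 1)] * y1 - off[(3, 2)] * y2) / diag[3]
    quad = y0**2 + y1**2 + y2**2 + y3**2
    logdet_half = diag[0].log() + diag[1].log() + diag[2].log() + diag[3].log()
    return logdet_half + 0.5 * quad + float(2.0 * np.log(2 * np.pi))


def quaternion_prior_raw(raw: Tensor, eta: float) -> Tensor:
    """Per-sample unit-norm prior on the decoded rotation mean of a (B, 14) head."""
    mu = raw[:, 0:4] * ROT_SCALE + ROT_CENTER
    norm = (mu**2).sum(axis=1).sqrt()
    return eta * (1.0 - norm) ** 2
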