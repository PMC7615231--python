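"""Density decoding, NLL oracles, sampling, and the quaternion prior."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from guidenet.heads import (
    BivariateGaussianParams,
    GazeMixtureParams,
    decode_mg,
    decode_og,
    decode_op,
    nll_bivariate,
    nll_mg_raw,
    nll_mixture,
    nll_og_raw,
    nll_quat,
    nll_quat_raw,
    point_prediction,
    quaternion_prior,
    quaternion_prior_raw,
    sample,
)
from guidenet.nn import Tensor


def test_decode_og_squash_fixed_points():
    p = decode_og(np.zeros(5))
    assert p.mu == pytest.approx([0, 0])
    assert p.sigma == pytest.approx([1, 1])
    assert p.rho == 0.0


def test_decode_og_mean_bounded_for_extreme_raw():
    # +-30 saturates the sigmoid to within 1e-13 of the bound but not onto it
    for v in (-30.0, 30.0):
        p = decode_og(np.array([v, v, 0, 0, 0]))
        assert np.all(np.abs(p.mu) < 0.5)
    for v in (-1e3, 1e3):  # float saturation never escapes the closed interval
        p = decode_og(np.array([v, v, 0, 0, 0]))
        assert np.all(np.abs(p.mu) <= 0.5)


def test_decoded_covariances_positive_definite(rng):
    for _ in range(1000):
        p = decode_og(rng.normal(scale=3, size=5))
        assert np.linalg.eigvalsh(p.covariance()).min() > 0
    for _ in range(1000):
        q = decode_op(rng.normal(scale=3, size=14))
        ev = np.linalg.eigvalsh(q.covariance())
        # strictly PD by construction; eigvalsh can report ~-1e-21 on
        # ill-conditioned factors, so allow relative numerical zero
        assert ev.min() > -1e-12 * max(1.0, ev.max())
        assert np.all(np.diag(q.chol) > 0)


def test_decode_mg_weights_and_degenerate_single_component(rng):
    p = decode_mg(np.zeros(18), L=3)
    assert p.pi == pytest.approx([1 / 3] * 3)
    raw = rng.normal(size=6)
    single = decode_mg(raw, L=1)
    og = decode_og(raw[:5])
    assert single.pi == pytest.approx([1.0])
    assert single.components[0].mu == pytest.approx(og.mu)
    for _ in range(1000):
        assert decode_mg(rng.normal(size=18), L=3).pi.sum() == pytest.approx(1.0)
    with pytest.raises(ValueError):
        decode_mg(np.zeros(0), L=0)


def test_decode_op_consumes_exactly_14_numbers():
    from guidenet.heads import ROT_SCALE

    p = decode_op(np.zeros(14))
    # the rotation mean decodes around the identity rotation
    assert p.mu == pytest.approx([1, 0, 0, 0])
    assert np.allclose(p.covariance(), (ROT_SCALE * np.log(2.0)) ** 2 * np.eye(4))
    with pytest.raises(ValueError):
        decode_op(np.zeros(13))


def test_nll_bivariate_closed_form_and_oracle(rng):
    std = BivariateGaussianParams(mu=np.zeros(2), sigma=np.ones(2), rho=0.0)
    assert nll_bivariate(std, [0, 0]) == pytest.approx(np.log(2 * np.pi))
    for _ in range(100):
        p = decode_og(rng.normal(size=5))
        s = rng.normal(scale=0.3, size=2)
        oracle = -multivariate_normal(mean=p.mu, cov=p.covariance()).logpdf(s)
        assert nll_bivariate(p, s) == pytest.approx(oracle, abs=1e-8)


def test_nll_bivariate_minimized_at_mean(rng):
    p = decode_og(rng.normal(size=5))
    at_mu = nll_bivariate(p, p.mu)
    for _ in range(50):
        assert at_mu <= nll_bivariate(p, p.mu + rng.normal(scale=0.1, size=2))


def test_nll_mixture_oracle_and_symmetries(rng):
    for _ in range(100):
        m = decode_mg(rng.normal(size=18), L=3)
        s = rng.normal(scale=0.3, size=2)
        direct = -np.log(
            sum(w * multivariate_normal(mean=c.mu, cov=c.covariance()).pdf(s) for w, c in zip(m.pi, m.components))
        )
        assert nll_mixture(m, s) == pytest.approx(direct, abs=1e-8)
        # permutation invariance
        perm = GazeMixtureParams(components=m.components[::-1], pi=m.pi[::-1])
        assert nll_mixture(perm, s) == pytest.approx(nll_mixture(m, s), abs=1e-10)
        # log-sum-exp sandwich: max-component density bounds below,
        # weighted single component bounds above
        per_comp = [nll_bivariate(c, s) for c in m.components]
        lo = min(per_comp)
        hi = min(nc - np.log(w) for nc, w in zip(per_comp, m.pi))
        assert lo - 1e-9 <= nll_mixture(m, s) <= hi + 1e-9
    single = decode_mg(rng.normal(size=6), L=1)
    s = rng.normal(size=2)
    assert nll_mixture(single, s) == pytest.approx(nll_bivariate(single.components[0], s))


def test_nll_quat_closed_form_and_oracle(rng):
    from guidenet.heads import ROT_CENTER, ROT_SCALE

    r = rng.normal(size=4)
    # raw chosen so the decoded mean is exactly r and the covariance is I
    raw = np.concatenate([(r - ROT_CENTER) / ROT_SCALE, np.full(4, 1.0 / ROT_SCALE), np.zeros(6)])
    p = decode_op(raw)
    assert np.allclose(p.mu, r)
    assert np.allclose(p.covariance(), np.eye(4), atol=1e-8)
    assert nll_quat(p, r) == pytest.approx(2 * np.log(2 * np.pi), abs=1e-4)
    for _ in range(100):
        p = decode_op(rng.normal(size=14))
        x = rng.normal(size=4)
        oracle = -multivariate_normal(mean=p.mu, cov=p.covariance()).logpdf(x)
        assert nll_quat(p, x) == pytest.approx(oracle, rel=1e-9, abs=1e-8)


def test_quaternion_prior_zero_iff_unit(rng):
    u = rng.normal(size=4)
    u /= np.linalg.norm(u)
    assert quaternion_prior(u, eta=50.0) == pytest.approx(0.0, abs=1e-12)
    assert quaternion_prior(np.zeros(4), eta=50.0) == pytest.approx(50.0)
    assert quaternion_prior(2 * u, eta=50.0) > 0


def test_quaternion_prior_gradient_vanishes_only_on_sphere(rng):
    mu = Tensor(rng.normal(size=(1, 4)) * 2.0, requires_grad=True)
    raw = Tensor(np.zeros((1, 14)))
    # build the raw head with our mu in the first 4 slots via concat
    from guidenet.nn import concat

    full = concat([mu, Tensor(np.zeros((1, 10)))], axis=1)
    quaternion_prior_raw(full, eta=50.0).sum().backward()
    assert np.linalg.norm(mu.grad) > 1e-6
    from guidenet.heads import ROT_CENTER, ROT_SCALE

    unit = rng.normal(size=4)
    unit /= np.linalg.norm(unit)
    mu2 = Tensor(((unit - ROT_CENTER) / ROT_SCALE)[None], requires_grad=True)  # decodes to `unit`
    full2 = concat([mu2, Tensor(np.zeros((1, 10)))], axis=1)
    quaternion_prior_raw(full2, eta=50.0).sum().backward()
    assert np.linalg.norm(mu2.grad) < 1e-8


def test_training_nlls_match_numpy_routes(rng):
    raw5 = rng.normal(size=(8, 5))
    tgt = rng.normal(scale=0.2, size=(8, 2))
    got = nll_og_raw(Tensor(raw5), tgt).data
    want = [nll_bivariate(decode_og(r), t) for r, t in zip(raw5, tgt)]
    assert np.allclose(got, want, atol=1e-10)

    raw14 = rng.normal(size=(8, 14))
    tgt4 = rng.normal(size=(8, 4))
    got = nll_quat_raw(Tensor(raw14), tgt4).data
    want = [nll_quat(decode_op(r), t) for r, t in zip(raw14, tgt4)]
    assert np.allclose(got, want, atol=1e-8)

    raw18 = rng.normal(size=(4, 18))
    tgt_mix = rng.normal(scale=0.2, size=(4, 3, 2))
    got = nll_mg_raw(Tensor(raw18), tgt_mix, L=3).data
    want = [
        np.mean([nll_mixture(decode_mg(r, 3), tgt_mix[i, l]) for l in range(3)])
        for i, r in enumerate(raw18)
    ]
    assert np.allclose(got, want, atol=1e-8)


def test_densities_integrate_to_one_on_grid(rng):
    p = BivariateGaussianParams(mu=np.array([0.05, -0.02]), sigma=np.array([0.05, 0.08]), rho=0.4)
    xs = np.linspace(-0.6, 0.7, 401)
    ys = np.linspace(-0.7, 0.6, 401)
    X, Y = np.meshgrid(xs, ys)
    dens = np.exp([-nll_bivariate(p, [x, y]) for x, y in zip(X.ravel(), Y.ravel())])
    integral = dens.sum() * (xs[1] - xs[0]) * (ys[1] - ys[0])
    assert integral == pytest.approx(1.0, rel=0.01)


def test_sampling_statistics_and_determinism(rng):
    p = decode_og(np.array([0.3, -0.2, np.log(0.05), np.log(0.08), 0.5]))
    draws = sample(p, 100_000, seed=5)
    se = p.sigma / np.sqrt(len(draws))
    assert np.all(np.abs(draws.mean(axis=0) - p.mu) < 3 * se)
    assert np.allclose(sample(p, 100, seed=9), sample(p, 100, seed=9))

    m = decode_mg(rng.normal(size=18), L=3)
    mdraws_idx = sample(m, 100_000, seed=11)
    # component frequencies are checked through the empirical mixture mean
    mix_mean = sum(w * c.mu for w, c in zip(m.pi, m.components))
    spread = np.sqrt(sum(w * (np.diag(c.covariance()) + c.mu**2) for w, c in zip(m.pi, m.components)))
    assert np.all(np.abs(mdraws_idx.mean(axis=0) - mix_mean) < 3 * spread / np.sqrt(100_000) + 1e-3)

    q = decode_op(rng.normal(size=14))
    qd = sample(q, 100_000, seed=13)
    assert np.all(np.abs(qd.mean(axis=0) - q.mu) < 3 * np.sqrt(np.diag(q.covariance()) / 100_000))


def test_point_prediction_shift_and_rotation():
    draws = np.tile([0.1, -0.1], (7, 1))
    assert point_prediction(draws) == pytest.approx([0.1, -0.1])
    sym = np.array([[0.2, 0.3], [-0.2, -0.3]])
    assert point_prediction(sym) == pytest.approx([0, 0])
    rot_draws = np.tile([-0.9, 0.1, 0.0, 0.0], (5, 1))
    out = point_prediction(rot_draws, kind="rotation")
    assert np.linalg.norm(out) == pytest.approx(1.0)
    assert out[0] > 0  # canonical sign


def test_og_head_ml_recovery_by_gradient_descent(rng):
    """Fitting the 5 raw parameters by gradient descent on the NLL of draws
    from a known bivariate Gaussian recovers mu within 0.01 and sigma
    within 5%."""
    true = BivariateGaussianParams(mu=np.array([0.08, -0.05]), sigma=np.array([0.06, 0.09]), rho=0.3)
    draws = rng.multivariate_normal(true.mu, true.covariance(), size=10_000)
    from guidenet.nn import AdamW, Parameter

    raw = Parameter(np.zeros((1, 5)))
    opt = AdamW([raw], lr=0.02, weight_decay=0.0)
    for _ in range(600):
        opt.zero_grad()
        t = Tensor(raw.data.repeat(len(draws), axis=0), requires_grad=True)
        nll_og_raw(t, draws).mean().backward()
        raw.grad = t.grad.sum(axis=0, keepdims=True)  # gradient wrt the shared raw vector
        opt.step()
    fit = decode_og(raw.data[0])
    assert np.all(np.abs(fit.mu - true.mu) < 0.01)
    assert np.all(np.abs(fit.sigma / true.sigma - 1) < 0.05)
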