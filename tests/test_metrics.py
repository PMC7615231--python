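"""Direction accuracy, gaze errors, and the five saliency metrics on
hand-computable toys."""

import numpy as np
import pytest

from guidenet.gaze import GazeSample
from guidenet.heads import BivariateGaussianParams, GazeMixtureParams
from guidenet.metrics import (
    SaliencyMap,
    auc_judd,
    best_of_n_error,
    cc,
    direction_accuracy,
    empirical_saliency,
    gaze_l2_error,
    kld,
    nss,
    render_saliency,
    sim,
    stage_split,
)
from guidenet.quat import UnitQuaternion, canonicalize, from_axis_angle, multiply, slerp
from guidenet.simulate import ScanSimConfig, simulate_probe


def _approach_trajectory(n=30, start=30.0):
    """Deterministic monotone geodesic approach from `start` degrees."""
    q_target = UnitQuaternion.identity()
    q0 = from_axis_angle([0, 1, 0], start)
    quats = [q0]
    for _ in range(n - 1):
        quats.append(slerp(quats[-1], q_target, 0.15))
    return np.array([q.to_array() for q in quats]), q_target


class TestStageSplit:
    def test_constant_fine_trajectory(self):
        q_target = UnitQuaternion.identity()
        q5 = from_axis_angle([1, 0, 0], 5.0)
        mask = stage_split(np.tile(q5.to_array(), (4, 1)), q_target)
        assert np.all(mask.labels == "fine")

    def test_boundary_is_fine(self):
        mask = stage_split(from_axis_angle([0, 0, 1], 10.0).to_array()[None], UnitQuaternion.identity())
        assert mask.labels[0] == "fine"
        mask2 = stage_split(from_axis_angle([0, 0, 1], 10.0001).to_array()[None], UnitQuaternion.identity())
        assert mask2.labels[0] == "coarse"

    def test_monotone_approach_crosses_once(self):
        quats, q_target = _approach_trajectory()
        mask = stage_split(quats, q_target)
        fine = mask.is_fine().astype(int)
        assert np.all(np.diff(fine) >= 0)  # coarse -> fine, never back
        assert fine[0] == 0 and fine[-1] == 1


class TestDirectionAccuracy:
    def test_truth_predictions_are_perfect(self):
        quats, q_target = _approach_trajectory()
        from guidenet.quat import _conj_arr, _mul_arr

        true_rots = canonicalize(_mul_arr(_conj_arr(quats[:-1]), quats[1:]))
        acc = direction_accuracy(true_rots, quats, q_target, policy="OP")
        assert acc.overall == 1.0 and acc.coarse == 1.0 and acc.fine == 1.0

    def test_identity_predictions_pass_non_strict(self):
        quats, q_target = _approach_trajectory()
        idents = np.tile([1.0, 0, 0, 0], (len(quats) - 1, 1))
        acc = direction_accuracy(idents, quats, q_target, policy="OP")
        assert acc.overall == 1.0

    def test_inverse_rotations_always_fail_under_sp(self):
        quats, q_target = _approach_trajectory()
        from guidenet.quat import _conj_arr, _mul_arr

        true_rots = _mul_arr(_conj_arr(quats[:-1]), quats[1:])
        inverse = _conj_arr(true_rots)
        acc = direction_accuracy(inverse, quats, q_target, policy="SP")
        assert acc.overall == 0.0

    def test_angle_bins_partition_frames(self):
        quats, q_target = _approach_trajectory()
        idents = np.tile([1.0, 0, 0, 0], (len(quats) - 1, 1))
        acc = direction_accuracy(idents, quats, q_target, policy="OP")
        assert set(acc.bins) == {(0.0, 10.0), (10.0, 20.0), (20.0, 30.0)}
        for v in acc.bins.values():
            assert v == 1.0 or np.isnan(v)


def test_gaze_l2_error_examples():
    a, b = GazeSample(0, 0), GazeSample(0.5 - 1e-12, 0)
    assert gaze_l2_error(a, b, (288, 224)) == pytest.approx(144.0, abs=1e-6)
    assert gaze_l2_error(a, a) == 0.0
    assert gaze_l2_error(a, b) == gaze_l2_error(b, a)


def test_best_of_n_error_properties(rng):
    truth = GazeSample(0.1, -0.1)
    single = np.array([[0.2, 0.0]])
    assert best_of_n_error(single, truth) == pytest.approx(
        gaze_l2_error(GazeSample(0.2, 0.0), truth)
    )
    samples = rng.normal(scale=0.1, size=(50, 2))
    errs = [best_of_n_error(samples[:k], truth) for k in (1, 5, 20, 50)]
    assert all(a >= b for a, b in zip(errs, errs[1:]))  # monotone non-increasing
    mean_err = np.mean(
        [gaze_l2_error(GazeSample(*s), truth) for s in samples]
    )
    assert best_of_n_error(samples, truth) <= mean_err


class TestSaliencyRendering:
    def test_tight_gaussian_peaks_at_anchor_plus_mean(self):
        d = BivariateGaussianParams(mu=np.zeros(2), sigma=np.array([0.01, 0.01]), rho=0.0)
        m = render_saliency(d, GazeSample(0.0, 0.0))
        assert m.values.sum() == pytest.approx(1.0, abs=1e-9)
        py, px = np.unravel_index(m.values.argmax(), m.values.shape)
        assert abs(px - 288 / 2) <= 1 and abs(py - 224 / 2) <= 1

    def test_two_separated_components_give_two_maxima(self):
        from guidenet.gaze import CenterWindow
        from scipy.ndimage import maximum_filter

        comps = (
            BivariateGaussianParams(np.zeros(2), np.array([0.02, 0.02]), 0.0),
            BivariateGaussianParams(np.zeros(2), np.array([0.02, 0.02]), 0.0),
        )
        mix = GazeMixtureParams(components=comps, pi=np.array([0.5, 0.5]))
        anchor = CenterWindow(np.array([[-0.25, 0.0], [0.25, 0.0]]), np.array([0.5, 0.5]), 0, 4)
        m = render_saliency(mix, anchor)
        local_max = (m.values == maximum_filter(m.values, size=9)) & (m.values > m.values.max() / 10)
        from scipy.ndimage import label

        n_peaks = label(local_max)[1]  # peaks can tie across adjacent pixels
        assert n_peaks == 2

    def test_off_screen_mass_flagged(self):
        d = BivariateGaussianParams(mu=np.array([0.45, 0.0]), sigma=np.array([0.2, 0.2]), rho=0.0)
        with pytest.warns(UserWarning, match="off-screen"):
            m = render_saliency(d, GazeSample(0.49, 0.0))
        assert m.off_screen_flag
        assert m.values.sum() == pytest.approx(1.0)


def test_empirical_saliency_basic_properties():
    pts = [GazeSample(0.1, 0.0), GazeSample(-0.2, 0.1)]
    m = empirical_saliency(pts)
    assert m.values.sum() == pytest.approx(1.0)
    m2 = empirical_saliency(pts[::-1])
    assert np.allclose(m.values, m2.values)
    single = empirical_saliency([GazeSample(0.1, 0.0)])
    py, px = np.unravel_index(single.values.argmax(), single.values.shape)
    assert abs(px - (0.6 * 288)) <= 1 and abs(py - (0.5 * 224)) <= 1


def _toy(vals):
    return SaliencyMap(values=np.asarray(vals, dtype=float), normalization="sum1")


class TestSaliencyMetrics:
    def test_sim_hand_toys(self):
        p = _toy([[0.5, 0.5], [0.0, 0.0]])
        q = _toy([[0.25, 0.25], [0.25, 0.25]])
        assert sim(p, q) == pytest.approx(0.5)
        assert sim(p, p) == pytest.approx(1.0)
        disjoint = _toy([[0.0, 0.0], [0.5, 0.5]])
        assert sim(p, disjoint) == 0.0

    def test_cc_hand_toys_and_oracle(self, rng):
        p = _toy([[0.4, 0.1], [0.3, 0.2]])
        assert cc(p, p) == pytest.approx(1.0)
        anti = _toy(0.25 - (p.values - 0.25))
        assert cc(p, anti) == pytest.approx(-1.0)
        a, b = rng.uniform(size=(5, 5)), rng.uniform(size=(5, 5))
        ma, mb = _toy(a / a.sum()), _toy(b / b.sum())
        av, bv = ma.values.ravel(), mb.values.ravel()
        want = np.mean((av - av.mean()) * (bv - bv.mean())) / (av.std() * bv.std())
        assert cc(ma, mb) == pytest.approx(want, abs=1e-10)
        const = _toy(np.full((2, 2), 0.25))
        with pytest.warns(UserWarning):
            assert cc(const, p) == 0.0

    def test_kld_hand_toys(self):
        p = _toy([1.0, 0.0])
        q = _toy([0.5, 0.5])
        assert kld(p, q) == pytest.approx(np.log(2), abs=1e-5)
        assert kld(q, q) == pytest.approx(0.0, abs=1e-5)
        for _ in range(20):
            a = np.random.default_rng(_).uniform(size=6)
            b = np.random.default_rng(_ + 100).uniform(size=6)
            assert kld(_toy(a / a.sum()), _toy(b / b.sum())) >= -1e-6  # Gibbs

    def test_auc_judd_extremes(self):
        h, w = 224, 288
        peak = np.zeros((h, w))
        peak[112, 144] = 1.0
        m = SaliencyMap(values=peak, normalization="sum1")
        fix = [GazeSample(0.0, 0.0)]
        assert auc_judd(m, fix) == pytest.approx(1.0, abs=1e-4)
        const = SaliencyMap(values=np.full((h, w), 1.0 / (h * w)), normalization="sum1")
        assert auc_judd(const, fix) == 0.5
        graded = SaliencyMap(values=np.linspace(0, 1, h * w).reshape(h, w), normalization="density")
        # many fixations confined to the lowest-saliency rows: thresholds sit
        # where nearly every pixel passes, collapsing the ROC toward zero area
        worst_fix = [GazeSample(x / w - 0.5 + 1e-3, -0.49) for x in range(10, 280, 15)]
        assert auc_judd(graded, worst_fix) < 0.15

    def test_nss_properties(self, rng):
        h, w = 224, 288
        const = SaliencyMap(values=np.ones((h, w)), normalization="density")
        assert nss(const, [GazeSample(0.0, 0.0)]) == 0.0
        vals = rng.uniform(size=(h, w))
        m = SaliencyMap(values=vals, normalization="density")
        py, px = np.unravel_index(vals.argmax(), vals.shape)
        bright = GazeSample((px + 0.5) / w - 0.5, (py + 0.5) / h - 0.5)
        assert nss(m, [bright]) > 0
        # direct-formula oracle
        fix = [GazeSample(0.1, -0.2), GazeSample(-0.3, 0.25)]
        z = (vals - vals.mean()) / vals.std()
        want = np.mean(
            [z[int((f.y + 0.5) * h), int((f.x + 0.5) * w)] for f in fix]
        )
        assert nss(m, fix) == pytest.approx(want, abs=1e-10)

    def test_matched_distribution_beats_translated_one(self, rng):
        """Sanity ordering: scoring fixations against their own generating
        density beats a translated copy on SIM/CC/AUC/NSS."""
        gen = BivariateGaussianParams(mu=np.zeros(2), sigma=np.array([0.04, 0.04]), rho=0.0)
        pts = [GazeSample(*p) for p in rng.multivariate_normal([0, 0], gen.covariance(), size=40)]
        matched = render_saliency(gen, GazeSample(0.0, 0.0))
        translated = render_saliency(gen, GazeSample(0.25, 0.15))
        emp = empirical_saliency(pts)
        assert sim(matched, emp) > sim(translated, emp)
        assert cc(matched, emp) > cc(translated, emp)
        assert auc_judd(matched, pts) > auc_judd(translated, pts)
        assert nss(matched, pts) > nss(translated, pts)
        assert kld(emp, matched) < kld(emp, translated)
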