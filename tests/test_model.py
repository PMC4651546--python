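"""Link functions, detection likelihood, and the joint density."""

import numpy as np
import pytest
from scipy import stats

from cooccupancy.model import (
    BobcatParams,
    DetectionHistory,
    DetectionParams,
    HareParams,
    Indicators,
    LatentState,
    PriorConfig,
    bobcat_occupancy_prob,
    detection_loglik,
    hare_occupancy_prob,
    inv_logit,
    log_joint,
)


def _w(on=True):
    return Indicators(np.ones(19, dtype=int) if on else np.zeros(19, dtype=int))


class TestOccupancyLinks:
    def test_intercept_only_hare_probability(self):
        # the selected-model prey intercept implies ~26% baseline occupancy
        p = hare_occupancy_prob(np.zeros(9), HareParams(intercept=-1.03), _w())
        assert p == pytest.approx(1 / (1 + np.exp(1.03)), abs=1e-12)
        assert p == pytest.approx(0.263, abs=5e-4)

    def test_single_grassland_slope(self):
        slopes = np.zeros(9)
        slopes[5] = 0.41  # grassland
        x = np.zeros(9)
        x[5] = 1.0
        p = hare_occupancy_prob(x, HareParams(intercept=0.0, slopes=slopes), _w())
        assert p == pytest.approx(inv_logit(0.41))
        assert p == pytest.approx(0.601, abs=5e-4)

    def test_indicators_off_leaves_intercept_only(self):
        slopes = np.arange(1.0, 10.0)
        x = np.ones(9)
        p = hare_occupancy_prob(x, HareParams(intercept=0.3, slopes=slopes), _w(False), eps=0.2)
        assert p == pytest.approx(inv_logit(0.5))

    def test_bobcat_branch_selection(self):
        params = BobcatParams(intercept_present=-3.2, intercept_absent=-2.82)
        p1 = bobcat_occupancy_prob(1, np.zeros(5), params, _w())
        p0 = bobcat_occupancy_prob(0, np.zeros(5), params, _w())
        assert p1 == pytest.approx(inv_logit(-3.2))
        assert p1 == pytest.approx(0.039, abs=5e-4)
        assert p0 == pytest.approx(inv_logit(-2.82))

    def test_bobcat_absent_branch_hand_link(self):
        # b0=-2.82, cell-road slope -1.04 at x=1, neighborhood-road slope 0.83 at x=1
        absent = np.array([-1.04, 0.0, 0.83, 0.0, 0.0])
        params = BobcatParams(intercept_absent=-2.82, slopes_absent=absent)
        u = np.array([1.0, 0.0, 1.0, 0.0, 0.0])
        p = bobcat_occupancy_prob(0, u, params, _w())
        assert p == pytest.approx(inv_logit(-3.03))
        assert p == pytest.approx(0.046, abs=5e-4)

    def test_branches_do_not_share_slopes(self):
        u = np.ones(5)
        a = BobcatParams(slopes_present=np.ones(5), slopes_absent=np.zeros(5))
        b = BobcatParams(slopes_present=np.ones(5), slopes_absent=np.full(5, 9.0))
        assert bobcat_occupancy_prob(1, u, a, _w()) == bobcat_occupancy_prob(1, u, b, _w())

    def test_positive_included_slope_is_monotone(self):
        slopes = np.zeros(9)
        slopes[2] = 1.3
        params = HareParams(slopes=slopes)
        xs = [np.eye(9)[2] * v for v in (-1.0, 0.0, 2.0)]
        ps = [hare_occupancy_prob(x, params, _w()) for x in xs]
        assert ps[0] < ps[1] < ps[2]

    def test_missing_covariate_rejected(self):
        x = np.zeros(9)
        x[3] = np.nan
        with pytest.raises(ValueError):
            hare_occupancy_prob(x, HareParams(), _w())


class TestDetectionLoglik:
    def test_absent_with_no_detections_is_certain(self):
        assert detection_loglik(0, 7, 0.5, 0) == pytest.approx(0.0)

    def test_binomial_closed_form(self):
        from math import comb, log

        expected = log(comb(7, 3)) + 7 * log(0.5)
        assert detection_loglik(3, 7, 0.5, 1) == pytest.approx(expected)

    def test_detection_without_occupancy_impossible(self):
        assert detection_loglik(2, 7, 0.5, 0) == -np.inf

    def test_y_above_k_rejected(self):
        with pytest.raises(ValueError):
            detection_loglik(8, 7, 0.5, 1)


class TestLogJoint:
    def _tiny_instance(self):
        """2 cells x 1 week with every factor hand-assembled in the test."""
        prey_x = np.array([[0.5] + [0.0] * 8, [-0.5] + [0.0] * 8])
        pred_u = np.array([[1.0, 0, 0, 0, 0], [-1.0, 0, 0, 0, 0]])
        hare = HareParams(intercept=-0.5, slopes=np.r_[0.8, np.zeros(8)], sigma2=0.3)
        bob = BobcatParams(
            intercept_present=-1.0,
            intercept_absent=-2.0,
            slopes_present=np.r_[0.5, np.zeros(4)],
            slopes_absent=np.r_[-0.5, np.zeros(4)],
            sigma2=0.4,
        )
        det = DetectionParams(p_bobcat=np.array([0.3, 0.6]), p_hare=np.array([[0.4], [0.7]]))
        hist = DetectionHistory(
            y_bobcat=np.array([[2], [0]]), y_hare=np.array([[0], [3]]), k=np.array([[7], [5]])
        )
        latent = LatentState(
            z_hare=np.array([[0], [1]]),
            z_bobcat=np.array([[1], [0]]),
            eps_hare=np.array([[0.1], [-0.2]]),
            eps_bobcat=np.array([[0.05], [0.15]]),
        )
        return prey_x, pred_u, hare, bob, det, hist, latent

    def test_matches_term_by_term_hand_assembly(self):
        prey_x, pred_u, hare, bob, det, hist, latent = self._tiny_instance()
        priors = PriorConfig()

        # independent re-derivation, factor by factor
        expected = 0.0
        for i in range(2):
            zh, zb = latent.z_hare[i, 0], latent.z_bobcat[i, 0]
            eh, eb = latent.eps_hare[i, 0], latent.eps_bobcat[i, 0]
            mu_h = 1 / (1 + np.exp(-(hare.intercept + prey_x[i] @ hare.slopes + eh)))
            expected += np.log(mu_h if zh else 1 - mu_h)
            eta1 = bob.intercept_present + pred_u[i] @ bob.slopes_present + eb
            eta0 = bob.intercept_absent + pred_u[i] @ bob.slopes_absent + eb
            mu_b = 1 / (1 + np.exp(-(eta1 if zh else eta0)))
            expected += np.log(mu_b if zb else 1 - mu_b)
            expected += stats.binom.logpmf(hist.y_hare[i, 0], hist.k[i, 0], det.p_hare[i, 0] * zh)
            expected += stats.binom.logpmf(
                hist.y_bobcat[i, 0], hist.k[i, 0], det.p_bobcat[i] * zb
            )
            expected += stats.norm.logpdf(eh, 0, np.sqrt(hare.sigma2))
            expected += stats.norm.logpdf(eb, 0, np.sqrt(bob.sigma2))
        expected += stats.norm.logpdf(hare.intercept, 0, priors.intercept_sd)
        expected += stats.norm.logpdf(bob.intercept_present, 0, priors.intercept_sd)
        expected += stats.norm.logpdf(bob.intercept_absent, 0, priors.intercept_sd)
        expected += stats.norm.logpdf(hare.slopes, 0, priors.hare_slope_sd).sum()
        expected += stats.norm.logpdf(bob.slopes_present, 0, priors.bobcat_slope_sd).sum()
        expected += stats.norm.logpdf(bob.slopes_absent, 0, priors.bobcat_slope_sd).sum()
        expected += 19 * np.log(0.5)  # all indicators on, Bern(1/2) each
        expected += stats.beta.logpdf(det.p_hare, 1, 1).sum()
        expected += stats.beta.logpdf(det.p_bobcat, 1, 1).sum()
        expected += stats.invgamma.logpdf(hare.sigma2, priors.sigma2_shape, scale=priors.sigma2_rate)
        expected += stats.invgamma.logpdf(bob.sigma2, priors.sigma2_shape, scale=priors.sigma2_rate)

        got = log_joint(
            hist, latent, hare, bob, det, _w(), priors,
            prey_design=prey_x, predator_design=pred_u,
        )
        assert got == pytest.approx(float(expected), rel=1e-10)

    def test_state_contradicting_data_is_impossible(self):
        prey_x, pred_u, hare, bob, det, hist, latent = self._tiny_instance()
        latent.z_hare[1, 0] = 0  # but Y_hare[1,0] = 3
        got = log_joint(
            hist, latent, hare, bob, det, _w(), PriorConfig(),
            prey_design=prey_x, predator_design=pred_u,
        )
        assert got == -np.inf

    def test_dimension_mismatch_rejected(self):
        prey_x, pred_u, hare, bob, det, hist, latent = self._tiny_instance()
        bad = LatentState(
            z_hare=np.zeros((3, 1), dtype=int),
            z_bobcat=np.zeros((3, 1), dtype=int),
            eps_hare=np.zeros((3, 1)),
            eps_bobcat=np.zeros((3, 1)),
        )
        with pytest.raises(ValueError):
            log_joint(
                hist, bad, hare, bob, det, _w(), PriorConfig(),
                prey_design=prey_x, predator_design=pred_u,
            )


class TestHistoryValidation:
    def test_y_cannot_exceed_k(self):
        with pytest.raises(ValueError):
            DetectionHistory(
                y_bobcat=np.array([[8]]), y_hare=np.array([[0]]), k=np.array([[7]])
            )

    def test_probability_outputs_bounded(self, rng):
        x = rng.normal(size=(50, 9))
        p = hare_occupancy_prob(x, HareParams(intercept=3.0, slopes=rng.normal(size=9) * 5), _w())
        assert np.all((p > 0) & (p < 1))
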