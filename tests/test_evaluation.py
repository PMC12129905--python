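"""Detector acceptance protocol: frames, agreement regression, matching."""

import numpy as np
import pytest

import rgcquant as rq
from rgcquant.evaluation import (
    FRAME_SIDE_UM,
    AgreementStats,
    accept_detector,
    agreement_regression,
    emulate_counter,
    frame_counts,
    match_detections,
    sample_frames,
)
from rgcquant.imgio import CentroidSet


def cs(points, label="detected"):
    pts = np.asarray(points, float).reshape(-1, 2)
    return CentroidSet(x=pts[:, 0], y=pts[:, 1], label=label)


class TestAgreementRegression:
    def test_identity(self):
        s = agreement_regression([3, 7, 11, 2], [3, 7, 11, 2])
        assert s.slope == pytest.approx(1.0)
        assert s.intercept == pytest.approx(0.0, abs=1e-9)
        assert s.r_squared == pytest.approx(1.0)

    def test_closed_form_line(self):
        s = agreement_regression([0, 1, 2], [1, 3, 5])
        assert s.slope == pytest.approx(2.0)
        assert s.intercept == pytest.approx(1.0)
        assert s.r_squared == pytest.approx(1.0)

    def test_negative_slope(self):
        s = agreement_regression([0, 1, 2], [2, 1, 0])
        assert s.slope == pytest.approx(-1.0)
        assert s.r_squared == pytest.approx(1.0)

    def test_zero_variance_x_is_degenerate(self):
        with pytest.raises(ValueError):
            agreement_regression([5, 5, 5], [1, 2, 3])

    def test_frame_order_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.integers(10, 60, 20)
        y = x + rng.integers(-3, 4, 20)
        perm = rng.permutation(20)
        s1 = agreement_regression(x, y)
        s2 = agreement_regression(x[perm], y[perm])
        assert s1.slope == pytest.approx(s2.slope)
        assert s1.r_squared == pytest.approx(s2.r_squared)


class TestMatchDetections:
    def test_perfect_prediction(self):
        pts = np.random.default_rng(1).uniform(0, 100, (20, 2))
        m = match_detections(cs(pts), cs(pts, "truth"), radius=2.0)
        assert m.precision == 1.0 and m.recall == 1.0 and m.fp == 0 and m.fn == 0

    def test_empty_prediction(self):
        m = match_detections(cs(np.empty((0, 2))), cs([(1.0, 1.0)], "truth"), 2.0)
        assert m.recall == 0.0 and m.fp == 0 and m.fn == 1 and m.degenerate

    def test_radius_is_a_hard_boundary(self):
        r = 3.0
        m = match_detections(cs([(0.0, r + 1e-6)]), cs([(0.0, 0.0)], "truth"), r)
        assert (m.tp, m.fp, m.fn) == (0, 1, 1)
        m2 = match_detections(cs([(0.0, r - 1e-6)]), cs([(0.0, 0.0)], "truth"), r)
        assert (m2.tp, m2.fp, m2.fn) == (1, 0, 0)

    def test_symmetry_swaps_precision_and_recall(self):
        rng = np.random.default_rng(2)
        a, b = rng.uniform(0, 50, (12, 2)), rng.uniform(0, 50, (9, 2))
        m1 = match_detections(cs(a), cs(b, "truth"), 5.0)
        m2 = match_detections(cs(b), cs(a, "truth"), 5.0)
        assert m1.tp == m2.tp
        assert m1.precision == pytest.approx(m2.recall)
        assert m1.recall == pytest.approx(m2.precision)

    def test_one_to_one_matching(self):
        # two predictions near one truth: only one may match
        m = match_detections(
            cs([(0.0, 0.0), (1.0, 0.0)]), cs([(0.5, 0.0)], "truth"), 2.0
        )
        assert (m.tp, m.fp, m.fn) == (1, 1, 0)

    def test_greedy_agrees_with_hungarian_on_separated_points(self):
        # hard-core-separated truth (as the generator produces): every
        # prediction is ambiguity-free, so greedy must equal the optimum
        rng = np.random.default_rng(3)
        for _ in range(10):
            gx, gy = np.meshgrid(np.arange(6) * 10.0, np.arange(6) * 10.0)
            t = np.column_stack([gx.ravel(), gy.ravel()])
            t += rng.uniform(-0.5, 0.5, t.shape)
            p = np.vstack([t + rng.normal(0, 0.4, t.shape), t[:4] + 5.0])
            mh = match_detections(cs(p), cs(t, "truth"), 2.0, method="hungarian")
            mg = match_detections(cs(p), cs(t, "truth"), 2.0, method="greedy")
            assert (mh.tp, mh.fp, mh.fn) == (mg.tp, mg.fp, mg.fn)

    def test_nonpositive_radius_is_domain_error(self):
        with pytest.raises(ValueError):
            match_detections(cs([(0, 0)]), cs([(0, 0)], "truth"), 0.0)


class TestSampleFrames:
    def test_counts_and_strata(self, mouse_retina):
        frames = sample_frames(mouse_retina.truth_mask, mouse_retina.onh_center, 48, 7)
        assert len(frames) == 48
        for stratum in ("central", "mid", "peripheral"):
            assert sum(f.stratum == stratum for f in frames) == 16

    def test_testing_set_size(self, mouse_retina):
        frames = sample_frames(mouse_retina.truth_mask, mouse_retina.onh_center, 24, 7)
        assert len(frames) == 24

    def test_deterministic(self, mouse_retina):
        f1 = sample_frames(mouse_retina.truth_mask, mouse_retina.onh_center, 24, 7)
        f2 = sample_frames(mouse_retina.truth_mask, mouse_retina.onh_center, 24, 7)
        assert [f.origin for f in f1] == [f.origin for f in f2]

    def test_frames_disjoint_when_geometry_allows(self):
        # a large plain disc hosts 2 frames per stratum without overlap
        from rgcquant.segmentation import RetinaMask

        px = 2.0
        n = 2001
        yy, xx = np.mgrid[0:n, 0:n]
        c = (n - 1) / 2
        disc = (xx - c) ** 2 + (yy - c) ** 2 <= (2000.0 / px) ** 2
        mask = RetinaMask(disc, px)
        frames = sample_frames(mask, (c * px, c * px), 6, seed=3)
        for i, a in enumerate(frames):
            for b in frames[i + 1 :]:
                assert (
                    abs(a.origin[0] - b.origin[0]) >= FRAME_SIDE_UM
                    or abs(a.origin[1] - b.origin[1]) >= FRAME_SIDE_UM
                )

    def test_frame_origins_distinct(self, mouse_retina):
        frames = sample_frames(mouse_retina.truth_mask, mouse_retina.onh_center, 24, 3)
        assert len({f.origin for f in frames}) == 24

    def test_frames_inside_mask(self, mouse_retina):
        frames = sample_frames(mouse_retina.truth_mask, mouse_retina.onh_center, 24, 5)
        for f in frames:
            xs = np.array([f.origin[0], f.origin[0] + f.side])
            ys = np.array([f.origin[1], f.origin[1] + f.side])
            gx, gy = np.meshgrid(xs, ys)
            assert mouse_retina.truth_mask.contains(gx.ravel(), gy.ravel()).all()

    def test_indivisible_total_rejected(self, mouse_retina):
        with pytest.raises(ValueError):
            sample_frames(mouse_retina.truth_mask, mouse_retina.onh_center, 25, 0)


class TestAcceptDetector:
    def test_perfect_model_accepted(self):
        truth = np.array([20, 35, 50, 28, 42, 31])
        ok, model, _ = accept_detector(truth, truth, truth, truth + 1)
        assert ok
        assert model.slope == pytest.approx(1.0)

    def test_doubled_counts_rejected_on_slope(self):
        truth = np.array([20, 35, 50, 28, 42, 31])
        ok, model, _ = accept_detector(2 * truth, truth, truth, truth)
        assert not ok
        assert model.slope == pytest.approx(2.0)

    def test_small_noise_accepted_in_most_seeded_runs(self):
        """Counts with 5% iid noise over 36 frames pass the protocol.

        Frame counts span the range seen across strata, retinas and injury
        states (the published testing sets pool all of these), so the
        between-frame variance dwarfs the 5% count noise.
        """
        rng = np.random.default_rng(4)
        accepted = 0
        n_runs = 200
        for _ in range(n_runs):
            truth = rng.uniform(100, 600, 36)
            model = truth + rng.normal(0, 0.05 * truth.mean(), 36)
            ca = truth + rng.normal(0, 0.02 * truth.mean(), 36)
            cb = truth + rng.normal(0, 0.02 * truth.mean(), 36)
            ok, _, _ = accept_detector(model, truth, ca, cb)
            accepted += ok
        assert accepted / n_runs >= 0.95


def test_emulated_counters_corrupt_truth(fish_retina):
    ca = emulate_counter(fish_retina.truth_centroids, fish_retina.truth_mask, 1)
    n = len(fish_retina.truth_centroids)
    # 2% misses and ~1% spurious marks
    assert 0.95 * n < len(ca) < 1.01 * n
    assert ca.label == "counter_A"


def test_detector_passes_protocol_on_generator_output(fish_preset):
    """End-to-end: pooled-condition frames + agreement regression accept the
    built-in detector."""
    from rgcquant.evaluation import run_acceptance_protocol

    report = run_acceptance_protocol(fish_preset, seed=7)
    assert report["accepted"], (report["model"], report["inter_counter"])
    assert report["injured_dpi"] == 14.0  # the course's maximal-loss time-point
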