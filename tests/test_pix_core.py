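import numpy as np
import pytest

import pixflow as pf
from pixflow.pix_core import (
    GateParams,
    _rms_rows,
    combine_directions,
    displacement_to_speed,
    gate_and_match,
    normalize_similarity,
    shifted_traces,
    similarity_map,
    velocity_map,
)
from pixflow.preprocess import Epoch, motion_contrast


def epoch_from_traces(traces, fps=300.0, pixel_um=1.0):
    """Build a 1-row epoch whose pixel traces are the given rows."""
    traces = np.asarray(traces, dtype=float)
    frames = traces.T[:, None, :]  # (T, 1, P)
    return Epoch(frames=frames, start_ms=0.0, fps=fps, pixel_um=pixel_um)


class TestGateParams:
    def test_z_threshold_tracks_hypotheses(self):
        from scipy.stats import norm

        g = GateParams(n_hypotheses=100)
        assert g.z_threshold == pytest.approx(norm.ppf(1 - 0.025 / 100))
        g2 = g.with_hypotheses(10_000)
        assert g2.z_threshold > g.z_threshold

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            GateParams(p_one_tail=0.0)
        with pytest.raises(ValueError):
            GateParams(n_hypotheses=0)


class TestShiftedTraces:
    def test_30_frame_epoch_compares_29_samples(self):
        ep = Epoch(np.random.default_rng(0).random((30, 2, 2)), 0.0, 300.0, 1.0)
        traces, fwd, bwd = shifted_traces(ep)
        assert fwd.shape[1] == 29 and bwd.shape[1] == 29

    def test_constant_trace_shift_invariant(self):
        ep = Epoch(np.full((5, 1, 1), 2.0), 0.0, 300.0, 1.0)
        traces, fwd, bwd = shifted_traces(ep)
        assert np.array_equal(fwd, bwd)

    def test_forward_then_backward_identity(self):
        ep = Epoch(np.random.default_rng(1).random((6, 1, 1)), 0.0, 300.0, 1.0)
        traces, fwd, bwd = shifted_traces(ep)
        # common support: forward drops the first sample, backward the last
        assert np.array_equal(fwd[:, :-1], traces[:, 1:-1])
        assert np.array_equal(bwd[:, 1:], traces[:, 1:-1])

    def test_short_epoch_errors(self):
        with pytest.raises(ValueError):
            shifted_traces(Epoch(np.ones((2, 1, 1)), 0.0, 300.0, 1.0))


class TestSimilarityMap:
    def test_exact_match_gives_zero_rms(self):
        # candidate 1's forward-shifted trace equals candidate 0's original
        t0 = np.array([0.0, 1.0, 2.0, 3.0, 1.0])
        t1 = np.array([9.0, 0.0, 1.0, 2.0, 3.0])  # t1 shifted fwd == t0[:-1]
        ep = epoch_from_traces([t0, t1])
        sim = similarity_map(ep, (0, 0), "forward")
        assert sim.rms[0, 1] == pytest.approx(0.0, abs=1e-12)
        assert sim.best_match == (0, 1)

    def test_hand_computed_rms_of_one(self):
        # reference [0,1,0] vs candidate shifted trace [1,0,1]
        t0 = np.array([0.0, 1.0, 0.0, 5.0])
        t1 = np.array([7.0, 1.0, 0.0, 1.0])  # forward-shifted: [1, 0, 1]
        ep = epoch_from_traces([t0, t1])
        sim = similarity_map(ep, (0, 0), "forward")
        assert sim.rms[0, 1] == pytest.approx(1.0)

    def test_candidate_support_restricts_comparison(self):
        rng = np.random.default_rng(2)
        ep = Epoch(rng.random((6, 4, 4)), 0.0, 300.0, 1.0)
        support = np.zeros((4, 4), dtype=bool)
        support[1, 1] = support[2, 3] = True
        sim = similarity_map(ep, (0, 0), "forward", support)
        assert np.isfinite(sim.rms).sum() == 2

    def test_mse_of_independent_noise_sums_variances(self):
        # Monte Carlo check of E[rms^2] = s1^2 + s2^2
        rng = np.random.default_rng(3)
        s1, s2, n = 1.2, 0.8, 29
        draws = 4000
        a = rng.normal(0, s1, (draws, n))
        b = rng.normal(0, s2, (draws, n))
        msqs = []
        for lo in range(0, draws, 500):
            block = _rms_rows(a[lo : lo + 500], b[lo : lo + 500])
            msqs.append(np.diag(block) ** 2)
        mean_sq = np.concatenate(msqs).mean()
        assert mean_sq == pytest.approx(s1**2 + s2**2, rel=0.05)

    def test_reference_outside_frame_errors(self):
        ep = Epoch(np.ones((4, 3, 3)), 0.0, 300.0, 1.0)
        with pytest.raises(ValueError):
            similarity_map(ep, (5, 0), "forward")


class TestNormalizeSimilarity:
    def test_constant_std_map_affine_in_rms(self):
        rng = np.random.default_rng(4)
        ep = Epoch(rng.random((8, 5, 5)), 0.0, 300.0, 1.0)
        sim = similarity_map(ep, (2, 2), "forward")
        raw_argmin = np.unravel_index(np.nanargmin(sim.rms), sim.rms.shape)
        out = normalize_similarity(sim, np.full((5, 5), 3.0))
        z_argmax = np.unravel_index(np.nanargmax(out.z), out.z.shape)
        assert z_argmax == raw_argmin
        # affine: z correlates perfectly with -rms
        ok = np.isfinite(out.z)
        r = np.corrcoef(out.z[ok], -sim.rms[ok])[0, 1]
        assert r == pytest.approx(1.0)

    def test_background_structure_rank_improves(self):
        # one true match plus a high-variance distractor region: after
        # normalization the true match's z rank must improve or hold
        # the sum-of-variances law makes raw RMS favour low-variance
        # candidates; an imperfect true match can be outranked by quiet
        # distractors until the SD map is subtracted
        rng = np.random.default_rng(5)
        T, P = 16, 40
        traces = rng.normal(0, 0.1, (P, T))
        traces[7] = np.concatenate([[0.0], traces[0, :-1]])
        traces[7] += rng.normal(0, 0.04, T)  # imperfect destination
        traces[20:30] *= 0.05  # low-variance structure: artificially low rms
        ep = epoch_from_traces(traces.tolist())
        sim = similarity_map(ep, (0, 0), "forward")
        rms_rank = (sim.rms.ravel() < sim.rms[0, 7]).sum()
        out = normalize_similarity(sim, motion_contrast(ep))
        z_rank = (out.z.ravel() > out.z[0, 7]).sum()
        assert z_rank <= rms_rank
        assert out.best_match == (0, 7)

    def test_small_support_errors(self):
        ep = Epoch(np.random.default_rng(0).random((5, 2, 2)), 0.0, 300.0, 1.0)
        support = np.zeros((2, 2), dtype=bool)
        support[0, 0] = True
        sim = similarity_map(ep, (0, 0), "forward", support)
        with pytest.raises(ValueError):
            normalize_similarity(sim, np.ones((2, 2)))


class TestDisplacementToSpeed:
    def test_zero(self):
        assert displacement_to_speed((0, 0), 300, 1.0) == 0.0

    def test_paper_15px_300fps_is_4p5(self):
        assert displacement_to_speed((0, 15), 300, 1.0) == pytest.approx(4.5)

    def test_3_4_5_at_200fps(self):
        assert displacement_to_speed((3, 4), 200, 1.0) == pytest.approx(1.0)

    def test_frame_lag_scaling(self):
        assert displacement_to_speed((0, 15), 300, 1.0, frame_lag=3) == pytest.approx(1.5)

    def test_invalid_lag(self):
        with pytest.raises(ValueError):
            displacement_to_speed((0, 1), 300, 1.0, frame_lag=0)


class TestGateAndMatch:
    def make_sim(self, z, ref=(0, 0)):
        z = np.asarray(z, dtype=float)
        from pixflow.pix_core import SimilarityMap

        return SimilarityMap(
            reference_pixel=ref, direction="forward",
            rms=np.zeros_like(z), z=z,
        )

    def test_speed_cap_16um_at_300fps_rejected(self):
        z = np.full((1, 20), -1.0)
        z[0, 16] = 10.0  # 16 px away -> 4.8 mm/s > 4.5
        sim = self.make_sim(z)
        gate = GateParams(n_hypotheses=20)
        assert gate_and_match(sim, gate, 300.0, 1.0) is None

    def test_15um_at_300fps_accepted(self):
        z = np.full((1, 20), -1.0)
        z[0, 15] = 10.0
        sim = self.make_sim(z)
        gate = GateParams(n_hypotheses=20)
        disp = gate_and_match(sim, gate, 300.0, 1.0)
        assert disp == (0, 15)
        assert displacement_to_speed(disp, 300.0, 1.0) == pytest.approx(4.5)

    def test_below_threshold_rejected(self):
        z = np.full((1, 20), 0.0)
        z[0, 3] = 1.0  # weak peak, below Bonferroni threshold
        sim = self.make_sim(z)
        assert gate_and_match(sim, GateParams(n_hypotheses=20), 300.0, 1.0) is None

    def test_tie_smaller_displacement_wins(self):
        z = np.full((1, 9), -1.0)
        z[0, 2] = z[0, 6] = 10.0  # ref at col 4: displacements -2 and +2... use asym
        sim = self.make_sim(z, ref=(0, 4))
        disp = gate_and_match(sim, GateParams(n_hypotheses=9), 300.0, 1.0)
        # equal distance ties broken by row-major candidate order
        assert disp == (0, -2)

    def test_tie_distance_beats_scan_order(self):
        z = np.full((1, 9), -1.0)
        z[0, 0] = z[0, 5] = 10.0  # ref col 4: displacements -4 and +1
        sim = self.make_sim(z, ref=(0, 4))
        assert gate_and_match(sim, GateParams(n_hypotheses=9), 300.0, 1.0) == (0, 1)


class TestCombineDirections:
    def test_mean(self):
        assert combine_directions(2.0, 3.0) == pytest.approx(2.5)

    def test_single_valid_falls_back(self):
        assert combine_directions(2.0, None) == 2.0
        assert combine_directions(None, 3.0) == 3.0

    def test_both_rejected(self):
        assert combine_directions(None, None) is None

    def test_best_mode_uses_peak_z(self):
        assert combine_directions(2.0, 3.0, z_fwd=5.0, z_bwd=4.0, mode="best") == 2.0
        assert combine_directions(2.0, 3.0, z_fwd=4.0, z_bwd=5.0, mode="best") == 3.0


class TestVelocityMap:
    def test_noise_epoch_mostly_rejected(self, noise_epoch_factory):
        # on a small field the speed gate passes a larger fraction of the
        # frame, so the family-wise bound is looser than at the calibration
        # geometry (128x128, exercised in the acceptance suite)
        ep = noise_epoch_factory(shape=(30, 48, 48), seed=11)
        fld = velocity_map(ep, None)
        assert fld.n_accepted / (48 * 48) <= 0.10

    def test_constant_phantom_recovery(self, straight_phantom_factory):
        truth = straight_phantom_factory(mean_velocity=0.9, duration_s=0.2, seed=1)
        seq = pf.preprocess_sequence(truth.sequence)
        ep = pf.split_epochs(seq)[0]
        fld = velocity_map(ep, truth.mask)
        tol = 0.5 * ep.pixel_um * ep.fps / 1000.0
        assert abs(np.nanmean(fld.speed) - 0.9) <= tol

    def test_speed_cap_invariant(self, straight_phantom_factory):
        truth = straight_phantom_factory(mean_velocity=1.2, duration_s=0.2, seed=2)
        seq = pf.preprocess_sequence(truth.sequence)
        fld = velocity_map(pf.split_epochs(seq)[0], truth.mask)
        assert np.nanmax(fld.speed) <= fld.v_max + 1e-9

    def test_time_reversal_invariance(self, straight_phantom_factory):
        truth = straight_phantom_factory(mean_velocity=0.6, duration_s=0.2, seed=3)
        seq = pf.preprocess_sequence(truth.sequence)
        ep = pf.split_epochs(seq)[0]
        rev = Epoch(ep.frames[::-1].copy(), ep.start_ms, ep.fps, ep.pixel_um)
        f1 = velocity_map(ep, truth.mask)
        f2 = velocity_map(rev, truth.mask)
        assert np.array_equal(np.isfinite(f1.speed), np.isfinite(f2.speed))
        assert np.allclose(np.nan_to_num(f1.speed), np.nan_to_num(f2.speed))

    def test_masked_vs_unmasked_agree_when_match_inside_mask(
        self, straight_phantom_factory
    ):
        truth = straight_phantom_factory(mean_velocity=0.9, duration_s=0.2, seed=4,
                                         field=(24, 60), margin=4)
        seq = pf.preprocess_sequence(truth.sequence)
        ep = pf.split_epochs(seq)[0]
        # 'best' mode makes the recorded displacement the one that produced
        # the speed, so agreement can be checked displacement-wise
        masked = velocity_map(ep, truth.mask, combine="best")
        unmasked = velocity_map(ep, None, combine="best")
        rows, cols = ep.shape
        both = np.isfinite(masked.speed) & np.isfinite(unmasked.speed)
        agree = 0
        total = 0
        for r, c in zip(*np.nonzero(both)):
            dr, dc = unmasked.displacement[r, c]
            if truth.mask[r + dr, c + dc]:
                total += 1
                if np.isclose(masked.speed[r, c], unmasked.speed[r, c]):
                    agree += 1
        assert total > 0
        # thresholds differ (n_hypotheses), so demand strong but not exact overlap
        assert agree / total >= 0.9

    def test_monotonic_equivalence_of_score_conventions(self):
        rng = np.random.default_rng(6)
        ep = Epoch(rng.random((8, 6, 6)), 0.0, 300.0, 1.0)
        sim = similarity_map(ep, (3, 3), "forward")
        rms = sim.rms.ravel()
        assert np.nanargmin(rms) == np.nanargmax(-rms) == np.nanargmax(1.0 / rms)

    def test_zero_variance_reference_rejected(self):
        rng = np.random.default_rng(7)
        frames = rng.random((10, 4, 4))
        frames[:, 1, 1] = 0.5  # constant trace carries no information
        ep = Epoch(frames, 0.0, 300.0, 1.0)
        fld = velocity_map(ep, None)
        assert np.isnan(fld.speed[1, 1])

    def test_identical_cell_phantom_degrades(self, straight_phantom_factory):
        good = straight_phantom_factory(mean_velocity=3.0, duration_s=0.2, seed=4,
                                        field=(40, 160), margin=5)
        bad = straight_phantom_factory(mean_velocity=3.0, duration_s=0.2, seed=4,
                                       field=(40, 160), margin=5,
                                       cell_diam_cv=0.0, cell_contrast_cv=0.0,
                                       gap_cv=0.0, lateral_sd_frac=0.0)
        results = {}
        for name, truth in [("good", good), ("bad", bad)]:
            seq = pf.preprocess_sequence(truth.sequence)
            fld = velocity_map(pf.split_epochs(seq)[0], truth.mask)
            results[name] = fld.n_accepted
        # the heterogeneous train is matched far more often than the
        # degenerate identical-cell train (documented expected failure)
        assert results["bad"] < 0.5 * results["good"]
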