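"""Cut-value math, curve construction, and the elbow recommendation."""

import numpy as np
import pytest

from ssimcut import (
    CutCurve,
    ModelSpec,
    SSIMCutAnalysis,
    analyze_model,
    build_model,
    cut_curve,
    cut_difference,
    cut_value,
    cut_value_rowsum,
    flat_condition_residual,
    mean_cut_curve,
    preferred_candidate,
    recommend_depth,
    row_sums,
)

from _oracles import cut_value_loops, random_ssim_like_matrix, two_block_matrix


class TestCutValue:
    def test_uniform_matrix(self):
        assert cut_value(np.ones((4, 4)), 2) == pytest.approx(1.0, abs=1e-15)

    def test_block_diagonal_zero_cross(self):
        s = np.zeros((4, 4))
        s[:2, :2] = 1.0
        s[2:, 2:] = 1.0
        assert cut_value(s, 2) == 0.0

    def test_matches_double_loop_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(2, 21))
            s = random_ssim_like_matrix(rng, n)
            for k in range(1, n):
                assert cut_value(s, k) == pytest.approx(
                    cut_value_loops(s, k), abs=1e-12)

    def test_k_out_of_range(self):
        s = np.ones((4, 4))
        for k in (0, 4, -1):
            with pytest.raises(IndexError):
                cut_value(s, k)


class TestRowSumForm:
    def test_identity_with_direct_form(self, rng):
        for _ in range(30):
            n = int(rng.integers(2, 21))
            s = random_ssim_like_matrix(rng, n)
            m = row_sums(s)
            for k in range(1, n):
                assert cut_value_rowsum(s, k, m) == pytest.approx(
                    cut_value(s, k), abs=1e-12)

    def test_uniform_matrix(self):
        assert cut_value_rowsum(np.ones((4, 4)), 2) == pytest.approx(1.0, abs=1e-15)

    def test_identity_holds_with_asymmetric_row_sums(self, rng):
        s = random_ssim_like_matrix(rng, 8)
        s[3] *= 0.5
        s[:, 3] = s[3]  # keep symmetric, but row 3 has very different mass
        np.fill_diagonal(s, 1.0)
        for k in range(1, 8):
            assert cut_value_rowsum(s, k) == pytest.approx(
                cut_value(s, k), abs=1e-12)

    def test_inconsistent_row_sums_rejected(self):
        from ssimcut import RowSums
        with pytest.raises(ValueError, match="row sums"):
            cut_value_rowsum(np.ones((4, 4)), 2, RowSums(np.ones(3)))


class TestCutCurve:
    def test_uniform_matrix_constant_curve(self):
        c = cut_curve(np.ones((5, 5)))
        np.testing.assert_allclose(c.values, 1.0)

    def test_planted_boundary_is_curve_minimum(self, rng):
        for n, k0 in [(8, 3), (12, 6), (20, 13)]:
            s = two_block_matrix(n, k0)
            c = cut_curve(s)
            assert int(np.argmin(c.values)) + 1 == k0

    @pytest.mark.parametrize("n", [2, 5, 17, 30])
    def test_length_is_n_minus_one(self, rng, n):
        c = cut_curve(random_ssim_like_matrix(rng, n))
        assert len(c.values) == n - 1

    def test_too_small_matrix_rejected(self):
        with pytest.raises(ValueError):
            cut_curve(np.ones((1, 1)))


class TestCutDifference:
    def test_constant_curve_gives_zeros(self):
        d = cut_difference(CutCurve(np.full(5, 0.3), 6))
        np.testing.assert_array_equal(d.values, 0.0)

    def test_linear_curve_gives_slope(self):
        d = cut_difference(CutCurve(0.1 * np.arange(5), 6))
        np.testing.assert_allclose(d.values, 0.1)

    def test_matches_pairwise_subtraction(self, rng):
        v = rng.random(9)
        d = cut_difference(CutCurve(v, 10))
        expected = [v[i + 1] - v[i] for i in range(8)]
        np.testing.assert_array_equal(d.values, expected)

    def test_needs_three_layers(self):
        with pytest.raises(ValueError):
            cut_difference(CutCurve(np.array([0.5]), 2))


class TestFlatConditionResidual:
    def test_uniform_matrix_balances(self):
        # n=6, k=2: column 3 has sum 6, first half sum 3 -> residual 0
        assert flat_condition_residual(np.ones((6, 6)), 2) == pytest.approx(0.0)

    def test_balanced_column_construction(self, rng):
        # construct column k+1 with equal mass before and after the split
        n, k = 7, 2
        s = random_ssim_like_matrix(rng, n)
        col = np.array([0.3, 0.5, 1.0, 0.7, 0.6, 0.2, 0.3])
        # mass of first k+1 entries = 1.8; remaining entries also sum to 1.8
        s[:, k] = col
        s[k, :] = col
        assert col[: k + 1].sum() == pytest.approx(col[k + 1 :].sum())
        assert flat_condition_residual(s, k) == pytest.approx(0.0, abs=1e-12)

    def test_small_relative_residual_on_flat_curves(self):
        # a uniform off-diagonal matrix has an exactly flat interior curve
        n = 10
        s = np.full((n, n), 0.6)
        np.fill_diagonal(s, 1.0)
        k = n // 2 - 1
        m = row_sums(s).values
        assert abs(flat_condition_residual(s, k)) / m[k + 1] < 0.15

    def test_k_range(self):
        with pytest.raises(IndexError):
            flat_condition_residual(np.ones((5, 5)), 4)


class TestMeanCutCurve:
    def test_single_curve_is_itself(self):
        c = CutCurve(np.array([0.1, 0.2]), 3)
        np.testing.assert_array_equal(mean_cut_curve([c]).values, c.values)

    def test_opposite_curves_cancel(self):
        v = np.array([0.4, -0.1, 0.3])
        avg = mean_cut_curve([CutCurve(v, 4), CutCurve(-v, 4)])
        np.testing.assert_allclose(avg.values, 0.0)

    def test_matches_pointwise_mean(self, rng):
        vals = [rng.random(6) for _ in range(10)]
        avg = mean_cut_curve([CutCurve(v, 7) for v in vals])
        np.testing.assert_allclose(avg.values, np.mean(vals, axis=0))

    def test_permutation_invariant(self, rng):
        curves = [CutCurve(rng.random(5), 6, [f"i{i}"]) for i in range(4)]
        a = mean_cut_curve(curves).values
        b = mean_cut_curve(curves[::-1]).values
        np.testing.assert_allclose(a, b)

    def test_mixed_lengths_rejected(self):
        with pytest.raises(ValueError, match="mixed"):
            mean_cut_curve([CutCurve(np.ones(3), 4), CutCurve(np.ones(4), 5)])


class TestRecommendDepth:
    def test_rise_then_flat_found_by_both_methods(self):
        k0 = 4
        vals = np.concatenate([0.1 * np.arange(1, k0 + 1),
                               np.full(5, 0.1 * k0)])
        curve = CutCurve(vals, len(vals) + 1)
        for method in ("chord_distance", "delta_threshold"):
            rec = recommend_depth(curve, method=method)
            assert rec.verdict == "depth_sufficient"
            assert rec.k_star == k0

    def test_strictly_linear_curve_still_rising(self):
        rec = recommend_depth(CutCurve(0.05 * np.arange(1, 9), 9))
        assert rec.verdict == "still_rising"
        assert rec.k_star is None

    def test_constant_curve_degenerate(self):
        rec = recommend_depth(CutCurve(np.full(8, 0.7), 9))
        assert rec.verdict == "degenerate"
        assert rec.k_star is None

    def test_scaling_matrix_scales_curve_and_keeps_argmax(self, rng):
        s = two_block_matrix(14, 6, noise_sd=0.05, rng=rng)
        base = cut_curve(s)
        for alpha in (0.3, 0.7, 1.0):
            scaled = cut_curve(alpha * s)
            np.testing.assert_allclose(scaled.values, alpha * base.values,
                                       atol=1e-12)
            assert recommend_depth(scaled).k_star == recommend_depth(base).k_star

    def test_planted_boundary_recovery_small(self, rng):
        hits = 0
        for t in range(50):
            n = (10, 20, 30)[t % 3]
            # a boundary in the central half — a boundary hugging either end
            # is not a meaningful depth recommendation
            k0 = int(rng.integers(n // 4, 3 * n // 4 + 1))
            s = two_block_matrix(n, k0, noise_sd=0.05, rng=rng)
            rec = recommend_depth(cut_curve(s))
            hits += rec.k_star == k0
        assert hits >= 45

    def test_needs_four_layers(self):
        with pytest.raises(ValueError):
            recommend_depth(CutCurve(np.array([0.1, 0.2]), 3))

    def test_preferred_candidate_mapping(self):
        assert preferred_candidate(5, [4, 8, 12]) == 8
        assert preferred_candidate(13, [4, 8, 12]) is None


class TestAnalyzeModel:
    def test_zero_weight_model_degenerate(self, rng):
        net = build_model(ModelSpec(conv_layers=4, input_size=32, seed=0))
        for _, op, p in net.parameters():
            op.params[p] = np.zeros_like(op.params[p])
        img = rng.random((32, 32, 3)).astype(np.float32)
        res = analyze_model(net, [img])
        assert res.verdict == "degenerate"
        np.testing.assert_allclose(res.matrices[0].values, 1.0)

    def test_deterministic_report(self, tiny_net, rng):
        imgs = [rng.random((32, 32, 3)).astype(np.float32) for _ in range(2)]
        r1 = analyze_model(tiny_net, imgs)
        r2 = analyze_model(tiny_net, imgs)
        assert r1.to_dict() == r2.to_dict()

    def test_per_class_grouping_counts(self, tiny_net, rng):
        imgs = [rng.random((32, 32, 3)).astype(np.float32) for _ in range(4)]
        res = analyze_model(tiny_net, imgs, labels=[0, 0, 1, 2])
        assert len(res.per_class_curves) == 3
        assert len(res.curve.values) == 3  # n-1 for 4 conv layers

    def test_failure_annotated_with_image_id(self, tiny_net):
        bad = np.zeros((16, 16, 3))  # wrong size for the model
        with pytest.raises(RuntimeError, match="my_img"):
            analyze_model(tiny_net, [bad], image_ids=["my_img"])

    def test_from_dataset_samples_one_per_class(self, small_dataset, tiny_net):
        analysis = SSIMCutAnalysis.from_dataset(tiny_net, small_dataset, seed=1)
        assert len(analysis.images) == 3
        assert sorted(analysis.labels) == [0, 1, 2]

    def test_summary_and_save(self, tiny_net, rng, tmp_path):
        imgs = [rng.random((32, 32, 3)).astype(np.float32)]
        res = analyze_model(tiny_net, imgs)
        text = res.summary()
        assert "cut-curve" in text and "verdict" in text
        res.save(tmp_path / "report.json")
        res.save_curve_csv(tmp_path / "curve.csv")
        assert (tmp_path / "report.json").exists()
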