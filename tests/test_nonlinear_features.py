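"""Non-linear feature oracles: brute-force enumerations written independently
of the implementation (plain loops), plus known-exponent recoveries."""

import numpy as np
import pytest

from fearsig.io import ValidationError
from fearsig.nonlinear_features import (
    DegenerateSeriesError,
    Embedding,
    correlation_dimension,
    dfa_alpha,
    embed,
    estimate_delay,
    estimate_dimension,
    multiscale_entropy,
    recurrence_matrix,
    rqa_measures,
    sample_entropy,
)

# ---------------------------------------------------------------------------
# Independent oracles


def mi_oracle(x, lag, bins=16):
    """Histogram mutual information by explicit double loop over bins."""
    a, b = x[:-lag], x[lag:]
    h, _, _ = np.histogram2d(a, b, bins=bins)
    n = h.sum()
    mi = 0.0
    px = h.sum(axis=1) / n
    py = h.sum(axis=0) / n
    for i in range(bins):
        for j in range(bins):
            p = h[i, j] / n
            if p > 0:
                mi += p * np.log(p / (px[i] * py[j]))
    return mi


def rqa_oracle(mat, l_min=2, v_min=2, theiler=1):
    """Direct line enumeration on a boolean recurrence matrix."""
    n = mat.shape[0]
    keep = np.array([[abs(i - j) >= theiler for j in range(n)] for i in range(n)])
    masked = mat & keep
    n_rec = int(masked.sum())
    rr = n_rec / keep.sum()

    diag_lines = []
    for k in range(theiler, n):
        for sign in (1, -1):
            run = 0
            for i in range(n - k):
                a, b = (i, i + k) if sign == 1 else (i + k, i)
                if mat[a, b]:
                    run += 1
                else:
                    if run:
                        diag_lines.append(run)
                    run = 0
            if run:
                diag_lines.append(run)
    long_d = [l for l in diag_lines if l >= l_min]
    det = sum(long_d) / n_rec if n_rec else 0.0
    lmax = max(diag_lines) if diag_lines else 0.0
    if long_d:
        vals, counts = np.unique(long_d, return_counts=True)
        p = counts / counts.sum()
        entr = float(-(p * np.log(p)).sum())
    else:
        entr = 0.0

    vert_lines = []
    for j in range(n):
        run = 0
        for i in range(n):
            if masked[i, j]:
                run += 1
            else:
                if run:
                    vert_lines.append(run)
                run = 0
        if run:
            vert_lines.append(run)
    long_v = [l for l in vert_lines if l >= v_min]
    lam = sum(long_v) / n_rec if n_rec else 0.0
    tt = float(np.mean(long_v)) if long_v else 0.0
    return rr, det, lam, lmax, entr, tt


def sampen_oracle(x, m, r):
    """Template counting with explicit loops (Richman-Moorman)."""
    n = len(x)
    b = a = 0
    for i in range(n - m):
        for j in range(i + 1, n - m):
            if max(abs(x[i + k] - x[j + k]) for k in range(m)) <= r:
                b += 1
                if max(abs(x[i + k] - x[j + k]) for k in range(m + 1)) <= r:
                    a += 1
    return -np.log(a / b) if a and b else 0.0


# ---------------------------------------------------------------------------
# Embedding parameter estimation


class TestEstimateDelay:
    def test_noisy_sinusoid_quarter_period(self):
        t = np.arange(2000)
        rng = np.random.default_rng(0)
        x = np.sin(2 * np.pi * t / 40.0) + 0.05 * rng.standard_normal(2000)
        assert abs(estimate_delay(x, 30) - 10) <= 2

    def test_matches_mi_curve_oracle(self):
        rng = np.random.default_rng(1)
        x = np.sin(2 * np.pi * np.arange(1200) / 36.0) + 0.1 * rng.standard_normal(1200)
        T = estimate_delay(x, 25)
        mi = np.array([mi_oracle(x, lag) for lag in range(1, 26)])
        # the returned lag is a local minimum of the independent MI curve
        left = mi[T - 2] if T >= 2 else np.inf
        right = mi[T] if T < len(mi) else np.inf
        assert mi[T - 1] <= min(left, right) + 1e-12

    def test_white_noise_minimum_at_small_lag(self):
        delays = [
            estimate_delay(np.random.default_rng(s).standard_normal(2000), 20)
            for s in range(10)
        ]
        assert np.median(delays) <= 3

    def test_constant_is_error(self):
        with pytest.raises(DegenerateSeriesError):
            estimate_delay(np.full(500, 2.0), 10)


class TestEstimateDimension:
    def test_noiseless_sinusoid_is_two(self):
        x = np.sin(2 * np.pi * np.arange(2000) / 40.0)
        assert estimate_dimension(x, 10) == 2

    def test_logistic_map_low_dimension(self):
        z = np.empty(2000)
        z[0] = 0.4
        for i in range(1999):
            z[i + 1] = 4 * z[i] * (1 - z[i])
        assert estimate_dimension(z, 1) <= 3

    def test_too_short_series_is_error(self):
        with pytest.raises(ValidationError):
            estimate_dimension(np.sin(np.arange(15)), delay=10, max_dim=5)


# ---------------------------------------------------------------------------
# Recurrence matrix and RQA


class TestRecurrenceMatrix:
    def test_matches_brute_force_threshold(self):
        rng = np.random.default_rng(0)
        pts = rng.standard_normal((50, 3))
        rp = recurrence_matrix(Embedding(1, 3, pts))
        # brute force O(n^2)
        d = np.array([[np.linalg.norm(pts[i] - pts[j]) for j in range(50)] for i in range(50)])
        eps = 0.10 * d[np.triu_indices(50, 1)].mean()
        expected = d <= eps
        np.fill_diagonal(expected, True)
        assert rp.threshold == pytest.approx(eps)
        np.testing.assert_array_equal(rp.matrix, expected)

    def test_two_far_clusters_are_block_diagonal(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 0.01, (20, 2))
        b = rng.normal(100, 0.01, (20, 2))
        rp = recurrence_matrix(Embedding(1, 2, np.vstack([a, b])))
        assert rp.matrix[:20, :20].all() and rp.matrix[20:, 20:].all()
        assert not rp.matrix[:20, 20:].any()

    def test_degenerate_cloud_is_error(self):
        with pytest.raises(DegenerateSeriesError):
            recurrence_matrix(Embedding(1, 2, np.zeros((20, 2))))

    def test_symmetry_and_rotation_invariance(self):
        rng = np.random.default_rng(2)
        pts = rng.standard_normal((60, 2))
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        rp1 = recurrence_matrix(Embedding(1, 2, pts))
        rp2 = recurrence_matrix(Embedding(1, 2, pts @ rot.T))
        np.testing.assert_array_equal(rp1.matrix, rp1.matrix.T)
        np.testing.assert_array_equal(rp1.matrix, rp2.matrix)


class TestRqaMeasures:
    def test_all_ones_matrix(self):
        from fearsig.nonlinear_features import RecurrenceMatrix

        mat = np.ones((30, 30), dtype=bool)
        m = rqa_measures(RecurrenceMatrix(mat, 1.0))
        assert m.recurrence_rate == 1.0
        # the two corner diagonals have length 1 < l_min, hence the tiny deficit;
        # the enumeration oracle agrees exactly
        rr, det, lam, *_ = rqa_oracle(mat)
        assert m.determinism == pytest.approx(det) and m.determinism > 0.99
        assert m.laminarity == pytest.approx(lam) and m.laminarity > 0.99

    def test_identity_only_matrix(self):
        from fearsig.nonlinear_features import RecurrenceMatrix

        m = rqa_measures(RecurrenceMatrix(np.eye(30, dtype=bool), 1.0), theiler=1)
        assert m.recurrence_rate == 0.0
        assert m.determinism == 0.0 and m.laminarity == 0.0
        assert m.longest_diagonal == 0.0 and m.trapping_time == 0.0

    def test_periodic_embedding_matches_line_oracle(self):
        x = np.sin(2 * np.pi * np.arange(110) / 25.0)
        rp = recurrence_matrix(embed(x, 6, 2))
        got = rqa_measures(rp)
        rr, det, lam, lmax, entr, tt = rqa_oracle(rp.matrix)
        assert got.determinism >= 0.9
        assert got.recurrence_rate == pytest.approx(rr)
        assert got.determinism == pytest.approx(det)
        assert got.laminarity == pytest.approx(lam)
        assert got.longest_diagonal == lmax
        assert got.diagonal_entropy == pytest.approx(entr)
        assert got.trapping_time == pytest.approx(tt)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_matrices_match_oracle_exactly(self, seed):
        rng = np.random.default_rng(seed)
        n = 80
        mat = rng.random((n, n)) < 0.15
        mat |= mat.T
        np.fill_diagonal(mat, True)
        from fearsig.nonlinear_features import RecurrenceMatrix

        got = rqa_measures(RecurrenceMatrix(mat, 1.0))
        rr, det, lam, lmax, entr, tt = rqa_oracle(mat)
        assert got.recurrence_rate == pytest.approx(rr)
        assert got.determinism == pytest.approx(det)
        assert got.laminarity == pytest.approx(lam)
        assert got.longest_diagonal == lmax
        assert got.diagonal_entropy == pytest.approx(entr)
        assert got.trapping_time == pytest.approx(tt)

    def test_det_lam_monotone_in_min_length(self):
        rng = np.random.default_rng(4)
        mat = rng.random((60, 60)) < 0.3
        mat |= mat.T
        from fearsig.nonlinear_features import RecurrenceMatrix

        rp = RecurrenceMatrix(mat, 1.0)
        dets = [rqa_measures(rp, l_min=l).determinism for l in (2, 3, 5)]
        lams = [rqa_measures(rp, v_min=v).laminarity for v in (2, 3, 5)]
        assert dets == sorted(dets, reverse=True)
        assert lams == sorted(lams, reverse=True)


class TestCorrelationDimension:
    def test_line_segment(self):
        rng = np.random.default_rng(0)
        u = rng.random(400)
        pts = np.column_stack([u, 2 * u, -0.5 * u])
        assert correlation_dimension(Embedding(1, 3, pts)) == pytest.approx(1.0, abs=0.2)

    def test_square(self):
        vals = []
        for s in range(10):
            pts = np.random.default_rng(s).random((400, 2))
            vals.append(correlation_dimension(Embedding(1, 2, pts)))
        assert np.mean(vals) == pytest.approx(2.0, abs=0.3)

    def test_collapsed_cloud_flagged_zero(self):
        pts = np.zeros((150, 2))
        assert correlation_dimension(Embedding(1, 2, pts)) == 0.0


class TestEntropy:
    def test_sample_entropy_matches_template_oracle(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(300)
        r = 0.2 * np.std(x)
        assert sample_entropy(x, 2, r) == pytest.approx(sampen_oracle(x, 2, r))

    def test_constant_mse_is_zero(self):
        np.testing.assert_array_equal(multiscale_entropy(np.full(800, 1.0)), np.zeros(5))

    def test_white_noise_entropy_decreases_with_scale(self):
        vals = np.mean(
            [multiscale_entropy(np.random.default_rng(s).standard_normal(1000)) for s in range(6)],
            axis=0,
        )
        assert vals[4] < vals[0]


class TestDfa:
    def test_white_noise_exponent(self):
        alphas = [dfa_alpha(np.random.default_rng(s).standard_normal(2048)) for s in range(12)]
        assert np.mean(alphas) == pytest.approx(0.5, abs=0.1)

    def test_random_walk_exponent(self):
        alphas = [
            dfa_alpha(np.cumsum(np.random.default_rng(100 + s).standard_normal(2048)))
            for s in range(12)
        ]
        assert np.mean(alphas) == pytest.approx(1.5, abs=0.15)

    def test_constant_flagged_zero(self):
        assert dfa_alpha(np.full(512, 3.0)) == 0.0

    def test_too_short_is_error(self):
        with pytest.raises(ValidationError):
            dfa_alpha(np.arange(32.0))
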