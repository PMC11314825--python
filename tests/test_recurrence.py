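import numpy as np
import pytest

from naive_rqa import naive_embed, naive_features, naive_recurrence
from rpaf.ecg import DegenerateSignalError, ParameterError
from rpaf.recurrence import (EmbeddingConfig, RecurrenceMatrix, embed,
                             line_histograms, recurrence_matrix, rp_to_image,
                             rqa_features)


def _rp(matrix):
    return RecurrenceMatrix(np.asarray(matrix, dtype=bool), eps=1.0,
                            config=EmbeddingConfig())


class TestEmbed:
    def test_lagged_components(self, rng):
        x = rng.normal(size=10)
        traj = embed(x, EmbeddingConfig(m=3, tau=3))
        assert traj.n_points == 4
        np.testing.assert_array_equal(traj.points[0], x[[0, 3, 6]])
        np.testing.assert_array_equal(traj.points[3], x[[3, 6, 9]])

    def test_paper_scale_length(self, rng):
        assert embed(rng.normal(size=5000)).n_points == 4994  # 5000 - (3-1)*3

    def test_m1_identity(self, rng):
        x = rng.normal(size=20)
        traj = embed(x, EmbeddingConfig(m=1, tau=1))
        np.testing.assert_array_equal(traj.points[:, 0], x)

    def test_too_short(self):
        with pytest.raises(ParameterError):
            embed(np.arange(6.0), EmbeddingConfig(m=4, tau=2))


class TestRecurrenceMatrix:
    def test_toy_example(self):
        traj = embed(np.array([0.0, 1.0, 10.0]), EmbeddingConfig(m=1, tau=1,
                                                                 eps_fraction=0.2))
        rp = recurrence_matrix(traj)
        assert rp.eps == pytest.approx(2.0)
        np.testing.assert_array_equal(
            rp.matrix.astype(int), [[1, 1, 0], [1, 1, 0], [0, 0, 1]])

    def test_symmetric_unit_diagonal(self, rng):
        rp = recurrence_matrix(embed(rng.normal(size=100)))
        assert np.array_equal(rp.matrix, rp.matrix.T)
        assert rp.matrix.diagonal().all()

    def test_strict_inequality_at_full_fraction(self, rng):
        """The pair realising the maximum distance stays non-recurrent."""
        traj = embed(rng.normal(size=50), EmbeddingConfig(m=1, tau=1, eps_fraction=1.0))
        rp = recurrence_matrix(traj)
        d = np.abs(traj.points - traj.points.T)
        i, j = np.unravel_index(np.argmax(d), d.shape)
        assert not rp.matrix[i, j]
        assert rp.matrix.sum() == rp.size**2 - (d == d.max()).sum()

    def test_degenerate(self):
        with pytest.raises(DegenerateSignalError):
            recurrence_matrix(embed(np.zeros(10)))

    def test_affine_invariance(self, rng):
        """R is bit-identical under x -> a*x + b for any a != 0."""
        x = rng.normal(size=120)
        ref = recurrence_matrix(embed(x)).matrix
        for _ in range(20):
            a = rng.uniform(-5, 5)
            a = a if abs(a) > 1e-3 else 1.7
            b = rng.uniform(-10, 10)
            got = recurrence_matrix(embed(a * x + b)).matrix
            np.testing.assert_array_equal(got, ref)

    def test_rec_monotone_in_eps(self, rng):
        traj = embed(rng.normal(size=150))
        recs = [recurrence_matrix(traj, f).matrix.mean()
                for f in (0.05, 0.1, 0.2, 0.5, 1.0)]
        assert all(a <= b for a, b in zip(recs, recs[1:]))


class TestLineHistograms:
    def test_identity_matrix(self):
        h = line_histograms(_rp(np.eye(5)))
        assert h.diagonal == {5: 1}
        assert h.vertical == {1: 5}

    def test_all_ones(self):
        h = line_histograms(_rp(np.ones((4, 4))))
        assert h.diagonal == {4: 1, 3: 2, 2: 2, 1: 2}
        assert h.vertical == {4: 4}

    def test_checkerboard(self):
        """Even-offset diagonals are fully recurrent, odd-offset ones empty,
        and every vertical run is an isolated point."""
        i, j = np.indices((4, 4))
        h = line_histograms(_rp((i + j) % 2 == 0))
        assert h.diagonal == {4: 1, 2: 2}
        assert h.vertical == {1: 8}

    def test_conservation(self, rng):
        """Sum of l*count over diagonal (and vertical) runs = recurrence points."""
        rp = recurrence_matrix(embed(rng.normal(size=80)))
        h = line_histograms(rp)
        total = int(rp.matrix.sum())
        assert sum(l * c for l, c in h.diagonal.items()) == total
        assert sum(v * c for v, c in h.vertical.items()) == total

    def test_theiler_excludes_loi(self):
        h = line_histograms(_rp(np.eye(6)), theiler=1)
        assert h.diagonal == {}


class TestRQAFeatures:
    def test_all_ones(self):
        f = rqa_features(_rp(np.ones((6, 6))))
        assert f.recurrence_rate == 1.0
        assert f.determinism == 1.0
        assert f.laminarity == 1.0
        assert f.l_max_norm == 1.0

    def test_identity(self):
        f = rqa_features(_rp(np.eye(10)))
        assert f.recurrence_rate == pytest.approx(0.1)
        assert f.determinism == 1.0  # every point on the line of identity

    def test_entropy_degenerate_and_uniform(self):
        # single diagonal length -> ENTR 0
        assert rqa_features(_rp(np.eye(10))).entropy == 0.0
        # two line lengths in equal counts -> ln 2 (LOI excluded via theiler)
        r = np.eye(7, dtype=bool)
        for k in (2, -2):
            r |= np.diag(np.ones(5, dtype=bool), k=k)  # two length-5 lines
        for k in (4, -4):
            r |= np.diag(np.ones(3, dtype=bool), k=k)  # two length-3 lines
        f = rqa_features(RecurrenceMatrix(r, 1.0, EmbeddingConfig()), theiler=1)
        assert f.entropy == pytest.approx(np.log(2))

    def test_trapping_time(self):
        r = np.zeros((6, 6), dtype=bool)
        r[:3, 0] = r[1:4, 2] = r[3:, 4] = True  # vertical lines all length 3
        f = rqa_features(RecurrenceMatrix(r, 1.0, EmbeddingConfig()))
        assert f.trapping_time == pytest.approx(3.0)

    def test_toy_rec(self):
        traj = embed(np.array([0.0, 1.0, 10.0]), EmbeddingConfig(m=1, tau=1,
                                                                 eps_fraction=0.2))
        f = rqa_features(recurrence_matrix(traj))
        assert f.recurrence_rate == pytest.approx(5 / 9)

    def test_sine_vs_noise_determinism(self):
        """A pure sine is highly deterministic; white noise much less so."""
        x = np.sin(2 * np.pi * 5 * np.arange(1000) / 500)
        det_sine = rqa_features(recurrence_matrix(embed(x))).determinism
        assert det_sine >= 0.95
        for seed in range(5):
            w = np.random.default_rng(seed).normal(size=1000)
            assert rqa_features(recurrence_matrix(embed(w))).determinism < det_sine


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(12))
    def test_random_signals_match_naive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(30, 120))
        m = int(rng.integers(1, 4))
        tau = int(rng.integers(1, 4))
        frac = float(rng.choice([0.05, 0.1, 0.3]))
        x = rng.normal(size=n)
        cfg = EmbeddingConfig(m=m, tau=tau, eps_fraction=frac)
        rp = recurrence_matrix(embed(x, cfg))
        ref_r, ref_eps = naive_recurrence(naive_embed(list(x), m, tau), frac)
        assert rp.eps == pytest.approx(ref_eps)
        np.testing.assert_array_equal(rp.matrix.astype(int), np.array(ref_r))
        got = rqa_features(rp).as_dict()
        ref = naive_features(ref_r)
        for key, val in ref.items():
            assert got[key] == pytest.approx(val, abs=1e-12), key


class TestRPImage:
    def test_all_ones(self):
        img = rp_to_image(_rp(np.ones((50, 50))), 10)
        np.testing.assert_allclose(img, 1.0)

    def test_identity_pooling(self):
        img = rp_to_image(_rp(np.eye(100)), 10)
        np.testing.assert_allclose(np.diag(img), 0.1)
        off = img - np.diag(np.diag(img))
        assert np.all(off == 0)

    def test_mean_preserved(self, rng):
        rp = recurrence_matrix(embed(rng.normal(size=106),
                                     EmbeddingConfig(m=1, tau=1, eps_fraction=0.3)))
        # 106 points, pooled into 53 blocks of 2: exact mean preservation
        img = rp_to_image(rp, 53)
        assert img.mean() == pytest.approx(rqa_features(rp).recurrence_rate)

    def test_small_matrix_zero_padded(self):
        img = rp_to_image(_rp(np.ones((5, 5))), 8)
        assert img.shape == (8, 8)
        assert img[:5, :5].all() and img[5:].sum() == 0 and img[:, 5:].sum() == 0
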