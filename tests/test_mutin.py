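"""Histogram entropy, KLD, mutual information, and greedy selection.

Numeric expectations are frozen from direct-summation oracles or closed
forms (Gaussian differential entropy, exhaustive pair/triple enumeration).
"""

import itertools

import numpy as np
import pytest

from eegmutin.dataset import SegmentSet
from eegmutin.mutin import (ChannelDistribution, JointDistribution, MutInMatrix,
                            SupportError, discretize, entropy,
                            joint_from_samples, kld, mutual_information,
                            pairwise_mutin_matrix, select_channels)


def dist(probs):
    probs = np.asarray(probs, float)
    return ChannelDistribution(np.arange(len(probs) + 1, dtype=float), probs)


def joint(mat):
    mat = np.asarray(mat, float)
    return JointDistribution(mat, dist(mat.sum(axis=1)), dist(mat.sum(axis=0)))


class TestDiscretize:
    def test_symmetric_split(self):
        d = discretize(np.array([0.0, 1.0, 2.0, 3.0]), n_bins=2)
        assert np.allclose(d.probabilities, [0.5, 0.5])

    def test_normalization(self):
        x = np.random.default_rng(0).standard_normal(500)
        assert discretize(x, 16).probabilities.sum() == pytest.approx(1.0)

    def test_constant_input_degenerate_flag(self):
        d = discretize(np.full(10, 3.3), 8)
        assert d.degenerate and d.probabilities.max() == 1.0

    def test_gaussian_entropy_matches_closed_form(self):
        # discretized entropy ~ differential entropy + ln(bin width)
        x = np.random.default_rng(1).standard_normal(10_000)
        d = discretize(x, 64)
        width = d.bin_edges[1] - d.bin_edges[0]
        expected = 0.5 * np.log(2 * np.pi * np.e) - np.log(width)
        assert entropy(d) == pytest.approx(expected, abs=0.1)


class TestEntropyKld:
    def test_uniform_entropy(self):
        assert entropy(dist([0.25] * 4)) == pytest.approx(np.log(4))

    def test_point_mass_entropy_zero(self):
        assert entropy(dist([0, 1, 0, 0])) == 0.0

    def test_direct_summation_oracle(self):
        p = [0.4, 0.1, 0.1, 0.4]
        expected = -sum(v * np.log(v) for v in p)
        assert entropy(dist(p)) == pytest.approx(expected, abs=1e-12)

    def test_kld_identity_of_indiscernibles(self):
        p = dist([0.3, 0.7])
        assert kld(p, p) == 0.0

    def test_kld_direct_summation(self):
        p, q = dist([0.5, 0.5]), dist([0.25, 0.75])
        expected = 0.5 * np.log(2.0) + 0.5 * np.log(2.0 / 3.0)
        assert kld(p, q) == pytest.approx(expected, abs=1e-12)
        assert kld(p, q) == pytest.approx(0.1438, abs=5e-5)

    def test_kld_asymmetric(self):
        p, q = dist([0.5, 0.5]), dist([0.25, 0.75])
        assert kld(p, q) != pytest.approx(kld(q, p))

    def test_kld_support_violation(self):
        with pytest.raises(SupportError):
            kld(dist([0.5, 0.5]), dist([1.0, 0.0]))


class TestMutualInformation:
    def test_independent_is_zero(self):
        pi, pj = np.array([0.3, 0.7]), np.array([0.6, 0.4])
        assert mutual_information(joint(np.outer(pi, pj))) \
            == pytest.approx(0.0, abs=1e-12)

    def test_perfect_dependence_equals_entropy(self):
        j = joint(np.diag([0.2, 0.3, 0.5]))
        assert mutual_information(j) == pytest.approx(
            entropy(j.marginal_i), abs=1e-12
        )

    def test_direct_summation_oracle(self):
        expected = 0.8 * np.log(1.6) + 0.2 * np.log(0.4)
        got = mutual_information(joint([[0.4, 0.1], [0.1, 0.4]]))
        assert got == pytest.approx(expected, abs=1e-12)
        assert got == pytest.approx(0.1927, abs=5e-5)

    def test_bounded_by_marginal_entropies(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            m = rng.random((4, 4))
            j = joint(m / m.sum())
            mi = mutual_information(j)
            assert -1e-12 <= mi <= min(entropy(j.marginal_i),
                                       entropy(j.marginal_j)) + 1e-9

    def test_estimator_consistency_in_sample_size(self):
        # fixed dependent pair: estimates at 1e5 and 1e6 samples agree < 5%
        rng = np.random.default_rng(3)
        z = rng.standard_normal(1_000_000)
        x = z + 0.5 * rng.standard_normal(1_000_000)
        est = {n: mutual_information(joint_from_samples(x[:n], z[:n], 64))
               for n in (100_000, 1_000_000)}
        assert abs(est[100_000] - est[1_000_000]) / est[1_000_000] < 0.05


class TestPairwiseMatrix:
    def test_duplicated_channel_reaches_self_entropy(self):
        rng = np.random.default_rng(4)
        base = rng.standard_normal((30, 1, 200)).astype(np.float32)
        ds = SegmentSet(np.concatenate([base, base, rng.standard_normal(
            (30, 1, 200)).astype(np.float32)], axis=1),
            np.zeros(30, int), np.ones(30, int), ["A", "Adup", "B"],
            n_classes=1)
        m = pairwise_mutin_matrix(ds, n_bins=32)
        assert m.values[0, 1] == pytest.approx(m.values[0, 0], abs=1e-9)

    def test_independent_channels_near_zero(self):
        rng = np.random.default_rng(5)
        ds = SegmentSet(rng.standard_normal((250, 2, 400)).astype(np.float32),
                        np.zeros(250, int), np.ones(250, int), ["A", "B"],
                        n_classes=1)
        m = pairwise_mutin_matrix(ds, n_bins=64)
        assert 0.0 <= m.values[0, 1] < 0.05

    def test_symmetry_and_diagonal(self, tiny_ds):
        ds, _ = tiny_ds
        m = pairwise_mutin_matrix(ds, n_bins=32, max_samples=30_000)
        assert np.array_equal(m.values, m.values.T)
        assert (np.diag(m.values) > 0).all()

    def test_single_channel_rejected(self):
        ds = SegmentSet(np.zeros((2, 1, 8), np.float32), [0, 0], [1, 1],
                        ["A"], n_classes=1)
        with pytest.raises(ValueError, match="2 channels"):
            pairwise_mutin_matrix(ds)


def random_mutin_matrix(rng, n):
    """Symmetric nonnegative matrix with entropy-like diagonal."""
    v = rng.random((n, n))
    v = (v + v.T) / 2 * 0.2
    np.fill_diagonal(v, 2.0 + rng.random(n))
    return MutInMatrix(v, [f"CH{i}" for i in range(n)])


class TestSelection:
    def test_target_equals_all_channels(self):
        m = random_mutin_matrix(np.random.default_rng(6), 5)
        res = select_channels(m, 5)
        assert sorted(res.channels) == sorted(m.channel_names)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_pair_matches_exhaustive_argmax(self, seed):
        m = random_mutin_matrix(np.random.default_rng(seed), 8)
        res = select_channels(m, 2)
        best = max(
            ((i, j) for i in range(8) for j in range(i + 1, 8)),
            key=lambda p: m.values[p],
        )
        assert set(res.channels) == {m.channel_names[best[0]],
                                     m.channel_names[best[1]]}

    def test_triple_recovers_informative_set(self, tiny_ds):
        # greedy triple equals exhaustive subset search over all 56 triples
        ds, gt = tiny_ds
        m = pairwise_mutin_matrix(ds, n_bins=64, max_samples=48_000)
        res = select_channels(m, 3)
        assert set(res.channels) == set(gt.informative_channels)

        def subset_score(idx):
            return sum(m.values[a, b]
                       for a, b in itertools.combinations(idx, 2))
        best = max(itertools.combinations(range(8), 3), key=subset_score)
        assert {m.channel_names[i] for i in best} == set(res.channels)

    def test_criterion_trace_length(self):
        m = random_mutin_matrix(np.random.default_rng(7), 6)
        res = select_channels(m, 4)
        assert len(res.criterion) == 4 and len(res.channels) == 4

    def test_target_out_of_range(self):
        m = random_mutin_matrix(np.random.default_rng(8), 4)
        with pytest.raises(ValueError, match="target_size"):
            select_channels(m, 1)
        with pytest.raises(ValueError, match="target_size"):
            select_channels(m, 5)
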