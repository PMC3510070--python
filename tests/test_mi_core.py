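import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from allodyn import mi_core
from allodyn.mi_core import (DeltaMIMatrix, MIConfig, MIMatrix, delta_mi,
                             entropy, ffd_discretize, jitter, joint_entropy,
                             mi_matrix, mutual_information, null_filter,
                             reparametrize)
from allodyn.rotamer_sampling import TrajectoryMatrix


def _traj(rows, sizes, label=""):
    rows = np.asarray(rows)
    return TrajectoryMatrix(rows, sizes, list(range(rows.shape[0])), label)


class TestReparametrize:
    def test_singleton_alphabet_maps_to_zero(self):
        np.testing.assert_array_equal(
            reparametrize(np.array([0, 0, 0]), 1), np.zeros(3))

    def test_three_symbols_map_to_unit_grid(self):
        np.testing.assert_allclose(
            reparametrize(np.array([0, 1, 2]), 3), [0.0, 0.5, 1.0])

    def test_mi_invariant_under_reparametrization(self):
        rng = np.random.default_rng(0)
        a = rng.integers(4, size=2000)
        b = np.where(rng.random(2000) < 0.7, a, rng.integers(4, size=2000))
        before = mutual_information(a, b)
        after = mutual_information(reparametrize(a, 4), reparametrize(b, 4))
        assert after == pytest.approx(before, abs=1e-12)

    @given(st.permutations(list(range(5))))
    @settings(deadline=None, max_examples=20, derandomize=True)
    def test_mi_invariant_under_monotone_relabeling(self, perm):
        # any injective relabeling (monotone or not) preserves plug-in MI
        rng = np.random.default_rng(1)
        a = rng.integers(5, size=500)
        b = np.where(rng.random(500) < 0.5, a, rng.integers(5, size=500))
        relabeled = np.array(perm)[a]
        assert mutual_information(relabeled, b) == pytest.approx(
            mutual_information(a, b), abs=1e-12)


class TestJitter:
    def test_zero_mean(self):
        rng = np.random.default_rng(2)
        x = np.zeros(1_000_000)
        noise = jitter(x, 1e-6, rng) - x
        assert abs(noise.mean()) < 5 * 1e-6 / np.sqrt(noise.size)

    def test_variance_matches_default(self):
        rng = np.random.default_rng(3)
        noise = jitter(np.zeros(200_000), 1e-6, rng)
        assert noise.var() == pytest.approx(1e-12, rel=0.2)

    def test_seeded_reproducibility(self):
        x = np.linspace(0, 1, 100)
        a = jitter(x, 1e-6, np.random.default_rng(7))
        b = jitter(x, 1e-6, np.random.default_rng(7))
        np.testing.assert_array_equal(a, b)


class TestFFD:
    def test_nine_distinct_values_three_bins(self):
        labels = ffd_discretize(np.arange(9.0), 3)
        assert np.bincount(labels).tolist() == [3, 3, 3]

    def test_constant_vector_single_bin(self):
        labels = ffd_discretize(np.ones(10), 3)
        assert len(set(labels)) == 1

    def test_sorted_ten_m5(self):
        labels = ffd_discretize(np.arange(1.0, 11.0), 5)
        np.testing.assert_array_equal(labels, [0] * 5 + [1] * 5)

    def test_last_bin_absorbs_remainder(self):
        labels = ffd_discretize(np.arange(10.0), 3)
        assert np.bincount(labels).tolist() == [3, 3, 4]

    def test_m_larger_than_n_errors(self):
        with pytest.raises(ValueError):
            ffd_discretize(np.arange(3.0), 4)

    @given(st.lists(st.floats(-1e3, 1e3), min_size=4, max_size=60),
           st.integers(1, 4))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_bin_sizes_and_tie_safety(self, values, m):
        values = np.asarray(values)
        labels = ffd_discretize(values, m)
        # equal values always share a label
        for v in np.unique(values):
            assert len(set(labels[values == v])) == 1
        assert labels.min() == 0


class TestEntropyAndMI:
    def test_uniform_four_symbols(self):
        assert entropy(np.repeat(np.arange(4), 25)) == pytest.approx(2.0)

    def test_single_symbol_zero_entropy_zero_mi(self):
        a = np.zeros(50, dtype=int)
        b = np.random.default_rng(0).integers(3, size=50)
        assert entropy(a) == 0.0
        assert mutual_information(a, b) == 0.0

    def test_perfect_dependency_one_bit(self):
        a = np.array([0, 0, 1, 1])
        assert mutual_information(a, a) == pytest.approx(1.0, abs=1e-9)
        assert joint_entropy(a, a) == pytest.approx(1.0, abs=1e-9)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            joint_entropy(np.arange(3), np.arange(4))

    @given(st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=25, derandomize=True)
    def test_mi_bounds(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(4, size=300)
        b = rng.integers(3, size=300)
        mi = mutual_information(a, b)
        assert mi >= 0.0
        assert mi <= min(entropy(a), entropy(b)) + 1e-9


class TestMIMatrix:
    def test_copy_pair_reaches_marginal_entropy(self):
        rng = np.random.default_rng(4)
        a = rng.integers(4, size=10_000)
        traj = _traj([a, a.copy(), rng.integers(4, size=10_000)], [4, 4, 4])
        m = mi_matrix(traj, MIConfig(seed=0))
        # frequency-based bin boundaries straddle symbol groups when the
        # empirical marginal is not exactly uniform, biasing MI slightly
        # below H; the deficit is a few percent at n = 1e4
        assert m.values[0, 1] == pytest.approx(m.values[0, 0], abs=0.2)
        assert m.values[0, 1] > 10 * m.values[0, 2]

    def test_independent_pairs_near_zero(self):
        rng = np.random.default_rng(5)
        traj = _traj(rng.integers(4, size=(6, 10_000)), [4] * 6)
        m = mi_matrix(traj, MIConfig(seed=1))
        off = m.values[~np.eye(6, dtype=bool)]
        assert off.max() < 0.05

    def test_symmetry_and_diagonal_entropy(self):
        rng = np.random.default_rng(6)
        traj = _traj(rng.integers(3, size=(4, 3000)), [3] * 4)
        m = mi_matrix(traj, MIConfig(seed=2))
        np.testing.assert_array_equal(m.values, m.values.T)
        assert np.all(m.values.diagonal() > 1.0)  # near log2(3)

    def test_single_residue_rejected(self):
        with pytest.raises(ValueError):
            mi_matrix(_traj(np.zeros((1, 10), dtype=int), [1]))


class TestNullFilter:
    def test_coupled_pair_survives(self):
        rng = np.random.default_rng(7)
        a = rng.integers(4, size=8000)
        traj = _traj([a, a.copy()], [4, 4])
        cfg = MIConfig(seed=3)
        filtered = null_filter(mi_matrix(traj, cfg), traj, cfg)
        assert filtered.values[0, 1] > 1.5

    def test_independent_pair_filtered_in_most_repetitions(self):
        zeroed = 0
        reps = 20
        for seed in range(reps):
            rng = np.random.default_rng(100 + seed)
            traj = _traj(rng.integers(4, size=(2, 10_000)), [4, 4])
            cfg = MIConfig(seed=seed)
            filtered = null_filter(mi_matrix(traj, cfg), traj, cfg)
            zeroed += filtered.values[0, 1] == 0.0
        assert zeroed >= 0.95 * reps

    def test_idempotent(self):
        rng = np.random.default_rng(8)
        a = rng.integers(4, size=5000)
        rows = [a, a.copy(), rng.integers(4, size=5000)]
        traj = _traj(rows, [4, 4, 4])
        cfg = MIConfig(seed=4)
        once = null_filter(mi_matrix(traj, cfg), traj, cfg)
        twice = null_filter(once, traj, cfg)
        np.testing.assert_array_equal(once.values, twice.values)


class TestDeltaMI:
    def _mat(self, values, label=""):
        return MIMatrix(np.asarray(values, float), [0, 1], label)

    def test_equal_states_zero(self):
        m = self._mat([[1.0, 0.3], [0.3, 1.0]])
        d = delta_mi(m, m)
        assert np.all(d.signed == 0) and np.all(d.normalized == 0)

    def test_signed_arithmetic(self):
        b = self._mat([[1.0, 0.5], [0.5, 1.0]], "bound")
        u = self._mat([[1.0, 0.3], [0.3, 1.0]], "unbound")
        d = delta_mi(b, u)
        assert d.signed[0, 1] == pytest.approx(0.2)
        assert d.absolute[0, 1] == pytest.approx(0.2)
        assert d.normalized.max() == pytest.approx(1.0)

    def test_residue_mismatch_rejected(self):
        b = self._mat([[1.0, 0.5], [0.5, 1.0]])
        u = MIMatrix(np.eye(2), [5, 6])
        with pytest.raises(ValueError):
            delta_mi(b, u)

    def test_normalized_is_absolute_over_max(self):
        d = DeltaMIMatrix(np.array([[0.0, -0.4], [-0.4, 0.0]]), [0, 1])
        assert d.absolute[0, 1] == pytest.approx(0.4)
        assert d.normalized[0, 1] == pytest.approx(1.0)


class TestMatrixIO:
    def test_tsv_round_trip(self, tmp_path):
        values = np.array([[0.0, 0.25], [0.25, 0.0]])
        path = tmp_path / "m.tsv"
        mi_core.write_matrix_tsv(values, [10, 11], path)
        back, ids = mi_core.read_matrix_tsv(path)
        np.testing.assert_allclose(back, values)
        assert ids == [10, 11]
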