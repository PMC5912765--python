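"""AMOVA tests, anchored on an independent brute-force oracle.

The oracle recomputes every pairwise squared distance with explicit Python
loops and rebuilds the variance-component arithmetic from the textbook
definitions, sharing no code with the implementation.
"""

import numpy as np
import pytest

from domssr import amova
from domssr.errors import ContractError, GroupNameError, SizeError, UndefinedPairError
from domssr.genotype_io import BandID, BinaryGenotypeMatrix, MISSING, Partition
from tests.conftest import random_binary_matrix


def amova_oracle(values, groups):
    """First-principles AMOVA on complete 0/1 data.

    ``groups`` maps group name -> list of row indices. Returns a dict of the
    same quantities as AmovaTable (no permutations).
    """
    n = values.shape[0]
    g = len(groups)

    def delta2(i, j):
        return sum(1 for k in range(values.shape[1]) if values[i, k] != values[j, k])

    ss_total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            ss_total += delta2(i, j)
    ss_total /= n

    ss_within = 0.0
    for rows in groups.values():
        acc = 0.0
        for a in range(len(rows)):
            for b in range(a + 1, len(rows)):
                acc += delta2(rows[a], rows[b])
        ss_within += acc / len(rows)

    ss_among = ss_total - ss_within
    ms_among = ss_among / (g - 1)
    sigma_within = ss_within / (n - g)
    sizes = [len(r) for r in groups.values()]
    n0 = (n - sum(s**2 for s in sizes) / n) / (g - 1)
    sigma_among = (ms_among - sigma_within) / n0
    phi = sigma_among / (sigma_among + sigma_within)
    return {
        "ss_among": ss_among,
        "ss_within": ss_within,
        "ss_total": ss_total,
        "sigma2_among": sigma_among,
        "sigma2_within": sigma_within,
        "phi_st": phi,
    }


class TestSquaredDistance:
    def test_identical_vectors(self):
        assert amova.squared_distance([1, 0, 1], [1, 0, 1]) == 0.0

    def test_toy_a1_vs_b1_all_mismatch(self, toy):
        matrix, _ = toy
        assert amova.squared_distance(matrix.values[0], matrix.values[3]) == 5.0

    def test_toy_a1_vs_a3_single_mismatch(self, toy):
        matrix, _ = toy
        assert amova.squared_distance(matrix.values[0], matrix.values[2]) == 1.0

    def test_missing_rescaled_to_full_band_count(self):
        x = np.array([1, 0, MISSING, 1])
        y = np.array([0, 0, 1, 1])
        # 1 mismatch over 3 compared bands, rescaled to 4 * 1/3
        assert amova.squared_distance(x, y) == pytest.approx(4 / 3)
        assert amova.squared_distance(x, y, rescale_missing=False) == 1.0

    def test_no_jointly_called_bands(self):
        with pytest.raises(UndefinedPairError):
            amova.squared_distance([MISSING, MISSING], [1, 0])


class TestAmovaOracleEquivalence:
    def test_toy_instance_matches_oracle(self, toy):
        matrix, partition = toy
        table = amova.amova(matrix, partition, n_permutations=99, seed=0)
        expected = amova_oracle(
            matrix.values,
            {"A": [0, 1, 2], "B": [3, 4, 5]},
        )
        for key, val in expected.items():
            assert getattr(table, key) == pytest.approx(val, abs=1e-9), key

    @pytest.mark.parametrize("seed", range(12))
    def test_random_small_instances_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))  # all instances N <= 8
        matrix = random_binary_matrix(rng, n, int(rng.integers(5, 15)))
        split = int(rng.integers(2, n - 1))
        assignments = {
            ind: ("g1" if i < split else "g2")
            for i, ind in enumerate(matrix.individuals)
        }
        partition = Partition(assignments)
        try:
            table = amova.amova(matrix, partition, n_permutations=99, seed=seed)
        except (SizeError, ContractError):
            pytest.skip("degenerate random instance")
        expected = amova_oracle(
            matrix.values,
            {"g1": list(range(split)), "g2": list(range(split, n))},
        )
        for key, val in expected.items():
            assert getattr(table, key) == pytest.approx(val, abs=1e-9), key

    def test_three_group_instance_matches_oracle(self):
        rng = np.random.default_rng(99)
        matrix = random_binary_matrix(rng, 8, 10)
        groups = {"a": [0, 1, 2], "b": [3, 4], "c": [5, 6, 7]}
        assignments = {
            matrix.individuals[i]: name
            for name, rows in groups.items()
            for i in rows
        }
        table = amova.amova(matrix, Partition(assignments), n_permutations=99, seed=1)
        expected = amova_oracle(matrix.values, groups)
        for key, val in expected.items():
            assert getattr(table, key) == pytest.approx(val, abs=1e-9), key


class TestAmovaBehaviour:
    def test_fixed_differences_give_phi_one(self):
        values = np.array(
            [[1, 1, 0, 0]] * 8 + [[0, 0, 1, 1]] * 8, dtype=np.int8
        )
        matrix = BinaryGenotypeMatrix(
            [f"i{k:02d}" for k in range(16)],
            [BandID("P1", 100 + j) for j in range(4)],
            values,
        )
        partition = Partition(
            {f"i{k:02d}": ("a" if k < 8 else "b") for k in range(16)}
        )
        table = amova.amova(matrix, partition, n_permutations=999, seed=0)
        assert table.phi_st == pytest.approx(1.0)
        # only a permutation reproducing the exact split ties the observed Phi
        assert table.p_value < 0.01

    def test_table_invariants(self, toy):
        matrix, partition = toy
        t = amova.amova(matrix, partition, n_permutations=99, seed=0)
        n = matrix.n_individuals
        assert t.df_among + t.df_within == n - 1
        assert t.ss_among + t.ss_within == pytest.approx(t.ss_total, rel=1e-9)
        assert t.pct_among + t.pct_within == pytest.approx(100.0, abs=1e-6)
        assert 1 / (t.n_permutations + 1) <= t.p_value <= 1.0
        assert t.pct_among == pytest.approx(100.0 * t.phi_st, abs=1e-9)

    def test_reproducible_from_seed(self, toy):
        matrix, partition = toy
        t1 = amova.amova(matrix, partition, n_permutations=199, seed=7)
        t2 = amova.amova(matrix, partition, n_permutations=199, seed=7)
        assert t1.p_value == t2.p_value

    def test_singleton_group_is_error(self, toy):
        matrix, _ = toy
        partition = Partition({"A1": "solo", **{
            k: "rest" for k in ["A2", "A3", "B1", "B2", "B3"]
        }})
        with pytest.raises(SizeError):
            amova.amova(matrix, partition, n_permutations=99)

    def test_all_identical_matrix_is_degenerate(self):
        values = np.ones((4, 3), dtype=np.int8)
        matrix = BinaryGenotypeMatrix(
            [f"i{k}" for k in range(4)],
            [BandID("P1", 100 + j) for j in range(3)],
            values,
        )
        partition = Partition({f"i{k}": ("a" if k < 2 else "b") for k in range(4)})
        with pytest.raises(ContractError):
            amova.amova(matrix, partition, n_permutations=99, seed=0)

    def test_too_few_permutations_rejected(self, toy):
        matrix, partition = toy
        with pytest.raises(SizeError):
            amova.amova(matrix, partition, n_permutations=10)


class TestPairwiseGroupAmovas:
    def _four_group_panel(self):
        rng = np.random.default_rng(21)
        matrix = random_binary_matrix(rng, 16, 20)
        assignments = {
            ind: f"g{i % 4}" for i, ind in enumerate(matrix.individuals)
        }
        return matrix, Partition(assignments)

    def test_each_contrast_satisfies_ss_additivity(self):
        matrix, partition = self._four_group_panel()
        tables = amova.pairwise_group_amovas(
            matrix, partition, [("g0", "g1"), ("g0", "g2")],
            n_permutations=99, seed=0,
        )
        assert len(tables) == 2
        for t in tables:
            assert t.ss_among + t.ss_within == pytest.approx(t.ss_total, rel=1e-9)
            assert t.df_among + t.df_within == 7  # 8 individuals per contrast

    def test_contrast_with_itself_is_error(self):
        matrix, partition = self._four_group_panel()
        with pytest.raises(GroupNameError):
            amova.pairwise_group_amovas(
                matrix, partition, [("g0", "g0")], n_permutations=99
            )

    def test_divergence_graded_contrast_ordering(self):
        from domssr.synthetic_data import SimConfig, simulate_panel

        cfg = SimConfig(
            n_groups=3,
            group_sizes=(12, 12, 12),
            n_primers=5,
            bands_per_primer=(8, 12),
            divergence=0.0,
            private_band_fraction=0.0,
            missing_rate=0.0,
            seed=2,
        )
        # groups 1/2 identical frequencies; group 3 diverged by hand
        matrix, partition, truth = simulate_panel(cfg)
        values = matrix.values.copy()
        rows3 = matrix.individual_index(partition.members("G3"))
        rng = np.random.default_rng(3)
        flip = rng.random(values.shape[1]) < 0.5
        values[np.ix_(rows3, np.flatnonzero(flip))] ^= 1
        for j in np.flatnonzero((values == 1).sum(axis=0) == 0):
            values[0, j] = 1  # keep the every-band-observed invariant
        matrix2 = BinaryGenotypeMatrix(matrix.individuals, matrix.bands, values)
        tables = amova.pairwise_group_amovas(
            matrix2, partition, [("G1", "G2"), ("G1", "G3")],
            n_permutations=99, seed=0,
        )
        assert tables[1].phi_st > tables[0].phi_st
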