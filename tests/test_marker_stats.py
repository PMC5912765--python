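import numpy as np
import pytest
from hypothesis import given, strategies as st

from domssr import marker_stats as ms
from domssr.errors import ContractError, InsufficientDataError
from domssr.genotype_io import MISSING
from tests.conftest import random_binary_matrix


class TestBandFrequencies:
    def test_toy_p1_all(self, toy):
        matrix, _ = toy
        np.testing.assert_allclose(
            ms.band_frequencies(matrix, "P1"), [1 / 3, 1 / 3, 1 / 3]
        )

    def test_toy_p2_group_a(self, toy):
        matrix, partition = toy
        freqs = ms.band_frequencies(matrix, "P2", subset=partition.members("A"))
        np.testing.assert_allclose(freqs, [1.0, 0.0])

    def test_single_present_call(self, toy):
        matrix, _ = toy
        freqs = ms.band_frequencies(matrix, "P2", subset=["B2"])
        np.testing.assert_allclose(freqs, [0.0, 1.0])

    def test_sums_to_one(self, toy):
        matrix, _ = toy
        for primer in matrix.primers:
            assert ms.band_frequencies(matrix, primer).sum() == pytest.approx(1.0)

    def test_no_present_calls_is_error(self, toy):
        matrix, _ = toy
        matrix.values[0, 3] = MISSING
        with pytest.raises(InsufficientDataError):
            ms.band_frequencies(matrix, "P2", subset=["A1"])


class TestPic:
    def test_monomorphic_is_zero(self):
        assert ms.pic([1.0]) == 0.0

    def test_two_equifrequent(self):
        # 1 - 0.5 - 2*(0.25*0.25), Botstein closed form
        assert ms.pic([0.5, 0.5]) == pytest.approx(0.375)

    def test_three_equifrequent(self):
        assert ms.pic([1 / 3, 1 / 3, 1 / 3]) == pytest.approx(16 / 27)

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = rng.dirichlet(np.ones(rng.integers(2, 8)))
            expected = 1.0 - sum(x**2 for x in p)
            expected -= sum(
                2 * p[i] ** 2 * p[j] ** 2
                for i in range(len(p))
                for j in range(i + 1, len(p))
            )
            assert ms.pic(p) == pytest.approx(expected, abs=1e-12)

    def test_bad_sum_is_contract_error(self):
        with pytest.raises(ContractError):
            ms.pic([0.5, 0.4])

    @given(
        st.lists(st.floats(min_value=0.01, max_value=1.0), min_size=1, max_size=10)
    )
    def test_permutation_invariant_and_below_one(self, weights):
        p = np.array(weights) / np.sum(weights)
        rng = np.random.default_rng(0)
        shuffled = rng.permutation(p)
        assert ms.pic(p) == pytest.approx(ms.pic(shuffled), abs=1e-12)
        assert ms.pic(p) < 1.0


class TestMultiplexAndEffective:
    def test_toy_p1(self, toy):
        matrix, _ = toy
        n, beta, e = ms.multiplex_and_effective(matrix, "P1")
        assert n == pytest.approx(1.5)  # per-row counts 2,2,1,1,2,1
        assert beta == 1.0
        assert e == pytest.approx(1.5)

    def test_toy_p2(self, toy):
        matrix, _ = toy
        n, beta, e = ms.multiplex_and_effective(matrix, "P2")
        assert (n, beta, e) == (1.0, 1.0, 1.0)

    def test_fixed_band_gives_zero_beta(self):
        from domssr.genotype_io import BandID, BinaryGenotypeMatrix

        matrix = BinaryGenotypeMatrix(
            ["a", "b"], [BandID("P1", 100)], np.array([[1], [1]])
        )
        n, beta, e = ms.multiplex_and_effective(matrix, "P1")
        assert beta == 0.0
        assert e == 0.0

    def test_individuals_with_missing_cells_excluded_from_n(self, toy):
        matrix, _ = toy
        matrix.values[0, 0] = MISSING  # A1 incomplete at P1
        n, _, _ = ms.multiplex_and_effective(matrix, "P1")
        assert n == pytest.approx(7 / 5)  # rows A2..B3: 2,1,1,2,1

    def test_all_incomplete_is_error(self, toy):
        matrix, _ = toy
        matrix.values[:, 0] = [MISSING] * 5 + [1]
        matrix.values[5, 1] = MISSING
        with pytest.raises(InsufficientDataError):
            ms.multiplex_and_effective(matrix, "P1")


class TestMarkerIndex:
    def test_paper_cv60_cultivars(self):
        # printed PIC 0.720 and E 2.938 give the printed MI 2.115 at 3 dp
        assert round(ms.marker_index(0.720, 2.938), 3) == 2.115

    def test_zero_pic(self):
        assert ms.marker_index(0.0, 5.0) == 0.0

    def test_toy_p1(self, toy):
        matrix, _ = toy
        p = ms.pic(ms.band_frequencies(matrix, "P1"))
        _, _, e = ms.multiplex_and_effective(matrix, "P1")
        assert ms.marker_index(p, e) == pytest.approx(8 / 9)


class TestResolvingPower:
    def test_band_at_half_frequency(self, toy):
        matrix, _ = toy
        rp, ib = ms.resolving_power(matrix, "P1")
        np.testing.assert_allclose(ib, [1.0, 1.0, 1.0])  # all M = 0.5
        assert rp == pytest.approx(3.0)

    def test_fixed_band_has_zero_ib(self):
        from domssr.genotype_io import BandID, BinaryGenotypeMatrix

        matrix = BinaryGenotypeMatrix(
            ["a", "b"], [BandID("P1", 100)], np.array([[1], [1]])
        )
        rp, ib = ms.resolving_power(matrix, "P1")
        assert ib[0] == pytest.approx(0.0)

    def test_brute_force_oracle_on_random_matrices(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            matrix = random_binary_matrix(rng, 8, 12)
            for primer in matrix.primers:
                cols = matrix.primer_columns(primer)
                expected = 0.0
                for j in cols:
                    col = matrix.values[:, j]
                    m = np.mean(col == 1)
                    expected += 1 - 2 * abs(0.5 - m)
                rp, _ = ms.resolving_power(matrix, primer)
                assert rp == pytest.approx(expected, abs=1e-12)


class TestProfileDiscrimination:
    def test_toy_p1(self, toy):
        matrix, _ = toy
        distinct, pct = ms.profile_discrimination(matrix, "P1")
        assert distinct == 4  # patterns 110, 100, 001, 011
        assert pct == pytest.approx(100 * 4 / 6)

    def test_all_identical(self):
        from domssr.genotype_io import BandID, BinaryGenotypeMatrix

        matrix = BinaryGenotypeMatrix(
            ["a", "b", "c"], [BandID("P1", 100)], np.ones((3, 1), dtype=np.int8)
        )
        assert ms.profile_discrimination(matrix, "P1")[0] == 1

    def test_denominator_is_full_count_despite_missing(self, toy):
        matrix, _ = toy
        matrix.values[0, 0] = MISSING  # A1 dropped from distinct computation
        distinct, pct = ms.profile_discrimination(matrix, "P1")
        assert pct == pytest.approx(100 * distinct / 6)

    def test_never_exceeds_bounds(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            matrix = random_binary_matrix(rng, 6, 8)
            for primer in matrix.primers:
                distinct, _ = ms.profile_discrimination(matrix, primer)
                n_bands = len(matrix.primer_columns(primer))
                assert distinct <= min(6, 2**n_bands)


class TestGeneDiversity:
    def test_toy_group_a(self, toy):
        matrix, partition = toy
        row = ms.gene_diversity(matrix, partition, "A")
        assert row.per_primer["P1"] == pytest.approx(0.48)  # 1-(0.6^2+0.4^2)
        assert row.per_primer["P2"] == pytest.approx(0.0)
        assert row.mean_diversity == pytest.approx(0.24)

    def test_equifrequent_closed_form(self):
        from domssr.genotype_io import BandID, BinaryGenotypeMatrix, Partition

        k = 4
        values = np.eye(k, dtype=np.int8)
        matrix = BinaryGenotypeMatrix(
            [f"i{j}" for j in range(k)],
            [BandID("P1", 100 + j) for j in range(k)],
            values,
        )
        partition = Partition({f"i{j}": "g" for j in range(k)})
        row = ms.gene_diversity(matrix, partition, "g")
        assert row.per_primer["P1"] == pytest.approx(1 - 1 / k)

    def test_single_band_carries_all_calls(self):
        from domssr.genotype_io import BandID, BinaryGenotypeMatrix, Partition

        values = np.array([[1, 0], [1, 0], [1, 1]], dtype=np.int8)
        matrix = BinaryGenotypeMatrix(
            ["a", "b", "c"],
            [BandID("P1", 100), BandID("P1", 110)],
            values,
        )
        partition = Partition({"a": "g", "b": "g", "c": "h"})
        row = ms.gene_diversity(matrix, partition, "g")
        assert row.per_primer["P1"] == pytest.approx(0.0)


class TestStatsTable:
    def test_toy_footer(self, toy):
        matrix, partition = toy
        table = ms.stats_table(matrix, partition)
        total = table[(table.subset == "all") & (table.primer == "Total")]
        assert total["N"].iloc[0] == 5
        rows = table[~table.primer.isin(["Total", "Mean"])]
        assert len(rows) == 2

    def test_footer_mean_is_sum_over_primer_count(self, toy):
        matrix, partition = toy
        table = ms.stats_table(matrix, partition)
        mean_row = table[table.primer == "Mean"].iloc[0]
        assert mean_row["N"] == pytest.approx(5 / 2)

    def test_identities_hold_per_row(self, toy):
        matrix, partition = toy
        table = ms.stats_table(
            matrix, partition,
            {"all": None, "A": partition.members("A")},
        )
        rows = table[~table.primer.isin(["Total", "Mean"])]
        np.testing.assert_allclose(rows["E"], rows["n"] * rows["beta"])
        np.testing.assert_allclose(rows["MI"], rows["PIC"] * rows["E"])
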