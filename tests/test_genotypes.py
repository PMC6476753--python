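import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from landres import (EncodingError, GenotypeTable, LandresError, ParseError,
                     allele_abundance, bray_curtis_matrix, marker_summary,
                     read_genepop, write_genepop)


def random_table(rng: np.random.Generator, n: int, loci: int,
                 max_allele: int = 9, missing_rate: float = 0.0) -> GenotypeTable:
    calls = rng.integers(1, max_allele + 1, (n, loci, 2))
    if missing_rate > 0:
        mask = rng.random((n, loci)) < missing_rate
        calls[mask] = 0
    return GenotypeTable(ids=[f"i{k}" for k in range(n)],
                         loci=[f"L{k}" for k in range(loci)], calls=calls)


class TestGenepopIO:
    def test_round_trip_identity(self, tmp_path):
        rng = np.random.default_rng(3)
        table = random_table(rng, 10, 5, missing_rate=0.1)
        path = tmp_path / "geno.gen"
        write_genepop(table, path)
        back = read_genepop(path)
        assert back.ids == table.ids
        assert back.loci == table.loci
        # calls are unordered pairs; round-trip preserves written order
        np.testing.assert_array_equal(np.sort(back.calls, axis=2),
                                      np.sort(table.calls, axis=2))

    def test_missing_serialized_as_zeros(self, tmp_path):
        table = GenotypeTable(ids=["a"], loci=["L1"],
                              calls=np.array([[[0, 0]]]))
        path = tmp_path / "m.gen"
        write_genepop(table, path)
        assert "000000" in path.read_text()
        assert (read_genepop(path).calls == 0).all()

    def test_two_digit_dialect(self, tmp_path):
        path = tmp_path / "two.gen"
        path.write_text("title\nL1\nL2\nPOP\nind1 , 0102 0304\n")
        table = read_genepop(path)
        np.testing.assert_array_equal(table.calls[0], [[1, 2], [3, 4]])

    def test_comma_separated_locus_line(self, tmp_path):
        path = tmp_path / "c.gen"
        path.write_text("title\nL1, L2, L3\nPOP\nx , 001001 002002 003003\n")
        assert read_genepop(path).loci == ["L1", "L2", "L3"]

    def test_token_count_mismatch_names_line(self, tmp_path):
        path = tmp_path / "bad.gen"
        path.write_text("title\nL1\nL2\nPOP\nind1 , 001001\n")
        with pytest.raises(ParseError, match=r":5:"):
            read_genepop(path)

    def test_large_allele_code_refused(self, tmp_path):
        table = GenotypeTable(ids=["a"], loci=["L1"],
                              calls=np.array([[[1000, 1]]]))
        with pytest.raises(EncodingError):
            write_genepop(table, tmp_path / "x.gen")

    def test_zero_loci_refused(self, tmp_path):
        table = GenotypeTable(ids=["a"], loci=[],
                              calls=np.zeros((1, 0, 2), dtype=int))
        with pytest.raises(EncodingError):
            write_genepop(table, tmp_path / "x.gen")


class TestAlleleAbundance:
    def test_homozygote_and_heterozygote(self):
        table = GenotypeTable(ids=["a", "b"], loci=["L1"],
                              calls=np.array([[[1, 1]], [[1, 2]]]))
        np.testing.assert_array_equal(allele_abundance(table, "a"), [2, 0])
        np.testing.assert_array_equal(allele_abundance(table, "b"), [1, 1])

    def test_unknown_individual_raises(self, tiny_table):
        with pytest.raises(LandresError, match="unknown individual"):
            allele_abundance(tiny_table, "nobody")

    def test_diploidy_conservation(self):
        rng = np.random.default_rng(5)
        table = random_table(rng, 8, 4, missing_rate=0.2)
        missing = table.missing_mask()
        for ind_idx, ind in enumerate(table.ids):
            vec = allele_abundance(table, ind)
            # per-locus slot sums equal 2 for every non-missing locus
            total = vec.sum()
            assert total == 2 * (~missing[ind_idx]).sum()


class TestBrayCurtis:
    def test_worked_two_locus_example(self, tiny_table):
        # slots (L1:1, L1:2, L2:2, L2:3): a_A=[2,0,1,1], a_B=[1,1,2,0]
        # BC = (1+1+1+1)/8 = 0.5
        G = bray_curtis_matrix(tiny_table)
        assert G.values[0, 1] == pytest.approx(0.5)

    def test_identical_genotypes_give_zero(self):
        calls = np.array([[[1, 2], [3, 3]]] * 3)
        table = GenotypeTable(ids=list("abc"), loci=["L1", "L2"], calls=calls)
        np.testing.assert_allclose(bray_curtis_matrix(table).values, 0.0)

    def test_disjoint_support_gives_one(self):
        table = GenotypeTable(ids=["a", "b"], loci=["L1", "L2"],
                              calls=np.array([[[1, 1], [2, 2]],
                                              [[3, 3], [4, 4]]]))
        assert bray_curtis_matrix(table).values[0, 1] == pytest.approx(1.0)

    def test_pairwise_deletion_of_missing_loci(self):
        # locus 2 missing in b: BC computed on locus 1 only
        table = GenotypeTable(ids=["a", "b"], loci=["L1", "L2"],
                              calls=np.array([[[1, 1], [2, 2]],
                                              [[1, 2], [0, 0]]]))
        assert bray_curtis_matrix(table).values[0, 1] == pytest.approx(2 / 4)

    def test_no_shared_locus_pair_raises(self):
        table = GenotypeTable(ids=["a", "b"], loci=["L1", "L2"],
                              calls=np.array([[[1, 1], [0, 0]],
                                              [[0, 0], [2, 2]]]))
        with pytest.raises(LandresError, match="no shared"):
            bray_curtis_matrix(table)

    def test_matches_scipy_on_complete_tables(self):
        # independent oracle: scipy cityblock form of Bray-Curtis on the
        # concatenated allele-abundance vectors (valid without missing data)
        from scipy.spatial.distance import braycurtis
        rng = np.random.default_rng(11)
        table = random_table(rng, 6, 5)
        G = bray_curtis_matrix(table)
        vecs = [allele_abundance(table, ind) for ind in table.ids]
        for i in range(6):
            for j in range(i + 1, 6):
                assert G.values[i, j] == pytest.approx(
                    braycurtis(vecs[i], vecs[j]), abs=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_range_symmetry_zero_diagonal(self, seed):
        rng = np.random.default_rng(seed)
        table = random_table(rng, 5, 3, missing_rate=0.1)
        try:
            G = bray_curtis_matrix(table)
        except LandresError:
            return  # a pair without shared loci is a documented error
        v = G.values
        assert (v >= 0).all() and (v <= 1).all()
        np.testing.assert_array_equal(v, v.T)
        np.testing.assert_array_equal(np.diag(v), 0.0)

    def test_invariant_to_locus_order(self):
        rng = np.random.default_rng(13)
        table = random_table(rng, 6, 4)
        perm = [2, 0, 3, 1]
        shuffled = GenotypeTable(ids=list(table.ids),
                                 loci=[table.loci[k] for k in perm],
                                 calls=table.calls[:, perm, :])
        np.testing.assert_allclose(bray_curtis_matrix(table).values,
                                   bray_curtis_matrix(shuffled).values)


class TestMarkerSummary:
    def test_monomorphic_locus(self):
        table = GenotypeTable(ids=list("abc"), loci=["L1"],
                              calls=np.array([[[2, 2]]] * 3))
        row = marker_summary(table).iloc[0]
        assert row.Ho == 0.0 and row.He == 0.0 and row.n_alleles == 1

    def test_single_heterozygote(self):
        table = GenotypeTable(ids=["a"], loci=["L1"],
                              calls=np.array([[[1, 2]]]))
        assert marker_summary(table).iloc[0].Ho == 1.0

    def test_unbiased_he_at_even_frequencies(self):
        # 25 homozygotes for each of two alleles: p = (0.5, 0.5), n = 50
        calls = np.array([[[1, 1]]] * 25 + [[[2, 2]]] * 25)
        table = GenotypeTable(ids=[f"i{k}" for k in range(50)],
                              loci=["L1"], calls=calls)
        he = marker_summary(table).iloc[0].He
        assert he == pytest.approx((100 / 99) * 0.5)

    def test_missing_fraction(self):
        table = GenotypeTable(ids=list("abcd"), loci=["L1"],
                              calls=np.array([[[1, 1]], [[0, 0]],
                                              [[1, 2]], [[0, 0]]]))
        assert marker_summary(table).iloc[0].missing_fraction == 0.5
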