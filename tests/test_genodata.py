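"""Genotype/phenotype data model, I/O dialects, filtering and imputation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from lofgwas.genodata import (
    MISSING,
    GenotypeMatrix,
    PhenotypeTable,
    align_samples,
    filter_maf,
    impute_mean,
    read_phenotype_table,
    read_snp_table,
    read_vcf,
    score_replicates,
    write_phenotype_table,
    write_snp_table,
    write_vcf,
)

from conftest import make_genotypes

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    "##contig=<ID=1,length=1000000>\n"
    "##contig=<ID=2,length=1000000>\n"
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ta\tb\tc\n"
)


def write_vcf_text(tmp_path, body):
    path = tmp_path / "t.vcf"
    path.write_text(VCF_HEADER + body)
    return path


class TestReadVcf:
    def test_gt_code_mapping(self, tmp_path):
        path = write_vcf_text(
            tmp_path,
            "1\t100\t.\tG\tT\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n"
            "1\t200\t.\tA\tC\t.\tPASS\t.\tGT\t./.\t0/0\t1/1\n",
        )
        g = read_vcf(path)
        assert list(g.sample_ids) == ["a", "b", "c"]
        assert g.calls[:, 0].tolist() == [2, 1, 0]
        assert g.calls[:, 1].tolist() == [MISSING, 2, 0]
        assert g.allele1[0] == "G" and g.allele2[0] == "T"
        assert list(g.snp_ids) == ["S1_100", "S1_200"]

    def test_non_biallelic_records_skipped(self, tmp_path):
        rows = [f"1\t{100 + i}\t.\tA\tC\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1" for i in range(4)]
        rows.insert(2, "1\t500\t.\tA\tC,G\t.\tPASS\t.\tGT\t0/0\t0/1\t1/2")
        path = write_vcf_text(tmp_path, "\n".join(rows) + "\n")
        g = read_vcf(path)
        assert g.n_snps == 4

    def test_no_usable_records_is_error(self, tmp_path):
        path = write_vcf_text(tmp_path, "1\t100\t.\tAT\tA\t.\tPASS\t.\tGT\t0/0\t0/0\t0/0\n")
        with pytest.raises(ValueError, match="no usable"):
            read_vcf(path)

    def test_vcf_round_trip(self, tmp_path, rng):
        calls = rng.integers(-1, 3, size=(5, 8)).astype(np.int8)
        g = make_genotypes(calls)
        write_vcf(g, tmp_path / "rt.vcf")
        g2 = read_vcf(tmp_path / "rt.vcf")
        np.testing.assert_array_equal(g.calls, g2.calls)
        assert list(g.snp_ids) == list(g2.snp_ids)
        np.testing.assert_array_equal(g.position, g2.position)


class TestSnpTable:
    def test_round_trip_identity(self, tmp_path, rng):
        calls = rng.integers(-1, 3, size=(6, 10)).astype(np.int8)
        g = make_genotypes(calls)
        write_snp_table(g, tmp_path / "g.tsv")
        g2 = read_snp_table(tmp_path / "g.tsv")
        np.testing.assert_array_equal(g.calls, g2.calls)
        assert list(g.sample_ids) == list(g2.sample_ids)
        np.testing.assert_array_equal(g.position, g2.position)

    def test_cross_reader_equivalence(self, tmp_path, rng):
        calls = rng.integers(-1, 3, size=(7, 12)).astype(np.int8)
        g = make_genotypes(calls)
        write_vcf(g, tmp_path / "x.vcf")
        write_snp_table(g, tmp_path / "x.tsv")
        np.testing.assert_array_equal(
            read_vcf(tmp_path / "x.vcf").calls, read_snp_table(tmp_path / "x.tsv").calls
        )

    def test_ragged_row_rejected(self, tmp_path):
        (tmp_path / "bad.tsv").write_text("sample\tS1_100\tS1_200\ns1\t0\n")
        with pytest.raises(ValueError, match="ragged"):
            read_snp_table(tmp_path / "bad.tsv")

    def test_invalid_code_rejected(self, tmp_path):
        (tmp_path / "bad.tsv").write_text("sample\tS1_100\ns1\t3\n")
        with pytest.raises(ValueError, match="invalid genotype"):
            read_snp_table(tmp_path / "bad.tsv")


class TestPhenotypeTable:
    def test_read_scores_and_na(self, tmp_path):
        (tmp_path / "p.tsv").write_text("sample\ttannin\ns1\t1\ns2\t0\ns3\tNA\n")
        p = read_phenotype_table(tmp_path / "p.tsv")
        assert p.trait_name == "tannin"
        assert p.trait.tolist() == [1, 0, MISSING]

    def test_headerless_file(self, tmp_path):
        (tmp_path / "p.tsv").write_text("s1\t1\ns2\t0\n")
        p = read_phenotype_table(tmp_path / "p.tsv")
        assert p.trait.tolist() == [1, 0]

    def test_duplicate_sample_rejected(self, tmp_path):
        (tmp_path / "p.tsv").write_text("s1\t1\ns1\t0\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_phenotype_table(tmp_path / "p.tsv")

    def test_non_binary_score_rejected(self, tmp_path):
        (tmp_path / "p.tsv").write_text("s1\t2\n")
        with pytest.raises(ValueError, match="non-binary"):
            read_phenotype_table(tmp_path / "p.tsv")

    def test_round_trip(self, tmp_path):
        p = PhenotypeTable(np.array(["a", "b", "c"], dtype=object), np.array([1, MISSING, 0]))
        write_phenotype_table(p, tmp_path / "p.tsv")
        p2 = read_phenotype_table(tmp_path / "p.tsv")
        assert p2.trait.tolist() == p.trait.tolist()

    def test_large_synthetic_cardinality(self, tmp_path, rng):
        lines = ["sample\ttrait"] + [f"acc{i}\t{rng.integers(0, 2)}" for i in range(336)]
        (tmp_path / "big.tsv").write_text("\n".join(lines) + "\n")
        assert read_phenotype_table(tmp_path / "big.tsv").n_samples == 336


class TestScoreReplicates:
    def test_unanimous_and_segregating(self):
        p = score_replicates({"a": [1, 1, 1], "b": [0, 0, 0], "c": [1, 0, 1]})
        assert p.trait.tolist() == [1, 0, MISSING]

    def test_discordant_count(self, rng):
        reps = {}
        discordant = {3, 9, 15}
        for i in range(20):
            base = int(rng.integers(0, 2))
            reps[f"s{i}"] = [base, 1 - base, base] if i in discordant else [base] * 3
        p = score_replicates(reps)
        assert int((p.trait == MISSING).sum()) == 3

    def test_empty_replicates_rejected(self):
        with pytest.raises(ValueError, match="no replicate"):
            score_replicates({"a": []})


class TestFilterMaf:
    def test_monomorphic_removed_and_half_kept(self):
        g = make_genotypes([[2, 2], [2, 0], [2, 0], [2, 2]])
        out = filter_maf(g, 0.01)
        assert list(out.snp_ids) == ["S1_110"]  # MAF 0.5 column survives
        assert filter_maf(g, 0.5).n_snps == 1

    def test_against_brute_force_recount(self, rng):
        calls = rng.integers(-1, 3, size=(40, 1000)).astype(np.int8)
        g = make_genotypes(calls, positions=list(range(1, 1001)))
        out = filter_maf(g, 0.05)
        expected = 0
        for j in range(1000):
            col = calls[:, j]
            obs = col[col != MISSING]
            if len(obs) == 0:
                continue
            f = obs.sum() / (2 * len(obs))
            if min(f, 1 - f) >= 0.05:
                expected += 1
        assert out.n_snps == expected

    @given(st.integers(0, 2**32 - 1))
    def test_idempotent(self, seed):
        r = np.random.default_rng(seed)
        calls = r.integers(-1, 3, size=(12, 30)).astype(np.int8)
        g = make_genotypes(calls)
        once = filter_maf(g, 0.1)
        twice = filter_maf(once, 0.1)
        np.testing.assert_array_equal(once.calls, twice.calls)


class TestAlignSamples:
    def test_identity_when_matched(self, tiny_panel):
        g, p = tiny_panel
        g2, p2 = align_samples(g, p)
        assert g2.n_samples == g.n_samples and p2.n_samples == p.n_samples
        np.testing.assert_array_equal(g2.sample_ids, p2.sample_ids)

    def test_intersection_and_missing_trait(self, rng):
        calls = rng.integers(0, 3, size=(10, 4)).astype(np.int8)
        g = make_genotypes(calls)
        trait = np.array([1, 0, MISSING, 1, 0, 1], dtype=np.int8)
        p = PhenotypeTable(np.array([f"s{i}" for i in range(2, 8)], dtype=object), trait)
        g2, p2 = align_samples(g, p)
        # 6 shared samples, one with MISSING trait
        assert g2.n_samples == p2.n_samples == 5
        assert (p2.trait != MISSING).all()

    def test_disjoint_ids_error(self, rng):
        g = make_genotypes(rng.integers(0, 3, size=(3, 2)).astype(np.int8))
        p = PhenotypeTable(np.array(["x", "y"], dtype=object), np.array([0, 1]))
        with pytest.raises(ValueError, match="no overlapping"):
            align_samples(g, p)


class TestImputeMean:
    def test_complete_matrix_passthrough(self, rng):
        calls = rng.integers(0, 3, size=(5, 4)).astype(np.int8)
        g = make_genotypes(calls)
        np.testing.assert_array_equal(impute_mean(g), calls.astype(float))

    def test_simple_mean(self):
        g = make_genotypes([[2], [0], [MISSING]])
        assert impute_mean(g)[2, 0] == 1.0

    def test_masked_cells_equal_column_means(self, rng):
        calls = rng.integers(0, 3, size=(30, 20)).astype(np.int8)
        mask = rng.random((30, 20)) < 0.1
        mask[0] = False  # keep every column partly observed
        masked = np.where(mask, MISSING, calls).astype(np.int8)
        g = make_genotypes(masked)
        dos = impute_mean(g)
        for j in range(20):
            obs = masked[:, j][masked[:, j] != MISSING]
            np.testing.assert_allclose(dos[mask[:, j], j], obs.mean())

    def test_all_missing_snp_error(self):
        g = make_genotypes([[MISSING, 0], [MISSING, 2]])
        with pytest.raises(ValueError, match="S1_100"):
            impute_mean(g)


class TestInvariants:
    def test_snps_sorted_and_id_consistency(self):
        g = GenotypeMatrix(
            sample_ids=np.array(["a"], dtype=object),
            snp_ids=np.array(["S2_5", "S1_9"], dtype=object),
            chromosome=np.array(["2", "1"], dtype=object),
            position=np.array([5, 9]),
            calls=np.array([[0, 2]], dtype=np.int8),
            allele1=np.array(["A", "A"], dtype=object),
            allele2=np.array(["C", "C"], dtype=object),
        )
        assert list(g.snp_ids) == ["S1_9", "S2_5"]
        assert g.calls.tolist() == [[2, 0]]

    def test_inconsistent_id_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            GenotypeMatrix(
                sample_ids=np.array(["a"], dtype=object),
                snp_ids=np.array(["S1_123"], dtype=object),
                chromosome=np.array(["1"], dtype=object),
                position=np.array([99]),
                calls=np.array([[0]], dtype=np.int8),
                allele1=np.array(["A"], dtype=object),
                allele2=np.array(["C"], dtype=object),
            )

    def test_bad_code_rejected(self):
        with pytest.raises(ValueError, match="codes"):
            make_genotypes([[3]])
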