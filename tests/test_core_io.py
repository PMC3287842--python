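"""I/O round trips, allele-frequency folding, and gene–variant mapping."""

import numpy as np
import pandas as pd
import pytest

import rarepool as rp
from rarepool.core import GeneRegion


class TestMatrixTsv:
    def test_direct_echo(self, tmp_path):
        path = tmp_path / "g.tsv"
        path.write_text("sample_id\tv1\ns1\t0\ns2\t2\n")
        gm, variants = rp.read_genotypes(path)
        assert gm.counts.tolist() == [[0], [2]]
        assert list(variants["variant_id"]) == ["v1"]
        assert variants["maf"].isna().all()

    def test_empty_variant_set(self, tmp_path):
        path = tmp_path / "g.tsv"
        path.write_text("sample_id\ns1\ns2\n")
        gm, variants = rp.read_genotypes(path)
        assert gm.n_variants == 0 and len(variants) == 0

    def test_bad_genotype_names_location(self, tmp_path):
        path = tmp_path / "g.tsv"
        path.write_text("sample_id\tv1\tv2\ns1\t0\t1\ns2\t0\t3\n")
        with pytest.raises(rp.ValidationError, match="v2"):
            rp.read_genotypes(path)

    def test_missing_requires_policy(self, tmp_path):
        path = tmp_path / "g.tsv"
        path.write_text("sample_id\tv1\ns1\t.\ns2\t1\n")
        with pytest.raises(rp.ValidationError, match="missing"):
            rp.read_genotypes(path)
        gm, _ = rp.read_genotypes(path, missing_policy="zero")
        assert gm.counts.tolist() == [[0], [1]]

    def test_major_allele_folded_at_load(self, tmp_path):
        # column counts the common allele: f = 5/6 > 0.5, flipped on load
        path = tmp_path / "g.tsv"
        path.write_text("sample_id\tv1\ns1\t2\ns2\t2\ns3\t1\n")
        gm, _ = rp.read_genotypes(path)
        assert gm.counts.ravel().tolist() == [0, 0, 1]

    def test_synthetic_round_trip(self, tmp_path, tiny_dataset):
        ds = tiny_dataset
        gpath, vpath = tmp_path / "g.tsv", tmp_path / "v.tsv"
        rp.write_genotypes(ds.genotypes, ds.variants, gpath, vpath)
        gm, variants = rp.read_genotypes(gpath, variants_path=vpath)
        np.testing.assert_array_equal(gm.counts, ds.genotypes.counts)
        assert gm.sample_ids == ds.genotypes.sample_ids
        assert list(variants["variant_id"]) == list(ds.variants["variant_id"])


class TestVcfMinimal:
    VCF = (
        "##fileformat=VCFv4.2\n"
        "##contig=<ID=1>\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3\n"
    )

    def test_gt_to_minor_counts(self, tmp_path):
        path = tmp_path / "t.vcf"
        path.write_text(
            self.VCF
            + "1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n"
            + "1\t200\trs2\tC\tT\t.\t.\t.\tGT\t1/1\t1/1\t0/1\n"
        )
        gm, variants = rp.read_genotypes(path, format="vcf-minimal")
        # rs2 alt frequency is 5/6 so it is folded to the REF allele
        np.testing.assert_array_equal(gm.counts, [[0, 0], [1, 0], [2, 1]])
        assert list(variants["pos"]) == [100, 200]

    def test_multiallelic_rejected(self, tmp_path):
        path = tmp_path / "t.vcf"
        path.write_text(self.VCF + "1\t100\trs1\tA\tG,T\t.\t.\t.\tGT\t0/0\t0/1\t1/2\n")
        with pytest.raises(rp.ValidationError, match="multi-allelic"):
            rp.read_genotypes(path, format="vcf-minimal")


class TestComputeMaf:
    def test_all_zero_column(self):
        gm = rp.GenotypeMatrix(["a", "b", "c"], np.zeros((3, 1), dtype=int))
        assert rp.compute_maf(gm)["maf"].iloc[0] == 0.0

    def test_half_frequency(self):
        gm = rp.GenotypeMatrix(list("abcd"), np.array([[0], [1], [2], [1]]))
        assert rp.compute_maf(gm)["maf"].iloc[0] == 0.5

    def test_matches_per_allele_tally(self, rng):
        counts = rng.integers(0, 3, size=(30, 50))
        gm = rp.GenotypeMatrix([f"s{i}" for i in range(30)], counts)
        maf = rp.compute_maf(gm)["maf"].to_numpy()
        for i in range(50):  # brute-force per-allele tally
            minor = 0
            for j in range(30):
                minor += counts[j, i]
            f = minor / 60
            assert maf[i] == pytest.approx(min(f, 1 - f))

    def test_folding_and_reorder_invariance(self, rng):
        counts = rng.integers(0, 3, size=(20, 5))
        gm = rp.GenotypeMatrix([f"s{i}" for i in range(20)], counts)
        maf = rp.compute_maf(gm)["maf"].to_numpy()
        flipped = rp.GenotypeMatrix(gm.sample_ids, 2 - counts)
        np.testing.assert_allclose(rp.compute_maf(flipped)["maf"].to_numpy(), maf)
        perm = rng.permutation(20)
        shuffled = rp.GenotypeMatrix([gm.sample_ids[j] for j in perm], counts[perm])
        np.testing.assert_allclose(rp.compute_maf(shuffled)["maf"].to_numpy(), maf)


class TestGeneMapping:
    def test_boundaries_inclusive(self):
        variants = pd.DataFrame(
            {"variant_id": ["a", "b", "c"], "chrom": "1", "pos": [10, 20, 21]}
        )
        idx = rp.map_variants_to_genes(variants, [GeneRegion("g", "1", 10, 20)])
        assert idx["g"].tolist() == [0, 1]

    def test_wrong_chromosome_excluded(self):
        variants = pd.DataFrame({"variant_id": ["a"], "chrom": "2", "pos": [10]})
        idx = rp.map_variants_to_genes(variants, [GeneRegion("g", "1", 1, 100)])
        assert idx["g"].size == 0

    def test_duplicate_gene_names_rejected(self):
        variants = pd.DataFrame({"variant_id": ["a"], "chrom": "1", "pos": [10]})
        regions = [GeneRegion("g", "1", 1, 5), GeneRegion("g", "1", 6, 9)]
        with pytest.raises(rp.ValidationError, match="duplicate"):
            rp.map_variants_to_genes(variants, regions)

    def test_matches_double_loop_oracle(self, rng):
        variants = pd.DataFrame(
            {
                "variant_id": [f"v{i}" for i in range(100)],
                "chrom": rng.choice(["1", "2"], 100),
                "pos": rng.integers(1, 1000, 100),
            }
        )
        regions = [
            GeneRegion(f"g{k}", rng.choice(["1", "2"]), int(s), int(s) + int(rng.integers(0, 300)))
            for k, s in enumerate(rng.integers(1, 900, 10))
        ]
        idx = rp.map_variants_to_genes(variants, regions)
        for r in regions:
            expect = [
                i
                for i in range(100)
                if variants["chrom"][i] == r.chrom and r.start <= variants["pos"][i] <= r.end
            ]
            assert idx[r.gene_name].tolist() == expect

    def test_order_invariance(self, rng):
        variants = pd.DataFrame(
            {"variant_id": [f"v{i}" for i in range(30)], "chrom": "1",
             "pos": rng.integers(1, 200, 30)}
        )
        regions = [GeneRegion(f"g{k}", "1", k * 20 + 1, k * 20 + 40) for k in range(5)]
        idx = rp.map_variants_to_genes(variants, regions)
        idx_rev = rp.map_variants_to_genes(variants, regions[::-1])
        assert {g: v.tolist() for g, v in idx.items()} == {
            g: v.tolist() for g, v in idx_rev.items()
        }


class TestPhenotypes:
    def _write(self, tmp_path, body):
        path = tmp_path / "p.tsv"
        path.write_text(body)
        return path

    def test_column_roles(self, tmp_path):
        path = self._write(
            tmp_path, "sample_id\tQ1\tAge\tSmoking\ns1\t0.5\t40\t0\ns2\t1.0\t50\t1\n"
        )
        t = rp.read_phenotypes(path, traits=["Q1"], covariates=["Age", "Smoking"])
        assert t.traits == ["Q1"] and t.covariates == ["Age", "Smoking"]

    def test_binary_value_out_of_range(self, tmp_path):
        path = self._write(tmp_path, "sample_id\tAff\ns1\t0\ns2\t2\n")
        with pytest.raises(rp.ValidationError, match="Aff"):
            rp.read_phenotypes(path, binary_traits=["Aff"])

    def test_join_error_lists_offenders(self, tmp_path):
        path = self._write(tmp_path, "sample_id\tQ1\ns1\t0.5\nsx\t1.0\n")
        with pytest.raises(rp.JoinError, match="sx"):
            rp.read_phenotypes(path, traits=["Q1"], genotype_sample_ids=["s1", "s2"])

    def test_round_trip(self, tmp_path, tiny_dataset):
        table = tiny_dataset.phenotype_frame()
        path = tmp_path / "p.tsv"
        rp.write_phenotypes(table, path)
        back = rp.read_phenotypes(
            path, traits=table.traits, covariates=table.covariates,
            replicate_col="replicate_id",
        )
        pd.testing.assert_frame_equal(
            back.data, table.data, check_dtype=False, check_exact=False, rtol=1e-9
        )


class TestResultsFile:
    def _results(self):
        mk = rp.TestResult
        return [
            mk("gB", "VT", 3, 1.5, 0.02, 0.1, 999, 0.25),
            mk("gA", "T1", 1, -0.3, None, None, 999, 0.8),
            mk("gA", "ZZ-not-testable", 0, None, None, None, 0, None, testable=False),
        ]

    def test_empty_gives_header_only(self, tmp_path):
        path = tmp_path / "r.tsv"
        rp.write_results([], path)
        assert path.read_text().strip() == "\t".join(
            ["gene", "test", "n_variants_used", "statistic", "optimal_threshold",
             "n_permutations", "p_value"]
        )

    def test_sorted_rows_and_round_trip(self, tmp_path):
        path = tmp_path / "r.tsv"
        rp.write_results(self._results(), path)
        back = rp.read_results(path)
        assert list(back["gene"]) == ["gA", "gB"]  # not-testable row omitted
        assert back["p_value"].tolist() == [0.8, 0.25]
        assert back["statistic"].tolist() == [-0.3, 1.5]
        assert back["optimal_threshold"].tolist()[1] == 0.02
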