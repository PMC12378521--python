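"""VCF/TSV round trips and the individual/marker QC filters."""

import numpy as np
import pytest

import gpeval as gp

VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID=chr1,length=100000>
##contig=<ID=chr2,length=50000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3
"""


def _write(tmp_path, body, name="panel.vcf"):
    path = tmp_path / name
    path.write_text(VCF_HEADER + body)
    return path


class TestReadVcf:
    def test_hand_checked_fixture(self, tmp_path):
        body = (
            "chr1\t100\tsnpA\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n"
            "chr1\t200\tsnpB\tC\tT\t.\tPASS\t.\tGT\t0/1\t0/1\t./.\n"
        )
        g = gp.read_vcf(_write(tmp_path, body))
        assert g.sample_ids == ["s1", "s2", "s3"]
        # snpA: ALT counts 0,1,2 -> freq 0.5, tie keeps ALT orientation
        np.testing.assert_array_equal(g.values[:, 0], [0, 1, 2])
        # snpB: counts 1,1,missing
        np.testing.assert_array_equal(g.values[:2, 1], [1, 1])
        assert g.mask[2, 1] and not g.mask[0, 0]
        assert [k.position for k in g.keys()] == [100, 200]
        assert g.keys()[0].id == "snpA"

    def test_non_biallelic_and_indels_dropped(self, tmp_path):
        rows = [
            "chr1\t100\ta\tA\tG\t.\t.\t.\tGT\t0/0\t0/1\t1/1",
            "chr1\t200\tb\tA\tG,T\t.\t.\t.\tGT\t0/0\t0/1\t1/1",  # triallelic
            "chr1\t300\tc\tA\tG\t.\t.\t.\tGT\t0/1\t0/1\t0/0",
            "chr1\t400\td\tAT\tA\t.\t.\t.\tGT\t0/0\t0/1\t1/1",  # indel
            "chr2\t100\te\tC\tT\t.\t.\t.\tGT\t1/1\t0/1\t0/0",
        ]
        g = gp.read_vcf(_write(tmp_path, "\n".join(rows) + "\n"))
        assert g.p == 3
        assert [k.id for k in g.keys()] == ["a", "c", "e"]

    def test_triallelic_only_among_five_keeps_four(self, tmp_path):
        rows = [
            f"chr1\t{100 * (i + 1)}\tsnp{i}\tA\t{'G,T' if i == 2 else 'G'}\t.\t.\t.\tGT\t0/0\t0/1\t1/1"
            for i in range(5)
        ]
        g = gp.read_vcf(_write(tmp_path, "\n".join(rows) + "\n"))
        assert g.p == 4

    def test_empty_panel_errors(self, tmp_path):
        body = "chr1\t100\ta\tA\tG,T\t.\t.\t.\tGT\t0/0\t0/1\t1/1\n"
        with pytest.raises(ValueError, match="no biallelic"):
            gp.read_vcf(_write(tmp_path, body))

    def test_write_read_round_trip(self, tmp_path, small_panel):
        path = tmp_path / "sim.vcf"
        gp.write_vcf(small_panel, path)
        back = gp.read_vcf(path)
        np.testing.assert_array_equal(back.values, small_panel.values)
        assert back.sample_ids == small_panel.sample_ids
        assert [str(k) for k in back.keys()] == [str(k) for k in small_panel.keys()]
        assert not back.mask.any()


class TestQc:
    def _panel_with_mask(self, values, mask):
        values = np.asarray(values, dtype=np.int8)
        n, p = values.shape
        layout = gp.GenomeLayout(
            (("chr1", 10_000),), (np.arange(1, p + 1) * 100,)
        )
        return gp.GenotypeMatrix(
            values=values,
            sample_ids=[f"s{i}" for i in range(n)],
            layout=layout,
            mask=np.asarray(mask, dtype=bool),
        )

    def test_individual_call_rate_rule(self):
        values = np.ones((4, 10), dtype=np.int8)
        values[:, ::2] = 0
        mask = np.zeros((4, 10), dtype=bool)
        mask[0, :5] = True  # individual 0 missing 50%
        g = self._panel_with_mask(values, mask)
        out, rep = gp.apply_qc(g, gp.QcThresholds(0.9, 0.0, 0.0))
        assert rep.individuals_removed == 1
        assert rep.removed_sample_ids == ["s0"]
        assert out.n == 3

    def test_maf_boundary_strictly_below(self):
        # 25 individuals: one SNP with MAF 0.02 (1 of 50 alleles), one with 0.05ate
        n = 50
        values = np.zeros((n, 3), dtype=np.int8)
        values[0, 0] = 2  # maf 2/100 = 0.02 -> removed
        values[:5, 1] = 1  # maf 5/100 = 0.05 -> retained (rule is strictly <)
        values[: n // 2, 2] = 1  # maf 0.25
        g = self._panel_with_mask(values, np.zeros_like(values, dtype=bool))
        out, rep = gp.apply_qc(g, gp.QcThresholds(0.9, 0.9, 0.05))
        assert rep.snps_low_maf == 1
        assert out.p == 2
        assert [k.position for k in out.keys()] == [200, 300]

    def test_complete_matrix_is_noop(self, small_panel):
        out, rep = gp.apply_qc(small_panel, gp.QcThresholds())
        removed = small_panel.p - out.p
        assert rep.individuals_removed == 0
        assert rep.snps_low_call_rate == 0
        assert rep.genotypes_imputed == 0
        assert rep.snps_low_maf == removed  # only low-MAF sim markers can go

    def test_qc_idempotent(self, tmp_path, small_panel):
        rng = np.random.default_rng(5)
        mask = rng.random(small_panel.values.shape) < 0.05
        g = gp.GenotypeMatrix(
            values=small_panel.values.copy(),
            sample_ids=list(small_panel.sample_ids),
            layout=small_panel.layout,
            mask=mask,
        )
        once, _ = gp.apply_qc(g, gp.QcThresholds())
        twice, rep2 = gp.apply_qc(once, gp.QcThresholds())
        np.testing.assert_array_equal(once.values, twice.values)
        assert rep2.individuals_removed == 0
        assert rep2.snps_low_call_rate == 0
        assert rep2.snps_low_maf == 0

    def test_snp_call_rate_rule_and_imputation(self):
        rng = np.random.default_rng(9)
        values = rng.integers(0, 3, size=(20, 5)).astype(np.int8)
        mask = np.zeros_like(values, dtype=bool)
        mask[:15, 0] = True  # SNP 0 call rate 0.25 -> dropped
        mask[0, 1] = True  # SNP 1 one missing call -> imputed
        g = self._panel_with_mask(values, mask)
        out, rep = gp.apply_qc(g, gp.QcThresholds(0.0, 0.9, 0.0))
        assert rep.snps_low_call_rate == 1
        assert rep.genotypes_imputed == 1
        assert out.mask is None
        # imputed value is the rounded mean genotype of the non-missing calls
        # (up to the final minor-allele re-orientation of the column)
        expected = int(np.clip(np.rint(values[1:, 1].mean()), 0, 2))
        assert out.values[0, 0] in (expected, 2 - expected)

    def test_all_individuals_removed_errors(self):
        values = np.zeros((3, 4), dtype=np.int8)
        mask = np.ones_like(values, dtype=bool)
        g = self._panel_with_mask(values, mask)
        with pytest.raises(ValueError, match="all individuals"):
            gp.apply_qc(g, gp.QcThresholds(0.9, 0.9, 0.05))


class TestTables:
    def test_phenotype_alignment_shuffled(self, tmp_path, small_panel):
        rng = np.random.default_rng(3)
        ids = list(small_panel.sample_ids)
        y = rng.normal(size=len(ids))
        order = rng.permutation(len(ids))
        path = tmp_path / "phen.tsv"
        with open(path, "w") as fh:
            fh.write("sample_id\tvalue\n")
            for i in order:
                fh.write(f"{ids[i]}\t{y[i]}\n")
        ph = gp.read_phenotypes(path, small_panel)
        np.testing.assert_allclose(ph.y, y)
        assert ph.sample_ids == ids

    def test_unknown_and_duplicate_ids_error(self, tmp_path, small_panel):
        path = tmp_path / "phen.tsv"
        path.write_text("sample_id\tvalue\nghost\t1.0\n")
        with pytest.raises(ValueError, match="ghost"):
            gp.read_phenotypes(path, small_panel)
        sid = small_panel.sample_ids[0]
        path.write_text(f"sample_id\tvalue\n{sid}\t1.0\n{sid}\t2.0\n")
        with pytest.raises(ValueError, match="duplicated"):
            gp.read_phenotypes(path, small_panel)

    def test_phenotype_round_trip(self, tmp_path, small_panel, small_trait):
        path = tmp_path / "phen.tsv"
        gp.write_phenotypes(small_trait, path)
        back = gp.read_phenotypes(path, small_panel)
        np.testing.assert_allclose(back.y, small_trait.y)

    def test_snp_list_round_trip(self, tmp_path):
        rng = np.random.default_rng(17)
        keys = [
            gp.SnpKey(f"chr{rng.integers(1, 5)}", int(p), f"id{i}")
            for i, p in enumerate(np.sort(rng.choice(10**6, 1000, replace=False)))
        ]
        path = tmp_path / "panel.snps"
        gp.write_snp_list(keys, path)
        assert gp.read_snp_list(path) == keys
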