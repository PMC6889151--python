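import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import grskit as gk
from grskit.errors import FormatError, HarmonizationError, ValidationError
from grskit.genotypes import _orient


def make_pheno(sample_ids, statuses=None):
    n = len(sample_ids)
    if statuses is None:
        statuses = [1] * (n // 2) + [0] * (n - n // 2)
    return pd.DataFrame(
        {
            "sample_id": sample_ids,
            "status": statuses,
            "sex": ["male"] * n,
            "age_group": ["7-9"] * n,
            "country": ["SE"] * n,
        }
    )


class TestDosageTsv:
    def test_counted_allele_from_column_name(self, tmp_path):
        path = tmp_path / "d.tsv"
        path.write_text(
            "sample_id\trs2736100_C_A\nx1\t2\nx2\t0\nx3\tNA\n"
        )
        records, samples = gk.read_dosage_tsv(path)
        assert samples == ["x1", "x2", "x3"]
        (rec,) = records
        assert (rec.allele_a, rec.allele_b) == ("C", "A")
        np.testing.assert_array_equal(rec.dosages[:2], [2.0, 0.0])
        assert np.isnan(rec.dosages[2])

    def test_cell_out_of_range_rejected(self, tmp_path):
        path = tmp_path / "d.tsv"
        path.write_text("sample_id\trs1_A_G\nx1\t3\n")
        with pytest.raises(ValidationError, match="rs1_A_G"):
            gk.read_dosage_tsv(path)

    def test_unparsable_column_rejected(self, tmp_path):
        path = tmp_path / "d.tsv"
        path.write_text("sample_id\trs1-A-G\nx1\t1\n")
        with pytest.raises(FormatError):
            gk.read_dosage_tsv(path)

    def test_five_snp_four_sample_file(self, tmp_path, bundled_weights):
        header = "sample_id\t" + "\t".join(
            f"{w.snp_id}_{w.risk_allele}_{w.other_allele}" for w in bundled_weights
        )
        body = "\n".join(f"s{i}\t" + "\t".join(["0", "1", "2", "1", "0"]) for i in range(4))
        (tmp_path / "d.tsv").write_text(header + "\n" + body + "\n")
        records, samples = gk.read_dosage_tsv(tmp_path / "d.tsv")
        assert len(records) == 5 and len(samples) == 4


class TestVcf:
    def test_round_trip_through_simulator_writer(self, tmp_path, bundled_weights):
        cohort, _ = gk.sample_cohort(gk.SimulationSpec(n_cases=3, n_controls=4, seed=5))
        gk.write_vcf(cohort, tmp_path / "g.vcf")
        records, samples = gk.read_vcf(tmp_path / "g.vcf")
        assert samples == cohort.sample_ids
        matrix = np.column_stack([r.dosages for r in records])
        np.testing.assert_array_equal(matrix, cohort.dosage_matrix)
        # ALT is the risk allele in the writer's convention
        for rec, w in zip(records, bundled_weights):
            assert (rec.allele_a, rec.allele_b) == (w.risk_allele, w.other_allele)

    def test_missing_and_het_calls(self, tmp_path):
        vcf = (
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=1>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3\n"
            "1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0/1\t./.\t1/1\n"
        )
        (tmp_path / "t.vcf").write_text(vcf)
        (rec,), samples = gk.read_vcf(tmp_path / "t.vcf")
        assert rec.dosages[0] == 1.0
        assert np.isnan(rec.dosages[1])
        assert rec.dosages[2] == 2.0

    def test_multiallelic_records_skipped(self, tmp_path, caplog):
        vcf = (
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=1>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\n"
            "1\t100\trs1\tA\tG,T\t.\tPASS\t.\tGT\t0/1\n"
            "1\t200\trs2\tA\tG\t.\tPASS\t.\tGT\t0/0\n"
        )
        (tmp_path / "t.vcf").write_text(vcf)
        with caplog.at_level("WARNING"):
            records, _ = gk.read_vcf(tmp_path / "t.vcf")
        assert [r.snp_id for r in records] == ["rs2"]
        assert any("non-biallelic" in m for m in caplog.messages)


class TestHarmonize:
    WEIGHT = gk.SnpWeight("rs9", "1", 100, "C", "A", 1.3)

    def record(self, counted, other, dosages):
        return gk.GenotypeRecord("rs9", "1", 100, counted, other, np.array(dosages, float))

    def test_identity_kept(self):
        d = _orient(self.record("C", "A", [0, 1, 2]), self.WEIGHT)
        np.testing.assert_array_equal(d, [0, 1, 2])

    def test_flip_when_other_allele_counted(self):
        d = _orient(self.record("A", "C", [2, 1, 0]), self.WEIGHT)
        np.testing.assert_array_equal(d, [0, 1, 2])

    def test_all_presentations_agree(self):
        """Any strand/orientation re-coding of a non-palindromic SNP yields
        the same oriented dosages (enumeration oracle)."""
        truth = np.array([0.0, 1.0, 2.0, np.nan])
        presentations = []
        for counted, other in [("C", "A"), ("A", "C"), ("G", "T"), ("T", "G")]:
            counts_risk = counted in ("C", "G")  # C or its complement G
            stored = truth if counts_risk else 2.0 - truth
            presentations.append(self.record(counted, other, stored))
        for rec in presentations:
            np.testing.assert_array_equal(_orient(rec, self.WEIGHT), truth)

    @given(st.lists(st.sampled_from([0.0, 1.0, 2.0]), min_size=1, max_size=20))
    @settings(deadline=None)
    def test_flip_involution(self, dosages):
        d = np.array(dosages)
        np.testing.assert_array_equal(2.0 - (2.0 - d), d)

    def test_missingness_preserved(self, bundled_weights):
        n = 6
        records = [
            gk.GenotypeRecord(
                w.snp_id, w.chrom, w.pos_bp, w.other_allele, w.risk_allele,
                np.array([0, 1, 2, np.nan, 1, np.nan]),
            )
            for w in bundled_weights
        ]
        pheno = make_pheno([f"s{i}" for i in range(n)])
        cohort = gk.harmonize(records, bundled_weights, pheno, [f"s{i}" for i in range(n)])
        assert np.isnan(cohort.dosage_matrix).sum(axis=0).tolist() == [2] * 5

    def test_missing_snp_listed(self, bundled_weights):
        records = [
            gk.GenotypeRecord("rs2736100", "5", 1, "C", "A", np.zeros(2)),
        ]
        pheno = make_pheno(["a", "b"])
        with pytest.raises(gk.MissingSnpError, match="rs4977756"):
            gk.harmonize(records, bundled_weights, pheno, ["a", "b"])

    def test_irreconcilable_alleles(self):
        rec = self.record("G", "A", [0, 1])  # G/A cannot be oriented to C/A
        pheno = make_pheno(["a", "b"])
        with pytest.raises(HarmonizationError, match="rs9"):
            gk.harmonize([rec], [self.WEIGHT], pheno, ["a", "b"])

    def test_palindromic_excluded_by_default(self):
        weight_pal = gk.SnpWeight("rsP", "1", 5, "A", "T", 1.2)
        rec = gk.GenotypeRecord("rsP", "1", 5, "A", "T", np.array([1.0, 1.0]))
        pheno = make_pheno(["a", "b"])
        cohort = gk.harmonize([rec], [weight_pal], pheno, ["a", "b"])
        assert cohort.n_snps == 0
        kept = gk.harmonize(
            [rec], [weight_pal], pheno, ["a", "b"],
            palindromic=gk.PalindromicPolicy.KEEP,
        )
        assert kept.n_snps == 1
        with pytest.raises(HarmonizationError):
            gk.harmonize(
                [rec], [weight_pal], pheno, ["a", "b"],
                palindromic=gk.PalindromicPolicy.ERROR,
            )


class TestPhenotypes:
    def test_read_and_categories(self, tmp_path):
        path = tmp_path / "p.tsv"
        path.write_text(
            "sample_id\tstatus\tsex\tage_group\tcountry\n"
            "a\t1\tmale\t7-9\tSE\nb\t0\tfemale\t15-19\tCH\n"
        )
        pheno = gk.read_phenotypes(path)
        assert list(pheno["status"]) == [1, 0]
        assert list(pheno["sex"].cat.categories) == ["male", "female"]

    def test_duplicate_sample_rejected(self, tmp_path):
        path = tmp_path / "p.tsv"
        path.write_text(
            "sample_id\tstatus\tsex\tage_group\tcountry\n"
            "a\t1\tmale\t7-9\tSE\na\t0\tmale\t7-9\tSE\n"
        )
        with pytest.raises(ValidationError, match="duplicate"):
            gk.read_phenotypes(path)

    def test_unknown_level_rejected(self, tmp_path):
        path = tmp_path / "p.tsv"
        path.write_text(
            "sample_id\tstatus\tsex\tage_group\tcountry\n"
            "a\t1\tmale\t7-9\tFI\n"
        )
        with pytest.raises(ValidationError, match="country"):
            gk.read_phenotypes(path)
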