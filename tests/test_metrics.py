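"""Conventional QC metrics: ti/tv, dbSNP fraction, het-AF variance, GC."""
from __future__ import annotations

import numpy as np
import pytest

from exosds.metrics import (
    af_concordance,
    dbsnp_fraction,
    dropout_candidates,
    flanking_gc,
    het_af_variance,
    qc_report,
    titv_ratio,
)
from exosds.simulate import PanelSpec, simulate_panel
from exosds.types import GenomicSite, TargetRegion

from conftest import make_set


@pytest.fixture
def region():
    return TargetRegion([("chr1", 0, 100_000)])


class TestTiTv:
    def test_three_transitions_one_transversion(self, region):
        x = make_set(
            "s", region,
            [
                ("chr1", 10, "A", "A", "G"),   # ti
                ("chr1", 20, "C", "C", "T"),   # ti
                ("chr1", 30, "G", "A", "G"),   # ti
                ("chr1", 40, "A", "A", "C"),   # tv
            ],
        )
        assert titv_ratio(x) == pytest.approx(3.0)

    def test_all_transitions_rejected(self, region):
        x = make_set("s", region, [("chr1", 10, "A", "A", "G")])
        with pytest.raises(ValueError, match="no transversions"):
            titv_ratio(x)

    def test_empty_set_rejected(self, region):
        with pytest.raises(ValueError, match="empty"):
            titv_ratio(make_set("s", region, []))


class TestDbsnpFraction:
    def test_fractions(self, region):
        calls = [("chr1", 10 * i, "A", "A", "G") for i in range(1, 101)]
        x = make_set("s", region, calls)
        known_all = {("chr1", 10 * i) for i in range(1, 101)}
        assert dbsnp_fraction(x, known_all) == 1.0
        assert dbsnp_fraction(x, {("chr2", 5)}) == 0.0
        known_97 = {("chr1", 10 * i) for i in range(1, 98)}
        assert dbsnp_fraction(x, known_97) == pytest.approx(0.97)

    def test_empty_inputs_rejected(self, region):
        with pytest.raises(ValueError):
            dbsnp_fraction(make_set("s", region, []), {("chr1", 10)})


def write_ad_vcf(path, rows):
    header = (
        "##fileformat=VCFv4.2\n"
        "##contig=<ID=chr1,length=100000>\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
    )
    path.write_text(header + "".join(rows), encoding="utf-8")
    return str(path)


class TestHetAfVariance:
    def test_balanced_hets_have_zero_variance(self, tmp_path, region):
        vcf = write_ad_vcf(
            tmp_path / "a.vcf",
            [
                f"chr1\t{pos}\t.\tA\tG\t.\tPASS\t.\tGT:AD\t0/1:25,25\n"
                for pos in (100, 200, 300)
            ],
        )
        assert het_af_variance(vcf, region) == pytest.approx(0.0)

    def test_hand_computed_sample_variance(self, tmp_path, region):
        vcf = write_ad_vcf(
            tmp_path / "a.vcf",
            [
                "chr1\t100\t.\tA\tG\t.\tPASS\t.\tGT:AD\t0/1:30,20\n",  # AF 0.4
                "chr1\t200\t.\tC\tT\t.\tPASS\t.\tGT:AD\t0/1:20,30\n",  # AF 0.6
            ],
        )
        assert het_af_variance(vcf, region) == pytest.approx(0.02)

    def test_matches_binomial_sampling_variance(self, tmp_path, region):
        """Depth-50 binomial read counts at 1,000 hets give variance near
        p(1-p)/n = 0.005."""
        rng = np.random.default_rng(4)
        rows = []
        for i in range(1, 1001):
            alt = int(rng.binomial(50, 0.5))
            rows.append(f"chr1\t{i * 10}\t.\tA\tG\t.\tPASS\t.\tGT:AD\t0/1:{50 - alt},{alt}\n")
        vcf = write_ad_vcf(tmp_path / "b.vcf", rows)
        var = het_af_variance(vcf, region)
        se = 0.005 * np.sqrt(2 / 999)  # SE of a sample variance, normal approx
        assert var == pytest.approx(0.005, abs=4 * se)

    def test_missing_ad_rejected(self, tmp_path, region):
        header = (
            "##fileformat=VCFv4.2\n##contig=<ID=chr1,length=100000>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
            "chr1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0/1\n"
        )
        path = tmp_path / "noad.vcf"
        path.write_text(header, encoding="utf-8")
        with pytest.raises(ValueError, match="AD"):
            het_af_variance(str(path), region)


class TestFlankingGc:
    def write_fasta(self, path, name, seq):
        path.write_text(f">{name}\n{seq}\n", encoding="utf-8")
        return str(path)

    def test_all_g_contig(self, tmp_path):
        fasta = self.write_fasta(tmp_path / "g.fa", "chr1", "G" * 400)
        [gc] = flanking_gc([GenomicSite("chr1", 200, "G")], fasta, flank_bp=100)
        assert gc == 1.0

    def test_alternating_at_contig(self, tmp_path):
        fasta = self.write_fasta(tmp_path / "at.fa", "chr1", "AT" * 200)
        [gc] = flanking_gc([GenomicSite("chr1", 200, "T")], fasta, flank_bp=100)
        assert gc == 0.0

    def test_hand_built_window_fraction(self, tmp_path):
        left = "G" * 50 + "A" * 50
        right = "C" * 30 + "T" * 70
        seq = "A" * 100 + left + "A" + right + "A" * 100
        fasta = self.write_fasta(tmp_path / "w.fa", "chr1", seq)
        [gc] = flanking_gc([GenomicSite("chr1", 201, "A")], fasta, flank_bp=100)
        assert gc == pytest.approx(0.40)

    def test_strand_symmetry(self, tmp_path):
        rng = np.random.default_rng(6)
        seq = "".join(rng.choice(list("ACGT"), size=401))
        comp = str.maketrans("ACGT", "TGCA")
        rc = seq.translate(comp)[::-1]
        f1 = self.write_fasta(tmp_path / "f.fa", "chr1", seq)
        f2 = self.write_fasta(tmp_path / "r.fa", "chr1", rc)
        base_f = seq[200]
        [gc1] = flanking_gc([GenomicSite("chr1", 201, base_f if base_f in "ACGT" else "A")], f1)
        [gc2] = flanking_gc([GenomicSite("chr1", 201, rc[200])], f2)
        assert gc1 == pytest.approx(gc2)

    def test_out_of_bounds_site_rejected(self, tmp_path):
        fasta = self.write_fasta(tmp_path / "s.fa", "chr1", "G" * 150)
        with pytest.raises(ValueError, match="bounds"):
            flanking_gc([GenomicSite("chr1", 10, "G")], fasta, flank_bp=100)


class TestAfConcordance:
    def test_identical_groups_on_diagonal(self, region):
        group = [
            make_set(f"s{i}", region, [("chr1", 100, "A", "A", "G")]) for i in range(3)
        ]
        points = af_concordance(group, [g.copy(f"t{i}") for i, g in enumerate(group)])
        assert all(p.freq_a == p.freq_b for p in points)
        assert not any(p.outlier for p in points)

    def test_coverage_of_binomial_envelope(self):
        """Two m=85 groups from identical frequencies: ~95% of pairs fall
        inside the 2-SD envelope (tolerance +/-3%)."""
        spec = PanelSpec(
            n_individuals=170, region_size=400_000, n_variant_sites=2_000,
            af_spectrum=("uniform", 0.05, 0.5), seed=1,
        )
        _, members = simulate_panel(spec)
        points = af_concordance(members[:85], members[85:])
        inside = np.mean([not p.outlier for p in points])
        assert inside == pytest.approx(0.95, abs=0.03)

    def test_false_negatives_surface_below_diagonal(self, region):
        """Dropping a common variant from every group-b member makes that
        site an outlier with freq_b < freq_a."""
        common = ("chr1", 500, "A", "A", "G")
        group_a = [make_set(f"a{i}", region, [common]) for i in range(20)]
        group_b = [make_set(f"b{i}", region, []) for i in range(20)]
        points = af_concordance(group_a, group_b)
        [pt] = [p for p in points if p.site == ("chr1", 500)]
        assert pt.outlier and pt.freq_b < pt.freq_a
        assert pt.carriers_a == 20 and pt.carriers_b == 0
        hits = dropout_candidates(points, m_a=20)
        assert pt in hits

    def test_empty_group_rejected(self, region):
        with pytest.raises(ValueError):
            af_concordance([], [make_set("b", region, [])])


def test_qc_report_bundles_available_metrics(region, tmp_path):
    x = make_set(
        "s", region,
        [("chr1", 10, "A", "A", "G"), ("chr1", 20, "C", "C", "A")],
    )
    report = qc_report(x, known={("chr1", 10)})
    assert report.titv == pytest.approx(1.0)
    assert report.dbsnp_fraction == pytest.approx(0.5)
    assert report.het_af_variance is None
    assert report.n_variants == 2
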