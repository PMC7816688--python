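import numpy as np
import pytest

from gvpop import snpio, synth
from gvpop.snpio import (
    OrfRecord,
    SnpIOError,
    read_annotation,
    read_count_table,
    read_reference,
    read_vcf_counts,
    validate_site_depths,
    write_count_table,
    write_reference,
    write_vcf_counts,
)

from conftest import build_matrix, random_matrix


class TestCountTable:
    def test_two_row_toy_roundtrip(self, tmp_path):
        m = build_matrix(
            positions=[10, 20],
            ref_bases=["A", "C"],
            isolate_counts={
                "x": [{"A": 90, "G": 10}, {"C": 50}],
                "y": [{"A": 100}, {"C": 30, "T": 20}],
                "z": [{"G": 80}, {"C": 80}],
            },
        )
        path = tmp_path / "counts.tsv"
        write_count_table(m, path)
        back = read_count_table(path)
        assert back.equals(m)
        assert back.n_sites == 2 and back.isolates == ["x", "y", "z"]

    def test_roundtrip_random_matrices(self, tmp_path):
        for seed in range(100):
            rng = np.random.default_rng(seed)
            m = random_matrix(rng, n_isolates=3, n_sites=8)
            path = tmp_path / f"m{seed}.tsv"
            write_count_table(m, path)
            assert read_count_table(path).equals(m)

    def test_declared_depth_conservation_violation(self):
        m = build_matrix([5], ["A"], {"x": [{"A": 50}]})
        with pytest.raises(SnpIOError, match="depth mismatch"):
            validate_site_depths(m, np.array([[60]]))

    @pytest.mark.parametrize(
        "positions,ref,err",
        [
            ([10, 10], ["A", "A"], "duplicate"),
            ([0], ["A"], "outside"),
            ([10_001], ["A"], "outside"),
            ([10], ["N"], "non-ACGT"),
        ],
    )
    def test_invalid_matrices_rejected(self, positions, ref, err):
        with pytest.raises(SnpIOError, match=err):
            build_matrix(positions, ref, {"x": [{"A": 1} for _ in positions]})

    def test_negative_count_rejected(self, tmp_path):
        path = tmp_path / "neg.tsv"
        path.write_text("position\tref\tx:A\tx:C\tx:G\tx:T\n10\tA\t-5\t0\t0\t0\n")
        with pytest.raises(SnpIOError, match="negative"):
            read_count_table(path)

    def test_malformed_header_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("pos\tbase\tx\n1\tA\t5\n")
        with pytest.raises(SnpIOError, match="header"):
            read_count_table(path)

    def test_parsing_is_row_order_independent(self, tmp_path):
        rng = np.random.default_rng(7)
        m = random_matrix(rng, n_isolates=3, n_sites=12)
        path = tmp_path / "sorted.tsv"
        write_count_table(m, path)
        lines = path.read_text().splitlines()
        shuffled = lines[:2] + list(rng.permutation(lines[2:]))
        path2 = tmp_path / "shuffled.tsv"
        path2.write_text("\n".join(shuffled) + "\n")
        assert read_count_table(path2).equals(read_count_table(path))

    def test_refalt_dialect(self, tmp_path):
        path = tmp_path / "s4.tsv"
        path.write_text(
            "position\tref\talt\ta:ref\ta:alt\tb:ref\tb:alt\n"
            "100\tA\tG\t120\t35\t90\t0\n"
            "200\tC\tT\t50\t50\t10\t80\n"
        )
        m = read_count_table(path, reference_length=1000)
        assert m.isolates == ["a", "b"]
        i_a, i_g = snpio.BASE_INDEX["A"], snpio.BASE_INDEX["G"]
        assert m.counts[0, 0, i_a] == 120 and m.counts[0, 0, i_g] == 35
        assert m.counts[0, 0].sum() == 155  # untyped bases carry zero


class TestFrequencies:
    def test_frequencies_sum_to_one_where_covered(self):
        rng = np.random.default_rng(3)
        m = random_matrix(rng)
        f = m.frequencies()
        depths = m.depths
        sums = f.sum(axis=2)
        assert np.allclose(sums[depths > 0], 1.0, atol=1e-9)
        assert (sums[depths == 0] == 0).all()
        assert ((f >= 0) & (f <= 1)).all()


class TestVcf:
    def _write(self, tmp_path, records):
        text = (
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=ref,length=5000>\n"
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="AD">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\n"
            + "".join(records)
        )
        path = tmp_path / "in.vcf"
        path.write_text(text)
        return path

    def test_biallelic_ad_mapping(self, tmp_path):
        path = self._write(
            tmp_path, ["ref\t50\t.\tA\tG\t.\tPASS\t.\tAD\t120,35\t10,2\n"]
        )
        m = read_vcf_counts(path)
        a, c, g, t = (snpio.BASE_INDEX[b] for b in "ACGT")
        assert m.counts[0, 0, a] == 120 and m.counts[0, 0, g] == 35
        assert m.counts[0, 0, c] == 0 and m.counts[0, 0, t] == 0

    def test_multiallelic_expansion(self, tmp_path):
        path = self._write(
            tmp_path, ["ref\t60\t.\tA\tG,T\t.\tPASS\t.\tAD\t100,20,15\t0,0,0\n"]
        )
        m = read_vcf_counts(path)
        a, g, t = (snpio.BASE_INDEX[b] for b in "AGT")
        assert m.counts[0, 0, a] == 100
        assert m.counts[0, 0, g] == 20
        assert m.counts[0, 0, t] == 15

    def test_missing_ad_field_rejected(self, tmp_path):
        path = tmp_path / "noad.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n##contig=<ID=ref,length=100>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\n"
            "ref\t5\t.\tA\tG\t.\tPASS\t.\tGT\t0/1\n"
        )
        with pytest.raises(SnpIOError, match="AD"):
            read_vcf_counts(path)

    def test_roundtrip_against_simulated_truth(self, tmp_path):
        ref, genotypes, _ = synth.make_panel(
            n_genotypes=2, n_private_snps=10, reference_length=20_000, seed=11
        )
        design = synth.MixtureDesign(
            {"p": {"ga": 1.0}, "q": {"ga": 0.4, "gb": 0.6}}
        )
        cfg = synth.SimulationConfig(depth=500, error_rate=0.0, seed=11)
        matrix, _ = synth.simulate_counts(ref, genotypes, design, cfg)
        path = tmp_path / "sim.vcf"
        write_vcf_counts(matrix, path)
        back = read_vcf_counts(path)
        assert back.equals(matrix)


class TestReference:
    def test_reference_roundtrip_and_length(self, tmp_path):
        rng = np.random.default_rng(5)
        ref = synth.random_reference(50_000, rng)
        path = tmp_path / "ref.fasta"
        write_reference(ref, path)
        back = read_reference(path)
        assert back.length == 50_000
        assert back.sequence == ref.sequence

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.fasta"
        path.write_text("")
        with pytest.raises(SnpIOError):
            read_reference(path)

    def test_multi_record_rejected(self, tmp_path):
        path = tmp_path / "two.fasta"
        path.write_text(">a\nACGT\n>b\nACGT\n")
        with pytest.raises(SnpIOError, match="single-record"):
            read_reference(path)

    def test_circular_base_access_wraps(self):
        ref = snpio.ReferenceGenome("r", "ACGT", circular=True)
        assert ref.base(5) == "A"
        assert ref.slice(4, 3) == "TAC"


class TestAnnotation:
    def test_plain_orf_length(self, tmp_path):
        path = tmp_path / "ann.tsv"
        path.write_text(
            "id\tstart\tend\tstrand\tfunction_class\n"
            "ORF1\t100\t1299\t+\tDNA replication\n"
        )
        orfs = read_annotation(path, reference_length=123_529)
        assert orfs[0].length == 1200 and not orfs[0].wraps

    def test_wraparound_length_matches_modular_arithmetic(self, tmp_path):
        path = tmp_path / "ann.tsv"
        path.write_text(
            "id\tstart\tend\tstrand\tfunction_class\n"
            "ORFW\t123000\t500\t+\tstructural protein\n"
        )
        L = 123_529
        orfs = read_annotation(path, reference_length=L)
        assert orfs[0].wraps
        # independent modular oracle
        assert orfs[0].length == (L - 123_000 + 1) + 500 == 1030
        assert orfs[0].contains(123_100) and orfs[0].contains(3)
        assert not orfs[0].contains(600)

    def test_unknown_function_class_rejected(self, tmp_path):
        path = tmp_path / "ann.tsv"
        path.write_text(
            "id\tstart\tend\tstrand\tfunction_class\n"
            "ORF1\t100\t399\t+\tvirus budding\n"
        )
        with pytest.raises(SnpIOError, match="unknown ORF function class"):
            read_annotation(path, reference_length=1000)

    def test_gff3_reading(self, tmp_path):
        path = tmp_path / "ann.gff3"
        path.write_text(
            "##gff-version 3\n"
            "ref\tsrc\tCDS\t100\t1299\t.\t+\t0\t"
            "ID=ORF1;function_class=metabolic process\n"
        )
        orfs = read_annotation(path, reference_length=5000)
        assert len(orfs) == 1
        assert orfs[0].id == "ORF1"
        assert orfs[0].function_class == "metabolic process"

    def test_coordinates_out_of_range_rejected(self):
        with pytest.raises(SnpIOError, match="outside reference"):
            OrfRecord("x", 10, 99_999, "+", "unknown", 1000)
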