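import numpy as np
import pytest
from Bio.Seq import Seq
from scipy import stats as sstats

from gvpop.orf_stats import (
    category_tallies,
    classify_all,
    classify_snp,
    compare_classes,
    density_table,
    is_transition,
    revcomp,
    tukey_transform,
)
from gvpop.snpio import OrfRecord, ReferenceGenome


def make_reference(rng, length=6000):
    seq = "".join(rng.choice(list("ACGT"), size=length))
    return ReferenceGenome("toy", seq, circular=True)


def random_annotation(rng, L):
    """Non-overlapping ORFs incl. one wrap-around and mixed strands."""
    orfs = [OrfRecord("ORFW", L - 299, 300, "+", "unknown", L)]  # 600 nt wrap
    cursor = 400
    i = 1
    while cursor + 900 < L - 400:
        length = 3 * int(rng.integers(60, 200))
        strand = "+" if rng.random() < 0.5 else "-"
        orfs.append(
            OrfRecord(f"ORF{i}", cursor, cursor + length - 1, strand,
                      "unknown", L)
        )
        cursor += length + int(rng.integers(20, 120))
        i += 1
    return orfs


def oracle_synonymy(reference, orf, position, alt_base):
    """Independent oracle: rebuild both genomes, extract and translate the ORF."""
    L = reference.length
    mutated = list(reference.sequence)
    mutated[position - 1] = alt_base
    mutated = "".join(mutated)

    def cds(genome):
        if orf.wraps:
            s = genome[orf.start - 1 :] + genome[: orf.end]
        else:
            s = genome[orf.start - 1 : orf.end]
        return s if orf.strand == "+" else str(Seq(s).reverse_complement())

    return str(Seq(cds(reference.sequence)).translate()) == str(
        Seq(cds(mutated)).translate()
    )


class TestClassification:
    def _plus_orf_reference(self):
        rng = np.random.default_rng(0)
        ref = make_reference(rng)
        orf = OrfRecord("ORF1", 100, 1299, "+", "DNA replication", ref.length)
        return ref, orf

    @pytest.mark.parametrize("position,codon_pos", [(100, 1), (101, 2), (102, 3),
                                                    (1299, 3)])
    def test_codon_position_frame_arithmetic(self, position, codon_pos):
        ref, orf = self._plus_orf_reference()
        base = ref.base(position)
        alt = "A" if base != "A" else "G"
        eff = classify_snp(position, base, alt, [orf], ref)
        assert eff.hits[0].codon_position == codon_pos

    def test_third_position_gga_to_ggg_synonymous(self):
        seq = "ATG" + "GGA" + "TAA" + "A" * 91  # 100 nt linear-ish toy
        ref = ReferenceGenome("t", seq, circular=True)
        orf = OrfRecord("O1", 1, 9, "+", "unknown", ref.length)
        eff = classify_snp(6, "A", "G", [orf], ref)
        assert eff.hits[0].ref_codon == "GGA"
        assert eff.hits[0].alt_codon == "GGG"
        assert eff.hits[0].synonymous  # both glycine

    def test_noncoding_snp_has_no_hits(self):
        ref, orf = self._plus_orf_reference()
        eff = classify_snp(50, ref.base(50), "A" if ref.base(50) != "A" else "C",
                           [orf], ref)
        assert not eff.coding and eff.synonymous is None

    def test_alt_equals_ref_rejected(self):
        ref, orf = self._plus_orf_reference()
        with pytest.raises(ValueError):
            classify_snp(100, ref.base(100), ref.base(100), [orf], ref)

    def test_orf_length_not_multiple_of_three_rejected(self):
        ref, _ = self._plus_orf_reference()
        orf = OrfRecord("bad", 100, 301, "+", "unknown", ref.length)
        with pytest.raises(ValueError, match="divisible by 3"):
            classify_snp(150, ref.base(150), "A" if ref.base(150) != "A" else "C",
                         [orf], ref)

    def test_200_random_snps_match_whole_genome_translation_oracle(self):
        rng = np.random.default_rng(42)
        ref = make_reference(rng)
        annotation = random_annotation(rng, ref.length)
        n_checked = 0
        while n_checked < 200:
            pos = int(rng.integers(1, ref.length + 1))
            base = ref.base(pos)
            alt = str(rng.choice([b for b in "ACGT" if b != base]))
            eff = classify_snp(pos, base, alt, annotation, ref)
            for hit in eff.hits:
                orf = next(o for o in annotation if o.id == hit.orf_id)
                assert hit.synonymous == oracle_synonymy(ref, orf, pos, alt)
                n_checked += 1

    def test_strand_invariance_of_synonymy(self):
        """Reverse-complementing the genome and flipping annotations leaves
        synonymy calls unchanged."""
        rng = np.random.default_rng(7)
        ref = make_reference(rng)
        L = ref.length
        orf = OrfRecord("O1", 500, 1099, "+", "unknown", L)
        flipped_ref = ReferenceGenome("t2", revcomp(ref.sequence), circular=True)
        flipped_orf = OrfRecord("O1", L - 1099 + 1, L - 500 + 1, "-", "unknown", L)
        for _ in range(50):
            pos = int(rng.integers(500, 1100))
            base = ref.base(pos)
            alt = str(rng.choice([b for b in "ACGT" if b != base]))
            eff = classify_snp(pos, base, alt, [orf], ref)
            mirror_pos = L - pos + 1
            comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
            eff2 = classify_snp(
                mirror_pos, comp[base], comp[alt], [flipped_orf], flipped_ref
            )
            assert eff.hits[0].synonymous == eff2.hits[0].synonymous
            assert eff.hits[0].codon_position == eff2.hits[0].codon_position

    def test_overlapping_orfs_reported_per_orf_and_deduplicated(self):
        rng = np.random.default_rng(3)
        ref = make_reference(rng)
        o1 = OrfRecord("ORFa", 100, 399, "+", "unknown", ref.length)
        o2 = OrfRecord("ORFb", 300, 599, "+", "unknown", ref.length)
        base = ref.base(350)
        alt = "A" if base != "A" else "C"
        eff = classify_snp(350, base, alt, [o1, o2], ref)
        assert len(eff.hits) == 2 and eff.overlapping
        assert eff.primary_hit.orf_id == "ORFa"  # lowest id wins the tally
        tall = category_tallies([eff])
        assert tall["coding"] == 1 and tall["in_overlapping_orfs"] == 1
        # conservative genome-wide call: nonsynonymous if nonsyn in any frame
        if not all(h.synonymous for h in eff.hits):
            assert tall["nonsynonymous"] == 1

    def test_partition_and_transition_tallies(self):
        rng = np.random.default_rng(11)
        ref = make_reference(rng)
        annotation = random_annotation(rng, ref.length)
        positions = rng.choice(np.arange(1, ref.length + 1), 150, replace=False)
        refs = [ref.base(int(p)) for p in positions]
        alts = [str(rng.choice([b for b in "ACGT" if b != r])) for r in refs]
        effects = classify_all(positions, refs, alts, annotation, ref)
        tall = category_tallies(effects)
        assert tall["coding"] + tall["noncoding"] == 150
        assert tall["transitions"] + tall["transversions"] == 150
        assert tall["transitions"] == sum(
            is_transition(r, a) for r, a in zip(refs, alts)
        )
        assert (
            tall["codon_pos_1"] + tall["codon_pos_2"] + tall["codon_pos_3"]
            == tall["coding"]
        )


class TestDensity:
    def test_density_arithmetic(self):
        rng = np.random.default_rng(0)
        ref = make_reference(rng)
        orf = OrfRecord("O1", 100, 1299, "+", "metabolic process", ref.length)
        effects = []
        for pos in (150, 600, 900):
            base = ref.base(pos)
            alt = "A" if base != "A" else "C"
            effects.append(classify_snp(pos, base, alt, [orf], ref))
        stats_rows, summary = density_table(effects, [orf])
        assert stats_rows[0].snp_count == 3
        assert stats_rows[0].density == pytest.approx(2.5)  # 3 / 1.2 kbp

    def test_zero_snp_orf_is_conserved(self):
        from gvpop.orf_stats import conserved_orfs

        rng = np.random.default_rng(0)
        ref = make_reference(rng)
        orfs = [
            OrfRecord("O1", 100, 399, "+", "unknown", ref.length),
            OrfRecord("O2", 500, 799, "+", "unknown", ref.length),
        ]
        base = ref.base(150)
        eff = classify_snp(150, base, "A" if base != "A" else "C", orfs, ref)
        rows, _ = density_table([eff], orfs)
        assert conserved_orfs(rows) == ["O2"]
        assert rows[1].density == 0.0

    def test_designed_poisson_class_rates_recovered(self):
        """Class mean densities recover a designed Poisson intensity within
        two standard errors."""
        rng = np.random.default_rng(5)
        L = 200_000
        ref = ReferenceGenome("t", "".join(rng.choice(list("ACGT"), size=L)), True)
        orfs, effects = [], []
        rates = {"DNA replication": 3.0, "unknown": 6.0}  # SNPs per kbp
        cursor = 10
        i = 0
        for cls, rate in rates.items():
            for _ in range(100):
                length = 900
                orf = OrfRecord(f"O{i}", cursor, cursor + length - 1, "+", cls, L)
                orfs.append(orf)
                k = rng.poisson(rate * length / 1000)
                for pos in rng.choice(
                    np.arange(orf.start, orf.end + 1), size=k, replace=False
                ):
                    base = ref.base(int(pos))
                    alt = "A" if base != "A" else "C"
                    effects.append(classify_snp(int(pos), base, alt, [orf], ref))
                cursor += length + 10
                i += 1
        _, summary = density_table(effects, orfs)
        for _, row in summary.iterrows():
            assert abs(row["mean"] - rates[row["function_class"]]) <= 2 * row["sem"]


class TestTukeyTransform:
    def test_normal_sample_keeps_lambda_near_one(self):
        rng = np.random.default_rng(1)
        x = rng.normal(50, 5, size=200)
        _, lam = tukey_transform(x)
        assert abs(lam - 1.0) <= 0.3

    def test_lognormal_sample_drives_lambda_to_zero(self):
        rng = np.random.default_rng(2)
        x = np.exp(rng.normal(0, 1, size=200))
        _, lam = tukey_transform(x)
        assert abs(lam) <= 0.15

    def test_monotone_for_positive_lambda(self):
        rng = np.random.default_rng(3)
        x = rng.gamma(2, 2, size=50) + 0.1
        t, lam = tukey_transform(x)
        order = np.argsort(x)
        assert (np.diff(t[order]) >= 0).all()

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            tukey_transform(np.ones(10))


class TestCompareClasses:
    def test_hand_worked_three_group_anova(self):
        # groups: (1,2,3), (2,3,4), (6,7,8); hand-computed sums of squares:
        # grand mean 4, SSB = 3*((2-4)^2+(3-4)^2+(7-4)^2) = 42, SSW = 6
        # F = (42/2)/(6/6) = 21
        res = compare_classes(
            {"a": [1, 2, 3], "b": [2, 3, 4], "unknown": [6, 7, 8]}
        )
        assert res.anova_f == pytest.approx(21.0, abs=1e-10)
        assert (res.df_between, res.df_within) == (2, 6)

    def test_f_equals_t_squared_for_two_groups(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(0, 1, 12), rng.normal(1, 1, 15)
        res = compare_classes({"a": a, "unknown": b})
        assert res.anova_f == pytest.approx(res.t_statistic**2, rel=1e-10)

    def test_null_p_values_are_uniform(self):
        rng = np.random.default_rng(6)
        pvals = []
        for _ in range(1000):
            groups = {k: rng.normal(0, 1, 8) for k in ("a", "b", "c")}
            pvals.append(compare_classes(groups, hsd=False).anova_p)
        ks = sstats.kstest(pvals, "uniform")
        assert ks.pvalue > 1e-3

    def test_power_at_three_sd_separation(self):
        rng = np.random.default_rng(8)
        hits = 0
        n_sim = 200
        for _ in range(n_sim):
            known = rng.normal(0, 1, 20)
            unknown = rng.normal(3, 1, 20)
            res = compare_classes({"a": known, "unknown": unknown}, hsd=False)
            hits += res.t_p < 0.001
        assert hits / n_sim > 0.99

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            compare_classes({"a": [1.0, 1.0], "b": [1.0, 1.0]})
        with pytest.raises(ValueError):
            compare_classes({"a": [1.0], "b": [1.0, 2.0]})
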