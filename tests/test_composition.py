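import numpy as np
import pytest

from gvpop import synth
from gvpop.composition import (
    collapse_groups,
    mixture_pattern,
    parse_cell,
    quantify,
)
from gvpop.specificity import MarkerSet, assign_specificity, build_marker_sets
from gvpop.variant_filter import apply_filters

from conftest import build_matrix


def small_mixture(proportions, depth=2000, error=0.001, seed=0, n_snps=50):
    """Two-genotype panel with private marker sets; returns (fm, sets, truth)."""
    ref, genotypes, truth = synth.make_panel(2, n_snps, 60_000, seed=seed)
    design = synth.MixtureDesign(proportions)
    cfg = synth.SimulationConfig(depth=depth, error_rate=error, seed=seed)
    rng = np.random.default_rng([seed, 77])
    matrix, sim_truth = synth.simulate_counts(ref, genotypes, design, cfg, rng=rng)
    fm = apply_filters(matrix)
    sets = {
        g.id: MarkerSet(
            label=(g.id,), positions=tuple(sorted(p for p, _ in g.snps)),
            name=g.id,
        )
        for g in genotypes
    }
    return fm, sets, truth


class TestQuantify:
    def test_pure_genotype_zero_error_is_exactly_100(self):
        fm, sets, _ = small_mixture({"i1": {"ga": 1.0}}, error=0.0)
        (q,) = quantify(fm, [sets["ga"]], isolates=["i1"])
        assert (q.statistic, q.p5, q.p95) == (100.0, 100.0, 100.0)
        assert q.format_cell() == "100 (100–100)"

    def test_percentile_bracketing_everywhere(self):
        fm, sets, _ = small_mixture(
            {"i1": {"ga": 0.7, "gb": 0.3}, "i2": {"gb": 1.0}}, seed=3
        )
        for q in quantify(fm, list(sets.values())):
            assert 0 <= q.p5 <= q.statistic <= q.p95 <= 100

    def test_seventy_thirty_mixture_recovers_design(self):
        depth = 2000
        fm, sets, _ = small_mixture(
            {"i1": {"ga": 0.7, "gb": 0.3}}, depth=depth, seed=5
        )
        (q,) = quantify(fm, [sets["ga"]], isolates=["i1"])
        se = np.sqrt(0.7 * 0.3 / depth) * 100
        assert abs(q.statistic - 70.0) <= 3 * se

    def test_scale_equivariance(self):
        fm, sets, _ = small_mixture({"i1": {"ga": 0.6, "gb": 0.4}}, seed=6)
        fm_scaled = apply_filters(
            _scaled_matrix(fm, factor=7)
        )
        q1 = quantify(fm, list(sets.values()))
        q2 = quantify(fm_scaled, list(sets.values()))
        for a, b in zip(q1, q2):
            assert a.statistic == pytest.approx(b.statistic)
            assert a.p5 == pytest.approx(b.p5)
            assert a.p95 == pytest.approx(b.p95)

    def test_mean_statistic_exposed(self):
        fm, sets, _ = small_mixture({"i1": {"ga": 0.7, "gb": 0.3}}, seed=7)
        (qm,) = quantify(fm, [sets["ga"]], isolates=["i1"], statistic="mean")
        assert abs(qm.statistic - 70.0) < 5

    def test_empty_marker_set_rejected(self):
        fm, sets, _ = small_mixture({"i1": {"ga": 1.0}}, seed=8)
        with pytest.raises(ValueError):
            MarkerSet(label=("x",), positions=()).size or quantify(
                fm, [MarkerSet(label=("x",), positions=())]
            )

    def test_parameter_recovery_mean_error_below_one_point(self):
        """Over 100 seeded replicates at depth 2000, error 0.001, the absolute
        error of recovered proportions stays below one percentage point on
        average."""
        errors = []
        for rep in range(100):
            rng = np.random.default_rng([99, rep])
            p = 0.3 + 0.4 * rng.random()
            fm, sets, _ = small_mixture(
                {"i1": {"ga": p, "gb": 1 - p}}, depth=2000, seed=100 + rep,
                n_snps=25,
            )
            (q,) = quantify(fm, [sets["ga"]], isolates=["i1"])
            errors.append(abs(q.statistic - 100 * p))
        assert np.mean(errors) < 1.0


def _scaled_matrix(fm, factor):
    from gvpop.snpio import BASE_INDEX, SnpMatrix

    n, m = fm.depths.shape
    counts = np.zeros((n, m, 4), dtype=np.int64)
    rows = np.arange(n)
    ref_idx = np.array([BASE_INDEX[b] for b in fm.ref_bases])
    alt_idx = np.array([BASE_INDEX[b] for b in fm.alt_bases])
    other = fm.depths - fm.ref_counts - fm.alt_counts
    for j in range(m):
        counts[rows, j, ref_idx] += fm.ref_counts[:, j] * factor
        counts[rows, j, alt_idx] += fm.alt_counts[:, j] * factor
    # spread leftovers onto an arbitrary distinct base so depth conserves
    for j in range(m):
        for i in range(n):
            if other[i, j]:
                k = next(
                    b for b in range(4) if b not in (ref_idx[i], alt_idx[i])
                )
                counts[i, j, k] += int(other[i, j]) * factor
    return SnpMatrix(
        fm.reference_name, fm.reference_length, fm.isolates,
        fm.positions, fm.ref_bases, counts, circular=fm.circular,
    )


class TestMixturePattern:
    def test_fifty_fifty_pattern(self):
        ref, genotypes, _ = synth.make_panel(
            2, 40, 60_000, seed=21, shared_group_spec={("ga", "gb"): 30}
        )
        design = synth.MixtureDesign({"mix": {"ga": 0.5, "gb": 0.5}})
        cfg = synth.SimulationConfig(depth=2000, error_rate=0.001, seed=21)
        matrix, truth = synth.simulate_counts(ref, genotypes, design, cfg)
        fm = apply_filters(matrix)
        shared_pos = set(truth["snp_positions"]) & set(
            p for p, _ in genotypes[0].snps
        ) & set(p for p, _ in genotypes[1].snps)
        set_a = MarkerSet(("ga",), tuple(
            sorted(set(p for p, _ in genotypes[0].snps) - shared_pos)
        ))
        set_b = MarkerSet(("gb",), tuple(
            sorted(set(p for p, _ in genotypes[1].snps) - shared_pos)
        ))
        shared = MarkerSet(("ga", "gb"), tuple(sorted(shared_pos)))
        pat = mixture_pattern(fm, "mix", set_a, set_b, shared)
        assert pat.f_a == pytest.approx(0.5, abs=0.05)
        assert pat.f_b == pytest.approx(0.5, abs=0.05)
        assert pat.f_ab == pytest.approx(1.0, abs=0.02)

    def test_pure_genotype_pattern(self):
        fm, sets, _ = small_mixture({"i1": {"ga": 1.0}}, seed=22)
        pat = mixture_pattern(fm, "i1", sets["ga"], sets["gb"])
        assert pat.f_a == pytest.approx(1.0, abs=0.01)
        assert pat.f_b == pytest.approx(0.0, abs=0.01)

    def test_overlapping_sets_rejected(self):
        fm, sets, _ = small_mixture({"i1": {"ga": 1.0}}, seed=23)
        with pytest.raises(ValueError):
            mixture_pattern(fm, "i1", sets["ga"], sets["ga"])


class TestCollapse:
    SCHEME = {
        "A": frozenset("A"),
        "B": frozenset("B"),
        "D": frozenset("D"),
        "F": frozenset("F"),
        "G": frozenset("G"),
        "BDEFG": frozenset("BDEFG"),
        "DEFG": frozenset("DEFG"),
    }

    def test_combined_group_remainder(self):
        med = {"V": {"A": 33.0, "B": 40.0, "D": 0.0, "F": 0.0, "G": 0.2,
                     "BDEFG": 67.0, "DEFG": 28.0}}
        (res,) = collapse_groups(med, self.SCHEME)
        # BDEFG -> BE, DEFG -> E; B = BE - E
        assert res.proportions["B"] == pytest.approx(39.0)
        assert res.proportions["E"] == pytest.approx(28.0)
        assert any("BDEFG collapsed to BE" in n for n in res.notes)

    def test_zero_remainder(self):
        med = {"x": {"B": 50.0, "D": 0.0, "F": 0.0, "G": 0.0,
                     "BDEFG": 50.0, "DEFG": 50.0}}
        (res,) = collapse_groups(med, self.SCHEME)
        assert res.proportions["B"] == 0.0

    def test_negative_remainder_warns_and_clamps(self):
        med = {"x": {"B": 10.0, "D": 0.0, "F": 0.0, "G": 0.0,
                     "BDEFG": 30.0, "DEFG": 45.0}}
        (res,) = collapse_groups(med, self.SCHEME)
        assert res.proportions["B"] == 0.0
        assert any("heterogeneity" in n for n in res.notes)

    def test_three_genotype_mixture_recovery_from_simulation(self):
        """A 30/20/50 three-lineage mixture with designed combined sets is
        recovered within binomial tolerance through the collapse arithmetic."""
        ref, genotypes, _ = synth.make_panel(
            3, 30, 80_000, seed=31,
            shared_group_spec={("ga", "gb", "gc"): 0, ("gb", "gc"): 40},
        )
        # ga ~ lineage A; gb ~ B; gc ~ E; shared(gb, gc) ~ combined BE
        design = synth.MixtureDesign(
            {"mix": {"ga": 0.3, "gb": 0.2, "gc": 0.5}}
        )
        cfg = synth.SimulationConfig(depth=2000, error_rate=0.001, seed=31)
        matrix, _ = synth.simulate_counts(ref, genotypes, design, cfg)
        fm = apply_filters(matrix)
        shared = set(p for p, _ in genotypes[1].snps) & set(
            p for p, _ in genotypes[2].snps
        )
        def med(positions, iso="mix"):
            ms = MarkerSet(("m",), tuple(sorted(positions)))
            (q,) = quantify(fm, [ms], isolates=[iso])
            return q.statistic

        a_med = med(set(p for p, _ in genotypes[0].snps))
        be_med = med(shared)
        e_med = med(set(p for p, _ in genotypes[2].snps) - shared)
        group_meds = {"mix": {"A": a_med, "D": 0.0, "F": 0.0, "G": 0.0,
                              "BDEFG": be_med, "DEFG": e_med}}
        (res,) = collapse_groups(group_meds, self.SCHEME)
        assert a_med == pytest.approx(30.0, abs=3)
        assert res.proportions["E"] == pytest.approx(50.0, abs=3)
        assert res.proportions["B"] == pytest.approx(20.0, abs=4)


class TestCellFormat:
    def test_format_parse_roundtrip(self):
        fm, sets, _ = small_mixture({"i1": {"ga": 0.7, "gb": 0.3}}, seed=41)
        (q,) = quantify(fm, [sets["ga"]], isolates=["i1"])
        stat, p5, p95 = parse_cell(q.format_cell(digits=2))
        assert stat == pytest.approx(q.statistic, abs=0.01)
        assert p5 == pytest.approx(q.p5, abs=0.01)
        assert p95 == pytest.approx(q.p95, abs=0.01)
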