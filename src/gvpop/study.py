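"""The worked 20-isolate study analysis, end to end.

Glue used by the numbered analysis drivers, the acceptance script and the
regression tests: build the default synthetic panel, run filtering →
specificity → composition → ORF statistics → HCPC (and the repeat-locus
read counting), and collect the headline numbers of the analysis in one
dictionary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import composition, hcpc, orf_stats, pe38_repeats, specificity, synth
from .variant_filter import FilteredMatrix, apply_filters, flag_reference_anomalies


@dataclass
class StudyResult:
    panel: synth.StudyPanel
    matrix: object
    filtered: FilteredMatrix
    assignment: specificity.SpecificityAssignment
    marker_sets: list[specificity.MarkerSet]
    named_sets: dict[str, specificity.MarkerSet]
    quantifications: list[composition.MarkerSetQuantification]
    collapse: dict[str, composition.GroupProportions]
    anomalies: list[int]
    effects: list
    tallies: dict
    pca: hcpc.PcaResult
    hclust: hcpc.HclustResult
    hcpc_result: hcpc.HcpcResult


def named_marker_sets(
    sp: synth.StudyPanel, assignment: specificity.SpecificityAssignment
) -> dict[str, specificity.MarkerSet]:
    """Recover the lineage marker sets by their specificity labels.

    The sets are found in the *data* (by label), not taken from the design;
    only the label → lineage-name mapping and the quantification allele
    (reference allele for the reference-identity set) come from the scheme.
    """
    by_label = {s.label: s for s in specificity.build_marker_sets(assignment)}
    named = {}
    for name, meta in sp.marker_scheme.items():
        s = by_label.get(tuple(meta["label"]))
        if s is not None:
            named[name] = specificity.MarkerSet(
                s.label, s.positions, allele=meta["allele"], name=name
            )
    return named


def run_study(seed: int, n_invariant_sites: int = 400) -> StudyResult:
    sp, matrix = synth.study_matrix(seed, n_invariant_sites=n_invariant_sites)
    fm = apply_filters(matrix)
    assignment = specificity.assign_specificity(
        fm, within=list(synth.FIELD_ISOLATES)
    )
    marker_sets = specificity.build_marker_sets(assignment)
    named = named_marker_sets(sp, assignment)
    quants = composition.quantify(fm, list(named.values()))

    # group-collapse arithmetic on the isolates quantified via combined sets
    by_cell = {(q.set_name, q.isolate): q.statistic for q in quants}
    group_medians = {}
    for iso in fm.isolates:
        meds = {}
        for name in named:
            group = synth.STUDY_GROUP_OF_SET.get(name)
            if group is not None:
                meds[group] = by_cell[(name, iso)]
        group_medians[iso] = meds
    collapse = {
        g.isolate: g
        for g in composition.collapse_groups(group_medians, synth.STUDY_SCHEME)
    }

    effects = orf_stats.classify_all(
        fm.positions, fm.ref_bases, fm.alt_bases, sp.annotation, sp.reference
    )
    tallies = orf_stats.category_tallies(effects)

    freq = hcpc.frequency_matrix(fm)
    pca = hcpc.run_pca(freq, scale=True)
    hclust = hcpc.hierarchical_cluster(pca, n_components=min(7, pca.n_components))
    result = hcpc.cut_and_consolidate(hclust, k=6)

    return StudyResult(
        panel=sp, matrix=matrix, filtered=fm, assignment=assignment,
        marker_sets=marker_sets, named_sets=named, quantifications=quants,
        collapse=collapse, anomalies=flag_reference_anomalies(fm),
        effects=effects, tallies=tallies, pca=pca, hclust=hclust,
        hcpc_result=result,
    )


def run_repeat_analysis(seed: int) -> list[pe38_repeats.RepeatHistogram]:
    """Simulate and count the repeat-locus read sets of the worked analysis."""
    histograms = []
    for i, (isolate, (dist, n_reads)) in enumerate(
        sorted(synth.STUDY_REPEAT_DESIGNS.items())
    ):
        rng = np.random.default_rng([seed, 300 + i])
        reads, _ = synth.simulate_repeat_reads(
            synth.STUDY_REPEAT_SPEC, dist, n_reads=n_reads, rng=rng,
            span_only=True,
        )
        histograms.append(
            pe38_repeats.count_repeats(
                [s for _, s in reads], synth.STUDY_REPEAT_SPEC, isolate=isolate
            )
        )
    return histograms


def headline_numbers(res: StudyResult, seed: int) -> dict[str, dict]:
    """The analysis' headline quantities, each with the problem size used."""
    n_iso = len(res.filtered.isolates)
    n_pos = res.assignment.n_positions
    inside, outside = specificity.partition_by_panel(
        res.assignment, res.panel.panel, "field"
    )
    cell = {(q.set_name, q.isolate): q for q in res.quantifications}

    def num(value, n):
        return {"value": float(np.round(value, 4)), "n": int(n)}

    sizes = {name: s.size for name, s in res.named_sets.items()}
    out = {
        "n_snp_positions": num(n_pos, n_iso),
        "snp_fraction_of_genome_percent": num(
            100.0 * n_pos / res.filtered.reference_length, n_pos
        ),
        "n_field_specific": num(len(inside), n_pos),
        "n_commercial_only": num(len(outside), n_pos),
        "n_transitions": num(res.tallies["transitions"], n_pos),
        "n_transversions": num(res.tallies["transversions"], n_pos),
        "n_coding": num(res.tallies["coding"], n_pos),
        "n_noncoding": num(res.tallies["noncoding"], n_pos),
        "marker_set_size_m": num(sizes.get("M", 0), n_pos),
        "marker_set_size_e2": num(sizes.get("E2", 0), n_pos),
        "marker_set_size_f": num(sizes.get("F", 0), n_pos),
        "marker_set_size_ale": num(sizes.get("ALE", 0), n_pos),
        "marker_set_size_ale_jq": num(sizes.get("FG", 0), n_pos),
        "marker_set_size_i12_i0x": num(sizes.get("I12+I0X", 0), n_pos),
        "marker_set_size_zy2": num(sizes.get("ZY2", 0), n_pos),
        "marker_set_size_bdefg": num(sizes.get("BDEFG", 0), n_pos),
        "marker_set_size_defg": num(sizes.get("DEFG", 0), n_pos),
        "median_m_in_m_percent": num(cell[("M", "M")].statistic, sizes["M"]),
        "median_m_in_ks1_percent": num(cell[("M", "KS1")].statistic, sizes["M"]),
        "median_m_in_ks2_percent": num(cell[("M", "KS2")].statistic, sizes["M"]),
        "median_m_in_zy_percent": num(cell[("M", "ZY")].statistic, sizes["M"]),
        "median_m_in_i0x_percent": num(cell[("M", "I0X")].statistic, sizes["M"]),
        "median_e_in_ks2_percent": num(
            cell[("DEFG", "KS2")].statistic, sizes["DEFG"]
        ),
        "median_e2_in_v15_percent": num(
            cell[("E2", "V15")].statistic, sizes["E2"]
        ),
        "median_s_in_v15_percent": num(
            cell[("DEFG", "V15")].statistic, sizes["DEFG"]
        ),
        "group_b_in_v34_percent": num(
            res.collapse["V34"].proportions.get("B", 0.0), sizes["BDEFG"]
        ),
        "group_b_in_0017_percent": num(
            res.collapse["0017"].proportions.get("B", 0.0), sizes["BDEFG"]
        ),
        "reference_anomaly_position": num(
            res.anomalies[0] if res.anomalies else 0, n_iso
        ),
        "pca_cumulative_variance_7pc_percent": num(
            res.pca.cumulative_at(7), n_iso
        ),
        "hcpc_suggested_k": num(res.hclust.suggested_k, n_iso),
        "m_v003_co_clustered": num(
            int(hcpc.co_clustered(res.hcpc_result, "M", "V003")), n_iso
        ),
        "ww_s_co_clustered": num(
            int(hcpc.co_clustered(res.hcpc_result, "WW", "S")), n_iso
        ),
    }

    hists = run_repeat_analysis(seed)
    table = pe38_repeats.summarize_panel(hists)
    row = table.set_index("isolate")
    out["repeat_pct_1x_v003"] = num(
        row.loc["V003", "pct_1x"], int(row.loc["V003", "n_informative"])
    )
    out["repeat_pct_1x_m"] = num(
        row.loc["M", "pct_1x"], int(row.loc["M", "n_informative"])
    )
    all_classes = sorted(
        {k for h in hists for k in h.counts}
    )
    out["repeat_copy_classes_max"] = num(max(all_classes), len(hists))
    return out
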