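import numpy as np
import pytest

from gvpop import specificity, synth, variant_filter
from gvpop.snpio import BASES, BASE_INDEX, SnpMatrix


def build_matrix(
    positions,
    ref_bases,
    isolate_counts,
    reference_length=10_000,
    reference_name="ref",
):
    """Small-matrix builder: ``isolate_counts[iso]`` is a list (one entry per
    site) of dicts base->count."""
    isolates = list(isolate_counts.keys())
    n = len(positions)
    counts = np.zeros((n, len(isolates), 4), dtype=np.int64)
    for j, iso in enumerate(isolates):
        for i, site in enumerate(isolate_counts[iso]):
            for b, c in site.items():
                counts[i, j, BASE_INDEX[b]] = c
    return SnpMatrix(
        reference_name, reference_length, isolates,
        np.array(positions), np.array(ref_bases), counts,
    )


def random_matrix(rng, n_isolates=5, n_sites=30, reference_length=100_000,
                  max_depth=400):
    """Random count matrix with arbitrary per-base counts (not mixture-model)."""
    positions = np.sort(
        rng.choice(np.arange(1, reference_length + 1), size=n_sites, replace=False)
    )
    ref_bases = rng.choice(list(BASES), size=n_sites)
    counts = rng.integers(0, max_depth, size=(n_sites, n_isolates, 4))
    # sprinkle zero-depth and ref-dominated sites
    zero = rng.random((n_sites, n_isolates)) < 0.1
    counts[zero] = 0
    return SnpMatrix(
        "ref", reference_length, [f"iso{j}" for j in range(n_isolates)],
        positions, ref_bases, counts,
    )


@pytest.fixture(scope="session")
def study_run():
    """One full study-panel simulation shared by the acceptance tests."""
    sp, matrix = synth.study_matrix(seed=20_09)
    fm = variant_filter.apply_filters(matrix)
    assignment = specificity.assign_specificity(
        fm, within=list(synth.FIELD_ISOLATES)
    )
    marker_sets = specificity.build_marker_sets(assignment)
    by_label = {s.label: s for s in marker_sets}
    named = {}
    for name, meta in sp.marker_scheme.items():
        s = by_label.get(tuple(meta["label"]))
        if s is not None:
            named[name] = specificity.MarkerSet(
                s.label, s.positions, allele=meta["allele"], name=name
            )
    return {
        "panel": sp,
        "matrix": matrix,
        "filtered": fm,
        "assignment": assignment,
        "marker_sets": marker_sets,
        "named_sets": named,
    }
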