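"""Consensus-free SNP specificity assignment.

Every retained SNP position is labelled with the *exact set of isolates in
which it is variable*: a singleton label marks an isolate-specific SNP, a
label with two or more members a group-specific SNP.  The label is the core
consensus-free primitive — no majority-rule consensus is ever built, so a
genotype present at 10% of an isolate's reads contributes to labels exactly
like a fixed genotype would.

Labels may be computed over a subset of isolates (typically the field
isolates, with commercial formulations quantified on the resulting marker
sets afterwards).  A position variable in no subset member falls back to a
label over the remaining isolates, so the label is never empty.

A special role is played by the *reference-identity* set: positions variable
in every subset isolate except one (canonically the strain the mapping
reference was built from).  At such positions the reference allele marks the
reference genotype, so downstream quantification uses the reference rather
than the alternative frequency there.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .snpio import IsolatePanel
from .variant_filter import FilteredMatrix

Label = tuple[str, ...]


def canonical_label(isolates) -> Label:
    return tuple(sorted(isolates))


@dataclass(frozen=True)
class SpecificityAssignment:
    """Per-position isolate-set labels over a filtered matrix."""

    positions: np.ndarray
    labels: tuple[Label, ...]
    isolates: tuple[str, ...]  # isolates the labels were computed over
    fallback_isolates: tuple[str, ...]  # complement used for empty labels

    def label_of(self, position: int) -> Label:
        idx = int(np.searchsorted(self.positions, position))
        if idx >= len(self.positions) or self.positions[idx] != position:
            raise KeyError(f"position {position} has no specificity label")
        return self.labels[idx]

    @property
    def n_positions(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class MarkerSet:
    """All SNP positions sharing one specificity label."""

    label: Label
    positions: tuple[int, ...]
    #: quantification allele: "alt" for ordinary sets, "ref" for
    #: reference-identity sets (see :func:`reference_marker_set`).
    allele: str = "alt"
    name: str | None = None

    @property
    def size(self) -> int:
        return len(self.positions)

    def __post_init__(self):
        if not self.label:
            raise ValueError("marker-set label must be nonempty")


class PipelineOrderError(RuntimeError):
    """A position with no variable isolate reached specificity assignment."""


def assign_specificity(
    fm: FilteredMatrix, within: Sequence[str] | None = None
) -> SpecificityAssignment:
    """Label every retained position with the exact set of variable isolates.

    ``within`` restricts the isolates over which labels are formed; positions
    variable only outside that subset are labelled with the complement
    isolates in which they are variable.
    """
    all_iso = list(fm.isolates)
    subset = list(within) if within is not None else all_iso
    unknown = set(subset) - set(all_iso)
    if unknown:
        raise KeyError(f"isolates not in matrix: {sorted(unknown)}")
    sub_idx = np.array([all_iso.index(i) for i in subset], dtype=np.intp)
    comp = [i for i in all_iso if i not in set(subset)]
    comp_idx = np.array([all_iso.index(i) for i in comp], dtype=np.intp)

    labels: list[Label] = []
    for row in range(fm.n_sites):
        var = fm.variable[row]
        members = [subset[k] for k, j in enumerate(sub_idx) if var[j]]
        if not members:
            members = [comp[k] for k, j in enumerate(comp_idx) if var[j]]
        if not members:
            raise PipelineOrderError(
                f"position {int(fm.positions[row])} has no variable isolate; "
                "nonvariant sites must be removed by filtering first"
            )
        labels.append(canonical_label(members))
    return SpecificityAssignment(
        positions=fm.positions.copy(),
        labels=tuple(labels),
        isolates=tuple(subset),
        fallback_isolates=tuple(comp),
    )


def build_marker_sets(assignment: SpecificityAssignment) -> list[MarkerSet]:
    """One marker set per distinct label, largest first."""
    by_label: dict[Label, list[int]] = {}
    for pos, label in zip(assignment.positions, assignment.labels):
        by_label.setdefault(label, []).append(int(pos))
    sets = [
        MarkerSet(label=label, positions=tuple(sorted(pos_list)))
        for label, pos_list in by_label.items()
    ]
    sets.sort(key=lambda s: (-s.size, s.label))
    total = sum(s.size for s in sets)
    assert total == assignment.n_positions  # partition invariant
    return sets


def reference_marker_set(
    assignment: SpecificityAssignment,
    reference_isolate: str,
    marker_sets: Sequence[MarkerSet] | None = None,
) -> MarkerSet | None:
    """The marker set identifying the reference strain's own genotype.

    Its label is the complement *all label isolates except the reference
    strain*: everywhere the whole rest of the panel is variable, the
    reference allele is what marks the reference genotype, so the returned
    set carries ``allele="ref"``.
    """
    target = canonical_label(set(assignment.isolates) - {reference_isolate})
    if not target:
        return None
    sets = marker_sets if marker_sets is not None else build_marker_sets(assignment)
    for s in sets:
        if s.label == target:
            return MarkerSet(
                label=s.label, positions=s.positions, allele="ref",
                name=reference_isolate,
            )
    return None


def partition_by_panel(
    assignment: SpecificityAssignment,
    panel: IsolatePanel,
    role: str = "field",
) -> tuple[list[int], list[int]]:
    """Split positions into (specific within the role subset, outside only).

    A position belongs to the subset partition iff its label intersects the
    subset.
    """
    subset = set(panel.ids(role))
    if not subset:
        raise ValueError(f"panel has no isolates with role {role!r}")
    inside, outside = [], []
    for pos, label in zip(assignment.positions, assignment.labels):
        (inside if subset & set(label) else outside).append(int(pos))
    return inside, outside
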