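"""Genotype-mixture quantification from marker-set allele frequencies.

Because the alternative frequency at a genotype's marker SNPs estimates the
proportion of reads — and hence occlusion-body genomes — carrying that
genotype, each cell of the composition table is simply a robust summary
(median, with 5th/95th percentiles) of f_alt over one marker set, evaluated
in one isolate.  Reference-identity marker sets are summarised on f_ref
instead (the reference allele is what marks the reference genotype there).

`collapse_groups` performs the arithmetic used to interpret combined
lineage labels: members of a combined group whose own specific marker sets
quantify at (near) zero in an isolate are removed from the label, and when a
collapsed superset and subset differ by exactly one member, the member's
proportion is the difference of the two medians.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .specificity import MarkerSet
from .variant_filter import FilteredMatrix


@dataclass(frozen=True)
class MarkerSetQuantification:
    """One composition-table cell: summary of allele frequency (percent)."""

    isolate: str
    label: tuple[str, ...]
    set_name: str | None
    n_snps: int
    statistic: float  # percent
    p5: float
    p95: float
    allele: str = "alt"

    def format_cell(self, digits: int = 0) -> str:
        fmt = f"{{:.{digits}f}}"
        return (
            f"{fmt.format(self.statistic)} "
            f"({fmt.format(self.p5)}–{fmt.format(self.p95)})"
        )


def parse_cell(text: str) -> tuple[float, float, float]:
    """Parse ``"70 (65-74)"`` back into (statistic, p5, p95)."""
    head, _, tail = text.partition("(")
    stat = float(head.strip())
    lo, _, hi = tail.rstrip(")").replace("–", "-").partition("-")
    return stat, float(lo), float(hi)


@dataclass(frozen=True)
class MixturePattern:
    """The three-frequency signature of a two-genotype mixture."""

    f_a: float
    f_b: float
    f_ab: float | None = None


@dataclass(frozen=True)
class GroupProportions:
    isolate: str
    proportions: dict[str, float]  # group name -> percent
    notes: tuple[str, ...] = ()


def _values_for(
    fm: FilteredMatrix, marker_set: MarkerSet, isolate: str, allele: str
) -> np.ndarray:
    """Allele frequencies of one isolate over a marker set.

    Positions absent from the filtered matrix were variable in no isolate:
    that is informative absence (f_alt = 0, f_ref = 1), not missing data.
    """
    j = fm.isolate_index(isolate)
    freq = fm.f_ref if allele == "ref" else fm.f_alt
    absent = 1.0 if allele == "ref" else 0.0
    values = np.empty(len(marker_set.positions))
    for k, p in enumerate(marker_set.positions):
        try:
            values[k] = freq[fm.position_index(p), j]
        except KeyError:
            values[k] = absent
    return values


def quantify(
    fm: FilteredMatrix,
    marker_sets: Sequence[MarkerSet],
    isolates: Sequence[str] | None = None,
    statistic: str = "median",
    percentiles: tuple[float, float] = (5.0, 95.0),
) -> list[MarkerSetQuantification]:
    """Summarise f_alt (or f_ref) over every (isolate, marker set) pair.

    Percentiles use linear interpolation between order statistics; values are
    returned in percent.
    """
    if statistic not in ("median", "mean"):
        raise ValueError("statistic must be 'median' or 'mean'")
    isolates = list(isolates) if isolates is not None else list(fm.isolates)
    out = []
    for ms in marker_sets:
        if ms.size == 0:
            raise ValueError(f"marker set {ms.label} is empty")
        for iso in isolates:
            values = _values_for(fm, ms, iso, ms.allele) * 100.0
            stat = float(np.median(values) if statistic == "median" else values.mean())
            p5, p95 = (float(x) for x in np.percentile(values, percentiles))
            out.append(
                MarkerSetQuantification(
                    isolate=iso, label=ms.label, set_name=ms.name,
                    n_snps=ms.size, statistic=stat, p5=p5, p95=p95,
                    allele=ms.allele,
                )
            )
    return out


def quantification_frame(quants: Sequence[MarkerSetQuantification]):
    """Long-format DataFrame of composition cells."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "isolate": q.isolate,
                "set": q.set_name or "+".join(q.label),
                "n_snps": q.n_snps,
                "allele": q.allele,
                "statistic": q.statistic,
                "p5": q.p5,
                "p95": q.p95,
            }
            for q in quants
        ]
    )


def mixture_pattern(
    fm: FilteredMatrix,
    isolate: str,
    set_a: MarkerSet,
    set_b: MarkerSet,
    shared: MarkerSet | None = None,
) -> MixturePattern:
    """Median f over genotype-a markers, genotype-b markers and shared markers.

    For an isolate that is a clean two-way mixture the three medians follow
    f_a + f_b ≈ f_ab ≈ 1 at positions shared by both genotypes.
    """
    if set(set_a.positions) & set(set_b.positions):
        raise ValueError("marker sets a and b must be disjoint")
    f_a = float(np.median(_values_for(fm, set_a, isolate, set_a.allele)))
    f_b = float(np.median(_values_for(fm, set_b, isolate, set_b.allele)))
    f_ab = None
    if shared is not None:
        f_ab = float(np.median(_values_for(fm, shared, isolate, shared.allele)))
    return MixturePattern(f_a=f_a, f_b=f_b, f_ab=f_ab)


def collapse_groups(
    group_medians: Mapping[str, Mapping[str, float]],
    scheme: Mapping[str, frozenset[str]],
    absence_threshold: float = 1.0,
    tolerance: float = 5.0,
) -> list[GroupProportions]:
    """Collapse combined lineage labels using absence of member-specific signal.

    Parameters
    ----------
    group_medians
        ``{isolate: {group_name: median_percent}}`` — quantifications of the
        single-member and combined marker sets.
    scheme
        ``{group_name: frozenset of member lineage letters}``; single-member
        groups define the member-specific signals.
    absence_threshold
        Percent below which a member's own specific set counts as absent.
    tolerance
        A subset median exceeding its superset median by more than this many
        points triggers a heterogeneity warning note (the remainder is
        clamped at 0 in the output).
    """
    singles = {next(iter(m)): name for name, m in scheme.items() if len(m) == 1}
    results = []
    for isolate, medians in group_medians.items():
        notes: list[str] = []
        proportions: dict[str, float] = {}
        # 1. member-specific signals from single-member sets
        specific: dict[str, float | None] = {
            letter: medians.get(name) for letter, name in singles.items()
        }
        for letter, value in specific.items():
            if value is not None and value >= absence_threshold:
                proportions[letter] = value
        # 2. collapse combined labels by dropping absent members
        collapsed: dict[frozenset[str], float] = {}
        for name, members in scheme.items():
            if name not in medians or len(members) == 1:
                continue
            kept = frozenset(
                m
                for m in members
                if not (
                    specific.get(m) is not None
                    and specific[m] < absence_threshold
                )
            )
            if kept != members:
                notes.append(
                    f"{name} collapsed to {''.join(sorted(kept))} "
                    f"(no specific signal for {''.join(sorted(members - kept))})"
                )
            if kept:
                collapsed[kept] = medians[name]
        # 3. combined groups collapsing to one member measure that member
        #    directly (e.g. DEFG -> E); they outrank remainder arithmetic
        from_collapse: set[str] = set()
        for members, value in collapsed.items():
            if len(members) == 1:
                (letter,) = members
                proportions[letter] = value
                from_collapse.add(letter)
        # 4. superset-minus-subset remainders fill the remaining members,
        #    overriding weak single-set signals (the combined sets are larger)
        comparable = dict(collapsed)
        for letter in from_collapse:
            comparable.setdefault(frozenset({letter}), proportions[letter])
        for sup, sup_val in collapsed.items():
            for sub, sub_val in comparable.items():
                if sub < sup and len(sup - sub) == 1:
                    (member,) = sup - sub
                    if member in from_collapse:
                        continue
                    remainder = sup_val - sub_val
                    if remainder < -tolerance:
                        notes.append(
                            f"heterogeneity warning: subset {''.join(sorted(sub))} "
                            f"median {sub_val:.1f} exceeds superset "
                            f"{''.join(sorted(sup))} median {sup_val:.1f}"
                        )
                    proportions[member] = float(np.clip(remainder, 0.0, 100.0))
                    notes.append(
                        f"{member} = {''.join(sorted(sup))} - "
                        f"{''.join(sorted(sub))} = {remainder:.1f}"
                    )
        results.append(
            GroupProportions(isolate=isolate, proportions=proportions,
                             notes=tuple(notes))
        )
    return results
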