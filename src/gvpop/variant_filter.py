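"""Stringency filtering of SNP candidate sites and first-alternative reduction.

A site/isolate combination counts as *variable* only when three conditions
hold simultaneously (all strict inequalities):

* total four-base read depth > ``min_total_depth`` (default 100),
* read count of the first alternative base > ``min_alt_count`` (default 10),
* the relative frequency of the reference **or** the alternative base
  exceeds ``min_freq`` (default 0.05).

The frequency rule is applied to whichever of the two focal alleles is
larger (``freq_applies="ref_or_alt"``); the stricter alternative-only
reading is available as ``freq_applies="alt"``.  The distinction matters
for mixed isolates carrying a minority genotype at a few percent: with
deep coverage such positions clear the absolute-count bound and are real
variability, and the reference allele trivially satisfies the frequency
bound.

The *first alternative* of a site is chosen once, globally, as the
non-reference base with the highest count summed over all isolates (ties
broken in A<C<G<T order), so that a site's alternative identity is shared
across isolates — a prerequisite for cross-isolate specificity labels.
Sites left with no variable isolate are dropped (the nonvariant-removal
step).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .snpio import BASES, BASE_INDEX, NucleotideCountSite, SnpMatrix


@dataclass(frozen=True)
class FilterConfig:
    min_total_depth: int = 100
    min_alt_count: int = 10
    min_freq: float = 0.05
    freq_applies: str = "ref_or_alt"  # "ref_or_alt" | "alt"

    def __post_init__(self):
        if self.min_total_depth < 0 or self.min_alt_count < 0 or self.min_freq < 0:
            raise ValueError("filter thresholds must be non-negative")
        if not self.min_freq < 1:
            raise ValueError("min_freq must be < 1")
        if self.freq_applies not in ("ref_or_alt", "alt"):
            raise ValueError("freq_applies must be 'ref_or_alt' or 'alt'")


@dataclass(frozen=True)
class FilteredSite:
    """A site reduced to reference + first alternative."""

    position: int
    ref_base: str
    alt_base: str | None  # None => nonvariant (no alternative reads anywhere)
    isolates: tuple[str, ...]
    ref_counts: tuple[int, ...]
    alt_counts: tuple[int, ...]
    depths: tuple[int, ...]
    f_alt: tuple[float, ...]
    variable: tuple[bool, ...] | None = None


class FilteredMatrix:
    """Filtered ref/alt view of a :class:`SnpMatrix` with variability flags."""

    def __init__(
        self,
        reference_name: str,
        reference_length: int,
        isolates: Sequence[str],
        positions: np.ndarray,
        ref_bases: np.ndarray,
        alt_bases: np.ndarray,
        ref_counts: np.ndarray,
        alt_counts: np.ndarray,
        depths: np.ndarray,
        variable: np.ndarray,
        config: FilterConfig,
        circular: bool = True,
    ):
        self.reference_name = reference_name
        self.reference_length = int(reference_length)
        self.isolates = list(isolates)
        self.positions = np.asarray(positions, dtype=np.int64)
        self.ref_bases = np.asarray(ref_bases, dtype="U1")
        self.alt_bases = np.asarray(alt_bases, dtype="U1")
        self.ref_counts = np.asarray(ref_counts, dtype=np.int64)
        self.alt_counts = np.asarray(alt_counts, dtype=np.int64)
        self.depths = np.asarray(depths, dtype=np.int64)
        self.variable = np.asarray(variable, dtype=bool)
        self.config = config
        self.circular = circular

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    @property
    def f_alt(self) -> np.ndarray:
        """(n_sites, n_isolates) alternative frequency over four-base depth."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.depths > 0, self.alt_counts / self.depths, 0.0)

    @property
    def f_ref(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.depths > 0, self.ref_counts / self.depths, 0.0)

    def position_index(self, position: int) -> int:
        idx = int(np.searchsorted(self.positions, position))
        if idx >= self.n_sites or self.positions[idx] != position:
            raise KeyError(f"position {position} not in filtered matrix")
        return idx

    def isolate_index(self, isolate: str) -> int:
        return self.isolates.index(isolate)


def select_first_alternative(site: NucleotideCountSite) -> FilteredSite:
    """Reduce one site to reference + the globally most frequent alternative."""
    isolates = tuple(site.counts.keys())
    totals = np.zeros(4, dtype=np.int64)
    per_iso = np.zeros((len(isolates), 4), dtype=np.int64)
    for j, iso in enumerate(isolates):
        for b, c in site.counts[iso].items():
            per_iso[j, BASE_INDEX[b]] = c
    totals = per_iso.sum(axis=0)
    ref_idx = BASE_INDEX[site.ref_base]
    masked = totals.copy()
    masked[ref_idx] = -1
    alt_idx = int(np.argmax(masked))  # ties -> lowest index -> A<C<G<T
    if masked[alt_idx] == 0:
        alt_idx = None  # nonvariant
    depths = per_iso.sum(axis=1)
    alt_counts = per_iso[:, alt_idx] if alt_idx is not None else np.zeros(len(isolates), int)
    with np.errstate(invalid="ignore", divide="ignore"):
        f_alt = np.where(depths > 0, alt_counts / depths, 0.0)
    return FilteredSite(
        position=site.position,
        ref_base=site.ref_base,
        alt_base=BASES[alt_idx] if alt_idx is not None else None,
        isolates=isolates,
        ref_counts=tuple(int(x) for x in per_iso[:, ref_idx]),
        alt_counts=tuple(int(x) for x in alt_counts),
        depths=tuple(int(x) for x in depths),
        f_alt=tuple(float(x) for x in f_alt),
    )


def apply_filters(matrix: SnpMatrix, cfg: FilterConfig | None = None) -> FilteredMatrix:
    """Apply the stringency filters and drop sites with no variable isolate."""
    cfg = cfg or FilterConfig()
    n, m, _ = matrix.counts.shape
    ref_idx = np.array([BASE_INDEX[b] for b in matrix.ref_bases], dtype=np.intp)
    rows = np.arange(n)

    totals = matrix.counts.sum(axis=1)  # (n, 4) summed over isolates
    masked = totals.copy()
    masked[rows, ref_idx] = -1
    alt_idx = masked.argmax(axis=1).astype(np.intp)
    nonvariant = masked[rows, alt_idx] <= 0

    depths = matrix.depths
    ref_counts = matrix.counts[rows[:, None], np.arange(m)[None, :], ref_idx[:, None]]
    alt_counts = matrix.counts[rows[:, None], np.arange(m)[None, :], alt_idx[:, None]]
    with np.errstate(invalid="ignore", divide="ignore"):
        f_alt = np.where(depths > 0, alt_counts / depths, 0.0)
        f_ref = np.where(depths > 0, ref_counts / depths, 0.0)
    if cfg.freq_applies == "alt":
        freq_ok = f_alt > cfg.min_freq
    else:
        freq_ok = np.maximum(f_alt, f_ref) > cfg.min_freq
    variable = (
        (depths > cfg.min_total_depth)
        & (alt_counts > cfg.min_alt_count)
        & freq_ok
    )
    variable[nonvariant] = False
    keep = variable.any(axis=1)

    alt_bases = np.array([BASES[k] for k in alt_idx], dtype="U1")
    return FilteredMatrix(
        matrix.reference_name,
        matrix.reference_length,
        matrix.isolates,
        matrix.positions[keep],
        matrix.ref_bases[keep],
        alt_bases[keep],
        ref_counts[keep],
        alt_counts[keep],
        depths[keep],
        variable[keep],
        cfg,
        circular=matrix.circular,
    )


def refilter(fm: FilteredMatrix, cfg: FilterConfig | None = None) -> FilteredMatrix:
    """Re-apply (possibly different) thresholds to an already filtered matrix.

    Used for the idempotence/monotonicity properties; the alternative base
    choice is kept.
    """
    cfg = cfg or fm.config
    with np.errstate(invalid="ignore", divide="ignore"):
        f_alt = np.where(fm.depths > 0, fm.alt_counts / fm.depths, 0.0)
        f_ref = np.where(fm.depths > 0, fm.ref_counts / fm.depths, 0.0)
    if cfg.freq_applies == "alt":
        freq_ok = f_alt > cfg.min_freq
    else:
        freq_ok = np.maximum(f_alt, f_ref) > cfg.min_freq
    variable = (
        (fm.depths > cfg.min_total_depth)
        & (fm.alt_counts > cfg.min_alt_count)
        & freq_ok
    )
    keep = variable.any(axis=1)
    return FilteredMatrix(
        fm.reference_name, fm.reference_length, fm.isolates,
        fm.positions[keep], fm.ref_bases[keep], fm.alt_bases[keep],
        fm.ref_counts[keep], fm.alt_counts[keep], fm.depths[keep],
        variable[keep], cfg, circular=fm.circular,
    )


def flag_reference_anomalies(
    fm: FilteredMatrix, min_freq_all: float = 0.92
) -> list[int]:
    """Positions where every covered isolate is near-fixed for the alternative.

    When the alternative frequency is >= ``min_freq_all`` in *all* isolates
    (including a re-sequencing of the reference strain itself), the reference
    base is most plausibly a consensus annotation error rather than a real
    polymorphism.
    """
    if len(fm.isolates) < 2:
        raise ValueError("anomaly flagging needs at least two isolates")
    f_alt = fm.f_alt
    covered = fm.depths > 0
    high = (f_alt >= min_freq_all) | ~covered
    mask = high.all(axis=1) & covered.any(axis=1)
    return [int(p) for p in fm.positions[mask]]
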