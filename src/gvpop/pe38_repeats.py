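"""Flank-anchored tandem-repeat copy-number counting directly from reads.

The copy number of a short tandem repeat (the canonical case: the 12-bp
motif GACACAGTGGAT in the granulovirus *pe38* gene, whose single-copy form
marks resistance-overcoming genotypes) is genotyped without alignment or
assembly: a read is informative iff both unique flanking sequences occur on
the same strand, upstream before downstream, each exactly once.  The
distance between the flanks, divided by the motif length, is the copy
number carried by that read; tallying informative reads yields a per-isolate
copy-number histogram that reflects the genotype mixture.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

from .orf_stats import revcomp


@dataclass(frozen=True)
class RepeatRegionSpec:
    upstream_flank: str
    downstream_flank: str
    motif: str

    def __post_init__(self):
        object.__setattr__(self, "upstream_flank", self.upstream_flank.upper())
        object.__setattr__(self, "downstream_flank", self.downstream_flank.upper())
        object.__setattr__(self, "motif", self.motif.upper())
        for name, flank in (
            ("upstream", self.upstream_flank),
            ("downstream", self.downstream_flank),
        ):
            if len(flank) < 6:
                raise ValueError(f"{name} flank shorter than 6 nt is too ambiguous")
            if self.motif in flank:
                raise ValueError(f"{name} flank contains a full copy of the motif")
        if not self.motif:
            raise ValueError("motif must be nonempty")

    @property
    def unit_length(self) -> int:
        return len(self.motif)

    def region(self, copies: int) -> str:
        """The locus sequence for a given copy number."""
        return self.upstream_flank + self.motif * copies + self.downstream_flank


@dataclass
class RepeatHistogram:
    isolate: str
    counts: dict[int, int] = field(default_factory=dict)
    irregular: int = 0  # flank distance not a motif multiple / not tandem copies
    ambiguous: int = 0  # a flank occurred more than once
    n_scanned: int = 0

    @property
    def total_informative(self) -> int:
        return sum(self.counts.values())

    @property
    def frequencies(self) -> dict[int, float]:
        total = self.total_informative
        if total == 0:
            return {}
        return {k: v / total for k, v in sorted(self.counts.items())}

    def dominant_class(self) -> int | None:
        if not self.counts:
            return None
        return max(sorted(self.counts), key=lambda k: self.counts[k])


def _find_all(haystack: str, needle: str, max_mismatch: int = 0) -> list[int]:
    if max_mismatch == 0:
        hits, start = [], 0
        while True:
            i = haystack.find(needle, start)
            if i < 0:
                return hits
            hits.append(i)
            start = i + 1
    hits = []
    n, m = len(haystack), len(needle)
    for i in range(n - m + 1):
        mism = 0
        for a, b in zip(haystack[i : i + m], needle):
            if a != b:
                mism += 1
                if mism > max_mismatch:
                    break
        else:
            hits.append(i)
    return hits


def _classify_read(
    seq: str, spec: RepeatRegionSpec, max_mismatch: int, verify_tandem: bool
) -> tuple[str, int | None]:
    """Return (status, copies): status in {uninformative, ambiguous, irregular, ok}."""
    for oriented in (seq, revcomp(seq)):
        ups = _find_all(oriented, spec.upstream_flank, max_mismatch)
        downs = _find_all(oriented, spec.downstream_flank, max_mismatch)
        if not ups or not downs:
            continue  # at most one flank in this orientation -> uninformative
        if len(ups) != 1 or len(downs) != 1:
            return "ambiguous", None
        up_end = ups[0] + len(spec.upstream_flank)
        down_start = downs[0]
        if down_start < up_end:
            continue  # wrong flank order in this orientation
        distance = down_start - up_end
        if distance % spec.unit_length != 0:
            return "irregular", None
        copies = distance // spec.unit_length
        if verify_tandem and max_mismatch == 0:
            if oriented[up_end:down_start] != spec.motif * copies:
                return "irregular", None
        return "ok", copies
    return "uninformative", None


def _iter_sequences(reads: str | Path | Iterable) -> Iterator[str]:
    if isinstance(reads, (str, Path)):
        path = Path(reads)
        opener = gzip.open if path.suffix == ".gz" else open
        stem = path.name[: -len(".gz")] if path.suffix == ".gz" else path.name
        fmt = "fastq" if stem.endswith((".fastq", ".fq")) else "fasta"
        from Bio import SeqIO

        with opener(path, "rt") as fh:
            for rec in SeqIO.parse(fh, fmt):
                yield str(rec.seq).upper()
    else:
        for item in reads:
            yield (str(item.seq) if hasattr(item, "seq") else str(item)).upper()


def count_repeats(
    reads: str | Path | Iterable,
    spec: RepeatRegionSpec,
    isolate: str = "",
    max_mismatch: int = 0,
    verify_tandem: bool = True,
) -> RepeatHistogram:
    """Histogram motif copy numbers over all informative reads.

    ``reads`` may be a FASTQ/FASTA path (gzip-transparent), an iterable of
    sequence strings, or Biopython records.  Reads where a flank occurs more
    than once are discarded as ambiguous; flank distances that are not an
    exact motif multiple (or whose spanned sequence is not tandem motif
    copies, when ``verify_tandem``) are tallied separately as irregular.
    """
    hist = RepeatHistogram(isolate=isolate)
    for seq in _iter_sequences(reads):
        hist.n_scanned += 1
        status, copies = _classify_read(seq, spec, max_mismatch, verify_tandem)
        if status == "ok":
            hist.counts[copies] = hist.counts.get(copies, 0) + 1
        elif status == "ambiguous":
            hist.ambiguous += 1
        elif status == "irregular":
            hist.irregular += 1
    return hist


def summarize_panel(
    histograms: Sequence[RepeatHistogram],
    reference_class: int | None = None,
) -> pd.DataFrame:
    """Per-isolate copy-number percentages; one row per isolate.

    Isolates with zero informative reads are reported with n=0 and no
    frequencies.  With ``reference_class`` given, isolates whose dominant
    copy number differs from it are flagged.
    """
    classes = sorted({k for h in histograms for k in h.counts})
    rows = []
    for h in histograms:
        row: dict = {"isolate": h.isolate, "n_informative": h.total_informative}
        freqs = h.frequencies
        for k in classes:
            row[f"pct_{k}x"] = round(100.0 * freqs[k], 4) if k in freqs else (
                0.0 if h.total_informative else None
            )
        if reference_class is not None:
            dom = h.dominant_class()
            row["dominant_class"] = dom
            row["deviates_from_reference"] = (
                dom is not None and dom != reference_class
            )
        rows.append(row)
    return pd.DataFrame(rows)
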