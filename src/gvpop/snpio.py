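"""Data model and readers/writers for multi-isolate nucleotide-count matrices.

The central container is :class:`SnpMatrix`: per-site A/C/G/T read counts for a
panel of deep-sequenced virus isolates, all mapped against one (circular)
reference genome.  Working on raw base counts rather than consensus calls is
what makes the downstream analysis consensus-free: minority genotypes inside a
mixed isolate stay visible as intermediate allele frequencies.

Supported on-disk formats:

* a TSV count-table dialect (``position  ref  <isolate>:A ... <isolate>:T``),
* a reduced ref/alt TSV dialect (``position  ref  alt  <isolate>:ref
  <isolate>:alt``) as distributed in supplementary SNP tables,
* multi-sample VCF with per-sample allelic depths (``AD``),
* single-record FASTA references and GFF3/TSV ORF annotations.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
#: IUPAC codes tolerated in references away from SNP-bearing positions.
AMBIGUITY_CODES = set("RYSWKMBDHVN")

FUNCTION_CLASSES = (
    "biological regulation",
    "DNA replication",
    "metabolic process",
    "structural protein",
    "virus transcription",
    "unknown",
)
_CLASS_ALIASES = {
    "structure protein": "structural protein",
    "unknown function": "unknown",
}


class SnpIOError(ValueError):
    """Malformed input file or invariant violation, with row context."""


def normalize_function_class(name: str) -> str:
    cls = _CLASS_ALIASES.get(name.strip(), name.strip())
    if cls not in FUNCTION_CLASSES:
        raise SnpIOError(
            f"unknown ORF function class {name!r}; expected one of {FUNCTION_CLASSES}"
        )
    return cls


@dataclass(frozen=True)
class NucleotideCountSite:
    """Per-isolate A/C/G/T read counts at one 1-based reference position."""

    position: int
    ref_base: str
    counts: Mapping[str, Mapping[str, int]]  # isolate -> base -> count

    def depth(self, isolate: str) -> int:
        return int(sum(self.counts[isolate].values()))

    def frequency(self, isolate: str, base: str) -> float:
        d = self.depth(isolate)
        return self.counts[isolate][base] / d if d else 0.0


@dataclass(frozen=True)
class IsolateInfo:
    id: str
    origin: str = ""
    genome_group: str | None = None
    role: str = "field"  # field | commercial | selected


@dataclass(frozen=True)
class IsolatePanel:
    """Metadata for the sequenced isolates (origin, lineage label, role)."""

    isolates: tuple[IsolateInfo, ...]

    def ids(self, role: str | None = None) -> list[str]:
        if role is None:
            return [i.id for i in self.isolates]
        return [i.id for i in self.isolates if i.role == role]

    def __contains__(self, isolate_id: str) -> bool:
        return any(i.id == isolate_id for i in self.isolates)


@dataclass(frozen=True)
class ReferenceGenome:
    name: str
    sequence: str
    circular: bool = False

    @property
    def length(self) -> int:
        return len(self.sequence)

    def base(self, position: int) -> str:
        """1-based, wrap-aware access."""
        if self.circular:
            return self.sequence[(position - 1) % self.length]
        if not 1 <= position <= self.length:
            raise IndexError(f"position {position} outside linear reference")
        return self.sequence[position - 1]

    def slice(self, start: int, length: int) -> str:
        """Wrap-aware 1-based slice of ``length`` bases starting at ``start``."""
        return "".join(self.base(start + i) for i in range(length))


@dataclass(frozen=True)
class OrfRecord:
    """An annotated ORF; ``end < start`` encodes wrap-around on a circular genome."""

    id: str
    start: int
    end: int
    strand: str
    function_class: str
    reference_length: int

    def __post_init__(self):
        if self.strand not in "+-":
            raise SnpIOError(f"ORF {self.id}: strand must be + or -")
        for coord in (self.start, self.end):
            if not 1 <= coord <= self.reference_length:
                raise SnpIOError(
                    f"ORF {self.id}: coordinate {coord} outside reference "
                    f"[1, {self.reference_length}]"
                )
        object.__setattr__(
            self, "function_class", normalize_function_class(self.function_class)
        )

    @property
    def wraps(self) -> bool:
        return self.end < self.start

    @property
    def length(self) -> int:
        if self.wraps:
            return self.reference_length - self.start + 1 + self.end
        return self.end - self.start + 1

    def contains(self, position: int) -> bool:
        if self.wraps:
            return position >= self.start or position <= self.end
        return self.start <= position <= self.end


class SnpMatrix:
    """Per-site x per-isolate nucleotide counts against a named reference.

    ``counts`` has shape ``(n_sites, n_isolates, 4)`` in fixed A,C,G,T order;
    positions are 1-based and strictly increasing.
    """

    def __init__(
        self,
        reference_name: str,
        reference_length: int,
        isolates: Sequence[str],
        positions: np.ndarray,
        ref_bases: np.ndarray,
        counts: np.ndarray,
        circular: bool = True,
        validate: bool = True,
    ):
        self.reference_name = reference_name
        self.reference_length = int(reference_length)
        self.isolates = list(isolates)
        self.positions = np.asarray(positions, dtype=np.int64)
        self.ref_bases = np.asarray(ref_bases, dtype="U1")
        self.counts = np.asarray(counts, dtype=np.int64)
        self.circular = bool(circular)
        order = np.argsort(self.positions, kind="stable")
        self.positions = self.positions[order]
        self.ref_bases = self.ref_bases[order]
        self.counts = self.counts[order]
        if validate:
            self._validate()

    # -- invariants ---------------------------------------------------------
    def _validate(self) -> None:
        if len(set(self.isolates)) != len(self.isolates):
            raise SnpIOError("isolate ids are not unique")
        if self.counts.shape != (len(self.positions), len(self.isolates), 4):
            raise SnpIOError("counts shape does not match positions/isolates")
        if (self.counts < 0).any():
            rows = np.unique(np.where((self.counts < 0).any(axis=(1, 2)))[0])
            raise SnpIOError(f"negative counts at site rows {rows.tolist()}")
        if len(self.positions) and (
            self.positions[0] < 1 or self.positions[-1] > self.reference_length
        ):
            raise SnpIOError("positions outside [1, reference_length]")
        dup = np.nonzero(np.diff(self.positions) == 0)[0]
        if dup.size:
            raise SnpIOError(
                f"duplicate positions {np.unique(self.positions[dup]).tolist()}"
            )
        bad = ~np.isin(self.ref_bases, list(BASES))
        if bad.any():
            raise SnpIOError(
                f"non-ACGT reference base at positions "
                f"{self.positions[bad].tolist()}"
            )

    # -- accessors ----------------------------------------------------------
    @property
    def n_sites(self) -> int:
        return len(self.positions)

    @property
    def depths(self) -> np.ndarray:
        """(n_sites, n_isolates) total four-base read depth."""
        return self.counts.sum(axis=2)

    def frequencies(self) -> np.ndarray:
        """(n_sites, n_isolates, 4) base frequencies; 0 where depth is 0."""
        d = self.depths[:, :, None].astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(d > 0, self.counts / d, 0.0)
        return f

    def site(self, index: int) -> NucleotideCountSite:
        return NucleotideCountSite(
            position=int(self.positions[index]),
            ref_base=str(self.ref_bases[index]),
            counts={
                iso: {b: int(self.counts[index, j, k]) for k, b in enumerate(BASES)}
                for j, iso in enumerate(self.isolates)
            },
        )

    def subset_isolates(self, ids: Sequence[str]) -> "SnpMatrix":
        idx = [self.isolates.index(i) for i in ids]
        return SnpMatrix(
            self.reference_name,
            self.reference_length,
            list(ids),
            self.positions.copy(),
            self.ref_bases.copy(),
            self.counts[:, idx, :].copy(),
            circular=self.circular,
        )

    def equals(self, other: "SnpMatrix") -> bool:
        return (
            self.reference_name == other.reference_name
            and self.reference_length == other.reference_length
            and self.isolates == other.isolates
            and np.array_equal(self.positions, other.positions)
            and np.array_equal(self.ref_bases, other.ref_bases)
            and np.array_equal(self.counts, other.counts)
        )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"SnpMatrix({self.reference_name!r}, {self.n_sites} sites x "
            f"{len(self.isolates)} isolates)"
        )


# ---------------------------------------------------------------------------
# count-table TSV
# ---------------------------------------------------------------------------

def write_count_table(matrix: SnpMatrix, path: str | Path) -> None:
    cols = {"position": matrix.positions, "ref": matrix.ref_bases}
    for j, iso in enumerate(matrix.isolates):
        for k, b in enumerate(BASES):
            cols[f"{iso}:{b}"] = matrix.counts[:, j, k]
    df = pd.DataFrame(cols)
    with open(path, "w") as fh:
        fh.write(
            f"# reference={matrix.reference_name}"
            f" length={matrix.reference_length}"
            f" circular={int(matrix.circular)}\n"
        )
        df.to_csv(fh, sep="\t", index=False)


def _parse_meta_header(path: str | Path) -> dict:
    meta = {"reference": "reference", "length": None, "circular": True}
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        for tok in first[1:].split():
            if "=" in tok:
                key, val = tok.split("=", 1)
                if key == "length":
                    meta["length"] = int(val)
                elif key == "circular":
                    meta["circular"] = bool(int(val))
                elif key == "reference":
                    meta["reference"] = val
    return meta


def read_count_table(
    path: str | Path,
    reference_name: str | None = None,
    reference_length: int | None = None,
    circular: bool | None = None,
) -> SnpMatrix:
    """Read a count TSV in either the full four-base or the ref/alt dialect.

    The dialect is sniffed from the header: ``<isolate>:A`` columns mark the
    four-base table, ``<isolate>:ref``/``<isolate>:alt`` the reduced dialect
    (in which the two untyped bases carry zero counts by construction).
    """
    meta = _parse_meta_header(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    df.columns = [str(c).strip() for c in df.columns]
    lower = {c.lower(): c for c in df.columns}
    if "position" not in lower or "ref" not in lower:
        raise SnpIOError("malformed header: need 'position' and 'ref' columns")
    ref_name = reference_name or meta["reference"]
    length = reference_length or meta["length"]
    if length is None:
        length = int(df[lower["position"]].max())
    circ = meta["circular"] if circular is None else circular

    four_base = [c for c in df.columns if c.endswith((":A", ":C", ":G", ":T"))]
    refalt = [c for c in df.columns if c.endswith((":ref", ":alt"))]
    positions = df[lower["position"]].to_numpy(dtype=np.int64)
    ref_bases = df[lower["ref"]].astype(str).str.upper().to_numpy(dtype="U1")

    if four_base:
        isolates = list(dict.fromkeys(c.rsplit(":", 1)[0] for c in four_base))
        counts = np.zeros((len(df), len(isolates), 4), dtype=np.int64)
        for j, iso in enumerate(isolates):
            for k, b in enumerate(BASES):
                col = f"{iso}:{b}"
                if col not in df.columns:
                    raise SnpIOError(f"malformed header: missing column {col}")
                counts[:, j, k] = _int_column(df, col)
    elif refalt:
        if "alt" not in lower:
            raise SnpIOError("ref/alt dialect needs an 'alt' base column")
        alt_bases = df[lower["alt"]].astype(str).str.upper().to_numpy(dtype="U1")
        isolates = list(dict.fromkeys(c.rsplit(":", 1)[0] for c in refalt))
        counts = np.zeros((len(df), len(isolates), 4), dtype=np.int64)
        ref_idx = _base_indices(ref_bases)
        alt_idx = _base_indices(alt_bases)
        rows = np.arange(len(df))
        for j, iso in enumerate(isolates):
            counts[rows, j, ref_idx] = _int_column(df, f"{iso}:ref")
            counts[rows, j, alt_idx] += _int_column(df, f"{iso}:alt")
    else:
        raise SnpIOError("malformed header: no per-isolate count columns found")

    return SnpMatrix(ref_name, length, isolates, positions, ref_bases, counts,
                     circular=circ)


def _int_column(df: pd.DataFrame, col: str) -> np.ndarray:
    vals = pd.to_numeric(df[col], errors="coerce")
    if vals.isna().any():
        row = int(vals.index[vals.isna()][0]) + 2  # 1-based incl. header
        raise SnpIOError(f"non-numeric count in column {col!r}, file row {row}")
    arr = vals.to_numpy()
    if (arr < 0).any():
        row = int(np.nonzero(arr < 0)[0][0]) + 2
        raise SnpIOError(f"negative count in column {col!r}, file row {row}")
    return arr.astype(np.int64)


def _base_indices(bases: np.ndarray) -> np.ndarray:
    idx = np.searchsorted(np.array(list(BASES)), bases)
    bad = ~np.isin(bases, list(BASES))
    if bad.any():
        raise SnpIOError(f"invalid base(s) {np.unique(bases[bad]).tolist()}")
    return idx


def validate_site_depths(
    matrix: SnpMatrix, declared_depths: np.ndarray
) -> None:
    """Check declared depths equal the four-base sums (conservation invariant)."""
    actual = matrix.depths
    declared = np.asarray(declared_depths, dtype=np.int64)
    if declared.shape != actual.shape:
        raise SnpIOError("declared depth table has wrong shape")
    bad = np.argwhere(declared != actual)
    if bad.size:
        i, j = bad[0]
        raise SnpIOError(
            f"depth mismatch at position {int(matrix.positions[i])}, isolate "
            f"{matrix.isolates[j]}: declared {int(declared[i, j])}, "
            f"base counts sum to {int(actual[i, j])}"
        )


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf_counts(path: str | Path) -> SnpMatrix:
    """Map per-sample allelic depths (AD) of a multi-sample VCF onto base counts.

    Multi-allelic records are expanded onto the four-base model; non-SNP
    alleles are rejected.
    """
    import pysam

    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if len(set(samples)) != len(samples):
            raise SnpIOError("sample names in VCF are not unique")
        if "AD" not in vcf.header.formats:
            raise SnpIOError("VCF lacks the per-sample AD (allelic depth) field")
        ref_name = None
        length = None
        for contig in vcf.header.contigs.values():
            ref_name = contig.name
            length = contig.length
            break
        positions, ref_bases, count_rows = [], [], []
        for rec in vcf.fetch() if vcf.index is not None else vcf:
            alleles = [rec.ref] + [a for a in (rec.alts or ())]
            if any(len(a) != 1 or a.upper() not in BASES for a in alleles):
                raise SnpIOError(
                    f"non-SNP allele at {rec.chrom}:{rec.pos}: {alleles}"
                )
            row = np.zeros((len(samples), 4), dtype=np.int64)
            for j, sample in enumerate(samples):
                ad = rec.samples[sample].get("AD")
                if ad is None:
                    raise SnpIOError(
                        f"missing AD for sample {sample} at {rec.pos}"
                    )
                for allele, depth in zip(alleles, ad):
                    if depth is not None:
                        row[j, BASE_INDEX[allele.upper()]] += int(depth)
            positions.append(rec.pos)
            ref_bases.append(rec.ref.upper())
            count_rows.append(row)
    if length is None:
        length = max(positions) if positions else 0
    counts = (
        np.stack(count_rows) if count_rows else np.zeros((0, len(samples), 4), int)
    )
    return SnpMatrix(
        ref_name or "reference", length, samples,
        np.array(positions), np.array(ref_bases), counts,
    )


def write_vcf_counts(matrix: SnpMatrix, path: str | Path) -> None:
    """Write counts as an uncompressed multi-sample VCF with AD fields."""
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={matrix.reference_name},length={matrix.reference_length}>",
        '##FORMAT=<ID=AD,Number=R,Type=Integer,'
        'Description="Allelic depths (ref first)">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(matrix.isolates),
    ]
    for i in range(matrix.n_sites):
        ref = str(matrix.ref_bases[i])
        present = matrix.counts[i].sum(axis=0) > 0
        alts = [b for k, b in enumerate(BASES) if present[k] and b != ref]
        alt_field = ",".join(alts) if alts else "."
        fields = []
        for j in range(len(matrix.isolates)):
            ad = [matrix.counts[i, j, BASE_INDEX[ref]]]
            ad += [matrix.counts[i, j, BASE_INDEX[b]] for b in alts]
            fields.append(",".join(str(int(x)) for x in ad))
        lines.append(
            f"{matrix.reference_name}\t{int(matrix.positions[i])}\t.\t{ref}\t"
            f"{alt_field}\t.\tPASS\t.\tAD\t" + "\t".join(fields)
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# reference FASTA
# ---------------------------------------------------------------------------

def read_reference(path: str | Path, circular: bool = True) -> ReferenceGenome:
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) == 0:
        raise SnpIOError(f"no FASTA record in {path}")
    if len(records) > 1:
        raise SnpIOError(f"expected a single-record reference, got {len(records)}")
    rec = records[0]
    seq = str(rec.seq).upper()
    bad = set(seq) - set(BASES) - AMBIGUITY_CODES
    if bad:
        raise SnpIOError(f"invalid characters in reference: {sorted(bad)}")
    return ReferenceGenome(rec.id, seq, circular=circular)


def write_reference(ref: ReferenceGenome, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{ref.name}\n")
        for i in range(0, ref.length, width):
            fh.write(ref.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# ORF annotation (GFF3 or TSV)
# ---------------------------------------------------------------------------

def read_annotation(
    path: str | Path, reference_length: int, circular: bool = True
) -> list[OrfRecord]:
    """Read ORF records with a ``function_class`` attribute from GFF3 or TSV.

    Wrap-around ORFs (end < start) are accepted only on circular references.
    """
    text = Path(path).read_text()
    if text.lstrip().startswith("##gff") or _looks_like_gff(text):
        orfs = _read_gff3(path, reference_length)
    else:
        orfs = _read_annotation_tsv(path, reference_length)
    for orf in orfs:
        if orf.wraps and not circular:
            raise SnpIOError(
                f"ORF {orf.id} wraps the origin but reference is not circular"
            )
    return orfs


def _looks_like_gff(text: str) -> bool:
    for line in text.splitlines():
        if line.startswith("#") or not line.strip():
            continue
        return len(line.split("\t")) == 9
    return False


def _read_gff3(path: str | Path, reference_length: int) -> list[OrfRecord]:
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    orfs = []
    for feat in db.all_features():
        if feat.featuretype not in ("CDS", "gene", "ORF"):
            continue
        attrs = {k.lower(): v for k, v in feat.attributes.items()}
        cls = (attrs.get("function_class") or attrs.get("product_class") or ["unknown"])[0]
        fid = (attrs.get("id") or attrs.get("locus_tag") or [feat.id])[0]
        start, end = feat.start, feat.end
        # GFF3 cannot encode end < start; wrap-around is conventionally stored
        # with end beyond the contig length.
        if end > reference_length:
            end -= reference_length
        orfs.append(
            OrfRecord(fid, start, end, feat.strand, cls, reference_length)
        )
    return orfs


def _read_annotation_tsv(path: str | Path, reference_length: int) -> list[OrfRecord]:
    df = pd.read_csv(path, sep="\t", comment="#")
    need = {"id", "start", "end", "strand", "function_class"}
    missing = need - set(c.lower() for c in df.columns)
    if missing:
        raise SnpIOError(f"annotation TSV missing columns {sorted(missing)}")
    df.columns = [c.lower() for c in df.columns]
    return [
        OrfRecord(
            str(r.id), int(r.start), int(r.end), str(r.strand),
            str(r.function_class), reference_length,
        )
        for r in df.itertuples()
    ]


def write_annotation_tsv(orfs: Iterable[OrfRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "id": o.id,
                "start": o.start,
                "end": o.end,
                "strand": o.strand,
                "function_class": o.function_class,
            }
            for o in orfs
        ]
    )
    df.to_csv(path, sep="\t", index=False)
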