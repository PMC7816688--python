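"""Synthetic references, genotype panels, mixed-isolate count matrices and
repeat-region reads with exact ground truth.

The generative model mirrors how deep sequencing of a mixed occlusion-body
preparation produces a count table: an isolate is a proportion-weighted pool
of genotypes; at a SNP carried by a subset of those genotypes, the
alternative read count is binomial with success probability equal to the
summed proportion of carrier genotypes, corrupted by a small uniform
base-miscall rate (each wrong base receives error/3).  Per-site depths are
truncated-normal around an isolate-specific mean, matching how mean±SD read
depths are reported for real panels.

:func:`study_panel` builds the default 20-isolate CpGV-like panel whose
design constants are the published population structure this package is
organised around: a 123,529 bp circular reference, marker sets of sizes
58/68/24/30/89/21/22/75/45 for the named lineages, 290 low-frequency
background sets, 30 commercial-only SNPs and one reference-anomaly site at
position 105,178 — 753 variable positions in total, 544 of them
transitions, 665 in ORFs and 88 intergenic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .pe38_repeats import RepeatRegionSpec
from .snpio import (
    BASES,
    BASE_INDEX,
    IsolateInfo,
    IsolatePanel,
    OrfRecord,
    ReferenceGenome,
    SnpMatrix,
)

TRANSITION_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}


@dataclass(frozen=True)
class GenotypeSpec:
    id: str
    snps: tuple[tuple[int, str], ...]  # (1-based position, alt base)
    groups: tuple[str, ...] = ()

    def __post_init__(self):
        positions = [p for p, _ in self.snps]
        if len(set(positions)) != len(positions):
            raise ValueError(f"genotype {self.id}: duplicate SNP positions")


@dataclass(frozen=True)
class MixtureDesign:
    proportions: Mapping[str, Mapping[str, float]]  # isolate -> genotype -> prop

    def __post_init__(self):
        for iso, props in self.proportions.items():
            vals = np.array(list(props.values()), dtype=float)
            if (vals < 0).any():
                raise ValueError(f"isolate {iso}: negative proportion")
            if abs(vals.sum() - 1.0) > 1e-9:
                raise ValueError(
                    f"isolate {iso}: proportions sum to {vals.sum()}, not 1"
                )

    @property
    def isolates(self) -> list[str]:
        return list(self.proportions.keys())


@dataclass(frozen=True)
class SimulationConfig:
    #: either a single fixed depth or {isolate: (mean, sd)} truncated at 1
    depth: int | Mapping[str, tuple[float, float]] = 2000
    error_rate: float = 0.001
    seed: int = 0
    read_length: int = 151
    n_invariant_sites: int = 0

    def __post_init__(self):
        if not 0 <= self.error_rate <= 0.05:
            raise ValueError("error_rate must be in [0, 0.05]")


def random_reference(
    length: int, rng: np.random.Generator, name: str = "synthetic_ref",
    circular: bool = True,
) -> ReferenceGenome:
    seq = "".join(rng.choice(list(BASES), size=length))
    return ReferenceGenome(name, seq, circular=circular)


def _draw_alt(ref: str, rng: np.random.Generator, transition: bool | None = None) -> str:
    if transition is True:
        return TRANSITION_PARTNER[ref]
    candidates = [b for b in BASES if b != ref]
    if transition is False:
        candidates = [b for b in candidates if b != TRANSITION_PARTNER[ref]]
    return str(rng.choice(candidates))


def make_panel(
    n_genotypes: int,
    n_private_snps: int,
    reference_length: int,
    seed: int,
    shared_group_spec: Mapping[tuple[str, ...], int] | None = None,
) -> tuple[ReferenceGenome, list[GenotypeSpec], dict]:
    """Generic panel: ``n_genotypes`` genotypes with private SNP sets plus
    optional group-shared SNP blocks; fully reproducible for a fixed seed."""
    shared_group_spec = dict(shared_group_spec or {})
    total = n_genotypes * n_private_snps + sum(shared_group_spec.values())
    if total >= reference_length / 10:
        raise ValueError("too many SNPs for the reference length")
    rng = np.random.default_rng(seed)
    reference = random_reference(reference_length, rng)
    positions = rng.choice(
        np.arange(1, reference_length + 1), size=total, replace=False
    )
    positions = [int(p) for p in positions]
    cursor = 0
    names = [f"g{chr(ord('a') + i)}" for i in range(n_genotypes)]
    private: dict[str, list[tuple[int, str]]] = {g: [] for g in names}
    for g in names:
        for _ in range(n_private_snps):
            pos = positions[cursor]
            cursor += 1
            private[g].append((pos, _draw_alt(reference.base(pos), rng)))
    shared: dict[tuple[str, ...], list[tuple[int, str]]] = {}
    for members, count in shared_group_spec.items():
        block = []
        for _ in range(count):
            pos = positions[cursor]
            cursor += 1
            block.append((pos, _draw_alt(reference.base(pos), rng)))
        shared[tuple(members)] = block
    genotypes = []
    for g in names:
        snps = list(private[g])
        for members, block in shared.items():
            if g in members:
                snps.extend(block)
        genotypes.append(GenotypeSpec(id=g, snps=tuple(sorted(snps))))
    truth = {
        "seed": seed,
        "private": {g: sorted(p for p, _ in private[g]) for g in names},
        "shared": {
            "+".join(members): sorted(p for p, _ in block)
            for members, block in shared.items()
        },
    }
    return reference, genotypes, truth


def simulate_counts(
    reference: ReferenceGenome,
    genotypes: Sequence[GenotypeSpec],
    design: MixtureDesign,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[SnpMatrix, dict]:
    """Draw a count matrix at all designed SNP positions (plus optional
    invariant padding sites) under the binomial mixture model."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    isolates = design.isolates
    by_id = {g.id: g for g in genotypes}
    for iso, props in design.proportions.items():
        unknown = set(props) - set(by_id)
        if unknown:
            raise KeyError(f"isolate {iso} mixes unknown genotypes {sorted(unknown)}")

    # designed positions with their alt base (must be consistent across genotypes)
    alt_at: dict[int, str] = {}
    for g in genotypes:
        for pos, alt in g.snps:
            if alt_at.setdefault(pos, alt) != alt:
                raise ValueError(f"conflicting alt bases designed at {pos}")
    snp_positions = sorted(alt_at)
    invariant = []
    if cfg.n_invariant_sites:
        pool = np.setdiff1d(
            np.arange(1, reference.length + 1), np.array(snp_positions, dtype=int)
        )
        invariant = sorted(
            int(p) for p in rng.choice(pool, size=cfg.n_invariant_sites, replace=False)
        )
    positions = np.array(sorted(snp_positions + invariant), dtype=np.int64)
    n, m = len(positions), len(isolates)
    pos_index = {int(p): i for i, p in enumerate(positions)}
    ref_bases = np.array([reference.base(int(p)) for p in positions], dtype="U1")

    # carrier proportion q per (site, isolate)
    q = np.zeros((n, m))
    for j, iso in enumerate(isolates):
        for gid, prop in design.proportions[iso].items():
            for pos, _alt in by_id[gid].snps:
                q[pos_index[pos], j] += prop
    q = np.clip(q, 0.0, 1.0)

    ref_idx = np.array([BASE_INDEX[b] for b in ref_bases], dtype=np.intp)
    alt_idx = ref_idx.copy()  # invariant sites: alt slot unused (q == 0 there)
    for pos, alt in alt_at.items():
        alt_idx[pos_index[pos]] = BASE_INDEX[alt]

    eps = cfg.error_rate
    pvals = np.full((n, m, 4), eps / 3.0)
    rows = np.arange(n)
    p_alt = q * (1 - eps) + (1 - q) * eps / 3.0
    p_ref = (1 - q) * (1 - eps) + q * eps / 3.0
    for j in range(m):
        pvals[rows, j, ref_idx] = p_ref[:, j]
        pvals[rows, j, alt_idx] = np.where(
            alt_idx == ref_idx, pvals[rows, j, ref_idx], p_alt[:, j]
        )
    pvals /= pvals.sum(axis=2, keepdims=True)

    # depths
    if isinstance(cfg.depth, Mapping):
        depths = np.empty((n, m), dtype=np.int64)
        for j, iso in enumerate(isolates):
            mean, sd = cfg.depth[iso]
            depths[:, j] = np.maximum(
                1, np.rint(rng.normal(mean, sd, size=n))
            ).astype(np.int64)
    else:
        depths = np.full((n, m), int(cfg.depth), dtype=np.int64)

    counts = rng.multinomial(depths, pvals)
    matrix = SnpMatrix(
        reference.name, reference.length, isolates, positions, ref_bases, counts,
        circular=reference.circular,
    )
    truth = {
        "seed": cfg.seed,
        "error_rate": eps,
        "snp_positions": snp_positions,
        "invariant_positions": invariant,
        "alt_bases": {str(p): a for p, a in sorted(alt_at.items())},
        "carrier_fraction": {
            iso: {str(int(p)): float(q[pos_index[int(p)], j]) for p in snp_positions}
            for j, iso in enumerate(isolates)
        },
    }
    return matrix, truth


# ---------------------------------------------------------------------------
# repeat-region reads
# ---------------------------------------------------------------------------

def _random_pad(
    length: int, rng: np.random.Generator, forbidden: Sequence[str]
) -> str:
    while True:
        pad = "".join(rng.choice(list(BASES), size=length))
        if not any(f in pad for f in forbidden):
            return pad


def simulate_repeat_reads(
    spec: RepeatRegionSpec,
    copy_distribution: Mapping[int, float],
    n_reads: int,
    rng: np.random.Generator,
    read_length: int = 151,
    pad: int = 80,
    span_only: bool = False,
    error_rate: float = 0.0,
) -> tuple[list[tuple[str, str]], dict]:
    """Reads over a synthetic repeat locus; a known fraction spans both flanks.

    Returns ``[(read_id, sequence), ...]`` plus the designed truth.  With
    ``span_only`` every read covers the whole flank-to-flank region, so at
    error rate 0 the recovered histogram equals the design exactly.
    """
    from .orf_stats import revcomp

    classes = sorted(copy_distribution)
    weights = np.array([copy_distribution[k] for k in classes], dtype=float)
    if not np.isclose(weights.sum(), 1.0):
        raise ValueError("copy distribution must sum to 1")
    max_copies = max(classes)
    min_span = len(spec.region(max_copies))
    if read_length < min_span and span_only:
        raise ValueError(
            f"read length {read_length} cannot span the {max_copies}x region "
            f"({min_span} nt)"
        )
    forbidden = (spec.upstream_flank, spec.downstream_flank, spec.motif)
    loci = {}
    for k in classes:
        left = _random_pad(pad, rng, forbidden)
        right = _random_pad(pad, rng, forbidden)
        loci[k] = left + spec.region(k) + right
    reads = []
    drawn = rng.choice(len(classes), size=n_reads, p=weights)
    for i, ci in enumerate(drawn):
        k = classes[int(ci)]
        locus = loci[k]
        span = len(spec.region(k))
        if span_only:
            lo = max(0, pad + span - read_length)
            hi = min(pad, len(locus) - read_length)
            if hi < lo:
                raise ValueError("read length too short to span this copy class")
        else:
            lo, hi = 0, len(locus) - read_length
        start = int(rng.integers(lo, hi + 1))
        seq = locus[start : start + read_length]
        if error_rate > 0:
            seq = _mutate(seq, error_rate, rng)
        if rng.random() < 0.5:
            seq = revcomp(seq)
        reads.append((f"read_{i}_{k}x", seq))
    truth = {
        "distribution": {str(k): float(copy_distribution[k]) for k in classes},
        "n_reads": n_reads,
        "drawn_counts": {
            str(k): int((drawn == i).sum()) for i, k in enumerate(classes)
        },
        "span_only": span_only,
    }
    return reads, truth


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    out = list(seq)
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    for i in hits:
        out[i] = _draw_alt(out[i], rng)
    return "".join(out)


def write_fastq(reads: Sequence[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_truth(truth: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth, indent=1, sort_keys=True))


# ===========================================================================
# the default study panel: 20 CpGV-like isolates
# ===========================================================================

STUDY_REFERENCE_LENGTH = 123_529
STUDY_ANOMALY_POSITION = 105_178
STUDY_N_TRANSITIONS = 544
STUDY_N_CODING = 665
STUDY_N_NONCODING = 88

FIELD_ISOLATES = (
    "M", "E2", "I12", "I0X", "S", "WW", "JQ", "ZY", "ZY2", "ALE", "KS1", "KS2",
)
COMMERCIAL_ISOLATES = ("R5", "V003", "0006P", "0006F", "V15")
SELECTED_ISOLATES = ("0015", "0017", "V34")
STUDY_ISOLATES = FIELD_ISOLATES + COMMERCIAL_ISOLATES + SELECTED_ISOLATES

#: per-isolate mean and SD of read depth, the reported sequencing scale
STUDY_DEPTHS: dict[str, tuple[float, float]] = {
    "M": (3995, 622), "E2": (4045, 725), "I12": (3603, 593),
    "I0X": (3406, 523), "S": (3320, 614), "WW": (928, 204),
    "JQ": (950, 184), "ZY": (595, 121), "ZY2": (968, 195),
    "ALE": (1076, 209), "KS1": (1057, 214), "KS2": (776, 149),
    "R5": (540, 162), "V003": (1301, 234), "0006P": (1584, 438),
    "0006F": (3734, 657), "V15": (2654, 448), "0015": (4345, 818),
    "0017": (2361, 371), "V34": (2389, 404),
}

STUDY_GENOME_GROUPS = {
    "M": "A", "E2": "B", "I12": "D", "I0X": "D", "S": "E", "WW": "E",
    "JQ": "F", "ZY": "F", "ZY2": "F", "ALE": "G", "KS1": "AD", "KS2": "AD",
    "R5": "AB", "V003": "A", "0006P": "AB", "0006F": "AB", "V15": "BE",
    "0015": "B", "0017": None, "V34": None,
}

#: genotype mixture of every isolate before background allocation; the gA
#: (reference-genotype) share also hosts the low-frequency background sets.
STUDY_MIXTURES: dict[str, dict[str, float]] = {
    "M":    {"gA": 1.00},
    "E2":   {"gA": 0.20, "gB": 0.80},
    "I12":  {"gA": 0.56, "gD": 0.02, "gE": 0.42},
    "I0X":  {"gA": 0.93, "gD": 0.07},
    "S":    {"gE": 1.00},
    "WW":   {"gE": 1.00},
    "JQ":   {"gA": 0.01, "gF": 0.80, "gE": 0.17, "gG2": 0.02},
    "ZY":   {"gA": 0.77, "gE": 0.23},
    "ZY2":  {"gA": 0.15, "gF": 0.61, "gF2": 0.16, "gE": 0.08},
    "ALE":  {"gA": 0.14, "gG": 0.80, "gE": 0.06},
    "KS1":  {"gA": 0.69, "gE": 0.31},
    "KS2":  {"gA": 0.86, "gE": 0.14},
    "V003": {"gA": 1.00},
    "R5":   {"gA": 0.33, "gB": 0.03, "gE": 0.64},
    "0006F": {"gA": 0.26, "gE": 0.74},
    "0006P": {"gA": 0.32, "gE": 0.68},
    "V15":  {"gA": 0.09, "gB": 0.42, "gE": 0.49},
    "0015": {"gA": 0.19, "gB": 0.81},
    "V34":  {"gA": 0.33, "gB": 0.39, "gE": 0.28},
    "0017": {"gA": 0.61, "gB": 0.11, "gE": 0.19, "gC": 0.09},
}

#: named marker sets: name -> (size, carrier genotypes)
STUDY_MARKER_SETS: dict[str, tuple[int, tuple[str, ...]]] = {
    "M":       (58, ("gB", "gD", "gE", "gF", "gF2")),
    "E2":      (68, ("gB",)),
    "I12+I0X": (24, ("gD",)),
    "ZY2":     (30, ("gF2",)),
    "F":       (89, ("gF", "gF2")),
    "ALE":     (21, ("gG",)),
    "FG":      (22, ("gG", "gG2")),
    "BDEFG":   (75, ("gB", "gE", "gF", "gF2")),
    "DEFG":    (45, ("gE", "gF", "gF2")),
}

#: lineage-letter scheme of the named sets, for group-collapse arithmetic
STUDY_SCHEME: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "B": frozenset("B"),
    "D": frozenset("D"),
    "F": frozenset("F"),
    "G": frozenset("G"),
    "FG": frozenset("FG"),
    "BDEFG": frozenset("BDEFG"),
    "DEFG": frozenset("DEFG"),
}
STUDY_GROUP_OF_SET = {
    "M": "A", "E2": "B", "I12+I0X": "D", "F": "F", "ALE": "G",
    "FG": "FG", "BDEFG": "BDEFG", "DEFG": "DEFG",
}

#: low-frequency background specificity labels (none collides with a named
#: label); labels containing ZY carry 7% to clear the absolute-count bound at
#: ZY's shallow depth, all others 5%.
BACKGROUND_LABELS: tuple[tuple[str, ...], ...] = (
    ("I12",), ("I0X",), ("ZY",), ("KS1",), ("KS2",),
    ("I12", "ZY"), ("I12", "KS1"), ("I12", "KS2"),
    ("I0X", "ZY"), ("I0X", "KS1"), ("I0X", "KS2"),
    ("ZY", "KS1"), ("ZY", "KS2"), ("KS1", "KS2"),
    ("E2", "I12"), ("E2", "KS1"), ("E2", "ZY"),
    ("ALE", "KS2"), ("ALE", "I0X"),
    ("I12", "ZY", "KS1"), ("I0X", "ZY", "KS2"), ("I12", "I0X", "KS1"),
    ("I12", "KS1", "KS2"), ("I0X", "KS1", "KS2"),
)
N_BACKGROUND_POSITIONS = 290
N_COMMERCIAL_ONLY = 30


def _background_delta(label: tuple[str, ...]) -> float:
    return 0.07 if "ZY" in label else 0.05


#: pe38-style repeat locus: the canonical 12-bp motif with synthetic unique
#: flanks of the stated lengths (12 nt upstream, 10 nt downstream)
STUDY_REPEAT_SPEC = RepeatRegionSpec(
    upstream_flank="ATTCGGTCAAGC",
    downstream_flank="TGGCTTACAA",
    motif="GACACAGTGGAT",
)

#: designed motif copy-number mixtures for the repeat read sets simulated in
#: the worked analysis (single-copy fraction marks resistance-overcoming
#: genotypes)
STUDY_REPEAT_DESIGNS: dict[str, tuple[dict[int, float], int]] = {
    "M": ({1: 0.001, 2: 0.999}, 3000),
    "V003": ({1: 0.95, 2: 0.05}, 1361),
    "KS2": ({1: 0.10, 2: 0.20, 3: 0.30, 4: 0.30, 5: 0.10}, 400),
}


@dataclass(frozen=True)
class StudyPanel:
    reference: ReferenceGenome
    annotation: tuple[OrfRecord, ...]
    genotypes: tuple[GenotypeSpec, ...]
    design: MixtureDesign
    config: SimulationConfig
    panel: IsolatePanel
    marker_scheme: dict
    repeat_spec: RepeatRegionSpec
    truth: dict


def generate_annotation(
    reference_length: int,
    rng: np.random.Generator,
    must_cover: Sequence[int] = (),
) -> list[OrfRecord]:
    """Tile the circular genome with non-overlapping ORFs plus one ORF
    wrapping the origin; positions in ``must_cover`` are guaranteed coding."""
    classes = list(
        ("biological regulation", "DNA replication", "metabolic process",
         "structural protein", "virus transcription")
    )
    orfs: list[tuple[int, int]] = []
    # wrap-around ORF across the origin
    wrap_end = int(rng.integers(400, 900))
    wrap_len = 3 * int(rng.integers(250, 400))
    wrap_start = reference_length - (wrap_len - wrap_end) + 1
    cursor = wrap_end + int(rng.integers(40, 200))
    while cursor < wrap_start - 400:
        length = 3 * int(rng.integers(100, 800))
        end = min(cursor + length - 1, wrap_start - 40)
        length = ((end - cursor + 1) // 3) * 3
        if length < 150:
            break
        orfs.append((cursor, cursor + length - 1))
        cursor = cursor + length + int(rng.integers(30, 250))
    # make sure required positions are inside an ORF
    spans = sorted(orfs)
    for pos in must_cover:
        inside = any(s <= pos <= e for s, e in spans) or (
            pos >= wrap_start or pos <= wrap_end
        )
        if not inside:
            # extend the nearest preceding ORF by whole codons to cover pos
            for i, (s, e) in enumerate(spans):
                nxt = spans[i + 1][0] if i + 1 < len(spans) else wrap_start
                if s <= pos and e < pos < nxt:
                    need = pos - e
                    ext = ((need + 2) // 3) * 3
                    if e + ext < nxt - 10:
                        spans[i] = (s, e + ext)
                    elif i + 1 < len(spans):
                        # extend the following ORF backwards instead
                        ns, ne = spans[i + 1]
                        back = ((ns - pos + 2) // 3) * 3
                        if ns - back > e + 10:
                            spans[i + 1] = (ns - back, ne)
                    break
    records = []
    for i, (s, e) in enumerate(sorted(spans), start=1):
        cls = (
            "unknown" if rng.random() < 0.42
            else classes[int(rng.integers(len(classes)))]
        )
        strand = "+" if rng.random() < 0.5 else "-"
        records.append(
            OrfRecord(f"ORF{i:03d}", s, e, strand, cls, reference_length)
        )
    records.append(
        OrfRecord(
            f"ORF{len(records) + 1:03d}", wrap_start, wrap_end,
            "+" if rng.random() < 0.5 else "-",
            "structural protein", reference_length,
        )
    )
    return records


def _coding_mask(annotation: Sequence[OrfRecord], length: int) -> np.ndarray:
    mask = np.zeros(length + 1, dtype=bool)  # index 1..length
    for orf in annotation:
        if orf.wraps:
            mask[orf.start : length + 1] = True
            mask[1 : orf.end + 1] = True
        else:
            mask[orf.start : orf.end + 1] = True
    mask[0] = False
    return mask


def study_panel(seed: int) -> StudyPanel:
    """Build the 20-isolate study panel (reference, annotation, genotypes,
    mixture design, depths) with full ground truth."""
    rng = np.random.default_rng(seed)
    reference = random_reference(STUDY_REFERENCE_LENGTH, rng, name="GV_ref")
    annotation = generate_annotation(
        STUDY_REFERENCE_LENGTH, rng, must_cover=(STUDY_ANOMALY_POSITION,)
    )
    mask = _coding_mask(annotation, STUDY_REFERENCE_LENGTH)
    coding_pool = np.flatnonzero(mask)
    noncoding_pool = np.flatnonzero(~mask[1:]) + 1

    n_total = (
        sum(size for size, _ in STUDY_MARKER_SETS.values())
        + N_BACKGROUND_POSITIONS + N_COMMERCIAL_ONLY + 1
    )
    coding_pool = coding_pool[coding_pool != STUDY_ANOMALY_POSITION]
    coding_positions = rng.choice(coding_pool, size=STUDY_N_CODING - 1, replace=False)
    coding_positions = np.append(coding_positions, STUDY_ANOMALY_POSITION)
    noncoding_positions = rng.choice(
        noncoding_pool, size=STUDY_N_NONCODING, replace=False
    )
    positions = np.concatenate([coding_positions, noncoding_positions])
    assert len(positions) == n_total == 753

    # alternative bases: fixed transition count, rest transversions
    is_ts = np.zeros(n_total, dtype=bool)
    is_ts[rng.choice(n_total, size=STUDY_N_TRANSITIONS, replace=False)] = True
    alts = {
        int(p): _draw_alt(reference.base(int(p)), rng, transition=bool(t))
        for p, t in zip(positions, is_ts)
    }

    # partition positions into marker sets (anomaly position is fixed)
    assignable = [int(p) for p in positions if p != STUDY_ANOMALY_POSITION]
    rng.shuffle(assignable)
    cursor = 0
    set_positions: dict[str, list[int]] = {}
    for name, (size, _carriers) in STUDY_MARKER_SETS.items():
        set_positions[name] = sorted(assignable[cursor : cursor + size])
        cursor += size
    bg_sizes = [13, 13] + [12] * (len(BACKGROUND_LABELS) - 2)
    assert sum(bg_sizes) == N_BACKGROUND_POSITIONS
    bg_positions: dict[tuple[str, ...], list[int]] = {}
    for label, size in zip(BACKGROUND_LABELS, bg_sizes):
        bg_positions[label] = sorted(assignable[cursor : cursor + size])
        cursor += size
    commercial_positions = sorted(assignable[cursor : cursor + N_COMMERCIAL_ONLY])
    cursor += N_COMMERCIAL_ONLY
    assert cursor == len(assignable)

    # genotypes
    def snps_of(pos_list):
        return tuple(sorted((p, alts[p]) for p in pos_list))

    carries: dict[str, list[int]] = {
        g: [] for g in ("gA", "gB", "gD", "gE", "gF", "gF2", "gG", "gG2", "gC")
    }
    for name, (_size, carriers) in STUDY_MARKER_SETS.items():
        for g in carriers:
            carries[g].extend(set_positions[name])
    carries["gC"].extend(commercial_positions)
    group_of = {
        "gA": ("A",), "gB": ("B",), "gD": ("D",), "gE": ("E",),
        "gF": ("F",), "gF2": ("F",), "gG": ("G",), "gG2": ("G",), "gC": (),
    }
    genotypes = []
    for g, pos_list in carries.items():
        pos_list = pos_list + [STUDY_ANOMALY_POSITION]  # anomaly in everyone
        genotypes.append(
            GenotypeSpec(id=g, snps=snps_of(pos_list), groups=group_of[g])
        )
    bg_names = {}
    for i, (label, pos_list) in enumerate(bg_positions.items(), start=1):
        gid = f"gBg{i:02d}"
        bg_names[label] = gid
        genotypes.append(
            GenotypeSpec(
                id=gid, snps=snps_of(pos_list + [STUDY_ANOMALY_POSITION])
            )
        )

    # mixtures: background genotypes take their share out of gA
    mixtures = {iso: dict(props) for iso, props in STUDY_MIXTURES.items()}
    for label, gid in bg_names.items():
        delta = _background_delta(label)
        for iso in label:
            mixtures[iso][gid] = delta
            mixtures[iso]["gA"] = round(mixtures[iso]["gA"] - delta, 10)
    for iso, props in mixtures.items():
        if props.get("gA", 1.0) < -1e-9:
            raise RuntimeError(f"background allocation exhausted gA in {iso}")
        if "gA" in props and props["gA"] <= 0:
            del props["gA"]
    design = MixtureDesign(proportions={iso: mixtures[iso] for iso in STUDY_ISOLATES})

    cfg = SimulationConfig(depth=STUDY_DEPTHS, error_rate=0.001, seed=seed)
    infos = (
        [IsolateInfo(i, genome_group=STUDY_GENOME_GROUPS[i], role="field")
         for i in FIELD_ISOLATES]
        + [IsolateInfo(i, genome_group=STUDY_GENOME_GROUPS[i], role="commercial")
           for i in COMMERCIAL_ISOLATES]
        + [IsolateInfo(i, genome_group=STUDY_GENOME_GROUPS[i], role="selected")
           for i in SELECTED_ISOLATES]
    )
    panel = IsolatePanel(isolates=tuple(infos))

    # expected specificity labels (over the field subset)
    expected_labels = {
        "M": tuple(sorted(set(FIELD_ISOLATES) - {"M"})),
        "E2": ("E2",),
        "I12+I0X": ("I0X", "I12"),
        "ZY2": ("ZY2",),
        "F": ("JQ", "ZY2"),
        "ALE": ("ALE",),
        "FG": ("ALE", "JQ"),
        "BDEFG": tuple(sorted(set(FIELD_ISOLATES) - {"M", "I0X"})),
        "DEFG": tuple(sorted(set(FIELD_ISOLATES) - {"M", "I0X", "E2"})),
    }
    marker_scheme = {
        name: {
            "size": len(set_positions[name]),
            "positions": set_positions[name],
            "label": expected_labels[name],
            "group": STUDY_GROUP_OF_SET.get(name),
            "allele": "ref" if name == "M" else "alt",
        }
        for name in STUDY_MARKER_SETS
    }
    truth = {
        "seed": seed,
        "n_positions": n_total,
        "anomaly_position": STUDY_ANOMALY_POSITION,
        "n_transitions": STUDY_N_TRANSITIONS,
        "n_coding": STUDY_N_CODING,
        "n_noncoding": STUDY_N_NONCODING,
        "commercial_only_positions": commercial_positions,
        "background": {
            "+".join(label): pos for label, pos in bg_positions.items()
        },
        "mixtures": {iso: dict(m) for iso, m in mixtures.items()},
    }
    return StudyPanel(
        reference=reference,
        annotation=tuple(annotation),
        genotypes=tuple(genotypes),
        design=design,
        config=cfg,
        panel=panel,
        marker_scheme=marker_scheme,
        repeat_spec=STUDY_REPEAT_SPEC,
        truth=truth,
    )


def study_matrix(seed: int, n_invariant_sites: int = 400) -> tuple[StudyPanel, SnpMatrix]:
    """Convenience: build the study panel and draw its count matrix."""
    sp = study_panel(seed)
    cfg = SimulationConfig(
        depth=STUDY_DEPTHS, error_rate=sp.config.error_rate, seed=seed,
        n_invariant_sites=n_invariant_sites,
    )
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    matrix, _ = simulate_counts(sp.reference, sp.genotypes, sp.design, cfg, rng=rng)
    return sp, matrix
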