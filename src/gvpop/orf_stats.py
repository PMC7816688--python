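"""SNP classification against an ORF annotation and per-class density statistics.

Classification is wrap-aware on circular genomes: an ORF with end < start
spans the origin, codon positions are counted in-frame along the coding
strand, and synonymy is decided by translating the reference and mutated
codons with the standard genetic code.  A SNP inside several overlapping
ORFs is classified per ORF; genome-wide tallies deduplicate it onto the
lexicographically lowest ORF id and count it nonsynonymous if it is
nonsynonymous in any containing frame (the conservative choice).

Per-ORF SNP density is SNPs per kbp of ORF length.  Densities are brought
to approximate normality with a Tukey ladder-of-powers transform before a
one-way ANOVA across functional classes, Tukey-HSD pairwise comparisons and
a pooled known-vs-unknown-function t test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .snpio import BASES, OrfRecord, ReferenceGenome

CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}


def is_transition(ref: str, alt: str) -> bool:
    return (ref in PURINES and alt in PURINES) or (
        ref in PYRIMIDINES and alt in PYRIMIDINES
    )


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class OrfHit:
    orf_id: str
    codon_position: int  # 1, 2, 3
    ref_codon: str
    alt_codon: str
    synonymous: bool


@dataclass(frozen=True)
class SnpEffect:
    position: int
    ref_base: str
    alt_base: str
    hits: tuple[OrfHit, ...]

    @property
    def coding(self) -> bool:
        return bool(self.hits)

    @property
    def primary_hit(self) -> OrfHit | None:
        """Deduplicated genome-wide assignment: lowest ORF id."""
        if not self.hits:
            return None
        return min(self.hits, key=lambda h: h.orf_id)

    @property
    def synonymous(self) -> bool | None:
        """Genome-wide call: nonsynonymous if nonsynonymous in any frame."""
        if not self.hits:
            return None
        return all(h.synonymous for h in self.hits)

    @property
    def overlapping(self) -> bool:
        return len(self.hits) > 1


def classify_snp(
    position: int,
    ref_base: str,
    alt_base: str,
    annotation: Sequence[OrfRecord],
    reference: ReferenceGenome,
) -> SnpEffect:
    """Classify one SNP: containing ORFs, codon position and synonymy per ORF."""
    if ref_base == alt_base:
        raise ValueError("alternative base equals reference base")
    if reference.base(position) != ref_base:
        raise ValueError(
            f"reference base mismatch at {position}: matrix says {ref_base}, "
            f"sequence says {reference.base(position)}"
        )
    L = reference.length
    hits = []
    for orf in annotation:
        if not orf.contains(position):
            continue
        if orf.length % 3 != 0:
            raise ValueError(f"ORF {orf.id} length {orf.length} not divisible by 3")
        if orf.strand == "+":
            offset = (position - orf.start) % L
        else:
            offset = (orf.end - position) % L
        codon_pos = offset % 3 + 1
        codon_start_offset = offset - (offset % 3)
        if orf.strand == "+":
            genomic = [orf.start + codon_start_offset + k for k in range(3)]
            ref_codon = "".join(reference.base(((p - 1) % L) + 1) for p in genomic)
            slot = codon_pos - 1
            alt_codon = ref_codon[:slot] + alt_base + ref_codon[slot + 1 :]
        else:
            genomic = [orf.end - codon_start_offset - k for k in range(3)]
            ref_codon = "".join(
                reference.base(((p - 1) % L) + 1).translate(_COMPLEMENT)
                for p in genomic
            )
            slot = codon_pos - 1
            alt_codon = (
                ref_codon[:slot]
                + alt_base.translate(_COMPLEMENT)
                + ref_codon[slot + 1 :]
            )
        syn = CODON_TABLE[ref_codon] == CODON_TABLE[alt_codon]
        hits.append(OrfHit(orf.id, codon_pos, ref_codon, alt_codon, syn))
    return SnpEffect(position, ref_base, alt_base, tuple(hits))


def classify_all(
    positions: Sequence[int],
    ref_bases: Sequence[str],
    alt_bases: Sequence[str],
    annotation: Sequence[OrfRecord],
    reference: ReferenceGenome,
) -> list[SnpEffect]:
    return [
        classify_snp(int(p), str(r), str(a), annotation, reference)
        for p, r, a in zip(positions, ref_bases, alt_bases)
    ]


def category_tallies(effects: Sequence[SnpEffect]) -> dict[str, int]:
    """Genome-wide SNP category counts (transition/transversion, coding,
    codon position, synonymy, overlaps)."""
    tall = {
        "total": len(effects),
        "transitions": 0,
        "transversions": 0,
        "coding": 0,
        "noncoding": 0,
        "codon_pos_1": 0,
        "codon_pos_2": 0,
        "codon_pos_3": 0,
        "synonymous": 0,
        "nonsynonymous": 0,
        "in_overlapping_orfs": 0,
    }
    for e in effects:
        tall["transitions" if is_transition(e.ref_base, e.alt_base) else
             "transversions"] += 1
        if e.coding:
            tall["coding"] += 1
            hit = e.primary_hit
            tall[f"codon_pos_{hit.codon_position}"] += 1
            tall["synonymous" if e.synonymous else "nonsynonymous"] += 1
            if e.overlapping:
                tall["in_overlapping_orfs"] += 1
        else:
            tall["noncoding"] += 1
    assert tall["coding"] + tall["noncoding"] == tall["total"]
    return tall


@dataclass(frozen=True)
class OrfSnpStats:
    orf_id: str
    snp_count: int
    length: int
    density: float  # SNPs per kbp
    function_class: str


def density_table(
    effects: Sequence[SnpEffect], annotation: Sequence[OrfRecord]
) -> tuple[list[OrfSnpStats], pd.DataFrame]:
    """Per-ORF SNP densities plus per-class mean ± SEM summary.

    Every containing ORF counts the SNP (overlaps are intentional here —
    density is a per-ORF quantity); fully conserved ORFs appear with density 0.
    """
    counts = {orf.id: 0 for orf in annotation}
    for e in effects:
        for hit in e.hits:
            counts[hit.orf_id] += 1
    rows = [
        OrfSnpStats(
            orf_id=orf.id,
            snp_count=counts[orf.id],
            length=orf.length,
            density=counts[orf.id] / (orf.length / 1000.0),
            function_class=orf.function_class,
        )
        for orf in annotation
    ]
    df = pd.DataFrame(
        [(r.function_class, r.density) for r in rows],
        columns=["function_class", "density"],
    )
    summary = (
        df.groupby("function_class")["density"]
        .agg(n="size", mean="mean", sem=lambda x: x.std(ddof=1) / np.sqrt(len(x)))
        .reset_index()
    )
    return rows, summary


def conserved_orfs(stats: Sequence[OrfSnpStats]) -> list[str]:
    return [s.orf_id for s in stats if s.snp_count == 0]


# ---------------------------------------------------------------------------
# Tukey ladder of powers + class comparison
# ---------------------------------------------------------------------------

def tukey_transform(
    values: Sequence[float], grid: np.ndarray | None = None
) -> tuple[np.ndarray, float]:
    """Tukey ladder-of-powers transform toward normality.

    lambda is chosen on a fixed grid (default -2..2, step 0.05) to maximise
    the Shapiro-Wilk W of the transformed sample; for lambda<0 the transform
    is negated to stay monotone increasing, lambda=0 means log.  Zeros or
    negatives restrict the grid to lambda>0.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 values")
    if np.allclose(x, x[0]):
        raise ValueError("constant input cannot be transformed to normal")
    if (x < 0).any():
        raise ValueError("values must be non-negative")
    if grid is None:
        grid = np.round(np.arange(-2.0, 2.0001, 0.05), 10)
    has_nonpositive = (x <= 0).any()
    best_w, best_lam, best_t = -np.inf, 1.0, x
    for lam in grid:
        if lam <= 0 and has_nonpositive:
            continue
        if lam > 0:
            t = x ** lam
        elif lam == 0:
            t = np.log(x)
        else:
            t = -(x ** lam)
        if np.allclose(t, t[0]):
            continue
        w = stats.shapiro(t).statistic
        if w > best_w:
            best_w, best_lam, best_t = w, float(lam), t
    return best_t, best_lam


@dataclass(frozen=True)
class ClassComparison:
    anova_f: float
    df_between: int
    df_within: int
    anova_p: float
    tukey_hsd: pd.DataFrame
    t_statistic: float
    t_p: float
    t_df: int


def compare_classes(
    densities_by_class: Mapping[str, Sequence[float]],
    unknown_class: str = "unknown",
    hsd: bool = True,
) -> ClassComparison:
    """One-way ANOVA + Tukey HSD across classes, and pooled known-vs-unknown t test."""
    groups = {k: np.asarray(v, dtype=float) for k, v in densities_by_class.items()}
    if len(groups) < 2:
        raise ValueError("need at least two classes")
    for name, g in groups.items():
        if g.size < 2:
            raise ValueError(f"class {name!r} has fewer than 2 observations")
    arrays = list(groups.values())
    if all(np.allclose(g, arrays[0][0]) for g in arrays):
        raise ValueError("all groups constant: F undefined")
    f_stat, p = stats.f_oneway(*arrays)
    k = len(arrays)
    n = sum(g.size for g in arrays)

    if hsd:
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        values = np.concatenate(arrays)
        labels = np.concatenate([[name] * g.size for name, g in groups.items()])
        res = pairwise_tukeyhsd(values, labels)
        hsd_df = pd.DataFrame(res.summary().data[1:], columns=res.summary().data[0])
    else:
        hsd_df = pd.DataFrame()

    known = np.concatenate([g for name, g in groups.items() if name != unknown_class])
    unknown = groups.get(unknown_class)
    if unknown is None:
        t_stat, t_p, t_df = np.nan, np.nan, 0
    else:
        t_stat, t_p = stats.ttest_ind(known, unknown, equal_var=True)
        t_df = known.size + unknown.size - 2
    return ClassComparison(
        anova_f=float(f_stat), df_between=k - 1, df_within=n - k,
        anova_p=float(p), tukey_hsd=hsd_df,
        t_statistic=float(t_stat), t_p=float(t_p), t_df=t_df,
    )
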