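"""Heme-binding motif census of c-type cytochromes.

The covalent heme C attachment site of a c-type cytochrome is the
cysteine-pair/histidine pattern CXXCH, with the rarer spaced variants
CX3CH (CXXXCH) and CX4CH (CXXXXCH).  Counting these motifs across a
proteome gives a census of putative c-type cytochromes; proteins carrying
several are multiheme cytochromes (MHCs), the workhorses of extracellular
electron transfer.

Scanning policy: because two heme attachments cannot share a cysteine, hits
are selected non-overlapping by a leftmost-start greedy rule with a
shortest-span tie-break at equal start, and scanning resumes immediately
after each accepted hit.  An ``overlap="allow"`` mode reports every match
of every class instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .records import GenomeAnnotation

MOTIF_CLASSES = ("CXXCH", "CX3CH", "CX4CH")
SPAN_BY_CLASS = {"CXXCH": 5, "CX3CH": 6, "CX4CH": 7}
CLASS_BY_SPAN = {5: "CXXCH", 6: "CX3CH", 7: "CX4CH"}

DEFAULT_BIN_EDGES = (1, 2, 3, 4, 10)
DEFAULT_MIN_MHC = 3


@dataclass(frozen=True)
class HemeMotifHit:
    protein_id: str
    start: int  # 0-based offset of the first C
    motif_class: str
    span: int


def _match_at(sequence: str, start: int, span: int) -> bool:
    """Does a heme motif of the given span start here?

    Anchors (first C, second C, terminal H) are literal; the wildcard
    positions between the cysteines accept any alphabetic character
    (including ambiguity codes); '*' never matches, so motifs cannot span
    an internal stop codon.
    """
    end = start + span
    if end > len(sequence):
        return False
    if sequence[start] != "C":
        return False
    if sequence[end - 2] != "C" or sequence[end - 1] != "H":
        return False
    for i in range(start + 1, end - 2):
        if not sequence[i].isalpha():
            return False
    return True


def enumerate_matches(sequence: str) -> list[tuple[int, int]]:
    """All ``(start, span)`` motif matches, overlapping ones included."""
    out = []
    for start in range(len(sequence)):
        for span in (5, 6, 7):
            if _match_at(sequence, start, span):
                out.append((start, span))
    return out


def scan_protein(
    sequence: str, protein_id: str = "", overlap: str = "greedy"
) -> list[HemeMotifHit]:
    """Scan one amino-acid sequence for heme-binding motifs.

    With ``overlap="greedy"`` (default) hits are non-overlapping:
    leftmost start wins, shortest span breaks ties at equal start, and the
    scan resumes at ``start + span``.  ``overlap="allow"`` returns every
    match.  An empty sequence yields an empty result.
    """
    if overlap not in {"greedy", "allow"}:
        raise ValueError(f"unknown overlap policy {overlap!r}")
    if overlap == "allow":
        return [
            HemeMotifHit(protein_id, s, CLASS_BY_SPAN[w], w)
            for s, w in enumerate_matches(sequence)
        ]
    hits: list[HemeMotifHit] = []
    pos = 0
    n = len(sequence)
    while pos < n:
        matched = False
        for span in (5, 6, 7):  # shortest span first at equal start
            if _match_at(sequence, pos, span):
                hits.append(HemeMotifHit(protein_id, pos, CLASS_BY_SPAN[span], span))
                pos += span
                matched = True
                break
        if not matched:
            pos += 1
    return hits


@dataclass(frozen=True)
class HemeProfile:
    protein_id: str
    n_cxxch: int
    n_cx3ch: int
    n_cx4ch: int
    category: str

    @property
    def total_hemes(self) -> int:
        return self.n_cxxch + self.n_cx3ch + self.n_cx4ch


def _categorize(total: int, bin_edges: Sequence[int]) -> str:
    """Bin a motif count into the histogram category labels.

    Edges ``(1, 2, 3, 4, 10)`` give bins ``1``, ``2``, ``3``, ``4-9``,
    ``10+`` — the layout used to contrast FeOB against NOB proteomes.
    """
    label = None
    for i, lo in enumerate(bin_edges):
        if total < lo:
            break
        if i + 1 < len(bin_edges):
            hi = bin_edges[i + 1] - 1
            label = str(lo) if hi == lo else f"{lo}-{hi}"
        else:
            label = f"{lo}+"
    if label is None:
        raise ValueError(f"count {total} below first bin edge {bin_edges[0]}")
    return label


def category_labels(bin_edges: Sequence[int] = DEFAULT_BIN_EDGES) -> list[str]:
    labels = []
    for i, lo in enumerate(bin_edges):
        if i + 1 < len(bin_edges):
            hi = bin_edges[i + 1] - 1
            labels.append(str(lo) if hi == lo else f"{lo}-{hi}")
        else:
            labels.append(f"{lo}+")
    return labels


def profile_protein(
    protein_id: str, sequence: str, bin_edges: Sequence[int] = DEFAULT_BIN_EDGES
) -> HemeProfile | None:
    hits = scan_protein(sequence, protein_id)
    if not hits:
        return None
    counts = {"CXXCH": 0, "CX3CH": 0, "CX4CH": 0}
    for h in hits:
        counts[h.motif_class] += 1
    total = sum(counts.values())
    return HemeProfile(
        protein_id=protein_id,
        n_cxxch=counts["CXXCH"],
        n_cx3ch=counts["CX3CH"],
        n_cx4ch=counts["CX4CH"],
        category=_categorize(total, bin_edges),
    )


@dataclass
class GenomeHemeSummary:
    genome_id: str
    n_motif_proteins: int
    n_mhc: int
    histogram: dict[str, int]


def profile_genome(
    genome: GenomeAnnotation,
    bin_edges: Sequence[int] = DEFAULT_BIN_EDGES,
    min_mhc: int = DEFAULT_MIN_MHC,
) -> tuple[list[HemeProfile], GenomeHemeSummary]:
    """Profile every protein of a genome; summarize counts and the
    per-category histogram (the per-genome bar-graph data)."""
    edges = tuple(bin_edges)
    if list(edges) != sorted(set(edges)):
        raise ValueError(f"bin_edges must be strictly increasing, got {bin_edges}")
    profiles = []
    hist = {label: 0 for label in category_labels(edges)}
    n_mhc = 0
    for p in genome.proteins:
        prof = profile_protein(p.protein_id, p.sequence, edges)
        if prof is None:
            continue
        profiles.append(prof)
        hist[prof.category] += 1
        if prof.total_hemes >= min_mhc:
            n_mhc += 1
    summary = GenomeHemeSummary(
        genome_id=genome.genome_id,
        n_motif_proteins=len(profiles),
        n_mhc=n_mhc,
        histogram=hist,
    )
    return profiles, summary


def cohort_heme_ratio(
    genomes_a: Iterable[GenomeAnnotation], genomes_b: Iterable[GenomeAnnotation]
) -> dict:
    """Ratio of mean per-genome counts of motif-bearing proteins (A over B).

    This is the FeOB-vs-NOB style contrast: how many more putative c-type
    cytochromes the first group's genomes carry on average.
    """
    counts_a = {
        g.genome_id: profile_genome(g)[1].n_motif_proteins for g in genomes_a
    }
    counts_b = {
        g.genome_id: profile_genome(g)[1].n_motif_proteins for g in genomes_b
    }
    if not counts_a or not counts_b:
        raise ValueError("both groups must be non-empty")
    mean_a = sum(counts_a.values()) / len(counts_a)
    mean_b = sum(counts_b.values()) / len(counts_b)
    if mean_b == 0:
        raise ValueError("degenerate denominator: group B has no motif-bearing proteins")
    return {
        "ratio": mean_a / mean_b,
        "mean_a": mean_a,
        "mean_b": mean_b,
        "counts_a": counts_a,
        "counts_b": counts_b,
    }
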