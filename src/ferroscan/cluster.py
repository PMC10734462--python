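"""Homolog clustering of motif-bearing proteins and cluster classification.

Edges connect protein pairs whose local alignment covers at least 80% of
*both* sequences (bidirectional coverage) and passes an identity floor.
Clusters are built by iterative greedy set cover: the unassigned protein
with the most unassigned neighbors becomes a centroid and absorbs them;
ties break toward the longer sequence, then the lexicographically smaller
id, so the partition is deterministic.

Classification follows the isolate-representative-first rule: a cluster
containing a catalog sequence inherits its role label outright; otherwise
each member is searched against the catalog and the majority label among
qualifying best hits is used (consensus), with ties reported as
"ambiguous" and no qualifying hits as "unclassified".
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

from .align import AlignmentResult, kmer_set, pairwise_align, shares_kmers
from .records import ProteinRecord, ReferenceCatalog

log = logging.getLogger(__name__)

DEFAULT_MIN_COV = 0.8
DEFAULT_MIN_ID = 30.0
CLASSIFY_MIN_ID = 35.0
CLASSIFY_MIN_COV = 0.7


def similarity_edges(
    proteins: list[ProteinRecord],
    min_cov: float = DEFAULT_MIN_COV,
    min_id: float = DEFAULT_MIN_ID,
    prefilter: bool = True,
) -> list[tuple[str, str]]:
    """All-vs-all similarity edges under bidirectional coverage.

    An undirected edge (a, b) is emitted iff the local alignment covers at
    least ``min_cov`` of both sequences and its identity is >= ``min_id``.
    """
    seqs = {p.protein_id: p.sequence for p in proteins}
    if len(seqs) != len(proteins):
        raise ValueError("duplicate protein ids in clustering input")
    kmers = {pid: kmer_set(s) for pid, s in seqs.items()} if prefilter else {}
    edges: list[tuple[str, str]] = []
    for a, b in itertools.combinations(sorted(seqs), 2):
        sa, sb = seqs[a], seqs[b]
        # the aligned region cannot exceed the shorter sequence, so a large
        # length mismatch can never satisfy bidirectional coverage
        if min(len(sa), len(sb)) < min_cov * max(len(sa), len(sb)):
            continue
        if prefilter and not shares_kmers(sa, sb, kmers[a], kmers[b]):
            continue
        res = pairwise_align(sa, sb, a, b)
        if (
            res.query_cov >= min_cov
            and res.target_cov >= min_cov
            and res.identity >= min_id
        ):
            edges.append((a, b))
    return edges


@dataclass
class ClusterAssignment:
    cluster_id: int
    centroid_id: str
    members: set[str] = field(default_factory=set)
    label: str = "unclassified"
    label_source: str = "none"  # isolate-representative | consensus | none


def greedy_cluster(
    proteins: list[ProteinRecord], edges: list[tuple[str, str]]
) -> list[ClusterAssignment]:
    """Partition proteins by iterative greedy set cover over the edge graph.

    Singletons (no surviving neighbors) become their own clusters.  The
    result is a partition: every protein appears in exactly one cluster.
    """
    length = {p.protein_id: len(p.sequence) for p in proteins}
    adj: dict[str, set[str]] = {p.protein_id: set() for p in proteins}
    for a, b in edges:
        if a == b:
            continue
        adj[a].add(b)
        adj[b].add(a)
    unassigned = set(adj)
    clusters: list[ClusterAssignment] = []
    while unassigned:
        # most unassigned neighbors; ties -> longer sequence -> smaller id
        centroid = min(
            unassigned,
            key=lambda pid: (-len(adj[pid] & unassigned), -length[pid], pid),
        )
        members = {centroid} | (adj[centroid] & unassigned)
        unassigned -= members
        clusters.append(
            ClusterAssignment(
                cluster_id=len(clusters), centroid_id=centroid, members=members
            )
        )
    return clusters


def classify_cluster(
    cluster: ClusterAssignment,
    proteins_by_id: dict[str, str],
    catalog: ReferenceCatalog,
    min_id: float = CLASSIFY_MIN_ID,
    min_cov: float = CLASSIFY_MIN_COV,
    prefilter: bool = True,
) -> ClusterAssignment:
    """Assign a functional label to one cluster (mutates and returns it)."""
    if len(catalog) == 0:
        raise ValueError("reference catalog is empty")
    catalog_ids = catalog.ids()
    inside = sorted(cluster.members & catalog_ids)
    if inside:
        roles = sorted({e.role_label for e in catalog if e.ref_id in inside})
        cluster.label = roles[0] if len(roles) == 1 else "ambiguous"
        cluster.label_source = "isolate-representative"
        return cluster
    votes: dict[str, int] = {}
    for pid in sorted(cluster.members):
        seq = proteins_by_id[pid]
        best = _best_catalog_hit(seq, catalog, min_id, min_cov, prefilter)
        if best is not None:
            votes[best] = votes.get(best, 0) + 1
    if not votes:
        cluster.label = "unclassified"
        cluster.label_source = "none"
        return cluster
    top = max(votes.values())
    winners = sorted(label for label, v in votes.items() if v == top)
    cluster.label = winners[0] if len(winners) == 1 else "ambiguous"
    cluster.label_source = "consensus"
    return cluster


def _best_catalog_hit(
    seq: str,
    catalog: ReferenceCatalog,
    min_id: float,
    min_cov: float,
    prefilter: bool,
) -> str | None:
    """Role label of the best qualifying catalog hit, or None."""
    qk = kmer_set(seq)
    best_label = None
    best_key = None
    for entry in catalog:
        if prefilter and not shares_kmers(seq, entry.sequence, qk):
            continue
        res = pairwise_align(seq, entry.sequence, "q", entry.ref_id)
        if res.identity < min_id or res.query_cov < min_cov or res.target_cov < min_cov:
            continue
        key = (res.score, res.identity, entry.ref_id)
        if best_key is None or key > best_key:
            best_key = key
            best_label = entry.role_label
    return best_label


def classify_clusters(
    clusters: list[ClusterAssignment],
    proteins: list[ProteinRecord],
    catalog: ReferenceCatalog,
    min_id: float = CLASSIFY_MIN_ID,
    min_cov: float = CLASSIFY_MIN_COV,
) -> list[ClusterAssignment]:
    by_id = {p.protein_id: p.sequence for p in proteins}
    for c in clusters:
        classify_cluster(c, by_id, catalog, min_id=min_id, min_cov=min_cov)
    return clusters


@dataclass(frozen=True)
class PangenomeBin:
    cluster_id: int
    bin: str  # near-core | accessory | strain-specific
    prevalence: float


NEAR_CORE_PREVALENCE = 0.85


def pangenome_bins(
    clusters: list[ClusterAssignment],
    genome_of: dict[str, str],
    n_genomes: int,
) -> list[PangenomeBin]:
    """Bin clusters by prevalence: near-core (> 85% of genomes),
    strain-specific (a single genome), accessory otherwise."""
    if n_genomes < 2:
        raise ValueError("pangenome binning needs at least 2 genomes")
    out = []
    for c in clusters:
        genomes = {genome_of[m] for m in c.members}
        prevalence = len(genomes) / n_genomes
        if len(genomes) == 1:
            label = "strain-specific"
        elif prevalence > NEAR_CORE_PREVALENCE:
            label = "near-core"
        else:
            label = "accessory"
        out.append(PangenomeBin(c.cluster_id, label, prevalence))
    return out
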