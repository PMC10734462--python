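"""Concatenated ribosomal-protein phylogeny.

Thirteen single-copy ribosomal proteins (L19, L20, L28, L17, L9_C, S16,
L21p, L27, L35p, S11, S20p, S6, S9) are extracted per genome by homology,
aligned per marker with a deterministic progressive aligner (k-mer
distances -> UPGMA guide tree -> profile-profile merges under BLOSUM62
with affine gaps), gap-masked (columns with > 70% gaps dropped, plus an
automated end trim), concatenated, and summarized into a neighbor-joining
tree over Poisson-corrected distances with bootstrap supports from column
resampling.  NJ is exact on additive distance matrices, which anchors the
correctness tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from Bio.Align import substitution_matrices
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj as skbio_nj

from .align import kmer_set, pairwise_align, shares_kmers
from .records import GenomeAnnotation, ReferenceCatalog

log = logging.getLogger(__name__)

RIBOSOMAL_MARKERS = (
    "L19", "L20", "L28", "L17", "L9_C", "S16", "L21p",
    "L27", "L35p", "S11", "S20p", "S6", "S9",
)

EXTRACT_MIN_ID = 40.0
EXTRACT_MIN_COV = 0.7
PRESENCE_THRESHOLD = 0.895  # marker kept when present in ~9 of 10 genomes
GAP_MASK_THRESHOLD = 0.70
END_TRIM_THRESHOLD = 0.5
DISTANCE_CAP = 10.0

GAP_OPEN = 11.0
GAP_EXTEND = 1.0

_AA = "ARNDCQEGHILKMFPSTWYV"
_AA_INDEX = {a: i for i, a in enumerate(_AA)}


def _blosum_matrix() -> np.ndarray:
    b62 = substitution_matrices.load("BLOSUM62")
    m = np.zeros((20, 20))
    for i, a in enumerate(_AA):
        for j, b in enumerate(_AA):
            m[i, j] = b62[a][b]
    return m


_B62 = _blosum_matrix()


@dataclass
class MarkerSet:
    """Per-genome sequences of the retained phylogenetic markers."""

    markers: list[str]
    sequences: dict[str, dict[str, str]]  # marker -> genome_id -> sequence
    dropped: dict[str, float] = field(default_factory=dict)  # marker -> prevalence


def extract_markers(
    genomes: list[GenomeAnnotation],
    catalog: ReferenceCatalog,
    marker_names: Sequence[str] = RIBOSOMAL_MARKERS,
    min_id: float = EXTRACT_MIN_ID,
    min_cov: float = EXTRACT_MIN_COV,
    presence_threshold: float = PRESENCE_THRESHOLD,
) -> MarkerSet:
    """Best qualifying hit per (genome, marker); markers below the cohort
    presence threshold are dropped with a logged reason."""
    sequences: dict[str, dict[str, str]] = {m: {} for m in marker_names}
    for marker in marker_names:
        refs = [(e, kmer_set(e.sequence)) for e in catalog.for_role(marker)]
        for g in genomes:
            best = None  # (score, identity, protein_id, seq)
            for p in g.proteins:
                pk = kmer_set(p.sequence)
                for entry, ek in refs:
                    if not shares_kmers(p.sequence, entry.sequence, pk, ek):
                        continue
                    res = pairwise_align(
                        p.sequence, entry.sequence, p.protein_id, entry.ref_id
                    )
                    if (
                        res.identity < min_id
                        or res.query_cov < min_cov
                        or res.target_cov < min_cov
                    ):
                        continue
                    key = (res.score, res.identity, p.protein_id)
                    if best is None or key > best[:3]:
                        best = key + (p.sequence,)
            if best is not None:
                sequences[marker][g.genome_id] = best[3]
    kept, dropped = [], {}
    for marker in marker_names:
        prevalence = len(sequences[marker]) / len(genomes) if genomes else 0.0
        if prevalence >= presence_threshold:
            kept.append(marker)
        else:
            dropped[marker] = prevalence
            log.info(
                "marker %s dropped: present in %.0f%% of genomes "
                "(threshold %.0f%%)",
                marker, 100 * prevalence, 100 * presence_threshold,
            )
    return MarkerSet(
        markers=kept,
        sequences={m: sequences[m] for m in kept},
        dropped=dropped,
    )


# ---------------------------------------------------------------------------
# progressive multiple alignment


def _profile(rows: list[str]) -> np.ndarray:
    """Column residue-frequency matrix (L x 20); gaps contribute nothing."""
    length = len(rows[0])
    prof = np.zeros((length, 20))
    for row in rows:
        for j, c in enumerate(row):
            idx = _AA_INDEX.get(c)
            if idx is not None:
                prof[j, idx] += 1.0
    return prof / len(rows)


def _align_profiles(
    rows_a: list[str], rows_b: list[str]
) -> tuple[list[str], list[str]]:
    """Global profile-profile alignment with affine gaps (Gotoh).

    Returns the two row groups with gap columns inserted.  Traceback
    tie-break is fixed (match > gap-in-B > gap-in-A) so the result is
    deterministic.
    """
    fa, fb = _profile(rows_a), _profile(rows_b)
    la, lb = fa.shape[0], fb.shape[0]
    S = fa @ _B62 @ fb.T
    neg = -1e30
    M = np.full((la + 1, lb + 1), neg)
    X = np.full((la + 1, lb + 1), neg)  # gap in B (step down in A)
    Y = np.full((la + 1, lb + 1), neg)  # gap in A (step right in B)
    M[0, 0] = 0.0
    for i in range(1, la + 1):
        X[i, 0] = -GAP_OPEN - GAP_EXTEND * (i - 1)
    for j in range(1, lb + 1):
        Y[0, j] = -GAP_OPEN - GAP_EXTEND * (j - 1)
    js = np.arange(1, lb + 1)
    for i in range(1, la + 1):
        prev_best = np.maximum(np.maximum(M[i - 1], X[i - 1]), Y[i - 1])
        M[i, 1:] = prev_best[:-1] + S[i - 1]
        X[i, 1:] = np.maximum(
            np.maximum(M[i - 1, 1:], Y[i - 1, 1:]) - GAP_OPEN,
            X[i - 1, 1:] - GAP_EXTEND,
        )
        # Y has an in-row recurrence; solve it with a running max
        a = np.maximum(M[i, :-1], X[i, :-1]) - GAP_OPEN + GAP_EXTEND * np.arange(lb)
        Y[i, 1:] = np.maximum.accumulate(a) - GAP_EXTEND * js
    # traceback
    path: list[tuple[Optional[int], Optional[int]]] = []
    i, j = la, lb
    finals = (M[la, lb], X[la, lb], Y[la, lb])
    state = int(np.argmax(finals))  # 0=M, 1=X, 2=Y; argmax prefers M on ties
    while i > 0 or j > 0:
        if state == 0 and i > 0 and j > 0:
            path.append((i - 1, j - 1))
            prev = (M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            state = int(np.argmax(prev))
            i, j = i - 1, j - 1
        elif state == 1 and i > 0:
            path.append((i - 1, None))
            came_open = max(M[i - 1, j], Y[i - 1, j]) - GAP_OPEN
            if came_open >= X[i - 1, j] - GAP_EXTEND:
                state = 0 if M[i - 1, j] >= Y[i - 1, j] else 2
            i -= 1
        elif state == 2 and j > 0:
            path.append((None, j - 1))
            came_open = max(M[i, j - 1], X[i, j - 1]) - GAP_OPEN
            if came_open >= Y[i, j - 1] - GAP_EXTEND:
                state = 0 if M[i, j - 1] >= X[i, j - 1] else 1
            j -= 1
        elif i > 0:
            path.append((i - 1, None))
            i -= 1
        else:
            path.append((None, j - 1))
            j -= 1
    path.reverse()
    out_a = ["".join(r[pa] if pa is not None else "-" for pa, _ in path) for r in rows_a]
    out_b = ["".join(r[pb] if pb is not None else "-" for _, pb in path) for r in rows_b]
    return out_a, out_b


def _kmer_distance(a: str, b: str, k: int = 3) -> float:
    ka = {a[i:i + k] for i in range(max(len(a) - k + 1, 0))}
    kb = {b[i:i + k] for i in range(max(len(b) - k + 1, 0))}
    if not ka or not kb:
        return 1.0
    return 1.0 - len(ka & kb) / min(len(ka), len(kb))


def align_marker(sequences: dict[str, str]) -> dict[str, str]:
    """Progressive multiple alignment of one marker's sequences.

    Input order does not matter: sequences are canonically ordered before
    the guide tree is built, so permuted input yields the same alignment.
    A single sequence is returned unchanged.
    """
    if not sequences:
        return {}
    if len(sequences) == 1:
        return dict(sequences)
    ids = sorted(sequences, key=lambda i: (sequences[i], i))
    n = len(ids)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = _kmer_distance(sequences[ids[i]], sequences[ids[j]])
            dist[i, j] = dist[j, i] = d
    link = linkage(squareform(dist, checks=False), method="average")
    groups: dict[int, tuple[list[str], list[str]]] = {
        i: ([ids[i]], [sequences[ids[i]]]) for i in range(n)
    }
    for step, (left, right, _d, _cnt) in enumerate(link):
        ga, gb = groups.pop(int(left)), groups.pop(int(right))
        rows_a, rows_b = _align_profiles(ga[1], gb[1])
        groups[n + step] = (ga[0] + gb[0], rows_a + rows_b)
    (_, (final_ids, final_rows)), = groups.items()
    return dict(zip(final_ids, final_rows))


# ---------------------------------------------------------------------------
# masking, concatenation, distances, NJ


@dataclass
class MaskedAlignment:
    genome_ids: list[str]
    matrix: dict[str, str]  # genome -> concatenated residues ('-' pads)
    column_map: list[tuple[str, int]]  # concatenated column -> (marker, column)

    @property
    def length(self) -> int:
        return len(self.column_map)


def _mask_block(
    rows: dict[str, str],
    gap_threshold: float,
    end_trim_threshold: float,
) -> tuple[dict[str, str], list[int]]:
    ids = list(rows)
    arr = np.array([list(rows[i]) for i in ids])
    gap_frac = (arr == "-").mean(axis=0)
    keep = [j for j in range(arr.shape[1]) if gap_frac[j] <= gap_threshold]
    # automated end trim: peel leading/trailing columns still gappy in
    # more than the end-trim fraction of rows
    while keep and gap_frac[keep[0]] > end_trim_threshold:
        keep.pop(0)
    while keep and gap_frac[keep[-1]] > end_trim_threshold:
        keep.pop()
    masked = {i: "".join(rows[i][j] for j in keep) for i in ids}
    return masked, keep


def mask_and_concat(
    blocks: dict[str, dict[str, str]],
    genome_ids: Sequence[str],
    gap_threshold: float = GAP_MASK_THRESHOLD,
    end_trim_threshold: float = END_TRIM_THRESHOLD,
) -> MaskedAlignment:
    """Mask gappy columns per marker block and concatenate.

    Columns with gap fraction strictly above ``gap_threshold`` are dropped
    (a column at exactly the threshold is retained).  Genomes missing a
    marker are padded with gaps after masking.  Blocks losing every column
    are dropped with a warning.
    """
    genome_ids = sorted(genome_ids)
    pieces: dict[str, list[str]] = {g: [] for g in genome_ids}
    column_map: list[tuple[str, int]] = []
    for marker, rows in blocks.items():
        if not rows:
            continue
        masked, kept = _mask_block(rows, gap_threshold, end_trim_threshold)
        width = len(kept)
        if width == 0:
            log.warning("marker %s: all columns masked; block dropped", marker)
            continue
        for g in genome_ids:
            pieces[g].append(masked.get(g, "-" * width))
        column_map.extend((marker, j) for j in kept)
    return MaskedAlignment(
        genome_ids=list(genome_ids),
        matrix={g: "".join(pieces[g]) for g in genome_ids},
        column_map=column_map,
    )


def pairwise_distances(
    alignment: MaskedAlignment,
    model: str = "poisson",
    column_indices: Optional[np.ndarray] = None,
) -> DistanceMatrix:
    """Distances over shared (both-ungapped) columns.

    ``p-distance`` is the raw mismatch fraction; ``poisson`` applies the
    correction d = -ln(1 - p).  Saturated pairs (p >= 1, or no shared
    columns) are set to a documented cap.
    """
    if model not in {"poisson", "p-distance"}:
        raise ValueError(f"unknown distance model {model!r}")
    ids = sorted(alignment.genome_ids)  # canonical order: taxon-order invariance
    arrs = {g: np.array(list(alignment.matrix[g])) for g in ids}
    if column_indices is not None:
        arrs = {g: a[column_indices] for g, a in arrs.items()}
    n = len(ids)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = arrs[ids[i]], arrs[ids[j]]
            shared = (a != "-") & (b != "-")
            total = int(shared.sum())
            if total == 0:
                d = DISTANCE_CAP
            else:
                p = float((a[shared] != b[shared]).mean())
                if model == "p-distance":
                    d = p
                elif p >= 1.0:
                    log.warning("saturated pair (%s, %s): distance capped", ids[i], ids[j])
                    d = DISTANCE_CAP
                else:
                    d = -np.log(1.0 - p)
            mat[i, j] = mat[j, i] = d
    return DistanceMatrix(mat, ids)


@dataclass
class PhyloTree:
    tree: TreeNode
    supports: dict[frozenset[str], float]  # bipartition -> percent support

    def newick(self) -> str:
        import io as _io

        buf = _io.StringIO()
        self.tree.write(buf)
        return buf.getvalue().strip()

    def _canonical(self, leaves: Sequence[str]) -> frozenset[str]:
        all_leaves = frozenset(t.name for t in self.tree.tips())
        side = frozenset(leaves)
        if min(all_leaves) in side:
            side = all_leaves - side
        return side

    def clade_support(self, leaves: Sequence[str]) -> Optional[float]:
        return self.supports.get(self._canonical(leaves))

    def is_monophyletic(self, leaves: Sequence[str]) -> bool:
        return self._canonical(leaves) in _tree_bipartitions(self.tree)


def _tree_bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions, canonicalized to the side *not* containing
    the lexicographically smallest leaf."""
    leaves = frozenset(t.name for t in tree.tips())
    ref = min(leaves)
    out: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(side) > len(leaves) - 2:
            continue
        if ref in side:
            side = leaves - side
        out.add(side)
    return out


def nj_tree(
    alignment: MaskedAlignment,
    model: str = "poisson",
    bootstraps: int = 1000,
    seed: int = 0,
    outgroup: Optional[Sequence[str]] = None,
) -> PhyloTree:
    """Neighbor-joining tree with bootstrap supports by column resampling."""
    if len(alignment.genome_ids) < 4:
        raise ValueError("need at least 4 genomes for a meaningful tree")
    dm = pairwise_distances(alignment, model=model)
    tree = skbio_nj(dm)
    main_bips = _tree_bipartitions(tree)
    counts = {b: 0 for b in main_bips}
    rng = np.random.default_rng(seed)
    ncols = alignment.length
    for _ in range(bootstraps):
        cols = rng.integers(0, ncols, size=ncols)
        bdm = pairwise_distances(alignment, model=model, column_indices=cols)
        bbips = _tree_bipartitions(skbio_nj(bdm))
        for b in main_bips:
            if b in bbips:
                counts[b] += 1
    supports = {
        b: 100.0 * c / bootstraps if bootstraps else 0.0 for b, c in counts.items()
    }
    _annotate_supports(tree, supports)
    if outgroup:
        tree = _root_on(tree, outgroup)
    return PhyloTree(tree=tree, supports=supports)


def _annotate_supports(tree: TreeNode, supports: dict[frozenset[str], float]) -> None:
    leaves = frozenset(t.name for t in tree.tips())
    ref = min(leaves)
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        canon = side if ref not in side else leaves - side
        if canon in supports:
            node.name = str(int(round(supports[canon])))


def _root_on(tree: TreeNode, outgroup: Sequence[str]) -> TreeNode:
    names = list(outgroup)
    if len(names) == 1:
        node = tree.find(names[0])
    else:
        node = tree.lowest_common_ancestor(names)
    try:
        return tree.root_at(node.parent if node.is_tip() else node)
    except Exception:
        log.warning("could not re-root on %s; returning unrooted tree", names)
        return tree


def nj_from_distance_matrix(dm: DistanceMatrix) -> TreeNode:
    """Plain NJ on a precomputed matrix (exact on additive matrices)."""
    return skbio_nj(dm)
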