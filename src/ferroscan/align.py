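"""Shared pairwise-alignment layer.

Protein comparisons use Smith-Waterman local alignment (BLOSUM62, affine
gap open 11 / extend 1) through Bio.Align.PairwiseAligner; identity is
computed over aligned columns and coverage as the aligned span over each
sequence's full length — the quantities the clustering and role-detection
thresholds are defined on.  Nucleotide gene comparisons (ANI) use edlib
global alignment with cigar-derived identity.

A shared-4-mer prescreen skips alignment of sequence pairs that share
fewer than a handful of distinct 4-mers; unrelated random proteins almost
never share four, while homologs at the identity levels the thresholds
care about always do.  It can be disabled wherever exactness matters more
than speed.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import edlib
from Bio import Align
from Bio.Align import substitution_matrices

DEFAULT_GAP_OPEN = 11
DEFAULT_GAP_EXTEND = 1
PREFILTER_K = 4
PREFILTER_MIN_SHARED = 4
PREFILTER_MIN_LEN = 40  # sequences shorter than this are always aligned


@dataclass(frozen=True)
class AlignmentResult:
    query_id: str
    target_id: str
    score: float
    identity: float  # percent of aligned columns identical
    query_cov: float  # fraction of query length inside the aligned region
    target_cov: float


@lru_cache(maxsize=None)
def _protein_aligner(gap_open: int, gap_extend: int) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -float(gap_open)
    aligner.extend_gap_score = -float(gap_extend)
    return aligner


_B62_ALPHABET = set("ARNDCQEGHILKMFPSTWYVBZX*")


def _sanitize(seq: str) -> str:
    # BLOSUM62 lacks rows for the rare codes U/O/J; map them to X.
    return "".join(c if c in _B62_ALPHABET else "X" for c in seq)


def pairwise_align(
    a: str,
    b: str,
    query_id: str = "a",
    target_id: str = "b",
    gap_open: int = DEFAULT_GAP_OPEN,
    gap_extend: int = DEFAULT_GAP_EXTEND,
) -> AlignmentResult:
    """Local protein alignment with identity and bidirectional coverage."""
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    aligner = _protein_aligner(gap_open, gap_extend)
    alns = aligner.align(_sanitize(a), _sanitize(b))
    try:
        aln = alns[0]
    except IndexError:
        return AlignmentResult(query_id, target_id, 0.0, 0.0, 0.0, 0.0)
    qblocks, tblocks = aln.aligned
    if len(qblocks) == 0:
        return AlignmentResult(query_id, target_id, float(aln.score), 0.0, 0.0, 0.0)
    matches = 0
    columns = 0
    for (qs, qe), (ts, te) in zip(qblocks, tblocks):
        columns += qe - qs
        for qa, tb in zip(a[qs:qe], b[ts:te]):
            if qa == tb:
                matches += 1
    # gap columns inside the local alignment also count as aligned columns
    qspan = int(qblocks[-1][1] - qblocks[0][0])
    tspan = int(tblocks[-1][1] - tblocks[0][0])
    gap_cols = (qspan - columns) + (tspan - columns)
    total_cols = columns + gap_cols
    identity = 100.0 * matches / total_cols if total_cols else 0.0
    return AlignmentResult(
        query_id=query_id,
        target_id=target_id,
        score=float(aln.score),
        identity=identity,
        query_cov=qspan / len(a),
        target_cov=tspan / len(b),
    )


def kmer_set(seq: str, k: int = PREFILTER_K) -> frozenset[str]:
    if len(seq) < k:
        return frozenset()
    return frozenset(seq[i:i + k] for i in range(len(seq) - k + 1))


def shares_kmers(
    a: str,
    b: str,
    kmers_a: frozenset[str] | None = None,
    kmers_b: frozenset[str] | None = None,
    min_shared: int = PREFILTER_MIN_SHARED,
) -> bool:
    """Prescreen: True if the pair is worth aligning."""
    if len(a) < PREFILTER_MIN_LEN or len(b) < PREFILTER_MIN_LEN:
        return True
    ka = kmers_a if kmers_a is not None else kmer_set(a)
    kb = kmers_b if kmers_b is not None else kmer_set(b)
    shared = 0
    small, big = (ka, kb) if len(ka) <= len(kb) else (kb, ka)
    for kmer in small:
        if kmer in big:
            shared += 1
            if shared >= min_shared:
                return True
    return False


def nucleotide_identity(a: str, b: str) -> float:
    """Percent identity of two nucleotide sequences under global alignment.

    Identity = matches / alignment columns (matches + mismatches + indels),
    with the edit distance taken from edlib.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    res = edlib.align(a, b, mode="NW", task="path")
    columns = _cigar_columns(res["cigar"])
    matches = columns - res["editDistance"]
    return 100.0 * matches / columns if columns else 0.0


def _cigar_columns(cigar: str) -> int:
    total = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            total += int(num)
            num = ""
    return total


def global_identity_excluding_terminal_gaps(a: str, b: str) -> float:
    """Percent identity under global alignment, terminal gaps excluded.

    Used for full-length 16S rRNA comparisons: matches / aligned columns
    after trimming leading and trailing gap columns.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -0.5
    aln = aligner.align(a, b)[0]
    qa, ta = _expand_alignment(aln, a, b)
    # trim terminal gap columns
    start = 0
    end = len(qa)
    while start < end and (qa[start] == "-" or ta[start] == "-"):
        start += 1
    while end > start and (qa[end - 1] == "-" or ta[end - 1] == "-"):
        end -= 1
    matches = sum(1 for x, y in zip(qa[start:end], ta[start:end]) if x == y)
    columns = end - start
    return 100.0 * matches / columns if columns else 0.0


def _expand_alignment(aln, a: str, b: str) -> tuple[str, str]:
    qrow: list[str] = []
    trow: list[str] = []
    qblocks, tblocks = aln.aligned
    qpos, tpos = 0, 0
    for (qs, qe), (ts, te) in zip(qblocks, tblocks):
        if qs > qpos:
            qrow.append(a[qpos:qs])
            trow.append("-" * (qs - qpos))
        if ts > tpos:
            qrow.append("-" * (ts - tpos))
            trow.append(b[tpos:ts])
        qrow.append(a[qs:qe])
        trow.append(b[ts:te])
        qpos, tpos = qe, te
    if qpos < len(a):
        qrow.append(a[qpos:])
        trow.append("-" * (len(a) - qpos))
    if tpos < len(b):
        qrow.append("-" * (len(b) - tpos))
        trow.append(b[tpos:])
    return "".join(qrow), "".join(trow)
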