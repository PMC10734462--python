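"""Pairwise genome similarity: AAI, gene-based ANI, and 16S identity.

AAI is the mean protein identity over reciprocal best hits between two
proteomes; ANI the mean nucleotide identity over bidirectional best hits
between the two gene sets, with structural-RNA genes (rRNA/tRNA) excluded
by default because their strong conservation inflates the estimate.  16S
identity is computed on near-full-length sequences only (>= 1,450 nt)
under global alignment with terminal gaps excluded.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Optional

import edlib
import numpy as np
import pandas as pd

from .align import (
    global_identity_excluding_terminal_gaps,
    kmer_set,
    nucleotide_identity,
    pairwise_align,
    shares_kmers,
)
from .records import GenomeAnnotation

log = logging.getLogger(__name__)

AAI_MIN_ID = 30.0
AAI_MIN_COV = 0.7
ANI_MIN_ID = 70.0
ANI_MIN_COV = 0.7
RRNA_MIN_LEN = 1450
LOW_SUPPORT_RBH = 10

IUPAC_NT = set("ACGTURYSWKMBDHVN-")


@dataclass(frozen=True)
class PairMetric:
    value: Optional[float]  # None when undefined (no reciprocal pairs)
    support: int


def _best_protein_hits(
    queries: dict[str, str],
    targets: dict[str, str],
    min_id: float,
    min_cov: float,
) -> dict[str, tuple[str, float]]:
    """Best qualifying hit in ``targets`` for each query protein."""
    tkmers = {tid: kmer_set(s) for tid, s in targets.items()}
    out: dict[str, tuple[str, float]] = {}
    for qid, qseq in queries.items():
        qk = kmer_set(qseq)
        best = None  # (score, identity, tid)
        for tid, tseq in targets.items():
            if min(len(qseq), len(tseq)) < min_cov * max(len(qseq), len(tseq)):
                continue
            if not shares_kmers(qseq, tseq, qk, tkmers[tid]):
                continue
            res = pairwise_align(qseq, tseq, qid, tid)
            if (
                res.identity < min_id
                or res.query_cov < min_cov
                or res.target_cov < min_cov
            ):
                continue
            key = (res.score, res.identity, tid)
            if best is None or key > best:
                best = key
        if best is not None:
            out[qid] = (best[2], best[1])
    return out


def aai(
    genome_a: GenomeAnnotation,
    genome_b: GenomeAnnotation,
    min_id: float = AAI_MIN_ID,
    min_cov: float = AAI_MIN_COV,
) -> PairMetric:
    """Average amino-acid identity over reciprocal best hits."""
    if genome_a.genome_id > genome_b.genome_id:
        # canonical orientation makes the metric exactly symmetric even when
        # the aligner could report different co-optimal alignments per direction
        genome_a, genome_b = genome_b, genome_a
    pa = {p.protein_id: p.sequence for p in genome_a.proteins}
    pb = {p.protein_id: p.sequence for p in genome_b.proteins}
    if not pa or not pb:
        raise ValueError("both proteomes must be non-empty")
    fwd = _best_protein_hits(pa, pb, min_id, min_cov)
    rev = _best_protein_hits(pb, pa, min_id, min_cov)
    identities = [
        ident
        for qid, (tid, ident) in fwd.items()
        if rev.get(tid, (None,))[0] == qid
    ]
    if not identities:
        return PairMetric(None, 0)
    if len(identities) < LOW_SUPPORT_RBH:
        log.warning(
            "AAI(%s, %s): only %d reciprocal pairs (low support)",
            genome_a.genome_id, genome_b.genome_id, len(identities),
        )
    return PairMetric(float(np.mean(identities)), len(identities))


def _gene_sets(
    genome: GenomeAnnotation, exclude_structural_rna: bool
) -> dict[str, str]:
    out = {}
    for gid, seq in genome.cds_nucleotides.items():
        if exclude_structural_rna and genome.nucleotide_types.get(gid) in {
            "rRNA",
            "tRNA",
        }:
            continue
        out[gid] = seq
    return out


def _best_nt_hits(
    queries: dict[str, str],
    targets: dict[str, str],
    min_id: float,
    min_cov: float,
) -> dict[str, tuple[str, float]]:
    out: dict[str, tuple[str, float]] = {}
    max_dist_frac = 1.0 - min_id / 100.0
    for qid, qseq in queries.items():
        best = None  # (identity, tid)
        k = int(max_dist_frac * 2 * max(len(qseq), 1)) + 1
        for tid, tseq in targets.items():
            if min(len(qseq), len(tseq)) < min_cov * max(len(qseq), len(tseq)):
                continue
            # cheap edit-distance bound before the full identity computation
            scr = edlib.align(qseq, tseq, mode="NW", task="distance", k=k)
            if scr["editDistance"] == -1:
                continue
            ident = nucleotide_identity(qseq, tseq)
            if ident < min_id:
                continue
            if best is None or (ident, tid) > best:
                best = (ident, tid)
        if best is not None:
            out[qid] = (best[1], best[0])
    return out


def ani(
    genome_a: GenomeAnnotation,
    genome_b: GenomeAnnotation,
    min_id: float = ANI_MIN_ID,
    min_cov: float = ANI_MIN_COV,
    exclude_structural_rna: bool = True,
) -> PairMetric:
    """Gene-based average nucleotide identity over bidirectional best hits."""
    if genome_a.genome_id > genome_b.genome_id:
        genome_a, genome_b = genome_b, genome_a
    ga = _gene_sets(genome_a, exclude_structural_rna)
    gb = _gene_sets(genome_b, exclude_structural_rna)
    if not ga or not gb:
        raise ValueError("both genomes need nucleotide gene sets for ANI")
    fwd = _best_nt_hits(ga, gb, min_id, min_cov)
    rev = _best_nt_hits(gb, ga, min_id, min_cov)
    identities = [
        ident
        for qid, (tid, ident) in fwd.items()
        if rev.get(tid, (None,))[0] == qid
    ]
    if not identities:
        return PairMetric(None, 0)
    return PairMetric(float(np.mean(identities)), len(identities))


def rrna_identity(
    seq_a: Optional[str], seq_b: Optional[str], min_len: int = RRNA_MIN_LEN
) -> Optional[PairMetric]:
    """16S percent identity, or None when either sequence is too short.

    Sequences must be IUPAC nucleotide strings; identity is over aligned
    columns excluding terminal gaps.
    """
    if seq_a is None or seq_b is None:
        return None
    for seq in (seq_a, seq_b):
        bad = set(seq.upper()) - IUPAC_NT
        if bad:
            raise ValueError(f"non-IUPAC nucleotide characters: {sorted(bad)}")
    if len(seq_a) < min_len or len(seq_b) < min_len:
        return None
    ident = global_identity_excluding_terminal_gaps(seq_a.upper(), seq_b.upper())
    return PairMetric(ident, min(len(seq_a), len(seq_b)))


def similarity_matrix(
    genomes: list[GenomeAnnotation], metric: str = "AAI", **kwargs
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Square symmetric percent matrix plus a support-count companion.

    ``metric`` is one of AAI, ANI, 16S.  The diagonal is 100 where defined;
    undefined off-diagonal pairs are NaN with support 0.
    """
    ids = [g.genome_id for g in genomes]
    values = pd.DataFrame(np.nan, index=ids, columns=ids, dtype=float)
    support = pd.DataFrame(0, index=ids, columns=ids, dtype=int)
    fns = {"AAI": aai, "ANI": ani}
    for g in genomes:
        if metric in fns:
            values.loc[g.genome_id, g.genome_id] = 100.0
            support.loc[g.genome_id, g.genome_id] = (
                g.n_proteins if metric == "AAI" else len(g.cds_nucleotides)
            )
        elif g.rrna_16s is not None and len(g.rrna_16s) >= RRNA_MIN_LEN:
            values.loc[g.genome_id, g.genome_id] = 100.0
            support.loc[g.genome_id, g.genome_id] = len(g.rrna_16s)
    for ga, gb in itertools.combinations(genomes, 2):
        if metric in fns:
            pm = fns[metric](ga, gb, **kwargs)
        elif metric == "16S":
            pm = rrna_identity(ga.rrna_16s, gb.rrna_16s, **kwargs)
        else:
            raise ValueError(f"unknown metric {metric!r}")
        if pm is None or pm.value is None:
            continue
        values.loc[ga.genome_id, gb.genome_id] = pm.value
        values.loc[gb.genome_id, ga.genome_id] = pm.value
        support.loc[ga.genome_id, gb.genome_id] = pm.support
        support.loc[gb.genome_id, ga.genome_id] = pm.support
    values.index.name = support.index.name = "genome_id"
    return values, support
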