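"""Porin-cytochrome complex calling from role homology plus gene order.

A complex definition lists subunit roles (some required, some optional),
each optionally constrained to a heme-count range (e.g. a decaheme
outer-membrane cytochrome must carry 10 motifs).  Candidates for each role
are found by local alignment against labeled reference sequences, then a
complex is called *complete* in a genome when, anchored on a required
multiheme subunit, every required role has a candidate on the same contig
within a gene-rank window.  A duplicated variant-flagged role (e.g. a
second periplasmic cytochrome in a PCC3 locus) upgrades the verdict to
*complete-variant*; required roles present but not all -> *partial*;
none -> *absent*.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from .align import kmer_set, pairwise_align, shares_kmers
from .hemes import profile_protein
from .records import GenomeAnnotation, ProteinRecord, ReferenceCatalog

log = logging.getLogger(__name__)

DEFAULT_WINDOW = 15
ROLE_MIN_ID = 30.0
ROLE_MIN_COV = 0.7

VERDICT_ORDER = {"absent": 0, "partial": 1, "complete": 2, "complete-variant": 2}


@dataclass(frozen=True)
class RoleSpec:
    role_label: str
    required: bool = True
    min_hemes: Optional[int] = None
    max_hemes: Optional[int] = None
    min_copies: int = 1
    variant_on_extra_copy: bool = False


@dataclass(frozen=True)
class ComplexDefinition:
    name: str
    roles: tuple[RoleSpec, ...]
    window: int = DEFAULT_WINDOW
    same_contig: bool = True

    def __post_init__(self) -> None:
        if not any(r.required for r in self.roles):
            raise ValueError(f"complex {self.name!r} has no required role")
        if self.window < 1:
            raise ValueError(f"complex {self.name!r}: window must be >= 1")

    @property
    def required_roles(self) -> list[RoleSpec]:
        return [r for r in self.roles if r.required]

    @property
    def anchor_role(self) -> RoleSpec:
        """First required role with a heme constraint, else first required."""
        for r in self.roles:
            if r.required and (r.min_hemes is not None or r.max_hemes is not None):
                return r
        return self.required_roles[0]


@dataclass(frozen=True)
class RoleHit:
    role_label: str
    protein: ProteinRecord
    identity: float
    total_hemes: int


@dataclass
class ComplexCall:
    genome_id: str
    complex_name: str
    verdict: str
    subunit_map: dict[str, list[str]] = field(default_factory=dict)
    anchor_contig: Optional[str] = None
    span: Optional[tuple[int, int]] = None


def find_role_candidates(
    genome: GenomeAnnotation,
    role_label: str,
    catalog: ReferenceCatalog,
    min_id: float = ROLE_MIN_ID,
    min_cov: float = ROLE_MIN_COV,
    min_hemes: Optional[int] = None,
    max_hemes: Optional[int] = None,
    prefilter: bool = True,
) -> list[RoleHit]:
    """Find genome proteins matching a role's reference sequences.

    A hit must pass identity/coverage thresholds against at least one
    reference for the role and, when a heme-count constraint applies
    (explicit or from the catalog entry), its total motif count must lie
    in ``[min_hemes, max_hemes]``.
    """
    refs = catalog.for_role(role_label)
    if min_hemes is None and max_hemes is None:
        # fall back to the catalog's expectation for this role, if any
        mins = {e.expected_min_hemes for e in refs if e.expected_min_hemes is not None}
        maxs = {e.expected_max_hemes for e in refs if e.expected_max_hemes is not None}
        min_hemes = min(mins) if mins else None
        max_hemes = max(maxs) if maxs else None
    ref_kmers = [(e, kmer_set(e.sequence)) for e in refs]
    hits: list[RoleHit] = []
    for p in genome.proteins:
        pk = kmer_set(p.sequence) if prefilter else None
        best_identity = None
        for entry, ek in ref_kmers:
            if prefilter and not shares_kmers(p.sequence, entry.sequence, pk, ek):
                continue
            res = pairwise_align(p.sequence, entry.sequence, p.protein_id, entry.ref_id)
            if (
                res.identity >= min_id
                and res.query_cov >= min_cov
                and res.target_cov >= min_cov
            ):
                if best_identity is None or res.identity > best_identity:
                    best_identity = res.identity
        if best_identity is None:
            continue
        prof = profile_protein(p.protein_id, p.sequence)
        total = prof.total_hemes if prof is not None else 0
        if min_hemes is not None and total < min_hemes:
            continue
        if max_hemes is not None and total > max_hemes:
            continue
        hits.append(RoleHit(role_label, p, best_identity, total))
    return hits


def collect_candidates(
    genome: GenomeAnnotation,
    definition: ComplexDefinition,
    catalog: ReferenceCatalog,
    min_id: float = ROLE_MIN_ID,
    min_cov: float = ROLE_MIN_COV,
) -> dict[str, list[RoleHit]]:
    return {
        r.role_label: find_role_candidates(
            genome,
            r.role_label,
            catalog,
            min_id=min_id,
            min_cov=min_cov,
            min_hemes=r.min_hemes,
            max_hemes=r.max_hemes,
        )
        for r in definition.roles
    }


def call_complex(
    genome: GenomeAnnotation,
    definition: ComplexDefinition,
    candidates: dict[str, list[RoleHit]],
) -> ComplexCall:
    """Evaluate one complex in one genome from per-role candidates.

    The verdict is decided by colocalization: anchored on each candidate of
    the anchor role in turn, the call is complete iff every required role
    has a candidate on the anchor's contig within ``window`` gene ranks.
    Among satisfying anchors the smallest-span solution wins, then the
    lowest anchor rank.
    """
    anchor = definition.anchor_role
    best = None  # (span_width, anchor_rank, call)
    for ahit in sorted(candidates.get(anchor.role_label, []), key=_hit_rank):
        call = _try_anchor(genome, definition, candidates, ahit)
        if call is None:
            continue
        width = call.span[1] - call.span[0]
        key = (width, ahit.protein.rank)
        if best is None or key < best[0]:
            best = (key, call)
    if best is not None:
        return best[1]
    n_roles_hit = sum(
        1 for r in definition.required_roles if candidates.get(r.role_label)
    )
    verdict = "partial" if n_roles_hit >= 1 else "absent"
    subunit_map = {
        r.role_label: sorted(h.protein.locus_tag for h in candidates.get(r.role_label, []))
        for r in definition.roles
        if candidates.get(r.role_label)
    }
    return ComplexCall(
        genome_id=genome.genome_id,
        complex_name=definition.name,
        verdict=verdict,
        subunit_map=subunit_map,
    )


def _hit_rank(hit: RoleHit) -> tuple[str, int]:
    return (hit.protein.contig_id, hit.protein.rank)


def _try_anchor(
    genome: GenomeAnnotation,
    definition: ComplexDefinition,
    candidates: dict[str, list[RoleHit]],
    ahit: RoleHit,
) -> Optional[ComplexCall]:
    contig = ahit.protein.contig_id
    arank = ahit.protein.rank
    window = definition.window

    def in_window(hit: RoleHit) -> bool:
        if definition.same_contig and hit.protein.contig_id != contig:
            return False
        return abs(hit.protein.rank - arank) <= window

    subunit_map: dict[str, list[str]] = {}
    ranks: list[int] = []
    variant = False
    for role in definition.roles:
        local = [h for h in candidates.get(role.role_label, []) if in_window(h)]
        if role.required and len(local) < role.min_copies:
            return None
        if local:
            subunit_map[role.role_label] = sorted(h.protein.locus_tag for h in local)
            ranks.extend(h.protein.rank for h in local)
            if role.variant_on_extra_copy and len(local) > role.min_copies:
                variant = True
    return ComplexCall(
        genome_id=genome.genome_id,
        complex_name=definition.name,
        verdict="complete-variant" if variant else "complete",
        subunit_map=subunit_map,
        anchor_contig=contig,
        span=(min(ranks), max(ranks)),
    )


def cohort_complex_matrix(
    genomes: list[GenomeAnnotation],
    definitions: list[ComplexDefinition],
    catalog: ReferenceCatalog,
    min_id: float = ROLE_MIN_ID,
    min_cov: float = ROLE_MIN_COV,
) -> tuple[pd.DataFrame, list[ComplexCall]]:
    """Genome x complex verdict table plus the underlying calls."""
    calls: list[ComplexCall] = []
    rows = {}
    for g in genomes:
        row = {}
        for d in definitions:
            cands = collect_candidates(g, d, catalog, min_id=min_id, min_cov=min_cov)
            call = call_complex(g, d, cands)
            calls.append(call)
            row[d.name] = call.verdict
        rows[g.genome_id] = row
    table = pd.DataFrame.from_dict(rows, orient="index")
    if not table.empty:
        table = table[[d.name for d in definitions]]
        table.index.name = "genome_id"
    return table, calls


def summarize_verdicts(table: pd.DataFrame) -> pd.DataFrame:
    """Counts of each verdict per complex (summary row data)."""
    out = {}
    for col in table.columns:
        out[col] = table[col].value_counts().to_dict()
    return (
        pd.DataFrame(out)
        .reindex(["complete", "complete-variant", "partial", "absent"])
        .fillna(0)
        .astype(int)
    )


def load_complex_definitions(path=None) -> list[ComplexDefinition]:
    """Load complex definitions from YAML (the shipped file by default)."""
    if path is None:
        path = Path(__file__).parent / "data" / "complexes.yaml"
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    defs = []
    for item in doc["complexes"]:
        roles = tuple(
            RoleSpec(
                role_label=r["role"],
                required=bool(r.get("required", True)),
                min_hemes=r.get("min_hemes"),
                max_hemes=r.get("max_hemes"),
                min_copies=int(r.get("min_copies", 1)),
                variant_on_extra_copy=bool(r.get("variant_on_extra_copy", False)),
            )
            for r in item["roles"]
        )
        defs.append(
            ComplexDefinition(
                name=item["name"],
                roles=roles,
                window=int(item.get("window", DEFAULT_WINDOW)),
                same_contig=bool(item.get("same_contig", True)),
            )
        )
    return defs
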