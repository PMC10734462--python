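"""Core domain records shared across the pipeline.

A cohort is a set of genomes, each carrying an ordered proteome (gene-order
ranks within contigs), CheckM-style quality metadata, and an optional 16S
sequence.  A reference catalog maps labeled representative proteins (iron
oxidases, porin-cytochrome subunits, metabolic markers, ribosomal proteins)
to the roles the downstream detectors search for.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional


@dataclass(frozen=True)
class ProteinRecord:
    """One protein-coding gene product with its genomic context.

    ``rank`` is the 0-based gene-order index within the contig (ascending by
    start coordinate); it is the coordinate system used for synteny calls.
    """

    protein_id: str
    genome_id: str
    locus_tag: str
    contig_id: str
    rank: int
    strand: str  # '+', '-' or 'unknown'
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for protein {self.protein_id!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GenomeAnnotation:
    """A genome with its ordered proteome and quality metadata."""

    genome_id: str
    group_label: str
    completeness: float
    contamination: float
    proteins: list[ProteinRecord] = field(default_factory=list)
    rrna_16s: Optional[str] = None
    cds_nucleotides: dict[str, str] = field(default_factory=dict)
    nucleotide_types: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.completeness <= 100.0:
            raise ValueError(
                f"completeness {self.completeness} outside [0, 100] "
                f"for genome {self.genome_id!r}"
            )
        if self.contamination < 0.0:
            raise ValueError(
                f"negative contamination for genome {self.genome_id!r}"
            )
        seen: set[str] = set()
        for rec in self.proteins:
            if rec.protein_id in seen:
                raise ValueError(
                    f"duplicate protein id {rec.protein_id!r} "
                    f"in genome {self.genome_id!r}"
                )
            seen.add(rec.protein_id)

    @property
    def n_proteins(self) -> int:
        return len(self.proteins)

    def by_id(self) -> dict[str, ProteinRecord]:
        return {p.protein_id: p for p in self.proteins}

    def contigs(self) -> dict[str, list[ProteinRecord]]:
        """Proteins grouped by contig, ordered by rank."""
        out: dict[str, list[ProteinRecord]] = {}
        for p in self.proteins:
            out.setdefault(p.contig_id, []).append(p)
        for recs in out.values():
            recs.sort(key=lambda r: r.rank)
        return out


@dataclass(frozen=True)
class RefEntry:
    """One labeled reference protein used for homology-based role detection."""

    ref_id: str
    role_label: str
    sequence: str
    complex_name: Optional[str] = None
    expected_min_hemes: Optional[int] = None
    expected_max_hemes: Optional[int] = None


class ReferenceCatalog:
    """Collection of labeled reference proteins, indexed by role."""

    def __init__(self, entries: Iterable[RefEntry]):
        self.entries: list[RefEntry] = list(entries)
        seen: set[str] = set()
        for e in self.entries:
            if e.ref_id in seen:
                raise ValueError(f"duplicate reference id {e.ref_id!r}")
            seen.add(e.ref_id)
        self._by_role: dict[str, list[RefEntry]] = {}
        for e in self.entries:
            self._by_role.setdefault(e.role_label, []).append(e)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def roles(self) -> list[str]:
        return sorted(self._by_role)

    def for_role(self, role_label: str) -> list[RefEntry]:
        try:
            return self._by_role[role_label]
        except KeyError:
            raise KeyError(
                f"role {role_label!r} absent from catalog "
                f"(available: {', '.join(self.roles)})"
            ) from None

    def has_role(self, role_label: str) -> bool:
        return role_label in self._by_role

    def ids(self) -> set[str]:
        return {e.ref_id for e in self.entries}
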