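"""Readers and writers for the external formats the pipeline touches.

Protein FASTA and reference-catalog FASTA go through Bio.SeqIO.  The GFF3
CDS subset is consumed with a small line reader so that malformed rows can
be reported with their line numbers.  The cohort sheet is a TSV with header
``genome_id  group  fasta  gff  completeness  contamination  [16s_fasta]
[cds_fasta]``; paths are resolved relative to the sheet.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd
from Bio import SeqIO

from .records import GenomeAnnotation, ProteinRecord, RefEntry, ReferenceCatalog

log = logging.getLogger(__name__)

COHORT_COLUMNS = ["genome_id", "group", "fasta", "gff", "completeness", "contamination"]


def read_protein_fasta(path) -> list[tuple[str, str, str]]:
    """Read a protein multi-FASTA as ``(id, description, sequence)`` tuples.

    Sequences are uppercased and line wrapping is collapsed; terminal stop
    codons ('*') are stripped while internal ones are retained (they split
    motif matching downstream).  Duplicate ids and empty files are errors.
    """
    path = Path(path)
    records: list[tuple[str, str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper().rstrip("*")
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append((rec.id, desc, seq))
    if not records:
        raise ValueError(f"no records in {path}")
    return records


@dataclass(frozen=True)
class CdsFeature:
    contig_id: str
    start: int  # 1-based inclusive
    end: int
    strand: str
    locus_tag: str
    protein_id: str


def _parse_gff_attributes(text: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in text.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" in part:
            key, _, val = part.partition("=")
            out[key.strip()] = val.strip()
    return out


def read_gff_cds(path) -> list[CdsFeature]:
    """Read the CDS rows of a GFF3 file.

    Only feature-type ``CDS`` rows are consumed; comments and other feature
    types are skipped.  ``locus_tag`` falls back to ``ID`` when absent.
    1-based inclusive coordinates are preserved.
    """
    path = Path(path)
    feats: list[CdsFeature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 columns, got {len(cols)}")
            contig, _source, ftype, start_s, end_s, _score, strand, _phase, attrs_s = cols
            if ftype != "CDS":
                continue
            start, end = int(start_s), int(end_s)
            if end < start:
                raise ValueError(f"{path}:{lineno}: CDS end {end} < start {start}")
            attrs = _parse_gff_attributes(attrs_s)
            if "ID" not in attrs:
                raise ValueError(f"{path}:{lineno}: CDS row missing ID attribute")
            protein_id = attrs["ID"]
            locus_tag = attrs.get("locus_tag", protein_id)
            if strand not in {"+", "-"}:
                strand = "unknown"
            feats.append(CdsFeature(contig, start, end, strand, locus_tag, protein_id))
    return feats


def assemble_genome(
    fasta_records: list[tuple[str, str, str]],
    cds_records: list[CdsFeature],
    *,
    genome_id: str,
    group_label: str,
    completeness: float,
    contamination: float,
    rrna_16s: Optional[str] = None,
    cds_nucleotides: Optional[dict[str, str]] = None,
    nucleotide_types: Optional[dict[str, str]] = None,
) -> GenomeAnnotation:
    """Join FASTA sequences with CDS coordinates into a GenomeAnnotation.

    Ranks are assigned per contig by ascending start coordinate.  Every CDS
    must have a sequence; FASTA records without a CDS are allowed (logged).
    """
    seqs = {rid: seq for rid, _desc, seq in fasta_records}
    missing = sorted(f.protein_id for f in cds_records if f.protein_id not in seqs)
    if missing:
        raise ValueError(
            f"genome {genome_id!r}: CDS without protein sequence: {', '.join(missing)}"
        )
    unmatched = set(seqs) - {f.protein_id for f in cds_records}
    if unmatched:
        log.info(
            "genome %s: %d FASTA records without CDS coordinates (ignored)",
            genome_id, len(unmatched),
        )
    by_contig: dict[str, list[CdsFeature]] = {}
    for f in cds_records:
        by_contig.setdefault(f.contig_id, []).append(f)
    proteins: list[ProteinRecord] = []
    for contig in sorted(by_contig):
        feats = sorted(by_contig[contig], key=lambda f: (f.start, f.end, f.protein_id))
        for rank, f in enumerate(feats):
            proteins.append(
                ProteinRecord(
                    protein_id=f.protein_id,
                    genome_id=genome_id,
                    locus_tag=f.locus_tag,
                    contig_id=contig,
                    rank=rank,
                    strand=f.strand,
                    sequence=seqs[f.protein_id],
                )
            )
    return GenomeAnnotation(
        genome_id=genome_id,
        group_label=group_label,
        completeness=float(completeness),
        contamination=float(contamination),
        proteins=proteins,
        rrna_16s=rrna_16s,
        cds_nucleotides=dict(cds_nucleotides or {}),
        nucleotide_types=dict(nucleotide_types or {}),
    )


@dataclass(frozen=True)
class Exclusion:
    genome_id: str
    reason: str
    value: float


def filter_cohort(
    genomes: list[GenomeAnnotation],
    min_completeness: float = 80.0,
    max_contamination: float = 7.0,
) -> tuple[list[GenomeAnnotation], list[Exclusion]]:
    """Apply the CheckM-style cohort quality filter.

    A genome is retained iff completeness >= ``min_completeness`` and
    contamination <= ``max_contamination`` (boundaries inclusive: removal
    requires strictly lower completeness / strictly higher contamination).
    """
    retained: list[GenomeAnnotation] = []
    excluded: list[Exclusion] = []
    for g in genomes:
        if g.completeness < min_completeness:
            excluded.append(Exclusion(g.genome_id, "completeness", g.completeness))
        elif g.contamination > max_contamination:
            excluded.append(Exclusion(g.genome_id, "contamination", g.contamination))
        else:
            retained.append(g)
    if not retained:
        log.warning("quality filter retained no genomes")
    return retained, excluded


def read_cohort_sheet(path) -> pd.DataFrame:
    """Read the cohort TSV and validate its header."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort sheet {path} missing columns: {', '.join(missing)}")
    if df["genome_id"].duplicated().any():
        dups = df.loc[df["genome_id"].duplicated(), "genome_id"].tolist()
        raise ValueError(f"duplicate genome ids in cohort sheet: {dups}")
    return df


def _read_first_fasta_seq(path) -> Optional[str]:
    for rec in SeqIO.parse(str(path), "fasta"):
        return str(rec.seq).upper()
    return None


def load_cohort(sheet_path) -> list[GenomeAnnotation]:
    """Load every genome referenced by a cohort sheet.

    Relative paths in the sheet are resolved against the sheet's directory.
    The optional ``16s_fasta`` column supplies the 16S sequence and the
    optional ``cds_fasta`` column nucleotide gene sequences (records whose
    description contains ``type=rRNA`` or ``type=tRNA`` are tagged so ANI
    can exclude them).
    """
    sheet_path = Path(sheet_path)
    base = sheet_path.parent
    df = read_cohort_sheet(sheet_path)
    genomes: list[GenomeAnnotation] = []
    for row in df.itertuples(index=False):
        fasta = read_protein_fasta(base / row.fasta)
        cds = read_gff_cds(base / row.gff)
        genomes.append(
            assemble_genome(
                fasta,
                cds,
                genome_id=row.genome_id,
                group_label=row.group,
                completeness=float(row.completeness),
                contamination=float(row.contamination),
            )
        )
    # optional columns handled via the dataframe to avoid itertuples renaming
    if "16s_fasta" in df.columns:
        for g, p in zip(genomes, df["16s_fasta"]):
            if isinstance(p, str) and p:
                g.rrna_16s = _read_first_fasta_seq(base / p)
    if "cds_fasta" in df.columns:
        for g, p in zip(genomes, df["cds_fasta"]):
            if not (isinstance(p, str) and p):
                continue
            for rec in SeqIO.parse(str(base / p), "fasta"):
                g.cds_nucleotides[rec.id] = str(rec.seq).upper()
                desc = rec.description
                if "type=rRNA" in desc:
                    g.nucleotide_types[rec.id] = "rRNA"
                elif "type=tRNA" in desc:
                    g.nucleotide_types[rec.id] = "tRNA"
                else:
                    g.nucleotide_types[rec.id] = "CDS"
    return genomes


def read_reference_catalog(path) -> ReferenceCatalog:
    """Read a labeled reference catalog FASTA.

    Header format: ``>ref_id role=<label> [complex=<name>] [min_hemes=<n>]
    [max_hemes=<n>]``.  Every entry must carry a role.
    """
    entries: list[RefEntry] = []
    for rid, desc, seq in read_protein_fasta(path):
        fields = dict(
            kv.partition("=")[::2] for kv in desc.split() if "=" in kv
        )
        if "role" not in fields:
            raise ValueError(f"catalog entry {rid!r} missing role= field")
        entries.append(
            RefEntry(
                ref_id=rid,
                role_label=fields["role"],
                sequence=seq,
                complex_name=fields.get("complex"),
                expected_min_hemes=(
                    int(fields["min_hemes"]) if "min_hemes" in fields else None
                ),
                expected_max_hemes=(
                    int(fields["max_hemes"]) if "max_hemes" in fields else None
                ),
            )
        )
    return ReferenceCatalog(entries)


def write_reference_catalog(catalog: ReferenceCatalog, path) -> None:
    with open(path, "w") as fh:
        for e in catalog:
            parts = [f"role={e.role_label}"]
            if e.complex_name:
                parts.append(f"complex={e.complex_name}")
            if e.expected_min_hemes is not None:
                parts.append(f"min_hemes={e.expected_min_hemes}")
            if e.expected_max_hemes is not None:
                parts.append(f"max_hemes={e.expected_max_hemes}")
            fh.write(f">{e.ref_id} {' '.join(parts)}\n")
            for i in range(0, len(e.sequence), 70):
                fh.write(e.sequence[i:i + 70] + "\n")


def write_fasta(records: list[tuple[str, str]], path, width: int = 70) -> None:
    """Write ``(id_or_header, sequence)`` pairs as FASTA."""
    with open(path, "w") as fh:
        for header, seq in records:
            fh.write(f">{header}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_exclusion_log(exclusions: list[Exclusion], path) -> None:
    df = pd.DataFrame(
        [(e.genome_id, e.reason, e.value) for e in exclusions],
        columns=["genome_id", "reason", "value"],
    )
    df.to_csv(path, sep="\t", index=False)
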