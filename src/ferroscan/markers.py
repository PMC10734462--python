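"""Metabolic marker presence/absence profiling and group summaries.

Detection is homology-based: each marker subunit is searched against the
labeled reference catalog with identity/coverage thresholds (plus a
heme-count check where the catalog specifies one, e.g. the monoheme
constraint on the Cyc2 iron oxidase).  A multi-subunit marker is present
when the fraction of subunits with a qualifying hit reaches the marker's
rule (default: all subunits).  Group-percent tables summarize prevalence
per genome group, the data behind prevalence dot plots.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from .records import GenomeAnnotation, ReferenceCatalog
from .synteny import ROLE_MIN_COV, ROLE_MIN_ID, find_role_candidates


@dataclass(frozen=True)
class MarkerDefinition:
    name: str
    subunits: tuple[str, ...]
    rule: float = 1.0  # fraction of subunits required

    def __post_init__(self) -> None:
        if not self.subunits:
            raise ValueError(f"marker {self.name!r} has no subunits")
        if not 0.0 < self.rule <= 1.0:
            raise ValueError(f"marker {self.name!r}: rule must be in (0, 1]")


@dataclass(frozen=True)
class MarkerHit:
    subunit: str
    locus_tag: str
    identity: float


def load_marker_definitions(path=None) -> list[MarkerDefinition]:
    if path is None:
        path = Path(__file__).parent / "data" / "markers.yaml"
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return [
        MarkerDefinition(
            name=m["name"],
            subunits=tuple(m["subunits"]),
            rule=float(m.get("rule", 1.0)),
        )
        for m in doc["markers"]
    ]


def validate_catalog(
    definitions: list[MarkerDefinition], catalog: ReferenceCatalog
) -> None:
    missing = [
        f"{d.name}:{s}"
        for d in definitions
        for s in d.subunits
        if not catalog.has_role(s)
    ]
    if missing:
        raise ValueError(
            "marker subunits without reference sequences: " + ", ".join(missing)
        )


def detect_marker(
    genome: GenomeAnnotation,
    definition: MarkerDefinition,
    catalog: ReferenceCatalog,
    min_id: float = ROLE_MIN_ID,
    min_cov: float = ROLE_MIN_COV,
) -> tuple[bool, list[MarkerHit]]:
    """Detect one marker in one genome; returns presence plus subunit hits."""
    hits: list[MarkerHit] = []
    n_found = 0
    for subunit in definition.subunits:
        cands = find_role_candidates(
            genome, subunit, catalog, min_id=min_id, min_cov=min_cov
        )
        if cands:
            n_found += 1
            best = max(cands, key=lambda h: h.identity)
            hits.append(MarkerHit(subunit, best.protein.locus_tag, best.identity))
    present = n_found / len(definition.subunits) >= definition.rule - 1e-9
    return present, hits


def marker_matrix(
    genomes: list[GenomeAnnotation],
    definitions: list[MarkerDefinition],
    catalog: ReferenceCatalog,
    min_id: float = ROLE_MIN_ID,
    min_cov: float = ROLE_MIN_COV,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Genome x marker boolean matrix plus per-hit detail table."""
    validate_catalog(definitions, catalog)
    rows = {}
    details = []
    for g in genomes:
        row = {}
        for d in definitions:
            present, hits = detect_marker(g, d, catalog, min_id=min_id, min_cov=min_cov)
            row[d.name] = present
            for h in hits:
                details.append(
                    (g.genome_id, d.name, h.subunit, h.locus_tag, round(h.identity, 2))
                )
        rows[g.genome_id] = row
    matrix = pd.DataFrame.from_dict(rows, orient="index")
    if not matrix.empty:
        matrix = matrix[[d.name for d in definitions]]
        matrix.index.name = "genome_id"
    detail = pd.DataFrame(
        details, columns=["genome_id", "marker", "subunit", "locus_tag", "identity"]
    )
    return matrix, detail


def group_percent(
    matrix: pd.DataFrame, grouping: dict[str, str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Group x marker percent-presence table (plus raw counts).

    ``grouping`` maps genome_id -> group label; every genome in the matrix
    must be labeled and no group may be empty.
    """
    unlabeled = [g for g in matrix.index if g not in grouping]
    if unlabeled:
        raise ValueError(f"genomes without group label: {unlabeled}")
    groups = pd.Series({g: grouping[g] for g in matrix.index}, name="group")
    counts = matrix.astype(int).groupby(groups).sum()
    sizes = groups.value_counts()
    for grp in sizes.index[sizes == 0]:
        raise ValueError(f"empty group {grp!r}")
    percent = counts.div(sizes, axis=0) * 100.0
    return percent, counts


def combo_flags(matrix: pd.DataFrame) -> pd.DataFrame:
    """Derived per-genome booleans over the marker matrix.

    ``iron_ox_both``/``iron_ox_either`` combine the two iron-oxidase genes;
    ``denitrification_to_n2o`` requires a nitrate reductase, a nitrite
    reductase and a nitric oxide reductase; ``full_denitrification``
    additionally requires nosZ.
    """
    def col(name: str) -> pd.Series:
        if name in matrix.columns:
            return matrix[name].astype(bool)
        return pd.Series(False, index=matrix.index)

    flags = pd.DataFrame(index=matrix.index)
    flags["iron_ox_both"] = col("cyc2") & col("mtoA")
    flags["iron_ox_either"] = col("cyc2") | col("mtoA")
    nar = col("narGH") | col("napAB")
    nir = col("nirK") | col("nirS")
    nor = col("norBC")
    flags["denitrification_to_n2o"] = nar & nir & nor
    flags["full_denitrification"] = flags["denitrification_to_n2o"] & col("nosZ")
    return flags
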