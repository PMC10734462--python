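"""End-to-end orchestration: quality filter -> heme census -> clustering ->
complex calling -> marker profiling -> genome metrics -> phylogeny, with a
run manifest recording inputs, parameters, per-stage counts, and checksums
of every artifact."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import cluster as cluster_mod
from . import hemes as hemes_mod
from . import io as io_mod
from . import markers as markers_mod
from . import metrics as metrics_mod
from . import phylo as phylo_mod
from . import synteny as synteny_mod

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Flat run configuration; unknown keys are rejected at load time."""

    cohort: str = ""
    catalog: str = ""
    out_dir: str = "ferroscan_out"
    seed: int = 0
    min_completeness: float = 80.0
    max_contamination: float = 7.0
    bin_edges: tuple[int, ...] = hemes_mod.DEFAULT_BIN_EDGES
    min_mhc: int = hemes_mod.DEFAULT_MIN_MHC
    cluster_min_cov: float = cluster_mod.DEFAULT_MIN_COV
    cluster_min_id: float = cluster_mod.DEFAULT_MIN_ID
    classify_min_id: float = cluster_mod.CLASSIFY_MIN_ID
    classify_min_cov: float = cluster_mod.CLASSIFY_MIN_COV
    role_min_id: float = synteny_mod.ROLE_MIN_ID
    role_min_cov: float = synteny_mod.ROLE_MIN_COV
    complexes_file: str = ""
    markers_file: str = ""
    distance_model: str = "poisson"
    bootstraps: int = 100
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        known = set(cls.__dataclass_fields__)
        unknown = sorted(set(doc) - known)
        if unknown:
            raise ValueError(f"unknown config keys: {', '.join(unknown)}")
        if "bin_edges" in doc and isinstance(doc["bin_edges"], str):
            doc = dict(doc)
            doc["bin_edges"] = tuple(int(x) for x in doc["bin_edges"].split(","))
        return cls(**doc)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunResult:
    out_dir: Path
    manifest: dict
    tables: dict = field(default_factory=dict)


def run_all(config: RunConfig) -> RunResult:
    """Execute every stage in order; artifacts land in ``config.out_dir``.

    A later-stage failure preserves earlier outputs; the manifest records
    the failure point.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(config).items()
        },
        "stages": {},
        "outputs": {},
        "status": "running",
    }
    tables: dict = {}
    try:
        _run_stages(config, out, manifest, tables)
        manifest["status"] = "ok"
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        _write_manifest(out, manifest)
        raise
    _write_manifest(out, manifest)
    return RunResult(out_dir=out, manifest=manifest, tables=tables)


def _register(out: Path, manifest: dict, path: Path) -> None:
    manifest["outputs"][str(path.relative_to(out))] = {
        "bytes": path.stat().st_size,
        "sha256": _sha256(path),
    }


def _run_stages(config: RunConfig, out: Path, manifest: dict, tables: dict) -> None:
    genomes = io_mod.load_cohort(config.cohort)
    catalog = io_mod.read_reference_catalog(config.catalog)
    manifest["stages"]["load"] = {"genomes": len(genomes), "references": len(catalog)}

    # 1. quality filter
    retained, excluded = io_mod.filter_cohort(
        genomes, config.min_completeness, config.max_contamination
    )
    io_mod.write_exclusion_log(excluded, out / "exclusions.tsv")
    _register(out, manifest, out / "exclusions.tsv")
    manifest["stages"]["filter"] = {"retained": len(retained), "excluded": len(excluded)}
    if not retained:
        raise RuntimeError("quality filter excluded every genome; nothing to analyze")
    grouping = {g.genome_id: g.group_label for g in retained}

    # 2. heme census
    heme_rows = []
    hist_rows = []
    motif_proteins = []
    for g in retained:
        profiles, summary = hemes_mod.profile_genome(
            g, config.bin_edges, config.min_mhc
        )
        by_id = g.by_id()
        for prof in profiles:
            heme_rows.append(
                (
                    g.genome_id, prof.protein_id, prof.n_cxxch, prof.n_cx3ch,
                    prof.n_cx4ch, prof.total_hemes, prof.category,
                )
            )
            motif_proteins.append(by_id[prof.protein_id])
        hist_rows.append(
            {"genome_id": g.genome_id, **summary.histogram, "n_mhc": summary.n_mhc}
        )
    hemes_df = pd.DataFrame(
        heme_rows,
        columns=[
            "genome_id", "protein_id", "n_cxxch", "n_cx3ch", "n_cx4ch",
            "total", "category",
        ],
    )
    hemes_df.to_csv(out / "hemes.tsv", sep="\t", index=False)
    hist_df = pd.DataFrame(hist_rows).set_index("genome_id")
    hist_df.to_csv(out / "heme_histogram.tsv", sep="\t")
    for p in ("hemes.tsv", "heme_histogram.tsv"):
        _register(out, manifest, out / p)
    manifest["stages"]["hemes"] = {
        "proteins_scanned": sum(g.n_proteins for g in retained),
        "motif_bearing": len(motif_proteins),
    }
    tables["hemes"] = hemes_df
    tables["heme_histogram"] = hist_df

    # 3. clustering + classification + pangenome bins
    edges = cluster_mod.similarity_edges(
        motif_proteins, config.cluster_min_cov, config.cluster_min_id
    )
    clusters = cluster_mod.greedy_cluster(motif_proteins, edges)
    cluster_mod.classify_clusters(
        clusters, motif_proteins, catalog,
        min_id=config.classify_min_id, min_cov=config.classify_min_cov,
    )
    genome_of = {p.protein_id: p.genome_id for p in motif_proteins}
    bins = cluster_mod.pangenome_bins(clusters, genome_of, len(retained))
    cluster_rows = [
        (c.cluster_id, c.centroid_id, m, genome_of[m], c.label, c.label_source)
        for c in clusters
        for m in sorted(c.members)
    ]
    clusters_df = pd.DataFrame(
        cluster_rows,
        columns=["cluster_id", "centroid", "member", "genome_id", "label",
                 "label_source"],
    )
    clusters_df.to_csv(out / "clusters.tsv", sep="\t", index=False)
    bins_df = pd.DataFrame(
        [(b.cluster_id, b.bin, round(b.prevalence, 4)) for b in bins],
        columns=["cluster_id", "bin", "prevalence"],
    )
    bins_df.to_csv(out / "pangenome_bins.tsv", sep="\t", index=False)
    for p in ("clusters.tsv", "pangenome_bins.tsv"):
        _register(out, manifest, out / p)
    manifest["stages"]["cluster"] = {
        "edges": len(edges), "clusters": len(clusters),
    }
    tables["clusters"] = clusters_df
    tables["pangenome_bins"] = bins_df

    # 4. complex calling
    defs = synteny_mod.load_complex_definitions(config.complexes_file or None)
    complex_table, calls = synteny_mod.cohort_complex_matrix(
        retained, defs, catalog,
        min_id=config.role_min_id, min_cov=config.role_min_cov,
    )
    complex_table.to_csv(out / "complexes.tsv", sep="\t")
    _register(out, manifest, out / "complexes.tsv")
    manifest["stages"]["complexes"] = {
        "complete": int((complex_table.isin(["complete", "complete-variant"])).sum().sum()),
        "partial": int((complex_table == "partial").sum().sum()),
    }
    tables["complexes"] = complex_table

    # 5. marker profiling
    mdefs = markers_mod.load_marker_definitions(config.markers_file or None)
    matrix, detail = markers_mod.marker_matrix(
        retained, mdefs, catalog,
        min_id=config.role_min_id, min_cov=config.role_min_cov,
    )
    percent, counts = markers_mod.group_percent(matrix, grouping)
    flags = markers_mod.combo_flags(matrix)
    matrix.astype(int).to_csv(out / "marker_matrix.tsv", sep="\t")
    percent.round(2).to_csv(out / "marker_group_percent.tsv", sep="\t")
    detail.to_csv(out / "marker_hits.tsv", sep="\t", index=False)
    flags.astype(int).to_csv(out / "marker_flags.tsv", sep="\t")
    for p in ("marker_matrix.tsv", "marker_group_percent.tsv", "marker_hits.tsv",
              "marker_flags.tsv"):
        _register(out, manifest, out / p)
    manifest["stages"]["markers"] = {
        "markers": len(mdefs),
        "present_calls": int(matrix.sum().sum()),
    }
    tables["marker_matrix"] = matrix
    tables["marker_group_percent"] = percent

    # 6. genome similarity metrics
    for metric, fname in (("AAI", "aai"), ("ANI", "ani"), ("16S", "rrna_identity")):
        try:
            values, support = metrics_mod.similarity_matrix(retained, metric)
        except ValueError as exc:
            log.warning("%s matrix skipped: %s", metric, exc)
            continue
        values.round(4).to_csv(out / f"{fname}.tsv", sep="\t")
        support.to_csv(out / f"{fname}_support.tsv", sep="\t")
        _register(out, manifest, out / f"{fname}.tsv")
        _register(out, manifest, out / f"{fname}_support.tsv")
        tables[fname] = values
    manifest["stages"]["metrics"] = {"pairs": len(retained) * (len(retained) - 1) // 2}

    # 7. phylogeny
    if len(retained) >= 4:
        marker_set = phylo_mod.extract_markers(retained, catalog)
        blocks = {
            m: phylo_mod.align_marker(marker_set.sequences[m])
            for m in marker_set.markers
        }
        masked = phylo_mod.mask_and_concat(
            blocks, [g.genome_id for g in retained]
        )
        tree = phylo_mod.nj_tree(
            masked, model=config.distance_model,
            bootstraps=config.bootstraps, seed=config.seed,
        )
        with open(out / "tree.nwk", "w") as fh:
            fh.write(tree.newick() + "\n")
        aln_path = out / "concat_alignment.fasta"
        io_mod.write_fasta(
            [(g, masked.matrix[g]) for g in masked.genome_ids], aln_path
        )
        pd.DataFrame(
            masked.column_map, columns=["marker", "marker_column"]
        ).to_csv(out / "column_map.tsv", sep="\t", index_label="concat_column")
        for p in ("tree.nwk", "concat_alignment.fasta", "column_map.tsv"):
            _register(out, manifest, out / p)
        manifest["stages"]["tree"] = {
            "markers_used": len(marker_set.markers),
            "alignment_columns": masked.length,
        }
        tables["tree"] = tree
    else:
        log.warning("fewer than 4 genomes; phylogeny stage skipped")
        manifest["stages"]["tree"] = {"skipped": "fewer than 4 genomes"}


def _write_manifest(out: Path, manifest: dict) -> None:
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def summary_report(run: RunResult) -> dict:
    """Cohort report mirroring the pipeline's main tables as JSON."""
    required = ["heme_histogram", "marker_matrix", "complexes"]
    missing = [k for k in required if k not in run.tables]
    if missing:
        raise ValueError(f"missing stage outputs: {', '.join(missing)}")
    report = {
        "heme_histogram": run.tables["heme_histogram"].to_dict(orient="index"),
        "marker_matrix": {
            g: {m: bool(v) for m, v in row.items()}
            for g, row in run.tables["marker_matrix"].to_dict(orient="index").items()
        },
        "marker_group_percent": run.tables["marker_group_percent"]
        .round(2)
        .to_dict(orient="index"),
        "complex_verdicts": run.tables["complexes"].to_dict(orient="index"),
    }
    if "tree" in run.tables and not isinstance(run.tables["tree"], pd.DataFrame):
        report["tree_newick"] = run.tables["tree"].newick()
    out_path = run.out_dir / "report.json"
    with open(out_path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
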