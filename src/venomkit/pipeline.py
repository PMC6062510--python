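"""End-to-end orchestration: catalog -> Ka/Ks -> categories/acceleration ->
clusters -> enrichment -> genome metrics.

A :class:`RunConfig` names the input files per stage; stages whose inputs are
absent from the config are skipped. Reports carry the package version and a
SHA-256 hash of the canonical config, and a rerun on identical inputs is
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__, io
from .enrichment import anchor_genes, enrichment_report
from .families import (
    apply_curation,
    build_family_table,
    detect_gene_clusters,
    keyword_screen,
    label_records,
    summarize_family,
)
from .genome import flow_cytometry_size, kmer_genome_size
from .ng import CodonAlignmentPair, PairRejected, pairwise_ng
from .trees import classify_ohnolog_scenario, parse_labeled_tree, sv_monophyletic

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """A run configuration references missing files or bad thresholds."""


@dataclass(frozen=True)
class RunConfig:
    """Paths and options of one full run. All path fields are optional; a
    stage runs when its inputs are present."""

    out_dir: str
    gene_table: str | None = None  # TSV: gene_id, family, label, scaffold_id, annotation, cds
    keywords: str | None = None  # one keyword per line
    exclusions: str | None = None  # curated-out gene ids
    inhibitors: str | None = None  # venom-inhibitor gene ids
    marker_table: str | None = None  # TSV: marker_id, chromosome, chrom_class
    marker_hits: str | None = None  # TSV: marker_id, scaffold_id
    gene_scaffolds: str | None = None  # TSV: gene_id, scaffold_id (anchoring)
    kmer_histogram: str | None = None  # depth/count text
    flow_panel: str | None = None  # TSV: name, fluorescence, genome_size_gb
    trees: tuple[str, ...] = ()  # newick files with id|species|LABEL tips
    alpha: float = 0.05  # acceleration test level
    kmer_error_cutoff: int = 10
    ks_breakpoints: tuple[float, float] = (0.2, 0.5)

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigError(f"alpha {self.alpha} outside (0, 1)")
        if self.kmer_error_cutoff < 1:
            raise ConfigError("kmer_error_cutoff must be >= 1")
        for name in (
            "gene_table", "keywords", "exclusions", "inhibitors",
            "marker_table", "marker_hits", "gene_scaffolds",
            "kmer_histogram", "flow_panel",
        ):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise ConfigError(f"{name}: no such file: {path}")
        for path in self.trees:
            if not Path(path).exists():
                raise ConfigError(f"trees: no such file: {path}")

    def to_dict(self) -> dict:
        return {
            "out_dir": self.out_dir,
            "gene_table": self.gene_table,
            "keywords": self.keywords,
            "exclusions": self.exclusions,
            "inhibitors": self.inhibitors,
            "marker_table": self.marker_table,
            "marker_hits": self.marker_hits,
            "gene_scaffolds": self.gene_scaffolds,
            "kmer_histogram": self.kmer_histogram,
            "flow_panel": self.flow_panel,
            "trees": list(self.trees),
            "alpha": self.alpha,
            "kmer_error_cutoff": self.kmer_error_cutoff,
            "ks_breakpoints": list(self.ks_breakpoints),
        }

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        raw["trees"] = tuple(raw.get("trees", ()))
        raw["ks_breakpoints"] = tuple(raw.get("ks_breakpoints", (0.2, 0.5)))
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def config_hash(self) -> str:
        """Hash of the analytic configuration (inputs and options; the output
        directory does not affect results and is excluded)."""
        payload = {k: v for k, v in self.to_dict().items() if k != "out_dir"}
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def run_full(config: RunConfig) -> dict:
    """Run every configured stage; returns a summary dict (also written to
    ``run_summary.json`` in the output directory alongside per-stage files)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "stages": {},
    }
    log_lines: list[str] = []

    def stage_log(stage: str, **counts):
        line = f"{stage}: " + ", ".join(f"{k}={v}" for k, v in counts.items())
        logger.info(line)
        log_lines.append(line)
        summary["stages"][stage] = counts

    records = []
    if config.gene_table:
        records = io.read_gene_table(config.gene_table)
        stage_log("load_genes", n_records=len(records))

    # --- catalog: keyword screen + curation ---------------------------------
    if records and config.keywords:
        keywords = io.read_keywords(config.keywords)
        annotations = {r.gene_id: r.annotation for r in records}
        hits = keyword_screen(annotations, keywords)
        exclusions = io.read_id_list(config.exclusions) if config.exclusions else []
        inhibitors = io.read_id_list(config.inhibitors) if config.inhibitors else []
        try:
            venom_related, accounting = apply_curation(hits, exclusions, inhibitors)
        except ValueError as exc:
            raise ConfigError(f"curation stage: {exc}") from exc
        records = label_records(records, exclusions, inhibitors)
        stage_log(
            "catalog",
            candidates=accounting.n_candidates,
            excluded=accounting.n_excluded_unrelated,
            inhibitors=accounting.n_inhibitors,
            venom_related=accounting.n_venom_related,
        )
        summary["curation"] = {
            "n_candidates": accounting.n_candidates,
            "n_excluded_unrelated": accounting.n_excluded_unrelated,
            "n_inhibitors": accounting.n_inhibitors,
            "n_venom_related": accounting.n_venom_related,
        }

    # --- Ka/Ks + family table -----------------------------------------------
    if records and any(r.cds for r in records):
        families = sorted({r.family for r in records if r.label in ("SV", "NV")})
        summaries = []
        estimates = []
        for fam in families:
            fam_records = [r for r in records if r.family == fam]
            try:
                s = summarize_family(fam, fam_records, alpha=config.alpha)
            except ValueError as exc:
                raise ConfigError(f"family {fam}: {exc}") from exc
            summaries.append(s)
            for group in ("SV", "NV"):
                members = [r for r in fam_records if r.label == group and r.cds]
                from itertools import combinations

                for ra, rb in combinations(members, 2):
                    try:
                        estimates.append(
                            pairwise_ng(
                                CodonAlignmentPair(
                                    ra.gene_id, rb.gene_id, ra.cds, rb.cds
                                )
                            )
                        )
                    except (PairRejected, ValueError):
                        continue
        table = build_family_table(summaries)
        table.to_csv(out / "family_table.tsv", sep="\t", index=False)
        io.write_kaks_tsv(estimates, out / "kaks_pairs.tsv")
        stage_log(
            "kaks", families=len(families), pairs=len(estimates),
            accelerated=sum(1 for s in summaries if s.accelerated),
        )

        clusters = detect_gene_clusters(records)
        io.write_clusters_tsv(clusters, out / "gene_clusters.tsv")
        stage_log("clusters", n_clusters=len(clusters))

    # --- enrichment ----------------------------------------------------------
    if config.marker_table and config.marker_hits and config.gene_scaffolds:
        markers = io.read_marker_table(config.marker_table)
        hits_map = io.read_two_column_map(config.marker_hits)
        gene_scaffolds = dict(io.read_two_column_map(config.gene_scaffolds))
        assignments = anchor_genes(gene_scaffolds, hits_map, markers)
        focal = [
            r.gene_id
            for r in records
            if r.label in ("SV", "NV") and r.gene_id in assignments
        ]
        if focal:
            result = enrichment_report(assignments, focal)
            io.write_enrichment_json(result, out / "enrichment.json")
            stage_log(
                "enrichment",
                anchored=len(assignments),
                focal=len(focal),
                focal_mic_percent=result.focal_mic_percent,
            )
            summary["enrichment"] = {
                "p_two_sided": result.p_two_sided,
                "odds_ratio": result.odds_ratio,
                "focal_mic_percent": result.focal_mic_percent,
            }
        else:
            stage_log("enrichment", anchored=len(assignments), focal=0)

    # --- genome metrics ------------------------------------------------------
    metrics: dict = {}
    if config.kmer_histogram:
        hist = io.read_kmer_histogram(config.kmer_histogram)
        peak, size = kmer_genome_size(hist, config.kmer_error_cutoff)
        metrics["kmer"] = {
            "peak_depth": peak,
            "genome_size_bases": size,
            "error_cutoff": config.kmer_error_cutoff,
        }
        stage_log("kmer_genome_size", peak_depth=peak, genome_size=int(size))
    if config.flow_panel:
        panel = io.read_flow_panel(config.flow_panel)
        metrics["flow_cytometry"] = {"genome_size_gb": flow_cytometry_size(panel)}
        stage_log(
            "flow_cytometry",
            genome_size_gb=round(metrics["flow_cytometry"]["genome_size_gb"], 3),
        )
    if metrics:
        metrics["version"] = __version__
        metrics["config_hash"] = config.config_hash()
        (out / "genome_metrics.json").write_text(json.dumps(metrics, indent=2) + "\n")
        summary["genome_metrics"] = metrics

    # --- trees ---------------------------------------------------------------
    if config.trees:
        rows = []
        for path in config.trees:
            tree = parse_labeled_tree(Path(path).read_text())
            rows.append(
                {
                    "tree": Path(path).name,
                    "sv_monophyletic": sv_monophyletic(tree),
                    "scenario": classify_ohnolog_scenario(tree),
                }
            )
        import pandas as pd

        pd.DataFrame(rows).to_csv(out / "tree_scenarios.tsv", sep="\t", index=False)
        stage_log("trees", n_trees=len(rows))

    (out / "run.log").write_text(
        "\n".join(
            [f"venomkit {__version__} config {config.config_hash()}"] + log_lines
        )
        + "\n"
    )
    (out / "run_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    return summary
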