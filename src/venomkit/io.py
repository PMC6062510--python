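"""Readers and writers for the pipeline's plain-text formats.

FASTA goes through Biopython; tabular data through pandas. All formats are
uncompressed text: aligned CDS FASTA, gene/annotation TSV, one-keyword-per-
line lists, marker tables, two-column k-mer histograms, and flow-cytometry
reference panels.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .enrichment import EnrichmentResult, Marker
from .families import GeneCluster, GeneRecord
from .genome import FlowCytometryPanel, KmerHistogram
from .ng import CodonAlignmentPair, SubstitutionEstimate

KAKS_COLUMNS = [
    "id_a", "id_b", "codons_used", "S", "N", "Sd", "Nd", "pS", "pN",
    "Ks", "Ka", "ratio", "flags",
]


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """(id, sequence) tuples from a FASTA file; ids from the first word of
    the description line."""
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    seqs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    SeqIO.write(seqs, str(path), "fasta")


def read_aligned_pairs(path: str | Path) -> list[CodonAlignmentPair]:
    """Pairwise pre-aligned CDS FASTA: consecutive records form one pair."""
    entries = read_fasta(path)
    if len(entries) % 2 != 0:
        raise ValueError(
            f"{path}: pairwise FASTA must hold an even number of records"
        )
    return [
        CodonAlignmentPair(
            id_a=entries[i][0],
            id_b=entries[i + 1][0],
            seq_a=entries[i][1],
            seq_b=entries[i + 1][1],
        )
        for i in range(0, len(entries), 2)
    ]


def _fmt(x: float) -> str:
    if isinstance(x, float) and math.isnan(x):
        return "NA"
    if x == math.inf:
        return "inf"
    return f"{x:.6g}"


def write_kaks_tsv(
    estimates: Iterable[SubstitutionEstimate], path: str | Path
) -> None:
    rows = []
    for e in estimates:
        rows.append(
            {
                "id_a": e.id_a,
                "id_b": e.id_b,
                "codons_used": e.sites.codons_used,
                "S": _fmt(e.sites.S),
                "N": _fmt(e.sites.N),
                "Sd": _fmt(e.sites.Sd),
                "Nd": _fmt(e.sites.Nd),
                "pS": _fmt(e.pS),
                "pN": _fmt(e.pN),
                "Ks": _fmt(e.Ks),
                "Ka": _fmt(e.Ka),
                "ratio": _fmt(e.ratio),
                "flags": ",".join(sorted(e.flags)),
            }
        )
    pd.DataFrame(rows, columns=KAKS_COLUMNS).to_csv(path, sep="\t", index=False)


def read_gene_table(path: str | Path) -> list[GeneRecord]:
    """Gene annotation TSV with columns gene_id, family, label, scaffold_id,
    annotation and optionally cds."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"gene_id", "family", "label", "scaffold_id", "annotation"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        GeneRecord(
            gene_id=row.gene_id,
            family=row.family or "other",
            label=row.label or "candidate",
            scaffold_id=row.scaffold_id,
            cds=getattr(row, "cds", ""),
            annotation=row.annotation,
        )
        for row in df.itertuples(index=False)
    ]


def write_gene_table(records: Iterable[GeneRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "gene_id": r.gene_id,
                "family": r.family,
                "label": r.label,
                "scaffold_id": r.scaffold_id,
                "annotation": r.annotation,
                "cds": r.cds,
            }
            for r in records
        ]
    ).to_csv(path, sep="\t", index=False)


def read_keywords(path: str | Path) -> list[str]:
    """One keyword per line; blank lines and '#' comments skipped."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def read_id_list(path: str | Path) -> list[str]:
    return read_keywords(path)


def read_marker_table(path: str | Path) -> list[Marker]:
    """TSV with columns marker_id, chromosome, chrom_class."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [
        Marker(row.marker_id, row.chromosome, row.chrom_class)
        for row in df.itertuples(index=False)
    ]


def write_marker_table(markers: Iterable[Marker], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"marker_id": m.marker_id, "chromosome": m.chromosome,
             "chrom_class": m.chrom_class}
            for m in markers
        ]
    ).to_csv(path, sep="\t", index=False)


def read_two_column_map(path: str | Path) -> list[tuple[str, str]]:
    """Headered two-column TSV (e.g. marker->scaffold hits, gene->scaffold)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] != 2:
        raise ValueError(f"{path}: expected exactly two columns")
    return [tuple(row) for row in df.itertuples(index=False)]


def read_kmer_histogram(path: str | Path, k: int = 27) -> KmerHistogram:
    """Two-column whitespace-separated depth/count text (the common k-mer
    counter 'histo' dialect)."""
    entries: dict[int, int] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        depth_s, count_s = line.split()[:2]
        entries[int(depth_s)] = int(count_s)
    return KmerHistogram(k=k, entries=entries)


def write_kmer_histogram(hist: KmerHistogram, path: str | Path) -> None:
    lines = [f"{d} {c}" for d, c in sorted(hist.entries.items())]
    Path(path).write_text("\n".join(lines) + "\n")


def read_flow_panel(path: str | Path) -> FlowCytometryPanel:
    """TSV with columns name, fluorescence, genome_size_gb; the row named
    'sample' (genome_size empty) is the query."""
    df = pd.read_csv(path, sep="\t")
    refs: list[tuple[float, float]] = []
    sample = None
    for _, row in df.iterrows():
        if str(row["name"]).lower() == "sample":
            sample = float(row["fluorescence"])
        else:
            refs.append((float(row["fluorescence"]), float(row["genome_size_gb"])))
    if sample is None:
        raise ValueError(f"{path}: no row named 'sample'")
    return FlowCytometryPanel(references=tuple(refs), sample_fluorescence=sample)


def write_clusters_tsv(clusters: Sequence[GeneCluster], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "scaffold_id": c.scaffold_id,
                "family": c.family,
                "n_genes": len(c.gene_ids),
                "gene_ids": ",".join(c.gene_ids),
            }
            for c in clusters
        ],
        columns=["scaffold_id", "family", "n_genes", "gene_ids"],
    ).to_csv(path, sep="\t", index=False)


def write_enrichment_json(result: EnrichmentResult, path: str | Path) -> None:
    t = result.table
    payload = {
        "table": {"focal_mic": t.a, "focal_mac": t.b, "other_mic": t.c,
                  "other_mac": t.d},
        "focal_mic_fraction": result.focal_mic_fraction,
        "other_mic_fraction": result.other_mic_fraction,
        "focal_mic_percent": result.focal_mic_percent,
        "other_mic_percent": result.other_mic_percent,
        "odds_ratio": result.odds_ratio,
        "p_two_sided": result.p_two_sided,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
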