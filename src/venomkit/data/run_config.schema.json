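{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "venomkit run configuration",
  "type": "object",
  "required": ["out_dir"],
  "additionalProperties": false,
  "properties": {
    "out_dir": {"type": "string", "description": "Report output directory"},
    "gene_table": {"type": ["string", "null"], "description": "TSV: gene_id, family, label, scaffold_id, annotation[, cds]"},
    "keywords": {"type": ["string", "null"], "description": "One keyword per line"},
    "exclusions": {"type": ["string", "null"], "description": "Curated-out gene ids, one per line"},
    "inhibitors": {"type": ["string", "null"], "description": "Venom-inhibitor gene ids, one per line"},
    "marker_table": {"type": ["string", "null"], "description": "TSV: marker_id, chromosome, chrom_class (MIC/MAC)"},
    "marker_hits": {"type": ["string", "null"], "description": "TSV: marker_id, scaffold_id"},
    "gene_scaffolds": {"type": ["string", "null"], "description": "TSV: gene_id, scaffold_id"},
    "kmer_histogram": {"type": ["string", "null"], "description": "Two-column depth/count text"},
    "flow_panel": {"type": ["string", "null"], "description": "TSV: name, fluorescence, genome_size_gb; row 'sample' is the query"},
    "trees": {"type": "array", "items": {"type": "string"}, "description": "Newick files with id|species|LABEL tips"},
    "alpha": {"type": "number", "exclusiveMinimum": 0, "exclusiveMaximum": 1, "default": 0.05},
    "kmer_error_cutoff": {"type": "integer", "minimum": 1, "default": 10},
    "ks_breakpoints": {"type": "array", "items": {"type": "number"}, "minItems": 2, "maxItems": 2, "default": [0.2, 0.5]}
  }
}
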