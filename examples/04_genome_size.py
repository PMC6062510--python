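"""Estimate genome size from a k-mer depth histogram and from flow cytometry.

The k-mer histogram carries a Poisson coverage peak near 43x over a 1-Mb
synthetic genome plus an error shoulder below 10x; the estimator excludes
the shoulder, finds the peak, and divides the retained k-mer instances by
the peak depth. The flow-cytometry panel regresses genome size on
fluorescence over two reference species.
"""

from venomkit import FlowCytometryPanel, flow_cytometry_size, kmer_genome_size
from venomkit.simulate import KmerConfig, generate_kmer_histogram

cfg = KmerConfig(seed=5, genome_size=1_000_000, mean_depth=43,
                 error_fraction=0.3)
hist = generate_kmer_histogram(cfg)
peak, size = kmer_genome_size(hist, error_cutoff=10)
print(f"distinct k-mers     : {hist.total_kmers:,}")
print(f"peak depth          : {peak}x")
print(f"genome size         : {size:,.0f} bases "
      f"(truth {cfg.genome_size:,}; error "
      f"{100 * abs(size - cfg.genome_size) / cfg.genome_size:.2f}%)")

panel = FlowCytometryPanel(
    references=[(100.0, 1.2), (216.7, 2.6)],  # chicken ~1.2 Gb, gecko ~2.6 Gb
    sample_fluorescence=150.0,
)
print(f"flow-cytometry size : {flow_cytometry_size(panel):.2f} Gb")
# The k-mer estimate ignores the 30% error k-mers entirely (they sit below
# the 10x cutoff); the flow-cytometry value is the two-point regression line
# evaluated at the sample's fluorescence.
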