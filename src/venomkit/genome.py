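"""Genome-size estimation from k-mer spectra and flow-cytometry panels.

The k-mer route uses the standard estimator: in a depth histogram of counted
k-mers, the low-depth shoulder (sequencing errors and heterozygous SNPs) is
cut away, the modal depth of the remaining distribution is taken as the
haploid peak coverage, and genome size is the number of retained k-mer
instances divided by that peak depth. The flow-cytometry route regresses
known reference genome sizes on fluorescence and evaluates the line at the
sample's fluorescence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class KmerHistogram:
    """A k-mer depth histogram: depth -> number of distinct k-mers."""

    k: int
    entries: Mapping[int, int]

    def __post_init__(self):
        for depth, count in self.entries.items():
            if depth <= 0 or count < 0:
                raise ValueError(f"invalid histogram entry ({depth}, {count})")

    @property
    def total_kmers(self) -> int:
        """Distinct k-mers (sum of counts)."""
        return sum(self.entries.values())

    @property
    def total_instances(self) -> int:
        """k-mer instances (sum of depth x count)."""
        return sum(d * c for d, c in self.entries.items())


@dataclass(frozen=True)
class FlowCytometryPanel:
    """Reference fluorescence/genome-size points plus a sample fluorescence.

    ``references`` holds (fluorescence in arbitrary units, genome size); at
    least two references with distinct fluorescences are required.
    """

    references: Sequence[tuple[float, float]]
    sample_fluorescence: float

    def __post_init__(self):
        if len(self.references) < 2:
            raise ValueError("at least two reference points required")
        fl = [f for f, _ in self.references]
        if len(set(fl)) < 2:
            raise ValueError("reference fluorescences must not all coincide")


def kmer_genome_size(
    hist: KmerHistogram, error_cutoff: int = 10
) -> tuple[int, float]:
    """Estimate (peak_depth, genome size in bases) from a k-mer histogram.

    Entries below ``error_cutoff`` (default 10, excluding the error/
    heterozygosity shoulder below ~10x) are discarded; the peak depth is the
    modal depth of the remainder (ties resolved to the lowest depth, logged)
    and the genome size is the retained k-mer instances divided by it.
    """
    retained = {d: c for d, c in hist.entries.items() if d >= error_cutoff and c > 0}
    if not retained:
        raise ValueError(
            f"histogram has no k-mers at depth >= {error_cutoff}; "
            "cannot locate a coverage peak"
        )
    max_count = max(retained.values())
    modal_depths = sorted(d for d, c in retained.items() if c == max_count)
    if len(modal_depths) > 1:
        logger.info(
            "modal depth tie at %s; using the lowest (%d)",
            modal_depths,
            modal_depths[0],
        )
    peak_depth = modal_depths[0]
    instances = sum(d * c for d, c in retained.items())
    return peak_depth, instances / peak_depth


def flow_cytometry_size(panel: FlowCytometryPanel) -> float:
    """Genome size by ordinary least squares of size on fluorescence."""
    fl = np.array([f for f, _ in panel.references], dtype=float)
    gs = np.array([g for _, g in panel.references], dtype=float)
    slope, intercept = np.polyfit(fl, gs, 1)
    return float(intercept + slope * panel.sample_fluorescence)


def percent(numerator: float, denominator: float, ndigits: int = 1) -> float:
    """Percentage rounded to ``ndigits`` (round-half-even is fine here; used
    for summary arithmetic like anchored-gene and anchored-length shares)."""
    if denominator == 0:
        raise ZeroDivisionError("percentage of zero denominator")
    return round(100.0 * numerator / denominator, ndigits)
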