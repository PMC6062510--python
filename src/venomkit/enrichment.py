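"""Chromosome anchoring and microchromosome enrichment testing.

Snake (and bird) karyotypes split into large macrochromosomes (MAC) and
small, gene- and GC-rich microchromosomes (MIC). Genome scaffolds are
anchored to chromosomes through synteny marker genes whose cytological
location is known in a related species; a focal gene set (e.g. venom-related
genes) is then tested for enrichment on microchromosomes with a two-sided
Fisher exact test on the resulting 2x2 table.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping

logger = logging.getLogger(__name__)

CHROM_CLASSES = ("MIC", "MAC")


@dataclass(frozen=True)
class Marker:
    """A synteny marker gene with a known cytological location."""

    marker_id: str
    chromosome: str
    chrom_class: str  # "MIC" or "MAC"


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts: row 1 = focal genes (MIC, MAC), row 2 = other genes."""

    a: int  # focal on MIC
    b: int  # focal on MAC
    c: int  # other on MIC
    d: int  # other on MAC

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def margins_positive(self) -> bool:
        return (
            self.a + self.b > 0
            and self.c + self.d > 0
            and self.a + self.c > 0
            and self.b + self.d > 0
        )


@dataclass(frozen=True)
class EnrichmentResult:
    table: ContingencyTable
    focal_mic_fraction: float
    other_mic_fraction: float
    focal_mic_percent: int  # round-half-up integer percent
    other_mic_percent: int
    odds_ratio: float
    p_two_sided: float


def round_half_up_percent(numerator: float, denominator: float, ndigits: int = 0) -> float:
    """Percentage with round-half-up (the convention of printed tables)."""
    if denominator == 0:
        raise ZeroDivisionError("percentage of an empty set")
    quant = Decimal(1).scaleb(-ndigits)
    value = Decimal(100 * numerator) / Decimal(denominator)
    out = value.quantize(quant, rounding=ROUND_HALF_UP)
    return int(out) if ndigits == 0 else float(out)


def _log_binom(n: int, k: int) -> float:
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def fisher_exact_two_sided(table: ContingencyTable) -> float:
    """Exact two-sided Fisher p for a 2x2 table.

    Uses the probability-mass definition: the sum of hypergeometric
    probabilities, over all tables with the observed margins, that do not
    exceed the observed table's probability (with 1e-12 relative slack on
    the comparison). Computed from log-factorials; deterministic.
    """
    if not table.margins_positive():
        raise ValueError("Fisher test requires all four margins positive")
    r1 = table.a + table.b
    r2 = table.c + table.d
    c1 = table.a + table.c
    n = table.total

    def log_pmf(x: int) -> float:
        return _log_binom(r1, x) + _log_binom(r2, c1 - x) - _log_binom(n, c1)

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    log_obs = log_pmf(table.a)
    cutoff = log_obs + math.log1p(1e-12)
    p = 0.0
    for x in range(lo, hi + 1):
        lp = log_pmf(x)
        if lp <= cutoff:
            p += math.exp(lp)
    return min(p, 1.0)


def anchor_genes(
    gene_scaffold_map: Mapping[str, str],
    scaffold_marker_hits: Iterable[tuple[str, str]],
    marker_table: Iterable[Marker],
) -> dict[str, tuple[str, str]]:
    """Assign genes to chromosomes through their scaffolds' synteny markers.

    ``scaffold_marker_hits`` is an iterable of (marker_id, scaffold_id)
    placements. Every gene on a scaffold carrying at least one marker
    inherits that scaffold's chromosome; scaffolds whose markers disagree
    on the chromosome are left unanchored (logged), as are genes on
    markerless scaffolds. Returns gene_id -> (chromosome, chrom_class).
    """
    markers: dict[str, Marker] = {}
    chrom_class: dict[str, str] = {}
    for m in marker_table:
        if m.chrom_class not in CHROM_CLASSES:
            raise ValueError(
                f"marker {m.marker_id}: unknown chromosome class {m.chrom_class!r}"
            )
        if chrom_class.setdefault(m.chromosome, m.chrom_class) != m.chrom_class:
            raise ValueError(
                f"chromosome {m.chromosome} assigned to both classes"
            )
        markers[m.marker_id] = m

    scaffold_chroms: dict[str, set[str]] = {}
    for marker_id, scaffold_id in scaffold_marker_hits:
        if marker_id not in markers:
            raise ValueError(f"hit references unknown marker {marker_id!r}")
        scaffold_chroms.setdefault(scaffold_id, set()).add(
            markers[marker_id].chromosome
        )

    scaffold_anchor: dict[str, tuple[str, str]] = {}
    for scaffold_id, chroms in scaffold_chroms.items():
        if len(chroms) == 1:
            chrom = next(iter(chroms))
            scaffold_anchor[scaffold_id] = (chrom, chrom_class[chrom])
        else:
            logger.info(
                "scaffold %s has markers on %d chromosomes; left unanchored",
                scaffold_id,
                len(chroms),
            )

    return {
        gene: scaffold_anchor[scaffold]
        for gene, scaffold in gene_scaffold_map.items()
        if scaffold in scaffold_anchor
    }


def enrichment_report(
    assignments: Mapping[str, tuple[str, str]],
    focal_ids: Iterable[str],
) -> EnrichmentResult:
    """Build the focal-vs-other MIC/MAC table and test MIC enrichment.

    ``assignments`` maps anchored genes to (chromosome, class); ``focal_ids``
    must be a nonempty subset of the anchored genes.
    """
    focal = set(focal_ids)
    if not focal:
        raise ValueError("focal gene set is empty")
    missing = focal - set(assignments)
    if missing:
        raise ValueError(f"focal genes not anchored: {sorted(missing)[:5]}")
    a = b = c = d = 0
    for gene, (_chrom, cls) in assignments.items():
        if gene in focal:
            if cls == "MIC":
                a += 1
            else:
                b += 1
        elif cls == "MIC":
            c += 1
        else:
            d += 1
    table = ContingencyTable(a, b, c, d)
    odds = math.inf if b * c == 0 else (a * d) / (b * c)
    return EnrichmentResult(
        table=table,
        focal_mic_fraction=a / (a + b),
        other_mic_fraction=c / (c + d) if c + d else math.nan,
        focal_mic_percent=round_half_up_percent(a, a + b),
        other_mic_percent=round_half_up_percent(c, c + d) if c + d else 0,
        odds_ratio=odds,
        p_two_sided=fisher_exact_two_sided(table),
    )


def gc_content(sequence: str) -> float:
    """(G+C)/(A+C+G+T) of a sequence; N and gap characters are ignored.

    Raises ``ValueError`` when no countable base remains.
    """
    seq = sequence.upper()
    counts = {base: seq.count(base) for base in "ACGT"}
    denom = sum(counts.values())
    if denom == 0:
        raise ValueError("no unambiguous bases in sequence")
    return (counts["G"] + counts["C"]) / denom


def pooled_gc_content(sequences: Iterable[str]) -> float:
    """Length-weighted GC over a set of sequences (one pooled fraction)."""
    g = n = 0
    for seq in sequences:
        s = seq.upper()
        g += s.count("G") + s.count("C")
        n += sum(s.count(b) for b in "ACGT")
    if n == 0:
        raise ValueError("no unambiguous bases in sequence set")
    return g / n
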