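"""Nei-Gojobori (NG86) pairwise Ka/Ks estimation.

The estimator counts synonymous (S) and nonsynonymous (N) sites per codon as
fractions of the three single-nucleotide changes at each position, averages
syn/nonsyn step counts over the mutational pathways between differing codons,
converts the proportions pS = Sd/S and pN = Nd/N into distances with the
Jukes-Cantor correction d = -(3/4) ln(1 - 4p/3), and reports the Ka/Ks ratio.
Ka/Ks < 1 indicates purifying (stabilizing) selection on a pair of coding
sequences; Ka/Ks > 1 indicates diversifying (positive) selection.

Conventions (fixed here, since published NG86 variants differ):

* single-nucleotide changes that create a stop codon count as nonsynonymous
  in the site fractions, so s + n == 3 per codon exactly;
* mutational pathways that pass through a stop codon are excluded from the
  pathway average (with a fallback to all pathways when none survive);
* codon columns containing a gap, an ambiguous base, or an in-frame stop in
  either sequence are masked before counting;
* p >= 3/4 leaves the Jukes-Cantor distance undefined (flagged, never
  clamped), and Ks == 0 leaves the ratio undefined (infinite sentinel when
  Ka > 0).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from . import codons as _c

logger = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGT")
_ALPHABET = frozenset("ACGTN-")

#: flags attached to a SubstitutionEstimate
FLAG_IDENTICAL = "identical"
FLAG_KS_ZERO = "ks_zero"
FLAG_UNDEF_S = "correction_undefined_s"
FLAG_UNDEF_N = "correction_undefined_n"


class PairRejected(ValueError):
    """The aligned pair cannot be estimated (no codon column survives)."""


@dataclass(frozen=True)
class CodonAlignmentPair:
    """A frame-aligned pair of coding sequences, the unit of Ka/Ks estimation.

    Sequences are normalized to uppercase; both must have equal length,
    divisible by 3, over the alphabet {A, C, G, T, N, -} with the reading
    frame starting at position 0.
    """

    id_a: str
    id_b: str
    seq_a: str
    seq_b: str

    def __post_init__(self):
        object.__setattr__(self, "seq_a", self.seq_a.upper())
        object.__setattr__(self, "seq_b", self.seq_b.upper())
        if len(self.seq_a) != len(self.seq_b):
            raise ValueError(
                f"aligned sequences differ in length: {self.id_a} "
                f"({len(self.seq_a)}) vs {self.id_b} ({len(self.seq_b)})"
            )
        if len(self.seq_a) % 3 != 0:
            raise ValueError(f"alignment length {len(self.seq_a)} not divisible by 3")
        for seq, name in ((self.seq_a, self.id_a), (self.seq_b, self.id_b)):
            bad = set(seq) - _ALPHABET
            if bad:
                raise ValueError(f"invalid characters in {name}: {sorted(bad)}")

    def codon_columns(self):
        """Yield (codon_a, codon_b) per alignment column triplet."""
        for i in range(0, len(self.seq_a), 3):
            yield self.seq_a[i : i + 3], self.seq_b[i : i + 3]


@dataclass(frozen=True)
class SiteCounts:
    """NG86 internals: fractional site and difference counts for a pair."""

    S: float
    N: float
    Sd: float
    Nd: float
    codons_used: int


@dataclass(frozen=True)
class SubstitutionEstimate:
    """Pairwise NG86 result: proportions, Jukes-Cantor distances, and ratio.

    ``Ks``/``Ka`` are NaN when the correction is undefined (p >= 3/4); the
    ``ratio`` is NaN or +inf (a non-number sentinel either way) exactly when
    Ks is 0 or either correction is undefined.
    """

    id_a: str
    id_b: str
    sites: SiteCounts
    pS: float
    pN: float
    Ks: float
    Ka: float
    ratio: float
    flags: frozenset[str] = field(default_factory=frozenset)

    @property
    def ratio_defined(self) -> bool:
        return math.isfinite(self.ratio)


def codon_site_fractions(codon: str) -> tuple[float, float]:
    """Fractional (synonymous, nonsynonymous) site counts of one codon.

    Each of the three positions contributes the fraction of its three
    possible single-nucleotide changes that are synonymous; changes creating
    a stop codon count as nonsynonymous, so the two fractions sum to 3.

    Raises ``ValueError`` for stop codons or codons with ambiguous bases —
    the caller masks such columns.
    """
    codon = codon.upper()
    if len(codon) != 3 or not set(codon) <= _VALID_BASES:
        raise ValueError(f"ambiguous or malformed codon {codon!r}")
    if _c.is_stop(codon):
        raise ValueError(f"stop codon {codon!r} has no site decomposition")
    return _c.SITE_FRACTIONS[codon]


def count_substitutions(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Pathway-averaged (synonymous, nonsynonymous) differences between two
    sense codons.

    With one difference the change is classified directly; with two (three)
    differences the syn/nonsyn step counts are averaged over the 2 (6)
    mutational pathways, excluding pathways that pass through a stop codon.
    If every pathway crosses a stop, all pathways are used and a warning is
    logged. The two counts always sum to the Hamming distance.
    """
    codon_a, codon_b = codon_a.upper(), codon_b.upper()
    for codon in (codon_a, codon_b):
        if len(codon) != 3 or not set(codon) <= _VALID_BASES:
            raise ValueError(f"ambiguous or malformed codon {codon!r}")
        if _c.is_stop(codon):
            raise ValueError(f"stop codon {codon!r} not countable")
    if (codon_a, codon_b) in _c.ALL_PATHS_THROUGH_STOPS:
        logger.warning(
            "all mutational pathways between %s and %s pass through a stop "
            "codon; averaging over all pathways",
            codon_a,
            codon_b,
        )
    return _c.PATHWAY_COUNTS[(codon_a, codon_b)]


def jukes_cantor(p: float) -> float:
    """Jukes-Cantor distance d = -(3/4) ln(1 - 4p/3); NaN for p >= 3/4."""
    if p < 0:
        raise ValueError("proportion must be nonnegative")
    if p >= 0.75:
        return math.nan
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def _usable_column(codon_a: str, codon_b: str) -> bool:
    if not (set(codon_a) <= _VALID_BASES and set(codon_b) <= _VALID_BASES):
        return False
    return not (_c.is_stop(codon_a) or _c.is_stop(codon_b))


def pairwise_ng(pair: CodonAlignmentPair) -> SubstitutionEstimate:
    """NG86 estimate for one aligned pair.

    Codon columns with a gap, an N, or an in-frame stop in either sequence
    are masked. S and N are the means of the two sequences' per-sequence
    site totals. Raises :class:`PairRejected` when no codon column survives.
    """
    s_a = n_a = s_b = n_b = 0.0
    sd = nd = 0.0
    used = 0
    for codon_a, codon_b in pair.codon_columns():
        if not _usable_column(codon_a, codon_b):
            continue
        used += 1
        fs_a = _c.SITE_FRACTIONS[codon_a]
        fs_b = _c.SITE_FRACTIONS[codon_b]
        s_a += fs_a[0]
        n_a += fs_a[1]
        s_b += fs_b[0]
        n_b += fs_b[1]
        d = _c.PATHWAY_COUNTS[(codon_a, codon_b)]
        sd += d[0]
        nd += d[1]
    if used == 0:
        raise PairRejected(
            f"no codon column survives masking for pair ({pair.id_a}, {pair.id_b})"
        )
    S = (s_a + s_b) / 2.0
    N = (n_a + n_b) / 2.0
    pS = sd / S if S > 0 else math.nan
    pN = nd / N if N > 0 else math.nan
    Ks = jukes_cantor(pS) if not math.isnan(pS) else math.nan
    Ka = jukes_cantor(pN) if not math.isnan(pN) else math.nan

    flags: set[str] = set()
    if sd == 0.0 and nd == 0.0:
        flags.add(FLAG_IDENTICAL)
    if math.isnan(pS) or pS >= 0.75:
        flags.add(FLAG_UNDEF_S)
    if math.isnan(pN) or pN >= 0.75:
        flags.add(FLAG_UNDEF_N)

    if math.isnan(Ks) or math.isnan(Ka):
        ratio = math.nan
    elif Ks == 0.0:
        flags.add(FLAG_KS_ZERO)
        ratio = math.inf if Ka > 0.0 else math.nan
    else:
        ratio = Ka / Ks

    return SubstitutionEstimate(
        id_a=pair.id_a,
        id_b=pair.id_b,
        sites=SiteCounts(S=S, N=N, Sd=sd, Nd=nd, codons_used=used),
        pS=pS,
        pN=pN,
        Ks=Ks,
        Ka=Ka,
        ratio=ratio,
        flags=frozenset(flags),
    )


def classify_selection(estimate: SubstitutionEstimate) -> str:
    """Label a pair by its Ka/Ks ratio.

    ratio > 1 -> ``diversifying``; ratio < 1 -> ``purifying``; an undefined
    (non-finite) ratio or exactly 1 -> ``undefined``.
    """
    r = estimate.ratio
    if not math.isfinite(r) or r == 1.0:
        return "undefined"
    return "diversifying" if r > 1.0 else "purifying"
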