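"""Standard genetic code tables shared by the Ka/Ks estimator and the simulator.

Everything here is derived once, at import time, from Biopython's table 1
(the standard nuclear code). Only sense (non-stop) codons participate in
site counting and in the codon substitution process.
"""

from __future__ import annotations

from itertools import permutations

from Bio.Data import CodonTable

NUCLEOTIDES = "ACGT"

_TABLE = CodonTable.unambiguous_dna_by_id[1]

#: codon -> one-letter amino acid, sense codons only
TRANSLATION: dict[str, str] = dict(_TABLE.forward_table)

#: the three stop codons of the standard code
STOP_CODONS: frozenset[str] = frozenset(_TABLE.stop_codons)

#: the 61 sense codons, lexicographic order
SENSE_CODONS: tuple[str, ...] = tuple(sorted(TRANSLATION))

_PURINES = {"A", "G"}


def is_stop(codon: str) -> bool:
    return codon in STOP_CODONS


def is_transition(base_a: str, base_b: str) -> bool:
    """True for A<->G and C<->T changes."""
    return base_a != base_b and (base_a in _PURINES) == (base_b in _PURINES)


def single_step_neighbors(codon: str):
    """Yield (position, new_base, neighbor_codon) for all 9 single-nucleotide
    changes of a codon (stop neighbors included; callers decide their fate)."""
    for pos in range(3):
        for base in NUCLEOTIDES:
            if base == codon[pos]:
                continue
            yield pos, base, codon[:pos] + base + codon[pos + 1 :]


def is_synonymous(codon_a: str, codon_b: str) -> bool:
    """Same amino acid under the standard code; both codons must be sense."""
    return TRANSLATION[codon_a] == TRANSLATION[codon_b]


def _site_fractions(codon: str) -> tuple[float, float]:
    syn = 0.0
    for _pos, _base, neighbor in single_step_neighbors(codon):
        # changes into a stop codon count as nonsynonymous
        if not is_stop(neighbor) and is_synonymous(codon, neighbor):
            syn += 1.0
    s = syn / 3.0
    return s, 3.0 - s


#: codon -> (synonymous sites, nonsynonymous sites); s + n == 3 exactly
SITE_FRACTIONS: dict[str, tuple[float, float]] = {
    c: _site_fractions(c) for c in SENSE_CODONS
}


def _enumerate_pathways(codon_a: str, codon_b: str):
    """All orderings of the differing positions, each yielding
    (passes_through_stop, syn_steps, nonsyn_steps)."""
    diff_positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
    for order in permutations(diff_positions):
        current = codon_a
        syn = nonsyn = 0
        through_stop = False
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if is_stop(nxt) or is_stop(current):
                # steps into or out of a stop intermediate are nonsynonymous
                through_stop = True
                nonsyn += 1
            elif is_synonymous(current, nxt):
                syn += 1
            else:
                nonsyn += 1
            current = nxt
        yield through_stop, syn, nonsyn


def _pathway_counts(codon_a: str, codon_b: str) -> tuple[float, float]:
    if codon_a == codon_b:
        return 0.0, 0.0
    paths = list(_enumerate_pathways(codon_a, codon_b))
    chosen = [(s, n) for stop, s, n in paths if not stop]
    if not chosen:  # every pathway crosses a stop: average over all of them
        chosen = [(s, n) for _stop, s, n in paths]
    sd = sum(p[0] for p in chosen) / len(chosen)
    nd = sum(p[1] for p in chosen) / len(chosen)
    return sd, nd


#: (codon_a, codon_b) -> (sd, nd), pathway-averaged with stop-free pathways
#: preferred; covers all 61 x 61 sense codon pairs
PATHWAY_COUNTS: dict[tuple[str, str], tuple[float, float]] = {
    (a, b): _pathway_counts(a, b) for a in SENSE_CODONS for b in SENSE_CODONS
}

#: codon pairs for which every mutational pathway crosses a stop codon
ALL_PATHS_THROUGH_STOPS: frozenset[tuple[str, str]] = frozenset(
    pair
    for pair in PATHWAY_COUNTS
    if pair[0] != pair[1]
    and all(stop for stop, _s, _n in _enumerate_pathways(*pair))
)
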