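"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's precomputed tables: codons are
translated with Biopython directly and pathways enumerated from first
principles, so agreement with the library is a two-route check.
"""

from itertools import permutations

from Bio.Seq import Seq

STOPS = {"TAA", "TAG", "TGA"}


def translate(codon: str) -> str:
    return str(Seq(codon).translate())


def oracle_site_fractions(codon: str) -> tuple[float, float]:
    aa = translate(codon)
    syn = 0
    for pos in range(3):
        for base in "ACGT":
            if base == codon[pos]:
                continue
            neighbor = codon[:pos] + base + codon[pos + 1 :]
            if neighbor not in STOPS and translate(neighbor) == aa:
                syn += 1
    return syn / 3.0, 3.0 - syn / 3.0


def oracle_count_substitutions(codon_a: str, codon_b: str) -> tuple[float, float]:
    diffs = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diffs:
        return 0.0, 0.0
    stop_free: list[tuple[int, int]] = []
    everything: list[tuple[int, int]] = []
    for order in permutations(diffs):
        codon = codon_a
        steps: list[tuple[str, str]] = []
        for pos in order:
            nxt = codon[:pos] + codon_b[pos] + codon[pos + 1 :]
            steps.append((codon, nxt))
            codon = nxt
        intermediates_ok = all(
            c not in STOPS for _x, c in steps[:-1]
        )
        syn = sum(
            1
            for x, y in steps
            if x not in STOPS and y not in STOPS and translate(x) == translate(y)
        )
        nonsyn = len(steps) - syn
        everything.append((syn, nonsyn))
        if intermediates_ok:
            stop_free.append((syn, nonsyn))
    paths = stop_free or everything
    return (
        sum(p[0] for p in paths) / len(paths),
        sum(p[1] for p in paths) / len(paths),
    )


def oracle_pairwise(seq_a: str, seq_b: str):
    """Codon-by-codon NG86 on two equal-length stop-free sequences.

    Returns (S, N, Sd, Nd, codons_used).
    """
    assert len(seq_a) == len(seq_b) and len(seq_a) % 3 == 0
    s_a = n_a = s_b = n_b = sd = nd = 0.0
    used = 0
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i : i + 3], seq_b[i : i + 3]
        if not (set(ca) <= set("ACGT") and set(cb) <= set("ACGT")):
            continue
        if ca in STOPS or cb in STOPS:
            continue
        used += 1
        fa = oracle_site_fractions(ca)
        fb = oracle_site_fractions(cb)
        s_a += fa[0]
        n_a += fa[1]
        s_b += fb[0]
        n_b += fb[1]
        d = oracle_count_substitutions(ca, cb)
        sd += d[0]
        nd += d[1]
    return (s_a + s_b) / 2, (n_a + n_b) / 2, sd, nd, used
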