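"""Seeded generators for every input the pipeline consumes.

The generators emulate the statistical structure of a venom-gene study:

* codon sequence pairs diverged under a continuous-time codon process with a
  nonsynonymous/synonymous rate ratio omega and a transition/transversion
  ratio kappa (no indels, no rate heterogeneity, uniform sense-codon
  ancestor);
* gene families with a 2R-WGD history — one ancestor, four ohnolog lineages,
  one co-opted for venom and expanded to ``n_sv`` SV copies, the others
  carrying ``n_nv`` NV copies — with per-group omegas;
* gene-to-scaffold-to-chromosome anchoring data with a controllable
  microchromosome enrichment odds ratio and marker density;
* k-mer depth histograms with a Poisson coverage peak and an error shoulder
  at depths 1-3;
* labeled gene trees realizing the ohnolog co-option scenarios.

Every generator is a pure function of its config: the same seed gives
byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import codons as _c
from .enrichment import Marker
from .families import GeneRecord, categorize_family
from .genome import KmerHistogram
from .ng import CodonAlignmentPair

# ---------------------------------------------------------------------------
# codon process


def _rate_tables(omega: float, kappa: float):
    """Per-codon exit rates and (target, rate) lists for the codon process.

    Single-nucleotide changes have rate kappa^[transition] x (omega if
    nonsynonymous else 1); changes into stop codons have rate 0.
    """
    targets: dict[str, list[tuple[str, float]]] = {}
    exit_rate: dict[str, float] = {}
    for codon in _c.SENSE_CODONS:
        rows: list[tuple[str, float]] = []
        total = 0.0
        for pos, base, neighbor in _c.single_step_neighbors(codon):
            if _c.is_stop(neighbor):
                continue
            rate = kappa if _c.is_transition(codon[pos], base) else 1.0
            if not _c.is_synonymous(codon, neighbor):
                rate *= omega
            rows.append((neighbor, rate))
            total += rate
        targets[codon] = rows
        exit_rate[codon] = total
    return targets, exit_rate


@dataclass(frozen=True)
class CodonPairConfig:
    """One diverged coding-sequence pair.

    ``t`` is the total divergence between the two descendants in expected
    substitutions per codon (each lineage evolves for t/2), normalized
    against the ancestor's realized exit rates.
    """

    seed: int
    n_codons: int = 500
    omega: float = 0.5
    kappa: float = 1.0
    t: float = 0.2

    def __post_init__(self):
        if self.omega <= 0 or self.kappa <= 0 or self.t < 0 or self.n_codons < 1:
            raise ValueError("omega, kappa > 0; t >= 0; n_codons >= 1 required")


@dataclass(frozen=True)
class SubstitutionEvent:
    lineage: str  # "a" or "b"
    codon_index: int
    from_codon: str
    to_codon: str
    synonymous: bool


def _random_ancestor(n_codons: int, rng: np.random.Generator) -> list[str]:
    idx = rng.integers(0, len(_c.SENSE_CODONS), size=n_codons)
    return [_c.SENSE_CODONS[i] for i in idx]


def _evolve(
    seq: Sequence[str],
    duration: float,
    scale: float,
    targets,
    exit_rate,
    rng: np.random.Generator,
    lineage: str,
    events: list[SubstitutionEvent],
) -> list[str]:
    """Gillespie simulation of each codon independently for ``duration``."""
    out = []
    for i, codon in enumerate(seq):
        current = codon
        time = 0.0
        while True:
            rate = exit_rate[current] / scale
            if rate <= 0.0:
                break
            time += rng.exponential(1.0 / rate)
            if time > duration:
                break
            rows = targets[current]
            total = exit_rate[current]
            u = rng.random() * total
            acc = 0.0
            nxt = rows[-1][0]
            for target, r in rows:
                acc += r
                if u <= acc:
                    nxt = target
                    break
            events.append(
                SubstitutionEvent(
                    lineage, i, current, nxt, _c.is_synonymous(current, nxt)
                )
            )
            current = nxt
        out.append(current)
    return out


def evolve_codon_pair(
    config: CodonPairConfig,
) -> tuple[CodonAlignmentPair, list[SubstitutionEvent]]:
    """Draw an ancestor and evolve two independent descendants.

    Returns the aligned pair plus the true per-event substitution log (the
    simulator's ground truth for validating the counting estimator).
    """
    rng = np.random.default_rng(config.seed)
    targets, exit_rate = _rate_tables(config.omega, config.kappa)
    ancestor = _random_ancestor(config.n_codons, rng)
    # normalize so one unit of t is one expected substitution per codon of
    # the ancestor
    scale = sum(exit_rate[c] for c in ancestor) / len(ancestor)
    events: list[SubstitutionEvent] = []
    half = config.t / 2.0
    seq_a = _evolve(ancestor, half, scale, targets, exit_rate, rng, "a", events)
    seq_b = _evolve(ancestor, half, scale, targets, exit_rate, rng, "b", events)
    pair = CodonAlignmentPair(
        id_a="sim_a", id_b="sim_b", seq_a="".join(seq_a), seq_b="".join(seq_b)
    )
    return pair, events


# ---------------------------------------------------------------------------
# family architectures


@dataclass(frozen=True)
class FamilyArchitecture:
    """Copy numbers and selection regimes of one simulated family."""

    name: str
    n_sv: int
    n_nv: int
    omega_sv: float = 1.5
    omega_nv: float = 0.4

    def __post_init__(self):
        if self.n_sv < 1 or self.n_nv < 0:
            raise ValueError("n_sv >= 1 and n_nv >= 0 required")

    @property
    def category(self) -> str:
        return categorize_family(self.n_sv)


@dataclass(frozen=True)
class FamilySetConfig:
    """A set of families with a shared 2R-WGD history.

    Each family evolves one ancestor into four ohnolog lineages (branch
    ``t_wgd`` each); one lineage is co-opted for venom and expanded into
    ``n_sv`` SV copies, the other three carry the ``n_nv`` NV copies
    (round-robin), each copy on its own terminal branch ``t_dup``. Branch
    lengths are expected substitutions per codon. Genes are laid on
    scaffolds in blocks of ``genes_per_scaffold`` per family, producing
    tandem-cluster structure.
    """

    seed: int
    families: tuple[FamilyArchitecture, ...]
    n_codons: int = 300
    kappa: float = 1.0
    t_wgd: float = 0.15
    t_dup: float = 0.1
    genes_per_scaffold: int = 3


def generate_family_set(
    config: FamilySetConfig,
) -> tuple[list[GeneRecord], "pd.DataFrame"]:
    """Simulate GeneRecords plus a truth table (label, category, true omega)."""
    import pandas as pd

    rng = np.random.default_rng(config.seed)
    records: list[GeneRecord] = []
    truth_rows = []
    for fam in config.families:
        ancestor = _random_ancestor(config.n_codons, rng)
        targets_nv, exit_nv = _rate_tables(fam.omega_nv, config.kappa)
        targets_sv, exit_sv = _rate_tables(fam.omega_sv, config.kappa)
        # one normalization per family ancestor, under the NV regime, so SV
        # and NV branch lengths share units
        scale = sum(exit_nv[c] for c in ancestor) / len(ancestor)
        events: list[SubstitutionEvent] = []

        ohnologs = [
            _evolve(
                ancestor,
                config.t_wgd,
                scale,
                targets_sv if k == 0 else targets_nv,
                exit_sv if k == 0 else exit_nv,
                rng,
                f"ohnolog{k}",
                events,
            )
            for k in range(4)
        ]
        copies: list[tuple[str, str, list[str], float]] = []
        for i in range(fam.n_sv):
            seq = _evolve(
                ohnologs[0], config.t_dup, scale, targets_sv, exit_sv,
                rng, "sv", events,
            )
            copies.append((f"sv{fam.name}{i + 1:02d}", "SV", seq, fam.omega_sv))
        for i in range(fam.n_nv):
            parent = ohnologs[1 + i % 3]
            seq = _evolve(
                parent, config.t_dup, scale, targets_nv, exit_nv,
                rng, "nv", events,
            )
            copies.append((f"nv{fam.name}{i + 1:02d}", "NV", seq, fam.omega_nv))
        for j, (gene_id, label, seq, omega) in enumerate(copies):
            scaffold = f"scf_{fam.name}_{j // config.genes_per_scaffold + 1}"
            records.append(
                GeneRecord(
                    gene_id=gene_id,
                    family=fam.name,
                    label=label,
                    scaffold_id=scaffold,
                    cds="".join(seq),
                    annotation=f"simulated {fam.name} {label} gene",
                )
            )
            truth_rows.append(
                {
                    "gene_id": gene_id,
                    "family": fam.name,
                    "label": label,
                    "true_omega": omega,
                    "category": fam.category,
                    "scaffold_id": scaffold,
                }
            )
    return records, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# anchoring data


@dataclass(frozen=True)
class AnchoringConfig:
    """MIC/MAC gene placements with a controllable enrichment odds ratio.

    Non-focal genes land on a microchromosome with probability
    ``mic_fraction``; focal genes with the probability whose odds are
    ``odds_ratio`` times the baseline odds. Each gene sits on its own
    scaffold block (``genes_per_scaffold`` genes per scaffold) and each
    scaffold carries a marker with probability ``marker_density``.
    """

    seed: int
    n_focal: int = 47
    n_other: int = 2602
    mic_fraction: float = 0.33
    odds_ratio: float = 1.0
    n_mic_chromosomes: int = 10
    n_mac_chromosomes: int = 8
    marker_density: float = 1.0
    genes_per_scaffold: int = 1
    #: optional explicit names for the focal genes (overrides n_focal)
    focal_gene_ids: tuple[str, ...] | None = None

    def __post_init__(self):
        if not 0 < self.mic_fraction < 1:
            raise ValueError("mic_fraction must be in (0, 1)")
        if self.odds_ratio <= 0:
            raise ValueError("odds_ratio must be positive")
        if not 0 <= self.marker_density <= 1:
            raise ValueError("marker_density must be in [0, 1]")


@dataclass(frozen=True)
class AnchoringData:
    marker_table: tuple[Marker, ...]
    gene_scaffold_map: dict[str, str]
    scaffold_marker_hits: tuple[tuple[str, str], ...]
    focal_ids: frozenset[str]
    truth: dict[str, str]  # gene -> true chromosome class


def generate_anchoring_data(config: AnchoringConfig) -> AnchoringData:
    rng = np.random.default_rng(config.seed)
    base_odds = config.mic_fraction / (1 - config.mic_fraction)
    focal_odds = base_odds * config.odds_ratio
    p_focal = focal_odds / (1 + focal_odds)

    if config.focal_gene_ids is not None:
        genes = [(g, True) for g in config.focal_gene_ids]
    else:
        genes = [(f"venom{i:05d}", True) for i in range(config.n_focal)]
    genes += [(f"gene{i:05d}", False) for i in range(config.n_other)]

    gene_scaffold: dict[str, str] = {}
    scaffold_chrom: dict[str, str] = {}
    truth: dict[str, str] = {}
    for j, (gene, focal) in enumerate(genes):
        p = p_focal if focal else config.mic_fraction
        on_mic = rng.random() < p
        if on_mic:
            chrom = f"mic{int(rng.integers(config.n_mic_chromosomes)) + 1}"
        else:
            chrom = f"mac{int(rng.integers(config.n_mac_chromosomes)) + 1}"
        scaffold = f"scaffold{j // config.genes_per_scaffold:05d}"
        gene_scaffold[gene] = scaffold
        # first gene on a scaffold fixes its chromosome
        scaffold_chrom.setdefault(scaffold, chrom)
        truth[gene] = "MIC" if scaffold_chrom[scaffold].startswith("mic") else "MAC"

    markers: list[Marker] = []
    hits: list[tuple[str, str]] = []
    for k, (scaffold, chrom) in enumerate(sorted(scaffold_chrom.items())):
        if rng.random() < config.marker_density:
            marker_id = f"marker{k:05d}"
            cls = "MIC" if chrom.startswith("mic") else "MAC"
            markers.append(Marker(marker_id, chrom, cls))
            hits.append((marker_id, scaffold))

    return AnchoringData(
        marker_table=tuple(markers),
        gene_scaffold_map=gene_scaffold,
        scaffold_marker_hits=tuple(hits),
        focal_ids=frozenset(g for g, focal in genes if focal),
        truth=truth,
    )


# ---------------------------------------------------------------------------
# k-mer histograms


@dataclass(frozen=True)
class KmerConfig:
    """A coverage histogram: Poisson(mean_depth) peak over ``genome_size``
    distinct k-mers plus an error shoulder at depths 1-3 holding
    ``error_fraction`` x genome_size additional distinct k-mers."""

    seed: int
    genome_size: int = 1_000_000
    mean_depth: float = 43.0
    error_fraction: float = 0.1
    k: int = 27

    def __post_init__(self):
        if self.genome_size < 0 or self.mean_depth <= 0 or self.error_fraction < 0:
            raise ValueError("invalid k-mer histogram configuration")


def generate_kmer_histogram(config: KmerConfig) -> KmerHistogram:
    rng = np.random.default_rng(config.seed)
    entries: dict[int, int] = {}
    if config.genome_size:
        depths = rng.poisson(config.mean_depth, size=config.genome_size)
        depths = depths[depths > 0]
        counts = np.bincount(depths)
        entries = {int(d): int(c) for d, c in enumerate(counts) if c > 0}
    n_err = int(round(config.error_fraction * config.genome_size))
    if n_err:
        err_depths = rng.integers(1, 4, size=n_err)
        for d, c in zip(*np.unique(err_depths, return_counts=True)):
            entries[int(d)] = entries.get(int(d), 0) + int(c)
    return KmerHistogram(k=config.k, entries=entries)


# ---------------------------------------------------------------------------
# scenario trees


@dataclass(frozen=True)
class ScenarioTreeConfig:
    """A labeled family tree realizing one co-option scenario.

    ``single_copy_cooption`` joins a random SV-only subtree to a random
    NV-only subtree; ``independent_diversification`` interleaves two SV
    clades between NV clades.
    """

    seed: int
    scenario: str = "single_copy_cooption"
    n_sv: int = 4
    n_nv: int = 4
    species: tuple[str, ...] = ("habu", "pitviper", "cobra")


def _random_subtree(tips: list[str], rng: np.random.Generator) -> str:
    nodes = list(tips)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = f"({nodes[i]},{nodes[j]})"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    return nodes[0]


def generate_scenario_tree(config: ScenarioTreeConfig) -> str:
    """Newick string with inline ``id|species|LABEL`` tips."""
    rng = np.random.default_rng(config.seed)

    def tips(label: str, n: int, prefix: str) -> list[str]:
        return [
            f"{prefix}{i + 1}|{config.species[int(rng.integers(len(config.species)))]}|{label}"
            for i in range(n)
        ]

    sv = tips("SV", config.n_sv, "sv")
    nv = tips("NV", config.n_nv, "nv")
    if config.scenario == "single_copy_cooption":
        if config.n_sv < 1 or config.n_nv < 1:
            raise ValueError("scenario needs SV and NV tips")
        left = _random_subtree(sv, rng) if len(sv) > 1 else sv[0]
        right = _random_subtree(nv, rng) if len(nv) > 1 else nv[0]
        return f"({left},{right});"
    if config.scenario == "independent_diversification":
        if config.n_sv < 2 or config.n_nv < 2:
            raise ValueError("scenario needs >=2 SV and >=2 NV tips")
        half_sv = len(sv) // 2
        half_nv = len(nv) // 2
        parts = [
            _random_subtree(sv[:half_sv], rng) if half_sv > 1 else sv[0],
            _random_subtree(nv[:half_nv], rng) if half_nv > 1 else nv[0],
            _random_subtree(sv[half_sv:], rng) if len(sv) - half_sv > 1 else sv[-1],
            _random_subtree(nv[half_nv:], rng) if len(nv) - half_nv > 1 else nv[-1],
        ]
        return f"(({parts[0]},{parts[1]}),({parts[2]},{parts[3]}));"
    raise ValueError(f"unknown scenario {config.scenario!r}")
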