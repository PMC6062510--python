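"""Determinism and statistical fidelity of the synthetic-data generators."""

import math

import numpy as np
import pytest

from venomkit import kmer_genome_size, pairwise_ng
from venomkit.codons import SITE_FRACTIONS
from venomkit.ng import FLAG_IDENTICAL
from venomkit.simulate import (
    AnchoringConfig,
    CodonPairConfig,
    FamilyArchitecture,
    FamilySetConfig,
    KmerConfig,
    ScenarioTreeConfig,
    evolve_codon_pair,
    generate_anchoring_data,
    generate_family_set,
    generate_kmer_histogram,
    generate_scenario_tree,
)


class TestCodonPairs:
    def test_same_seed_is_byte_identical(self):
        cfg = CodonPairConfig(seed=42, n_codons=50, omega=0.7)
        p1, e1 = evolve_codon_pair(cfg)
        p2, e2 = evolve_codon_pair(cfg)
        assert p1.seq_a == p2.seq_a and p1.seq_b == p2.seq_b
        assert e1 == e2

    def test_zero_branch_length_keeps_descendants_identical(self):
        pair, events = evolve_codon_pair(CodonPairConfig(seed=1, n_codons=30, t=0.0))
        assert pair.seq_a == pair.seq_b
        assert events == []
        est = pairwise_ng(pair)
        assert FLAG_IDENTICAL in est.flags

    def test_event_log_is_consistent_with_sequences(self):
        cfg = CodonPairConfig(seed=5, n_codons=80, omega=1.0, t=0.4)
        pair, events = evolve_codon_pair(cfg)
        # replaying each lineage's events on the shared ancestor must land on
        # the reported descendant; with t=0 on lineage b the ancestor is seq_b
        by_lineage = {"a": {}, "b": {}}
        first_state = {}
        for ev in events:
            first_state.setdefault((ev.lineage, ev.codon_index), ev.from_codon)
            by_lineage[ev.lineage][ev.codon_index] = ev.to_codon
        for lineage, seq in (("a", pair.seq_a), ("b", pair.seq_b)):
            for idx, final in by_lineage[lineage].items():
                assert seq[3 * idx : 3 * idx + 3] == final

    def test_neutral_event_ratio_matches_site_composition(self):
        """At omega=1, kappa=1 the nonsyn/syn event ratio over >=10,000 events
        approaches the N/S site ratio of the codons the events start from
        (rates are proportional to site counts when every change is equally
        likely), after removing the stop-producing changes, which the site
        fractions count as nonsynonymous but which the process forbids."""
        from venomkit.codons import is_stop, single_step_neighbors

        syn = nonsyn = 0
        total_s = total_n = 0.0
        for seed in range(60):
            cfg = CodonPairConfig(seed=seed, n_codons=2500, omega=1.0,
                                  kappa=1.0, t=0.08)
            _pair, events = evolve_codon_pair(cfg)
            for ev in events:
                if ev.synonymous:
                    syn += 1
                else:
                    nonsyn += 1
                s, n = SITE_FRACTIONS[ev.from_codon]
                stops = sum(
                    1 for _p, _b, nb in single_step_neighbors(ev.from_codon)
                    if is_stop(nb)
                )
                total_s += s
                total_n += n - stops / 3.0
        assert syn + nonsyn >= 10_000
        assert nonsyn / syn == pytest.approx(total_n / total_s, rel=0.05)

    def test_rates_respond_to_omega(self):
        # stronger purifying selection -> fewer nonsynonymous events
        def nonsyn_fraction(omega):
            _, events = evolve_codon_pair(
                CodonPairConfig(seed=99, n_codons=3000, omega=omega, t=0.2)
            )
            return sum(not e.synonymous for e in events) / len(events)

        assert nonsyn_fraction(0.2) < nonsyn_fraction(1.0) < nonsyn_fraction(3.0)


class TestFamilySet:
    def test_truth_table_matches_architecture(self):
        fams = (
            FamilyArchitecture("Hyal", n_sv=1, n_nv=4, omega_sv=0.5, omega_nv=0.5),
            FamilyArchitecture("MP", n_sv=10, n_nv=40),
        )
        records, truth = generate_family_set(FamilySetConfig(seed=2, families=fams))
        assert len(records) == 55
        hyal = truth[truth.family == "Hyal"]
        assert (hyal.category == "I").all()
        assert (hyal.label == "SV").sum() == 1
        mp = truth[truth.family == "MP"]
        assert (mp.category == "III").all()
        assert (mp.label == "SV").sum() == 10
        assert set(truth[truth.label == "SV"].true_omega) == {0.5, 1.5}

    def test_minimal_post_wgd_state(self):
        fam = FamilyArchitecture("NGF", n_sv=1, n_nv=3, omega_sv=0.5,
                                 omega_nv=0.5)
        records, truth = generate_family_set(FamilySetConfig(seed=4, families=(fam,)))
        assert len(records) == 4  # one SV + three NV ohnolog descendants

    def test_determinism(self):
        cfg = FamilySetConfig(
            seed=9, families=(FamilyArchitecture("SP", n_sv=3, n_nv=6),)
        )
        r1, t1 = generate_family_set(cfg)
        r2, t2 = generate_family_set(cfg)
        assert [x.cds for x in r1] == [x.cds for x in r2]
        assert t1.equals(t2)

    def test_sv_group_faster_than_nv_under_selection_contrast(self):
        from venomkit.families import summarize_family

        fam = FamilyArchitecture("MP", n_sv=6, n_nv=12, omega_sv=1.5,
                                 omega_nv=0.4)
        records, _ = generate_family_set(FamilySetConfig(seed=21, families=(fam,)))
        s = summarize_family("MP", records)
        assert s.sv_stats.mean > s.nv_stats.mean


class TestAnchoringGenerator:
    def test_zero_marker_density_anchors_nothing(self):
        from venomkit import anchor_genes, enrichment_report

        data = generate_anchoring_data(
            AnchoringConfig(seed=3, n_focal=5, n_other=50, marker_density=0.0)
        )
        assignments = anchor_genes(
            data.gene_scaffold_map, data.scaffold_marker_hits, data.marker_table
        )
        assert assignments == {}
        with pytest.raises(ValueError):
            enrichment_report(assignments, data.focal_ids)

    def test_odds_ratio_shifts_focal_mic_rate(self):
        def focal_mic_rate(odds):
            data = generate_anchoring_data(
                AnchoringConfig(seed=8, n_focal=2000, n_other=100,
                                odds_ratio=odds, mic_fraction=0.33)
            )
            mics = sum(1 for g in data.focal_ids if data.truth[g] == "MIC")
            return mics / len(data.focal_ids)

        assert focal_mic_rate(1.0) == pytest.approx(0.33, abs=0.04)
        assert focal_mic_rate(10.0) > 0.7

    def test_focal_gene_ids_override(self):
        data = generate_anchoring_data(
            AnchoringConfig(seed=1, n_other=20,
                            focal_gene_ids=("svMP01", "svMP02"))
        )
        assert data.focal_ids == {"svMP01", "svMP02"}


class TestKmerGenerator:
    def test_error_free_recovery(self):
        """At an integer mean depth the Poisson pmf ties exactly at
        lambda-1 and lambda (p(k) = p(k-1) * lambda/k), so the empirical mode
        lands on 42 or 43 and the size estimate carries at most a ~1/43
        relative bias; at a non-integer mean the mode is unique and recovery
        is tighter."""
        cfg = KmerConfig(seed=6, genome_size=500_000, mean_depth=43,
                         error_fraction=0.0)
        peak, size = kmer_genome_size(generate_kmer_histogram(cfg))
        assert peak in (42, 43)
        assert abs(size - cfg.genome_size) / cfg.genome_size <= 43 / 42 - 1 + 0.005
        cfg = KmerConfig(seed=6, genome_size=500_000, mean_depth=43.5,
                         error_fraction=0.0)
        peak, size = kmer_genome_size(generate_kmer_histogram(cfg))
        assert peak == 43
        assert abs(size - cfg.genome_size) / cfg.genome_size < 0.02

    def test_sub_cutoff_error_mass_does_not_move_the_estimate(self):
        clean = KmerConfig(seed=6, genome_size=500_000, error_fraction=0.0)
        noisy = KmerConfig(seed=6, genome_size=500_000, error_fraction=0.3)
        _, s_clean = kmer_genome_size(generate_kmer_histogram(clean))
        _, s_noisy = kmer_genome_size(generate_kmer_histogram(noisy))
        assert s_noisy == pytest.approx(s_clean, rel=1e-12)

    def test_empty_genome_errors_downstream(self):
        hist = generate_kmer_histogram(KmerConfig(seed=1, genome_size=0,
                                                  error_fraction=0.0))
        assert hist.entries == {}
        with pytest.raises(ValueError):
            kmer_genome_size(hist)


class TestScenarioTrees:
    def test_determinism_and_labels(self):
        cfg = ScenarioTreeConfig(seed=12)
        assert generate_scenario_tree(cfg) == generate_scenario_tree(cfg)
        nwk = generate_scenario_tree(cfg)
        assert nwk.count("|SV") == 4 and nwk.count("|NV") == 4
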