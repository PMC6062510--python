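"""Catalog curation, duplication categories, group Ka/Ks, clusters, tables."""

import math

import numpy as np
import pytest

from venomkit import (
    GeneRecord,
    apply_curation,
    build_family_table,
    categorize_family,
    detect_acceleration,
    detect_gene_clusters,
    family_table_from_counts,
    group_kaks,
    keyword_screen,
    ks_strata,
    summarize_family,
)
from venomkit.families import GroupStats
from venomkit.ng import SiteCounts, SubstitutionEstimate


def _estimate(ks, id_a="a", id_b="b"):
    return SubstitutionEstimate(
        id_a=id_a, id_b=id_b, sites=SiteCounts(10, 20, 1, 2, 10),
        pS=0.1, pN=0.1, Ks=ks, Ka=0.1, ratio=0.1 / ks if ks else math.nan,
    )


class TestKeywordScreen:
    def test_substring_match_records_first_keyword(self):
        hits = keyword_screen(
            {"g1": "snake venom metalloproteinase precursor"},
            ["metalloproteinase"],
        )
        assert hits == {"g1": "metalloproteinase"}

    def test_false_positive_is_still_a_hit(self):
        # curation, not the screen, removes these
        hits = keyword_screen({"g2": "Anthrax Toxin Receptor"}, ["toxin"])
        assert hits == {"g2": "toxin"}

    def test_no_match_and_empty_inputs(self):
        kws = ["toxin", "lectin", "venom"]
        assert keyword_screen({"g3": "ribosomal protein"}, kws) == {}
        assert keyword_screen({}, kws) == {}
        with pytest.raises(ValueError):
            keyword_screen({"g": "x"}, [])


class TestCuration:
    def test_accounting_identity(self):
        cands = {f"g{i}" for i in range(340)}
        excl = {f"g{i}" for i in range(124)}
        inhib = {f"g{i}" for i in range(124, 148)}
        kept, acc = apply_curation(cands, excl, inhib)
        assert acc.n_venom_related == len(kept) == 192
        assert acc.n_candidates == 340
        assert acc.n_candidates == acc.n_venom_related + acc.n_excluded_unrelated + acc.n_inhibitors

    def test_no_lists_keeps_everything(self):
        kept, acc = apply_curation({f"g{i}" for i in range(10)}, [], [])
        assert len(kept) == 10 and acc.n_venom_related == 10

    def test_unknown_or_overlapping_ids_error(self):
        with pytest.raises(ValueError, match="gX"):
            apply_curation({"g1", "g2"}, ["gX"], [])
        with pytest.raises(ValueError, match="g1"):
            apply_curation({"g1", "g2"}, ["g1"], ["g1"])


class TestCategories:
    @pytest.mark.parametrize(
        "sv,cat", [(1, "I"), (2, "II"), (3, "II"), (4, "II"), (5, "III"), (11, "III")]
    )
    def test_boundaries(self, sv, cat):
        assert categorize_family(sv) == cat

    def test_zero_sv_is_outside_the_schema(self):
        with pytest.raises(ValueError):
            categorize_family(0)

    def test_total_and_monotone(self):
        order = {"I": 0, "II": 1, "III": 2}
        cats = [order[categorize_family(k)] for k in range(1, 40)]
        assert cats == sorted(cats)


class TestGroupKaks:
    def test_mean_and_se_with_n_minus_one_sd(self):
        ratios = (1.0, 2.0, 3.0)
        stats = GroupStats(3, 0, float(np.mean(ratios)),
                           float(np.std(ratios, ddof=1) / np.sqrt(3)), ratios)
        assert stats.mean == pytest.approx(2.0)
        assert stats.se == pytest.approx(0.5774, abs=1e-4)

    def test_group_kaks_computes_that_statistic(self):
        # stub estimator returning fixed ratios per pair
        seq = "ATG" * 10
        records = [GeneRecord(f"g{i}", "MP", "SV", cds=seq) for i in range(3)]
        ratios = iter([1.0, 2.0, 3.0])

        def estimator(pair):
            r = next(ratios)
            return SubstitutionEstimate(
                id_a=pair.id_a, id_b=pair.id_b,
                sites=SiteCounts(10, 20, 1, 2, 10),
                pS=0.1, pN=0.1, Ks=0.1, Ka=0.1 * r, ratio=r,
            )

        stats = group_kaks(records, estimator)
        assert stats.n_pairs_used == 3
        assert stats.mean == pytest.approx(2.0)
        assert stats.se == pytest.approx(0.5774, abs=1e-4)

    def test_single_gene_group_undefined(self):
        stats = group_kaks([GeneRecord("g1", "MP", "SV", cds="ATG" * 5)])
        assert not stats.defined

    def test_two_identical_genes_excluded(self):
        seq = "ATGAAACCCGGGTTT"
        recs = [GeneRecord("g1", "MP", "SV", cds=seq),
                GeneRecord("g2", "MP", "SV", cds=seq)]
        stats = group_kaks(recs)
        assert not stats.defined
        assert stats.n_pairs_excluded == 1


class TestAcceleration:
    def test_separated_groups_flagged(self, rng):
        sv = GroupStats(20, 0, 1.25, 0.05,
                        tuple(rng.gauss(1.25, 0.2) for _ in range(20)))
        nv = GroupStats(20, 0, 0.52, 0.02,
                        tuple(rng.gauss(0.52, 0.1) for _ in range(20)))
        accelerated, exceeds = detect_acceleration(sv, nv)
        assert accelerated is True

    def test_welch_agrees_with_permutation_oracle(self, rng):
        from scipy import stats as ss

        sv = tuple(rng.gauss(1.25, 0.3) for _ in range(12))
        nv = tuple(rng.gauss(0.52, 0.15) for _ in range(12))
        accelerated, _ = detect_acceleration(
            GroupStats(12, 0, float(np.mean(sv)), 0.1, sv),
            GroupStats(12, 0, float(np.mean(nv)), 0.1, nv),
        )
        perm = ss.permutation_test(
            (np.array(sv), np.array(nv)),
            lambda x, y, axis=-1: np.mean(x, axis=axis) - np.mean(y, axis=axis),
            alternative="greater", n_resamples=20000,
            rng=np.random.default_rng(1),
        )
        assert accelerated == (perm.pvalue < 0.05)

    def test_identical_groups_not_flagged(self):
        ratios = (0.5, 0.5, 0.5, 0.5, 0.5, 0.5)
        g = GroupStats(6, 0, 0.5, 0.0, ratios)
        accelerated, exceeds = detect_acceleration(g, g)
        assert accelerated is False
        assert exceeds is False

    def test_mean_above_one_reported_separately(self):
        sv = GroupStats(5, 0, 1.047, 0.438, (0.5, 0.7, 1.0, 1.2, 1.8))
        nv = GroupStats(5, 0, 0.9, 0.1, (0.8, 0.85, 0.9, 0.95, 1.0))
        accelerated, exceeds = detect_acceleration(sv, nv)
        assert exceeds is True
        assert accelerated is False  # overlapping distributions

    def test_undefined_groups_yield_none(self):
        undef = GroupStats(0, 0, math.nan, math.nan, (), reason="too few")
        ok = GroupStats(3, 0, 1.0, 0.1, (0.9, 1.0, 1.1))
        assert detect_acceleration(undef, ok) == (None, None)


class TestKsStrata:
    @pytest.mark.parametrize(
        "ks,label",
        [(0.15, "low"), (0.75, "high"), (0.2, "intermediate"),
         (0.5, "high"), (0.0, "low"), (0.35, "intermediate")],
    )
    def test_half_open_bins(self, ks, label):
        strata = ks_strata([_estimate(ks)])
        assert strata[("a", "b")] == label

    def test_undefined_ks_unbinned(self):
        strata = ks_strata([_estimate(math.nan)])
        assert strata[("a", "b")] is None

    def test_breakpoints_must_increase(self):
        with pytest.raises(ValueError):
            ks_strata([], breakpoints=(0.5, 0.2))


class TestClusters:
    def test_scaffold_cluster_of_five(self):
        recs = [
            GeneRecord(g, "MP", "SV" if g.startswith("sv") else "NV",
                       scaffold_id="habu1_scaffold_2862")
            for g in ("svMP01", "svMP02", "svMP03", "svMP11", "nvMP57")
        ]
        clusters = detect_gene_clusters(recs)
        assert len(clusters) == 1
        assert len(clusters[0].gene_ids) == 5
        assert clusters[0].family == "MP"

    def test_singletons_yield_nothing(self):
        recs = [GeneRecord(f"g{i}", "MP", "SV", scaffold_id=f"s{i}") for i in range(5)]
        assert detect_gene_clusters(recs) == []

    def test_matches_brute_force_group_by(self, rng):
        recs = [
            GeneRecord(
                f"g{i}",
                rng.choice(["MP", "SP", "CTLP"]),
                rng.choice(["SV", "NV"]),
                scaffold_id=f"s{rng.randrange(12)}",
            )
            for i in range(50)
        ]
        expected = {}
        for r in recs:
            expected.setdefault((r.scaffold_id, r.family), set()).add(r.gene_id)
        expected = {k: v for k, v in expected.items() if len(v) >= 2}
        got = {(c.scaffold_id, c.family): set(c.gene_ids)
               for c in detect_gene_clusters(recs)}
        assert got == expected


class TestFamilyTable:
    COUNTS = {
        "MP": (11, 57), "SP": (11, 34), "CTLP": (10, 40), "PLA2": (9, 31),
        "3FTX": (4, 2), "APase": (2, 10), "CRISP": (2, 2),
        "Vespryn": (1, 11), "5Nase": (1, 10), "DDPase": (1, 7), "Hyal": (1, 5),
        "NGF": (1, 3), "VEGF": (1, 2), "LAAO": (1, 2), "PDE": (1, 2),
        "PLB": (1, 4), "BNP": (1, 1), "GPCase": (1, 1),
    }

    def test_catalog_totals_and_category_membership(self):
        table = family_table_from_counts(self.COUNTS)
        total = table[table.family == "Total"].iloc[0]
        assert total.sv_count == 60
        assert total.nv_count == 224
        body = table[table.family != "Total"]
        assert (body.category == "I").sum() == 11
        assert (body.category == "II").sum() == 3
        assert (body.category == "III").sum() == 4

    def test_ordering_is_category_then_sv_count(self):
        table = family_table_from_counts(self.COUNTS)
        assert list(table.family[:4]) == ["MP", "SP", "CTLP", "PLA2"]
        assert list(table.category[:4]) == ["III"] * 4

    def test_totals_invariant_to_input_order(self):
        items = list(self.COUNTS.items())
        a = family_table_from_counts(dict(items))
        b = family_table_from_counts(dict(reversed(items)))
        assert a.equals(b)

    def test_empty_catalog(self):
        table = family_table_from_counts({})
        total = table[table.family == "Total"].iloc[0]
        assert total.sv_count == 0 and total.nv_count == 0

    def test_summarize_family_rolls_up(self):
        from venomkit.simulate import FamilyArchitecture, FamilySetConfig, generate_family_set

        fam = FamilyArchitecture("CRISP", n_sv=2, n_nv=4, omega_sv=1.0, omega_nv=0.4)
        records, truth = generate_family_set(FamilySetConfig(seed=3, families=(fam,)))
        s = summarize_family("CRISP", records)
        assert s.sv_count == 2 and s.nv_count == 4
        assert s.category == "II"
        table = build_family_table([s])
        assert table.iloc[0].family == "CRISP"
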