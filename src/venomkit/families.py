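"""Venom gene-family cataloguing, duplication categories, and acceleration.

A venom-gland catalog distinguishes SV genes (expressed venom components)
from NV genes (their non-venom paralogs). Families are placed in duplication
categories by their SV copy number (I: a single SV copy; II: 2-4 copies;
III: highly expanded families such as metalloproteinases, serine proteases,
C-type lectin-like proteins and PLA2). Accelerated evolution of a family's
SV genes is detected by comparing within-group pairwise Ka/Ks distributions
between SV and NV genes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ng import CodonAlignmentPair, PairRejected, SubstitutionEstimate, pairwise_ng

logger = logging.getLogger(__name__)

#: the 18 family short names of the venom-related catalog
FAMILY_NAMES = (
    "MP", "SP", "CTLP", "PLA2", "3FTX", "APase", "CRISP", "Vespryn",
    "5Nase", "DDPase", "Hyal", "NGF", "VEGF", "LAAO", "PDE", "PLB",
    "BNP", "GPCase",
)

LABELS = ("SV", "NV", "inhibitor", "excluded", "candidate")


@dataclass(frozen=True)
class GeneRecord:
    """One gene of the catalog: identity, family, SV/NV label, location, CDS."""

    gene_id: str
    family: str = "other"
    label: str = "candidate"
    scaffold_id: str = ""
    cds: str = ""
    annotation: str = ""

    def __post_init__(self):
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r} for {self.gene_id}")


@dataclass(frozen=True)
class CurationAccounting:
    """Bookkeeping of the keyword-screen curation."""

    n_candidates: int
    n_excluded_unrelated: int
    n_inhibitors: int
    n_venom_related: int

    def __post_init__(self):
        if self.n_venom_related != (
            self.n_candidates - self.n_excluded_unrelated - self.n_inhibitors
        ):
            raise ValueError("curation accounting identity violated")


@dataclass(frozen=True)
class GroupStats:
    """Mean +/- SE of retained pairwise Ka/Ks ratios within one gene group."""

    n_pairs_used: int
    n_pairs_excluded: int
    mean: float
    se: float
    ratios: tuple[float, ...] = ()
    reason: str | None = None

    @property
    def defined(self) -> bool:
        return self.reason is None


@dataclass(frozen=True)
class GeneFamilySummary:
    family: str
    sv_count: int
    nv_count: int
    category: str
    sv_stats: GroupStats | None = None
    nv_stats: GroupStats | None = None
    accelerated: bool | None = None
    mean_exceeds_one: bool | None = None


def keyword_screen(
    annotations: Mapping[str, str], keywords: Sequence[str]
) -> dict[str, str]:
    """Case-insensitive substring screen of annotation text.

    Returns gene_id -> first matching keyword (in keyword-list order). An
    empty annotation map yields an empty result; an empty keyword list is an
    error.
    """
    if not keywords:
        raise ValueError("keyword list is empty")
    lowered = [(kw, kw.lower()) for kw in keywords]
    hits: dict[str, str] = {}
    for gene_id, text in annotations.items():
        t = text.lower()
        for kw, kw_low in lowered:
            if kw_low in t:
                hits[gene_id] = kw
                break
    return hits


def apply_curation(
    candidates: Iterable[str],
    exclusion_ids: Iterable[str],
    inhibitor_ids: Iterable[str],
) -> tuple[set[str], CurationAccounting]:
    """Remove curated-out genes and venom inhibitors from the candidate set.

    The two lists must be disjoint subsets of the candidates; violations
    raise ``ValueError`` naming the offending id.
    """
    cand = set(candidates)
    excl = set(exclusion_ids)
    inhib = set(inhibitor_ids)
    both = excl & inhib
    if both:
        raise ValueError(f"id in both curation lists: {sorted(both)[0]!r}")
    for name, ids in (("exclusion", excl), ("inhibitor", inhib)):
        stray = ids - cand
        if stray:
            raise ValueError(
                f"{name} id not among candidates: {sorted(stray)[0]!r}"
            )
    retained = cand - excl - inhib
    accounting = CurationAccounting(
        n_candidates=len(cand),
        n_excluded_unrelated=len(excl),
        n_inhibitors=len(inhib),
        n_venom_related=len(retained),
    )
    return retained, accounting


def label_records(
    records: Iterable[GeneRecord],
    exclusion_ids: Iterable[str],
    inhibitor_ids: Iterable[str],
) -> list[GeneRecord]:
    """Relabel candidate records after curation (excluded / inhibitor)."""
    excl = set(exclusion_ids)
    inhib = set(inhibitor_ids)
    out = []
    for rec in records:
        if rec.gene_id in excl:
            out.append(replace(rec, label="excluded"))
        elif rec.gene_id in inhib:
            out.append(replace(rec, label="inhibitor"))
        else:
            out.append(rec)
    return out


def categorize_family(sv_count: int) -> str:
    """Duplication category from the SV copy number.

    1 -> "I"; 2-4 -> "II"; >=5 -> "III". A family without an SV copy has no
    category and raises ``ValueError``.
    """
    if sv_count < 1:
        raise ValueError("a venom gene family needs at least one SV copy")
    if sv_count == 1:
        return "I"
    if sv_count <= 4:
        return "II"
    return "III"


def group_kaks(
    records: Sequence[GeneRecord],
    estimator: Callable[[CodonAlignmentPair], SubstitutionEstimate] = pairwise_ng,
) -> GroupStats:
    """Mean +/- SE of Ka/Ks over all unordered within-group pairs.

    Pairs whose ratio is undefined (identical sequences, Ks == 0, or a
    Jukes-Cantor correction out of domain) are excluded and counted. SE uses
    the n-1 sample standard deviation over sqrt(n). Fewer than two usable
    genes, or fewer than two retained ratios, yield an undefined result with
    a reason.
    """
    usable = [r for r in records if r.cds]
    if len(usable) < 2:
        return GroupStats(0, 0, math.nan, math.nan, (), reason="fewer than 2 usable genes")
    ratios: list[float] = []
    excluded = 0
    for rec_a, rec_b in combinations(usable, 2):
        try:
            pair = CodonAlignmentPair(rec_a.gene_id, rec_b.gene_id, rec_a.cds, rec_b.cds)
            est = estimator(pair)
        except (PairRejected, ValueError) as exc:
            logger.info("pair (%s, %s) rejected: %s", rec_a.gene_id, rec_b.gene_id, exc)
            excluded += 1
            continue
        if math.isfinite(est.ratio):
            ratios.append(est.ratio)
        else:
            excluded += 1
    if excluded:
        logger.info("%d pair(s) excluded from group statistics", excluded)
    if len(ratios) < 2:
        return GroupStats(
            len(ratios), excluded, math.nan, math.nan, tuple(ratios),
            reason="fewer than 2 retained ratios",
        )
    arr = np.asarray(ratios)
    mean = float(arr.mean())
    se = float(arr.std(ddof=1) / math.sqrt(len(arr)))
    return GroupStats(len(ratios), excluded, mean, se, tuple(ratios))


def detect_acceleration(
    sv_stats: GroupStats, nv_stats: GroupStats, alpha: float = 0.05
) -> tuple[bool | None, bool | None]:
    """Flag accelerated evolution of SV genes relative to NV paralogs.

    The primary flag is a one-sided two-sample location test (SV > NV) on
    the retained Ka/Ks ratios at level ``alpha``: Welch's t when both groups
    have at least 5 ratios, otherwise an exact/permutation test on the mean
    difference. Whether the SV mean exceeds 1 is reported separately — an SV
    group can be significantly faster than its NV paralogs with a mean still
    below 1. Undefined group statistics yield (None, None).
    """
    if not (sv_stats.defined and nv_stats.defined):
        return None, None
    sv = np.asarray(sv_stats.ratios)
    nv = np.asarray(nv_stats.ratios)
    if np.ptp(np.concatenate([sv, nv])) == 0.0:
        return False, bool(sv_stats.mean > 1.0)
    if min(len(sv), len(nv)) >= 5:
        result = stats.ttest_ind(sv, nv, equal_var=False, alternative="greater")
        p = float(result.pvalue)
    else:
        perm = stats.permutation_test(
            (sv, nv),
            lambda x, y, axis=-1: np.mean(x, axis=axis) - np.mean(y, axis=axis),
            alternative="greater",
            n_resamples=9999,
            rng=np.random.default_rng(0),
        )
        p = float(perm.pvalue)
    return bool(p < alpha), bool(sv_stats.mean > 1.0)


def ks_strata(
    estimates: Iterable[SubstitutionEstimate],
    breakpoints: tuple[float, float] = (0.2, 0.5),
) -> dict[tuple[str, str], str | None]:
    """Bin pairs by their synonymous distance Ks.

    Half-open bins [0, b1) -> "low", [b1, b2) -> "intermediate",
    [b2, inf) -> "high"; pairs with undefined Ks map to None. Ks roughly
    tracks divergence time, so the strata separate recent from ancient
    duplicates.
    """
    b1, b2 = breakpoints
    if not b1 < b2:
        raise ValueError("breakpoints must be strictly increasing")
    out: dict[tuple[str, str], str | None] = {}
    for est in estimates:
        key = (est.id_a, est.id_b)
        if math.isnan(est.Ks):
            out[key] = None
        elif est.Ks < b1:
            out[key] = "low"
        elif est.Ks < b2:
            out[key] = "intermediate"
        else:
            out[key] = "high"
    return out


@dataclass(frozen=True)
class GeneCluster:
    scaffold_id: str
    family: str
    gene_ids: tuple[str, ...]


def detect_gene_clusters(records: Iterable[GeneRecord]) -> list[GeneCluster]:
    """Same-family venom-related genes (SV or NV) co-located on one scaffold.

    Returns clusters of size >= 2, sorted by size (descending) then scaffold
    id; gene ids within a cluster are sorted.
    """
    groups: dict[tuple[str, str], list[str]] = {}
    for rec in records:
        if rec.label in ("SV", "NV") and rec.scaffold_id:
            groups.setdefault((rec.scaffold_id, rec.family), []).append(rec.gene_id)
    clusters = [
        GeneCluster(scaffold, family, tuple(sorted(genes)))
        for (scaffold, family), genes in groups.items()
        if len(genes) >= 2
    ]
    clusters.sort(key=lambda c: (-len(c.gene_ids), c.scaffold_id, c.family))
    return clusters


_CATEGORY_ORDER = {"III": 0, "II": 1, "I": 2}


def summarize_family(
    family: str,
    records: Sequence[GeneRecord],
    estimator: Callable[[CodonAlignmentPair], SubstitutionEstimate] = pairwise_ng,
    alpha: float = 0.05,
) -> GeneFamilySummary:
    """Roll one family's records up to counts, category and acceleration."""
    sv = [r for r in records if r.label == "SV"]
    nv = [r for r in records if r.label == "NV"]
    sv_stats = group_kaks(sv, estimator)
    nv_stats = group_kaks(nv, estimator)
    accelerated, exceeds = detect_acceleration(sv_stats, nv_stats, alpha)
    return GeneFamilySummary(
        family=family,
        sv_count=len(sv),
        nv_count=len(nv),
        category=categorize_family(len(sv)),
        sv_stats=sv_stats,
        nv_stats=nv_stats,
        accelerated=accelerated,
        mean_exceeds_one=exceeds,
    )


def build_family_table(summaries: Iterable[GeneFamilySummary]) -> pd.DataFrame:
    """Per-family report plus a totals row.

    Rows are ordered Category III, II, I, then by SV count descending, ties
    alphabetically; the final row "Total" sums the SV and NV counts. The
    layout mirrors a venom-gene catalog table (family, copy numbers,
    duplication category, acceleration flag).
    """
    rows = []
    for s in sorted(
        summaries,
        key=lambda s: (_CATEGORY_ORDER[s.category], -s.sv_count, s.family),
    ):
        rows.append(
            {
                "family": s.family,
                "category": s.category,
                "sv_count": s.sv_count,
                "nv_count": s.nv_count,
                "sv_mean_kaks": None if s.sv_stats is None or not s.sv_stats.defined
                else round(s.sv_stats.mean, 3),
                "sv_se_kaks": None if s.sv_stats is None or not s.sv_stats.defined
                else round(s.sv_stats.se, 3),
                "nv_mean_kaks": None if s.nv_stats is None or not s.nv_stats.defined
                else round(s.nv_stats.mean, 3),
                "nv_se_kaks": None if s.nv_stats is None or not s.nv_stats.defined
                else round(s.nv_stats.se, 3),
                "accelerated": s.accelerated,
                "sv_mean_exceeds_one": s.mean_exceeds_one,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "family", "category", "sv_count", "nv_count", "sv_mean_kaks",
            "sv_se_kaks", "nv_mean_kaks", "nv_se_kaks", "accelerated",
            "sv_mean_exceeds_one",
        ],
    )
    total = {
        "family": "Total",
        "category": "",
        "sv_count": int(df["sv_count"].sum()) if len(df) else 0,
        "nv_count": int(df["nv_count"].sum()) if len(df) else 0,
    }
    return pd.concat([df, pd.DataFrame([total])], ignore_index=True)


def family_table_from_counts(
    counts: Mapping[str, tuple[int, int]]
) -> pd.DataFrame:
    """Family table built from bare (sv_count, nv_count) pairs per family,
    without sequence data (no Ka/Ks columns filled)."""
    summaries = [
        GeneFamilySummary(
            family=fam,
            sv_count=sv,
            nv_count=nv,
            category=categorize_family(sv),
        )
        for fam, (sv, nv) in counts.items()
    ]
    return build_family_table(summaries)
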