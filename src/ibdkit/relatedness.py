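"""Pairwise relationship classification and cohort screening.

Categories follow the unequivocal expectations — identical samples share
100% IBD2, parent-child pairs 100% IBD1, full siblings 25/50/25 — with
second-degree relationships (half-sib, avuncular, grandparent) expected
at K1 ≈ 0.5, K2 ≈ 0.  Pairs below the named categories fall into
half-open K1 bins down to the relatedness cutoff of 0.025.  Any
candidate call must be *confirmed* by at least one IBD1/IBD2 segment of
10 Mb or more (an IBS0-free region); an unconfirmed K1 above the cutoff
is demoted to unrelated and flagged — elevated K1 without a contiguous
segment reflects conserved-haplotype background, not recent ancestry.

Anomaly flags mark sharing a pedigree annotation forbids: IBD2 between
parent and child or between second-degree relatives reveals a second
path of ancestry (bilineal relatedness); IBD0 between parent and child
reveals a chromosomal abnormality or systematic genotype error.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import pandas as pd

from .config import AnalysisConfig
from .genotype_io import GenotypeTable
from .ibd import (CottermanEstimate, IBD_1, IBD_2, IBDSegment, analyze_pair,
                  relatedness_coefficient)

CAT_IDENTICAL = "identical"
CAT_PARENT_CHILD = "parent-child"
CAT_FULL_SIBLING = "full-sibling"
CAT_SECOND_DEGREE = "second-degree"
CAT_UNRELATED = "unrelated"

FLAG_PC_IBD2 = "PC_with_IBD2"
FLAG_PC_IBD0 = "PC_with_IBD0"
FLAG_SECOND_IBD2 = "SECOND_with_IBD2"
FLAG_UNCONFIRMED = "UNCONFIRMED_K1"

_ANNOTATION_TYPES = {"parent-child", "second-degree", "full-sibling", "none"}


@dataclass
class RelationshipCall:
    id1: str
    id2: str
    group: str | None
    k0: float
    k1: float
    k2: float
    r: float
    category: str
    flags: set[str] = field(default_factory=set)
    confirmed: bool = False


def confirm_ibd1_segment(segments: list[IBDSegment], config: AnalysisConfig) -> bool:
    """True iff some IBD1/IBD2 segment reaches the confirmation length (>=10 Mb)."""
    return any(s.state in (IBD_1, IBD_2) and s.size_mb >= config.confirm_segment_min_mb
               for s in segments)


def _k1_bin(k1: float, config: AnalysisConfig) -> str | None:
    """Half-open K1 bin label, or None below the relatedness cutoff."""
    upper = config.second_k1_min
    for lower in config.k1_bin_edges:
        if lower <= k1 < upper:
            return f"K1 [{lower:g},{upper:g})"
        upper = lower
    return None


def classify_pair(estimate: CottermanEstimate, segments: list[IBDSegment],
                  config: AnalysisConfig, ids: tuple[str, str] = ("a", "b"),
                  group: str | None = None) -> RelationshipCall:
    """Classify one pair from its Cotterman estimate and IBD segments."""
    k0, k1, k2 = estimate.k0, estimate.k1, estimate.k2
    flags: set[str] = set()

    if k2 >= config.identical_k2_min:
        category = CAT_IDENTICAL
    elif k1 >= config.pc_k1_min and k2 < config.pc_k2_max:
        category = CAT_PARENT_CHILD
        if k2 >= config.anomaly_k_cutoff:
            flags.add(FLAG_PC_IBD2)
        if k0 >= config.anomaly_k_cutoff:
            flags.add(FLAG_PC_IBD0)
    elif config.sib_k1_min <= k1 <= config.sib_k1_max and k2 >= config.sib_k2_min:
        category = CAT_FULL_SIBLING
    elif config.second_k1_min <= k1 <= config.second_k1_max and k2 < config.sib_k2_min:
        category = CAT_SECOND_DEGREE
        if k2 >= config.anomaly_k_cutoff:
            flags.add(FLAG_SECOND_IBD2)
    else:
        category = _k1_bin(k1, config) or CAT_UNRELATED

    confirmed = False
    if category != CAT_UNRELATED:
        confirmed = confirm_ibd1_segment(segments, config)
        if not confirmed:
            flags.add(FLAG_UNCONFIRMED)
            category = CAT_UNRELATED

    return RelationshipCall(
        id1=ids[0], id2=ids[1], group=group, k0=k0, k1=k1, k2=k2,
        r=relatedness_coefficient(estimate), category=category,
        flags=flags, confirmed=confirmed)


def flag_anomalies(call: RelationshipCall, annotated_type: str,
                   config: AnalysisConfig) -> set[str]:
    """Flags for sharing inconsistent with the annotated relationship type."""
    if annotated_type not in _ANNOTATION_TYPES:
        raise ValueError(f"unknown annotated relationship type {annotated_type!r}")
    flags: set[str] = set()
    if annotated_type == "parent-child":
        if call.k2 >= config.anomaly_k_cutoff:
            flags.add(FLAG_PC_IBD2)
        if call.k0 >= config.anomaly_k_cutoff:
            flags.add(FLAG_PC_IBD0)
    elif annotated_type == "second-degree":
        if call.k2 >= config.anomaly_k_cutoff:
            flags.add(FLAG_SECOND_IBD2)
    return flags


def count_comparisons(group_sizes: dict[str, int] | list[int], mode: str) -> int:
    """Closed-form number of pairwise comparisons.

    within-group: sum of C(n_i, 2) over groups; all-pairs: C(N, 2).
    """
    sizes = list(group_sizes.values()) if isinstance(group_sizes, dict) else list(group_sizes)
    if mode == "within-group":
        return sum(n * (n - 1) // 2 for n in sizes)
    if mode == "all-pairs":
        total = sum(sizes)
        return total * (total - 1) // 2
    raise ValueError(f"unknown mode {mode!r}; expected 'within-group' or 'all-pairs'")


def screen_cohort(table: GenotypeTable, config: AnalysisConfig,
                  mode: str = "within-group") -> tuple[list[RelationshipCall], int]:
    """Classify every pair in scope; returns calls and the comparison count.

    Within-group mode compares samples sharing a group label (groups of
    fewer than two contribute no pairs); all-pairs mode compares every
    sample pair.  The returned count always equals the closed form.
    """
    ids = table.sample_ids
    groups = {iid: table.group_of(iid) for iid in ids}
    if mode == "within-group":
        by_group: dict[str, list[str]] = {}
        for iid in ids:
            if groups[iid] is not None:
                by_group.setdefault(groups[iid], []).append(iid)
        pairs = [(a, b) for members in by_group.values()
                 for a, b in itertools.combinations(members, 2)]
        expected = count_comparisons({g: len(v) for g, v in by_group.items()}, mode)
    elif mode == "all-pairs":
        pairs = list(itertools.combinations(ids, 2))
        expected = count_comparisons([len(ids)], "all-pairs")
    else:
        raise ValueError(f"unknown mode {mode!r}")

    markers = table.markers
    calls: list[RelationshipCall] = []
    for a, b in pairs:
        analysis = analyze_pair(table.calls_for(a), table.calls_for(b),
                                markers, config, pair=(a, b))
        g = groups[a] if groups[a] == groups[b] else None
        calls.append(classify_pair(analysis.estimate, analysis.segments,
                                   config, ids=(a, b), group=g))
    assert len(pairs) == expected
    return calls, len(pairs)


def calls_frame(calls: list[RelationshipCall]) -> pd.DataFrame:
    """Relationship calls as a report-ready frame."""
    return pd.DataFrame([{
        "iid1": c.id1, "iid2": c.id2, "group": c.group or "",
        "k0": round(c.k0, 4), "k1": round(c.k1, 4), "k2": round(c.k2, 4),
        "r": round(c.r, 4), "category": c.category,
        "flags": ",".join(sorted(c.flags)), "confirmed": c.confirmed,
    } for c in calls])
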