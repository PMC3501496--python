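"""Trio-based autozygosity and inbreeding inference.

A run of homozygosity in a child that overlaps a region where the
child's parents are IBD1 with each other is evidence of autozygosity:
the child inherited the same ancestral allele down both sides.  IBD2
between a child and a parent at some locus is independent corroborating
evidence that the parents are related.  A child whose parents are
related but who shows no qualifying ROH overlap is *not* called inbred;
a trio missing a genotyped parent cannot be evaluated and is reported
``unknown``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .genotype_io import GenotypeTable
from .ibd import IBD_1, IBD_2, IBDSegment, analyze_pair
from .relatedness import confirm_ibd1_segment
from .roh import ROHRegion, detect_roh

VERDICT_INBRED = "inbred"
VERDICT_NOT_INBRED = "not_inbred"
VERDICT_UNKNOWN = "unknown"


class SingleParentError(ValueError):
    """Both parents are required to assess parental IBD1."""


@dataclass
class AutozygousSegment:
    """Intersection of a child ROH with a parental IBD1/IBD2 segment."""

    chrom: int
    start_bp: int
    end_bp: int
    roh: ROHRegion
    parental_segment: IBDSegment

    @property
    def size_mb(self) -> float:
        return (self.end_bp - self.start_bp + 1) / 1e6


@dataclass
class InbreedingReport:
    child_id: str
    father_id: str | None
    mother_id: str | None
    autozygous_segments: list[AutozygousSegment]
    child_roh: list[ROHRegion]
    parents_related: bool
    parental_k1: float | None
    ibd2_with_parent: list[str]
    verdict: str
    comment: str = ""

    @property
    def total_mb(self) -> float:
        return sum(s.size_mb for s in self.autozygous_segments)

    @property
    def n_regions(self) -> int:
        return len(self.autozygous_segments)


def parental_ibd1(father_calls: np.ndarray | None, mother_calls: np.ndarray | None,
                  markers: pd.DataFrame, config: AnalysisConfig,
                  ids: tuple[str, str] = ("father", "mother")):
    """IBD1/IBD2 segments between the two parents (windowed analysis).

    Returns (segments, estimate).  Raises :class:`SingleParentError` when
    either parent is ungenotyped — the trio must then be reported unknown.
    """
    if father_calls is None or mother_calls is None:
        raise SingleParentError("single parent: parental IBD1 cannot be assessed")
    analysis = analyze_pair(father_calls, mother_calls, markers, config, pair=ids)
    segments = [s for s in analysis.segments if s.state in (IBD_1, IBD_2)]
    return segments, analysis.estimate


def autozygous_overlap(child_roh: list[ROHRegion], parental_segments: list[IBDSegment],
                       config: AnalysisConfig) -> list[AutozygousSegment]:
    """Base-pair intersections of child ROH with parental IBD1/IBD2 segments.

    Only overlaps of at least ``autozygosity_min_overlap_mb`` qualify.
    """
    min_bp = config.autozygosity_min_overlap_mb * 1e6
    out: list[AutozygousSegment] = []
    for roh in child_roh:
        for seg in parental_segments:
            if seg.chrom != roh.chrom or seg.state not in (IBD_1, IBD_2):
                continue
            lo = max(roh.start_bp, seg.start_bp)
            hi = min(roh.stop_bp, seg.end_bp)
            if hi - lo + 1 >= min_bp:
                out.append(AutozygousSegment(chrom=roh.chrom, start_bp=lo,
                                             end_bp=hi, roh=roh, parental_segment=seg))
    return out


def assess_trio(table: GenotypeTable, child_id: str,
                father_id: str | None, mother_id: str | None,
                config: AnalysisConfig) -> InbreedingReport:
    """Full inbreeding assessment of one trio.

    Verdict is ``inbred`` iff a qualifying ROH x parental-IBD1 overlap
    exists, or the child shares IBD2 with a parent and has at least one
    ROH; ``unknown`` when a parent is ungenotyped; ``not_inbred``
    otherwise (including related parents with no qualifying overlap).
    """
    if child_id not in table.sample_ids:
        raise KeyError(f"child {child_id!r} not genotyped")
    present = set(table.sample_ids)
    father = table.calls_for(father_id) if father_id in present else None
    mother = table.calls_for(mother_id) if mother_id in present else None
    child = table.calls_for(child_id)
    markers = table.markers

    child_roh = detect_roh(child, markers, config, sample_id=child_id)

    ibd2_with_parent: list[str] = []
    for pid, calls in ((father_id, father), (mother_id, mother)):
        if calls is None:
            continue
        est = analyze_pair(child, calls, markers, config, pair=(child_id, pid)).estimate
        if est.k2 >= config.anomaly_k_cutoff:
            ibd2_with_parent.append(pid)

    try:
        parental_segments, parental_est = parental_ibd1(
            father, mother, markers, config,
            ids=(father_id or "father", mother_id or "mother"))
    except SingleParentError:
        return InbreedingReport(
            child_id=child_id, father_id=father_id, mother_id=mother_id,
            autozygous_segments=[], child_roh=child_roh, parents_related=False,
            parental_k1=None, ibd2_with_parent=ibd2_with_parent,
            verdict=VERDICT_UNKNOWN, comment="Single parent")

    parents_related = (parental_est.k1 >= config.k1_related_cutoff
                       and confirm_ibd1_segment(parental_segments, config))
    overlaps = autozygous_overlap(child_roh, parental_segments, config)

    if overlaps or (ibd2_with_parent and child_roh):
        verdict = VERDICT_INBRED
        comment = "ROH overlaps parental IBD1" if overlaps else "IBD2 with parent plus ROH"
    else:
        verdict = VERDICT_NOT_INBRED
        if parents_related and not child_roh:
            comment = "Parents related but child has no ROH"
        elif parents_related:
            comment = "Parents related but no qualifying ROH overlap"
        else:
            comment = ""
    return InbreedingReport(
        child_id=child_id, father_id=father_id, mother_id=mother_id,
        autozygous_segments=overlaps, child_roh=child_roh,
        parents_related=parents_related, parental_k1=parental_est.k1,
        ibd2_with_parent=ibd2_with_parent, verdict=verdict, comment=comment)


def report_frame(reports: list[InbreedingReport],
                 groups: dict[str, str] | None = None) -> pd.DataFrame:
    """Trio reports in the per-individual summary layout."""
    rows = []
    for r in reports:
        roh_chroms = sorted({x.chrom for x in r.child_roh})
        total_mb = sum(x.size_mb for x in r.child_roh)
        total_snps = sum(x.n_snps for x in r.child_roh)
        n = len(r.child_roh)
        rows.append({
            "iid": r.child_id,
            "group": (groups or {}).get(r.child_id, ""),
            "roh_chroms": ",".join(map(str, roh_chroms)),
            "total_mb": round(total_mb, 3),
            "total_snps": total_snps,
            "n_roh": n,
            "avg_size_mb": round(total_mb / n, 3) if n else 0.0,
            "avg_snps": round(total_snps / n, 1) if n else 0.0,
            "parents_related": r.parents_related,
            "parental_k1": round(r.parental_k1, 4) if r.parental_k1 is not None else "",
            "ibd2_with_parent": ",".join(r.ibd2_with_parent),
            "autozygous_mb": round(r.total_mb, 3),
            "n_autozygous": r.n_regions,
            "verdict": r.verdict,
            "comment": r.comment,
        })
    return pd.DataFrame(rows)
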