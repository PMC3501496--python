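"""Runs of homozygosity (ROH) per individual.

A run is a maximal stretch of consecutive autosomal markers with no
heterozygous call.  Missing calls are neutral: they neither break a run
nor count toward its SNP tally.  Runs are trimmed to their first and
last homozygous SNP, split where consecutive homozygous SNPs are farther
apart than the gap limit (sparse coverage must not inflate a region),
and reported only when they span at least ``roh_min_mb`` megabases and
``roh_min_snps`` homozygous SNPs (defaults 2 Mb / 400 SNPs).

Without intensity or copy-number data a reported region may reflect
either autozygosity or a hemizygous deletion; discriminating the two is
the job of the trio-based autozygosity overlap, not of this module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .genotype_io import AB, NC


@dataclass
class ROHRegion:
    sample_id: str
    chrom: int
    start_bp: int
    stop_bp: int
    n_snps: int

    @property
    def size_mb(self) -> float:
        return (self.stop_bp - self.start_bp + 1) / 1e6

    @property
    def snps_per_mb(self) -> float:
        return self.n_snps / self.size_mb


def _candidate_runs(codes: np.ndarray, pos: np.ndarray, gap_bp: int,
                    het_tolerance: int):
    """Yield (start_idx, stop_idx, n_snps, n_het) candidate runs over one
    chromosome's homozygous-SNP index space, before size filtering.

    Indices refer to the array of homozygous sites.  With a nonzero het
    tolerance, runs separated by single heterozygous calls are merged
    greedily left to right while the merged run's het count stays within
    the tolerance and no gap limit is crossed.
    """
    hom_idx = np.flatnonzero((codes != AB) & (codes != NC))
    if len(hom_idx) == 0:
        return []
    hom_pos = pos[hom_idx]
    # run id advances at each heterozygous call and at each oversized gap
    het_before = np.cumsum(codes == AB)[hom_idx]          # hets preceding each hom site
    new_run = np.empty(len(hom_idx), dtype=bool)
    new_run[0] = True
    new_run[1:] = (np.diff(het_before) > 0) | (np.diff(hom_pos) > gap_bp)
    starts = np.flatnonzero(new_run)
    stops = np.append(starts[1:], len(hom_idx)) - 1

    runs = [(int(s), int(e), int(e - s + 1), 0) for s, e in zip(starts, stops)]
    if het_tolerance <= 0 or len(runs) < 2:
        return [(hom_idx[s], hom_idx[e], n, h) for s, e, n, h in runs]

    merged = [runs[0]]
    for s, e, n, h in runs[1:]:
        ps, pe, pn, ph = merged[-1]
        n_het_between = int(het_before[s] - het_before[pe])
        gap_ok = hom_pos[s] - hom_pos[pe] <= gap_bp
        if gap_ok and n_het_between > 0 and ph + h + n_het_between <= het_tolerance:
            merged[-1] = (ps, e, pn + n, ph + h + n_het_between)
        else:
            merged.append((s, e, n, h))
    return [(hom_idx[s], hom_idx[e], n, h) for s, e, n, h in merged]


def detect_roh(sample_calls: np.ndarray, markers: pd.DataFrame,
               config: AnalysisConfig, sample_id: str = "sample") -> list[ROHRegion]:
    """Detect reportable runs of homozygosity in one sample."""
    calls = np.asarray(sample_calls, dtype=np.int8)
    if len(calls) != len(markers):
        raise ValueError("calls not aligned to markers")
    chrom_arr = markers["chrom"].to_numpy()
    pos_arr = markers["pos"].to_numpy()
    gap_bp = int(round(config.roh_gap_max_mb * 1e6))

    regions: list[ROHRegion] = []
    for chrom in np.unique(chrom_arr):
        sel = chrom_arr == chrom
        codes, pos = calls[sel], pos_arr[sel]
        for i0, i1, n_snps, _ in _candidate_runs(codes, pos, gap_bp,
                                                 config.roh_het_tolerance):
            start, stop = int(pos[i0]), int(pos[i1])
            size_mb = (stop - start + 1) / 1e6
            if size_mb >= config.roh_min_mb and n_snps >= config.roh_min_snps:
                regions.append(ROHRegion(sample_id=sample_id, chrom=int(chrom),
                                         start_bp=start, stop_bp=stop, n_snps=n_snps))
    return regions


def roh_table(regions: list[ROHRegion]) -> pd.DataFrame:
    """Per-region table (Individual ID, chrom, Start, Stop, Size, SNPs, SNPs/Mb)."""
    return pd.DataFrame([{
        "sample_id": r.sample_id, "chrom": r.chrom, "start_bp": r.start_bp,
        "stop_bp": r.stop_bp, "size_mb": round(r.size_mb, 3),
        "n_snps": r.n_snps, "snps_per_mb": round(r.snps_per_mb, 1),
    } for r in regions])


def summarize_roh(regions: list[ROHRegion], sample_ids: list[str]) -> pd.DataFrame:
    """Per-sample totals; samples with no regions report zeros."""
    rows = []
    by_sample: dict[str, list[ROHRegion]] = {s: [] for s in sample_ids}
    for r in regions:
        by_sample.setdefault(r.sample_id, []).append(r)
    for sid in sample_ids:
        regs = by_sample[sid]
        total_mb = sum(r.size_mb for r in regs)
        total_snps = sum(r.n_snps for r in regs)
        n = len(regs)
        rows.append({
            "sample_id": sid,
            "total_mb": round(total_mb, 3),
            "total_snps": total_snps,
            "n_regions": n,
            "avg_size_mb": round(total_mb / n, 3) if n else 0.0,
            "avg_snps": round(total_snps / n, 1) if n else 0.0,
        })
    return pd.DataFrame(rows)
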