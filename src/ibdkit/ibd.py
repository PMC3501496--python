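"""Windowed IBD-state classification and Cotterman coefficients.

The informative sites of a pair are partitioned, chromosome by
chromosome, into windows of a fixed number of informative SNPs
(default 500).  Each window is assigned an IBD state from its IBS
composition and the Cotterman coefficients K0/K1/K2 — the proportions of
the genome shared IBD0/IBD1/IBD2 — are the informative-site-weighted
fractions of windows in each state.  Contiguous same-state windows merge
into genomic IBD segments; long IBD1/IBD2 segments (>=10 Mb by default)
are what confirms a candidate relationship.

Window classification uses two fraction thresholds derived from the
exact IBS composition of pure-state regions among informative sites:

* an IBD0 region shows IBS0 at fraction 2p²q² / (6p²q² + 4pq(p²+q²)),
  about 0.11 under a uniform frequency spectrum, while IBD1/IBD2 regions
  show none (barring genotype error) — a window is IBD>=1 when its IBS0
  fraction is below ``window_ibs0_frac_tol``;
* an IBD1 region shows IBS1 at fraction exactly 2/3 (P(IBS1)=2pq,
  P(IBS2*)=pq, P(IBS0)=0) and carries 1.5x the informative-site density
  of an IBD2 region (3pq vs 2pq), while an IBD2 region shows no IBS1 —
  a window is IBD2 when its IBS1 fraction is below
  ``window_ibs1_frac_tol`` = (2/3)·1.5/(1.5+1) = 0.40, the point at
  which the majority of the window's base pairs are in the IBD2 state.

Both thresholds sit at the bp-majority midpoint so that windows
straddling a recombination breakpoint are assigned to the state covering
most of the window, keeping the genome-wide K estimates unbiased.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .ibs import IBS0, IBS1, IBS2_STAR, PairIBS, informative_sites, pair_ibs

IBD_0: int = 0
IBD_1: int = 1
IBD_2: int = 2


class InsufficientInformativeSites(ValueError):
    """No window could be formed from the pair's informative sites."""


@dataclass
class Window:
    """A run of informative SNPs on one chromosome with its IBS tallies."""

    chrom: int
    start_bp: int
    end_bp: int
    first_marker: int          # global marker index of first informative site
    last_marker: int
    n_informative: int
    n_ibs0: int = 0
    n_ibs1: int = 0
    n_ibs2_star: int = 0


@dataclass
class CottermanEstimate:
    """K0/K1/K2: proportions of the genome shared IBD0/IBD1/IBD2."""

    k0: float
    k1: float
    k2: float
    n_windows: int
    n_informative_sites: int

    def __post_init__(self) -> None:
        total = self.k0 + self.k1 + self.k2
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"k0+k1+k2 = {total!r}, expected 1")


@dataclass
class IBDSegment:
    """Maximal run of equal-state windows, as a genomic interval."""

    pair: tuple[str, str]
    chrom: int
    start_bp: int
    end_bp: int
    state: int
    n_windows: int

    @property
    def size_mb(self) -> float:
        return (self.end_bp - self.start_bp + 1) / 1e6


def make_windows(informative_idx: np.ndarray, markers: pd.DataFrame,
                 config: AnalysisConfig) -> list[Window]:
    """Partition informative sites into windows of ``config.window_size``.

    Windows never span a chromosome boundary.  On each chromosome the
    trailing remainder forms its own window when it holds at least half a
    window of sites, merges into the previous window otherwise, and
    stands alone if it is the chromosome's only run.  Window bp bounds
    tile the informative extent of the chromosome: each window starts at
    its first informative site and ends just before the next window's.
    """
    informative_idx = np.asarray(informative_idx)
    w = config.window_size
    chrom_all = markers["chrom"].to_numpy()
    pos_all = markers["pos"].to_numpy()
    chroms = chrom_all[informative_idx]
    windows: list[Window] = []
    for chrom in np.unique(chroms):
        idx = informative_idx[chroms == chrom]
        n = len(idx)
        if n == 0:
            continue
        n_full, rem = divmod(n, w)
        sizes = [w] * n_full
        if n_full == 0:
            sizes = [rem]
        elif rem >= w / 2:
            sizes.append(rem)
        elif rem:
            sizes[-1] += rem
        bounds = np.cumsum([0] + sizes)
        starts_bp = [int(pos_all[idx[b]]) for b in bounds[:-1]]
        for j, (lo, hi) in enumerate(zip(bounds[:-1], bounds[1:])):
            end_bp = (starts_bp[j + 1] - 1) if j + 1 < len(sizes) else int(pos_all[idx[hi - 1]])
            windows.append(Window(
                chrom=int(chrom), start_bp=starts_bp[j], end_bp=end_bp,
                first_marker=int(idx[lo]), last_marker=int(idx[hi - 1]),
                n_informative=int(hi - lo)))
    return windows


def fill_window_counts(windows: list[Window], ibs: PairIBS,
                       informative_idx: np.ndarray) -> None:
    """Tally IBS0/IBS1/IBS2* per window from the pair's state track."""
    if not windows:
        return
    states = ibs.states[informative_idx]
    # windows are stored in informative-site order; rebuild the slice bounds
    offsets = np.cumsum([0] + [w.n_informative for w in windows])
    is0 = (states == IBS0).astype(np.int64)
    is1 = (states == IBS1).astype(np.int64)
    is2 = (states == IBS2_STAR).astype(np.int64)
    c0 = np.add.reduceat(is0, offsets[:-1])
    c1 = np.add.reduceat(is1, offsets[:-1])
    c2 = np.add.reduceat(is2, offsets[:-1])
    for w, a, b, c in zip(windows, c0, c1, c2):
        w.n_ibs0, w.n_ibs1, w.n_ibs2_star = int(a), int(b), int(c)


def classify_window(window: Window, config: AnalysisConfig) -> int:
    """Assign an IBD state to one window from its IBS composition."""
    n = window.n_informative
    if n == 0:
        return IBD_0
    if window.n_ibs0 > config.window_ibs0_frac_tol * n:
        return IBD_0
    if window.n_ibs1 > config.window_ibs1_frac_tol * n:
        return IBD_1
    return IBD_2


def classify_windows(windows: list[Window], config: AnalysisConfig) -> np.ndarray:
    return np.array([classify_window(w, config) for w in windows], dtype=np.int8)


def estimate_cotterman(ibs: PairIBS, markers: pd.DataFrame,
                       config: AnalysisConfig) -> CottermanEstimate:
    """Windowed Cotterman coefficient estimate for one pair.

    K_i is the base-pair fraction of the windowed genome lying in
    windows classified IBD_i.  Weighting windows by their bp span
    matters: informative-site density falls with the IBD state (0.66,
    3pq and 2pq per marker for IBD0/1/2 respectively), so counting
    sites or windows would deflate K2 by ~30% relative for a sib pair.
    """
    inf_idx = informative_sites(ibs)
    windows = make_windows(inf_idx, markers, config)
    if not windows:
        raise InsufficientInformativeSites("insufficient informative sites")
    fill_window_counts(windows, ibs, inf_idx)
    states = classify_windows(windows, config)
    return _estimate_from_windows(windows, states)


def _estimate_from_windows(windows: list[Window], states: np.ndarray,
                           weights: np.ndarray | None = None) -> CottermanEstimate:
    if weights is None:
        weights = np.array([w.end_bp - w.start_bp + 1 for w in windows], dtype=np.float64)
    total = float(weights.sum())
    if total == 0:
        raise InsufficientInformativeSites("insufficient informative sites")
    k = [float(weights[states == s].sum()) / total for s in (IBD_0, IBD_1, IBD_2)]
    # absorb float rounding so conservation holds exactly
    k[0] = 1.0 - k[1] - k[2]
    return CottermanEstimate(k0=k[0], k1=k[1], k2=k[2],
                             n_windows=len(windows),
                             n_informative_sites=int(sum(w.n_informative for w in windows)))


def extract_segments(window_states: np.ndarray, windows: list[Window],
                     pair: tuple[str, str] = ("a", "b")) -> list[IBDSegment]:
    """Merge maximal runs of adjacent equal-state windows into segments."""
    if len(window_states) != len(windows):
        raise ValueError("one state per window required")
    segments: list[IBDSegment] = []
    run_start = 0
    for i in range(1, len(windows) + 1):
        boundary = (
            i == len(windows)
            or window_states[i] != window_states[run_start]
            or windows[i].chrom != windows[run_start].chrom
        )
        if boundary:
            first, last = windows[run_start], windows[i - 1]
            segments.append(IBDSegment(
                pair=tuple(pair), chrom=first.chrom,
                start_bp=first.start_bp, end_bp=last.end_bp,
                state=int(window_states[run_start]), n_windows=i - run_start))
            run_start = i
    return segments


def relatedness_coefficient(estimate: CottermanEstimate) -> float:
    """Relatedness coefficient r = K2 + K1/2, the expected genome fraction shared."""
    return estimate.k2 + estimate.k1 / 2.0


@dataclass
class PairAnalysis:
    """Full windowed analysis of one pair (IBS track through segments)."""

    pair: tuple[str, str]
    ibs: PairIBS
    windows: list[Window]
    window_states: np.ndarray
    estimate: CottermanEstimate
    segments: list[IBDSegment]


def analyze_pair(calls_a: np.ndarray, calls_b: np.ndarray, markers: pd.DataFrame,
                 config: AnalysisConfig,
                 pair: tuple[str, str] = ("a", "b")) -> PairAnalysis:
    """Run IBS → windows → classification → K estimate → segments for one pair."""
    ibs = pair_ibs(calls_a, calls_b, pair=pair)
    inf_idx = informative_sites(ibs)
    windows = make_windows(inf_idx, markers, config)
    if not windows:
        raise InsufficientInformativeSites("insufficient informative sites")
    fill_window_counts(windows, ibs, inf_idx)
    states = classify_windows(windows, config)
    estimate = _estimate_from_windows(windows, states)
    segments = extract_segments(states, windows, pair=pair)
    return PairAnalysis(pair=tuple(pair), ibs=ibs, windows=windows,
                        window_states=states, estimate=estimate, segments=segments)


def segments_frame(segments: list[IBDSegment]) -> pd.DataFrame:
    """Segments as a TSV/BED-ready frame."""
    return pd.DataFrame([{
        "iid1": s.pair[0], "iid2": s.pair[1], "chrom": s.chrom,
        "start_bp": s.start_bp, "end_bp": s.end_bp, "state": f"IBD{s.state}",
        "n_windows": s.n_windows, "size_mb": round(s.size_mb, 3),
    } for s in segments])
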