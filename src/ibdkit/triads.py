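"""Triad logic for discriminating second-degree relationship types.

Pairwise K estimates cannot tell a half-sib pair from avuncular or
grandparent-grandchild (all share K1 ≈ 0.5).  Comparing three window
tracks on one shared grid can:

* **Opposite inheritance** — a region where two putative siblings are
  IBD0 with each other (they drew *different* alleles from the shared
  parent) while a third individual is IBD1 with *both*.  A true aunt or
  uncle can do this (they carry both grandparental haplotypes); a single
  grandparent cannot, since exactly one of the siblings carries that
  grandparent's allele wherever they disagree.  Such regions therefore
  prove the candidate avuncular and the pair half- (or full-) siblings.
* **Nested sharing** — every segment a grandparent shares with a
  grandchild must pass through the intermediate parent, so the
  candidate-child IBD1 windows are contained in the candidate-parent
  track's IBD1/IBD2 windows.  Against a known parent, a nested fraction
  of ~1 together with a parent-child-grade candidate-parent track
  supports grandparent status.

Scenarios: 1 — avuncular to two half-siblings; 2 — avuncular to two
full siblings; 3 — half-sibling inference; 4 — third/fourth-degree
configurations (largely indistinguishable sets); 5 — ruling types out
(e.g. IBD2 between second-degree relatives excludes unilineal
half-sib/grandparent explanations).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .genotype_io import GenotypeTable
from .ibd import (IBD_0, IBD_1, IBD_2, CottermanEstimate, Window,
                  _estimate_from_windows, classify_window, extract_segments,
                  make_windows)
from .ibs import IBS0, IBS1, IBS2_STAR, pair_ibs
from .relatedness import (CAT_FULL_SIBLING, CAT_PARENT_CHILD,
                          CAT_SECOND_DEGREE, classify_pair)

PAIRS = ((0, 1), (0, 2), (1, 2))  # (s1,s2), (s1,cand), (s2,cand)


class NoSharedInformativeSites(ValueError):
    """A pair of the triad has no informative sites."""


@dataclass
class TriadRegion:
    chrom: int
    start_bp: int
    end_bp: int
    first_window: int
    n_windows: int

    @property
    def size_mb(self) -> float:
        return (self.end_bp - self.start_bp + 1) / 1e6


@dataclass
class TriadTracks:
    """Three aligned window-state tracks on one shared window grid."""

    ids: tuple[str, str, str]
    windows: list[Window]
    states: dict[tuple[int, int], np.ndarray]
    estimates: dict[tuple[int, int], CottermanEstimate]

    def track(self, i: int, j: int) -> np.ndarray:
        return self.states[tuple(sorted((i, j)))]

    def estimate(self, i: int, j: int) -> CottermanEstimate:
        return self.estimates[tuple(sorted((i, j)))]


@dataclass
class TriadVerdict:
    ids: tuple[str, str, str]
    scenarios: list[int]
    labels: dict[str, str]
    ruled_out: list[str]
    evidence: list[TriadRegion]
    indistinguishable: bool = False
    note: str = ""


def build_triad_tracks(table: GenotypeTable, s1: str, s2: str, cand: str,
                       config: AnalysisConfig) -> TriadTracks:
    """Window the union informative grid and classify each pair per window.

    Windows hold ``window_size`` sites informative in *any* of the three
    pairs; each pair is classified within a window from its own
    informative sites there.  A window where a pair has fewer than
    ``min_window_informative`` of its own sites inherits that pair's
    previous state (IBD0 at a chromosome start).
    """
    ids = (s1, s2, cand)
    calls = [table.calls_for(i) for i in ids]
    markers = table.markers
    tracks = {}
    pair_objs = {}
    masks = {}
    for (i, j) in PAIRS:
        p = pair_ibs(calls[i], calls[j], pair=(ids[i], ids[j]))
        if not p.informative_mask.any():
            raise NoSharedInformativeSites(
                f"pair ({ids[i]}, {ids[j]}) has no informative sites")
        pair_objs[(i, j)] = p
        masks[(i, j)] = p.informative_mask
    union_idx = np.flatnonzero(masks[(0, 1)] | masks[(0, 2)] | masks[(1, 2)])
    windows = make_windows(union_idx, markers, config)
    if not windows:
        raise NoSharedInformativeSites("no informative sites in any pair")

    # per-window marker-index bounds, as searchsorted keys
    firsts = np.array([w.first_marker for w in windows])
    lasts = np.array([w.last_marker for w in windows])
    chroms = np.array([w.chrom for w in windows])

    states_by_pair = {}
    estimates = {}
    for key, p in pair_objs.items():
        inf = np.flatnonzero(p.informative_mask)
        st = p.states[inf]
        lo = np.searchsorted(inf, firsts, side="left")
        hi = np.searchsorted(inf, lasts, side="right")
        c0 = np.cumsum(np.concatenate([[0], (st == IBS0).astype(np.int64)]))
        c1 = np.cumsum(np.concatenate([[0], (st == IBS1).astype(np.int64)]))
        c2 = np.cumsum(np.concatenate([[0], (st == IBS2_STAR).astype(np.int64)]))
        n0, n1, n2 = c0[hi] - c0[lo], c1[hi] - c1[lo], c2[hi] - c2[lo]
        n_inf = hi - lo
        track = np.empty(len(windows), dtype=np.int8)
        prev_by_chrom: dict[int, int] = {}
        for w_i in range(len(windows)):
            n = int(n_inf[w_i])
            chrom = int(chroms[w_i])
            if n >= config.min_window_informative:
                wtmp = Window(chrom=chrom, start_bp=0, end_bp=0, first_marker=0,
                              last_marker=0, n_informative=n, n_ibs0=int(n0[w_i]),
                              n_ibs1=int(n1[w_i]), n_ibs2_star=int(n2[w_i]))
                track[w_i] = classify_window(wtmp, config)
            else:
                track[w_i] = prev_by_chrom.get(chrom, IBD_0)
            prev_by_chrom[chrom] = track[w_i]
        states_by_pair[key] = track
        estimates[key] = _estimate_from_windows(windows, track)
    return TriadTracks(ids=ids, windows=windows, states=states_by_pair,
                       estimates=estimates)


def opposite_inheritance_regions(tracks: TriadTracks,
                                 config: AnalysisConfig) -> list[TriadRegion]:
    """Runs of >= ``min_opposite_windows`` windows with s1-s2 IBD0 and
    both s1-cand and s2-cand IBD1."""
    s12 = tracks.track(0, 1)
    s1c = tracks.track(0, 2)
    s2c = tracks.track(1, 2)
    hit = (s12 == IBD_0) & (s1c == IBD_1) & (s2c == IBD_1)
    chroms = np.array([w.chrom for w in tracks.windows])
    regions: list[TriadRegion] = []
    i = 0
    n = len(hit)
    while i < n:
        if not hit[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and hit[j + 1] and chroms[j + 1] == chroms[i]:
            j += 1
        if j - i + 1 >= config.min_opposite_windows:
            regions.append(TriadRegion(
                chrom=int(chroms[i]), start_bp=tracks.windows[i].start_bp,
                end_bp=tracks.windows[j].end_bp, first_window=i,
                n_windows=j - i + 1))
        i = j + 1
    return regions


def nested_sharing_fraction(conduit_states: np.ndarray,
                            cand_states: np.ndarray) -> float | None:
    """Fraction of candidate-track IBD1 windows where the conduit track is
    IBD1 or IBD2; ``None`` when the candidate track has no IBD1 window."""
    cand_ibd1 = np.asarray(cand_states) == IBD_1
    if not cand_ibd1.any():
        return None
    conduit = np.asarray(conduit_states)
    ok = (conduit == IBD_1) | (conduit == IBD_2)
    return float(ok[cand_ibd1].sum() / cand_ibd1.sum())


def _pair_category(tracks: TriadTracks, i: int, j: int,
                   config: AnalysisConfig) -> str:
    segs = extract_segments(tracks.track(i, j), tracks.windows,
                            pair=(tracks.ids[i], tracks.ids[j]))
    return classify_pair(tracks.estimate(i, j), segs, config,
                         ids=(tracks.ids[i], tracks.ids[j])).category


def classify_triad(tracks: TriadTracks, config: AnalysisConfig,
                   constraints: dict | None = None) -> TriadVerdict:
    """Apply the scenario rule table to one triad.

    ``constraints`` may pin known relationships:
    ``{"full_siblings": (id, id)}`` or ``{"parent_child": (parent, child)}``.
    Pinned pairs must be members of the triad.
    """
    constraints = constraints or {}
    ids = tracks.ids
    id_index = {iid: k for k, iid in enumerate(ids)}
    for key in ("full_siblings", "parent_child"):
        if key in constraints:
            a, b = constraints[key]
            if a not in id_index or b not in id_index:
                raise ValueError(f"constraint {key} names ids outside the triad")

    cats = {p: _pair_category(tracks, *p, config) for p in PAIRS}
    k2 = {p: tracks.estimate(*p).k2 for p in PAIRS}

    scenarios: list[int] = []
    labels: dict[str, str] = {}
    ruled_out: list[str] = []
    evidence: list[TriadRegion] = []
    notes: list[str] = []

    # --- grandparent support against a known parent (nested sharing) ----
    if "parent_child" in constraints:
        parent, child = constraints["parent_child"]
        pi, ci = id_index[parent], id_index[child]
        (xi,) = set(range(3)) - {pi, ci}
        frac = nested_sharing_fraction(tracks.track(pi, xi), tracks.track(ci, xi))
        cand_parent_cat = cats[tuple(sorted((pi, xi)))]
        child_cand_cat = cats[tuple(sorted((ci, xi)))]
        if (frac is not None and frac >= config.nested_fraction_min
                and cand_parent_cat == CAT_PARENT_CHILD
                and child_cand_cat in (CAT_SECOND_DEGREE, CAT_FULL_SIBLING)):
            labels[ids[xi]] = "grandparent"
            labels[child] = "grandchild"
            notes.append(f"nested sharing fraction {frac:.3f} through {parent}")
        elif frac is not None and frac < config.nested_fraction_min:
            ruled_out.append(f"{ids[xi]} grandparent of {child} via {parent}")
            scenarios.append(5)

    # --- opposite inheritance: avuncular candidate ----------------------
    regions = opposite_inheritance_regions(tracks, config)
    pinned_fs = constraints.get("full_siblings")
    s1s2_sibs = (cats[(0, 1)] == CAT_FULL_SIBLING
                 or (pinned_fs and set(pinned_fs) == {ids[0], ids[1]}))
    if regions:
        evidence.extend(regions)
        ruled_out.append(f"{ids[2]} grandparent of {ids[0]}/{ids[1]}")
        if s1s2_sibs:
            scenarios.append(2)
            labels[ids[2]] = "avuncular"
        elif cats[(0, 1)] in (CAT_SECOND_DEGREE,) or k2[(0, 1)] < config.anomaly_k_cutoff:
            scenarios.extend([1, 3])
            labels[ids[2]] = "avuncular"
            labels[ids[0]] = labels[ids[1]] = "half-sibling"

    # --- scenario 5: IBD2 where a unilineal relationship is claimed -----
    for p in PAIRS:
        if cats[p] == CAT_SECOND_DEGREE and k2[p] >= config.anomaly_k_cutoff:
            a, b = tracks.ids[p[0]], tracks.ids[p[1]]
            ruled_out.append(f"({a},{b}) unilineal half-sib/grandparent (IBD2 present)")
            if 5 not in scenarios:
                scenarios.append(5)

    # --- scenario 4: third/fourth-degree configurations -----------------
    second = [p for p in PAIRS if cats[p] == CAT_SECOND_DEGREE]
    distant = [p for p in PAIRS if cats[p].startswith("K1 [")]
    if len(second) == 2 and len(distant) == 1 and not regions:
        scenarios.append(4)
        notes.append("two second-degree plus one distant relationship; "
                     "pedigree set indistinguishable without opposite inheritance")

    indistinguishable = not labels
    if indistinguishable and not scenarios:
        notes.append("no discriminating sharing pattern; relationship types "
                     "indistinguishable from genetic data alone")
    return TriadVerdict(ids=ids, scenarios=sorted(set(scenarios)), labels=labels,
                        ruled_out=ruled_out, evidence=evidence,
                        indistinguishable=indistinguishable, note="; ".join(notes))


def verdict_frame(verdicts: list[TriadVerdict]) -> pd.DataFrame:
    return pd.DataFrame([{
        "s1": v.ids[0], "s2": v.ids[1], "candidate": v.ids[2],
        "scenarios": ",".join(map(str, v.scenarios)),
        "labels": ";".join(f"{k}={val}" for k, val in v.labels.items()),
        "ruled_out": ";".join(v.ruled_out),
        "evidence": ";".join(f"chr{r.chrom}:{r.start_bp}-{r.end_bp}" for r in v.evidence),
        "indistinguishable": v.indistinguishable,
        "note": v.note,
    } for v in verdicts])
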