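"""Gene-dropping pedigree simulator with ground-truth IBD.

Founder haplotypes are drawn under Hardy-Weinberg equilibrium from
per-marker allele frequencies and dropped through the pedigree one
meiosis at a time, with crossovers placed by a Haldane (no-interference)
model on a sex-averaged linear genetic map.  Every transmitted allele
keeps its founder-haplotype label, so the simulator can emit exact
per-pair IBD-state segments and per-individual autozygous segments —
the oracle against which the windowed estimators are validated.
Genotype error and missingness, when requested, are applied after the
truth labels are extracted, so robustness to noise is measurable.

The default genome approximates the human autosomes: 22 chromosomes,
~2,878 Mb, 1.25 cM/Mb (~3,597 cM).  The default marker count of
1,000,000 evenly spaced SNPs with Uniform(0.05, 0.95) allele
frequencies leaves an unrelated pair roughly 650,000 informative sites
— the density regime of a genome-wide SNP panel, where a
500-informative-SNP window spans a few megabases and second-degree IBD
segments are resolved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .genotype_io import NC, GenotypeTable
from .ibd import CottermanEstimate

#: human autosome lengths, Mb (rounded); total 2,878 Mb
HUMAN_AUTOSOME_MB: tuple[int, ...] = (
    249, 243, 198, 191, 181, 171, 159, 146, 141, 136, 135,
    134, 115, 107, 102, 90, 81, 78, 59, 63, 48, 51)

#: the 11 cohort group sizes used for comparison-count checks (total 1,397)
DEFAULT_GROUP_SIZES: dict[str, int] = {
    "ASW": 87, "CEU": 165, "CHB": 137, "CHD": 109, "GIH": 101, "JPT": 113,
    "LWK": 110, "MKK": 184, "MXL": 86, "TSI": 102, "YRI": 203}


class PedigreeError(ValueError):
    """Structurally invalid pedigree specification."""


@dataclass(frozen=True)
class PedigreeMember:
    id: str
    father: str | None = None
    mother: str | None = None
    group: str | None = None

    @property
    def is_founder(self) -> bool:
        return self.father is None and self.mother is None


@dataclass
class PedigreeSpec:
    """A pedigree as a list of members plus optional duplicate samples.

    Founders have no parents; every non-founder names exactly two
    parents present in the spec; the parent graph must be acyclic.
    ``duplicates`` maps a new sample id to an existing member whose
    genome it copies exactly (an MZ twin / re-genotyped aliquot).
    """

    members: list[PedigreeMember]
    duplicates: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        ids = [m.id for m in self.members]
        if len(set(ids)) != len(ids):
            raise PedigreeError("duplicate member ids")
        known = set(ids)
        g = nx.DiGraph()
        g.add_nodes_from(ids)
        for m in self.members:
            parents = (m.father, m.mother)
            if any(p is None for p in parents) != all(p is None for p in parents):
                raise PedigreeError(f"{m.id}: non-founders need both parents")
            for p in parents:
                if p is not None:
                    if p not in known:
                        raise PedigreeError(f"{m.id}: unknown parent {p}")
                    g.add_edge(p, m.id)
        if not nx.is_directed_acyclic_graph(g):
            raise PedigreeError("pedigree graph has a cycle")
        for dup, src in self.duplicates.items():
            if src not in known:
                raise PedigreeError(f"duplicate {dup}: unknown source {src}")
            if dup in known:
                raise PedigreeError(f"duplicate id {dup} collides with a member")

    @property
    def founders(self) -> list[str]:
        return [m.id for m in self.members if m.is_founder]

    @property
    def ids(self) -> list[str]:
        return [m.id for m in self.members] + list(self.duplicates)

    def topological_order(self) -> list[PedigreeMember]:
        index = {m.id: i for i, m in enumerate(self.members)}
        g = nx.DiGraph()
        g.add_nodes_from(index)
        for m in self.members:
            if not m.is_founder:
                g.add_edge(m.father, m.id)
                g.add_edge(m.mother, m.id)
        order = nx.lexicographical_topological_sort(g, key=lambda n: index[n])
        by_id = {m.id: m for m in self.members}
        return [by_id[n] for n in order]


@dataclass
class SimOptions:
    """Genome, marker and noise settings for one simulation."""

    chrom_lengths_mb: tuple[int, ...] = HUMAN_AUTOSOME_MB
    cm_per_mb: float = 1.25
    n_markers: int = 1_000_000
    freq_range: tuple[float, float] = (0.05, 0.95)
    error_rate: float = 0.0
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if any(l <= 0 for l in self.chrom_lengths_mb) or self.cm_per_mb <= 0:
            raise ValueError("chromosome lengths and map density must be positive")
        if self.n_markers < len(self.chrom_lengths_mb):
            raise ValueError("need at least one marker per chromosome")
        for name in ("error_rate", "missing_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")

    @property
    def n_chrom(self) -> int:
        return len(self.chrom_lengths_mb)


def _build_markers(opts: SimOptions) -> tuple[pd.DataFrame, np.ndarray]:
    """Evenly spaced markers per chromosome, allocated by physical length."""
    lengths_bp = np.asarray(opts.chrom_lengths_mb, dtype=np.int64) * 1_000_000
    share = lengths_bp / lengths_bp.sum()
    counts = np.maximum(1, np.round(share * opts.n_markers).astype(int))
    chroms, ids, cms, poss = [], [], [], []
    for c, (n, length) in enumerate(zip(counts, lengths_bp), start=1):
        step = length / n
        pos = (step / 2 + step * np.arange(n)).astype(np.int64) + 1
        chroms.append(np.full(n, c, dtype=np.int16))
        poss.append(pos)
        cms.append(pos * (opts.cm_per_mb / 1e6))
        ids.extend(f"m{c}_{j}" for j in range(n))
    markers = pd.DataFrame({
        "chrom": np.concatenate(chroms), "id": ids,
        "cm": np.concatenate(cms), "pos": np.concatenate(poss)})
    return markers, lengths_bp


class TruthIBD:
    """Simulator truth: founder-haplotype labels per individual.

    Exposes per-pair IBD-state tracks and segments, per-individual
    autozygosity, and bp-weighted true Cotterman fractions.  Segments
    tile each chromosome exactly, with boundaries at midpoints between
    markers of different state (chromosome ends close the first and
    last segments).
    """

    def __init__(self, markers: pd.DataFrame, chrom_lengths_bp: np.ndarray,
                 haplotypes: dict[str, np.ndarray]):
        self.markers = markers
        self.chrom_lengths_bp = chrom_lengths_bp
        self.haplotypes = haplotypes        # id -> (2, M) int32 founder-hap labels
        self._chrom = markers["chrom"].to_numpy()
        self._pos = markers["pos"].to_numpy()

    def ids(self) -> list[str]:
        return list(self.haplotypes)

    def _require(self, *ids: str) -> None:
        for i in ids:
            if i not in self.haplotypes:
                raise KeyError(f"unknown individual {i!r}")

    def pair_states(self, id1: str, id2: str) -> np.ndarray:
        """Per-marker true IBD state (0/1/2) for a pair."""
        self._require(id1, id2)
        a1, a2 = self.haplotypes[id1]
        b1, b2 = self.haplotypes[id2]
        m11, m12 = a1 == b1, a1 == b2
        m21, m22 = a2 == b1, a2 == b2
        ibd2 = (m11 & m22) | (m12 & m21)
        ibd1 = m11 | m12 | m21 | m22
        return (ibd1.astype(np.int8) + ibd2.astype(np.int8))

    def autozygous_mask(self, iid: str) -> np.ndarray:
        """True at markers where both haplotypes descend from one founder allele."""
        self._require(iid)
        h = self.haplotypes[iid]
        return h[0] == h[1]

    def _segments_from_states(self, states: np.ndarray) -> list[tuple[int, int, int, int]]:
        """(chrom, start_bp, end_bp, state) segments tiling every chromosome.

        State boundaries fall midway between adjacent markers of different
        state; the first and last segments extend to the chromosome ends.
        """
        out: list[tuple[int, int, int, int]] = []
        for c, length in enumerate(self.chrom_lengths_bp, start=1):
            sel = self._chrom == c
            st, pos = states[sel], self._pos[sel]
            if len(st) == 0:
                continue
            change = np.flatnonzero(np.diff(st)) + 1
            cuts = [int((pos[i - 1] + pos[i]) // 2) for i in change]
            edges = [1] + cuts + [int(length) + 1]
            idx0 = np.concatenate([[0], change])
            for j, i0 in enumerate(idx0):
                out.append((c, edges[j], edges[j + 1] - 1, int(st[i0])))
        return out

    def pair_segments(self, id1: str, id2: str) -> list[tuple[int, int, int, int]]:
        return self._segments_from_states(self.pair_states(id1, id2))

    def autozygous_segments(self, iid: str) -> list[tuple[int, int, int]]:
        segs = self._segments_from_states(self.autozygous_mask(iid).astype(np.int8))
        return [(c, s, e) for c, s, e, state in segs if state == 1]

    def autozygous_fraction(self, iid: str) -> float:
        segs = self.autozygous_segments(iid)
        return sum(e - s + 1 for _, s, e in segs) / float(self.chrom_lengths_bp.sum())


def true_cotterman(truth: TruthIBD, pair: tuple[str, str]) -> CottermanEstimate:
    """bp-weighted true IBD0/1/2 fractions for a pair."""
    segs = truth.pair_segments(*pair)
    total = float(truth.chrom_lengths_bp.sum())
    k = [0.0, 0.0, 0.0]
    for _, s, e, state in segs:
        k[state] += (e - s + 1) / total
    k[0] = 1.0 - k[1] - k[2]
    return CottermanEstimate(k0=k[0], k1=k[1], k2=k[2], n_windows=len(segs),
                             n_informative_sites=len(truth.markers))


def _meiosis(rng: np.random.Generator, haps: np.ndarray, chrom_slices: list[slice],
             cm_lengths: np.ndarray, chrom_lengths_bp: np.ndarray,
             pos: np.ndarray) -> np.ndarray:
    """One recombinant gamete: Haldane crossovers on each chromosome."""
    out = np.empty(haps.shape[1], dtype=haps.dtype)
    for sl, cm, length in zip(chrom_slices, cm_lengths, chrom_lengths_bp):
        n_xo = rng.poisson(cm / 100.0)
        current = int(rng.integers(2))
        if n_xo == 0:
            out[sl] = haps[current, sl]
            continue
        xo = np.sort(rng.uniform(0, length, n_xo))
        phase = (current + np.searchsorted(xo, pos[sl])) % 2
        out[sl] = np.where(phase == 0, haps[0, sl], haps[1, sl])
    return out


def gene_drop(ped: PedigreeSpec, opts: SimOptions,
              seed: int | np.random.SeedSequence = 0) -> tuple[GenotypeTable, TruthIBD]:
    """Drop founder genomes through the pedigree; return genotypes and truth."""
    rng = np.random.default_rng(seed)
    markers, chrom_lengths_bp = _build_markers(opts)
    m = len(markers)
    chrom_arr = markers["chrom"].to_numpy()
    pos = markers["pos"].to_numpy()
    chrom_ids = np.unique(chrom_arr)
    chrom_slices = []
    for c in chrom_ids:
        idx = np.flatnonzero(chrom_arr == c)
        chrom_slices.append(slice(int(idx[0]), int(idx[-1]) + 1))
    cm_lengths = np.asarray(opts.chrom_lengths_mb, dtype=float) * opts.cm_per_mb

    freqs = rng.uniform(*opts.freq_range, size=m)

    founders = ped.founders
    n_labels = 2 * len(founders)
    # per-haplotype B-allele indicator, drawn at the per-marker frequency
    founder_alleles = (rng.random((n_labels, m)) < freqs[None, :]).astype(np.uint8)

    haplotypes: dict[str, np.ndarray] = {}
    label = iter(range(n_labels))
    for member in ped.topological_order():
        if member.is_founder:
            h = np.empty((2, m), dtype=np.int32)
            h[0] = next(label)
            h[1] = next(label)
        else:
            h = np.empty((2, m), dtype=np.int32)
            h[0] = _meiosis(rng, haplotypes[member.father], chrom_slices,
                            cm_lengths, chrom_lengths_bp, pos)
            h[1] = _meiosis(rng, haplotypes[member.mother], chrom_slices,
                            cm_lengths, chrom_lengths_bp, pos)
        haplotypes[member.id] = h
    for dup, src in ped.duplicates.items():
        haplotypes[dup] = haplotypes[src]

    truth = TruthIBD(markers, chrom_lengths_bp, haplotypes)

    ids = ped.ids
    col = np.arange(m)
    calls = np.empty((len(ids), m), dtype=np.int8)
    for i, iid in enumerate(ids):
        h = haplotypes[iid]
        calls[i] = founder_alleles[h[0], col] + founder_alleles[h[1], col]
    # genotype code: #B-alleles carried (0=AA, 1=AB, 2=BB)

    if opts.error_rate > 0:
        err = rng.random(calls.shape) < opts.error_rate
        calls[err] = rng.integers(0, 3, size=int(err.sum()), dtype=np.int8)
    if opts.missing_rate > 0:
        calls[rng.random(calls.shape) < opts.missing_rate] = NC

    by_id = {mm.id: mm for mm in ped.members}
    rows = []
    for iid in ids:
        src = by_id.get(iid) or by_id[ped.duplicates[iid]]
        rows.append({"iid": iid, "fid": "SIM",
                     "father": (by_id[iid].father if iid in by_id else "0") or "0",
                     "mother": (by_id[iid].mother if iid in by_id else "0") or "0",
                     "sex": "0", "phenotype": "-9", "group": src.group})
    samples = pd.DataFrame(rows)
    table = GenotypeTable(samples=samples, markers=markers, calls=calls)
    return table, truth


# ---------------------------------------------------------------------------
# pedigree templates
# ---------------------------------------------------------------------------

def _ped(*members: tuple, duplicates: dict[str, str] | None = None) -> PedigreeSpec:
    return PedigreeSpec(
        members=[PedigreeMember(*mm) for mm in members],
        duplicates=duplicates or {})


def standard_pedigrees() -> dict[str, PedigreeSpec]:
    """Named pedigree templates covering the validated relationship types.

    Keys of interest: ``trio``; ``fullsib_quartet`` (sib pair S1/S2);
    ``halfsib_trio`` (H1/H2 share father F); ``halfsib_uncle`` (adds the
    shared father's full brother U — the avuncular candidate);
    ``halfsib_grandparent`` (adds the shared father's father GF);
    ``avuncular_fullsibs`` (uncle U vs full sibs S1/S2);
    ``grandparent_trio`` (GF, parent F, child C); ``avuncular_pair``
    (U vs single child C); ``first_cousins`` (C1/C2);
    ``inbred_trio`` (child I of first-cousin parents C1 x C2);
    ``mz_pair`` (founder A duplicated as A2).
    """
    peds: dict[str, PedigreeSpec] = {}
    peds["trio"] = _ped(("F",), ("M",), ("C", "F", "M"))
    peds["fullsib_quartet"] = _ped(("F",), ("M",), ("S1", "F", "M"), ("S2", "F", "M"))
    peds["halfsib_trio"] = _ped(("F",), ("M1",), ("M2",),
                                ("H1", "F", "M1"), ("H2", "F", "M2"))
    peds["halfsib_uncle"] = _ped(
        ("GF",), ("GM",), ("F", "GF", "GM"), ("U", "GF", "GM"),
        ("M1",), ("M2",), ("H1", "F", "M1"), ("H2", "F", "M2"))
    peds["halfsib_grandparent"] = _ped(
        ("GF",), ("GM",), ("F", "GF", "GM"),
        ("M1",), ("M2",), ("H1", "F", "M1"), ("H2", "F", "M2"))
    peds["avuncular_fullsibs"] = _ped(
        ("GF",), ("GM",), ("F", "GF", "GM"), ("U", "GF", "GM"),
        ("M",), ("S1", "F", "M"), ("S2", "F", "M"))
    peds["grandparent_trio"] = _ped(
        ("GF",), ("GM",), ("M",), ("F", "GF", "GM"), ("C", "F", "M"))
    peds["avuncular_pair"] = _ped(
        ("GF",), ("GM",), ("F", "GF", "GM"), ("U", "GF", "GM"),
        ("M",), ("C", "F", "M"))
    peds["first_cousins"] = _ped(
        ("GF",), ("GM",), ("P1", "GF", "GM"), ("P2", "GF", "GM"),
        ("S1",), ("S2",), ("C1", "P1", "S1"), ("C2", "P2", "S2"))
    peds["inbred_trio"] = _ped(
        ("GF",), ("GM",), ("P1", "GF", "GM"), ("P2", "GF", "GM"),
        ("S1",), ("S2",), ("C1", "P1", "S1"), ("C2", "P2", "S2"),
        ("I", "C1", "C2"))
    peds["mz_pair"] = _ped(("A",), duplicates={"A2": "A"})
    return peds


def cohort_pedigree(group_sizes: dict[str, int] | None = None) -> PedigreeSpec:
    """A multi-group cohort of unrelated founders with group labels."""
    sizes = group_sizes or DEFAULT_GROUP_SIZES
    members = []
    for group, n in sizes.items():
        for i in range(n):
            members.append(PedigreeMember(id=f"{group}_{i:04d}", group=group))
    return PedigreeSpec(members=members)


def truth_segments_frame(truth: TruthIBD, pairs: list[tuple[str, str]]) -> pd.DataFrame:
    """True pair IBD segments as a TSV-ready frame."""
    rows = []
    for a, b in pairs:
        for chrom, s, e, state in truth.pair_segments(a, b):
            rows.append({"iid1": a, "iid2": b, "chrom": chrom, "start_bp": s,
                         "end_bp": e, "state": state,
                         "size_mb": round((e - s + 1) / 1e6, 3)})
    return pd.DataFrame(rows)


def autozygosity_frame(truth: TruthIBD, ids: list[str]) -> pd.DataFrame:
    """True autozygous segments per individual as a TSV-ready frame."""
    rows = []
    for iid in ids:
        for chrom, s, e in truth.autozygous_segments(iid):
            rows.append({"iid": iid, "chrom": chrom, "start_bp": s, "end_bp": e,
                         "size_mb": round((e - s + 1) / 1e6, 3)})
    return pd.DataFrame(rows)
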