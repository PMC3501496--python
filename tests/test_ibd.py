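"""Windowing, IBD classification, Cotterman estimates and segments."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ibdkit.genotype_io import AB
from ibdkit.ibd import (IBD_0, IBD_1, IBD_2, CottermanEstimate,
                        InsufficientInformativeSites, Window, analyze_pair,
                        extract_segments, make_windows,
                        relatedness_coefficient)
from ibdkit.simulate import (SimOptions, gene_drop, standard_pedigrees,
                             true_cotterman)

from conftest import make_table


def _markers(chroms, positions):
    return pd.DataFrame({"chrom": np.asarray(chroms, dtype=np.int16),
                         "id": [f"m{i}" for i in range(len(chroms))],
                         "cm": np.asarray(positions) / 1e6,
                         "pos": np.asarray(positions, dtype=np.int64)})


class TestMakeWindows:
    @pytest.mark.parametrize("n, sizes", [
        (1250, [500, 500, 250]),     # trailing 250 >= half window: stands alone
        (1100, [500, 600]),          # trailing 100 < 250: merges backward
        (400, [400]),                # single short run stands alone
        (500, [500]),
    ])
    def test_trailing_rule(self, n, sizes, cfg):
        markers = _markers([1] * n, np.arange(1, n + 1) * 1000)
        ws = make_windows(np.arange(n), markers, cfg)
        assert [w.n_informative for w in ws] == sizes

    def test_windows_never_span_chromosomes(self, cfg):
        n = 700
        markers = _markers([1] * 300 + [2] * 400,
                           list(np.arange(1, 301) * 1000) + list(np.arange(1, 401) * 1000))
        ws = make_windows(np.arange(n), markers, cfg)
        assert [(w.chrom, w.n_informative) for w in ws] == [(1, 300), (2, 400)]

    def test_bp_bounds_tile_the_informative_extent(self, cfg):
        n = 1250
        pos = np.arange(1, n + 1) * 1000
        ws = make_windows(np.arange(n), _markers([1] * n, pos), cfg)
        for a, b in zip(ws[:-1], ws[1:]):
            assert b.start_bp == a.end_bp + 1
        assert ws[0].start_bp == 1000 and ws[-1].end_bp == n * 1000


class TestClassifyWindow:
    @pytest.mark.parametrize("counts, state", [
        ((0, 212, 288), IBD_1),
        ((0, 0, 500), IBD_2),
        ((41, 310, 149), IBD_0),     # IBS0 fraction 8.2%: unrelated-level
        ((0, 333, 167), IBD_1),      # analytic IBD1 composition (2/3 IBS1)
        ((2, 0, 498), IBD_2),        # tolerates sporadic IBS0 from genotype error
    ])
    def test_examples(self, counts, state, cfg):
        from ibdkit.ibd import classify_window
        w = Window(chrom=1, start_bp=1, end_bp=2, first_marker=0, last_marker=0,
                   n_informative=sum(counts), n_ibs0=counts[0], n_ibs1=counts[1],
                   n_ibs2_star=counts[2])
        assert classify_window(w, cfg) == state


def _brute_segments(states, chroms):
    """Independent oracle: enumerate maximal equal-state same-chromosome runs."""
    runs = []
    for i, (s, c) in enumerate(zip(states, chroms)):
        if runs and runs[-1][0] == s and runs[-1][1] == c:
            runs[-1][2].append(i)
        else:
            runs.append((s, c, [i]))
    return [(s, c, idx[0], idx[-1]) for s, c, idx in runs]


class TestExtractSegments:
    def _windows(self, chroms):
        return [Window(chrom=c, start_bp=1000 * i + 1, end_bp=1000 * (i + 1),
                       first_marker=i, last_marker=i, n_informative=1)
                for i, c in enumerate(chroms)]

    @pytest.mark.parametrize("states, chroms, expected", [
        ([1, 1, 1, 0, 0], [1] * 5, [(1, 3), (0, 2)]),
        ([1, 0, 1], [1] * 3, [(1, 1), (0, 1), (1, 1)]),
        ([1, 1], [1, 2], [(1, 1), (1, 1)]),   # chromosome boundary splits
    ])
    def test_examples(self, states, chroms, expected):
        segs = extract_segments(np.array(states), self._windows(chroms))
        assert [(s.state, s.n_windows) for s in segs] == expected

    @given(st.lists(st.tuples(st.integers(0, 2), st.integers(1, 2)),
                    min_size=1, max_size=9))
    def test_matches_brute_force_oracle(self, rows):
        states = np.array([s for s, _ in rows])
        chroms = sorted(c for _, c in rows)
        segs = extract_segments(states, self._windows(chroms))
        brute = _brute_segments(states.tolist(), chroms)
        assert [(s.state, s.chrom, s.n_windows) for s in segs] == \
            [(s, c, j - i + 1) for s, c, i, j in brute]

    def test_size_mb(self):
        segs = extract_segments(np.array([1]), self._windows([1]))
        assert segs[0].size_mb == pytest.approx(1000 / 1e6)


@pytest.mark.parametrize("k, r", [((0, 1, 0), 0.5), ((0, 0, 1), 1.0),
                                  ((1, 0, 0), 0.0), ((0.25, 0.5, 0.25), 0.5)])
def test_relatedness_coefficient(k, r):
    est = CottermanEstimate(k0=k[0], k1=k[1], k2=k[2], n_windows=1,
                            n_informative_sites=500)
    assert relatedness_coefficient(est) == pytest.approx(r)


def test_conservation_enforced():
    with pytest.raises(ValueError, match="expected 1"):
        CottermanEstimate(k0=0.5, k1=0.2, k2=0.2, n_windows=1,
                          n_informative_sites=1)


class TestEstimates:
    """Windowed estimates against gene-drop truth."""

    def test_mz_duplicate_is_all_ibd2(self, cfg, peds, fast_opts):
        table, _ = gene_drop(peds["mz_pair"], fast_opts, seed=3)
        est = analyze_pair(table.calls_for("A"), table.calls_for("A2"),
                           table.markers, cfg).estimate
        assert (est.k0, est.k1, est.k2) == (0.0, 0.0, 1.0)

    def test_parent_child_is_all_ibd1(self, cfg, peds, fast_opts):
        table, _ = gene_drop(peds["trio"], fast_opts, seed=6)
        est = analyze_pair(table.calls_for("M"), table.calls_for("C"),
                           table.markers, cfg).estimate
        assert (est.k0, est.k1, est.k2) == (0.0, 1.0, 0.0)

    def test_symmetry_and_conservation(self, cfg, peds, fast_opts):
        table, _ = gene_drop(peds["halfsib_trio"], fast_opts, seed=8)
        a, b = table.calls_for("H1"), table.calls_for("H2")
        e1 = analyze_pair(a, b, table.markers, cfg).estimate
        e2 = analyze_pair(b, a, table.markers, cfg).estimate
        assert (e1.k0, e1.k1, e1.k2) == (e2.k0, e2.k1, e2.k2)
        assert e1.k0 + e1.k1 + e1.k2 == pytest.approx(1.0, abs=1e-12)

    def test_parameter_recovery_within_tolerance(self, cfg, peds):
        """|estimated k_i - truth k_i| <= 0.02 at the default genome scale."""
        for name, pair, seed in [("halfsib_trio", ("H1", "H2"), 17),
                                 ("fullsib_quartet", ("S1", "S2"), 18)]:
            table, truth = gene_drop(peds[name], SimOptions(), seed=seed)
            est = analyze_pair(table.calls_for(pair[0]), table.calls_for(pair[1]),
                               table.markers, cfg).estimate
            tru = true_cotterman(truth, pair)
            for e, t in [(est.k0, tru.k0), (est.k1, tru.k1), (est.k2, tru.k2)]:
                assert abs(e - t) <= 0.02

    def test_halfsib_segments_jaccard_against_truth(self, cfg, peds):
        """Extracted IBD1 segments overlap truth with bp Jaccard >= 0.9."""
        table, truth = gene_drop(peds["halfsib_trio"], SimOptions(), seed=5)
        res = analyze_pair(table.calls_for("H1"), table.calls_for("H2"),
                           table.markers, cfg, pair=("H1", "H2"))
        est = [(s.chrom, s.start_bp, s.end_bp) for s in res.segments if s.state == IBD_1]
        tru = [(c, s, e) for c, s, e, st_ in truth.pair_segments("H1", "H2") if st_ == 1]
        inter = sum(max(0, min(e1, e2) - max(s1, s2) + 1)
                    for c1, s1, e1 in est for c2, s2, e2 in tru if c1 == c2)
        union = (sum(e - s + 1 for _, s, e in est)
                 + sum(e - s + 1 for _, s, e in tru) - inter)
        assert inter / union >= 0.9

    def test_hemizygous_deletion_artifact_inflates_k0(self, cfg, peds):
        """A long run without heterozygous calls in one member of a
        parent-child pair (a miscalled hemizygous deletion) produces
        spurious K0 — direction only."""
        opts = SimOptions(n_markers=200_000)
        table, truth = gene_drop(peds["trio"], opts, seed=31)
        child = table.calls_for("C").copy()
        father = table.calls_for("F")
        markers = table.markers
        base = analyze_pair(father, child, markers, cfg).estimate
        assert base.k0 == 0.0
        # drop the paternal allele over a 40 Mb stretch of chromosome 1:
        # the child's calls become homozygous for the maternal allele
        sel = ((markers["chrom"] == 1) & (markers["pos"] > 2e7)
               & (markers["pos"] < 6e7)).to_numpy()
        # a hemizygous child shows only one allele; callers report it as a
        # homozygote, so heterozygous calls vanish into random homozygotes
        rng = np.random.default_rng(0)
        hets = sel & (child == AB)
        child[hets] = np.where(rng.random(hets.sum()) < 0.5, 0, 2)
        est = analyze_pair(father, child, markers, cfg).estimate
        assert est.k0 > 0.0

    def test_estimate_cotterman_matches_full_analysis(self, cfg, peds, fast_opts):
        from ibdkit.ibd import estimate_cotterman
        from ibdkit.ibs import pair_ibs
        table, _ = gene_drop(peds["fullsib_quartet"], fast_opts, seed=4)
        ibs = pair_ibs(table.calls_for("S1"), table.calls_for("S2"))
        e1 = estimate_cotterman(ibs, table.markers, cfg)
        e2 = analyze_pair(table.calls_for("S1"), table.calls_for("S2"),
                          table.markers, cfg).estimate
        assert (e1.k0, e1.k1, e1.k2) == (e2.k0, e2.k1, e2.k2)

    def test_insufficient_sites_raises(self, cfg):
        t = make_table([[0, 0], [0, 0]])   # all concordant homozygotes
        with pytest.raises(InsufficientInformativeSites):
            analyze_pair(t.calls[0], t.calls[1], t.markers, cfg)
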