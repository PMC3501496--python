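"""Triad tracks, opposite inheritance, nested sharing, scenario logic."""

import numpy as np
import pytest

from ibdkit.ibd import IBD_0, IBD_2, CottermanEstimate, Window
from ibdkit.simulate import SimOptions, gene_drop
from ibdkit.triads import (NoSharedInformativeSites, TriadTracks,
                           build_triad_tracks, classify_triad,
                           nested_sharing_fraction,
                           opposite_inheritance_regions)


def _tracks(s12, s1c, s2c, ids=("s1", "s2", "c"), span=1000):
    n = len(s12)
    windows = [Window(chrom=1, start_bp=i * span + 1, end_bp=(i + 1) * span,
                      first_marker=i, last_marker=i, n_informative=500)
               for i in range(n)]

    def est(states):
        states = np.asarray(states)
        k = [float((states == s).mean()) for s in (0, 1, 2)]
        k[0] = 1 - k[1] - k[2]
        return CottermanEstimate(k0=k[0], k1=k[1], k2=k[2], n_windows=n,
                                 n_informative_sites=500 * n)

    return TriadTracks(
        ids=ids, windows=windows,
        states={(0, 1): np.asarray(s12, dtype=np.int8),
                (0, 2): np.asarray(s1c, dtype=np.int8),
                (1, 2): np.asarray(s2c, dtype=np.int8)},
        estimates={(0, 1): est(s12), (0, 2): est(s1c), (1, 2): est(s2c)})


class TestOppositeInheritance:
    def test_hand_built_region(self, cfg):
        t = _tracks([0, 0, 0], [1, 1, 1], [1, 1, 1])
        regions = opposite_inheritance_regions(t, cfg)
        assert len(regions) == 1 and regions[0].n_windows == 3

    def test_short_run_ignored(self, cfg):
        t = _tracks([0, 0, 1], [1, 1, 1], [1, 1, 1])
        assert opposite_inheritance_regions(t, cfg) == []

    def test_requires_both_candidates_ibd1(self, cfg):
        t = _tracks([0, 0, 0], [1, 1, 1], [0, 0, 0])
        assert opposite_inheritance_regions(t, cfg) == []


class TestNestedSharing:
    def test_fraction_values(self):
        conduit = np.array([1, 1, 2, 0, 1])
        cand = np.array([1, 0, 1, 1, 0])
        # cand IBD1 windows 0,2,3; conduit IBD>=1 at 0,2 -> 2/3
        assert nested_sharing_fraction(conduit, cand) == pytest.approx(2 / 3)

    def test_undefined_without_cand_ibd1(self):
        assert nested_sharing_fraction(np.array([1, 1]), np.array([0, 2])) is None


class TestSimulatedTriads:
    OPTS = SimOptions(n_markers=400_000)

    def test_mz_triplets_all_ibd2(self, cfg, peds):
        from ibdkit.simulate import PedigreeMember, PedigreeSpec
        ped = PedigreeSpec(members=[PedigreeMember("A")],
                           duplicates={"B": "A", "C": "A"})
        table, _ = gene_drop(ped, SimOptions(n_markers=60_000), seed=3)
        tracks = build_triad_tracks(table, "A", "B", "C", cfg)
        for key in ((0, 1), (0, 2), (1, 2)):
            assert (tracks.states[key] == IBD_2).all()

    def test_unrelated_trio_all_ibd0(self, cfg):
        from ibdkit.simulate import cohort_pedigree
        table, _ = gene_drop(cohort_pedigree({"G": 3}),
                             SimOptions(n_markers=60_000), seed=5)
        a, b, c = table.sample_ids
        tracks = build_triad_tracks(table, a, b, c, cfg)
        for key in ((0, 1), (0, 2), (1, 2)):
            assert (tracks.states[key] == IBD_0).all()

    def test_tracks_match_truth_states(self, cfg, peds):
        """Window states agree with the truth majority state in >=95% of
        windows for a half-sib + uncle triad."""
        table, truth = gene_drop(peds["halfsib_uncle"], self.OPTS, seed=11)
        tracks = build_triad_tracks(table, "H1", "H2", "U", cfg)
        pos = table.markers["pos"].to_numpy()
        chrom = table.markers["chrom"].to_numpy()
        for key, pair in [((0, 1), ("H1", "H2")), ((0, 2), ("H1", "U")),
                          ((1, 2), ("H2", "U"))]:
            ts = truth.pair_states(*pair)
            agree = 0
            for i, w in enumerate(tracks.windows):
                sel = (chrom == w.chrom) & (pos >= w.start_bp) & (pos <= w.end_bp)
                maj = np.bincount(ts[sel], minlength=3).argmax()
                agree += tracks.states[key][i] == maj
            assert agree / len(tracks.windows) >= 0.95

    def test_halfsib_uncle_scenario1(self, cfg, peds):
        table, _ = gene_drop(peds["halfsib_uncle"], self.OPTS, seed=11)
        tracks = build_triad_tracks(table, "H1", "H2", "U", cfg)
        v = classify_triad(tracks, cfg)
        assert 1 in v.scenarios and 3 in v.scenarios
        assert v.labels["U"] == "avuncular"
        assert v.labels["H1"] == v.labels["H2"] == "half-sibling"
        assert v.evidence and not v.indistinguishable

    def test_swap_invariance(self, cfg, peds):
        table, _ = gene_drop(peds["halfsib_uncle"], self.OPTS, seed=12)
        t1 = build_triad_tracks(table, "H1", "H2", "U", cfg)
        t2 = build_triad_tracks(table, "H2", "H1", "U", cfg)
        v1, v2 = classify_triad(t1, cfg), classify_triad(t2, cfg)
        assert v1.scenarios == v2.scenarios and v1.labels == v2.labels

    def test_fullsib_uncle_scenario2(self, cfg, peds):
        table, _ = gene_drop(peds["avuncular_fullsibs"], self.OPTS, seed=13)
        tracks = build_triad_tracks(table, "S1", "S2", "U", cfg)
        v = classify_triad(tracks, cfg, constraints={"full_siblings": ("S1", "S2")})
        assert 2 in v.scenarios and v.labels["U"] == "avuncular"

    def test_grandparent_never_shows_opposite_inheritance(self, cfg, peds):
        """A single grandparent cannot be IBD1 to both half-sibs where they
        are IBD0 — error-free replicates yield no opposite regions."""
        for seed in (11, 12, 13):
            table, _ = gene_drop(peds["halfsib_grandparent"], self.OPTS, seed=seed)
            tracks = build_triad_tracks(table, "H1", "H2", "GF", cfg)
            assert opposite_inheritance_regions(tracks, cfg) == []

    def test_grandparent_supported_by_nested_sharing(self, cfg, peds):
        table, _ = gene_drop(peds["grandparent_trio"], self.OPTS, seed=2)
        tracks = build_triad_tracks(table, "C", "F", "GF", cfg)
        v = classify_triad(tracks, cfg, constraints={"parent_child": ("F", "C")})
        assert v.labels.get("GF") == "grandparent"
        frac = nested_sharing_fraction(tracks.track(1, 2), tracks.track(0, 2))
        assert frac == pytest.approx(1.0)

    def test_fourth_degree_indistinguishable(self, cfg):
        """Two second-degree links plus one distant link with no opposite
        inheritance: the pedigree set cannot be resolved."""
        s12 = ([1] * 4 + [0] * 4) * 25                  # K1 = 0.5, 20 Mb runs
        s1c = ([0] * 2 + [1] * 4 + [0] * 2) * 25        # K1 = 0.5, 20 Mb runs
        s2c = ([1] * 3 + [0] * 22) * 8                  # K1 = 0.12, 15 Mb runs
        t = _tracks(s12, s1c, s2c, span=5_000_000)
        v = classify_triad(t, cfg)
        assert 4 in v.scenarios
        assert v.indistinguishable

    def test_constraint_outside_triad_rejected(self, cfg):
        t = _tracks([0], [0], [0])
        with pytest.raises(ValueError, match="outside the triad"):
            classify_triad(t, cfg, constraints={"parent_child": ("x", "y")})

    def test_no_informative_sites_raises(self, cfg):
        from conftest import make_table
        t = make_table(np.zeros((3, 10)), ids=["a", "b", "c"])
        with pytest.raises(NoSharedInformativeSites):
            build_triad_tracks(t, "a", "b", "c", cfg)
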