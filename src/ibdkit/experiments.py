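"""Replicated simulation experiments for estimator validation.

Each experiment gene-drops a pedigree template at the default genome
scale (22 autosomes, ~2,878 Mb / ~3,597 cM, 1,000,000 markers), runs
the windowed Cotterman estimator with default settings, and collects
per-replicate results.  Replicate ``i`` draws its random stream from
``SeedSequence([base_seed, i])`` so experiments are reproducible and
replicates independent.
"""

from __future__ import annotations

import numpy as np

from .config import AnalysisConfig
from .ibd import analyze_pair
from .simulate import SimOptions, gene_drop, standard_pedigrees

#: (template, pair) per second-degree relationship type
SECOND_DEGREE_TEMPLATES = (
    ("halfsib_trio", ("H1", "H2")),
    ("grandparent_trio", ("GF", "C")),
    ("avuncular_pair", ("U", "C")),
)


def _estimate(template: str, pair: tuple[str, str], seed,
              opts: SimOptions, config: AnalysisConfig):
    table, _ = gene_drop(standard_pedigrees()[template], opts, seed=seed)
    return analyze_pair(table.calls_for(pair[0]), table.calls_for(pair[1]),
                        table.markers, config, pair=pair).estimate


def pair_k_estimate(template: str, pair: tuple[str, str], seed: int,
                    opts: SimOptions | None = None,
                    config: AnalysisConfig | None = None) -> tuple[float, float, float]:
    """One simulated pair's estimated (K0, K1, K2)."""
    est = _estimate(template, pair, seed, opts or SimOptions(),
                    config or AnalysisConfig())
    return est.k0, est.k1, est.k2


def fullsib_k_experiment(n_pairs: int, base_seed: int,
                         opts: SimOptions | None = None,
                         config: AnalysisConfig | None = None) -> np.ndarray:
    """Estimated (K0, K1, K2) for ``n_pairs`` independent full-sib pairs."""
    opts = opts or SimOptions()
    config = config or AnalysisConfig()
    out = np.empty((n_pairs, 3))
    for i in range(n_pairs):
        est = _estimate("fullsib_quartet", ("S1", "S2"),
                        np.random.SeedSequence([base_seed, i]), opts, config)
        out[i] = (est.k0, est.k1, est.k2)
    return out


def second_degree_k_experiment(n_pairs: int, base_seed: int,
                               opts: SimOptions | None = None,
                               config: AnalysisConfig | None = None) -> np.ndarray:
    """Estimated (K0, K1, K2) for a mix of half-sib, grandparent-grandchild
    and avuncular pairs (templates cycled)."""
    opts = opts or SimOptions()
    config = config or AnalysisConfig()
    out = np.empty((n_pairs, 3))
    for i in range(n_pairs):
        template, pair = SECOND_DEGREE_TEMPLATES[i % len(SECOND_DEGREE_TEMPLATES)]
        est = _estimate(template, pair, np.random.SeedSequence([base_seed, i]),
                        opts, config)
        out[i] = (est.k0, est.k1, est.k2)
    return out


def inbred_roh_fractions(n_children: int, base_seed: int,
                         opts: SimOptions | None = None,
                         config: AnalysisConfig | None = None) -> np.ndarray:
    """Detected-ROH genome fraction for children of first-cousin parents.

    The expectation is the inbreeding coefficient F = 1/16, minus the
    small share of autozygous bp in segments below the reporting
    thresholds.
    """
    from .roh import detect_roh

    opts = opts or SimOptions()
    config = config or AnalysisConfig()
    ped = standard_pedigrees()["inbred_trio"]
    genome_bp = sum(opts.chrom_lengths_mb) * 1e6
    out = np.empty(n_children)
    for i in range(n_children):
        table, _ = gene_drop(ped, opts, seed=np.random.SeedSequence([base_seed, i]))
        regions = detect_roh(table.calls_for("I"), table.markers, config, "I")
        out[i] = sum(r.stop_bp - r.start_bp + 1 for r in regions) / genome_bp
    return out


def grandparent_opposite_region_counts(n_replicates: int, base_seed: int,
                                       opts: SimOptions | None = None,
                                       config: AnalysisConfig | None = None) -> np.ndarray:
    """Opposite-inheritance region counts for half-sib + grandparent triads
    (the logical expectation is zero in every error-free replicate)."""
    from .triads import build_triad_tracks, opposite_inheritance_regions

    opts = opts or SimOptions()
    config = config or AnalysisConfig()
    ped = standard_pedigrees()["halfsib_grandparent"]
    out = np.empty(n_replicates, dtype=int)
    for i in range(n_replicates):
        table, _ = gene_drop(ped, opts, seed=np.random.SeedSequence([base_seed, i]))
        tracks = build_triad_tracks(table, "H1", "H2", "GF", config)
        out[i] = len(opposite_inheritance_regions(tracks, config))
    return out
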