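"""Per-marker identity-by-state classification for a pair of samples.

At each marker a pair of biallelic calls is in one of five states:

* ``IBS0`` — opposite homozygotes (AA/BB),
* ``IBS1`` — one shared allele state (hom/het in either order),
* ``IBS2_HOM`` — identical homozygotes (a *concordant homozygote*),
* ``IBS2_STAR`` — both heterozygous (AB/AB),
* ``MISSING`` — either call is NC.

Concordant homozygotes carry no information about descent sharing (two
unrelated people are often both AA at a common allele), so the
*informative* sites are IBS0, IBS1 and IBS2*; downstream windowing runs
on those only.  For two independent Hardy-Weinberg genotypes at allele
frequency p, P(IBS2*) = 4p²q² and P(IBS0) = 2p²q², so the ratio
IBS2*/(IBS0+IBS2*) is 2/3 for unrelated pairs regardless of frequency —
the calibration point of the IBS2*_ratio statistic.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np

from .genotype_io import AA, AB, BB, NC

MISSING: int = -1
IBS0: int = 0
IBS1: int = 1
IBS2_HOM: int = 2
IBS2_STAR: int = 3

STATE_NAMES = {MISSING: "MISSING", IBS0: "IBS0", IBS1: "IBS1",
               IBS2_HOM: "IBS2_HOM", IBS2_STAR: "IBS2_STAR"}

#: states that inform IBD inference
_INFORMATIVE = (IBS0, IBS1, IBS2_STAR)


@dataclass
class PairIBS:
    """Per-marker IBS state track for one pair of samples."""

    pair: tuple[str, str]
    states: np.ndarray  # int8, one state per marker

    @cached_property
    def counts(self) -> dict[int, int]:
        """Tally of markers per state; sums to the marker count."""
        vals, cnt = np.unique(self.states, return_counts=True)
        out = {s: 0 for s in STATE_NAMES}
        out.update(dict(zip(vals.tolist(), cnt.tolist())))
        return out

    @cached_property
    def informative_mask(self) -> np.ndarray:
        """True where the state is IBS0, IBS1 or IBS2*."""
        s = self.states
        return (s == IBS0) | (s == IBS1) | (s == IBS2_STAR)

    @property
    def n_markers(self) -> int:
        return len(self.states)


def pair_ibs(calls_a: np.ndarray, calls_b: np.ndarray,
             pair: tuple[str, str] = ("a", "b")) -> PairIBS:
    """Classify every marker of an aligned call-vector pair into an IBS state."""
    a = np.asarray(calls_a, dtype=np.int8)
    b = np.asarray(calls_b, dtype=np.int8)
    if a.shape != b.shape:
        raise ValueError(
            f"call vectors differ in length: {a.shape[0]} vs {b.shape[0]}")

    missing = (a == NC) | (b == NC)
    both_het = (a == AB) & (b == AB)
    opposite_hom = ((a == AA) & (b == BB)) | ((a == BB) & (b == AA))
    concordant_hom = (a == b) & (a != AB) & ~missing

    states = np.full(a.shape, IBS1, dtype=np.int8)
    states[opposite_hom] = IBS0
    states[concordant_hom] = IBS2_HOM
    states[both_het] = IBS2_STAR
    states[missing] = MISSING
    return PairIBS(pair=tuple(pair), states=states)


def informative_sites(ibs: PairIBS) -> np.ndarray:
    """Indices of informative markers (IBS0/IBS1/IBS2*), in marker order."""
    return np.flatnonzero(ibs.informative_mask)


def ibs2star_ratio(ibs: PairIBS) -> float | None:
    """IBS2*/(IBS0+IBS2*); ``None`` when the denominator is zero.

    2/3 is the expectation for unrelated pairs; values above it indicate
    excess heterozygote concordance, i.e. descent sharing.
    """
    c = ibs.counts
    denom = c[IBS0] + c[IBS2_STAR]
    if denom == 0:
        return None
    return c[IBS2_STAR] / denom


def ibs_track_frame(ibs: PairIBS, markers) -> "pd.DataFrame":
    """BED-like per-marker IBS state track (chrom, start, end, state)."""
    import pandas as pd

    return pd.DataFrame({
        "chrom": markers["chrom"].to_numpy(),
        "start": markers["pos"].to_numpy(),
        "end": markers["pos"].to_numpy(),
        "state": [STATE_NAMES[s] for s in ibs.states],
    })
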