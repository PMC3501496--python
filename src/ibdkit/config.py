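"""Analysis configuration.

Every threshold used by the pipeline is a named field with the published
default, so a run can be reproduced from its manifest alone.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass
class AnalysisConfig:
    """Thresholds and sizes for the relatedness-audit pipeline.

    Defaults follow the published procedure: 500-informative-SNP windows,
    a K1 relatedness cutoff of 0.025, anomaly cutoffs of 0.001 on K0/K2,
    confirmation by an IBS0-free segment of at least 10 Mb, and minimal
    runs of homozygosity of 2 Mb and 400 SNPs.
    """

    #: number of informative SNPs per IBD-classification window
    window_size: int = 500
    #: window is IBD>=1 iff its IBS0 fraction (among informative sites) is below this.
    #: An IBD0 region has IBS0 fraction ~0.11 among informative sites; 0.06 sits at the
    #: bp-majority midpoint for windows straddling an IBD0/IBD1 breakpoint.
    window_ibs0_frac_tol: float = 0.06
    #: window is IBD2 (given IBD>=1) iff its IBS1 fraction is below this.
    #: An IBD1 region has IBS1 fraction exactly 2/3 among informative sites and 1.5x the
    #: informative density of an IBD2 region; 0.40 = (2/3)*1.5/2.5 is the bp-majority midpoint.
    window_ibs1_frac_tol: float = 0.40
    #: minimum per-pair informative sites in a shared-grid window to classify it directly
    min_window_informative: int = 25

    #: pairs with K1 at or above this are candidate relatives
    k1_related_cutoff: float = 0.025
    #: unexpected K0/K2 sharing at or above this is flagged
    anomaly_k_cutoff: float = 0.001
    #: candidate relationships are confirmed by an IBD1/IBD2 segment at least this long
    confirm_segment_min_mb: float = 10.0

    # relationship category boundaries
    identical_k2_min: float = 0.95
    pc_k1_min: float = 0.95
    pc_k2_max: float = 0.05
    sib_k1_min: float = 0.38
    sib_k1_max: float = 0.62
    sib_k2_min: float = 0.05
    second_k1_min: float = 0.35
    second_k1_max: float = 0.70
    #: lower edges of the residual half-open K1 bins, descending
    k1_bin_edges: tuple[float, ...] = (0.30, 0.20, 0.10, 0.025)

    # runs of homozygosity
    roh_min_mb: float = 2.0
    roh_min_snps: int = 400
    #: split a run where consecutive homozygous SNPs are farther apart than this
    roh_gap_max_mb: float = 1.0
    #: heterozygous calls tolerated inside one reported region (0 = strict)
    roh_het_tolerance: int = 0

    #: child-ROH x parental-IBD1 overlap must reach this to count as autozygous
    autozygosity_min_overlap_mb: float = 1.0

    # triad reconstruction
    min_opposite_windows: int = 3
    nested_fraction_min: float = 0.95

    random_seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        positive = (
            "window_size", "confirm_segment_min_mb", "roh_min_mb", "roh_min_snps",
            "roh_gap_max_mb", "autozygosity_min_overlap_mb", "min_opposite_windows",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("k1_related_cutoff", "anomaly_k_cutoff", "window_ibs0_frac_tol",
                     "window_ibs1_frac_tol", "nested_fraction_min"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.roh_het_tolerance < 0:
            raise ValueError("roh_het_tolerance must be >= 0")
        if tuple(sorted(self.k1_bin_edges, reverse=True)) != tuple(self.k1_bin_edges):
            raise ValueError("k1_bin_edges must be descending")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["k1_bin_edges"] = list(self.k1_bin_edges)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "k1_bin_edges" in d:
            d = dict(d, k1_bin_edges=tuple(d["k1_bin_edges"]))
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        """Load from a YAML or JSON mapping of field names to values."""
        text = Path(path).read_text()
        data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        return cls.from_dict(data)
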