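"""PLINK-style text genotype IO and autosome filtering.

Genotypes are held as small-integer call codes on an ordered autosomal
marker map:

* ``AA = 0`` — homozygous for the per-marker A allele,
* ``AB = 1`` — heterozygous,
* ``BB = 2`` — homozygous for the B allele,
* ``NC = -1`` — no call (missing).

The A allele at each marker is the lexicographically smaller of the
observed non-zero alleles, which makes the encoding deterministic; all
downstream identity-by-state logic is invariant to the choice.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

AA: int = 0
AB: int = 1
BB: int = 2
NC: int = -1

#: non-autosomal chromosome codes in PLINK's numeric dialect
_LETTER_CHROM = {"X": 23, "Y": 24, "XY": 25, "MT": 26, "M": 26}
MAX_AUTOSOME = 22


class GenotypeFormatError(ValueError):
    """Malformed ped/map input."""


class TriallelicMarkerError(GenotypeFormatError):
    """More than two distinct non-zero alleles observed at one marker."""


class NoAutosomalMarkersError(ValueError):
    """Autosome filtering removed every marker."""


def parse_chrom(label: str) -> int:
    """Parse a chromosome label in numeric (1-26) or letter (X/Y/XY/MT) dialect."""
    label = str(label).strip().upper()
    if label in _LETTER_CHROM:
        return _LETTER_CHROM[label]
    try:
        value = int(label)
    except ValueError:
        raise GenotypeFormatError(f"unparseable chromosome label {label!r}") from None
    if not 0 < value <= 26:
        raise GenotypeFormatError(f"chromosome code {value} outside 1-26")
    return value


@dataclass
class GenotypeTable:
    """Samples x ordered markers with calls in {AA, AB, BB, NC}.

    ``samples`` carries iid plus the ped pedigree columns (fid, father,
    mother, sex, phenotype) and an optional group label; ``markers`` has
    columns (chrom, id, cm, pos) sorted by (chrom, pos); ``calls`` is an
    int8 array of shape (n_samples, n_markers). ``allele_a``/``allele_b``
    keep the nucleotide designated A/B at each marker so a table can be
    written back to ped/map bit-exactly.
    """

    samples: pd.DataFrame
    markers: pd.DataFrame
    calls: np.ndarray
    allele_a: np.ndarray = None
    allele_b: np.ndarray = None

    def __post_init__(self) -> None:
        if self.allele_a is None:
            self.allele_a = np.full(self.n_markers, "A", dtype=object)
        if self.allele_b is None:
            self.allele_b = np.full(self.n_markers, "B", dtype=object)
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        if self.calls.shape != (len(self.samples), len(self.markers)):
            raise ValueError("calls shape does not match samples x markers")
        if self.samples["iid"].duplicated().any():
            dup = self.samples["iid"][self.samples["iid"].duplicated()].iloc[0]
            raise ValueError(f"duplicate sample ID {dup!r}")
        if self.calls.size and ((self.calls < NC) | (self.calls > BB)).any():
            raise ValueError("calls contain codes outside {AA, AB, BB, NC}")
        chrom = self.markers["chrom"].to_numpy()
        pos = self.markers["pos"].to_numpy()
        if len(chrom) > 1:
            dc = np.diff(chrom)
            if (dc < 0).any():
                raise ValueError("markers are not sorted by (chrom, pos)")
            same = dc == 0
            dp = np.diff(pos)
            if (dp[same] < 0).any():
                raise ValueError("markers are not sorted by (chrom, pos)")
            if (dp[same] == 0).any():
                j = np.flatnonzero(same & (dp == 0))[0]
                raise GenotypeFormatError(
                    f"duplicate marker position chrom {chrom[j]} pos {pos[j]}")

    # -- accessors -------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples["iid"])

    def sample_index(self, iid: str) -> int:
        idx = self.samples.index[self.samples["iid"] == iid]
        if len(idx) == 0:
            raise KeyError(f"unknown sample {iid!r}")
        return int(self.samples.index.get_indexer(idx)[0])

    def calls_for(self, iid: str) -> np.ndarray:
        return self.calls[self.sample_index(iid)]

    def group_of(self, iid: str) -> str | None:
        if "group" not in self.samples.columns:
            return None
        g = self.samples.loc[self.samples["iid"] == iid, "group"]
        return None if g.empty or pd.isna(g.iloc[0]) else str(g.iloc[0])

    def subset_markers(self, mask: np.ndarray) -> "GenotypeTable":
        return GenotypeTable(
            samples=self.samples.copy(),
            markers=self.markers.loc[mask].reset_index(drop=True),
            calls=self.calls[:, np.asarray(mask)],
            allele_a=self.allele_a[np.asarray(mask)],
            allele_b=self.allele_b[np.asarray(mask)],
        )


def read_map(map_source: str | Path) -> pd.DataFrame:
    """Read a PLINK .map file into a (chrom, id, cm, pos) frame sorted by position."""
    df = pd.read_csv(map_source, sep=r"\s+", header=None, dtype=str, comment="#")
    if df.shape[1] != 4:
        raise GenotypeFormatError(
            f"map file must have 4 columns (chrom, id, cM, bp); found {df.shape[1]}")
    out = pd.DataFrame({
        "chrom": [parse_chrom(c) for c in df[0]],
        "id": df[1].astype(str),
        "cm": pd.to_numeric(df[2]),
        "pos": pd.to_numeric(df[3]).astype(np.int64),
    })
    if (out["pos"] <= 0).any():
        bad = out.loc[out["pos"] <= 0].iloc[0]
        raise GenotypeFormatError(f"non-positive bp position for marker {bad['id']!r}")
    out["_order"] = np.arange(len(out))
    out = out.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    return out


def read_ped_map(ped_source: str | Path, map_source: str | Path) -> GenotypeTable:
    """Read whitespace-delimited ped/map text into a :class:`GenotypeTable`.

    Nucleotide pairs are encoded against the per-marker A/B designation;
    any genotype containing a ``0`` allele (including half-missing calls)
    becomes NC. Marker order follows the map after sorting by (chrom, pos).
    """
    markers = read_map(map_source)
    order = markers["_order"].to_numpy()
    markers = markers.drop(columns="_order")
    n_markers = len(markers)

    fam_rows: list[list[str]] = []
    geno_rows: list[np.ndarray] = []
    with open(ped_source) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            if len(tokens) != 6 + 2 * n_markers:
                raise GenotypeFormatError(
                    f"ped line {lineno}: expected {6 + 2 * n_markers} fields "
                    f"({n_markers} markers), found {len(tokens)}")
            fam_rows.append(tokens[:6])
            geno_rows.append(np.array(tokens[6:], dtype=object))
    if not fam_rows:
        raise GenotypeFormatError("ped file contains no samples")

    geno = np.vstack(geno_rows)                      # (n, 2*M) in map-file order
    # encode allele strings as small ints over the (sorted) vocabulary so the
    # per-marker A/B designation is fully vectorized
    vocab, inv = np.unique(geno, return_inverse=True)
    codes = inv.reshape(geno.shape).astype(np.int16)
    a1 = codes[:, 0::2][:, order]
    a2 = codes[:, 1::2][:, order]
    zero_code = int(np.searchsorted(vocab, "0")) if "0" in vocab else -1

    present = np.zeros((len(vocab), n_markers), dtype=bool)
    for k in range(len(vocab)):
        present[k] = ((a1 == k) | (a2 == k)).any(axis=0)
    nonzero = np.array([v != "0" for v in vocab])
    present &= nonzero[:, None]
    n_alleles = present.sum(axis=0)
    if (n_alleles > 2).any():
        j = int(np.argmax(n_alleles > 2))
        obs = sorted(vocab[present[:, j]])
        raise TriallelicMarkerError(
            f"marker {markers['id'][j]!r}: more than two alleles {obs}")

    # lexicographically first observed non-zero allele is A (vocab is sorted)
    a_code = np.where(n_alleles > 0, present.argmax(axis=0), -1)
    rev_last = len(vocab) - 1 - present[::-1].argmax(axis=0)
    b_code = np.where(n_alleles > 1, rev_last, -1)

    allele_a = np.where(n_alleles > 0, vocab[np.maximum(a_code, 0)], "A").astype(object)
    fallback_b = np.where(allele_a == "A", "B", "A")
    allele_b = np.where(n_alleles > 1, vocab[np.maximum(b_code, 0)],
                        fallback_b).astype(object)

    missing = (a1 == zero_code) | (a2 == zero_code)
    n_a = (a1 == a_code[None, :]).astype(np.int8) + (a2 == a_code[None, :]).astype(np.int8)
    calls = np.where(missing, NC, 2 - n_a).astype(np.int8)  # 2 A-alleles -> AA(0)

    fam = pd.DataFrame(fam_rows, columns=["fid", "iid", "father", "mother", "sex", "phenotype"])
    samples = fam[["iid", "fid", "father", "mother", "sex", "phenotype"]].copy()
    return GenotypeTable(samples=samples, markers=markers, calls=calls,
                         allele_a=allele_a, allele_b=allele_b)


def write_ped_map(table: GenotypeTable, ped_path: str | Path, map_path: str | Path) -> None:
    """Write ped/map text; a read of the output reproduces the table exactly."""
    m = table.markers
    with open(map_path, "w") as fh:
        for chrom, mid, cm, pos in zip(m["chrom"], m["id"], m["cm"], m["pos"]):
            fh.write(f"{chrom} {mid} {cm:g} {pos}\n")

    s = table.samples
    fid = s["fid"] if "fid" in s else pd.Series(["0"] * len(s))
    father = s["father"] if "father" in s else pd.Series(["0"] * len(s))
    mother = s["mother"] if "mother" in s else pd.Series(["0"] * len(s))
    sex = s["sex"] if "sex" in s else pd.Series(["0"] * len(s))
    phe = s["phenotype"] if "phenotype" in s else pd.Series(["-9"] * len(s))

    a = np.asarray(table.allele_a, dtype=object)
    b = np.asarray(table.allele_b, dtype=object)
    with open(ped_path, "w") as fh:
        for i, iid in enumerate(s["iid"]):
            row = table.calls[i]
            first = np.where(row == BB, b, a)         # AA/AB -> a, BB -> b
            second = np.where(row == AA, a, b)        # AB/BB -> b, AA -> a
            first = np.where(row == NC, "0", first)
            second = np.where(row == NC, "0", second)
            geno = " ".join(f"{x} {y}" for x, y in zip(first, second))
            fh.write(f"{fid.iloc[i]} {iid} {father.iloc[i]} {mother.iloc[i]} "
                     f"{sex.iloc[i]} {phe.iloc[i]} {geno}\n")


def filter_autosomes(table: GenotypeTable) -> GenotypeTable:
    """Retain only markers on chromosomes 1-22, preserving order."""
    mask = (table.markers["chrom"] >= 1) & (table.markers["chrom"] <= MAX_AUTOSOME)
    if not mask.any():
        raise NoAutosomalMarkersError("no autosomal markers")
    if mask.all():
        return table
    return table.subset_markers(mask.to_numpy())


def read_sample_annotations(path: str | Path) -> pd.DataFrame:
    """Read a TSV of sample annotations: ID, group, father, mother (0 = unknown)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = {c.lower(): c for c in df.columns}
    if "id" not in cols:
        raise GenotypeFormatError("annotation file needs an ID column")
    out = pd.DataFrame({"iid": df[cols["id"]].astype(str)})
    for name in ("group", "father", "mother"):
        if name in cols:
            vals = df[cols[name]].astype(str)
            out[name] = vals.where(~vals.isin(["0", "nan", ""]), other=pd.NA)
        else:
            out[name] = pd.NA
    return out


def attach_annotations(table: GenotypeTable, annotations: pd.DataFrame) -> GenotypeTable:
    """Merge group/father/mother annotations into the sample frame by ID."""
    merged = table.samples.drop(columns=[c for c in ("group",) if c in table.samples], errors="ignore")
    merged = merged.merge(annotations, on="iid", how="left", suffixes=("", "_ann"))
    for name in ("father", "mother"):
        ann = f"{name}_ann"
        if ann in merged:
            merged[name] = merged[ann].fillna(merged[name])
            merged = merged.drop(columns=ann)
    return GenotypeTable(samples=merged, markers=table.markers, calls=table.calls,
                         allele_a=table.allele_a, allele_b=table.allele_b)
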