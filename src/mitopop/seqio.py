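"""Alignment input/output, haplotype collapsing and site statistics.

The central container is :class:`Alignment`: a rectangular nucleotide
alignment (A, C, G, T, N and the gap character ``-``) with named partitions
(half-open column ranges, e.g. a protein-coding fragment followed by an rRNA
fragment) and an individual-to-deme map.  Demes may optionally carry group
labels (for hierarchical analyses) and geographic coordinates.

Haplotype collapsing reduces the alignment to the unique sequences and a
haplotype-by-deme count matrix, the basic object consumed by the diversity,
network and structure analyses.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from scipy import stats

VALID = set("ACGTN-")
BASES = "ACGT"

__all__ = [
    "Alignment",
    "HaplotypeTable",
    "SiteStats",
    "AlignmentError",
    "MetadataError",
    "read_alignment",
    "write_alignment",
    "collapse_haplotypes",
    "site_statistics",
    "base_homogeneity_chi2",
]


class AlignmentError(ValueError):
    """Malformed alignment (ragged lengths, empty, bad symbols)."""


class MetadataError(ValueError):
    """Population metadata does not cover the alignment."""


@dataclass
class Alignment:
    """A rectangular alignment with deme labels and named partitions.

    Parameters
    ----------
    ids
        Individual labels, in file order.
    seqs
        Upper-case aligned sequences, one per individual, equal length.
    partitions
        Mapping name -> half-open column range ``(start, stop)``.  The
        ranges must tile ``[0, L)`` without overlap.
    deme_of
        Mapping individual id -> deme label.
    group_of
        Optional mapping deme -> group label.
    coords
        Optional mapping deme -> (latitude, longitude) in decimal degrees.
    """

    ids: list[str]
    seqs: list[str]
    partitions: dict[str, tuple[int, int]] = field(default_factory=dict)
    deme_of: dict[str, str] = field(default_factory=dict)
    group_of: dict[str, str] = field(default_factory=dict)
    coords: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.seqs:
            raise AlignmentError("empty alignment")
        L = len(self.seqs[0])
        if any(len(s) != L for s in self.seqs):
            raise AlignmentError("sequences have unequal lengths")
        bad = set("".join(self.seqs)) - VALID
        if bad:
            raise AlignmentError(f"invalid symbols in alignment: {sorted(bad)}")
        missing = [i for i in self.ids if i not in self.deme_of]
        if missing:
            raise MetadataError(f"individuals missing from popmap: {missing}")
        if not self.partitions:
            self.partitions = {"all": (0, L)}
        cols = sorted(self.partitions.values())
        if cols[0][0] != 0 or cols[-1][1] != L or any(
            a[1] != b[0] for a, b in itertools.pairwise(cols)
        ):
            raise AlignmentError("partitions do not tile the alignment")

    @property
    def L(self) -> int:
        return len(self.seqs[0])

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def demes(self) -> list[str]:
        seen: dict[str, None] = {}
        for i in self.ids:
            seen.setdefault(self.deme_of[i], None)
        return list(seen)

    def matrix(self) -> np.ndarray:
        """Alignment as an (n, L) array of single-byte strings."""
        return np.frombuffer(
            "".join(self.seqs).encode(), dtype="S1"
        ).reshape(self.n, self.L)

    def subset(self, ids: list[str]) -> "Alignment":
        idx = {i: k for k, i in enumerate(self.ids)}
        missing = [i for i in ids if i not in idx]
        if missing:
            raise MetadataError(f"unknown individuals: {missing}")
        return Alignment(
            ids=list(ids),
            seqs=[self.seqs[idx[i]] for i in ids],
            partitions=dict(self.partitions),
            deme_of={i: self.deme_of[i] for i in ids},
            group_of=dict(self.group_of),
            coords=dict(self.coords),
        )

    def deme_members(self, deme: str) -> list[str]:
        return [i for i in self.ids if self.deme_of[i] == deme]


@dataclass
class HaplotypeTable:
    """Unique haplotypes and their per-deme counts.

    ``counts`` is a haplotype-by-deme integer DataFrame; haplotypes are
    labelled H1..Hk in order of first appearance.
    """

    hap_seqs: dict[str, str]
    counts: pd.DataFrame
    hap_of: dict[str, str] = field(default_factory=dict)

    @property
    def n_haplotypes(self) -> int:
        return len(self.hap_seqs)

    @property
    def n_per_deme(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        """Table shaped like a haplotype-frequency report, with margins."""
        out = self.counts.copy()
        out["Tot."] = out.sum(axis=1)
        out.loc["Tot."] = out.sum(axis=0)
        return out


@dataclass
class SiteStats:
    """Variable / parsimony-informative site counts and base composition."""

    n_variable: dict[str, int]
    n_informative: dict[str, int]
    base_freqs: pd.DataFrame  # per-taxon rows + "pooled" row; columns ACGT


def _read_popmap(popmap_path: str | Path) -> tuple[dict, dict]:
    df = pd.read_csv(popmap_path, dtype=str, skipinitialspace=True)
    cols = [c.strip().lower() for c in df.columns]
    df.columns = cols
    if "id" not in cols or "deme" not in cols:
        raise MetadataError("popmap must have columns id,deme[,group]")
    deme_of = dict(zip(df["id"], df["deme"]))
    group_of = {}
    if "group" in cols:
        sub = df.dropna(subset=["group"])
        group_of = dict(zip(sub["deme"], sub["group"]))
    return deme_of, group_of


def read_alignment(
    fasta_path: str | Path,
    popmap_path: str | Path,
    partitions: dict[str, tuple[int, int]] | None = None,
    coords_path: str | Path | None = None,
) -> Alignment:
    """Read a FASTA alignment plus its population map.

    Unknown nucleotide symbols (IUPAC ambiguity codes etc.) are mapped to N.
    Raises :class:`AlignmentError` for ragged alignments and
    :class:`MetadataError` when the popmap does not cover every sequence.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise AlignmentError(f"no sequences in {fasta_path}")
    ids = [r.id for r in records]
    seqs = []
    for r in records:
        s = str(r.seq).upper()
        s = "".join(c if c in VALID else "N" for c in s)
        seqs.append(s)
    deme_of, group_of = _read_popmap(popmap_path)
    missing = [i for i in ids if i not in deme_of]
    if missing:
        raise MetadataError(f"popmap missing ids: {missing}")
    coords = {}
    if coords_path is not None:
        cf = pd.read_csv(coords_path, skipinitialspace=True)
        cf.columns = [c.strip().lower() for c in cf.columns]
        for _, row in cf.iterrows():
            lat, lon = float(row["lat"]), float(row["lon"])
            if not (-90 <= lat <= 90 and -180 <= lon <= 180):
                raise MetadataError(f"coordinates out of range for {row['deme']}")
            coords[str(row["deme"])] = (lat, lon)
    return Alignment(
        ids=ids,
        seqs=seqs,
        partitions=partitions or {},
        deme_of=deme_of,
        group_of=group_of,
        coords=coords,
    )


def write_alignment(
    a: Alignment,
    fasta_path: str | Path,
    popmap_path: str | Path | None = None,
    coords_path: str | Path | None = None,
) -> None:
    records = [
        SeqRecord(Seq(s), id=i, description="") for i, s in zip(a.ids, a.seqs)
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    if popmap_path is not None:
        rows = {"id": a.ids, "deme": [a.deme_of[i] for i in a.ids]}
        if a.group_of:
            rows["group"] = [a.group_of.get(a.deme_of[i], "") for i in a.ids]
        pd.DataFrame(rows).to_csv(popmap_path, index=False)
    if coords_path is not None and a.coords:
        pd.DataFrame(
            [(d, lat, lon) for d, (lat, lon) in a.coords.items()],
            columns=["deme", "lat", "lon"],
        ).to_csv(coords_path, index=False)


def _compatible(s: str, t: str) -> bool:
    """True when two sequences differ only at positions where either is N."""
    return all(x == y or x == "N" or y == "N" for x, y in zip(s, t))


def collapse_haplotypes(a: Alignment) -> HaplotypeTable:
    """Collapse identical sequences into haplotypes.

    Sequences differing only at N positions are merged into the earlier
    haplotype; gaps are genuine states for collapsing.  Haplotypes are
    labelled H1..Hk in order of first appearance.
    """
    demes = a.demes
    reps: list[str] = []  # representative sequences
    labels: list[str] = []
    counts = np.zeros((0, len(demes)), dtype=int)
    deme_idx = {d: k for k, d in enumerate(demes)}
    hap_of: dict[str, str] = {}
    rows: list[np.ndarray] = []
    for ind, seq in zip(a.ids, a.seqs):
        for h, rep in enumerate(reps):
            if seq == rep or _compatible(seq, rep):
                break
        else:
            reps.append(seq)
            labels.append(f"H{len(reps)}")
            rows.append(np.zeros(len(demes), dtype=int))
            h = len(reps) - 1
        rows[h][deme_idx[a.deme_of[ind]]] += 1
        hap_of[ind] = labels[h]
    counts = pd.DataFrame(np.vstack(rows), index=labels, columns=demes)
    return HaplotypeTable(
        hap_seqs=dict(zip(labels, reps)), counts=counts, hap_of=hap_of
    )


def _expand_codon_partitions(
    partitions: dict[str, tuple[int, int]],
    codon_partition: str | None,
    frame: int | None,
) -> dict[str, tuple[int, int] | np.ndarray]:
    out: dict[str, tuple[int, int] | np.ndarray] = dict(partitions)
    if codon_partition is not None:
        if frame is None:
            raise ValueError(
                "reading frame required for codon sub-partitions"
            )
        start, stop = partitions[codon_partition]
        cols = np.arange(start, stop)
        for pos in range(3):
            sel = cols[(cols - start - frame) % 3 == pos]
            out[f"{codon_partition}_pos{pos + 1}"] = sel
    return out


def site_statistics(
    a: Alignment,
    codon_partition: str | None = None,
    frame: int | None = None,
) -> SiteStats:
    """Variable and parsimony-informative site counts plus base composition.

    A column is variable when it holds >=2 distinct states (gap and N
    excluded); parsimony-informative when >=2 states each occur in >=2
    sequences.  Codon sub-partitions of a protein-coding partition are
    produced when ``codon_partition`` is given (``frame`` is the 0-based
    offset of the first complete codon).
    """
    m = a.matrix()
    n, L = m.shape
    var = np.zeros(L, dtype=bool)
    inf = np.zeros(L, dtype=bool)
    for j in range(L):
        col = m[:, j]
        keep = (col != b"N") & (col != b"-")
        vals, cnt = np.unique(col[keep], return_counts=True)
        var[j] = len(vals) >= 2
        inf[j] = (cnt >= 2).sum() >= 2
    parts = _expand_codon_partitions(a.partitions, codon_partition, frame)
    n_variable = {"overall": int(var.sum())}
    n_informative = {"overall": int(inf.sum())}
    for name, rng in parts.items():
        sel = np.arange(*rng) if isinstance(rng, tuple) else rng
        n_variable[name] = int(var[sel].sum())
        n_informative[name] = int(inf[sel].sum())
    freq_rows = []
    for i, ind in enumerate(a.ids):
        row = m[i]
        tot = np.isin(row, [b"A", b"C", b"G", b"T"]).sum()
        freq_rows.append(
            [np.count_nonzero(row == b.encode()) / tot if tot else np.nan
             for b in BASES]
        )
    bf = pd.DataFrame(freq_rows, index=a.ids, columns=list(BASES))
    pooled = (
        bf.mul([np.isin(m[i], [b"A", b"C", b"G", b"T"]).sum() for i in range(n)],
               axis=0).sum()
    )
    bf.loc["pooled"] = pooled / pooled.sum()
    return SiteStats(n_variable=n_variable, n_informative=n_informative,
                     base_freqs=bf)


def base_homogeneity_chi2(a: Alignment) -> tuple[float, int, float]:
    """Chi-squared test of base-frequency homogeneity across taxa.

    Builds the taxa-by-4 count table of A/C/G/T (gaps and N excluded) and
    computes the contingency chi-squared with df = (n_taxa - 1) * 3.
    """
    if a.n < 2:
        raise AlignmentError("need >=2 sequences for the homogeneity test")
    m = a.matrix()
    table = np.array(
        [[np.count_nonzero(m[i] == b.encode()) for b in BASES]
         for i in range(a.n)],
        dtype=float,
    )
    if (table.sum(axis=1) == 0).any():
        bad = [a.ids[i] for i in np.where(table.sum(axis=1) == 0)[0]]
        raise AlignmentError(f"taxa with no countable bases: {bad}")
    rows = table.sum(axis=1, keepdims=True)
    cols = table.sum(axis=0, keepdims=True)
    expected = rows @ cols / table.sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = np.where(expected > 0, (table - expected) ** 2 / expected, 0.0)
    chi2 = float(terms.sum())
    df = (a.n - 1) * 3
    p = float(stats.chi2.sf(chi2, df))
    return chi2, df, p
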