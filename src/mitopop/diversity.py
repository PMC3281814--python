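"""Per-deme molecular diversity statistics.

Implements the unbiased haplotype diversity estimator
``h = n (1 - sum p_i^2) / (n - 1)`` and the mean number of pairwise
differences ``pi`` (with its per-site version, the nucleotide diversity
``pi_n = pi / L``), the quantities conventionally reported per sampling
locality in mtDNA phylogeography.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .seqio import Alignment, collapse_haplotypes

__all__ = [
    "DiversityRecord",
    "haplotype_diversity",
    "pairwise_differences",
    "pairwise_difference_stats",
    "diversity_table",
]


@dataclass
class DiversityRecord:
    deme: str
    N: int
    H: int
    h: float
    pi: float
    pi_n: float


def haplotype_diversity(counts) -> float:
    """Unbiased haplotype diversity from a vector of haplotype counts.

    h = n (1 - sum p_i^2) / (n - 1) with p_i = count_i / n; requires n >= 2.
    """
    c = np.asarray(counts, dtype=float)
    if (c < 0).any():
        raise ValueError("haplotype counts must be non-negative")
    n = c.sum()
    if n < 2:
        raise ValueError("haplotype diversity requires n >= 2")
    p = c / n
    return float(n * (1.0 - (p ** 2).sum()) / (n - 1.0))


def pairwise_differences(a: Alignment, ids: list[str] | None = None) -> np.ndarray:
    """Matrix of pairwise site differences with pairwise deletion.

    Positions where either sequence is N or a gap are excluded from the
    comparison of that pair.
    """
    sub = a if ids is None else a.subset(ids)
    m = sub.matrix()
    miss = (m == b"N") | (m == b"-")
    n = m.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        neq = m[i] != m[i + 1:]
        ok = ~(miss[i] | miss[i + 1:])
        d[i, i + 1:] = d[i + 1:, i] = (neq & ok).sum(axis=1)
    return d


def pairwise_difference_stats(a: Alignment, deme: str) -> tuple[float, float]:
    """(pi, pi_n) for one deme: mean pairwise differences and its per-site value."""
    members = a.deme_members(deme)
    if len(members) < 2:
        raise ValueError(f"deme {deme!r} has fewer than 2 individuals")
    d = pairwise_differences(a, members)
    iu = np.triu_indices(len(members), k=1)
    pi = float(d[iu].mean())
    return pi, pi / a.L


def diversity_table(a: Alignment) -> pd.DataFrame:
    """Per-deme diversity report: N, H, h, pi, pi_n (percent)."""
    table = collapse_haplotypes(a)
    rows = []
    for deme in a.demes:
        counts = table.counts[deme]
        counts = counts[counts > 0]
        n = int(counts.sum())
        pi, pi_n = pairwise_difference_stats(a, deme)
        rows.append(
            DiversityRecord(
                deme=deme,
                N=n,
                H=int(len(counts)),
                h=haplotype_diversity(counts.to_numpy()),
                pi=pi,
                pi_n=100.0 * pi_n,
            )
        )
    return pd.DataFrame(
        [(r.deme, r.N, r.H, round(r.h, 3), round(r.pi, 3), round(r.pi_n, 2))
         for r in rows],
        columns=["deme", "N", "H", "h", "pi", "pi_n_pct"],
    )
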