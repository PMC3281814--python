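"""Population structure: pairwise PhiST, AMOVA and sequential Bonferroni.

The analysis of molecular variance partitions sums of squared pairwise
sequence distances into hierarchical variance components (within demes,
among demes, and optionally among groups of demes) following the
Excoffier–Quattro–Smouse framework.  The count of differing sites between
two sequences is used directly as the squared Euclidean distance, the
standard convention for haplotype data.  Significance is assessed by
permutation: individuals among demes for F_ST, individuals among demes
within groups for F_SC, and whole demes among groups for F_CT.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diversity import pairwise_differences
from .seqio import Alignment

__all__ = [
    "PhiStMatrix",
    "AmovaResult",
    "amova",
    "pairwise_phist",
    "sequential_bonferroni",
]


@dataclass
class AmovaResult:
    design: str  # "one-level" | "two-level"
    ss: dict[str, float]
    df: dict[str, int]
    var_components: dict[str, float]
    pct_variation: dict[str, float]
    fixation: dict[str, float]
    pvals: dict[str, float | None]
    warnings: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        strata = list(self.ss)
        comp = list(self.var_components.values())
        return pd.DataFrame(
            {
                "source": strata,
                "ss": [round(self.ss[s], 2) for s in strata],
                "df": [self.df[s] for s in strata],
                "variance": [round(v, 4) for v in comp],
                "pct_variation": [
                    round(self.pct_variation[s], 2) for s in strata
                ],
            }
        )


@dataclass
class PhiStMatrix:
    demes: list[str]
    phist: pd.DataFrame
    pvals: pd.DataFrame
    significant: pd.DataFrame
    initial_alpha: float

    def lower_triangle(self) -> pd.DataFrame:
        out = self.phist.copy().astype(object)
        k = len(self.demes)
        for i in range(k):
            for j in range(i, k):
                out.iloc[i, j] = "-" if i == j else ""
        return out


def _ssd(d2: np.ndarray, groups: np.ndarray) -> float:
    """Sum over strata of (sum of squared distances within stratum)/size."""
    tot = 0.0
    for g in np.unique(groups):
        idx = np.where(groups == g)[0]
        sub = d2[np.ix_(idx, idx)]
        tot += sub.sum() / (2.0 * len(idx))
    return tot


def _one_level_components(d2: np.ndarray, pops: np.ndarray):
    N = len(pops)
    labels, counts = np.unique(pops, return_counts=True)
    P = len(labels)
    ssd_t = d2.sum() / (2.0 * N)
    ssd_wp = _ssd(d2, pops)
    ss_ap = ssd_t - ssd_wp
    df_ap, df_wp = P - 1, N - P
    ms_ap = ss_ap / df_ap
    ms_wp = ssd_wp / df_wp
    n_prime = (N - (counts ** 2).sum() / N) / (P - 1)
    sigma_w = ms_wp
    sigma_a = (ms_ap - ms_wp) / n_prime
    total = sigma_a + sigma_w
    fst = sigma_a / total if total != 0 else 0.0
    return {
        "ss": {"among_demes": ss_ap, "within_demes": ssd_wp},
        "df": {"among_demes": df_ap, "within_demes": df_wp},
        "var": {"Va": sigma_a, "Vb": sigma_w},
        "fst": fst,
    }


def _two_level_components(d2: np.ndarray, pops: np.ndarray, grp: np.ndarray):
    N = len(pops)
    ssd_t = d2.sum() / (2.0 * N)
    ssd_wp = _ssd(d2, pops)
    ssd_wg = _ssd(d2, grp)
    ss_ag = ssd_t - ssd_wg
    ss_ap = ssd_wg - ssd_wp
    pop_labels = np.unique(pops)
    grp_labels = np.unique(grp)
    P, G = len(pop_labels), len(grp_labels)
    df_ag, df_ap, df_wp = G - 1, P - G, N - P
    n_p = {p: np.count_nonzero(pops == p) for p in pop_labels}
    grp_of_pop = {}
    for p in pop_labels:
        grp_of_pop[p] = grp[pops == p][0]
    N_g = {g: np.count_nonzero(grp == g) for g in grp_labels}
    sum_np2_over_Ng = sum(
        n_p[p] ** 2 / N_g[grp_of_pop[p]] for p in pop_labels
    )
    sum_np2_over_N = sum(n_p[p] ** 2 for p in pop_labels) / N
    sum_Ng2_over_N = sum(v ** 2 for v in N_g.values()) / N
    n2 = (sum_np2_over_Ng - sum_np2_over_N) / df_ag
    n3 = (N - sum_Ng2_over_N) / df_ag
    ms_wp = ssd_wp / df_wp
    ms_ag = ss_ag / df_ag
    sigma_c = ms_wp
    if df_ap > 0:
        n1 = (N - sum_np2_over_Ng) / df_ap
        sigma_b = (ss_ap / df_ap - sigma_c) / n1
    else:
        sigma_b = 0.0  # one deme per group: no within-group stratum
    sigma_a = (ms_ag - sigma_c - n2 * sigma_b) / n3
    return {
        "ss": {
            "among_groups": ss_ag,
            "among_demes_within_groups": ss_ap,
            "within_demes": ssd_wp,
        },
        "df": {
            "among_groups": df_ag,
            "among_demes_within_groups": df_ap,
            "within_demes": df_wp,
        },
        "var": {"Va": sigma_a, "Vb": sigma_b, "Vc": sigma_c},
    }


def _two_level_indices(var: dict[str, float]) -> dict[str, float]:
    a, b, c = var["Va"], var["Vb"], var["Vc"]
    total = a + b + c
    return {
        "F_CT": a / total if total else 0.0,
        "F_SC": b / (b + c) if (b + c) else 0.0,
        "F_ST": (a + b) / total if total else 0.0,
    }


def amova(
    a_or_d2,
    pops=None,
    grouping: dict[str, str] | None = None,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> AmovaResult:
    """One- or two-level AMOVA from an alignment or a squared-distance matrix.

    Parameters
    ----------
    a_or_d2
        Either an :class:`~mitopop.seqio.Alignment` or an (n, n) matrix of
        squared pairwise distances.
    pops
        Deme label per individual (ignored when an Alignment is given).
    grouping
        Optional deme -> group map; triggers the two-level design.
    n_perm, seed
        Permutation count and RNG seed for the significance tests.
    """
    if isinstance(a_or_d2, Alignment):
        aln = a_or_d2
        d2 = pairwise_differences(aln)
        pops = np.array([aln.deme_of[i] for i in aln.ids])
    else:
        d2 = np.asarray(a_or_d2, dtype=float)
        pops = np.asarray(pops)
    rng = np.random.default_rng(seed)
    warnings: list[str] = []

    if grouping is None:
        res = _one_level_components(d2, pops)
        fst = res["fst"]
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(pops)
            if _one_level_components(d2, perm)["fst"] >= fst - 1e-12:
                count += 1
        p = (count + 1) / (n_perm + 1)
        var = res["var"]
        total = sum(var.values())
        pct = {
            "among_demes": 100 * var["Va"] / total if total else np.nan,
            "within_demes": 100 * var["Vb"] / total if total else np.nan,
        }
        return AmovaResult(
            design="one-level",
            ss=res["ss"],
            df=res["df"],
            var_components=var,
            pct_variation=pct,
            fixation={"F_ST": fst},
            pvals={"F_ST": p},
            warnings=warnings,
        )

    grp = np.array([grouping[p] for p in pops])
    res = _two_level_components(d2, pops, grp)
    fix = _two_level_indices(res["var"])
    pop_labels = list(np.unique(pops))
    grp_of_pop = {p: grouping[p] for p in pop_labels}
    P, G = len(pop_labels), len(np.unique(grp))
    pvals: dict[str, float | None] = {}

    if P == G:
        warnings.append("each group holds a single deme; F_SC undefined")
        pvals["F_SC"] = None
    else:
        count = 0
        for _ in range(n_perm):
            perm = pops.copy()
            for g in np.unique(grp):
                idx = np.where(grp == g)[0]
                perm[idx] = rng.permutation(perm[idx])
            v = _two_level_components(d2, perm, grp)["var"]
            if _two_level_indices(v)["F_SC"] >= fix["F_SC"] - 1e-12:
                count += 1
        pvals["F_SC"] = (count + 1) / (n_perm + 1)

    # F_CT: permute whole demes among groups, keeping group sizes in demes
    group_sizes = [grp_of_pop[p] for p in pop_labels]
    count = 0
    for _ in range(n_perm):
        shuffled = rng.permutation(group_sizes)
        gmap = dict(zip(pop_labels, shuffled))
        pgrp = np.array([gmap[p] for p in pops])
        v = _two_level_components(d2, pops, pgrp)["var"]
        if _two_level_indices(v)["F_CT"] >= fix["F_CT"] - 1e-12:
            count += 1
    pvals["F_CT"] = (count + 1) / (n_perm + 1)

    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pops)
        v = _two_level_components(d2, perm, grp)["var"]
        if _two_level_indices(v)["F_ST"] >= fix["F_ST"] - 1e-12:
            count += 1
    pvals["F_ST"] = (count + 1) / (n_perm + 1)

    var = res["var"]
    total = sum(var.values())
    pct = {
        "among_groups": 100 * var["Va"] / total if total else np.nan,
        "among_demes_within_groups": 100 * var["Vb"] / total if total else np.nan,
        "within_demes": 100 * var["Vc"] / total if total else np.nan,
    }
    return AmovaResult(
        design="two-level",
        ss=res["ss"],
        df=res["df"],
        var_components=var,
        pct_variation=pct,
        fixation=fix,
        pvals=pvals,
        warnings=warnings,
    )


def sequential_bonferroni(pvals, alpha: float = 0.05):
    """Holm step-down ("sequential Bonferroni") significance flags.

    Sorts p-values ascending, compares p_(i) with alpha/(k - i) (0-based i),
    and stops at the first failure.  Returns (flags, initial_threshold).
    """
    p = np.asarray(pvals, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    k = len(p)
    order = np.argsort(p, kind="stable")
    flags = np.zeros(k, dtype=bool)
    for rank, idx in enumerate(order):
        if p[idx] <= alpha / (k - rank):
            flags[idx] = True
        else:
            break
    return flags, alpha / k


def pairwise_phist(
    a: Alignment,
    n_perm: int = 10_000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> PhiStMatrix:
    """Pairwise PhiST between demes with permutation p-values and Holm flags.

    Each deme pair is analysed as a two-deme one-level AMOVA on the
    site-difference matrix; p-values come from shuffling individuals
    between the two demes.  Demes with fewer than 2 individuals are
    excluded with a warning entry in the result.
    """
    d2_all = pairwise_differences(a)
    pops_all = np.array([a.deme_of[i] for i in a.ids])
    demes = [d for d in a.demes if np.count_nonzero(pops_all == d) >= 2]
    rng = np.random.default_rng(seed)
    k = len(demes)
    phist = pd.DataFrame(np.zeros((k, k)), index=demes, columns=demes)
    pvals = pd.DataFrame(np.ones((k, k)), index=demes, columns=demes)
    flat_p, pairs = [], []
    for i in range(k):
        for j in range(i + 1, k):
            idx = np.where(np.isin(pops_all, [demes[i], demes[j]]))[0]
            d2 = d2_all[np.ix_(idx, idx)]
            pops = pops_all[idx]
            obs = _one_level_components(d2, pops)["fst"]
            count = 0
            for _ in range(n_perm):
                perm = rng.permutation(pops)
                if _one_level_components(d2, perm)["fst"] >= obs - 1e-12:
                    count += 1
            p = (count + 1) / (n_perm + 1)
            phist.iloc[i, j] = phist.iloc[j, i] = obs
            pvals.iloc[i, j] = pvals.iloc[j, i] = p
            flat_p.append(p)
            pairs.append((i, j))
    flags, alpha0 = sequential_bonferroni(flat_p, alpha)
    sig = pd.DataFrame(
        np.zeros((k, k), dtype=bool), index=demes, columns=demes
    )
    for (i, j), f in zip(pairs, flags):
        sig.iloc[i, j] = sig.iloc[j, i] = bool(f)
    return PhiStMatrix(
        demes=demes, phist=phist, pvals=pvals, significant=sig,
        initial_alpha=alpha0,
    )
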