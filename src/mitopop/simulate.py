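"""Coalescent simulator and fixture factory.

Provides the statistical structures the analyses assume — panmixia, island
and stepping-stone migration, a two-deme isolation-with-migration history,
sudden demographic expansion and spatial (infinite-island) expansion — plus
a deterministic study-design fixture: 7 demes in 3 divergent groups, 93
individuals, two concatenated partitions and 27 planted haplotypes.

Time is measured in mutational units: a pair of lineages accumulates one
expected mutation per unit, so each lineage mutates at rate 1/2 and the
within-deme coalescence rate per pair is 1/theta.  Under the infinite-sites
model every mutation strikes a fresh alignment column, so pairwise sequence
differences equal path mutation counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .seqio import Alignment

__all__ = ["SimConfig", "simulate", "sample_genealogy",
           "pairwise_path_mutations", "make_study_fixture"]

AT_RICH = {"A": 0.33, "C": 0.17, "G": 0.19, "T": 0.31}


@dataclass
class SimConfig:
    """Scenario description for the coalescent simulator.

    theta values are mutation-scaled (2 N_f u per sequence); M = 2 N_f m;
    T (isolation-with-migration split) is in units of N_f generations;
    tau (expansions) is in mutational units.
    """

    scenario: str = "panmictic"
    sample_sizes: tuple[int, ...] = (20,)
    theta: float = 5.0
    M: float = 0.0
    T: float = 0.0
    tau: float = 0.0
    theta0: float = 0.0
    theta1: float = 0.0
    L: int = 1025
    mutation: str = "infinite_sites"  # or "hky"
    kappa: float = 4.0
    base_freqs: dict[str, float] = field(default_factory=lambda: dict(AT_RICH))
    partitions: dict[str, tuple[int, int]] | None = None
    rate_multipliers: dict[str, float] | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if any(s < 1 for s in self.sample_sizes):
            raise ValueError("sample sizes must be >= 1")
        if min(self.theta, self.M, self.T, self.tau) < 0:
            raise ValueError("rates and times must be non-negative")
        if self.scenario in ("island", "stepping_stone") and len(self.sample_sizes) < 2:
            raise ValueError(f"{self.scenario} needs >= 2 demes")
        if self.scenario == "im_pair" and len(self.sample_sizes) != 2:
            raise ValueError("im_pair needs exactly 2 demes")


def sample_genealogy(cfg: SimConfig, rng: np.random.Generator):
    """Sample a genealogy under the configured scenario.

    Returns (parents, times, branch_mut_rate_time) where parents[i] is the
    parent node of i (-1 for the root) and times are node ages in
    mutational units.  Leaves are numbered deme-block-wise.
    """
    n_tot = sum(cfg.sample_sizes)
    parents = np.full(2 * n_tot - 1, -1, dtype=int)
    times = np.zeros(2 * n_tot - 1)
    # active lineages: list of (node_id, deme)
    active: list[tuple[int, int]] = []
    k = 0
    for d, s in enumerate(cfg.sample_sizes):
        for _ in range(s):
            active.append((k, d))
            k += 1
    nxt = n_tot
    t = 0.0
    theta = max(cfg.theta, 1e-12)

    def coal_pair(pool: list[int]) -> None:
        nonlocal nxt
        i, j = rng.choice(len(pool), size=2, replace=False)
        a, b = pool[i], pool[j]
        parents[active[a][0]] = nxt
        parents[active[b][0]] = nxt
        times[nxt] = t
        deme = active[a][1]
        for idx in sorted((a, b), reverse=True):
            del active[idx]
        active.append((nxt, deme))
        nxt += 1

    if cfg.scenario in ("panmictic", "sudden_expansion"):
        while len(active) > 1:
            kk = len(active)
            if cfg.scenario == "panmictic":
                rate = kk * (kk - 1) / 2.0 / theta
                t += rng.exponential(1.0 / rate)
            else:
                th_now = max(cfg.theta1, 1e-9) if t < cfg.tau else max(cfg.theta0, 1e-9)
                rate = kk * (kk - 1) / 2.0 / th_now
                dt = rng.exponential(1.0 / rate)
                if t < cfg.tau < t + dt:
                    t = cfg.tau
                    continue
                t += dt
            coal_pair(list(range(len(active))))
    elif cfg.scenario in ("island", "stepping_stone", "im_pair", "spatial_expansion"):
        n_demes = len(cfg.sample_sizes) if cfg.scenario != "spatial_expansion" else 1
        merge_time = (
            cfg.T * theta if cfg.scenario == "im_pair"
            else cfg.tau if cfg.scenario == "spatial_expansion"
            else np.inf
        )
        mig_rate_per_lineage = cfg.M / (2.0 * theta)
        merged = False
        next_private = n_demes  # spatial expansion emigrants get private demes
        while len(active) > 1:
            if merged:
                kk = len(active)
                rate = kk * (kk - 1) / 2.0 / theta
                t += rng.exponential(1.0 / rate)
                coal_pair(list(range(len(active))))
                continue
            by_deme: dict[int, list[int]] = {}
            for idx, (_, d) in enumerate(active):
                by_deme.setdefault(d, []).append(idx)
            coal_rates = {
                d: len(v) * (len(v) - 1) / 2.0 / theta
                for d, v in by_deme.items()
            }
            can_migrate = [
                idx for idx, (_, d) in enumerate(active)
                if cfg.scenario != "spatial_expansion" or d == 0
            ]
            mig_total = mig_rate_per_lineage * len(can_migrate)
            total = sum(coal_rates.values()) + mig_total
            if total <= 0:
                t = merge_time
                merged = True
                continue
            dt = rng.exponential(1.0 / total)
            if t + dt >= merge_time:
                t = merge_time
                merged = True
                continue
            t += dt
            u = rng.random() * total
            acc = 0.0
            done = False
            for d, r in coal_rates.items():
                acc += r
                if u < acc:
                    coal_pair(by_deme[d])
                    done = True
                    break
            if not done:
                idx = can_migrate[rng.integers(len(can_migrate))]
                node, d = active[idx]
                if cfg.scenario == "spatial_expansion":
                    new_d = next_private
                    next_private += 1
                elif cfg.scenario == "im_pair":
                    new_d = 1 - d
                elif cfg.scenario == "island":
                    choices = [x for x in range(n_demes) if x != d]
                    new_d = choices[rng.integers(len(choices))]
                else:  # stepping stone, reflecting ends
                    step = rng.choice([-1, 1])
                    new_d = int(np.clip(d + step, 0, n_demes - 1))
                active[idx] = (node, new_d)
    else:
        raise ValueError(f"unknown scenario {cfg.scenario!r}")
    return parents, times


def pairwise_path_mutations(
    parents: np.ndarray, times: np.ndarray, n_leaves: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Poisson mutations per branch (rate 1/2 per lineage) -> pairwise diffs."""
    n_nodes = len(parents)
    muts = np.zeros(n_nodes)
    for i in range(n_nodes):
        if parents[i] >= 0:
            blen = times[parents[i]] - times[i]
            muts[i] = rng.poisson(0.5 * blen)
    # mutation count from node to root
    to_root = np.zeros(n_nodes)
    order = np.argsort(times[n_leaves:])[::-1] + n_leaves  # root first
    for i in list(order) + list(range(n_leaves)):
        if parents[i] >= 0:
            to_root[i] = to_root[parents[i]] + muts[i]
    # ancestor sets for LCA by walking up
    d = np.zeros((n_leaves, n_leaves))
    ancestors = []
    for leaf in range(n_leaves):
        path = {}
        x = leaf
        while x >= 0:
            path[x] = to_root[x]
            x = parents[x]
        ancestors.append(path)
    for i in range(n_leaves):
        for j in range(i + 1, n_leaves):
            common = ancestors[i].keys() & ancestors[j].keys()
            lca_val = max(ancestors[i][x] for x in common)
            d[i, j] = d[j, i] = (
                to_root[i] + to_root[j] - 2 * lca_val
            )
    return d


def _mutate_infinite_sites(
    parents, times, n_leaves, L, base_freqs, rng
) -> list[str]:
    bases = np.array(list("ACGT"))
    probs = np.array([base_freqs[b] for b in "ACGT"])
    probs = probs / probs.sum()
    anc = rng.choice(bases, size=L, p=probs)
    n_nodes = len(parents)
    branch_sites: dict[int, list[int]] = {}
    total = 0
    free_sites = list(rng.permutation(L))
    for i in range(n_nodes):
        if parents[i] < 0:
            continue
        blen = times[parents[i]] - times[i]
        k = rng.poisson(0.5 * blen)
        if total + k > L:
            raise ValueError(
                "more mutations than sites; raise L or lower theta"
            )
        branch_sites[i] = [free_sites.pop() for _ in range(k)]
        total += k
    seqs_arr: dict[int, np.ndarray] = {}
    root = int(np.argmax(times))
    order = sorted(range(n_nodes), key=lambda i: -times[i])
    seqs_arr[root] = anc.copy()
    for i in order:
        if i == root:
            continue
        s = seqs_arr[parents[i]].copy()
        for site in branch_sites.get(i, []):
            cur = s[site]
            alt = [b for b in "ACGT" if b != cur]
            s[site] = alt[rng.integers(3)]
        seqs_arr[i] = s
    return ["".join(seqs_arr[i]) for i in range(n_leaves)]


def _hky_transition(kappa: float, freqs: np.ndarray):
    """HKY rate matrix normalized to one expected substitution per unit."""
    q = np.zeros((4, 4))
    # order A C G T; transitions: A<->G (0,2), C<->T (1,3)
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            rate = freqs[j]
            if (i, j) in ((0, 2), (2, 0), (1, 3), (3, 1)):
                rate *= kappa
            q[i, j] = rate
    np.fill_diagonal(q, -q.sum(axis=1))
    scale = -(freqs * np.diag(q)).sum()
    q /= scale
    w, v = np.linalg.eig(q)
    vinv = np.linalg.inv(v)

    def P(t: float) -> np.ndarray:
        return np.real(v @ np.diag(np.exp(w * t)) @ vinv)

    return P


def _mutate_hky(cfg: SimConfig, parents, times, n_leaves, rng) -> list[str]:
    L = cfg.L
    freqs = np.array([cfg.base_freqs[b] for b in "ACGT"])
    freqs = freqs / freqs.sum()
    P = _hky_transition(cfg.kappa, freqs)
    parts = cfg.partitions or {"all": (0, L)}
    mult = cfg.rate_multipliers or {k: 1.0 for k in parts}
    # per-site substitution rate so that sequence-level rate is 1/2
    weights = np.ones(L)
    for name, (a, b) in parts.items():
        weights[a:b] = mult.get(name, 1.0)
    weights *= (L / weights.sum()) / L  # mean per-site multiplier 1/L
    n_nodes = len(parents)
    root = int(np.argmax(times))
    idx = {b: i for i, b in enumerate("ACGT")}
    bases = np.array(list("ACGT"))
    states: dict[int, np.ndarray] = {
        root: rng.choice(4, size=L, p=freqs)
    }
    order = sorted(range(n_nodes), key=lambda i: -times[i])
    # group sites by multiplier to share transition matrices
    unique_w = np.unique(weights)
    site_groups = {w: np.where(weights == w)[0] for w in unique_w}
    for i in order:
        if i == root:
            continue
        blen = 0.5 * (times[parents[i]] - times[i])
        parent_state = states[parents[i]]
        s = parent_state.copy()
        for w, sites in site_groups.items():
            pm = np.clip(P(blen * w), 0, 1)
            pm = pm / pm.sum(axis=1, keepdims=True)
            ps = parent_state[sites]
            u = rng.random(len(sites))
            cum = np.cumsum(pm[ps], axis=1)
            s[sites] = (u[:, None] > cum).sum(axis=1)
        states[i] = s
    return ["".join(bases[states[i]]) for i in range(n_leaves)]


def simulate(cfg: SimConfig) -> tuple[Alignment, dict[str, Any]]:
    """Simulate an alignment under the configured scenario, with truth record."""
    rng = np.random.default_rng(cfg.seed)
    parents, times = sample_genealogy(cfg, rng)
    n_tot = sum(cfg.sample_sizes)
    if cfg.mutation == "infinite_sites":
        seqs = _mutate_infinite_sites(
            parents, times, n_tot, cfg.L, cfg.base_freqs, rng
        )
    elif cfg.mutation == "hky":
        seqs = _mutate_hky(cfg, parents, times, n_tot, rng)
    else:
        raise ValueError(f"unknown mutation model {cfg.mutation!r}")
    ids, deme_of = [], {}
    k = 0
    for d, s in enumerate(cfg.sample_sizes):
        for _ in range(s):
            name = f"d{d}_i{k}"
            ids.append(name)
            deme_of[name] = f"deme{d}"
            k += 1
    aln = Alignment(
        ids=ids, seqs=seqs,
        partitions=dict(cfg.partitions) if cfg.partitions else {},
        deme_of=deme_of,
    )
    truth = {
        "scenario": cfg.scenario,
        "theta": cfg.theta, "M": cfg.M, "T": cfg.T, "tau": cfg.tau,
        "theta0": cfg.theta0, "theta1": cfg.theta1,
        "tmrca": float(times.max()),
        "seed": cfg.seed,
    }
    return aln, truth


# ---------------------------------------------------------------------------
# Deterministic study-design fixture
# ---------------------------------------------------------------------------

STUDY_DEMES = {
    # deme: (sample size, lat, lon, group)
    "ALB": (16, 40.944, 19.866, "AlbSItaly"),
    "KO3": (10, 39.616, 19.820, "Corfu"),
    "KO4": (14, 39.628, 19.831, "Corfu"),
    "AVE": (20, 40.050, 16.245, "AlbSItaly"),
    "CIR": (13, 41.348, 13.047, "CItaly"),
    "FO": (10, 41.441, 12.732, "CItaly"),
    "CP": (10, 41.705, 12.396, "CItaly"),
}

# haplotype -> {deme: count}; 27 haplotypes over 93 individuals, three
# divergent groups, with the historically reported per-deme frequency spectra
STUDY_COUNTS = {
    "H1": {"ALB": 1}, "H2": {"ALB": 9}, "H3": {"ALB": 4}, "H4": {"ALB": 1},
    "H5": {"ALB": 1}, "H6": {"AVE": 1}, "H7": {"AVE": 3}, "H8": {"AVE": 16},
    "H9": {"CIR": 1}, "H10": {"CIR": 1}, "H11": {"CIR": 4}, "H12": {"CIR": 6},
    "H13": {"CIR": 1}, "H14": {"CP": 1}, "H15": {"CP": 9}, "H16": {"FO": 1},
    "H17": {"FO": 6}, "H18": {"FO": 2}, "H19": {"FO": 1}, "H20": {"KO3": 1},
    "H21": {"KO3": 1, "KO4": 4}, "H22": {"KO3": 5, "KO4": 8},
    "H23": {"KO3": 1}, "H24": {"KO3": 1}, "H25": {"KO3": 1},
    "H26": {"KO4": 1}, "H27": {"KO4": 1},
}

_GROUP_OF_HAP = {
    **{f"H{i}": "AlbSItaly" for i in range(1, 9)},
    **{f"H{i}": "CItaly" for i in range(9, 20)},
    **{f"H{i}": "Corfu" for i in range(20, 28)},
}

# steps from the group ancestor; H9 and H20 are planted far outliers
_HAP_STEPS = {
    "H1": 2, "H2": 0, "H3": 1, "H4": 3, "H5": 4, "H6": 2, "H7": 5, "H8": 4,
    "H9": 17, "H10": 2, "H11": 1, "H12": 0, "H13": 3, "H14": 6, "H15": 1,
    "H16": 4, "H17": 2, "H18": 5, "H19": 6, "H20": 16, "H21": 1, "H22": 0,
    "H23": 2, "H24": 3, "H25": 4, "H26": 1, "H27": 2,
}

L_STUDY = 1025
STUDY_PARTITIONS = {"COI": (0, 560), "16S": (560, 1025)}


def make_study_fixture(seed: int = 0) -> tuple[Alignment, dict[str, Any]]:
    """Deterministic 93-individual, 7-deme, 27-haplotype fixture.

    Three planted haplogroups separated by ~30 mutational steps (beyond any
    95% connection limit), within-group haplotypes a few steps from the
    group ancestor on disjoint sites, and two far outlier haplotypes (H9,
    H20) 16-17 steps from their own group.  The per-deme haplotype
    frequency spectra reproduce the study design exactly, so e.g. the CP
    deme carries two haplotypes 5 sites apart with counts 9 and 1.
    """
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    probs = np.array([AT_RICH[b] for b in "ACGT"])
    probs = probs / probs.sum()
    root = rng.choice(bases, size=L_STUDY, p=probs)
    free = list(rng.permutation(L_STUDY))

    def mutate(seq: np.ndarray, k: int) -> np.ndarray:
        out = seq.copy()
        for _ in range(k):
            site = free.pop()
            alt = [b for b in "ACGT" if b != out[site]]
            out[site] = alt[rng.integers(3)]
        return out

    group_anc = {g: mutate(root, 15) for g in ("AlbSItaly", "Corfu", "CItaly")}
    hap_seq: dict[str, str] = {}
    gen_order = ["H15"] + [h for h in STUDY_COUNTS if h != "H15"]
    for hap in gen_order:
        anc = group_anc[_GROUP_OF_HAP[hap]]
        if hap == "H14":  # 5 steps beyond H15 so the CP pair is 5 apart
            base = np.array(list(hap_seq["H15"]))
            hap_seq[hap] = "".join(mutate(base, 5))
        else:
            hap_seq[hap] = "".join(mutate(anc, _HAP_STEPS[hap]))
    ids, seqs, deme_of = [], [], {}
    counter: dict[str, int] = {}
    for hap, percounts in STUDY_COUNTS.items():
        for deme, cnt in percounts.items():
            for _ in range(cnt):
                counter[deme] = counter.get(deme, 0) + 1
                name = f"{deme}_{counter[deme]:02d}"
                ids.append(name)
                seqs.append(hap_seq[hap])
                deme_of[name] = deme
    order = np.argsort([list(STUDY_DEMES).index(deme_of[i]) for i in ids],
                       kind="stable")
    ids = [ids[i] for i in order]
    seqs = [seqs[i] for i in order]
    aln = Alignment(
        ids=ids, seqs=seqs, partitions=dict(STUDY_PARTITIONS),
        deme_of=deme_of,
        group_of={d: STUDY_DEMES[d][3] for d in STUDY_DEMES},
        coords={d: (STUDY_DEMES[d][1], STUDY_DEMES[d][2]) for d in STUDY_DEMES},
    )
    truth = {
        "n_haplotypes": len(STUDY_COUNTS),
        "hap_seqs": hap_seq,
        "counts": STUDY_COUNTS,
        "groups": {d: STUDY_DEMES[d][3] for d in STUDY_DEMES},
        "seed": seed,
    }
    return aln, truth
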