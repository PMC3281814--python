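"""Two-deme isolation-with-migration Bayesian inference (genealogy MCMC).

The model: two demes of equal mutation-scaled size theta = 2 N_f u that
split from a common ancestral deme (same size) T coalescent time units
(N_f generations) ago and have since exchanged migrants symmetrically at
scaled rate M = 2 N_f m.  A Metropolis-Hastings sampler explores
genealogies (topology, node times and per-branch migration paths) jointly
with (theta, M, T) under independent uniform priors on [0, bound];
mutation is HKY (or JC) with the likelihood computed by Felsenstein
pruning, branch lengths being node-age differences times theta/2 per
sequence (theta/(2 L) per site).

Times inside the sampler are in units of N_f generations: the within-deme
coalescence rate per lineage pair is 1, the per-lineage migration rate
M/2, and the expected number of mutations per sequence per unit time
theta/2.  TMRCA is reported in mutational units (root age times theta/2).

Moves: sliding-window parameter updates, node-time slides within
event-free windows, subtree pruning-regrafting with prior-bridge
resimulation of the migration path on the moved branch, and bridge
refreshes of single-branch migration paths.  Proposal densities of the
bridges are corrected by analytic two-state transition probabilities, so
the chain targets the exact posterior.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .seqio import Alignment

__all__ = ["IMConfig", "IMPosterior", "run_mdiv", "summarize_im",
           "hky_pruning_loglik", "estimate_kappa"]

NEG_INF = float("-inf")


# ---------------------------------------------------------------------------
# HKY likelihood machinery
# ---------------------------------------------------------------------------

BASE_INDEX = {b: i for i, b in enumerate("ACGT")}
TRANSITIONS = {(0, 2), (2, 0), (1, 3), (3, 1)}  # A<->G, C<->T


def _hky_eig(kappa: float, freqs: np.ndarray):
    q = np.zeros((4, 4))
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            q[i, j] = freqs[j] * (kappa if (i, j) in TRANSITIONS else 1.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    q /= -(freqs * np.diag(q)).sum()  # one expected substitution per unit
    w, v = np.linalg.eig(q)
    return np.real(w), np.real(v), np.real(np.linalg.inv(v))


def _branch_pmats(blens: np.ndarray, eig) -> np.ndarray:
    w, v, vinv = eig
    e = np.exp(np.outer(blens, w))  # (nb, 4)
    p = np.einsum("ij,bj,jk->bik", v, e, vinv)
    return np.clip(p, 1e-300, None)


def _compress_columns(seqs: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Unique alignment columns (as leaf-state matrix) and their weights."""
    arr = np.array([[BASE_INDEX.get(c, -1) for c in s] for s in seqs])
    cols, weights = np.unique(arr.T, axis=0, return_counts=True)
    return cols.T, weights.astype(float)  # (n_leaves, npat), (npat,)


def hky_pruning_loglik(
    parents: np.ndarray,
    times: np.ndarray,
    patterns: np.ndarray,
    weights: np.ndarray,
    mut_rate_per_site: float,
    kappa: float,
    freqs: np.ndarray,
    eig=None,
) -> float:
    """Felsenstein pruning log-likelihood of site patterns on a genealogy.

    ``mut_rate_per_site`` converts node-age differences to expected
    substitutions per site.  Missing states (-1) are treated as fully
    ambiguous.
    """
    if eig is None:
        eig = _hky_eig(kappa, freqs)
    n_nodes = len(parents)
    n_leaves, npat = patterns.shape
    blens = np.zeros(n_nodes)
    for i in range(n_nodes):
        if parents[i] >= 0:
            blens[i] = (times[parents[i]] - times[i]) * mut_rate_per_site
    pmats = _branch_pmats(blens, eig)
    partial = np.zeros((n_nodes, 4, npat))
    for leaf in range(n_leaves):
        st = patterns[leaf]
        lik = np.zeros((4, npat))
        ok = st >= 0
        lik[:, ~ok] = 1.0
        lik[st[ok], np.where(ok)[0]] = 1.0
        partial[leaf] = lik
    children: dict[int, list[int]] = {}
    for i in range(n_nodes):
        if parents[i] >= 0:
            children.setdefault(parents[i], []).append(i)
    order = sorted(children, key=lambda i: times[i])
    scale = 0.0
    for node in order:
        prod = np.ones((4, npat))
        for c in children[node]:
            prod *= pmats[c] @ partial[c]
        mx = prod.max(axis=0)
        mx = np.where(mx > 0, mx, 1.0)
        partial[node] = prod / mx
        scale += float(weights @ np.log(mx))
    root = order[-1]
    site_lik = freqs @ partial[root]
    return float(weights @ np.log(np.clip(site_lik, 1e-300, None))) + scale


def estimate_kappa(seqs: list[str]) -> float:
    """Crude empirical HKY kappa from pairwise transition/transversion counts."""
    arr = np.array([[BASE_INDEX.get(c, -1) for c in s] for s in seqs])
    ts = tv = 0
    n = len(seqs)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = arr[i], arr[j]
            ok = (a >= 0) & (b >= 0) & (a != b)
            for x, y in zip(a[ok], b[ok]):
                if (x, y) in TRANSITIONS:
                    ts += 1
                else:
                    tv += 1
    if tv == 0:
        return 10.0
    counts = np.bincount(arr[arr >= 0], minlength=4).astype(float)
    f = counts / counts.sum()
    ts_pairs = f[0] * f[2] + f[1] * f[3]
    tv_pairs = (f[0] + f[2]) * (f[1] + f[3])
    r = ts / tv
    return max(0.5, r * tv_pairs / ts_pairs)


# ---------------------------------------------------------------------------
# Genealogy state
# ---------------------------------------------------------------------------

@dataclass
class GenealogyState:
    """Augmented genealogy: tree, node ages, per-edge migration paths.

    ``events[i]`` lists (time, deme_after) flips on the edge above node i,
    ascending; ``deme_start[i]`` is the lineage deme at the node itself.
    """

    parents: np.ndarray
    times: np.ndarray
    deme_start: np.ndarray  # meaningful for leaves; internal demes derived
    events: dict[int, list[tuple[float, int]]]

    def copy(self) -> "GenealogyState":
        return GenealogyState(
            self.parents.copy(), self.times.copy(), self.deme_start.copy(),
            {k: list(v) for k, v in self.events.items()},
        )

    @property
    def root(self) -> int:
        return int(np.where(self.parents < 0)[0][0])

    def node_deme(self, i: int) -> int:
        """Deme of the lineage just above node i, derived by propagation.

        Internal-node demes are always recomputed from the leaf labels and
        migration paths, so they can never go stale under time or split
        moves.  Above the split the labels are bookkeeping continuations
        (lowest-id child), matching the prior walk's convention.
        """
        n_leaves = self.n_leaves()
        if i < n_leaves:
            return int(self.deme_start[i])
        ch = sorted(np.where(self.parents == i)[0])
        c = int(ch[0])
        return self.deme_at(c, self.times[i])

    def deme_at(self, i: int, t: float) -> int:
        d = self.node_deme(i)
        for te, da in self.events.get(i, []):
            if te <= t:
                d = da
            else:
                break
        return d

    def n_leaves(self) -> int:
        return (len(self.parents) + 1) // 2


def _log_structured_prior(st: GenealogyState, M: float, T: float) -> float:
    """Log density of the augmented genealogy under the IM coalescent."""
    n_nodes = len(st.parents)
    n_leaves = st.n_leaves()
    timeline: list[tuple[float, str, Any]] = []
    for i in range(n_nodes):
        if i >= n_leaves:
            timeline.append((st.times[i], "coal", i))
        for te, da in st.events.get(i, []):
            timeline.append((te, "mig", (i, da)))
    timeline.sort(key=lambda x: x[0])
    children: dict[int, list[int]] = {}
    for i in range(n_nodes):
        if st.parents[i] >= 0:
            children.setdefault(st.parents[i], []).append(i)
    # current deme per active lineage (edge id)
    active = {i: int(st.deme_start[i]) for i in range(n_leaves)}
    logp = 0.0
    t_now = 0.0
    split_done = T <= 0.0

    def interval(t_from: float, t_to: float) -> float:
        out = 0.0
        lo = t_from
        while lo < t_to - 1e-300:
            hi = min(t_to, T) if lo < T else t_to
            k = len(active)
            if lo < T:
                k0 = sum(1 for d in active.values() if d == 0)
                k1 = k - k0
                rate = k0 * (k0 - 1) / 2 + k1 * (k1 - 1) / 2 + k * M / 2
            else:
                rate = k * (k - 1) / 2
            out -= rate * (hi - lo)
            lo = hi
        return out

    for t, kind, info in timeline:
        logp += interval(t_now, t)
        t_now = t
        if kind == "mig":
            if t >= T:
                return NEG_INF
            if M <= 0:
                return NEG_INF
            i, da = info
            if i not in active:
                return NEG_INF
            if active[i] == da:
                return NEG_INF
            active[i] = da
            logp += np.log(M / 2)
        else:
            node = info
            ch = children.get(node, [])
            if len(ch) != 2 or any(c not in active for c in ch):
                return NEG_INF
            if t < T:
                if active[ch[0]] != active[ch[1]]:
                    return NEG_INF
                new_d = active[ch[0]]
            else:
                new_d = active[ch[0]]  # demes irrelevant above T
            for c in ch:
                del active[c]
            if node != st.root:
                active[node] = new_d
            # coalescence of a specific pair has rate 1: log(1) = 0
    if len(active) > 0:
        return NEG_INF
    return logp


# ---------------------------------------------------------------------------
# Bridge simulation of two-state migration paths
# ---------------------------------------------------------------------------

def _simulate_path(
    start: int, t0: float, t1: float, M: float, rng
) -> list[tuple[float, int]]:
    """Forward two-state path (flip rate M/2) on [t0, t1)."""
    out = []
    d, t = start, t0
    if M <= 0:
        return out
    while True:
        t += rng.exponential(2.0 / M)
        if t >= t1:
            return out
        d = 1 - d
        out.append((t, d))


def _path_logdensity(k_flips: int, duration: float, M: float) -> float:
    if M <= 0:
        return NEG_INF if k_flips > 0 else 0.0
    return k_flips * np.log(M / 2) - (M / 2) * duration


def _flip_prob(M: float, duration: float, same: bool) -> float:
    """Two-state symmetric chain: P(end state | start state)."""
    if M <= 0:
        return 1.0 if same else 0.0
    e = np.exp(-M * duration)
    return (1 + e) / 2 if same else (1 - e) / 2


def _propose_bridge(
    start: int, target: int | None, t0: float, t1: float, T: float,
    M: float, rng, max_tries: int = 30,
):
    """Bridge path on [t0, min(t1, T)); returns (path, log q) or None.

    ``target`` constrains the deme at the top of the segment (None when the
    branch top lies above T).  log q is the proposal log-density of the
    returned path.
    """
    hi = min(t1, T)
    if hi <= t0:
        return [], 0.0
    dur = hi - t0
    if target is None:
        path = _simulate_path(start, t0, hi, M, rng)
        return path, _path_logdensity(len(path), dur, M)
    for _ in range(max_tries):
        path = _simulate_path(start, t0, hi, M, rng)
        end = start if not path else path[-1][1]
        if end == target:
            norm = _flip_prob(M, dur, start == target)
            if norm <= 0:
                return None
            return path, _path_logdensity(len(path), dur, M) - np.log(norm)
    return None


def _bridge_logq(
    path: list[tuple[float, int]], start: int, target: int | None,
    t0: float, t1: float, T: float, M: float,
) -> float:
    """Proposal log-density that _propose_bridge would assign to ``path``."""
    hi = min(t1, T)
    if hi <= t0:
        return 0.0 if not path else NEG_INF
    dur = hi - t0
    base = _path_logdensity(len(path), dur, M)
    if target is None:
        return base
    norm = _flip_prob(M, dur, start == target)
    if norm <= 0:
        return NEG_INF
    return base - np.log(norm)


# ---------------------------------------------------------------------------
# Sampler
# ---------------------------------------------------------------------------

@dataclass
class IMConfig:
    """Priors (upper bounds, all required) and chain settings."""

    theta_max: float
    M_max: float
    T_max: float
    steps: int = 4000
    burnin: float = 0.1
    n_chains: int = 3
    thin: int = 2
    seed: int | None = None
    substitution: str = "hky"  # or "jc"
    kappa: float | None = None
    rhat_threshold: float = 1.2

    def __post_init__(self) -> None:
        if min(self.theta_max, self.M_max, self.T_max) < 0:
            raise ValueError("prior bounds must be positive")
        if not 0 <= self.burnin < 1:
            raise ValueError("burn-in fraction must be in [0, 1)")


@dataclass
class IMPosterior:
    traces: dict[str, np.ndarray]  # theta, M, T, tmrca (concatenated chains)
    chain_traces: list[dict[str, np.ndarray]]
    modes: dict[str, float]
    rhat: dict[str, float]
    flagged: bool
    flags: list[str] = field(default_factory=list)
    accept_rates: dict[str, float] = field(default_factory=dict)


def _init_state(
    leaf_demes: np.ndarray, M: float, T: float, rng
) -> GenealogyState:
    """Simulate a valid genealogy from the structured coalescent prior."""
    n = len(leaf_demes)
    parents = np.full(2 * n - 1, -1, dtype=int)
    times = np.zeros(2 * n - 1)
    deme_start = np.zeros(2 * n - 1, dtype=int)
    deme_start[:n] = leaf_demes
    events: dict[int, list[tuple[float, int]]] = {}
    active = {i: int(leaf_demes[i]) for i in range(n)}
    t = 0.0
    nxt = n
    while len(active) > 1:
        k = len(active)
        if t < T:
            k0 = sum(1 for d in active.values() if d == 0)
            k1 = k - k0
            c_rate = k0 * (k0 - 1) / 2 + k1 * (k1 - 1) / 2
            m_rate = k * M / 2
            total = c_rate + m_rate
            if total <= 0:
                t = T
                continue
            dt = rng.exponential(1.0 / total)
            if t + dt >= T:
                t = T
                continue
            t += dt
            if rng.random() < m_rate / total:
                i = list(active)[rng.integers(k)]
                active[i] = 1 - active[i]
                events.setdefault(i, []).append((t, active[i]))
                continue
            # coalescence: choose deme weighted by pair counts
            w0 = k0 * (k0 - 1) / 2
            w1 = k1 * (k1 - 1) / 2
            d = 0 if rng.random() < w0 / (w0 + w1) else 1
            pool = [i for i in active if active[i] == d]
        else:
            t += rng.exponential(2.0 / (k * (k - 1)))
            pool = list(active)
        i, j = rng.choice(len(pool), 2, replace=False)
        a, b = pool[i], pool[j]
        parents[a] = parents[b] = nxt
        times[nxt] = t
        deme_start[nxt] = active[a]
        del active[a], active[b]
        active[nxt] = int(deme_start[nxt])
        nxt += 1
    return GenealogyState(parents, times, deme_start, events)


class _Sampler:
    def __init__(self, patterns, weights, leaf_demes, cfg: IMConfig,
                 kappa, freqs, L, rng):
        self.patterns = patterns
        self.weights = weights
        self.leaf_demes = leaf_demes
        self.cfg = cfg
        self.L = L
        self.rng = rng
        self.freqs = freqs
        self.kappa = kappa
        self.eig = _hky_eig(kappa, freqs)
        self.theta = min(max(0.5, cfg.theta_max / 10), cfg.theta_max * 0.9)
        self.M = min(0.05, cfg.M_max / 2)
        self.T = cfg.T_max / 2
        for _ in range(100):
            self.state = _init_state(leaf_demes, self.M, self.T, rng)
            if np.isfinite(self._prior(self.state, self.M, self.T)):
                break
        self.logP = self._prior(self.state, self.M, self.T)
        self.logL = self._lik(self.state, self.theta)
        self.prop = {"theta": 0, "M": 0, "T": 0, "time": 0, "spr": 0, "path": 0}
        self.acc = dict(self.prop)

    # -- target pieces ----------------------------------------------------
    def _prior(self, st, M, T):
        return _log_structured_prior(st, M, T)

    def _lik(self, st, theta):
        if self.patterns is None:
            return 0.0
        return hky_pruning_loglik(
            st.parents, st.times, self.patterns, self.weights,
            mut_rate_per_site=theta / (2.0 * self.L),
            kappa=self.kappa, freqs=self.freqs, eig=self.eig,
        )

    def _mh(self, kind, d_logtarget, log_hastings=0.0):
        self.prop[kind] += 1
        if d_logtarget + log_hastings > np.log(self.rng.random() + 1e-300):
            self.acc[kind] += 1
            return True
        return False

    # -- parameter moves ---------------------------------------------------
    def move_theta(self):
        w = self.cfg.theta_max / 10
        t_new = _reflect(self.theta + self.rng.uniform(-w, w),
                         1e-9, self.cfg.theta_max)
        logL_new = self._lik(self.state, t_new)
        if self._mh("theta", logL_new - self.logL):
            self.theta, self.logL = t_new, logL_new

    def move_M(self):
        if self.cfg.M_max <= 0:
            return
        w = max(self.cfg.M_max / 10, 0.02)
        m_new = _reflect(self.M + self.rng.uniform(-w, w), 0.0, self.cfg.M_max)
        logP_new = self._prior(self.state, m_new, self.T)
        if self._mh("M", logP_new - self.logP):
            self.M, self.logP = m_new, logP_new

    def move_T(self):
        w = self.cfg.T_max / 10
        t_new = _reflect(self.T + self.rng.uniform(-w, w), 0.0, self.cfg.T_max)
        logP_new = self._prior(self.state, self.M, t_new)
        if self._mh("T", logP_new - self.logP):
            self.T, self.logP = t_new, logP_new

    # -- genealogy moves ---------------------------------------------------
    def move_node_time(self):
        st = self.state
        n_leaves = st.n_leaves()
        n_nodes = len(st.parents)
        node = int(self.rng.integers(n_leaves, n_nodes))
        children = [i for i in range(n_nodes) if st.parents[i] == node]
        lo = 0.0
        for c in children:
            lo = max(lo, st.times[c])
            if st.events.get(c):
                lo = max(lo, st.events[c][-1][0])
        is_root = st.parents[node] < 0
        if is_root:
            w = max(0.5, self.T / 2)
            t_new = st.times[node] + self.rng.uniform(-w, w)
            if t_new <= lo:
                self.prop["time"] += 1
                return
            log_h = 0.0
        else:
            hi = st.times[st.parents[node]]
            if st.events.get(node):
                hi = min(hi, st.events[node][0][0])
            if hi <= lo:
                self.prop["time"] += 1
                return
            t_new = self.rng.uniform(lo, hi)
            log_h = 0.0
        new = st.copy()
        new.times[node] = t_new
        logP_new = self._prior(new, self.M, self.T)
        if logP_new == NEG_INF:
            self.prop["time"] += 1
            return
        logL_new = self._lik(new, self.theta)
        if self._mh("time", (logP_new - self.logP) + (logL_new - self.logL),
                    log_h):
            self.state, self.logP, self.logL = new, logP_new, logL_new

    def _edges(self, st):
        return [i for i in range(len(st.parents)) if st.parents[i] >= 0]

    def move_spr(self):
        st = self.state
        rng = self.rng
        self.prop["spr"] += 1
        n_nodes = len(st.parents)
        root = st.root
        candidates = [i for i in range(n_nodes) if st.parents[i] >= 0]
        i = int(candidates[rng.integers(len(candidates))])
        p = int(st.parents[i])
        sib = [c for c in range(n_nodes) if st.parents[c] == p and c != i][0]
        g = int(st.parents[p])
        if g < 0 and (st.events.get(sib) or st.events.get(p)):
            return  # would drop sibling-path events irreversibly
        old_attach_time = st.times[p]
        old_path = list(st.events.get(i, []))
        stem_w = max(0.5, self.T)

        new = st.copy()
        # detach: remove p, splice sib to g
        if g >= 0:
            new.parents[sib] = g
            new.events[sib] = new.events.get(sib, []) + new.events.get(p, [])
            if not new.events[sib]:
                del new.events[sib]
        else:
            new.parents[sib] = -1
            new.events.pop(sib, None)
        new.parents[p] = -2  # detached marker
        new.events.pop(p, None)
        new.events.pop(i, None)
        sub_root = sib if g < 0 else _find_root(new, sib)

        # candidate target edges in the detached tree + stem
        in_subtree = _descendants(new, i) | {i}
        edges = [e for e in range(n_nodes)
                 if new.parents[e] >= 0 and e not in in_subtree
                 and e != p]
        n_targets = len(edges) + 1  # + stem
        choice = int(rng.integers(n_targets))
        t_i = st.times[i]
        if choice < len(edges):
            e = edges[choice]
            lo = max(t_i, new.times[e])
            hi = new.times[new.parents[e]]
            if hi <= lo:
                return
            t_att = rng.uniform(lo, hi)
            log_q_att = -np.log(n_targets) - np.log(hi - lo)
        else:
            e = sub_root
            base = max(t_i, new.times[sub_root])
            t_att = base + rng.exponential(stem_w)
            log_q_att = -np.log(n_targets) - (t_att - base) / stem_w \
                + np.log(1.0 / stem_w)

        # reverse-attachment density (reattach at the old location)
        if g >= 0:
            lo_r = max(t_i, st.times[sib])
            hi_r = st.times[g]
            if hi_r <= lo_r:
                return
            log_q_att_rev = -np.log(n_targets) - np.log(hi_r - lo_r)
        else:
            base_r = max(t_i, st.times[sib])
            log_q_att_rev = -np.log(n_targets) \
                - (old_attach_time - base_r) / stem_w + np.log(1.0 / stem_w)

        # build attachment: new internal node p at t_att on edge e
        new.parents[p] = -1
        new.times[p] = t_att
        if choice < len(edges):
            gp = new.parents[e]
            new.parents[e] = p
            new.parents[p] = gp
            new.parents[i] = p
            ev = new.events.pop(e, [])
            below = [x for x in ev if x[0] <= t_att]
            above = [x for x in ev if x[0] > t_att]
            if below:
                new.events[e] = below
            if above:
                new.events[p] = above
            host_deme = new.deme_at(e, min(t_att, self.T - 1e-12)) \
                if t_att < self.T else None
        else:
            new.parents[e] = p
            new.parents[i] = p
            new.parents[p] = -1
            host_deme = new.deme_at(e, min(t_att, self.T - 1e-12)) \
                if t_att < self.T else None
        target = host_deme if t_att < self.T else None
        prop = _propose_bridge(new.node_deme(i), target, t_i, t_att,
                               self.T, self.M, rng)
        if prop is None:
            return
        path_new, log_q_path = prop
        if path_new:
            new.events[i] = path_new
        # reverse path density for the old path at the old attachment
        old_target = (st.deme_at(sib, min(old_attach_time, self.T - 1e-12))
                      if old_attach_time < self.T else None)
        log_q_path_rev = _bridge_logq(
            old_path, st.node_deme(i), old_target, t_i,
            old_attach_time, self.T, self.M,
        )
        logP_new = self._prior(new, self.M, self.T)
        if logP_new == NEG_INF:
            return
        logL_new = self._lik(new, self.theta)
        log_h = (log_q_att_rev + log_q_path_rev) - (log_q_att + log_q_path)
        self.prop["spr"] -= 1  # counted again in _mh
        if self._mh("spr", (logP_new - self.logP) + (logL_new - self.logL),
                    log_h):
            self.state, self.logP, self.logL = new, logP_new, logL_new

    def move_path(self):
        st = self.state
        rng = self.rng
        edges = [i for i in range(len(st.parents))
                 if st.parents[i] >= 0 and st.times[i] < self.T]
        if not edges:
            self.prop["path"] += 1
            return
        i = int(edges[rng.integers(len(edges))])
        t0, t1 = st.times[i], st.times[st.parents[i]]
        target = (st.deme_at(i, min(t1, self.T) - 1e-12)
                  if min(t1, self.T) > t0 else None)
        old_path = list(st.events.get(i, []))
        prop = _propose_bridge(st.node_deme(i), target, t0, t1,
                               self.T, self.M, rng)
        if prop is None:
            self.prop["path"] += 1
            return
        path_new, log_q_new = prop
        new = st.copy()
        new.events.pop(i, None)
        if path_new:
            new.events[i] = path_new
        logP_new = self._prior(new, self.M, self.T)
        if logP_new == NEG_INF:
            self.prop["path"] += 1
            return
        log_q_old = _bridge_logq(old_path, st.node_deme(i), target,
                                 t0, t1, self.T, self.M)
        if self._mh("path", logP_new - self.logP, log_q_old - log_q_new):
            self.state, self.logP = new, logP_new

    # -- main loop ---------------------------------------------------------
    def run(self, n_sweeps: int, record_every: int):
        n = self.state.n_leaves()
        trace = {"theta": [], "M": [], "T": [], "tmrca": [], "root_age": []}
        for sweep in range(n_sweeps):
            self.move_theta()
            self.move_M()
            self.move_T()
            for _ in range(max(2, n // 2)):
                self.move_node_time()
            for _ in range(max(2, n // 2)):
                self.move_spr()
            if self.M > 0:
                self.move_path()
            if sweep % record_every == 0:
                root_age = float(self.state.times[self.state.root])
                trace["theta"].append(self.theta)
                trace["M"].append(self.M)
                trace["T"].append(self.T)
                trace["root_age"].append(root_age)
                trace["tmrca"].append(root_age * self.theta / 2.0)
        return {k: np.array(v) for k, v in trace.items()}


def _reflect(x: float, lo: float, hi: float) -> float:
    span = hi - lo
    if span <= 0:
        return lo
    x = (x - lo) % (2 * span)
    return lo + (x if x <= span else 2 * span - x)


def _find_root(st: GenealogyState, i: int) -> int:
    while st.parents[i] >= 0:
        i = int(st.parents[i])
    return i


def _descendants(st: GenealogyState, node: int) -> set[int]:
    out, stack = set(), [node]
    kids: dict[int, list[int]] = {}
    for i in range(len(st.parents)):
        if st.parents[i] >= 0:
            kids.setdefault(int(st.parents[i]), []).append(i)
    while stack:
        x = stack.pop()
        for c in kids.get(x, []):
            out.add(c)
            stack.append(c)
    return out


def _mode_fd(x: np.ndarray) -> float:
    """Histogram mode with Freedman-Diaconis binning."""
    x = np.asarray(x)
    if len(x) < 10 or np.ptp(x) == 0:
        return float(np.median(x))
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    width = 2 * iqr / len(x) ** (1 / 3)
    if width <= 0:
        return float(np.median(x))
    nbins = max(5, min(200, int(np.ceil(np.ptp(x) / width))))
    hist, edges = np.histogram(x, bins=nbins)
    k = int(np.argmax(hist))
    return float(0.5 * (edges[k] + edges[k + 1]))


def _rhat(chains: list[np.ndarray]) -> float:
    """Gelman-Rubin potential scale reduction over chains."""
    m = len(chains)
    n = min(len(c) for c in chains)
    if m < 2 or n < 4:
        return 1.0
    arr = np.stack([c[:n] for c in chains])
    means = arr.mean(axis=1)
    w = arr.var(axis=1, ddof=1).mean()
    b = n * means.var(ddof=1)
    if w <= 0:
        return 1.0
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))


def run_mdiv(
    a: Alignment | None,
    deme_pair: tuple[str, str] | None,
    cfg: IMConfig,
    leaf_demes: np.ndarray | None = None,
    seqs: list[str] | None = None,
) -> IMPosterior:
    """Sample the IM posterior for a pair of demes.

    Either pass an alignment plus the deme pair, or (for simulation
    studies and prior-recovery checks) explicit ``leaf_demes`` and
    optionally ``seqs``; ``seqs=None`` runs the sampler without data,
    targeting the prior.
    """
    if a is not None:
        d0, d1 = deme_pair
        ids = a.deme_members(d0) + a.deme_members(d1)
        sub = a.subset(ids)
        seqs = sub.seqs
        leaf_demes = np.array(
            [0 if a.deme_of[i] == d0 else 1 for i in ids]
        )
        L = a.L
    else:
        if leaf_demes is None:
            raise ValueError("need an alignment or explicit leaf demes")
        L = len(seqs[0]) if seqs else 1000
    if seqs is not None:
        if any("-" in s for s in seqs):
            raise ValueError("gapped sequences not supported in the IM sampler")
        patterns, weights = _compress_columns(seqs)
        counts = np.bincount(patterns[patterns >= 0], minlength=4).astype(float)
        freqs = counts / counts.sum() if counts.sum() else np.full(4, 0.25)
        freqs = np.clip(freqs, 0.02, None)
        freqs /= freqs.sum()
        if cfg.substitution == "jc":
            kappa, freqs = 1.0, np.full(4, 0.25)
        else:
            kappa = cfg.kappa if cfg.kappa is not None else estimate_kappa(seqs)
    else:
        patterns = weights = None
        kappa, freqs = 1.0, np.full(4, 0.25)

    ss = np.random.SeedSequence(cfg.seed)
    chain_traces = []
    accept = {}
    for c, child in enumerate(ss.spawn(cfg.n_chains)):
        rng = np.random.default_rng(child)
        s = _Sampler(patterns, weights, leaf_demes, cfg, kappa, freqs, L, rng)
        tr = s.run(cfg.steps, record_every=cfg.thin)
        burn = int(cfg.burnin * len(tr["theta"]))
        chain_traces.append({k: v[burn:] for k, v in tr.items()})
        if c == 0:
            accept = {
                k: (s.acc[k] / s.prop[k] if s.prop[k] else 0.0)
                for k in s.prop
            }
    traces = {
        k: np.concatenate([ct[k] for ct in chain_traces])
        for k in chain_traces[0]
    }
    rhat = {
        k: _rhat([ct[k] for ct in chain_traces])
        for k in ("theta", "M", "T")
    }
    flags = [
        f"poor mixing for {k} (rhat={v:.3f})"
        for k, v in rhat.items() if v > cfg.rhat_threshold
    ]
    modes = {k: _mode_fd(v) for k, v in traces.items()}
    return IMPosterior(
        traces=traces, chain_traces=chain_traces, modes=modes, rhat=rhat,
        flagged=bool(flags), flags=flags, accept_rates=accept,
    )


def summarize_im(
    p: IMPosterior, rm, generation_years: tuple[float, float] = (1.0, 10.0)
) -> dict[str, Any]:
    """Natural-unit summary over a generation-time range.

    N_ef = theta/(2 u g); divergence and TMRCA are converted to
    generations with the same rate basis (T_gens = T * N_ef;
    TMRCA_gens = TMRCA/(u g)) and reported as (short-generation,
    long-generation) ranges.
    """
    from .mismatch import RateModel  # noqa: F401 (type reference)

    u = rm.u_seq
    th, tdiv, tmrca = p.modes["theta"], p.modes["T"], p.modes["tmrca"]
    out: dict[str, Any] = {"theta": th, "M": p.modes["M"], "T_scaled": tdiv,
                           "TMRCA_mut": tmrca, "flagged": p.flagged}
    g_lo, g_hi = generation_years
    nef = {g: th / (2 * u * g) for g in (g_lo, g_hi)}
    out["N_ef_range"] = (nef[g_hi], nef[g_lo])
    out["T_range"] = (tdiv * nef[g_hi], tdiv * nef[g_lo])
    out["TMRCA_range"] = (tmrca / (u * g_hi), tmrca / (u * g_lo))
    out["tmrca_over_T"] = (
        out["TMRCA_range"][1] / out["T_range"][1]
        if out["T_range"][1] > 0 else float("inf")
    )
    return out
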