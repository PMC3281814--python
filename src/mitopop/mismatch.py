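"""Mismatch distributions, expansion-model fitting and Fu's FS.

Two expected mismatch models are fitted by least squares (SSD):

* sudden demographic expansion: a population of mutation-scaled size
  theta0 grew instantaneously to theta1 at tau mutational time units ago.
  The pairwise coalescence hazard is 1/theta1 on (0, tau) and 1/theta0
  beyond, and the number of differences given coalescence at x is
  Poisson(x), giving a closed-form mixture of an incomplete-gamma term and
  a Poisson-convolved geometric tail.

* spatial (infinite-island) expansion: the sampled deme (theta = 2 N u)
  exchanges migrants at scaled rate M = 2 N m with infinitely many demes;
  at tau the process collapses to a single ancestral deme of the same
  theta.  Within the recent phase a pair either coalesces (rate 1/theta)
  or separates forever (rate M/theta), so the probability of a recent
  coalescence is 1/(1+M) of the events.

Goodness of fit uses a parametric bootstrap: samples of the observed size
are simulated under the fitted model, refitted, and P_SSD is the fraction
of simulated SSDs at least as large as the observed one.

Fu's FS is computed from the Ewens sampling distribution
(S' = Pr(K >= k_obs | theta = pi_hat, n), FS = ln(S'/(1-S'))) with its
p-value calibrated against neutral constant-size coalescent simulations.

Natural-unit conversions use the package's sequence mutation rate
u_seq (mutations per sequence per year): T = tau / (2 u), N = theta / (2 u),
m = M / (2 N).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import optimize, special

from .diversity import pairwise_differences
from .seqio import Alignment
from .simulate import SimConfig, pairwise_path_mutations, sample_genealogy

__all__ = [
    "MismatchFit",
    "RateModel",
    "observed_mismatch",
    "expected_mismatch_demographic",
    "expected_mismatch_spatial",
    "fit_demographic",
    "fit_spatial",
    "to_natural_units",
    "fu_fs",
]

THETA_CAP = 9999.0


@dataclass
class RateModel:
    """Sequence-level mutation rate for converting mutation-scaled estimates.

    ``u_seq`` is in mutations per sequence per year; the default 2e-5
    corresponds to a 2%-per-Myr divergence basis over roughly a kilobase.
    """

    u_seq: float = 2e-5
    generation_years: float = 1.0
    basis: str = "2% sequence divergence per Myr"

    def __post_init__(self) -> None:
        if self.u_seq <= 0:
            raise ValueError("u_seq must be positive")


@dataclass
class MismatchFit:
    model: str  # "demographic" | "spatial"
    obs: np.ndarray
    obs_mean: float
    n: int
    params: dict[str, float]
    ssd: float
    p_ssd: float | None = None
    conversions: dict[str, float] | None = None
    flags: list[str] = field(default_factory=list)


def observed_mismatch(
    a: Alignment, subset: list[str] | None = None
) -> tuple[np.ndarray, float]:
    """Normalized histogram of pairwise differences and its mean."""
    ids = subset if subset is not None else a.ids
    if len(ids) < 2:
        raise ValueError("mismatch distribution requires n >= 2")
    d = pairwise_differences(a, ids)
    iu = np.triu_indices(len(ids), k=1)
    vals = d[iu].astype(int)
    hist = np.bincount(vals)
    return hist / hist.sum(), float(vals.mean())


def _geom(theta: float, j: np.ndarray) -> np.ndarray:
    """Equilibrium mismatch: theta^j / (1+theta)^(j+1)."""
    if theta <= 0:
        return (j == 0).astype(float)
    return np.exp(j * np.log(theta) - (j + 1) * np.log1p(theta))


def _poisson_pmf(k: np.ndarray, lam: float) -> np.ndarray:
    if lam <= 0:
        return (k == 0).astype(float)
    return np.exp(k * np.log(lam) - lam - special.gammaln(k + 1))


def _shifted_geometric(tau: float, theta: float, j: np.ndarray) -> np.ndarray:
    """Poisson(tau) convolved with the equilibrium geometric of theta."""
    jmax = int(j.max())
    ks = np.arange(jmax + 1)
    pois = _poisson_pmf(ks, tau)
    geom = _geom(theta, ks)
    return np.convolve(pois, geom)[: jmax + 1][j]


def expected_mismatch_demographic(
    tau: float, theta0: float, theta1: float, jmax: int
) -> np.ndarray:
    """Expected mismatch under a sudden demographic expansion, j = 0..jmax."""
    j = np.arange(jmax + 1)
    th1 = max(theta1, 1e-12)
    a = (1.0 + th1) / th1
    recent = _geom(th1, j) * special.gammainc(j + 1, a * tau)
    surv = np.exp(-tau / th1)
    ancestral = surv * _shifted_geometric(tau, theta0, j)
    return recent + ancestral


def expected_mismatch_spatial(
    tau: float, theta: float, M: float, jmax: int
) -> np.ndarray:
    """Expected mismatch under the infinite-island spatial expansion."""
    j = np.arange(jmax + 1)
    th = max(theta, 1e-12)
    a = 1.0 + (1.0 + M) / th
    recent = special.gammainc(j + 1, a * tau) * np.exp(
        -(j + 1) * np.log(a) - np.log(th)
    )
    p_nocoal = 1.0 - (1.0 - np.exp(-(1.0 + M) * tau / th)) / (1.0 + M)
    ancestral = p_nocoal * _shifted_geometric(tau, theta, j)
    return recent + ancestral


def _ssd(obs: np.ndarray, exp_: np.ndarray) -> float:
    return float(((obs - exp_) ** 2).sum())


def _fit_curve(
    obs: np.ndarray, model: str,
    warm_start: dict[str, float] | None = None,
) -> tuple[dict[str, float], float]:
    jmax = len(obs) - 1
    mean = float((np.arange(jmax + 1) * obs).sum())
    m = max(mean, 0.5)

    if model == "demographic":
        def objective(u):
            tau, th0, th1 = u[0] ** 2, u[1] ** 2, min(u[2] ** 2, THETA_CAP)
            return _ssd(obs, expected_mismatch_demographic(tau, th0, th1, jmax))
        starts = [
            (np.sqrt(t), np.sqrt(t0), np.sqrt(t1))
            for t in (0.25 * m, m, 2.0 * m)
            for t0 in (0.01, 0.5 * m)
            for t1 in (m, 20.0 * m)
        ]
    else:
        def objective(u):
            tau, th, mm = u[0] ** 2, u[1] ** 2, min(u[2] ** 2, THETA_CAP)
            return _ssd(obs, expected_mismatch_spatial(tau, th, mm, jmax))
        starts = [
            (np.sqrt(t), np.sqrt(th), np.sqrt(mm))
            for t in (0.25 * m, m, 2.0 * m)
            for th in (0.05, 0.5 * m)
            for mm in (0.1, 1.0, 50.0)
        ]
    if warm_start is not None:
        # bootstrap refits start near the generating parameters
        w = np.sqrt(np.maximum(list(warm_start.values()), 1e-8))
        starts = [tuple(w), (np.sqrt(0.5 * m), w[1], w[2]),
                  (np.sqrt(2.0 * m), w[1], w[2])]

    best = None
    for s in starts:
        res = optimize.minimize(
            objective, np.asarray(s, dtype=float), method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-10, "maxiter": 2000},
        )
        if best is None or res.fun < best.fun:
            best = res
    u = best.x
    if model == "demographic":
        params = {
            "tau": u[0] ** 2, "theta0": u[1] ** 2,
            "theta1": min(u[2] ** 2, THETA_CAP),
        }
    else:
        params = {
            "tau": u[0] ** 2, "theta": u[1] ** 2, "M": min(u[2] ** 2, THETA_CAP),
        }
    return params, float(best.fun)


def _simulate_mismatch(
    model: str, params: dict[str, float], n: int, rng: np.random.Generator
) -> np.ndarray:
    if model == "demographic":
        cfg = SimConfig(
            scenario="sudden_expansion", sample_sizes=(n,),
            tau=params["tau"], theta0=params["theta0"],
            theta1=params["theta1"],
        )
    else:
        cfg = SimConfig(
            scenario="spatial_expansion", sample_sizes=(n,),
            theta=params["theta"], M=params["M"], tau=params["tau"],
        )
    parents, times = sample_genealogy(cfg, rng)
    d = pairwise_path_mutations(parents, times, n, rng)
    iu = np.triu_indices(n, k=1)
    vals = d[iu].astype(int)
    hist = np.bincount(vals)
    return hist / hist.sum()


def _bootstrap_p(
    model: str, params: dict[str, float], ssd_obs: float, n: int,
    n_boot: int, seed: int | None,
) -> float:
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_boot):
        obs_b = _simulate_mismatch(model, params, n, rng)
        _, ssd_b = _fit_curve(obs_b, model, warm_start=params)
        if ssd_b >= ssd_obs - 1e-15:
            count += 1
    return (count + 1) / (n_boot + 1)


def _make_fit(
    obs, n, model, n_boot, seed, rate_model
) -> MismatchFit:
    obs = np.asarray(obs, dtype=float)
    if obs.ndim != 1 or obs.sum() <= 0:
        raise ValueError("observed mismatch must be a non-empty histogram")
    obs = obs / obs.sum()
    mean = float((np.arange(len(obs)) * obs).sum())
    params, ssd = _fit_curve(obs, model)
    flags = []
    capped = [k for k, v in params.items()
              if k.startswith("theta") and v >= THETA_CAP]
    if capped:
        flags.append(f"parameters at solver ceiling: {capped}")
    if model == "demographic" and abs(params["theta0"] - params["theta1"]) < 1e-3:
        flags.append("theta0 ~ theta1: tau unidentifiable (stationary)")
    fit = MismatchFit(
        model=model, obs=obs, obs_mean=mean, n=n, params=params,
        ssd=ssd, flags=flags,
    )
    if n_boot:
        fit.p_ssd = _bootstrap_p(model, params, ssd, n, n_boot, seed)
    if rate_model is not None:
        fit.conversions = to_natural_units(fit, rate_model)
    return fit


def fit_demographic(
    obs, n: int, n_boot: int = 0, seed: int | None = None,
    rate_model: RateModel | None = None,
) -> MismatchFit:
    """Fit the sudden demographic expansion model to an observed mismatch."""
    return _make_fit(obs, n, "demographic", n_boot, seed, rate_model)


def fit_spatial(
    obs, n: int, n_boot: int = 0, seed: int | None = None,
    rate_model: RateModel | None = None,
) -> MismatchFit:
    """Fit the spatial (infinite-island) expansion model."""
    return _make_fit(obs, n, "spatial", n_boot, seed, rate_model)


def to_natural_units(fit: MismatchFit, rm: RateModel) -> dict[str, float]:
    """Convert mutation-scaled parameters to years / effective sizes / rates."""
    two_u = 2.0 * rm.u_seq
    out: dict[str, float] = {
        "T_years": fit.params["tau"] / two_u * rm.generation_years
    }
    if fit.model == "demographic":
        out["N0"] = fit.params["theta0"] / two_u
        out["N1"] = fit.params["theta1"] / two_u
    else:
        N = fit.params["theta"] / two_u
        out["N"] = N
        out["m_immigration"] = (
            fit.params["M"] / (2.0 * N) if N > 0 else float("inf")
        )
    return out


# ---------------------------------------------------------------------------
# Fu's FS
# ---------------------------------------------------------------------------

def _log_stirling_first(n: int) -> np.ndarray:
    """log |s(n, k)| for k = 0..n via the Pochhammer recursion."""
    cur = np.full(n + 1, -np.inf)
    cur[0] = 0.0  # s(0,0) = 1
    for m in range(1, n + 1):
        # |s(m,k)| = (m-1)|s(m-1,k)| + |s(m-1,k-1)|
        scale = np.log(m - 1) if m > 1 else -np.inf
        cur = np.logaddexp(cur + scale,
                           np.concatenate(([-np.inf], cur[:-1])))
    return cur


def ewens_k_tail(n: int, theta: float, k_obs: int) -> float:
    """Pr(K >= k_obs) under the Ewens sampling distribution."""
    if theta <= 0:
        return 1.0 if k_obs <= 1 else 0.0
    ls = _log_stirling_first(n)
    ks = np.arange(1, n + 1)
    log_poch = special.gammaln(theta + n) - special.gammaln(theta)
    logp = ls[1:] + ks * np.log(theta) - log_poch
    p = np.exp(logp - special.logsumexp(logp))
    return float(p[k_obs - 1:].sum())


def _fs_from_stats(n: int, k: int, pi: float) -> float:
    sp = ewens_k_tail(n, pi, k)
    sp = min(max(sp, 1e-300), 1.0 - 1e-16)
    return float(np.log(sp / (1.0 - sp)))


def fu_fs(
    a: Alignment, subset: list[str] | None = None,
    n_sim: int = 10_000, seed: int | None = None,
) -> tuple[float, float]:
    """Fu's FS with a simulated neutral null distribution.

    FS = ln(S'/(1-S')) with S' = Pr(K >= k_obs | theta = pi_hat, n); the
    p-value is the fraction of neutral constant-size coalescent samples
    whose FS is as small as the observed one (small FS indicates an excess
    of haplotypes, the expansion signal).
    """
    ids = subset if subset is not None else a.ids
    if len(ids) < 3:
        raise ValueError("Fu's FS requires n >= 3")
    sub = a.subset(ids)
    k_obs = len(set(sub.seqs))
    d = pairwise_differences(sub)
    iu = np.triu_indices(len(ids), k=1)
    pi = float(d[iu].mean())
    if pi == 0 or k_obs == 1:
        raise ValueError("monomorphic sample: FS undefined")
    fs_obs = _fs_from_stats(len(ids), k_obs, pi)
    rng = np.random.default_rng(seed)
    n = len(ids)
    count = 0
    cfg = SimConfig(scenario="panmictic", sample_sizes=(n,), theta=pi)
    for _ in range(n_sim):
        parents, times = sample_genealogy(cfg, rng)
        dsim = pairwise_path_mutations(parents, times, n, rng)
        vals = dsim[iu]
        pi_s = float(vals.mean())
        k_s = _count_haplotypes_from_dist(dsim)
        if pi_s == 0 or k_s == 1:
            fs_s = np.inf
        else:
            fs_s = _fs_from_stats(n, k_s, pi_s)
        if fs_s <= fs_obs + 1e-12:
            count += 1
    return fs_obs, (count + 1) / (n_sim + 1)


def _count_haplotypes_from_dist(d: np.ndarray) -> int:
    n = d.shape[0]
    labels = -np.ones(n, dtype=int)
    k = 0
    for i in range(n):
        if labels[i] >= 0:
            continue
        labels[i] = k
        same = np.where(d[i] == 0)[0]
        labels[same] = k
        k += 1
    return k
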