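"""Isolation-with-migration sampler: likelihood core, prior targeting,
structural invariants and natural-unit summaries."""

import numpy as np
import pytest
from scipy.linalg import expm

from mitopop.imcoal import (
    GenealogyState,
    IMConfig,
    IMPosterior,
    _hky_eig,
    _log_structured_prior,
    estimate_kappa,
    hky_pruning_loglik,
    run_mdiv,
    summarize_im,
)
from mitopop.mismatch import RateModel


def oracle_likelihood(parents, times, patterns, weights, rate, kappa, freqs):
    """Brute-force likelihood: sum over all internal state assignments,
    with transition matrices from scipy expm (independent of the pruning
    implementation)."""
    q = np.zeros((4, 4))
    for i in range(4):
        for j in range(4):
            if i != j:
                q[i, j] = freqs[j] * (
                    kappa if (i, j) in {(0, 2), (2, 0), (1, 3), (3, 1)} else 1.0
                )
    np.fill_diagonal(q, -q.sum(axis=1))
    q /= -(freqs * np.diag(q)).sum()
    n_nodes = len(parents)
    n_leaves = patterns.shape[0]
    internal = [i for i in range(n_nodes) if i >= n_leaves]
    pm = {}
    for i in range(n_nodes):
        if parents[i] >= 0:
            pm[i] = expm(q * (times[parents[i]] - times[i]) * rate)
    total = 0.0
    for pat_idx in range(patterns.shape[1]):
        site = 0.0
        from itertools import product
        for assign in product(range(4), repeat=len(internal)):
            states = {}
            for leaf in range(n_leaves):
                states[leaf] = patterns[leaf, pat_idx]
            for node, s in zip(internal, assign):
                states[node] = s
            root = internal[-1]
            lik = freqs[states[root]]
            for i in range(n_nodes):
                if parents[i] >= 0:
                    lik *= pm[i][states[parents[i]], states[i]]
            site += lik
        total += weights[pat_idx] * np.log(site)
    return total


class TestLikelihoodCore:
    def test_pruning_matches_enumeration_oracle(self):
        # fixed 4-taxon genealogy: ((0,1),(2,3))
        parents = np.array([4, 4, 5, 5, 6, 6, -1])
        times = np.array([0, 0, 0, 0, 0.3, 0.5, 1.1])
        patterns = np.array([
            [0, 1, 2, 3, 0], [0, 1, 2, 0, 0], [1, 1, 3, 3, 0], [2, 1, 3, 3, 0],
        ])
        weights = np.array([3.0, 1.0, 2.0, 1.0, 10.0])
        freqs = np.array([0.33, 0.17, 0.19, 0.31])
        got = hky_pruning_loglik(parents, times, patterns, weights,
                                 mut_rate_per_site=0.08, kappa=4.0,
                                 freqs=freqs)
        want = oracle_likelihood(parents, times, patterns, weights,
                                 0.08, 4.0, freqs)
        assert got == pytest.approx(want, abs=1e-10)

    def test_transition_matrices_are_stochastic(self):
        eig = _hky_eig(3.0, np.array([0.25, 0.25, 0.25, 0.25]))
        from mitopop.imcoal import _branch_pmats
        p = _branch_pmats(np.array([0.01, 0.5, 3.0]), eig)
        assert np.allclose(p.sum(axis=2), 1.0, atol=1e-10)

    def test_kappa_estimate_positive(self):
        assert estimate_kappa(["ACGTACGT", "GCGTACGC", "ACATACGT"]) > 0


class TestStructuredPrior:
    def test_cross_deme_coalescence_below_split_invalid(self):
        # leaves 0 (deme 0) and 1 (deme 1) coalescing below T with no
        # migration must have zero prior density
        st = GenealogyState(
            parents=np.array([2, 2, -1]), times=np.array([0.0, 0.0, 0.5]),
            deme_start=np.array([0, 1, 0]), events={},
        )
        assert _log_structured_prior(st, M=0.0, T=2.0) == -np.inf
        assert np.isfinite(_log_structured_prior(st, M=0.0, T=0.3))

    def test_migration_reconciles_cross_deme_join(self):
        st = GenealogyState(
            parents=np.array([2, 2, -1]), times=np.array([0.0, 0.0, 0.5]),
            deme_start=np.array([0, 1, 0]),
            events={1: [(0.2, 0)]},
        )
        assert np.isfinite(_log_structured_prior(st, M=0.5, T=2.0))
        # but migration with M = 0 is impossible
        assert _log_structured_prior(st, M=0.0, T=2.0) == -np.inf
        # and migration above the split time is meaningless
        st.events[1] = [(1.5, 0)]
        assert _log_structured_prior(st, M=0.5, T=1.0) == -np.inf

    def test_density_value_simple_case(self):
        # two same-deme leaves, coalescence at t: density = exp(-(1+M) t)
        # (pair coalescence rate 1, two lineages migrating at M/2 each)
        st = GenealogyState(
            parents=np.array([2, 2, -1]), times=np.array([0.0, 0.0, 0.7]),
            deme_start=np.array([0, 0, 0]), events={},
        )
        got = _log_structured_prior(st, M=0.8, T=5.0)
        assert got == pytest.approx(-(1 + 0.8) * 0.7)


class TestPriorRecovery:
    def test_no_data_chain_targets_uniform_priors(self):
        cfg = IMConfig(theta_max=5, M_max=2, T_max=3, steps=6000,
                       n_chains=2, thin=3, seed=42)
        post = run_mdiv(None, None, cfg,
                        leaf_demes=np.array([0, 0, 1, 1]))
        for name, ub in (("theta", 5.0), ("M", 2.0), ("T", 3.0)):
            tr = post.traces[name]
            assert tr.mean() == pytest.approx(ub / 2, abs=0.12 * ub)
            assert tr.std() == pytest.approx(ub / np.sqrt(12), abs=0.1 * ub)
            # coarse KS distance against the uniform CDF
            xs = np.sort(tr)
            cdf = np.arange(1, len(xs) + 1) / len(xs)
            d = np.abs(cdf - xs / ub).max()
            assert d < 0.12

    def test_m_zero_keeps_split_older_than_cross_coalescence(self, study_aln):
        # with no migration the two demes' lineages may only meet above T
        cfg = IMConfig(theta_max=10, M_max=0.0, T_max=4, steps=400,
                       n_chains=1, thin=1, seed=3)
        post = run_mdiv(study_aln, ("CP", "FO"), cfg)
        assert (post.traces["root_age"] >= post.traces["T"] - 1e-9).all()


class TestSummaries:
    def _fake_posterior(self):
        return IMPosterior(
            traces={}, chain_traces=[],
            modes={"theta": 0.8, "M": 0.2, "T": 2.0, "tmrca": 1.2,
                   "root_age": 3.0},
            rhat={}, flagged=False,
        )

    def test_nef_range_spans_factor_ten(self):
        summ = summarize_im(self._fake_posterior(), RateModel())
        lo, hi = summ["N_ef_range"]
        assert hi == pytest.approx(10 * lo)
        assert hi == pytest.approx(0.8 / (2 * 2e-5))

    def test_hand_converted_table(self):
        summ = summarize_im(self._fake_posterior(), RateModel())
        # T in generations at 1-yr generations: T * theta/(2u)
        assert summ["T_range"][1] == pytest.approx(2.0 * 0.8 / (4e-5))
        assert summ["TMRCA_range"][1] == pytest.approx(1.2 / 2e-5)
        assert summ["tmrca_over_T"] == pytest.approx(
            (1.2 / 2e-5) / (2.0 * 0.8 / 4e-5)
        )

    def test_flag_propagates(self):
        p = self._fake_posterior()
        p.flagged = True
        assert summarize_im(p, RateModel())["flagged"]


def test_config_validation():
    with pytest.raises(ValueError):
        IMConfig(theta_max=-1, M_max=1, T_max=1)
    with pytest.raises(ValueError):
        IMConfig(theta_max=1, M_max=1, T_max=1, burnin=1.5)
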