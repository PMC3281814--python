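"""Mismatch distributions, expansion fits, conversions and Fu's FS."""

import numpy as np
import pytest

from mitopop.diversity import pairwise_difference_stats
from mitopop.mismatch import (
    RateModel,
    ewens_k_tail,
    expected_mismatch_demographic,
    expected_mismatch_spatial,
    fit_demographic,
    fit_spatial,
    fu_fs,
    observed_mismatch,
    to_natural_units,
)

from conftest import make_alignment


class TestExpectedCurves:
    @pytest.mark.parametrize("tau,th0,th1", [
        (0.0, 2.0, 2.0), (5.0, 0.5, 50.0), (3.0, 0.0, 9999.0), (12.0, 1.0, 8.0),
    ])
    def test_demographic_sums_to_one(self, tau, th0, th1):
        v = expected_mismatch_demographic(tau, th0, th1, 600)
        assert v.sum() == pytest.approx(1.0, abs=1e-6)
        assert (v >= 0).all()

    @pytest.mark.parametrize("tau,th,M", [
        (6.0, 0.9, 1.0), (2.0, 3.0, 0.01), (4.0, 1.0, 9999.0), (0.0, 2.0, 1.0),
    ])
    def test_spatial_sums_to_one(self, tau, th, M):
        v = expected_mismatch_spatial(tau, th, M, 600)
        assert v.sum() == pytest.approx(1.0, abs=1e-6)
        assert (v >= 0).all()

    def test_stationary_curve_is_equilibrium_geometric(self):
        j = np.arange(101)
        geom = 2.0 ** j / 3.0 ** (j + 1)
        v = expected_mismatch_demographic(4.0, 2.0, 2.0, 100)
        np.testing.assert_allclose(v, geom, atol=1e-12)

    def test_high_migration_limit_approaches_demographic(self):
        a = expected_mismatch_spatial(5.0, 1.0, 9999.0, 60)
        b = expected_mismatch_demographic(5.0, 1.0, 1e9, 60)
        assert np.abs(a - b).max() < 5e-4


class TestObservedMismatch:
    def test_identical_sequences_point_mass(self):
        obs, mean = observed_mismatch(make_alignment(["ACGT"] * 4))
        assert obs.tolist() == [1.0]
        assert mean == 0.0

    def test_nine_one_five_apart(self):
        seqs = ["A" * 20] * 9 + ["TTTTT" + "A" * 15]
        obs, mean = observed_mismatch(make_alignment(seqs))
        assert mean == pytest.approx(1.0)
        assert obs[0] == pytest.approx(36 / 45)
        assert obs[5] == pytest.approx(9 / 45)

    def test_mean_equals_pi(self, study_aln):
        for deme in ("ALB", "KO3", "CP"):
            ids = study_aln.deme_members(deme)
            _, mean = observed_mismatch(study_aln, ids)
            pi, _ = pairwise_difference_stats(study_aln, deme)
            assert mean == pytest.approx(pi)


class TestFitting:
    def test_noise_free_demographic_recovery(self):
        truth = dict(tau=5.0, theta0=0.5, theta1=50.0)
        obs = expected_mismatch_demographic(*truth.values(), 80)
        fit = fit_demographic(obs, n=20)
        assert fit.params["tau"] == pytest.approx(truth["tau"], rel=0.10)
        assert fit.ssd < 1e-10

    def test_noise_free_spatial_recovery(self):
        truth = dict(tau=6.0, theta=0.9, M=1.0)
        obs = expected_mismatch_spatial(*truth.values(), 80)
        fit = fit_spatial(obs, n=20)
        assert fit.params["tau"] == pytest.approx(truth["tau"], rel=0.15)
        assert fit.params["M"] == pytest.approx(truth["M"], rel=0.15)
        assert fit.ssd < 1e-10

    def test_stationary_observation_flat_fit(self):
        obs = expected_mismatch_demographic(0.0, 2.0, 2.0, 60)
        fit = fit_demographic(obs, n=20)
        assert fit.ssd < 1e-8  # equilibrium curve is fit essentially exactly

    def test_bootstrap_p_in_range(self, rng):
        obs = expected_mismatch_demographic(4.0, 0.2, 20.0, 40)
        fit = fit_demographic(obs, n=15, n_boot=20, seed=9)
        assert 0.0 < fit.p_ssd <= 1.0


class TestConversions:
    def test_printed_natural_unit_cells(self):
        rm = RateModel()  # u_seq = 2e-5/yr
        dem = _fake("demographic", tau=8.996, theta0=0.0, theta1=1.740)
        conv = to_natural_units(dem, rm)
        assert conv["T_years"] == pytest.approx(224_900)
        alb = _fake("demographic", tau=5.501, theta0=0.002, theta1=2.338)
        assert to_natural_units(alb, rm)["N1"] == pytest.approx(58_450)
        cor = _fake("demographic", tau=0.576, theta0=0.627, theta1=9999.0)
        assert to_natural_units(cor, rm)["N0"] == pytest.approx(15_675)
        ave = _fake("spatial", tau=0.334, theta=0.065, M=9999.0)
        assert to_natural_units(ave, rm)["T_years"] == pytest.approx(8_350)

    def test_immigration_rate_definition(self):
        rm = RateModel()
        alb = _fake("spatial", tau=3.901, theta=0.902, M=1.057)
        conv = to_natural_units(alb, rm)
        assert conv["N"] == pytest.approx(22_550)
        assert conv["m_immigration"] == pytest.approx(2.3e-5, rel=0.02)

    def test_zero_tau_gives_zero_time(self):
        f = _fake("demographic", tau=0.0, theta0=1.0, theta1=2.0)
        assert to_natural_units(f, RateModel())["T_years"] == 0.0

    def test_generation_time_scales_linearly(self):
        f = _fake("demographic", tau=2.0, theta0=0.1, theta1=1.0)
        t1 = to_natural_units(f, RateModel(generation_years=1))["T_years"]
        t10 = to_natural_units(f, RateModel(generation_years=10))["T_years"]
        assert t10 == pytest.approx(10 * t1)

    def test_bad_rate_rejected(self):
        with pytest.raises(ValueError):
            RateModel(u_seq=0.0)


def _fake(model, **params):
    class F:
        pass
    f = F()
    f.model = model
    f.params = params
    return f


def ewens_tail_oracle(n, theta, k_obs):
    """Independent Ewens K-tail via the sequential new-allele construction.

    The number of alleles is a sum of independent Bernoullis with
    p_i = theta/(theta+i-1); the distribution comes from direct polynomial
    convolution, no Stirling numbers involved.
    """
    dist = np.array([1.0])
    for i in range(1, n + 1):
        p = theta / (theta + i - 1)
        nxt = np.zeros(len(dist) + 1)
        nxt[: len(dist)] += dist * (1 - p)
        nxt[1:] += dist * p
        dist = nxt
    return dist[k_obs:].sum()


class TestFuFS:
    @pytest.mark.parametrize("n,theta,k", [
        (5, 1.0, 2), (8, 0.5, 3), (8, 3.0, 6), (6, 2.0, 1), (7, 1.3, 7),
    ])
    def test_ewens_tail_matches_enumeration_oracle(self, n, theta, k):
        assert ewens_k_tail(n, theta, k) == pytest.approx(
            ewens_tail_oracle(n, theta, k), rel=1e-10
        )

    def test_monomorphic_sample_signalled(self):
        with pytest.raises(ValueError):
            fu_fs(make_alignment(["ACGT"] * 5))

    def test_known_small_case(self):
        fs, p = fu_fs(make_alignment(["AAAAA"] * 4 + ["AATAA"]),
                      n_sim=60, seed=1)
        # k=2, n=5, pi = 4/10 = 0.4
        expect_sp = ewens_tail_oracle(5, 0.4, 2)
        assert fs == pytest.approx(np.log(expect_sp / (1 - expect_sp)))
        assert 0 < p <= 1

    def test_neutral_data_usually_not_significant(self, rng):
        # the conventional 0.02 cutoff corresponds to a ~5% test, so the
        # vast majority of neutral datasets must stay non-significant
        from mitopop.simulate import SimConfig, simulate

        hits = total = 0
        for _ in range(12):
            aln, _ = simulate(SimConfig(
                scenario="panmictic", sample_sizes=(15,), theta=2.0, L=600,
                seed=int(rng.integers(2 ** 31)),
            ))
            try:
                _, p = fu_fs(aln, n_sim=150, seed=int(rng.integers(2 ** 31)))
            except ValueError:
                continue  # monomorphic draw: statistic undefined
            total += 1
            hits += p <= 0.02
        assert total >= 8
        assert hits <= 2
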