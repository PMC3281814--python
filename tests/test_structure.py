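"""PhiST, AMOVA variance components and sequential Bonferroni."""

import numpy as np
import pytest

from mitopop.diversity import pairwise_differences
from mitopop.structure import (
    _one_level_components,
    _two_level_components,
    _two_level_indices,
    amova,
    pairwise_phist,
    sequential_bonferroni,
)

from conftest import make_alignment


def oracle_one_level(d2, pops):
    """Independent expected-mean-squares solution for one-level AMOVA."""
    pops = np.asarray(pops)
    labels = sorted(set(pops))
    N = len(pops)
    P = len(labels)
    ssd_total = sum(
        d2[i, j] for i in range(N) for j in range(i + 1, N)
    ) / N
    ssd_within = 0.0
    for lab in labels:
        idx = [k for k in range(N) if pops[k] == lab]
        ssd_within += sum(
            d2[i, j] for i in idx for j in idx if i < j
        ) / len(idx)
    ss_among = ssd_total - ssd_within
    ms_among = ss_among / (P - 1)
    ms_within = ssd_within / (N - P)
    sizes = [np.sum(pops == lab) for lab in labels]
    n_c = (N - sum(s * s for s in sizes) / N) / (P - 1)
    sigma_w = ms_within
    sigma_a = (ms_among - ms_within) / n_c
    return sigma_a, sigma_w


class TestAmovaComponents:
    def test_matches_ems_oracle_one_level(self, rng):
        for _ in range(20):
            sizes = rng.integers(2, 6, size=rng.integers(2, 4))
            N = int(sizes.sum())
            pops = np.repeat([str(k) for k in range(len(sizes))], sizes)
            x = rng.random((N, 5)) * 4
            d2 = ((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2)
            res = _one_level_components(d2, pops)
            sa, sw = oracle_one_level(d2, pops)
            assert res["var"]["Va"] == pytest.approx(sa, rel=1e-9)
            assert res["var"]["Vb"] == pytest.approx(sw, rel=1e-9)

    def test_fixed_demes_ten_sites_apart_give_phist_one(self):
        seqs = ["A" * 20] * 5 + ["T" * 10 + "A" * 10] * 5
        aln = make_alignment(seqs, demes=["x"] * 5 + ["y"] * 5)
        ph = pairwise_phist(aln, n_perm=99, seed=1)
        assert ph.phist.loc["x", "y"] == pytest.approx(1.0)
        assert ph.pvals.loc["x", "y"] < 0.05

    def test_identical_demes_phist_near_zero(self, rng):
        pool = ["".join(rng.choice(list("ACGT"), 30)) for _ in range(6)]
        seqs = [pool[rng.integers(6)] for _ in range(20)]
        aln = make_alignment(seqs, demes=["x"] * 10 + ["y"] * 10)
        ph = pairwise_phist(aln, n_perm=199, seed=2)
        assert abs(ph.phist.loc["x", "y"]) < 0.15
        assert ph.pvals.loc["x", "y"] > 0.05

    def test_two_level_identity_and_oracle(self, rng):
        # (1-F_CT)(1-F_SC) = 1-F_ST must hold to 1e-12
        for _ in range(10):
            sizes = [2, 3, 2, 4, 3]
            pops = np.repeat([f"p{k}" for k in range(5)], sizes)
            grp = {"p0": "g1", "p1": "g1", "p2": "g2", "p3": "g2", "p4": "g3"}
            x = rng.random((sum(sizes), 4)) * 3
            d2 = ((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2)
            res = _two_level_components(
                d2, pops, np.array([grp[p] for p in pops])
            )
            fx = _two_level_indices(res["var"])
            lhs = (1 - fx["F_CT"]) * (1 - fx["F_SC"])
            assert abs(lhs - (1 - fx["F_ST"])) < 1e-12
            # within-deme component equals the one-level oracle's MS_within
            _, sw = oracle_one_level(d2, pops)
            assert res["var"]["Vc"] == pytest.approx(sw, rel=1e-9)

    def test_identical_composition_components_near_zero(self):
        seqs = (["A" * 10, "A" * 9 + "T"] * 6)
        aln = make_alignment(seqs, demes=["x", "x", "x", "x", "y", "y",
                                          "y", "y", "z", "z", "z", "z"])
        res = amova(aln, n_perm=99, seed=3)
        # balanced identical composition: estimate at or below zero (negative
        # components are retained, not truncated), clearly non-significant
        assert res.fixation["F_ST"] <= 0.0
        assert res.pvals["F_ST"] > 0.05

    def test_study_fixture_two_level_majority_among_groups(self, study_aln):
        res = amova(study_aln, grouping=study_aln.group_of,
                    n_perm=199, seed=4)
        assert res.design == "two-level"
        assert res.pct_variation["among_groups"] > 50
        assert sum(res.pct_variation.values()) == pytest.approx(100, abs=0.1)
        fx = res.fixation
        assert (1 - fx["F_CT"]) * (1 - fx["F_SC"]) == pytest.approx(
            1 - fx["F_ST"], abs=1e-12
        )
        assert res.pvals["F_CT"] is not None

    def test_singleton_groups_flag_fsc_undefined(self, rng):
        pops = np.repeat(["a", "b"], 4)
        x = rng.random((8, 3))
        d2 = ((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2)
        res = amova(d2, pops, grouping={"a": "g1", "b": "g2"},
                    n_perm=49, seed=0)
        assert res.pvals["F_SC"] is None
        assert res.warnings


class TestSequentialBonferroni:
    def test_initial_threshold_for_21_tests(self):
        flags, alpha0 = sequential_bonferroni([0.5] * 21)
        assert alpha0 == pytest.approx(0.05 / 21)
        assert round(alpha0, 4) == 0.0024  # prints as ~0.0023-0.0024

    def test_all_ones_no_flags(self):
        flags, _ = sequential_bonferroni([1.0] * 5)
        assert not flags.any()

    def test_holm_steps_hand_example(self):
        # thresholds 0.05/3, 0.05/2, 0.05/1 -> all pass
        flags, _ = sequential_bonferroni([0.001, 0.02, 0.03])
        assert flags.tolist() == [True, True, True]

    def test_stops_at_first_failure(self):
        flags, _ = sequential_bonferroni([0.001, 0.04, 0.03])
        # sorted: 0.001 <= 0.05/3, then 0.03 > 0.05/2 stops the procedure
        assert flags.tolist() == [True, False, False]

    def test_rejects_bad_pvalues(self):
        with pytest.raises(ValueError):
            sequential_bonferroni([0.5, 1.2])


def test_phist_matrix_shape_and_symmetry(study_aln):
    ph = pairwise_phist(study_aln, n_perm=49, seed=5)
    m = ph.phist.to_numpy()
    assert np.allclose(m, m.T)
    assert np.allclose(np.diag(m), 0)
    assert ((ph.pvals.to_numpy() >= 0) & (ph.pvals.to_numpy() <= 1)).all()
    assert ph.initial_alpha == pytest.approx(0.05 / 21)
    # planted divergent groups: between-group PhiST far above zero
    assert ph.phist.loc["ALB", "CP"] > 0.5
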