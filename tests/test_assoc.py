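"""Region statistics: algebraic identities, oracles, null uniformity."""

import numpy as np
import pytest
from scipy.stats import kstest

from pleiofam.assoc import (beta_weights, burden_test, cauchy_omnibus,
                            genotype_summary, hek_test, hok_test, run_all,
                            score_components)
from pleiofam.jgee import fit_null

from conftest import make_unrelated_families


def fitted_setup(rng, n_fam=80, p=5, K=2, kind="continuous"):
    fams = make_unrelated_families(rng, n_fam=n_fam, p=p, K=K, kind=kind)
    fit = fit_null(fams, kind)
    omegas = [np.eye(3)] * n_fam
    G = np.vstack([f.g for f in fams])
    gs = genotype_summary(G, K=K)
    return fams, fit, omegas, gs


class TestGenotypeSummary:
    def test_flat_beta_weights_are_one(self, rng):
        m = rng.uniform(0.01, 0.5, 20)
        assert np.allclose(beta_weights(m, (1, 1)), 1.0)

    def test_beta_1_25_density_value(self):
        # Beta(1,25) density at m = 0.5: 25 * 0.5^24
        assert beta_weights(np.array([0.5]), (1, 25))[0] == pytest.approx(25 / 2**24)

    def test_duplicated_variant_has_unit_correlation(self, rng):
        g = rng.binomial(2, 0.3, size=(50, 1)).astype(float)
        gs = genotype_summary(np.hstack([g, g]))
        assert gs.H[0, 1] == pytest.approx(1.0)

    def test_major_allele_folding(self, rng):
        g = rng.binomial(2, 0.8, size=(200, 1)).astype(float)
        gs = genotype_summary(g)
        assert gs.m[0] <= 0.5
        assert gs.flip[0]
        assert np.allclose(gs.fold(g), 2.0 - g)

    def test_monomorphic_dropped_and_all_mono_rejected(self, rng):
        g = rng.binomial(2, 0.3, size=(50, 2)).astype(float)
        g[:, 1] = 0.0
        gs = genotype_summary(g)
        assert list(gs.kept) == [0]
        with pytest.raises(ValueError, match="monomorphic"):
            genotype_summary(np.zeros((50, 2)))

    def test_founder_mask_restricts_frequency(self):
        # variant fixed in the founders is monomorphic from the founders'
        # viewpoint even though the full sample is polymorphic
        g = np.array([[2.0], [2.0], [1.0], [0.0]])
        with pytest.raises(ValueError, match="monomorphic"):
            genotype_summary(g, founder_mask=[True, True, False, False])
        gs = genotype_summary(g)  # all-sample frequency 5/8 -> folded, kept
        assert gs.kept.size == 1 and gs.flip[0]


class TestScoreComponents:
    def test_cho_equals_sum_of_che(self, rng):
        _, fit, omegas, gs = fitted_setup(rng)
        sc = score_components(fit, omegas, gs)
        assert sc.C_Ho == pytest.approx(sc.C_He.sum(), rel=1e-10)

    def test_k1_cho_equals_che(self, rng):
        _, fit, omegas, gs = fitted_setup(rng, K=1)
        sc = score_components(fit, omegas, gs)
        assert sc.C_He.shape == (1, 1)
        assert sc.C_Ho == pytest.approx(sc.C_He[0, 0], rel=1e-12)

    def test_brute_force_loop_oracle(self, rng):
        # independent per-element loop over families, variants and traits
        fams, fit, omegas, gs = fitted_setup(rng, n_fam=12, p=3)
        sc = score_components(fit, omegas, gs)
        K, p = fit.K, gs.p
        Z = np.zeros((p, K))
        C_Ho = 0.0
        for fam, A, S, Om in zip(fit.families, fit.A, fit.S, omegas):
            n = fam.n
            g = gs.fold(fam.g)
            u = np.zeros(n)
            for k in range(K):
                b = A[k * n:(k + 1) * n] * S[k * n:(k + 1) * n]
                u += b
                for l in range(p):
                    Z[l, k] += g[:, l] @ b
            C_Ho += u @ Om @ u
        assert np.allclose(sc.Z, Z, atol=1e-10)
        assert sc.C_Ho == pytest.approx(C_Ho, rel=1e-10)

    def test_omega_identity_k1_quadratic(self, rng):
        # Omega = I, K = 1, identity link: C_Ho = sum_i ||A S||^2
        _, fit, omegas, _ = fitted_setup(rng, K=1)
        gs = genotype_summary(np.vstack([f.g for f in fit.families]), K=1)
        sc = score_components(fit, omegas, gs)
        direct = sum(float((A * S) @ (A * S)) for A, S in zip(fit.A, fit.S))
        assert sc.C_Ho == pytest.approx(direct, rel=1e-10)

    def test_dimension_mismatch_rejected(self, rng):
        _, fit, omegas, gs = fitted_setup(rng)
        with pytest.raises(ValueError, match="Omega"):
            score_components(fit, [np.eye(4)] * len(omegas), gs)


class TestIdentities:
    def test_single_variant_hok_equals_bt(self, rng):
        _, fit, omegas, _ = fitted_setup(rng, p=1)
        gs = genotype_summary(np.vstack([f.g for f in fit.families]), K=2,
                              weights=(1, 25))
        sc = score_components(fit, omegas, gs)
        p_hok = hok_test(sc, gs).p
        p_bt = burden_test(sc, gs).p
        assert abs(p_hok - p_bt) < 1e-10

    def test_k1_hek_equals_hok(self, rng):
        _, fit, omegas, _ = fitted_setup(rng, K=1)
        gs = genotype_summary(np.vstack([f.g for f in fit.families]), K=1,
                              weights=(1, 25))
        sc = score_components(fit, omegas, gs)
        hok, hek = hok_test(sc, gs), hek_test(sc, gs)
        assert hok.statistic == pytest.approx(hek.statistic, rel=1e-12)
        assert hok.p == pytest.approx(hek.p, rel=1e-10)

    def test_burden_numerator_identity(self, rng):
        # (sum_i sum_k S'A Delta g~)^2 == (sum_l w_l sum_k Z_lk)^2
        fams, fit, omegas, gs = fitted_setup(rng)
        sc = score_components(fit, omegas, gs)
        K = fit.K
        acc = 0.0
        for fam, A, S in zip(fit.families, fit.A, fit.S):
            n = fam.n
            gt = gs.fold(fam.g) @ gs.w
            for k in range(K):
                acc += (A[k * n:(k + 1) * n] * S[k * n:(k + 1) * n]) @ gt
        assert acc**2 == pytest.approx(float(np.sum(gs.w * sc.Z.sum(1))) ** 2, rel=1e-10)

    def test_hok_matches_genotype_permutation_oracle(self, rng):
        # unrelated individuals, K=1: permuting genotypes against fixed
        # residuals realizes the retrospective null
        fams, fit, omegas, gs = fitted_setup(rng, n_fam=70, p=4, K=1)
        sc = score_components(fit, omegas, gs)
        obs = hok_test(sc, gs)
        b = np.concatenate([A * S for A, S in zip(fit.A, fit.S)])
        G = gs.fold(np.vstack([f.g for f in fams]))
        n = b.size
        n_perm = 100_000
        exceed = 0
        for chunk in range(10):
            perms = np.argsort(rng.random((n_perm // 10, n)), axis=1)
            Zp = b[perms] @ G                       # (chunk, p)
            stats = (Zp**2 * gs.w).sum(axis=1)
            exceed += int(np.sum(stats >= obs.statistic))
        p_perm = exceed / n_perm
        se = np.sqrt(max(p_perm * (1 - p_perm), 1e-6) / n_perm)
        assert abs(obs.p - p_perm) < max(4 * se, 0.1 * max(p_perm, obs.p))


class TestCauchyOmnibus:
    def test_half_half_gives_half(self):
        res = cauchy_omnibus(0.5, 0.5)
        assert res.statistic == pytest.approx(0.0)
        assert res.p == pytest.approx(0.5)

    @pytest.mark.parametrize("p", [0.9, 0.3, 0.01, 1e-8])
    def test_equal_inputs_fixed_point(self, p):
        assert cauchy_omnibus(p, p).p == pytest.approx(p, rel=1e-9)

    def test_antisymmetric_pair_cancels(self):
        assert cauchy_omnibus(0.01, 0.99).p == pytest.approx(0.5, abs=1e-12)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            cauchy_omnibus(0.0, 0.5)
        with pytest.raises(ValueError):
            cauchy_omnibus(0.5, 1.5)

    def test_tiny_input_clipped_and_flagged(self):
        res = cauchy_omnibus(1e-300, 0.5)
        assert "clipped" in res.flags
        assert 0 < res.p < 1e-14


class TestRunAll:
    def test_consistent_with_individual_calls(self, rng):
        _, fit, omegas, gs = fitted_setup(rng)
        sc = score_components(fit, omegas, gs)
        res = run_all(fit, omegas, gs)
        assert res["HoK"].p == hok_test(sc, gs).p
        assert res["BT"].p == burden_test(sc, gs).p
        assert res["HoO"].p == cauchy_omnibus(res["HoK"].p, res["BT"].p).p
        assert res["HeO"].p == cauchy_omnibus(res["HeK"].p, res["BT"].p).p

    def test_null_pvalues_uniform(self, rng):
        # small unrelated-cohort null replicates through the full stack
        pvals = {m: [] for m in ("HoK", "HeK", "BT")}
        for _ in range(400):
            fams = make_unrelated_families(rng, n_fam=60, p=4)
            fit = fit_null(fams, "continuous")
            omegas = [np.eye(3)] * 60
            gs = genotype_summary(np.vstack([f.g for f in fams]), K=2)
            res = run_all(fit, omegas, gs)
            for m in pvals:
                pvals[m].append(res[m].p)
        for m, ps in pvals.items():
            assert kstest(ps, "uniform").pvalue > 0.01, m
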