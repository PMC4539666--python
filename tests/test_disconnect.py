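"""Disconnect LRT, BH adjustment, fold-change filter and grouping."""

import numpy as np
import pytest
from scipy import stats

from fpdisconnect import (
    CombinedProfile,
    DoseDesign,
    IN_VITRO,
    IN_VIVO,
    adjust_bh,
    call_disconnects,
    classify_gene,
    fit_interaction,
    fit_projected,
    fp_design_matrix,
    lrt,
    max_dose_fold_change,
)
from fpdisconnect import test_disconnect as run_disconnect_test
from fpdisconnect import test_dose_response as run_dose_response_test
from fpdisconnect.fp import fit_ols
from fpdisconnect._batch import BatchDesign, p_from_rss
from .conftest import random_profile
from .test_fp import normal_equations_fit


def bh_stepup_oracle(p):
    """Classical BH step-up recursion, written independently."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * m / rank)
        adj[i] = prev
    return adj


def combined_from(vitro, vivo):
    return CombinedProfile.from_profiles(vitro, vivo)


class TestLRT:
    def test_equal_likelihoods_give_unit_p(self):
        stat, p = lrt(-3.5, -3.5, df=3)
        assert stat == 0.0 and p == 1.0

    def test_chi_square_tail(self):
        _, p = lrt(7.815 / 2, 0.0, df=3)
        assert p == pytest.approx(1 - stats.chi2.cdf(7.815, 3), abs=1e-12)
        assert p == pytest.approx(0.05, abs=1e-3)

    def test_negative_difference_clipped(self):
        stat, p = lrt(-1.0, 0.0, df=2)
        assert stat == 0.0 and p == 1.0

    def test_null_pvalues_approximately_uniform(self, rng):
        """Fixed-basis 3-df LRT with exact F calibration is uniform."""
        n, G = 20, 4000
        idx = np.concatenate([np.repeat([1, 2, 3, 4], 2),
                              np.repeat([1, 2, 3, 4], 3)])
        X = fp_design_matrix(idx, 1.0, 2.0)
        Xint = np.hstack([X, X * (np.arange(n) >= 8)[:, None]])
        Y = rng.normal(0, 1, (G, n))
        p = np.empty(G)
        for g in range(G):
            red = fit_ols(Y[g], X)
            full = fit_ols(Y[g], Xint)
            p[g] = p_from_rss(red.rss, full.rss, n, df=3, k_full_mean=6,
                              calibration="f")
        assert stats.kstest(p, "uniform").pvalue > 0.01


class TestProjectedAndInteraction:
    def test_duplicated_system_matches_single_system_fit(self, rng):
        vitro = random_profile(rng, system=IN_VITRO)
        vivo_copy = random_profile(rng, system=IN_VIVO)
        vivo_copy.values = vitro.values.copy()
        vivo_copy.dose_idx = vitro.dose_idx.copy()
        comb = combined_from(vitro, vivo_copy)
        proj = fit_projected(comb, (0.5, 2.0))
        X = fp_design_matrix(vitro.dose_idx, 0.5, 2.0)
        solo, _ = normal_equations_fit(vitro.values, X)
        np.testing.assert_allclose(proj.beta, solo, atol=1e-8)

    def test_projected_matches_stacked_oracle(self, vitro_vivo_pair):
        vitro, vivo = vitro_vivo_pair
        comb = combined_from(vitro, vivo)
        fit = fit_projected(comb, (0.0, 1.0))
        X = fp_design_matrix(comb.dose_idx, 0.0, 1.0)
        beta, rss = normal_equations_fit(comb.values, X)
        np.testing.assert_allclose(fit.beta, beta, atol=1e-8)
        assert fit.rss == pytest.approx(rss, abs=1e-8)

    def test_gamma_zero_on_identical_systems(self, rng):
        vitro = random_profile(rng, system=IN_VITRO)
        vivo = random_profile(rng, system=IN_VIVO)
        vivo.values = vitro.values.copy()
        vivo.dose_idx = vitro.dose_idx.copy()
        fit = fit_interaction(combined_from(vitro, vivo), (1.0, 2.0))
        np.testing.assert_allclose(fit.beta[3:], 0.0, atol=1e-8)

    def test_interaction_equals_two_separate_fits(self, vitro_vivo_pair):
        vitro, vivo = vitro_vivo_pair
        comb = combined_from(vitro, vivo)
        fit = fit_interaction(comb, (0.5, 1.5))
        Xv = fp_design_matrix(vitro.dose_idx, 0.5, 1.5)
        Xw = fp_design_matrix(vivo.dose_idx, 0.5, 1.5)
        bv, rv = normal_equations_fit(vitro.values, Xv)
        bw, rw = normal_equations_fit(vivo.values, Xw)
        np.testing.assert_allclose(fit.beta[:3], bv, atol=1e-8)
        np.testing.assert_allclose(fit.beta[:3] + fit.beta[3:], bw, atol=1e-8)
        assert fit.rss == pytest.approx(rv + rw, abs=1e-8)
        assert fit.sigma2 == pytest.approx((rv + rw) / comb.n_obs, abs=1e-10)

    def test_gamma0_shift_equivariance(self, vitro_vivo_pair):
        vitro, vivo = vitro_vivo_pair
        base = fit_interaction(combined_from(vitro, vivo), (1.0, 2.0))
        vivo.values = vivo.values + 0.7
        shifted = fit_interaction(combined_from(vitro, vivo), (1.0, 2.0))
        assert shifted.beta[3] - base.beta[3] == pytest.approx(0.7, abs=1e-8)
        np.testing.assert_allclose(shifted.beta[4:], base.beta[4:], atol=1e-8)

    def test_projected_nested_in_interaction(self, vitro_vivo_pair):
        vitro, vivo = vitro_vivo_pair
        comb = combined_from(vitro, vivo)
        assert (fit_projected(comb, (0.0, 0.0)).logL
                <= fit_interaction(comb, (0.0, 0.0)).logL + 1e-10)


class TestDoseResponse:
    def test_statistic_is_twice_loglik_difference(self, rng):
        from fpdisconnect import fit_null, select_powers
        prof = random_profile(rng)
        res = run_dose_response_test(prof)
        oracle = 2 * (select_powers(prof).logL - fit_null(prof).logL)
        assert res.stat == pytest.approx(max(0.0, oracle), abs=1e-8)

    def test_strong_trend_detected(self, rng):
        prof = random_profile(rng, mu=np.array([0, 2 / 3, 4 / 3, 2.0]),
                              sigma=0.1)
        assert run_dose_response_test(prof).p_raw < 1e-4

    def test_flat_profile_mostly_non_significant(self, rng):
        """AIC selection inflates the level somewhat; at the exact F
        calibration a flat gene stays non-significant in >= 80% of draws."""
        hits = sum(
            run_dose_response_test(random_profile(rng, sigma=0.05)).significant
            for _ in range(200)
        )
        assert hits <= 40


class TestDisconnectTest:
    def test_identical_systems_not_disconnected(self, rng):
        vitro = random_profile(rng, system=IN_VITRO)
        vivo = random_profile(rng, system=IN_VIVO)
        vivo.values = vitro.values.copy()
        vivo.dose_idx = vitro.dose_idx.copy()
        res = run_disconnect_test(vitro, vivo)
        assert res.stat == pytest.approx(0.0, abs=1e-8)
        assert res.p_raw == pytest.approx(1.0, abs=1e-6)

    def test_opposite_profiles_detected(self, rng):
        mu = np.array([0, 1 / 3, 2 / 3, 1.0])
        vitro = random_profile(rng, mu=mu, sigma=0.2, system=IN_VITRO)
        vivo = random_profile(rng, DoseDesign((3, 3, 3, 3)), mu=-mu,
                              sigma=0.2, system=IN_VIVO)
        res = run_disconnect_test(vitro, vivo)
        assert res.p_raw < 0.001
        assert res.max_fc > 1.0

    def test_statistic_matches_explicit_stacked_designs(self, vitro_vivo_pair):
        from fpdisconnect import select_powers
        vitro, vivo = vitro_vivo_pair
        res = run_disconnect_test(vitro, vivo, direction="vitro_to_vivo")
        powers = select_powers(vitro).powers
        assert powers == res.powers
        idx = np.concatenate([vitro.dose_idx, vivo.dose_idx])
        y = np.concatenate([vitro.values, vivo.values])
        X = fp_design_matrix(idx, *powers)
        ind = (np.arange(idx.size) >= vitro.n_obs).astype(float)[:, None]
        _, rss0 = normal_equations_fit(y, X)
        _, rss1 = normal_equations_fit(y, np.hstack([X, X * ind]))
        oracle_stat = idx.size * np.log(rss0 / rss1)
        assert res.stat == pytest.approx(oracle_stat, abs=1e-6)

    def test_direction_asymmetry_both_computed(self, rng):
        mu = np.array([0, 0.3, 0.1, 0.8])
        vitro = random_profile(rng, mu=mu, sigma=0.3, system=IN_VITRO)
        vivo = random_profile(rng, DoseDesign((3, 3, 3, 3)), mu=-mu,
                              sigma=0.3, system=IN_VIVO)
        a = run_disconnect_test(vitro, vivo, "vitro_to_vivo")
        b = run_disconnect_test(vitro, vivo, "vivo_to_vitro")
        assert a.direction != b.direction
        assert np.isfinite(a.p_raw) and np.isfinite(b.p_raw)

    def test_mismatched_gene_rejected(self, rng):
        vitro = random_profile(rng, system=IN_VITRO, gene="gA")
        vivo = random_profile(rng, system=IN_VIVO, gene="gB")
        with pytest.raises(ValueError):
            run_disconnect_test(vitro, vivo)

    def test_batch_engine_matches_scalar_path(self, rng):
        """The vectorised design used in simulations reproduces the
        per-profile test to numerical precision."""
        dv = DoseDesign((2, 2, 2, 2))
        dw = DoseDesign((3, 3, 3, 3))
        bd = BatchDesign(dv.dose_indices, dw.dose_indices)
        G = 20
        Yv = rng.normal(0, 0.5, (G, dv.n_obs)) + np.linspace(0, 1, dv.n_obs)
        Yw = rng.normal(0, 0.5, (G, dw.n_obs))
        _, rss0, rss1, gamma = bd.disconnect_rss(Yv, Yw)
        p_batch = p_from_rss(rss0, rss1, bd.n, 3, 6, "f")
        for g in range(G):
            vitro = random_profile(rng, dv, system=IN_VITRO)
            vivo = random_profile(rng, dw, system=IN_VIVO)
            vitro.values = Yv[g]
            vivo.values = Yw[g]
            res = run_disconnect_test(vitro, vivo)
            assert res.p_raw == pytest.approx(p_batch[g], abs=1e-9)
            np.testing.assert_allclose(res.gamma, gamma[g], atol=1e-7)


class TestBHAndFilter:
    def test_single_p_unchanged(self):
        assert adjust_bh([0.03])[0] == pytest.approx(0.03)

    def test_stepup_recursion_by_hand(self):
        np.testing.assert_allclose(
            adjust_bh([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03], atol=1e-12
        )

    def test_matches_classical_stepup_oracle(self, rng):
        for _ in range(10):
            p = rng.uniform(0, 1, rng.integers(1, 50))
            np.testing.assert_allclose(adjust_bh(p), bh_stepup_oracle(p),
                                       atol=1e-12)
            assert np.all(adjust_bh(p) >= p - 1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_bh([0.5, 1.5])

    def test_fdr_controlled_on_mixture(self, rng):
        """Empirical FDR of BH calls on a null/alternative p mixture."""
        fdrs = []
        for _ in range(50):
            p0 = rng.uniform(0, 1, 200)
            p1 = rng.beta(0.05, 8, 100)
            p = np.concatenate([p0, p1])
            truth = np.arange(300) >= 200
            calls = adjust_bh(p) <= 0.10
            fp = (calls & ~truth).sum()
            fdrs.append(fp / max(1, calls.sum()))
        assert np.mean(fdrs) <= 0.10 + 0.03

    def test_call_semantics_with_fold_change_boundary(self, rng):
        vitro = random_profile(rng, system=IN_VITRO)
        vivo = random_profile(rng, DoseDesign((3, 3, 3, 3)), system=IN_VIVO)
        base = run_disconnect_test(vitro, vivo)
        import dataclasses
        cases = [
            dataclasses.replace(base, p_raw=0.01, max_fc=0.5),   # filtered
            dataclasses.replace(base, p_raw=0.012, max_fc=1.0),  # boundary kept
            dataclasses.replace(base, p_raw=0.9, max_fc=3.0),    # not significant
        ]
        called = call_disconnects(cases, q=0.10, fc_min=1.0)
        assert [r.disconnected for r in called] == [False, True, False]
        assert all(r.p_bh >= r.p_raw - 1e-15 for r in called)


class TestFoldChangeAndGroups:
    def test_identical_profiles_zero(self, rng):
        vitro = random_profile(rng, system=IN_VITRO)
        vivo = random_profile(rng, system=IN_VIVO)
        vivo.values = vitro.values.copy()
        vivo.dose_idx = vitro.dose_idx.copy()
        assert max_dose_fold_change(vitro, vivo) == 0.0

    def test_single_dose_difference(self):
        from .conftest import make_profile
        idx = np.repeat([1, 2, 3, 4], 2)
        vitro = make_profile(np.array([0, 0, 0, 0, 0, 0, 1, 1.0]),
                             dose_idx=idx, system=IN_VITRO)
        vivo = make_profile(np.zeros(8), dose_idx=idx, system=IN_VIVO)
        assert max_dose_fold_change(vitro, vivo) == pytest.approx(1.0)

    def test_matches_per_dose_loop(self, vitro_vivo_pair):
        vitro, vivo = vitro_vivo_pair
        mv, mw = vitro.dose_means(), vivo.dose_means()
        oracle = max(abs(mv[i] - mw[i]) for i in mv)
        assert max_dose_fold_change(vitro, vivo) == pytest.approx(oracle)

    def test_within_system_amplitude_mode(self, vitro_vivo_pair):
        vitro, vivo = vitro_vivo_pair
        mv, mw = vitro.dose_means(), vivo.dose_means()
        oracle = max(abs(v) for d in (mv, mw) for v in d.values())
        got = max_dose_fold_change(vitro, vivo, mode="within_systems")
        assert got == pytest.approx(oracle)

    @pytest.mark.parametrize(
        "vitro_sig,vivo_sig,expected",
        [(True, True, "both"), (True, False, "vitro_only"),
         (False, True, "vivo_only"), (False, False, "neither")],
    )
    def test_gene_grouping(self, vitro_sig, vivo_sig, expected):
        assert classify_gene(vitro_sig, vivo_sig) == expected
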