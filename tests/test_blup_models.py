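import logging

import numpy as np
import pytest
import scipy.sparse as sp

import msblup.blup_models as bm
from msblup.blup_models import (assemble_mme, fit_model_II, fit_model_M,
                                fit_model_MI, fit_model_MS, gls_oracle)
from msblup.marker_data import MarkerMatrix, VarianceComponents, ms_design
from msblup.pedigree_algebra import build_A, build_D, parse_pedigree

VC = VarianceComponents


def _incidence(ids, ped):
    idx = [ped.index_of(i) for i in ids]
    Z = np.zeros((len(idx), ped.n))
    Z[np.arange(len(idx)), idx] = 1.0
    return Z


def _random_problem(seed, n=15, n_markers=8, n_obs=None):
    rng = np.random.default_rng(seed)
    from conftest import random_pedigree_records
    ped = parse_pedigree(random_pedigree_records(rng, n))
    W = rng.integers(0, 3, size=(ped.n, n_markers)).astype(float)
    markers = MarkerMatrix(W=W, marker_ids=tuple(f"m{j}" for j in range(n_markers)),
                           ped=ped)
    if n_obs is None:
        n_obs = max(3, ped.n - 2)
    obs = list(rng.choice(ped.ids, size=n_obs, replace=False))
    y = rng.normal(size=n_obs)
    return ped, markers, obs, y


class TestAssembleMme:
    def test_no_random_blocks_is_ols(self):
        y = np.array([1.0, 2.0, 6.0])
        lhs, rhs, _ = assemble_mme(np.ones((3, 1)), [], y, 1.0)
        assert np.linalg.solve(lhs, rhs)[0] == pytest.approx(y.mean())

    def test_infinite_shrinkage_zeroes_random_effects(self):
        rng = np.random.default_rng(0)
        T = rng.normal(size=(6, 3))
        y = rng.normal(size=6)
        lhs, rhs, offsets = assemble_mme(np.ones((6, 1)), [(T, None, 1e-12)], y, 1.0)
        sol = np.linalg.solve(lhs, rhs)
        assert np.allclose(sol[offsets[1]:], 0.0, atol=1e-9)

    def test_matches_gls_on_small_system(self):
        rng = np.random.default_rng(1)
        T = rng.integers(0, 3, size=(4, 1)).astype(float)
        y = rng.normal(size=4)
        s2, se2 = 0.5, 0.8
        lhs, rhs, offsets = assemble_mme(np.ones((4, 1)), [(T, None, s2)], y, se2)
        sol = np.linalg.solve(lhs, rhs)
        beta, (blup,) = gls_oracle(y, np.ones((4, 1)), [(T, None, s2)], se2)
        assert sol[0] == pytest.approx(beta[0], abs=1e-10)
        assert np.allclose(sol[offsets[1]:], blup, atol=1e-10)


class TestGlsOracle:
    def test_residual_only(self):
        y = np.array([1.0, 3.0, 5.0])
        beta, blups = gls_oracle(y, np.ones((3, 1)), [], 2.0)
        assert beta[0] == pytest.approx(3.0)
        assert blups == []

    def test_scalar_shrinkage_closed_form(self):
        # one random effect observed twice: BLUP = (s2/(s2+se2/2)) * ...;
        # check against the single-record textbook form with one extra record
        # fixing the mean
        y = np.array([2.0, 0.0])
        T = np.array([[1.0], [0.0]])
        s2, se2 = 1.0, 1.0
        beta, (blup,) = gls_oracle(y, np.ones((2, 1)), [(T, None, s2)], se2)
        # explicit GLS on this 2-record system
        V = se2 * np.eye(2) + s2 * (T @ T.T)
        Vi = np.linalg.inv(V)
        mu = (np.ones(2) @ Vi @ y) / (np.ones(2) @ Vi @ np.ones(2))
        assert beta[0] == pytest.approx(mu)
        assert blup[0] == pytest.approx(s2 * (T.T @ Vi @ (y - mu))[0])


class TestModelII:
    def test_single_confounded_record(self):
        ped = parse_pedigree([("b1", None, None)])
        fit = fit_model_II([3.0], ["b1"], ped, VC(sigma_u2=0.4, sigma_e2=0.6))
        assert fit.mu_hat == pytest.approx(3.0)
        assert fit.u_hat[0] == pytest.approx(0.0, abs=1e-10)

    def test_full_sib_antisymmetry(self):
        ped = parse_pedigree([("b1", None, None), ("b2", None, None),
                              ("c1", "b1", "b2"), ("c2", "b1", "b2")])
        fit = fit_model_II([1.0, -1.0], ["c1", "c2"], ped,
                           VC(sigma_u2=0.5, sigma_e2=0.5))
        u1 = fit.u_hat[ped.index_of("c1")]
        u2 = fit.u_hat[ped.index_of("c2")]
        assert u1 == pytest.approx(-u2, abs=1e-10)
        assert u1 > 0

    def test_unphenotyped_get_predictions(self, five_ped):
        fit = fit_model_II([1.0, 0.5, -0.2], ["d4", "d5", "b3"], five_ped,
                           VC(sigma_u2=0.3, sigma_e2=0.7))
        assert fit.u_hat.shape == (5,)
        assert np.isfinite(fit.u_hat).all()
        assert fit.u_hat[five_ped.index_of("b1")] != 0  # pulled in through A


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
@pytest.mark.parametrize("kind", ["II", "M", "MI", "MS"])
def test_mme_equals_gls_oracle(kind, seed):
    """Every model's MME solution matches the closed-form GLS/BLUP oracle."""
    ped, markers, obs, y = _random_problem(seed)
    vc = VC(sigma_u2=0.4, sigma_m2=0.07, sigma_e2=0.6)
    Z = _incidence(obs, ped)
    A = build_A(ped)
    if kind == "II":
        fit = fit_model_II(y, obs, ped, vc)
        beta, (u,) = gls_oracle(y, np.ones_like(y), [(Z, A, vc.sigma_u2)],
                                vc.sigma_e2)
        assert np.allclose(fit.u_hat, u, atol=1e-8)
    elif kind == "M":
        fit = fit_model_M(y, obs, markers, vc)
        beta, (m,) = gls_oracle(y, np.ones_like(y),
                                [(Z @ markers.W, None, vc.sigma_m2)], vc.sigma_e2)
        assert np.allclose(fit.m_hat, m, atol=1e-8)
    elif kind == "MI":
        fit = fit_model_MI(y, obs, markers, ped, vc)
        beta, (u, m) = gls_oracle(
            y, np.ones_like(y),
            [(Z, A, vc.sigma_u2), (Z @ markers.W, None, vc.sigma_m2)],
            vc.sigma_e2)
        assert np.allclose(fit.m_hat, m, atol=1e-8)
        assert np.allclose(fit.u_hat, u + markers.W @ m, atol=1e-8)
    else:
        # keep only descendant records for the oracle design
        desc_obs = [(i, yy) for i, yy in zip(obs, y)
                    if not ped.is_base[ped.index_of(i)]]
        if len(desc_obs) < 2:
            pytest.skip("too few descendant records in this draw")
        ids, yd = zip(*desc_obs)
        yd = np.array(yd)
        fit = fit_model_MS(yd, list(ids), markers, ped, vc)
        D = build_D(ped)
        _, C = ms_design(markers, D)
        Z_d = _incidence(list(ids), ped)[:, ped.n_base:]
        beta, (u_b, m) = gls_oracle(
            yd, np.ones_like(yd),
            [(Z_d @ D, None, vc.sigma_u2), (Z_d @ C, None, vc.sigma_m2)],
            vc.sigma_e2)
        assert np.allclose(fit.u_b_hat, u_b, atol=1e-8)
        assert np.allclose(fit.m_hat, m, atol=1e-8)
    assert fit.mu_hat == pytest.approx(beta[0], abs=1e-8)


@pytest.mark.parametrize("seed", [0, 5, 9])
def test_snp_blup_equals_gblup(seed):
    """SNP-BLUP and GBLUP with G = WW' give identical genetic values."""
    ped, markers, obs, y = _random_problem(seed, n=12, n_markers=6)
    vc = VC(sigma_m2=0.2, sigma_e2=0.5)
    fit = fit_model_M(y, obs, markers, vc)
    G = markers.W @ markers.W.T
    Z = _incidence(obs, ped)
    _, (u_gblup,) = gls_oracle(y, np.ones_like(y), [(Z, G, vc.sigma_m2)],
                               vc.sigma_e2)
    assert np.allclose(fit.u_hat, u_gblup, atol=1e-8)


class TestModelM:
    def test_all_zero_markers(self, trio_ped):
        markers = MarkerMatrix(W=np.zeros((3, 2)), marker_ids=("a", "b"),
                               ped=trio_ped)
        fit = fit_model_M([1.0, 2.0, 3.0], ["b1", "b2", "c"], markers,
                          VC(sigma_m2=1.0, sigma_e2=1.0))
        assert np.allclose(fit.m_hat, 0.0)
        assert fit.mu_hat == pytest.approx(2.0)

    def test_monomorphic_marker_gets_zero_effect(self, trio_ped):
        W = np.array([[2.0, 0.0], [2.0, 1.0], [2.0, 2.0]])
        markers = MarkerMatrix(W=W, marker_ids=("mono", "poly"), ped=trio_ped)
        fit = fit_model_M([0.4, 0.1, 1.2], ["b1", "b2", "c"], markers,
                          VC(sigma_m2=0.5, sigma_e2=0.5))
        assert fit.m_hat[0] == pytest.approx(0.0, abs=1e-10)
        assert fit.m_hat[1] != pytest.approx(0.0, abs=1e-6)


class TestNestingLimits:
    def test_mi_approaches_ii_as_marker_variance_vanishes(self):
        ped, markers, obs, y = _random_problem(7)
        ii = fit_model_II(y, obs, ped, VC(sigma_u2=0.4, sigma_e2=0.6))
        dists = []
        for lam in (1e3, 1e6):
            mi = fit_model_MI(y, obs, markers, ped,
                              VC(sigma_u2=0.4, sigma_m2=0.4 / lam, sigma_e2=0.6))
            dists.append(np.max(np.abs(mi.u_hat - ii.u_hat)))
        assert dists[1] < dists[0]
        assert dists[1] < 1e-4

    def test_mi_approaches_m_as_individual_variance_vanishes(self):
        ped, markers, obs, y = _random_problem(8)
        m = fit_model_M(y, obs, markers, VC(sigma_m2=0.1, sigma_e2=0.6))
        dists = []
        for lam in (1e3, 1e6):
            mi = fit_model_MI(y, obs, markers, ped,
                              VC(sigma_u2=0.4 / lam, sigma_m2=0.1, sigma_e2=0.6))
            dists.append(np.max(np.abs(mi.u_hat - m.u_hat)))
        assert dists[1] < dists[0]
        assert dists[1] < 1e-4


class TestModelMS:
    def test_hand_assembled_trio_system(self, trio_ped):
        # parents' dosages (2, 0), child 1: the marker coefficient for the
        # child record is 2*1 - (0.5*2 + 0.5*0) = 1, and the transmission row
        # is (1/2, 1/2); solve the literal 4x4 system for (mu, u_b1, u_b2, m)
        W = np.array([[2.0], [0.0], [1.0]])
        markers = MarkerMatrix(W=W, marker_ids=("m1",), ped=trio_ped)
        y, s_u2, s_m2, s_e2 = 2.0, 0.4, 0.1, 0.6
        lam_u, lam_m = s_e2 / s_u2, s_e2 / s_m2
        lhs = np.array([
            [1.0, 0.5,          0.5,          1.0],
            [0.5, 0.25 + lam_u, 0.25,         0.5],
            [0.5, 0.25,         0.25 + lam_u, 0.5],
            [1.0, 0.5,          0.5,          1.0 + lam_m],
        ])
        rhs = np.array([y, 0.5 * y, 0.5 * y, y])
        sol = np.linalg.solve(lhs, rhs)
        fit = fit_model_MS([y], ["c"], markers, trio_ped,
                           VC(sigma_u2=s_u2, sigma_m2=s_m2, sigma_e2=s_e2))
        assert fit.mu_hat == pytest.approx(sol[0], abs=1e-10)
        assert np.allclose(fit.u_b_hat, sol[1:3], atol=1e-10)
        assert fit.m_hat[0] == pytest.approx(sol[3], abs=1e-10)
        # eq7 composition of the child's genetic value
        child = fit.u_hat[trio_ped.index_of("c")]
        assert child == pytest.approx(0.5 * (sol[1] + sol[2]) + 1.0 * sol[3],
                                      abs=1e-10)

    def test_base_phenotypes_ignored_with_warning(self, trio_ped, caplog):
        W = np.array([[2.0], [0.0], [1.0]])
        markers = MarkerMatrix(W=W, marker_ids=("m1",), ped=trio_ped)
        vc = VC(sigma_u2=0.4, sigma_m2=0.1, sigma_e2=0.6)
        with caplog.at_level(logging.WARNING):
            both = fit_model_MS([5.0, 2.0], ["b1", "c"], markers, trio_ped, vc)
        assert "base individuals" in caplog.text
        only = fit_model_MS([2.0], ["c"], markers, trio_ped, vc)
        assert np.allclose(both.u_hat, only.u_hat)

    def test_eq6_vs_eq7_composition(self, five_ped):
        rng = np.random.default_rng(2)
        W = rng.integers(0, 3, size=(5, 3)).astype(float)
        markers = MarkerMatrix(W=W, marker_ids=("a", "b", "c"), ped=five_ped)
        vc = VC(sigma_u2=0.4, sigma_m2=0.1, sigma_e2=0.6)
        y, obs = [0.3, -1.0], ["d4", "d5"]
        e7 = fit_model_MS(y, obs, markers, five_ped, vc, design_choice="eq7")
        e6 = fit_model_MS(y, obs, markers, five_ped, vc, design_choice="eq6")
        # same estimated effects, different descendant composition by W_d m
        assert np.allclose(e6.m_hat, e7.m_hat)
        assert np.allclose(e7.u_hat[five_ped.n_base:] - e6.u_hat[five_ped.n_base:],
                           markers.W_d @ e7.m_hat)

    def test_requires_descendant_phenotypes(self, trio_ped):
        W = np.zeros((3, 1))
        markers = MarkerMatrix(W=W, marker_ids=("m1",), ped=trio_ped)
        with pytest.raises(ValueError, match="descendants"):
            fit_model_MS([1.0], ["b1"], markers, trio_ped,
                         VC(sigma_u2=1, sigma_m2=1, sigma_e2=1))


def test_solver_paths_agree(monkeypatch):
    """Direct MME factorization and the observation-space solver coincide."""
    ped, markers, obs, y = _random_problem(13, n=18, n_markers=10)
    vc = VC(sigma_u2=0.4, sigma_m2=0.05, sigma_e2=0.6)
    direct = fit_model_MI(y, obs, markers, ped, vc)
    monkeypatch.setattr(bm, "MME_DIRECT_LIMIT", 0)
    obs_space = fit_model_MI(y, obs, markers, ped, vc)
    assert direct.diagnostics["solver"] == "mme_direct"
    assert obs_space.diagnostics["solver"] == "observation_space"
    assert direct.mu_hat == pytest.approx(obs_space.mu_hat, abs=1e-8)
    assert np.allclose(direct.u_hat, obs_space.u_hat, atol=1e-8)


def test_prediction_invariant_to_input_ordering():
    """Permuting pedigree records and marker columns leaves per-id
    predictions unchanged."""
    rng = np.random.default_rng(3)
    records = [("b1", None, None), ("b2", None, None), ("b3", None, None),
               ("d4", "b1", "b2"), ("d5", "d4", "b3"), ("d6", "d4", "b3")]
    W = rng.integers(0, 3, size=(6, 5)).astype(float)
    obs, y = ["d4", "d5", "d6"], [0.2, -0.5, 1.0]
    vc = VC(sigma_u2=0.4, sigma_m2=0.1, sigma_e2=0.6)

    ped1 = parse_pedigree(records)
    ids1 = [r[0] for r in records]
    m1 = MarkerMatrix(W=W[[ids1.index(i) for i in ped1.ids]],
                      marker_ids=("a", "b", "c", "d", "e"), ped=ped1)

    perm_records = [records[i] for i in (4, 0, 3, 1, 5, 2)]
    col_perm = [2, 0, 4, 1, 3]
    ped2 = parse_pedigree(perm_records)
    m2 = MarkerMatrix(W=W[[ids1.index(i) for i in ped2.ids]][:, col_perm],
                      marker_ids=tuple("cadbe"), ped=ped2)

    for fitter in (
        lambda p, m: fit_model_MS(y, obs, m, p, vc),
        lambda p, m: fit_model_MI(y, obs, m, p, vc),
        lambda p, m: fit_model_M(y, obs, m, vc),
    ):
        f1, f2 = fitter(ped1, m1), fitter(ped2, m2)
        assert np.allclose(f1.predictions(ids1), f2.predictions(ids1), atol=1e-8)
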