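import numpy as np
import pandas as pd
import pytest

from cspic.models import (
    MarkerDesign,
    build_kernel,
    fit_bayesb,
    fit_model,
    fit_rkhs,
    fit_rrblup,
    predict,
)
from conftest import make_matrix


def toy_panel(rng, n=20, m=50, h2=0.8, n_qtl=None):
    dos = (rng.random((n, m)) < rng.uniform(0.2, 0.8, m)).astype(np.int8) * 2
    g = make_matrix(dos)
    design = MarkerDesign.from_genotypes(g)
    beta = np.zeros(m)
    qtl = rng.choice(m, n_qtl or m, replace=False)
    beta[qtl] = rng.normal(0, 0.3, len(qtl))
    gval = design.Z @ beta
    ve = np.var(gval) * (1 - h2) / h2 if h2 < 1 else 0.0
    y = 3.0 + gval + rng.normal(0, np.sqrt(ve), n)
    return g, design, y, gval


class TestRRBLUP:
    def test_constant_phenotype_degenerates(self, rng):
        g, design, *_ = toy_panel(rng)
        with pytest.warns(UserWarning, match="zero phenotypic variance"):
            fit = fit_rrblup(np.full(20, 2.5), design)
        assert np.all(fit.alpha == 0) and fit.mu == 2.5

    def test_fixed_lambda_matches_ridge_oracle(self, rng):
        _, design, y, _ = toy_panel(rng)
        lam = 7.5
        fit = fit_rrblup(y, design, lam=lam)
        Z = design.Z
        oracle = np.linalg.solve(
            Z.T @ Z + lam * np.eye(Z.shape[1]), Z.T @ (y - fit.mu)
        )
        np.testing.assert_allclose(fit.alpha, oracle, atol=1e-8)

    def test_gblup_equivalence_on_gebvs(self, rng):
        _, design, y, _ = toy_panel(rng)
        fit = fit_rrblup(y, design)
        lam = fit.var_params["lambda"]
        Z = design.Z
        c = Z.shape[1]
        G = Z @ Z.T / c
        u = G @ np.linalg.solve(G + (lam / c) * np.eye(len(y)), y - fit.mu)
        np.testing.assert_allclose(fit.fitted - fit.mu, u, atol=1e-8)

    def test_marker_column_order_invariance(self, rng):
        g, design, y, _ = toy_panel(rng)
        perm = rng.permutation(g.n_loci)
        design_p = MarkerDesign.from_genotypes(g.subset_loci(perm))
        p1 = fit_rrblup(y, design).fitted
        p2 = fit_rrblup(y, design_p).fitted
        # identical up to the REML optimizer's stopping tolerance
        np.testing.assert_allclose(p1, p2, atol=1e-5)


class TestBayesB:
    def test_pi_one_is_exact_null_model(self, rng):
        _, design, y, _ = toy_panel(rng)
        fit = fit_bayesb(y, design, pi=1.0)
        assert np.all(fit.alpha == 0)
        assert fit.mu == y.mean()
        np.testing.assert_array_equal(fit.extras["inclusion_prob"], 0)

    def test_same_seed_identical_posterior(self, rng):
        _, design, y, _ = toy_panel(rng, n=30, m=60)
        kw = dict(n_iter=1500, burn_in=300, seed=11)
        f1 = fit_bayesb(y, design, **kw)
        f2 = fit_bayesb(y, design, **kw)
        np.testing.assert_array_equal(f1.alpha, f2.alpha)

    def test_qtl_markers_gain_inclusion_probability(self, rng):
        local = np.random.default_rng(77)
        n, m, nq = 150, 400, 10
        dos = (local.random((n, m)) < 0.5).astype(np.int8) * 2
        design = MarkerDesign.from_genotypes(make_matrix(dos))
        qtl = local.choice(m, nq, replace=False)
        beta = np.zeros(m)
        beta[qtl] = local.choice([-1.0, 1.0], nq)
        gval = design.Z @ beta
        y = gval + local.normal(0, np.sqrt(np.var(gval) * 2 / 3), n)
        fit = fit_bayesb(y, design, n_iter=3000, burn_in=500, seed=5)
        incl = fit.extras["inclusion_prob"]
        is_q = np.zeros(m, bool)
        is_q[qtl] = True
        assert incl[is_q].mean() > incl[~is_q].mean()

    def test_invalid_arguments(self, rng):
        _, design, y, _ = toy_panel(rng)
        with pytest.raises(ValueError):
            fit_bayesb(y, design, pi=1.5)
        with pytest.raises(ValueError):
            fit_bayesb(y, design, n_iter=100, burn_in=200)

    def test_pi_zero_common_variance_close_to_rrblup(self, rng):
        local = np.random.default_rng(31)
        n, m = 120, 300
        dos = (local.random((n, m)) < 0.5).astype(np.int8) * 2
        design = MarkerDesign.from_genotypes(make_matrix(dos))
        beta = local.normal(0, 0.2, m)
        gval = design.Z @ beta
        y = gval + local.normal(0, np.sqrt(np.var(gval)), n)
        acc_rr = np.corrcoef(fit_rrblup(y, design).fitted, gval)[0, 1]
        fb = fit_bayesb(y, design, pi=0.0, n_iter=3000, burn_in=500, seed=3)
        acc_bb = np.corrcoef(fb.fitted, gval)[0, 1]
        assert acc_bb == pytest.approx(acc_rr, abs=0.05)


class TestKernel:
    def test_unit_diagonal_and_identical_rows(self, rng):
        g, design, *_ = toy_panel(rng, n=10)
        K = build_kernel(design, 1.0)
        np.testing.assert_allclose(np.diag(K), 1.0)
        d2 = MarkerDesign(
            np.vstack([design.Z[0], design.Z[0]]), design.center, [], design.marker_ids
        )
        assert build_kernel(d2, 2.0)[0, 1] == pytest.approx(1.0)

    def test_bandwidth_zero_limit_all_ones(self, rng):
        _, design, *_ = toy_panel(rng, n=8)
        K = build_kernel(design, 1e-9)
        np.testing.assert_allclose(K, 1.0, atol=1e-6)

    def test_positive_semidefinite(self, rng):
        _, design, *_ = toy_panel(rng, n=10)
        K = build_kernel(design, 1.5)
        assert np.linalg.eigvalsh(K).min() >= -1e-8

    def test_invalid_bandwidth(self, rng):
        _, design, *_ = toy_panel(rng, n=5)
        with pytest.raises(ValueError):
            build_kernel(design, 0.0)


class TestRKHS:
    def test_fixed_lambda_matches_kernel_ridge_oracle(self, rng):
        _, design, y, _ = toy_panel(rng, n=20)
        lam = 0.8
        fit = fit_rkhs(y, design, bandwidth=1.0, lam=lam)
        K = build_kernel(design, 1.0)
        mu = fit.extras["kernels"][0]["mu"]
        oracle = mu + K @ np.linalg.solve(K + lam * np.eye(20), y - mu)
        np.testing.assert_allclose(fit.fitted, oracle, atol=1e-6)

    def test_interpolation_limit_on_noise_free_data(self, rng):
        _, design, y, gval = toy_panel(rng, n=25, h2=1.0)
        fit = fit_rkhs(y, design, bandwidth=1.0, lam=1e-6)
        assert np.corrcoef(fit.fitted, y)[0, 1] > 0.99

    def test_constant_phenotype_predicts_constant(self, rng):
        _, design, *_ = toy_panel(rng, n=15)
        y = np.full(15, 4.0)
        fit = fit_rkhs(y, design, lam=1.0)
        np.testing.assert_allclose(fit.fitted, 4.0, atol=1e-8)

    def test_gibbs_deterministic_and_close_to_closed_form(self, rng):
        _, design, y, _ = toy_panel(rng, n=30)
        f1 = fit_rkhs(y, design, seed=2, n_iter=4000, burn_in=800)
        f2 = fit_rkhs(y, design, seed=2, n_iter=4000, burn_in=800)
        np.testing.assert_array_equal(f1.fitted, f2.fitted)
        assert np.corrcoef(f1.fitted, y)[0, 1] > 0.5

    def test_multi_kernel_averaging(self, rng):
        _, design, y, _ = toy_panel(rng, n=15)
        fit = fit_rkhs(y, design, bandwidth=[0.5, 1.0, 2.5], lam=0.5)
        assert len(fit.extras["kernels"]) == 3
        preds = predict(fit, design.Z + design.center)
        np.testing.assert_allclose(preds, fit.fitted, atol=1e-8)


class TestPredict:
    def test_training_predictions_reproduce_fitted(self, rng):
        g, design, y, _ = toy_panel(rng)
        fit = fit_rrblup(y, design)
        np.testing.assert_allclose(predict(fit, g), fit.fitted, atol=1e-10)

    def test_hand_computed_linear_prediction(self, rng):
        g, design, y, _ = toy_panel(rng)
        fit = fit_rrblup(y, design, lam=2.0)
        new = make_matrix((rng.random((4, 50)) < 0.5).astype(np.int8) * 2)
        expected = fit.mu + (new.dosage - design.center) @ fit.alpha
        np.testing.assert_allclose(predict(fit, new), expected, atol=1e-10)

    def test_marker_mismatch_errors(self, rng):
        g, design, y, _ = toy_panel(rng)
        fit = fit_rrblup(y, design)
        bad = make_matrix(np.zeros((2, 3), np.int8), locus_ids=["X1", "X2", "X3"])
        with pytest.raises(KeyError, match="absent"):
            predict(fit, bad)

    def test_unknown_model_kind(self, rng):
        _, design, y, _ = toy_panel(rng)
        with pytest.raises(ValueError, match="unknown model"):
            fit_model("svm", y, design)


def test_accuracy_increases_with_heritability():
    """Prediction accuracy against true genetic values rises with h2 for
    all three model families (median over seeds)."""
    accs = {"rrblup": {}, "bayesb": {}, "rkhs": {}}
    for h2 in (0.2, 0.5, 0.8):
        per_model = {k: [] for k in accs}
        for s in range(8):
            local = np.random.default_rng(1000 * s + int(h2 * 10))
            n, m = 120, 300
            dos = (local.random((n, m)) < 0.5).astype(np.int8) * 2
            design = MarkerDesign.from_genotypes(make_matrix(dos))
            beta = local.normal(0, 0.2, m)
            gval = design.Z @ beta
            y = gval + local.normal(0, np.sqrt(np.var(gval) * (1 - h2) / h2), n)
            tr, te = np.arange(0, 90), np.arange(90, 120)
            d_tr = MarkerDesign(
                design.Z[tr] - design.Z[tr].mean(0),
                design.center + design.Z[tr].mean(0),
                [],
                design.marker_ids,
            )
            for kind, kw in (
                ("rrblup", {}),
                ("bayesb", {"n_iter": 1500, "burn_in": 300, "seed": s}),
                ("rkhs", {"n_iter": 3000, "burn_in": 600, "seed": s}),
            ):
                fit = fit_model(kind, y[tr], d_tr, **kw)
                preds = predict(fit, dos[te].astype(float))
                per_model[kind].append(np.corrcoef(preds, gval[te])[0, 1])
        for kind in accs:
            accs[kind][h2] = float(np.median(per_model[kind]))
    for kind, by_h2 in accs.items():
        assert by_h2[0.2] < by_h2[0.5] < by_h2[0.8], (kind, by_h2)
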