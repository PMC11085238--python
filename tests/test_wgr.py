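import numpy as np
import pandas as pd
import pytest

import soygp
from soygp.geno import GenotypeMatrix
from soygp.wgr import McmcConfig, compute_grm, gibbs_bayesb, gibbs_bl, gibbs_brr


def _matrix(dosage, ids=None):
    dosage = np.asarray(dosage, float)
    n, m = dosage.shape
    ids = ids or [f"s{i}" for i in range(n)]
    return GenotypeMatrix(
        sample_ids=np.array(ids, dtype=object),
        marker_ids=np.array([f"m{j}" for j in range(m)], dtype=object),
        chrom=np.array(["1"] * m, dtype=object),
        pos=np.arange(1, m + 1),
        dosage=dosage,
    )


def _structured_instance(n, m, h2=0.8, seed=0):
    """Two-subpopulation cohort: gives the GRM real structure, so REML has
    an interior optimum (an unstructured n << m draw makes G ≈ I and the
    variance ratio unidentifiable)."""
    half = n // 2
    cfg = soygp.SimPanelConfig(
        n_markers=m, panel_sizes={"A": half, "E": n - half},
        cluster_assignment={"A": "I", "E": "II"},
        fst_within_cluster=0.0, fst_between_cluster=0.25, seed=seed,
    )
    g, _, _ = soygp.simulate_founder_panels(cfg)
    arch = soygp.TraitArchitecture(n_qtl=max(m // 3, 2), target_h2=0.9)
    eff = soygp.assign_qtl_effects(g, arch, seed=seed + 1)
    rng = np.random.default_rng(seed + 2)
    gv = g.dosage @ eff[:, 0]
    gv = (gv - gv.mean()) / gv.std()
    y = pd.Series(gv + rng.standard_normal(n) * np.sqrt((1 - h2) / h2),
                  index=g.sample_ids)
    return g, y


def _instance(n, m, h2=0.5, n_qtl=None, seed=0):
    """Polygenic instance: genotypes, centered Z, y, true effects."""
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.1, 0.9, size=m)
    X = rng.binomial(2, p, size=(n, m)).astype(float)
    g = _matrix(X)
    pc = X.mean(axis=0) / 2.0
    Z = X - 2 * pc
    n_qtl = n_qtl or m
    beta = np.zeros(m)
    qtl = rng.choice(m, size=n_qtl, replace=False)
    beta[qtl] = rng.standard_normal(n_qtl)
    gv = Z @ beta
    gv = gv / gv.std()
    noise = rng.standard_normal(n) * np.sqrt((1 - h2) / h2)
    y = pd.Series(gv + noise, index=g.sample_ids)
    return g, Z, y, beta, gv


class TestGrm:
    def test_hand_example(self):
        g = _matrix([[0.0, 2.0], [2.0, 0.0]])
        grm = compute_grm(g, freqs=np.array([0.5, 0.5]))
        assert grm.c == pytest.approx(1.0)
        np.testing.assert_allclose(grm.G, [[2.0, -2.0], [-2.0, 2.0]])

    def test_duplicated_individual(self):
        rng = np.random.default_rng(1)
        X = rng.integers(0, 3, size=(6, 40)).astype(float)
        X[3] = X[0]
        grm = compute_grm(_matrix(X))
        np.testing.assert_allclose(grm.G[0], grm.G[3])
        assert grm.G[0, 3] == pytest.approx(grm.G[0, 0])

    def test_marker_order_invariance(self):
        rng = np.random.default_rng(2)
        X = rng.integers(0, 3, size=(8, 30)).astype(float)
        g = _matrix(X)
        g.pos = np.ones(30, dtype=np.int64)  # tied positions: any order valid
        perm = rng.permutation(30)
        g2 = g.subset(markers=list(g.marker_ids[perm]))
        np.testing.assert_allclose(
            compute_grm(g).G, compute_grm(g2).G, atol=1e-10
        )

    def test_psd_and_mean_diagonal(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(0.1, 0.9, 200)
        X = rng.binomial(2, p, size=(50, 200)).astype(float)
        grm = compute_grm(_matrix(X))
        eig = np.linalg.eigvalsh(grm.G)
        assert eig.min() > -1e-8
        assert np.mean(np.diag(grm.G)) == pytest.approx(1.0, abs=0.1)

    def test_all_monomorphic_rejected(self):
        with pytest.raises(ValueError, match="monomorphic"):
            compute_grm(_matrix(np.zeros((4, 5))))


class TestRemlGblup:
    def test_zero_variance_y_gives_flat_gebvs(self):
        g, Z, y, *_ = _instance(30, 50, seed=4)
        flat = pd.Series(1.0, index=y.index)
        fit = soygp.reml_gblup(flat, compute_grm(g))
        assert fit.extra["boundary"]
        assert float(fit.gebv.std()) == pytest.approx(0.0, abs=1e-9)

    def test_heritability_recovery(self):
        errs = []
        for seed in range(20):
            g, Z, y, *_ = _instance(500, 300, h2=0.5, seed=seed)
            fit = soygp.fit_model("GBLUP", g, y)
            errs.append(fit.extra["h2_model"] - 0.5)
        assert abs(float(np.mean(errs))) <= 0.1

    def test_equivalence_with_rrblup(self):
        g, y = _structured_instance(50, 300, seed=5)
        train = y.iloc[:40]
        fg = soygp.fit_model("GBLUP", g, train)
        fr = soygp.fit_model("RRBLUP", g, train)
        assert not fg.extra["boundary"]
        assert float(np.abs(fg.gebv - fr.gebv).max()) <= 1e-6

    def test_constant_shift_moves_only_intercept(self):
        g, Z, y, *_ = _instance(60, 80, seed=6)
        f1 = soygp.fit_model("GBLUP", g, y)
        f2 = soygp.fit_model("GBLUP", g, y + 7.0)
        assert f2.mu - f1.mu == pytest.approx(7.0, abs=1e-4)
        np.testing.assert_allclose(f1.gebv, f2.gebv, atol=1e-5)


class TestRrblup:
    def test_rank_one_signal(self):
        rng = np.random.default_rng(7)
        x = rng.integers(0, 3, size=(30, 1)).astype(float)
        g = _matrix(x)
        y = pd.Series(2.5 * x[:, 0], index=g.sample_ids)
        fit = soygp.fit_model("RRBLUP", g, y)
        r = np.corrcoef(fit.gebv, y)[0, 1]
        assert r == pytest.approx(1.0, abs=1e-6)

    def test_effect_recovery(self):
        g, Z, y, beta, _ = _instance(300, 1000, h2=0.8, seed=8)
        fit = soygp.fit_model("RRBLUP", g, y)
        assert np.corrcoef(fit.beta, beta)[0, 1] > 0.4


class TestGibbsBrr:
    def test_matches_closed_form_ridge_with_fixed_variances(self):
        g, Z, y, beta, gv = _instance(100, 200, h2=0.7, seed=9)
        s2e_true = float(np.var(y - gv))
        s2b_true = float(np.var(gv)) / float(np.sum(np.var(Z, axis=0)))
        fit = gibbs_brr(
            y, Z, McmcConfig(n_iter=2000, burn_in=500, seed=1),
            fix_sigma2_beta=s2b_true, fix_sigma2_e=s2e_true,
        )
        lam = s2e_true / s2b_true
        yc = y.to_numpy() - y.mean()
        ridge = np.linalg.solve(Z.T @ Z + lam * np.eye(200), Z.T @ yc)
        assert np.corrcoef(fit.beta, ridge)[0, 1] >= 0.999

    def test_null_signal_shrinks_to_zero(self):
        rng = np.random.default_rng(10)
        g, Z, _, _, _ = _instance(80, 100, seed=10)
        y = pd.Series(rng.standard_normal(80), index=g.sample_ids)
        fit = gibbs_brr(y, Z, McmcConfig(n_iter=1500, burn_in=300, seed=2))
        # posterior-mean effects hover around zero
        assert float(np.abs(fit.beta).mean()) < 0.05

    def test_chains_agree_across_seeds(self):
        g, Z, y, *_ = _instance(200, 500, h2=0.6, seed=11)
        cfg = dict(n_iter=2500, burn_in=500)
        f1 = gibbs_brr(y, Z, McmcConfig(**cfg, seed=1))
        f2 = gibbs_brr(y, Z, McmcConfig(**cfg, seed=99))
        assert np.corrcoef(f1.gebv, f2.gebv)[0, 1] >= 0.99

    def test_deterministic_given_seed(self):
        g, Z, y, *_ = _instance(40, 60, seed=12)
        cfg = McmcConfig(n_iter=400, burn_in=100, seed=5)
        f1 = gibbs_brr(y, Z, cfg)
        f2 = gibbs_brr(y, Z, cfg)
        np.testing.assert_array_equal(f1.beta, f2.beta)

    def test_doubling_iterations_stays_within_mc_error(self):
        g, Z, y, *_ = _instance(100, 200, h2=0.6, seed=13)
        f1 = gibbs_brr(y, Z, McmcConfig(n_iter=2000, burn_in=500, seed=3))
        f2 = gibbs_brr(y, Z, McmcConfig(n_iter=4000, burn_in=500, seed=3))
        diff = float(np.abs(f1.gebv - f2.gebv).mean())
        mc_se = f1.extra["gebv_mc_se"] * np.sqrt(f1.extra["n_saved"])
        assert diff < mc_se  # well under one per-draw MC SD


class TestGibbsBl:
    def test_large_lambda_collapses_effects(self):
        g, Z, y, *_ = _instance(60, 80, h2=0.8, seed=14)
        fit = gibbs_bl(
            y, Z, McmcConfig(n_iter=800, burn_in=200, seed=4),
            fix_lambda=1e4,
        )
        assert float(np.abs(fit.beta).max()) < 1e-3

    def test_small_lambda_approaches_least_squares(self):
        rng = np.random.default_rng(15)
        Z = rng.standard_normal((100, 20))
        beta = rng.standard_normal(20)
        y = pd.Series(Z @ beta + 0.1 * rng.standard_normal(100),
                      index=[f"s{i}" for i in range(100)])
        ols = np.linalg.lstsq(
            np.column_stack([np.ones(100), Z]), y.to_numpy(), rcond=None
        )[0][1:]
        fit = gibbs_bl(
            y, Z, McmcConfig(n_iter=2000, burn_in=500, seed=5),
            fix_lambda=1e-3, fix_sigma2_e=0.01,
        )
        assert np.corrcoef(fit.beta, ols)[0, 1] > 0.999
        np.testing.assert_allclose(fit.beta, ols, atol=0.05)

    def test_sparse_truth_ordering(self):
        for seed in range(10):
            g, Z, y, beta, _ = _instance(150, 500, h2=0.8, n_qtl=10, seed=seed)
            fit = gibbs_bl(y, Z, McmcConfig(n_iter=800, burn_in=200, seed=seed))
            qtl = beta != 0
            assert (np.abs(fit.beta[qtl]).mean()
                    > np.abs(fit.beta[~qtl]).mean())


class TestGibbsBayesB:
    def test_pi_one_reduces_to_ridge_type_fit(self):
        # with every marker included, BayesB is a marker-specific-variance
        # ridge; as the slab df grows those variances concentrate and the
        # fit converges on the common-variance BRR fit
        g, Z, y, *_ = _instance(120, 300, h2=0.7, seed=16)
        cors = []
        for df in (5, 20, 100):
            hyper = {"df_beta": float(df)}
            fb = gibbs_bayesb(y, Z, McmcConfig(2000, 500, seed=6),
                              fix_pi=1.0, hyper=hyper)
            fr = gibbs_brr(y, Z, McmcConfig(2000, 500, seed=6), hyper=hyper)
            cors.append(np.corrcoef(fb.gebv, fr.gebv)[0, 1])
        assert cors == sorted(cors)
        assert cors[-1] >= 0.98

    def test_null_signal_keeps_inclusion_below_prior(self):
        # pure-noise y: no marker should be preferred, and inclusion must
        # not exceed the prior mean (the slab expects signal that is absent)
        rng = np.random.default_rng(18)
        g, Z, _, _, _ = _instance(80, 150, seed=18)
        y = pd.Series(rng.standard_normal(80), index=g.sample_ids)
        fit = gibbs_bayesb(y, Z, McmcConfig(n_iter=1500, burn_in=300, seed=8))
        pip = fit.extra["pip"]
        assert float(pip.mean()) < 0.55
        assert float(pip.max()) < 0.9  # no spurious confident discovery

    def test_sparse_truth_inclusion_ordering(self):
        for seed in range(10):
            g, Z, y, beta, _ = _instance(150, 500, h2=0.8, n_qtl=10, seed=seed)
            fit = gibbs_bayesb(
                y, Z, McmcConfig(n_iter=800, burn_in=200, seed=seed)
            )
            qtl = beta != 0
            pip = fit.extra["pip"]
            assert pip[qtl].mean() > pip[~qtl].mean()


class TestPredictGebv:
    def test_training_predictions_reproduce_fit(self):
        g, Z, y, *_ = _instance(60, 100, seed=18)
        for model in ("GBLUP", "RRBLUP"):
            fit = soygp.fit_model(model, g, y)
            pred = soygp.predict_gebv(fit, g)
            np.testing.assert_allclose(pred, fit.gebv, atol=1e-10)

    def test_new_sample_identical_to_training_sample(self):
        g, Z, y, *_ = _instance(50, 80, seed=19)
        fit = soygp.fit_model("RRBLUP", g, y)
        clone = g.subset(samples=[g.sample_ids[0]])
        clone.sample_ids = np.array(["clone"], dtype=object)
        pred = soygp.predict_gebv(fit, clone)
        assert pred.iloc[0] == pytest.approx(fit.gebv.iloc[0], abs=1e-10)

    def test_heldout_identity_rrblup_vs_gblup(self):
        g, y = _structured_instance(50, 300, seed=22)
        train = y.iloc[:40]
        held = g.subset(samples=list(g.sample_ids[40:]))
        gtr = g.subset(samples=list(y.index[:40]))
        fg = soygp.fit_model("GBLUP", gtr, train)
        fr = soygp.fit_model("RRBLUP", gtr, train)
        assert not fg.extra["boundary"]  # identity needs interior REML optima
        pg = soygp.predict_gebv(fg, held)
        pr = soygp.predict_gebv(fr, held)
        np.testing.assert_allclose(pg, pr, atol=1e-6)

    def test_missing_marker_rejected(self):
        g, Z, y, *_ = _instance(40, 50, seed=21)
        fit = soygp.fit_model("RRBLUP", g, y)
        reduced = g.subset(markers=list(g.marker_ids[:30]))
        with pytest.raises(ValueError, match="absent"):
            soygp.predict_gebv(fit, reduced)
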