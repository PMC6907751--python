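"""Design construction, posterior sampling, WAIC and odds-ratio curves."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from genesupport.approval_model import (
    DesignMatrix,
    EvidenceBlock,
    ModelSpec,
    PosteriorFit,
    build_design,
    fit_approval_model,
    odds_ratio_curve,
    select_model_universe,
    waic,
)


def empty_design(n=0):
    return DesignMatrix(X=np.empty((n, 0)), columns=[], standardization={})


class TestModelUniverse:
    def test_active_unapproved_excluded_inactive_unknown_kept(self):
        pairs = pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(12)],
            "indication": ["i"] * 12,
            "latest_phase": pd.array([1, 2, 3, 4, None, None, 0, 1, 2, 3, 4, None],
                                     dtype="Int64"),
            "approved":    [0, 0, 0, 1, 0, 0, 0, 0, 0, 0, 1, 0],
            "active":      [1, 0, 0, 0, 1, 0, 0, 1, 0, 1, 1, 0],
        })
        out = select_model_universe(pairs)
        # hand selection: drop the 4 active unapproved (rows 0,4,7,9)
        assert sorted(out["gene_id"]) == sorted(
            [f"g{i}" for i in (1, 2, 3, 5, 6, 8, 10, 11)]
        )
        assert out.loc[out["gene_id"] == "g5", "y"].tolist() == [0]
        assert out.loc[out["gene_id"] == "g10", "y"].tolist() == [1]


class TestDesign:
    def make_pairs(self, n=100, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(n)],
            "indication": ["i1"] * n,
            "ind_class": rng.choice(["a", "b"], size=n),
            "tgt_class": rng.choice(["x", "y"], size=n),
            "dev_time": rng.uniform(0, 30, size=n),
        })

    def test_one_hot_counts_and_reference_level(self):
        pairs = self.make_pairs()
        design = build_design(pairs, categorical=["ind_class", "tgt_class"],
                              continuous=["dev_time"], rare_level_min=1)
        # 2 levels each -> 1 indicator each (alphabetical first dropped)
        assert design.columns == ["ind_class[b]", "tgt_class[y]", "dev_time"]

    def test_continuous_standardized(self):
        pairs = self.make_pairs()
        design = build_design(pairs, continuous=["dev_time"])
        col = design.X[:, design.columns.index("dev_time")]
        assert abs(col.mean()) < 1e-9
        assert abs(col.std() - 1.0) < 1e-9

    def test_missing_continuous_imputed_with_indicator(self):
        pairs = self.make_pairs()
        pairs.loc[:9, "dev_time"] = np.nan
        design = build_design(pairs, continuous=["dev_time"])
        assert "dev_time_missing" in design.columns
        col = design.X[:, design.columns.index("dev_time")]
        assert np.all(col[:10] == 0.0)

    def test_rare_levels_pooled(self):
        pairs = self.make_pairs()
        pairs.loc[:4, "ind_class"] = "rare"
        design = build_design(pairs, categorical=["ind_class"], rare_level_min=20)
        assert not any("rare" in c for c in design.columns)

    def test_constant_column_dropped_with_warning(self):
        pairs = self.make_pairs()
        pairs["flat"] = 3.14
        with pytest.warns(UserWarning, match="constant"):
            design = build_design(pairs, continuous=["flat"])
        assert "flat" not in design.columns

    def test_evidence_block_gene_without_association_gets_zero_eta(self):
        pairs = self.make_pairs(n=30)
        evidence = pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(30)],
            "indication": ["i1"] * 30,
            "source": ["OMIM"] * 30,
            "e_c": [0.5] * 15 + [np.nan] * 15,
            "has_assoc": [1] * 15 + [0] * 15,
        })
        design = build_design(pairs, evidence=evidence)
        blk = design.evidence["OMIM"]
        assert np.all(blk.exists[15:] == 0)
        assert np.all(blk.z[15:] == 0.0)


def fit_prior_only(seed=5, **spec_kw):
    spec = ModelSpec(seed=seed, **spec_kw)
    return fit_approval_model(np.empty(0), empty_design(), spec)


class TestSampler:
    def test_prior_only_recovers_prior(self):
        """With no data the posterior is the prior: alpha centered at
        -2.2 with SD 0.75, implying ~10% baseline approval."""
        fit = fit_prior_only()
        alpha = fit.params("alpha")
        assert np.median(alpha) == pytest.approx(-2.2, abs=0.05)
        assert alpha.std() == pytest.approx(0.75, rel=0.08)
        assert expit(np.median(alpha)) == pytest.approx(0.0997, abs=0.01)

    def test_diagnostics_recorded_and_pass(self):
        fit = fit_prior_only()
        assert fit.converged
        assert fit.rhat.max() <= 1.01
        assert fit.ess.min() >= 400

    def test_seeded_fit_reproducible(self):
        a = fit_prior_only(seed=9).draws
        b = fit_prior_only(seed=9).draws
        np.testing.assert_array_equal(a, b)

    def test_chain_count_configurable(self):
        fit = fit_prior_only(chains=2, draws=500)
        assert fit.chain_draws.shape[0] == 2

    def test_row_permutation_leaves_posterior_unchanged(self):
        """The likelihood is exchangeable in rows; permuting the data
        changes nothing given the same seed (proposals depend on data
        only through the mode and Hessian, which are permutation
        invariant)."""
        rng = np.random.default_rng(2)
        n = 300
        x = rng.normal(size=n)
        y = (rng.random(n) < expit(-1 + x)).astype(int)
        design = DesignMatrix(X=x[:, None], columns=["x"], standardization={})
        fit1 = fit_approval_model(y, design, ModelSpec(seed=3, chains=2))
        perm = rng.permutation(n)
        design2 = DesignMatrix(X=x[perm][:, None], columns=["x"], standardization={})
        fit2 = fit_approval_model(y[perm], design2, ModelSpec(seed=3, chains=2))
        # summation order shifts the optimizer's mode by float rounding;
        # the posterior itself is unchanged
        np.testing.assert_allclose(np.median(fit1.draws, axis=0),
                                   np.median(fit2.draws, axis=0), atol=1e-4)


class TestWaic:
    def simulated_fit(self, seed=0, n=400):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        y = (rng.random(n) < expit(-1 + 0.8 * x)).astype(int)
        design = DesignMatrix(X=x[:, None], columns=["x"], standardization={})
        return fit_approval_model(y, design, ModelSpec(seed=seed, chains=2))

    def test_waic_matches_independent_recomputation(self):
        """Recompute WAIC from the saved pointwise log-likelihoods with
        plain numpy, independently of the library formula."""
        fit = self.simulated_fit()
        value, se = waic(fit, max_draws=500, seed=1)
        ll = fit.log_lik_pointwise(max_draws=500, seed=1)
        lppd = np.sum(np.log(np.mean(np.exp(ll), axis=0)))
        p_w = np.sum(np.var(ll, axis=0, ddof=1))
        assert value == pytest.approx(-2 * (lppd - p_w), rel=1e-10)

    def test_waic_agrees_with_arviz(self):
        """Cross-check against ArviZ's WAIC (elpd scale, times -2)."""
        import warnings

        import arviz as az

        fit = self.simulated_fit()
        ll = fit.log_lik_pointwise(max_draws=2000)
        value, _ = waic(fit, max_draws=2000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            idata = az.from_dict(
                posterior={"theta": fit.chain_draws},
                log_likelihood={"y": ll[None, :, :]},
            )
            ref = az.waic(idata, scale="deviance")
        assert value == pytest.approx(float(ref.elpd_waic), rel=0.02)

    def test_identical_fits_identical_waic(self):
        f1, f2 = self.simulated_fit(3), self.simulated_fit(3)
        assert waic(f1) == waic(f2)

    def test_too_few_draws_rejected(self):
        fit = self.simulated_fit()
        small = PosteriorFit(chain_draws=fit.chain_draws[:, :20, :],
                             param_names=fit.param_names, rhat=fit.rhat,
                             ess=fit.ess, spec=fit.spec, design=fit.design,
                             y=fit.y)
        with pytest.raises(ValueError, match="draws"):
            waic(small)


class TestOddsRatioCurve:
    def degenerate_fit(self, gammas):
        """A fit whose draws are all identical, for closed-form checks."""
        block = EvidenceBlock(exists=np.ones(1), z=np.zeros(1), mean=0.3, sd=0.2)
        design = DesignMatrix(X=np.empty((1, 0)), columns=[], standardization={},
                              evidence={"OMIM": block})
        names = ["alpha"] + [f"gamma_OMIM[{j}]" for j in range(len(gammas))]
        draws = np.tile(np.array([[-2.2, *gammas]]), (200, 1))[None, :, :]
        return PosteriorFit(chain_draws=draws, param_names=names,
                            rhat=np.ones(len(names)), ess=np.full(len(names), 1e4),
                            spec=ModelSpec(degree=len(gammas) - 1), design=design,
                            y=np.zeros(1))

    def test_zero_gammas_give_flat_unit_curve(self):
        curve = odds_ratio_curve(self.degenerate_fit([0.0, 0.0, 0.0]), "OMIM")
        assert np.allclose(curve[["or_median", "or_lo", "or_hi"]], 1.0)

    def test_single_draw_matches_closed_form(self):
        gammas = np.array([0.5, 0.8, -0.3])
        curve = odds_ratio_curve(self.degenerate_fit(gammas.tolist()), "OMIM")
        z = (curve["similarity"].to_numpy() - 0.3) / 0.2
        expected = np.exp(gammas[0] + gammas[1] * z + gammas[2] * z**2)
        np.testing.assert_allclose(curve["or_median"], expected, rtol=1e-12)

    def test_band_contains_median(self):
        fit = TestWaic().simulated_fit()
        # give it a fake evidence block so the curve machinery runs
        fit.design.evidence["GWAS"] = EvidenceBlock(
            exists=np.ones(1), z=np.zeros(1), mean=0.5, sd=0.25)
        fit.param_names = ["alpha", "gamma_GWAS[0]"]
        curve = odds_ratio_curve(fit, "GWAS")
        assert (curve["or_lo"] <= curve["or_median"]).all()
        assert (curve["or_median"] <= curve["or_hi"]).all()

    def test_grid_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            odds_ratio_curve(self.degenerate_fit([0.0]), "OMIM",
                             grid=np.array([-0.1, 0.5]))
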