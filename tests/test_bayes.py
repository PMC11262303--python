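"""Outlier screening, log-posterior gradient, sampling and diagnostics."""
import numpy as np
import pandas as pd
import pytest

from aecnet.bayes_model import (
    Diagnostics,
    HierarchicalLogNormal,
    ModelSpec,
    PosteriorDraws,
    _Posterior,
    diagnostics,
    prior_predictive,
    predictive_interval_coverage,
    remove_outliers,
    total_post_warmup_draws,
)
from aecnet.simulate import DEFAULT_CONDITIONS, GenerativeParams, simulate_measure_table


def cell_table(values, condition="Pre"):
    return pd.DataFrame(
        {
            "subject": [f"s{i}" for i in range(len(values))],
            "condition": condition,
            "band": "alpha",
            "measure": "T",
            "value": values,
        }
    )


# -- brute-force quartile oracle --------------------------------------------


def quartiles_oracle(values, rule):
    """Hand-rolled Q1/Q3 under the declared interpolation rule."""
    x = np.sort(np.asarray(values, float))
    n = x.size

    def q(p):
        h = p * (n - 1)
        lo, hi = int(np.floor(h)), int(np.ceil(h))
        if rule == "midpoint":
            return x[lo] if lo == hi else 0.5 * (x[lo] + x[hi])
        return x[lo] + (h - lo) * (x[hi] - x[lo])  # linear

    return q(0.25), q(0.75)


def boxplot_keep_oracle(values, rule):
    q1, q3 = quartiles_oracle(values, rule)
    iqr = q3 - q1
    return [(v >= q1 - 1.5 * iqr) and (v <= q3 + 1.5 * iqr) for v in values]


class TestOutlierScreening:
    @pytest.mark.parametrize("rule", ["midpoint", "linear"])
    def test_matches_bruteforce_oracle(self, rng, rule):
        for _ in range(20):
            vals = np.round(rng.lognormal(0, 1, size=rng.integers(4, 30)), 6)
            kept, removed = remove_outliers(cell_table(vals), interpolation=rule)
            expect = boxplot_keep_oracle(vals, rule)
            assert list(kept["value"]) == [v for v, k in zip(vals, expect) if k]
            assert len(removed) == expect.count(False)

    @pytest.mark.parametrize("rule,expect_removed", [("midpoint", 0), ("linear", 1)])
    def test_small_skewed_cell(self, rule, expect_removed):
        """{1,2,3,100}: the midpoint fences keep 100, the linear fences drop it.

        Frozen from the brute-force oracle: midpoint Q1=1.5, Q3=51.5 gives an
        upper fence of 126.5 (100 kept); linear Q1=1.75, Q3=27.25 gives 65.5.
        """
        vals = [1.0, 2.0, 3.0, 100.0]
        assert boxplot_keep_oracle(vals, rule).count(False) == expect_removed
        _, removed = remove_outliers(cell_table(vals), interpolation=rule)
        assert len(removed) == expect_removed

    def test_zero_iqr_removes_nothing(self):
        kept, removed = remove_outliers(cell_table([5.0, 5.0, 5.0, 5.0]))
        assert len(kept) == 4 and len(removed) == 0

    def test_symmetric_sample_identity(self):
        vals = [1.0, 2.0, 3.0, 4.0, 5.0]
        kept, removed = remove_outliers(cell_table(vals))
        assert len(removed) == 0

    def test_small_cell_passes_with_warning(self):
        with pytest.warns(UserWarning, match="unscreened"):
            kept, removed = remove_outliers(cell_table([1.0, 2.0, 1000.0]))
        assert len(kept) == 3

    def test_cells_screened_independently(self):
        t1 = cell_table([1.0, 1.1, 0.9, 1.05], condition="Pre")
        t2 = cell_table([10.0, 11.0, 9.0, 10.5], condition="Stim01")
        kept, removed = remove_outliers(pd.concat([t1, t2], ignore_index=True))
        # pooled screening would flag one condition wholesale; per-cell keeps all
        assert len(removed) == 0


class TestChainArithmetic:
    def test_publication_scale_draw_count(self):
        assert total_post_warmup_draws(4, 14_000, 4_000) == 40_000

    def test_warmup_bound(self):
        with pytest.raises(ValueError):
            total_post_warmup_draws(4, 1000, 1000)


class TestGradient:
    @pytest.mark.parametrize(
        "shared,likelihood",
        [(True, "lognormal"), (False, "lognormal"), (True, "student_t")],
    )
    def test_analytic_gradient_matches_finite_differences(self, shared, likelihood):
        gp = GenerativeParams(
            alpha_bar=np.log(0.3), beta_bar={c: 0.1 for c in DEFAULT_CONDITIONS[1:]},
            n_subjects=8,
        )
        table = simulate_measure_table(gp, DEFAULT_CONDITIONS, seed=0)
        subjects = sorted(table["subject"].unique())
        others = list(DEFAULT_CONDITIONS[1:])
        subj = table["subject"].map({s: i for i, s in enumerate(subjects)}).to_numpy()
        cond = table["condition"].map(
            {"Pre": -1, **{c: j for j, c in enumerate(others)}}
        ).to_numpy()
        post = _Posterior(
            np.log(table["value"].to_numpy()), subj, cond,
            len(subjects), len(others),
            ModelSpec(likelihood=likelihood), mu_k=-1.2, shared_slope=shared,
        )
        rng = np.random.default_rng(3)
        theta = post.initial_point() + 0.3 * rng.standard_normal(post.dim)
        _, grad = post(theta)
        h = 1e-6
        for i in rng.choice(post.dim, size=15, replace=False):
            tp, tm = theta.copy(), theta.copy()
            tp[i] += h
            tm[i] -= h
            fd = (post(tp)[0] - post(tm)[0]) / (2 * h)
            assert grad[i] == pytest.approx(fd, rel=1e-4, abs=1e-6)


@pytest.fixture(scope="module")
def fitted():
    gp = GenerativeParams(
        alpha_bar=np.log(0.3), beta_bar={c: 0.1 for c in DEFAULT_CONDITIONS[1:]},
        sigma_alpha=0.05, sigma_beta=0.05, sigma=0.05, n_subjects=30,
    )
    table = simulate_measure_table(gp, DEFAULT_CONDITIONS, seed=21)
    model = HierarchicalLogNormal(iterations=700, warmup=400, seed=13).fit(table)
    return model, table


class TestFit:

    def test_slopes_recovered(self, fitted):
        model, _ = fitted
        med = np.median(model.draws_.flat("beta_bar"), axis=0)
        np.testing.assert_allclose(med, 0.1, atol=0.06)

    def test_convergence_diagnostics(self, fitted):
        model, _ = fitted
        assert model.diagnostics_.max_rhat < 1.1
        assert model.diagnostics_.min_ess > 100

    def test_positive_scales_in_every_draw(self, fitted):
        model, _ = fitted
        for name in ("sigma_alpha", "sigma_beta", "sigma"):
            assert (model.draws_.flat(name) > 0).all()
        assert (np.abs(model.draws_.flat("rho")) < 1).all()

    def test_same_seed_reproduces_summaries(self, fitted):
        model, table = fitted
        again = HierarchicalLogNormal(iterations=700, warmup=400, seed=13).fit(table)
        np.testing.assert_allclose(
            np.median(model.draws_.flat("beta_bar"), axis=0),
            np.median(again.draws_.flat("beta_bar"), axis=0),
            atol=1e-12,
        )

    def test_posterior_predictive_covers_observed(self, fitted):
        model, table = fitted
        sims = model.sample_posterior_predictive(n_datasets=100, seed=0)
        assert predictive_interval_coverage(sims, table, mass=0.9) >= 0.8

    def test_nonpositive_values_rejected(self, null_table):
        bad = null_table.copy()
        bad.loc[0, "value"] = 0.0
        with pytest.raises(ValueError, match="non-positive"):
            HierarchicalLogNormal(iterations=200, warmup=100).fit(bad)

    def test_mixed_measures_rejected(self, null_table):
        bad = null_table.copy()
        bad.loc[0, "measure"] = "E"
        with pytest.raises(ValueError, match="per measure"):
            HierarchicalLogNormal().fit(bad)


class TestPriorPredictive:
    def test_values_positive_and_near_center(self):
        spec = ModelSpec()
        sims = prior_predictive(spec, mu_k=np.log(0.3), conditions=DEFAULT_CONDITIONS,
                                n_subjects=10, n_draws=50, seed=0)
        values = np.concatenate([s["value"].to_numpy() for s in sims])
        assert (values > 0).all()
        # an order of magnitude around 0.3 given 0.2-scale log priors
        assert np.median(values) == pytest.approx(0.3, rel=0.5)
        assert ((values > 0.03) & (values < 3.0)).mean() > 0.95

    def test_noninformative_variant_much_wider(self):
        tight = prior_predictive(ModelSpec(), mu_k=0.0, conditions=("pre", "s"),
                                 n_subjects=20, n_draws=100, seed=1)
        wide = prior_predictive(ModelSpec().noninformative(), mu_k=0.0,
                                conditions=("pre", "s"), n_subjects=20,
                                n_draws=100, seed=1)
        var_tight = np.var(np.log(np.concatenate([s["value"] for s in tight])))
        var_wide = np.var(np.log(np.concatenate([s["value"] for s in wide])))
        assert var_wide / var_tight > 10

    def test_zero_scale_testing_hook(self):
        spec = ModelSpec(
            prior_alpha_scale=0.0, prior_beta_scale=0.0,
            prior_sigma_alpha=0.0, prior_sigma_beta=0.0, prior_sigma=0.0,
        )
        sims = prior_predictive(spec, mu_k=np.log(0.3), conditions=("pre", "s"),
                                n_subjects=5, n_draws=3, seed=0)
        for s in sims:
            np.testing.assert_allclose(s["value"], 0.3, rtol=1e-12)


class TestDiagnostics:
    def _draws(self, arrays):
        return PosteriorDraws(
            params={"x": np.asarray(arrays)}, conditions=[], reference="Pre",
            subjects=[],
        )

    def test_converged_chains(self, rng):
        d = diagnostics(self._draws(rng.standard_normal((4, 1000))))
        assert 0.99 <= float(d.rhat["x"]) <= 1.02

    def test_split_chains_detected(self, rng):
        chains = rng.standard_normal((2, 1000))
        chains[1] += 10.0
        d = diagnostics(self._draws(chains))
        assert float(d.rhat["x"]) > 1.5

    def test_white_noise_ess_near_total(self, rng):
        d = diagnostics(self._draws(rng.standard_normal((4, 2500))))
        assert float(d.ess["x"]) == pytest.approx(10_000, rel=0.1)

    def test_single_chain_rejected(self, rng):
        with pytest.raises(ValueError, match="single chain"):
            diagnostics(self._draws(rng.standard_normal((1, 1000))))
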