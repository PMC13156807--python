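"""Variance-component estimation: EMS closed forms and the Gibbs path."""

import numpy as np
import pandas as pd
import pytest

import gtrel
from gtrel import MCMCConfig
from gtrel.exceptions import BalanceError, DesignError, FamilyError


class TestEstimateEMS:
    def test_toy_exact(self, toy_table, one_facet_design):
        fit = gtrel.estimate_ems(toy_table, one_facet_design)
        assert fit.components["p"] == pytest.approx(4.0, abs=1e-12)
        assert fit.components["i"] == pytest.approx(0.5, abs=1e-12)
        assert fit.components["pi,e"] == pytest.approx(0.0, abs=1e-12)
        assert fit.grand_mean == pytest.approx(3.5, abs=1e-12)

    def test_constant_scores_give_zero_components(self, toy_df,
                                                  one_facet_design):
        toy_df["score"] = 7.0
        fit = gtrel.estimate_ems(gtrel.ObservationTable(toy_df),
                                 one_facet_design)
        assert all(v == 0.0 for v in fit.components.values())

    def test_negative_component_truncated_and_flagged(self,
                                                      one_facet_design):
        # person means identical but trials disagree within persons:
        # MS_person = 0 < MS_interaction, so the raw person component
        # is negative
        df = pd.DataFrame({
            "person": ["A", "A", "B", "B"],
            "trial": [1, 2, 1, 2],
            "score": [0.0, 1.0, 1.0, 0.0],
        })
        fit = gtrel.estimate_ems(gtrel.ObservationTable(df),
                                 one_facet_design)
        assert fit.raw_components["p"] < 0
        assert fit.components["p"] == 0.0
        assert fit.truncation_flags["p"]

    def test_unbalanced_raises_balance_error(self, toy_df,
                                             one_facet_design):
        unbalanced = toy_df.iloc[:-1]
        with pytest.raises(BalanceError, match="estimate_bayes"):
            gtrel.estimate_ems(gtrel.ObservationTable(unbalanced),
                               one_facet_design)

    def test_non_gaussian_family_rejected(self, toy_table):
        design = gtrel.DesignSpec(facets=[gtrel.Facet("trial")],
                                  family="lognormal")
        with pytest.raises(FamilyError):
            gtrel.estimate_ems(toy_table, design)

    def test_two_facet_recovery_over_replicates(self, two_facet_design):
        truth = {"p": 2.0, "i": 0.4, "o": 0.3, "pi": 1.0, "po": 0.5,
                 "oi": 0.1, "pio,e": 2.0}
        sums = {k: 0.0 for k in truth}
        n_rep = 20
        for rep in range(n_rep):
            spec = gtrel.SimulationSpec(
                n_persons=80, n_trials=16, n_occasions=4,
                components=truth, mu=1.0, seed=1000 + rep)
            table, _ = gtrel.simulate(spec)
            fit = gtrel.estimate_ems(table, two_facet_design)
            for k in truth:
                sums[k] += fit.raw_components[k]
        for k, v in truth.items():
            assert sums[k] / n_rep == pytest.approx(v, rel=0.25, abs=0.06)

    def test_splits_recovery_over_replicates(self, splits_design):
        truth = {"p": 1.0, "s": 0.2, "i:s": 0.3, "ps": 0.4,
                 "p(i:s),e": 2.0}
        sums = {k: 0.0 for k in truth}
        n_rep = 20
        for rep in range(n_rep):
            spec = gtrel.SimulationSpec(
                n_persons=60, n_trials=40, trials_per_split=5,
                components=truth, mu=0.0, seed=2000 + rep)
            table, _ = gtrel.simulate(spec)
            fit = gtrel.estimate_ems(table, splits_design)
            for k in truth:
                sums[k] += fit.raw_components[k]
        # the split main effect has only 8 levels, so its estimate is
        # noisy even averaged over replicates — hence the wider band
        for k, v in truth.items():
            assert sums[k] / n_rep == pytest.approx(v, rel=0.25, abs=0.12)


class TestEstimateBayes:
    @staticmethod
    @pytest.fixture(scope="class")
    def small_fit():
        spec = gtrel.SimulationSpec(
            n_persons=50, n_trials=20,
            components={"p": 1.0, "i": 0.3, "pi,e": 2.0}, mu=5.0, seed=42)
        table, _ = gtrel.simulate(spec)
        design = gtrel.DesignSpec(facets=[gtrel.Facet("trial")])
        return gtrel.estimate_bayes(
            table, design, seed=7,
            mcmc=MCMCConfig(chains=2, draws=500, warmup=400))

    def test_every_draw_strictly_positive(self, small_fit):
        assert min(v.min() for v in small_fit.draws.values()) > 0

    def test_point_estimate_is_posterior_median(self, small_fit):
        for k, d in small_fit.draws.items():
            assert small_fit.components[k] == pytest.approx(
                float(np.median(d)))

    def test_convergence_diagnostics_reported(self, small_fit):
        assert small_fit.diagnostics["rhat_max"] < 1.01
        assert small_fit.scale == "identity"

    def test_unbalanced_data_accepted(self):
        spec = gtrel.SimulationSpec(
            n_persons=40, n_trials=30,
            components={"p": 1.0, "i": 0.2, "pi,e": 2.0},
            retention=0.7, seed=10)
        table, _ = gtrel.simulate(spec)
        counts = table.data.groupby("person").size()
        assert counts.nunique() > 1  # genuinely unbalanced
        design = gtrel.DesignSpec(facets=[gtrel.Facet("trial")])
        fit = gtrel.estimate_bayes(
            table, design, seed=3,
            mcmc=MCMCConfig(chains=2, draws=500, warmup=400))
        assert fit.components["p"] > 0

    def test_lognormal_family_models_log_scale(self):
        truth = {"p": 0.3, "i": 0.05, "pi,e": 0.5}
        spec = gtrel.SimulationSpec(
            n_persons=80, n_trials=30, components=truth, mu=50.0,
            family="lognormal", seed=12)
        table, _ = gtrel.simulate(spec)
        assert (table.data["score"] > 0).all()
        design = gtrel.DesignSpec(facets=[gtrel.Facet("trial")],
                                  family="lognormal")
        fit = gtrel.estimate_bayes(
            table, design, seed=4,
            mcmc=MCMCConfig(chains=2, draws=500, warmup=400))
        assert fit.scale == "log"
        assert fit.components["pi,e"] == pytest.approx(truth["pi,e"],
                                                       rel=0.25)

    def test_lognormal_rejects_nonpositive_scores(self, toy_df):
        toy_df.loc[0, "score"] = -1.0
        design = gtrel.DesignSpec(facets=[gtrel.Facet("trial")],
                                  family="lognormal")
        with pytest.raises(FamilyError):
            gtrel.estimate_bayes(gtrel.ObservationTable(toy_df), design,
                                 seed=1)

    def test_gamma_chisq_family_models_sqrt_scale(self):
        truth = {"p": 0.5, "i": 0.1, "pi,e": 1.0}
        spec = gtrel.SimulationSpec(
            n_persons=80, n_trials=30, components=truth, mu=25.0,
            family="gamma_chisq", seed=13)
        table, _ = gtrel.simulate(spec)
        assert (table.data["score"] >= 0).all()
        design = gtrel.DesignSpec(facets=[gtrel.Facet("trial")],
                                  family="gamma_chisq")
        fit = gtrel.estimate_bayes(
            table, design, seed=5,
            mcmc=MCMCConfig(chains=2, draws=500, warmup=400))
        assert fit.scale == "sqrt"
        assert fit.components["pi,e"] == pytest.approx(truth["pi,e"],
                                                       rel=0.3)


class TestComponentsByFixedLevel:
    def test_per_level_person_variance_ordering(self):
        spec = gtrel.SimulationSpec(
            n_persons=120, n_trials=40,
            components={"p": 1.0, "i": 0.2, "pi,e": 2.0},
            fixed_facet="task",
            fixed_levels={
                "t1": {"components": {"p": 1.0}},
                "t2": {"components": {"p": 2.0}},
                "t3": {"components": {"p": 4.0}},
            },
            seed=30)
        table, _ = gtrel.simulate(spec)
        design = gtrel.DesignSpec(facets=[gtrel.Facet("trial"),
                                          gtrel.Facet("task", "fixed")])
        fit = gtrel.estimate_ems(table, design)
        per = gtrel.components_by_fixed_level(fit, "task")
        ps = [per[t].components["p"] for t in ("t1", "t2", "t3")]
        assert ps[0] < ps[1] < ps[2]

    def test_hidden_facet_returns_single_entry(self, toy_df,
                                               one_facet_design):
        toy_df["task"] = "flanker"
        table = gtrel.ObservationTable(toy_df)
        design = gtrel.DesignSpec(facets=[gtrel.Facet("trial")],
                                  declared_hidden=["task"])
        fit = gtrel.estimate_ems(table, design)
        per = gtrel.components_by_fixed_level(fit, "task")
        assert list(per) == ["flanker"]
        assert per["flanker"] is fit

    def test_unknown_facet_raises(self, toy_table, one_facet_design):
        fit = gtrel.estimate_ems(toy_table, one_facet_design)
        with pytest.raises(DesignError):
            gtrel.components_by_fixed_level(fit, "task")


class TestEstimateCovariances:
    @staticmethod
    def _pair_table(seed=31, cov_p=0.5, cov_e=0.8, concurrent=True):
        spec = gtrel.SimulationSpec(
            n_persons=200, n_trials=40,
            components={"p": 1.0, "i": 0.2, "pi,e": 2.0},
            covariances={"p": cov_p, "pi,e": cov_e},
            concurrent=concurrent, seed=seed)
        return gtrel.simulate(spec)[0]

    def test_identity_copy_recovers_variances(self, one_facet_design):
        table = self._pair_table()
        x_only = table.data[table.data["measure"] == "X"]
        y_copy = x_only.copy()
        y_copy["measure"] = "Y"
        doubled = gtrel.ObservationTable(
            pd.concat([x_only, y_copy], ignore_index=True))
        cov = gtrel.estimate_covariances(doubled, one_facet_design,
                                         concurrent=True)
        fit = gtrel.estimate_ems(
            gtrel.ObservationTable(x_only.drop(columns="measure")),
            one_facet_design)
        assert cov.covariances["p"] == pytest.approx(
            fit.components["p"], rel=1e-9)
        assert cov.covariances["pi,e"] == pytest.approx(
            fit.components["pi,e"], rel=1e-9)

    def test_concurrent_recovery(self, one_facet_design):
        cov = gtrel.estimate_covariances(
            self._pair_table(), one_facet_design, concurrent=True)
        assert cov.covariances["p"] == pytest.approx(0.5, abs=0.15)
        assert cov.covariances["pi,e"] == pytest.approx(0.8, abs=0.1)

    def test_independent_measures_near_zero(self, one_facet_design):
        table = self._pair_table(seed=77, cov_p=0.0, cov_e=0.0)
        cov = gtrel.estimate_covariances(table, one_facet_design,
                                         concurrent=True)
        assert cov.covariances["p"] == pytest.approx(0.0, abs=0.15)
        assert cov.covariances["pi,e"] == pytest.approx(0.0, abs=0.1)

    def test_non_concurrent_error_covariance_exactly_zero(
            self, one_facet_design):
        table = self._pair_table(concurrent=False, cov_e=0.0)
        cov = gtrel.estimate_covariances(table, one_facet_design,
                                         concurrent=False)
        assert cov.covariances["pi,e"] == 0.0

    def test_three_measures_rejected(self, one_facet_design):
        table = self._pair_table()
        extra = table.data[table.data["measure"] == "X"].copy()
        extra["measure"] = "Z"
        tripled = gtrel.ObservationTable(
            pd.concat([table.data, extra], ignore_index=True))
        with pytest.raises(DesignError):
            gtrel.estimate_covariances(tripled, one_facet_design,
                                       concurrent=True)

    def test_bayes_estimator_concurrent(self, one_facet_design):
        table = self._pair_table(seed=55)
        cov = gtrel.estimate_covariances(
            table, one_facet_design, concurrent=True, estimator="bayes",
            seed=9, mcmc=MCMCConfig(chains=2, draws=500, warmup=400))
        assert cov.covariances["p"] == pytest.approx(0.5, abs=0.2)
        assert cov.covariances["pi,e"] == pytest.approx(0.8, abs=0.1)
        assert cov.draws is not None
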