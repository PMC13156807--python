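"""Coefficient engine: error variances, coefficients, projections,
contrasts, and the structural properties every coefficient must obey."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import gtrel
from gtrel.exceptions import DesignError, UndefinedCoefficientError
from tests.conftest import make_vcs

var = st.floats(min_value=0.0, max_value=10.0)
posvar = st.floats(min_value=1e-3, max_value=10.0)
nprime = st.integers(min_value=1, max_value=500)


class TestErrorVariances:
    def test_one_facet_fixture(self):
        vc = make_vcs({"p": 1.0, "i": 0.5, "pi,e": 1.0})
        rel, abso = gtrel.error_variances(
            vc, gtrel.DStudyScenario(n_trials=4))
        assert rel == pytest.approx(0.25, abs=1e-12)
        assert abso == pytest.approx(0.375, abs=1e-12)

    def test_splits_fixture(self, splits_vcs):
        rel, abso = gtrel.error_variances(
            splits_vcs,
            gtrel.DStudyScenario(n_splits=4, n_trials_per_split=5))
        assert rel == pytest.approx(0.1, abs=1e-12)
        assert abso == pytest.approx(0.14, abs=1e-12)

    def test_absolute_equals_relative_without_facet_means(self):
        vc = make_vcs({"p": 3.0, "i": 0.0, "pi,e": 2.0})
        rel, abso = gtrel.error_variances(
            vc, gtrel.DStudyScenario(n_trials=7))
        assert abso == rel

    def test_missing_component_named(self):
        vc = make_vcs({"p": 1.0, "pi,e": 1.0})
        with pytest.raises(Exception, match="'i'"):
            gtrel.error_variances(vc, gtrel.DStudyScenario(n_trials=2))


class TestCoefficient:
    def test_toy_g_and_d(self, toy_table, one_facet_design):
        fit = gtrel.estimate_ems(toy_table, one_facet_design)
        sc = gtrel.DStudyScenario(n_trials=2, coefficient="G")
        assert gtrel.coefficient(fit, sc).value == pytest.approx(
            1.0, abs=1e-12)
        d = gtrel.coefficient(fit, sc.replace(coefficient="D"))
        assert d.value == pytest.approx(4 / 4.25, abs=1e-12)
        assert d.sem_abs == pytest.approx(
            math.sqrt(d.absolute_error_variance), abs=1e-12)

    @pytest.mark.parametrize("kind,expected", [
        ("CES_G", 2 / 2.45),
        ("CES_D", 2 / 2.645),
        ("CE_G", 2.25 / 2.45),
        ("CS_G", 2.1 / 2.45),
    ])
    def test_two_facet_fixture(self, two_facet_vcs, kind, expected):
        sc = gtrel.DStudyScenario(n_trials=10, n_occasions=2,
                                  coefficient=kind)
        est = gtrel.coefficient(two_facet_vcs, sc)
        assert est.value == pytest.approx(expected, abs=1e-12)

    def test_ce_requires_two_facet(self):
        vc = make_vcs({"p": 1.0, "i": 0.5, "pi,e": 1.0})
        with pytest.raises(DesignError):
            gtrel.coefficient(
                vc, gtrel.DStudyScenario(n_trials=2, coefficient="CE_G"))

    def test_zero_person_variance_gives_zero(self):
        vc = make_vcs({"p": 0.0, "i": 0.5, "pi,e": 1.0})
        for kind in ("G", "D", "ICC_rel", "ICC_abs"):
            est = gtrel.coefficient(
                vc, gtrel.DStudyScenario(n_trials=3, coefficient=kind))
            assert est.value == 0.0

    def test_all_zero_components_undefined(self):
        vc = make_vcs({"p": 0.0, "i": 0.0, "pi,e": 0.0})
        with pytest.raises(UndefinedCoefficientError):
            gtrel.coefficient(vc, gtrel.DStudyScenario(n_trials=3))

    def test_icc_rel_equals_g_at_one_trial(self):
        vc = make_vcs({"p": 2.0, "i": 0.5, "pi,e": 3.0})
        g1 = gtrel.coefficient(
            vc, gtrel.DStudyScenario(n_trials=1, coefficient="G")).value
        icc = gtrel.coefficient(
            vc, gtrel.DStudyScenario(n_trials=50,
                                     coefficient="ICC_rel")).value
        assert icc == pytest.approx(g1, abs=1e-12)

    def test_value_is_median_of_per_draw_values(self):
        rng = np.random.default_rng(0)
        draws = {
            "p": np.exp(rng.normal(0.0, 0.8, 400)),
            "i": np.exp(rng.normal(-1.5, 0.5, 400)),
            "pi,e": np.exp(rng.normal(0.5, 0.6, 400)),
        }
        vc = gtrel.VarianceComponentSet(
            components={k: float(np.median(v)) for k, v in draws.items()},
            grand_mean=0.0, estimator="bayes", layout="one_facet",
            draws=draws)
        sc = gtrel.DStudyScenario(n_trials=5, coefficient="G")
        est = gtrel.coefficient(vc, sc)
        per_draw = draws["p"] / (draws["p"] + draws["pi,e"] / 5)
        assert est.value == pytest.approx(float(np.median(per_draw)))
        assert est.interval[0] < est.value < est.interval[1]


class TestCutScore:
    def test_at_grand_mean_equals_dependability(self, two_facet_vcs):
        sc = gtrel.DStudyScenario(n_trials=10, n_occasions=2,
                                  cut_score=two_facet_vcs.grand_mean)
        cut = gtrel.cut_score_coefficient(two_facet_vcs, sc)
        d = gtrel.coefficient(
            two_facet_vcs, sc.replace(coefficient="CES_D"))
        assert cut.value == pytest.approx(d.value, abs=1e-12)

    def test_one_facet_fixture(self):
        vc = make_vcs({"p": 1.0, "i": 0.5, "pi,e": 1.0}, grand_mean=2.0)
        sc = gtrel.DStudyScenario(n_trials=4, cut_score=0.0)  # (mu-C)^2=4
        est = gtrel.cut_score_coefficient(vc, sc)
        assert est.value == pytest.approx(5 / 5.375, abs=1e-12)

    def test_monotone_in_cut_distance_with_limit_one(self):
        vc = make_vcs({"p": 1.0, "i": 0.5, "pi,e": 1.0}, grand_mean=0.0)
        values = [
            gtrel.cut_score_coefficient(
                vc, gtrel.DStudyScenario(n_trials=4, cut_score=c)).value
            for c in (0.0, 1.0, 5.0, 50.0, 5000.0)
        ]
        assert all(a <= b for a, b in zip(values, values[1:]))
        assert values[-1] == pytest.approx(1.0, abs=1e-4)


class TestProject:
    def test_exact_minimal_n(self):
        vc = make_vcs({"p": 1.0, "i": 0.0, "pi,e": 1.0})
        proj = gtrel.project(vc, None, "G", range(1, 21), 0.8)
        assert proj.minimal_n == 4
        assert proj.table["value"].iloc[3] == pytest.approx(0.8, abs=1e-12)

    def test_unreachable_target_reports_asymptote(self, two_facet_vcs):
        sc = gtrel.DStudyScenario(n_occasions=1)
        proj = gtrel.project(two_facet_vcs, None, "CES_G",
                             range(1, 200), 0.95, scenario=sc)
        # person x occasion error does not vanish with more trials
        assert not proj.reachable
        asym = 2.0 / (2.0 + 0.5)  # p / (p + po/n_o)
        assert proj.asymptote == pytest.approx(asym, abs=1e-12)

    def test_grid_values_monotone(self, two_facet_vcs):
        sc = gtrel.DStudyScenario(n_occasions=2)
        proj = gtrel.project(two_facet_vcs, None, "CES_D",
                             range(1, 101), 0.9, scenario=sc)
        vals = proj.table["value"].to_numpy()
        assert (np.diff(vals) >= -1e-15).all()

    def test_bad_target_rejected(self):
        vc = make_vcs({"p": 1.0, "i": 0.0, "pi,e": 1.0})
        with pytest.raises(ValueError):
            gtrel.project(vc, None, "G", [1, 2], 1.5)


class TestProperties:
    @given(p=posvar, i=var, pie=posvar, n1=nprime, n2=nprime)
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_trials_and_d_le_g(self, p, i, pie, n1, n2):
        vc = make_vcs({"p": p, "i": i, "pi,e": pie})
        lo, hi = min(n1, n2), max(n1, n2)
        for kind in ("G", "D"):
            a = gtrel.coefficient(
                vc, gtrel.DStudyScenario(n_trials=lo,
                                         coefficient=kind)).value
            b = gtrel.coefficient(
                vc, gtrel.DStudyScenario(n_trials=hi,
                                         coefficient=kind)).value
            assert a <= b + 1e-12
        g = gtrel.coefficient(
            vc, gtrel.DStudyScenario(n_trials=lo, coefficient="G")).value
        d = gtrel.coefficient(
            vc, gtrel.DStudyScenario(n_trials=lo, coefficient="D")).value
        assert d <= g + 1e-12

    @given(p=posvar, i=var, pie=posvar)
    @settings(max_examples=100, deadline=None)
    def test_limit_is_one_when_person_variance_positive(self, p, i, pie):
        vc = make_vcs({"p": p, "i": i, "pi,e": pie})
        for kind in ("G", "D"):
            est = gtrel.coefficient(
                vc, gtrel.DStudyScenario(n_trials=math.inf,
                                         coefficient=kind))
            assert est.value == pytest.approx(1.0, abs=1e-12)

    @given(p=posvar, ps=var, pise=posvar, n_s=st.integers(1, 20),
           k=st.integers(1, 20))
    @settings(max_examples=100, deadline=None)
    def test_split_design_matches_crossed_without_split_variance(
            self, p, ps, pise, n_s, k):
        # sigma2_s = sigma2_ps = 0 and k*n_s trials total: the split
        # blocking is then pure bookkeeping and G must match the
        # crossed design evaluated at n' = k * n_s
        split_vc = make_vcs(
            {"p": p, "s": 0.0, "i:s": 0.0, "ps": 0.0, "p(i:s),e": pise},
            layout="splits")
        crossed_vc = make_vcs({"p": p, "i": 0.0, "pi,e": pise})
        g_split = gtrel.coefficient(
            split_vc, gtrel.DStudyScenario(
                n_splits=n_s, n_trials_per_split=k,
                coefficient="G")).value
        g_crossed = gtrel.coefficient(
            crossed_vc, gtrel.DStudyScenario(n_trials=n_s * k,
                                             coefficient="G")).value
        assert g_split == pytest.approx(g_crossed, rel=1e-12)


class TestContrast:
    @staticmethod
    def _estimate(draw_values):
        return gtrel.ReliabilityEstimate(
            value=float(np.median(draw_values)),
            relative_error_variance=0.1, absolute_error_variance=0.2,
            sem_rel=0.1 ** 0.5, sem_abs=0.2 ** 0.5, kind="D",
            scenario=gtrel.DStudyScenario(n_trials=10),
            draws=np.asarray(draw_values),
        )

    def test_identical_draws_centered_at_zero(self):
        d = np.linspace(0.4, 0.6, 200)
        out = gtrel.contrast({"a": self._estimate(d),
                              "b": self._estimate(d.copy())})
        row = out.iloc[0]
        assert row["median_diff"] == 0.0
        assert row["p_gt_0"] == pytest.approx(0.5)

    def test_disjoint_draws_probability_one(self):
        out = gtrel.contrast({
            "hi": self._estimate(np.linspace(0.8, 0.9, 100)),
            "lo": self._estimate(np.linspace(0.1, 0.2, 100)),
        })
        row = out.iloc[0]
        assert row["p_gt_0"] == 1.0
        assert row["ci_low"] > 0

    def test_point_only_estimates_rejected(self):
        est = self._estimate(np.linspace(0.4, 0.6, 100))
        point = gtrel.ReliabilityEstimate(
            value=0.5, relative_error_variance=0.1,
            absolute_error_variance=0.2, sem_rel=0.1 ** 0.5,
            sem_abs=0.2 ** 0.5, kind="D",
            scenario=gtrel.DStudyScenario(n_trials=10))
        with pytest.raises(ValueError, match="draws"):
            gtrel.contrast({"a": est, "b": point})
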