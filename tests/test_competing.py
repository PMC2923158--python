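"""Survival submodel: risk sets, linked hazards, likelihood, CIF."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

from jointcr import (
    BaselineHazard,
    JointDataset,
    ModelSpec,
    RandomEffects,
    SurvivalParams,
    SurvivalRecord,
    at_risk,
    cumulative_incidence,
    cumulative_linked_hazard,
    hazard_ratio_summaries,
    survival_loglik,
)
from jointcr.competing import coherence_check


def _baseline(h1=0.5, h2=0.3, end=30.0):
    return BaselineHazard(
        cuts={1: np.array([0.0, end]), 2: np.array([0.0, end])},
        heights={1: np.array([h1]), 2: np.array([h2])},
    )


def _params(**kw):
    defaults = dict(
        beta={1: np.array([0.0]), 2: np.array([0.0])},
        gamma={1: 0.0, 2: 0.0},
        baseline=_baseline(),
        submodel_kind="subdistribution",
    )
    defaults.update(kw)
    return SurvivalParams(**defaults)


class TestAtRisk:
    def test_other_cause_failure_stays_at_risk_under_subdistribution(self):
        rec = SurvivalRecord(1, 3.0, 2)
        assert at_risk(rec, 5.0, cause=1, kind="subdistribution", horizon=28.0)

    def test_other_cause_failure_leaves_under_cause_specific(self):
        rec = SurvivalRecord(1, 3.0, 2)
        assert not at_risk(rec, 5.0, cause=1, kind="cause_specific", horizon=28.0)

    def test_own_cause_failure_removes_under_both_kinds(self):
        rec = SurvivalRecord(1, 3.0, 1)
        for kind in ("subdistribution", "cause_specific"):
            assert not at_risk(rec, 5.0, cause=1, kind=kind, horizon=28.0)

    def test_subdistribution_risk_set_is_superset_and_shrinks(self):
        rng = np.random.default_rng(0)
        recs = [
            SurvivalRecord(i, float(rng.uniform(0.5, 20)), int(rng.integers(0, 3)))
            for i in range(50)
        ]
        prev_sizes = {"subdistribution": 51, "cause_specific": 51}
        for t in np.linspace(0.5, 27.0, 15):
            sizes = {}
            for kind in prev_sizes:
                in_risk = [at_risk(r, t, 1, kind, 28.0) for r in recs]
                sizes[kind] = sum(in_risk)
            cs = [at_risk(r, t, 1, "cause_specific", 28.0) for r in recs]
            sd = [at_risk(r, t, 1, "subdistribution", 28.0) for r in recs]
            assert all(s or not c for c, s in zip(cs, sd))  # superset
            assert sizes["subdistribution"] <= prev_sizes["subdistribution"]
            assert sizes["cause_specific"] <= prev_sizes["cause_specific"]
            prev_sizes = sizes


class TestCumulativeLinkedHazard:
    def test_gamma_zero_reduces_to_proportional_hazards(self):
        p = _params(beta={1: np.array([0.7]), 2: np.array([0.0])})
        got = cumulative_linked_hazard(p, RandomEffects(0.4, 0.9), np.array([1.0]), 2.0, 5.0, 1)
        assert got == pytest.approx(0.5 * math.exp(0.7) * 3.0, rel=1e-12)

    def test_matches_adaptive_quadrature(self):
        baseline = BaselineHazard(
            cuts={1: np.array([0.0, 2.0, 7.0, 30.0]), 2: np.array([0.0, 30.0])},
            heights={1: np.array([0.4, 0.15, 0.05]), 2: np.array([0.2])},
        )
        p = _params(
            beta={1: np.array([0.3, -0.2]), 2: np.array([0.0, 0.0])},
            gamma={1: 0.8, 2: -0.5},
            baseline=baseline,
        )
        re = RandomEffects(0.6, -0.35)
        z = np.array([1.0, 0.5])

        def lam(s):
            j = np.searchsorted(baseline.cuts[1], s, side="right") - 1
            return baseline.heights[1][j] * math.exp(
                float(z @ p.beta[1]) + 0.8 * (re.U0 + re.U1 * s)
            )

        for a, b in [(0.0, 1.5), (1.0, 6.0), (0.5, 25.0)]:
            expected = quad(lam, a, b, limit=400, epsabs=1e-13, epsrel=1e-13)[0]
            got = cumulative_linked_hazard(p, re, z, a, b, 1)
            assert got == pytest.approx(expected, rel=1e-10)

    def test_tiny_slope_coefficient_matches_limit(self):
        p = _params(gamma={1: 1e-12, 2: 0.0})
        re = RandomEffects(0.0, 1.0)  # gamma*U1 = 1e-12
        got = cumulative_linked_hazard(p, re, np.array([0.0]), 1.0, 4.0, 1)
        assert got == pytest.approx(0.5 * 3.0, rel=1e-8)

    def test_rejects_reversed_interval(self):
        with pytest.raises(ValueError, match="a <= b"):
            cumulative_linked_hazard(
                _params(), RandomEffects(0, 0), np.array([0.0]), 5.0, 2.0, 1
            )


def _two_subject_dataset():
    obs = pd.DataFrame({"subject_id": [1, 2], "t": [0.0, 0.0], "y": [6.0, 7.0]})
    surv = pd.DataFrame({"subject_id": [1, 2], "time": [1.0, 2.0], "delta": [1, 0]})
    cov = pd.DataFrame({"subject_id": [1, 2], "treatment": [0.0, 0.0]})
    return JointDataset(obs, surv, cov, horizon=2.5)


class TestSurvivalLoglik:
    def test_pencil_and_paper_two_subjects_one_interval(self):
        ds = _two_subject_dataset()
        baseline = BaselineHazard(
            cuts={1: np.array([0.0, 2.6]), 2: np.array([0.0, 2.6])},
            heights={1: np.array([0.5]), 2: np.array([0.3])},
        )
        re = (np.zeros(2), np.zeros(2))
        # subdistribution: subject 1 (cause-1 event at 1) stays at risk for
        # cause 2 until the horizon 2.5
        p = _params(baseline=baseline)
        expected = (math.log(0.5) - 0.5 * 1 - 0.5 * 2) + (-0.3 * 2.5 - 0.3 * 2)
        assert survival_loglik(p, re, ds) == pytest.approx(expected, rel=1e-12)
        # cause-specific: subject 1's cause-2 exposure stops at its own time
        p_cs = _params(baseline=baseline, submodel_kind="cause_specific")
        expected_cs = (math.log(0.5) - 0.5 * 1 - 0.5 * 2) + (-0.3 * 1 - 0.3 * 2)
        assert survival_loglik(p_cs, re, ds) == pytest.approx(expected_cs, rel=1e-12)

    def test_cause_specific_factorizes_into_independent_likelihoods(self):
        from jointcr import SimulationDesign, simulate_dataset

        ds = simulate_dataset(SimulationDesign(n=20, seed=13))
        baseline = BaselineHazard(
            cuts={
                1: np.array([0.0, ds.horizon * 1.01]),
                2: np.array([0.0, ds.horizon * 1.01]),
            },
            heights={1: np.array([0.08]), 2: np.array([0.2])},
        )
        p = _params(baseline=baseline, submodel_kind="cause_specific")
        re = (np.zeros(20), np.zeros(20))
        total = survival_loglik(p, re, ds)
        # naive per-cause piecewise-exponential log-likelihood
        naive = 0.0
        for k, h in ((1, 0.08), (2, 0.2)):
            for _, row in ds.survival.iterrows():
                if row["delta"] == k:
                    naive += math.log(h)
                naive -= h * row["time"]
        assert total == pytest.approx(naive, rel=1e-10)

    def test_other_cause_failure_extends_only_subdistribution_likelihood(self):
        # flipping a censored subject to a cause-2 failure at the same time
        # changes the cause-1 subdistribution exposure but not the
        # cause-specific one
        def _ds(delta2):
            obs = pd.DataFrame({"subject_id": [1, 2], "t": [0.0, 0.0], "y": [6.0, 7.0]})
            surv = pd.DataFrame(
                {"subject_id": [1, 2], "time": [1.0, 2.0], "delta": [1, delta2]}
            )
            cov = pd.DataFrame({"subject_id": [1, 2], "treatment": [0.0, 0.0]})
            return JointDataset(obs, surv, cov, horizon=10.0)

        baseline = BaselineHazard(
            cuts={1: np.array([0.0, 10.1]), 2: np.array([0.0, 10.1])},
            heights={1: np.array([0.5]), 2: np.array([0.3])},
        )

        def cause1_part(ds, kind):
            from jointcr.competing import SurvivalEngine

            eng = SurvivalEngine(
                ds,
                ModelSpec(submodel_kind=kind),
                cuts=baseline.cuts,
            )
            return float(
                np.sum(
                    eng.loglik_terms(
                        1, np.zeros(1), 0.0, baseline.heights[1], np.zeros(2), np.zeros(2)
                    )
                )
            )

        sub_cens = cause1_part(_ds(0), "subdistribution")
        sub_fail = cause1_part(_ds(2), "subdistribution")
        cs_cens = cause1_part(_ds(0), "cause_specific")
        cs_fail = cause1_part(_ds(2), "cause_specific")
        assert sub_fail != pytest.approx(sub_cens)  # risk-set extension
        assert cs_fail == pytest.approx(cs_cens)  # unchanged after failure
        assert sub_fail - sub_cens == pytest.approx(-0.5 * 8.0, rel=1e-10)


class TestCumulativeIncidence:
    def test_zero_at_time_zero(self):
        assert cumulative_incidence(_params(), RandomEffects(0, 0), np.array([0.0]), 0.0, 1) == 0.0

    def test_monotone_over_random_configurations(self):
        rng = np.random.default_rng(7)
        grid = np.linspace(0.0, 25.0, 12)
        for _ in range(100):
            baseline = _baseline(
                h1=float(rng.uniform(0.01, 0.5)), h2=float(rng.uniform(0.01, 0.5))
            )
            p = _params(
                beta={1: rng.normal(size=1), 2: rng.normal(size=1)},
                gamma={1: float(rng.normal()), 2: float(rng.normal())},
                baseline=baseline,
            )
            re = RandomEffects(float(rng.normal()), float(rng.normal() * 0.3))
            z = np.array([float(rng.integers(0, 2))])
            vals = [cumulative_incidence(p, re, z, float(t), 1) for t in grid]
            # mathematically < 1; float saturation to 1.0 allowed
            assert all(0.0 <= v <= 1.0 for v in vals)
            assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_larger_covariate_effect_raises_incidence(self):
        z = np.array([1.0])
        re = RandomEffects(0.0, 0.0)
        lo = cumulative_incidence(_params(beta={1: np.array([0.3]), 2: np.array([0.0])}), re, z, 5.0, 1)
        hi = cumulative_incidence(_params(beta={1: np.array([0.6]), 2: np.array([0.0])}), re, z, 5.0, 1)
        assert hi > lo

    def test_unsupported_under_cause_specific(self):
        p = _params(submodel_kind="cause_specific")
        with pytest.raises(NotImplementedError):
            cumulative_incidence(p, RandomEffects(0, 0), np.array([0.0]), 1.0, 1)

    def test_coherence_monitor_returns_max_total(self):
        p = _params(baseline=_baseline(h1=0.01, h2=0.01))
        worst = coherence_check(p, RandomEffects(0, 0), np.array([0.0]), np.linspace(0, 10, 5))
        assert 0.0 <= worst <= 1.0


class TestHazardRatioSummaries:
    def test_null_draws_give_unit_hazard_ratio(self):
        table = hazard_ratio_summaries(np.zeros(500), names=["treatment"])
        assert table.loc["treatment"].tolist() == [1.0, 1.0, 1.0]

    def test_constant_log2_gives_two(self):
        table = hazard_ratio_summaries(np.full(100, math.log(2.0)))
        assert np.allclose(table.iloc[0], 2.0)

    def test_matches_direct_percentiles_on_fixture(self):
        rng = np.random.default_rng(3)
        draws = rng.normal(0.2, 0.3, size=(1000, 2))
        table = hazard_ratio_summaries(draws, names=["a", "b"])
        assert table.loc["a", "hr"] == pytest.approx(np.exp(draws[:, 0]).mean())
        assert table.loc["b", "lo2.5"] == pytest.approx(
            np.percentile(np.exp(draws[:, 1]), 2.5)
        )
        assert table.loc["b", "hi97.5"] == pytest.approx(
            np.percentile(np.exp(draws[:, 1]), 97.5)
        )
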