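"""GLM marginalization, interaction tetrad, and no-interaction conditions."""

import math

import numpy as np
import pytest

from tagbias import (
    CausalGLM,
    HaplotypeJoint,
    build_joint_dmx,
    get_link,
    haplotypes_from_ld,
    lemma_conditions,
    marker_eta_grid,
    stratum_marker_rrs,
)
from tagbias.exceptions import FeasibilityError

from conftest import random_feasible_joint

LINKS = ["identity", "log", "logit"]


def _model(link, beta0, beta_d, beta_x, beta_dx=0.0):
    return CausalGLM(
        link=get_link(link), beta0=beta0, beta_d=beta_d,
        beta_x=beta_x, beta_dx=beta_dx,
    )


def _safe_coeffs(link, rng):
    """Random causal coefficients keeping all four cell means in-domain."""
    if link == "identity":
        return (rng.uniform(0.1, 0.4), rng.uniform(-0.05, 0.05),
                rng.uniform(-0.05, 0.05))
    if link == "log":
        return (math.log(rng.uniform(0.001, 0.01)),
                math.log(rng.uniform(0.5, 2.0)),
                math.log(rng.uniform(0.5, 2.0)))
    return (rng.uniform(-4, 0), rng.uniform(-1, 1), rng.uniform(-1, 1))


class TestBuildJointDMX:
    def test_worked_example_conditional(self, table1_joint):
        jd = build_joint_dmx(table1_joint, theta=1.5,
                             convention="baseline_unexposed")
        assert jd.pr_d_given_mx(1, 1)[1] == pytest.approx(0.075 / 0.125, abs=1e-12)
        # unexposed stratum untouched
        assert jd.pr_d_given_mx(1, 0)[1] == pytest.approx(0.5, abs=1e-12)

    def test_unit_tilt_removes_ge_dependence(self, table1_joint):
        jd = build_joint_dmx(table1_joint, theta=1.0,
                             convention="baseline_unexposed")
        for m in (0, 1):
            np.testing.assert_allclose(
                jd.pr_d_given_mx(m, 0), jd.pr_d_given_mx(m, 1), atol=1e-14
            )

    def test_marginal_mixture_reproduces_input(self, table1_joint):
        jd = build_joint_dmx(table1_joint, theta=1.5, exposure_prev=0.3,
                             convention="marginal")
        mixture = jd.p.sum(axis=2)  # over x
        np.testing.assert_allclose(
            mixture, table1_joint.as_array(), atol=1e-12
        )
        assert jd.p[:, :, 1].sum() == pytest.approx(0.3, abs=1e-12)

    def test_marginal_infeasible_prevalence(self):
        j = haplotypes_from_ld(0.05, 0.1, "d_prime", 1.0, "+")
        with pytest.raises(FeasibilityError, match="kappa"):
            build_joint_dmx(j, theta=5.0, exposure_prev=0.9,
                            convention="marginal")


class TestEtaGrid:
    @pytest.mark.parametrize("link", LINKS)
    def test_null_causal_model_gives_null_interaction(self, link, table1_joint):
        beta0 = -2.0 if link != "log" else math.log(0.05)
        model = _model(link, beta0, 0.0, 0.3)
        jd = build_joint_dmx(table1_joint, theta=2.0,
                             convention="baseline_unexposed")
        assert marker_eta_grid(model, jd).beta_mx == pytest.approx(0.0, abs=1e-14)

    def test_marker_equals_causal_passes_through_interaction(self):
        j = HaplotypeJoint(h_DM=0.2, h_Dm=0.0, h_dM=0.0, h_dm=0.8)
        c = 0.37
        model = _model("logit", -2.0, 0.5, 0.3, beta_dx=c)
        jd = build_joint_dmx(j, theta=1.7, convention="baseline_unexposed")
        assert marker_eta_grid(model, jd).beta_mx == pytest.approx(c, abs=1e-12)

    def test_log_link_matches_risk_engine(self, table1_joint):
        """Cross-module oracle: log-link beta_MX equals the log of the
        risk-ratio interaction from the forward engine."""
        model = _model("log", math.log(0.01), math.log(2), 0.0)
        jd = build_joint_dmx(table1_joint, theta=1.5,
                             convention="baseline_unexposed")
        expected = math.log(
            stratum_marker_rrs(table1_joint, 2.0, 1.5).interaction_ratio
        )
        assert marker_eta_grid(model, jd).beta_mx == pytest.approx(
            expected, abs=1e-12
        )
        assert expected == pytest.approx(math.log(1.6 / 1.5), abs=1e-12)

    def test_identity_link_closure(self):
        """Identity marginalization is linear: the tetrad of mixed cell
        means equals beta_MX exactly."""
        rng = np.random.default_rng(11)
        for _ in range(25):
            j = random_feasible_joint(rng, min_mass=1e-3)
            model = _model("identity", *_safe_coeffs("identity", rng),
                           beta_dx=rng.uniform(-0.05, 0.05))
            jd = build_joint_dmx(j, theta=rng.uniform(0.5, 2.0),
                                 convention="baseline_unexposed")
            mu = np.empty((2, 2))
            for m in (0, 1):
                for x in (0, 1):
                    cond = jd.pr_d_given_mx(m, x)
                    mu[m, x] = sum(cond[d] * model.mean(d, x) for d in (0, 1))
            brute = mu[1, 1] - mu[0, 1] - mu[1, 0] + mu[0, 0]
            assert marker_eta_grid(model, jd).beta_mx == pytest.approx(
                brute, abs=1e-12
            )


class TestLemmaConditions:
    def test_unit_tilt_satisfies_condition_four(self, table1_joint):
        model = _model("log", math.log(0.01), math.log(2), 0.1)
        jd = build_joint_dmx(table1_joint, theta=1.0,
                             convention="baseline_unexposed")
        rep = lemma_conditions(model, jd)
        assert rep.cond4_d_indep_x_given_m
        assert rep.cond4_link_guaranteed
        assert abs(rep.beta_mx) < 1e-12

    def test_perfect_marker_satisfies_condition_two(self):
        j = HaplotypeJoint(h_DM=0.3, h_Dm=0.0, h_dM=0.0, h_dm=0.7)
        model = _model("logit", -2.0, 0.8, 0.2)
        jd = build_joint_dmx(j, theta=2.0, convention="baseline_unexposed")
        rep = lemma_conditions(model, jd)
        assert rep.cond2_marker_is_causal
        assert abs(rep.beta_mx) < 1e-12

    def test_worked_example_breaks_every_condition(self, table1_joint):
        model = _model("log", math.log(0.01), math.log(2), 0.0)
        jd = build_joint_dmx(table1_joint, theta=1.5,
                             convention="baseline_unexposed")
        rep = lemma_conditions(model, jd)
        assert not rep.any_guaranteed()
        assert abs(rep.beta_mx) > 0.01


def _condition_cases(rng, n_draws):
    """Yield (model, jdmx, guaranteed) across random configurations, each
    engineered to satisfy one sufficient no-interaction condition."""
    for _ in range(n_draws):
        link = rng.choice(LINKS)
        theta = rng.uniform(0.4, 2.5)
        beta0, beta_d, beta_x = _safe_coeffs(link, rng)

        # (1) no causal main effect
        j = random_feasible_joint(rng, min_mass=1e-3)
        jd = build_joint_dmx(j, theta, convention="baseline_unexposed")
        yield _model(link, beta0, 0.0, beta_x), jd, True

        # (2) marker identical to the causal variant
        p = rng.uniform(0.1, 0.9)
        j2 = HaplotypeJoint(h_DM=p, h_Dm=0.0, h_dM=0.0, h_dm=1 - p)
        jd2 = build_joint_dmx(j2, theta, convention="baseline_unexposed")
        yield _model(link, beta0, beta_d, beta_x), jd2, True

        # (3) D independent of M given X (linkage equilibrium; the tilt
        # preserves the product form within each stratum)
        p_D, p_M = rng.uniform(0.1, 0.9, size=2)
        j3 = haplotypes_from_ld(p_D, p_M, "d_prime", 0.0, "+")
        jd3 = build_joint_dmx(j3, theta, convention="baseline_unexposed")
        yield _model(link, beta0, beta_d, beta_x), jd3, True

        # (4) D independent of X given M: guaranteed for identity/log only
        j4 = random_feasible_joint(rng, min_mass=1e-3)
        jd4 = build_joint_dmx(j4, 1.0, convention="baseline_unexposed")
        yield (
            _model(link, beta0, beta_d, beta_x),
            jd4,
            link in ("identity", "log"),
        )


def test_lemma_theorem_over_randomized_draws():
    """Whenever a sufficient condition holds (with null causal interaction),
    the marker interaction vanishes to 1e-10; >=1000 randomized draws."""
    rng = np.random.default_rng(20140904)
    checked = 0
    for model, jd, guaranteed in _condition_cases(rng, 260):
        rep = lemma_conditions(model, jd, tol=1e-9)
        if guaranteed:
            assert rep.any_guaranteed()
            assert abs(rep.beta_mx) < 1e-10
        checked += 1
    assert checked >= 1000


def test_logit_rare_outcome_limit():
    """Under D-X independence given M, the logit-link interaction decays to
    zero as the outcome becomes rare."""
    rng = np.random.default_rng(3)
    j = random_feasible_joint(rng, min_mass=1e-3)
    jd = build_joint_dmx(j, theta=1.0, convention="baseline_unexposed")
    values = []
    for beta0 in (-5.0, -10.0, -15.0, -20.0):
        model = _model("logit", beta0, 0.7, 0.4)
        values.append(abs(marker_eta_grid(model, jd).beta_mx))
    assert all(a > b for a, b in zip(values, values[1:]))
    assert values[-1] < 1e-6
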