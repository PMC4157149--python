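"""Sample size and power for a marker-by-exposure interaction, case-control.

The test is a Wald test of the interaction coefficient in a prospective
logistic regression fitted to case-control data, with the marker coded as a
carrier indicator by default.  The expected per-subject Fisher information
for the interaction coefficient is computed from the exact 2 x 2 x 2
(marker x exposure x case status) cell probabilities implied by a causal
scenario (haplotype joint, per-allele disease risk ratio, exposure tilt) and
the design (case:control ratio, exposure prevalence, baseline disease
risk).  The required total sample size for a detectable multiplicative
interaction IR is then

    n = (z_{1-alpha/2} + z_{power})^2 / (log(IR)^2 * info_per_subject),

rounded up.  Tiny spurious interactions — the typical product of LD-induced
misclassification — translate into enormous required samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import norm

from .exceptions import ConfigError
from .haplotypes import HaplotypeJoint, diploid_expansion

__all__ = [
    "DesignSpec",
    "Scenario",
    "MarkerCellModel",
    "interaction_information",
    "sample_size_for_interaction",
    "analytic_power",
    "simulated_power",
]


@dataclass(frozen=True)
class DesignSpec:
    """Case-control design parameters.

    Attributes
    ----------
    alpha:
        Two-sided significance level.
    power:
        Target power.
    case_control_ratio:
        Controls per case (1 = balanced).
    exposure_prev:
        Population prevalence of the binary exposure.
    disease_prev:
        Marginal disease risk in the source population (sets the baseline
        of the risk model; the marker is carrier-coded for the 2x2x2 table
        and the >1e6 conclusions are insensitive to these choices).
    """

    alpha: float = 0.05
    power: float = 0.80
    case_control_ratio: float = 1.0
    exposure_prev: float = 0.5
    disease_prev: float = 0.01

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1) or not (0 < self.power < 1):
            raise ConfigError("alpha and power must lie in (0, 1)")
        if self.case_control_ratio <= 0:
            raise ConfigError("case_control_ratio must be > 0")
        if not (0 < self.exposure_prev < 1):
            raise ConfigError("exposure_prev must lie in (0, 1)")
        if not (0 < self.disease_prev < 1):
            raise ConfigError("disease_prev must lie in (0, 1)")


@dataclass(frozen=True)
class Scenario:
    """Causal configuration: haplotype joint plus per-allele effect sizes."""

    joint: HaplotypeJoint
    rr_disease: float
    theta: float


@dataclass(frozen=True)
class MarkerCellModel:
    """Observable-level model: Pr(carrier, exposure) cells and cell risks.

    ``pr_cx[c, x]`` is the joint probability of carrier status c and
    exposure x; ``risk[c, x]`` is Pr(Y=1 | c, x).
    """

    pr_cx: np.ndarray
    risk: np.ndarray

    @property
    def interaction_odds_ratio(self) -> float:
        o = self.risk / (1 - self.risk)
        return float(o[1, 1] * o[0, 0] / (o[1, 0] * o[0, 1]))

    def override_interaction(self, interaction_ratio: float) -> "MarkerCellModel":
        """Replace the (carrier, exposed) cell so the odds-scale interaction
        equals ``interaction_ratio``, keeping all other cells fixed."""
        o = self.risk / (1 - self.risk)
        o11 = o[1, 0] * o[0, 1] / o[0, 0] * interaction_ratio
        risk = self.risk.copy()
        risk[1, 1] = o11 / (1 + o11)
        return MarkerCellModel(pr_cx=self.pr_cx, risk=risk)


def marker_cell_model(scenario: Scenario, design: DesignSpec) -> MarkerCellModel:
    """Exact carrier x exposure cell probabilities and risks for a scenario.

    Subjects carry two independent haplotypes; exposure depends on the
    causal dosage as Pr(X=1 | d) = kappa * theta**d with kappa matched to
    the design's exposure prevalence; disease risk is multiplicative in the
    causal dosage with the baseline set so that the cohort prevalence equals
    the design's disease prevalence.
    """
    p9 = diploid_expansion(scenario.joint)  # P[g_D, g_M]
    p_gd = p9.sum(axis=1)
    th = scenario.theta ** np.arange(3)
    kappa = design.exposure_prev / (p_gd @ th)
    px1_d = kappa * th
    if px1_d.max() > 1 + 1e-12:
        raise ConfigError(
            "exposure prevalence unattainable with this tilt "
            f"(Pr(X=1|dosage 2) = {px1_d.max()!r})"
        )
    rr = scenario.rr_disease ** np.arange(3)
    baseline = design.disease_prev / (p_gd @ rr)
    risk_d = baseline * rr
    if risk_d.max() > 1:
        raise ConfigError(
            f"disease model infeasible: Pr(Y=1|dosage 2) = {risk_d.max()!r} > 1"
        )

    pr_cx = np.zeros((2, 2))
    num = np.zeros((2, 2))  # accumulates Pr(Y=1, c, x)
    for g_d in range(3):
        for g_m in range(3):
            c = 1 if g_m > 0 else 0
            for x in (0, 1):
                mass = p9[g_d, g_m] * (px1_d[g_d] if x else 1 - px1_d[g_d])
                pr_cx[c, x] += mass
                num[c, x] += mass * risk_d[g_d]
    if np.any(pr_cx <= 0):
        raise ConfigError(
            "degenerate marker/exposure cell (zero probability); cannot "
            "compute interaction information"
        )
    return MarkerCellModel(pr_cx=pr_cx, risk=num / pr_cx)


def _casecontrol_information(model: MarkerCellModel, design: DesignSpec) -> np.ndarray:
    """Expected per-subject information matrix of the prospective logistic
    fit (intercept, carrier, exposure, product) to case-control data."""
    f_case = 1.0 / (1.0 + design.case_control_ratio)
    f_ctrl = 1.0 - f_case
    pr_y1 = float((model.pr_cx * model.risk).sum())
    pr_y0 = 1.0 - pr_y1
    info = np.zeros((4, 4))
    for c in (0, 1):
        for x in (0, 1):
            case_part = f_case * model.pr_cx[c, x] * model.risk[c, x] / pr_y1
            ctrl_part = f_ctrl * model.pr_cx[c, x] * (1 - model.risk[c, x]) / pr_y0
            pi_cell = case_part + ctrl_part
            if pi_cell <= 0:
                raise ConfigError(f"degenerate case-control cell (c={c}, x={x})")
            p_cell = case_part / pi_cell
            z = np.array([1.0, c, x, c * x])
            info += pi_cell * p_cell * (1 - p_cell) * np.outer(z, z)
    return info


def interaction_information(scenario: Scenario, design: DesignSpec) -> float:
    """Per-subject Fisher information for the interaction log-coefficient.

    The reciprocal of ``n`` times this value is the asymptotic variance of
    the fitted interaction coefficient at total sample size ``n``.
    """
    model = marker_cell_model(scenario, design)
    info = _casecontrol_information(model, design)
    return 1.0 / float(np.linalg.inv(info)[3, 3])


def sample_size_for_interaction(
    interaction_ratio: float,
    scenario: Scenario,
    design: DesignSpec,
) -> int:
    """Total subjects (cases + controls) to detect a multiplicative
    interaction of size ``interaction_ratio`` at the design's alpha/power.

    The information is evaluated at the alternative: the scenario's
    marker-level cell model with its interaction cell overridden (odds
    scale) to the requested ratio, so effect size and information refer to
    the same data-generating model.

    Raises
    ------
    ConfigError
        If ``interaction_ratio`` is 1 (infinite sample required).
    """
    if interaction_ratio <= 0:
        raise ConfigError("interaction_ratio must be > 0")
    if interaction_ratio == 1.0:
        raise ConfigError(
            "interaction_ratio = 1 means no effect: infinite sample size"
        )
    model = marker_cell_model(scenario, design).override_interaction(
        interaction_ratio
    )
    info = _casecontrol_information(model, design)
    unit_info = 1.0 / float(np.linalg.inv(info)[3, 3])
    z = norm.ppf(1 - design.alpha / 2) + norm.ppf(design.power)
    n = z * z / (math.log(interaction_ratio) ** 2 * unit_info)
    return int(math.ceil(n))


def analytic_power(
    n_total: int,
    interaction_ratio: float,
    scenario: Scenario,
    design: DesignSpec,
) -> float:
    """Wald-test power at a given total sample size (same alternative as
    :func:`sample_size_for_interaction`)."""
    model = marker_cell_model(scenario, design).override_interaction(
        interaction_ratio
    )
    info = _casecontrol_information(model, design)
    se = math.sqrt(float(np.linalg.inv(info)[3, 3]) / n_total)
    z_crit = norm.ppf(1 - design.alpha / 2)
    lam = abs(math.log(interaction_ratio)) / se
    return float(norm.cdf(lam - z_crit) + norm.cdf(-lam - z_crit))


def simulated_power(
    n_total: int,
    interaction_ratio: float,
    scenario: Scenario,
    design: DesignSpec,
    n_reps: int = 500,
    seed: int = 0,
) -> float:
    """Monte-Carlo power of the Wald interaction test.

    Cases and controls are drawn cell-wise (multinomial over the four
    carrier x exposure cells of the case and control populations) and the
    prospective logistic model is refitted per replicate; the rejection
    fraction at the design's alpha is returned.
    """
    from .simulate import _irls  # local import to avoid cycle
    from .glm import LOGIT

    model = marker_cell_model(scenario, design).override_interaction(
        interaction_ratio
    )
    f_case = 1.0 / (1.0 + design.case_control_ratio)
    n_cases = int(round(n_total * f_case))
    n_controls = n_total - n_cases
    pr_y1 = float((model.pr_cx * model.risk).sum())
    case_cells = (model.pr_cx * model.risk / pr_y1).ravel()
    ctrl_cells = (model.pr_cx * (1 - model.risk) / (1 - pr_y1)).ravel()
    design_mat = np.array(
        [[1.0, c, x, c * x] for c in (0, 1) for x in (0, 1)]
    )
    z_crit = norm.ppf(1 - design.alpha / 2)
    rng = np.random.default_rng(seed)
    rejected = 0
    for _ in range(n_reps):
        cases = rng.multinomial(n_cases, case_cells)
        ctrls = rng.multinomial(n_controls, ctrl_cells)
        tot = cases + ctrls
        if np.any(tot == 0):
            continue  # empty cell: model not fittable, test not rejected
        fit = _irls(
            design_mat, tot.astype(float), cases / tot, LOGIT,
            "carrier", 1e-10, 100,
        )
        if fit.converged and abs(fit.params[3]) / fit.se[3] > z_crit:
            rejected += 1
    return rejected / n_reps


def with_design(design: DesignSpec, **overrides) -> DesignSpec:
    """Convenience: a copy of ``design`` with fields replaced."""
    return replace(design, **overrides)
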