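"""Marker-level GLM obtained by marginalizing the causal-variant GLM.

The outcome follows a generalized linear model in the (unmeasured) causal
allele D and the binary exposure X,

    E(Y | D, X) = h^{-1}(b0* + bD* D + bX* X + bDX* D X),

with link h.  When the marker M has no effect on Y given D, the marker-level
cell means are mixtures over the conditional distribution of D,

    h^{-1}(eta_{m,x}) = sum_d h^{-1}(b0* + bD* d + bX* x + bDX* d x) Pr(d | m, x),

and the marker-by-exposure interaction on the link scale is the tetrad
difference

    beta_MX = eta_{1,1} - eta_{0,1} - eta_{1,0} + eta_{0,0}.

This term can be nonzero even when bDX* = 0: imperfect LD plus dependence of
D on X tilts Pr(d | m, x) differently across exposure strata.  Four
sufficient no-interaction conditions are checkable here: (1) no causal main
effect; (2) marker identical to the causal variant; (3) D independent of M
given X; (4) D independent of X given M — the last guaranteeing beta_MX = 0
only for the identity and log links (for logit it holds in the rare-outcome
limit).

All variables in this module are binary and allele-level (one chromosome,
one exposure indicator); diploid dosage analyses live in
:mod:`tagbias.simulate`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .exceptions import (
    FeasibilityError,
    LinkDomainError,
    UndefinedStratumError,
)
from .haplotypes import HaplotypeJoint

__all__ = [
    "LinkFunction",
    "IDENTITY",
    "LOG",
    "LOGIT",
    "get_link",
    "CausalGLM",
    "JointDMX",
    "EtaGrid",
    "LemmaReport",
    "build_joint_dmx",
    "marker_eta_grid",
    "lemma_conditions",
]


@dataclass(frozen=True)
class LinkFunction:
    """A GLM link h with its inverse, plus the valid mean domain."""

    name: str
    forward: Callable[[float], float]  # h: mean -> linear predictor
    inverse: Callable[[float], float]  # h^-1: linear predictor -> mean
    mean_lo: float
    mean_hi: float
    lo_open: bool
    hi_open: bool

    def check_mean(self, mu: float) -> None:
        ok = math.isfinite(mu)
        ok = ok and (mu > self.mean_lo if self.lo_open else mu >= self.mean_lo)
        ok = ok and (mu < self.mean_hi if self.hi_open else mu <= self.mean_hi)
        if not ok:
            raise LinkDomainError(
                f"mean {mu!r} outside valid domain of {self.name} link"
            )

    def __repr__(self) -> str:  # keep dataclass noise out of error messages
        return f"LinkFunction({self.name!r})"


def _expit(x: float) -> float:
    return 0.5 * (1.0 + math.tanh(0.5 * x))


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


IDENTITY = LinkFunction("identity", lambda m: m, lambda e: e,
                        -math.inf, math.inf, True, True)
LOG = LinkFunction("log", math.log, math.exp, 0.0, 1.0, True, False)
LOGIT = LinkFunction("logit", _logit, _expit, 0.0, 1.0, True, True)

_LINKS = {l.name: l for l in (IDENTITY, LOG, LOGIT)}


def get_link(name: str) -> LinkFunction:
    """Look up a link function by name (identity, log, logit)."""
    try:
        return _LINKS[name]
    except KeyError:
        raise ValueError(
            f"unknown link {name!r}; choose from {sorted(_LINKS)}"
        ) from None


@dataclass(frozen=True)
class CausalGLM:
    """Causal-scale GLM coefficients on the link scale.

    For the log link the coefficients are log risk ratios; for logit, log
    odds ratios.  Ratio-scale inputs are converted at the CLI boundary, not
    here.
    """

    link: LinkFunction
    beta0: float
    beta_d: float
    beta_x: float
    beta_dx: float = 0.0

    def mean(self, d: float, x: float) -> float:
        """E(Y | D=d, X=x); validates the link's mean domain."""
        mu = self.link.inverse(
            self.beta0 + self.beta_d * d + self.beta_x * x + self.beta_dx * d * x
        )
        self.link.check_mean(mu)
        return mu


@dataclass(frozen=True)
class JointDMX:
    """Probability mass over (d, m, x) in {0,1}^3 with derived conditionals."""

    p: np.ndarray = field(repr=False)  # p[d, m, x]

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        if p.shape != (2, 2, 2):
            raise ValueError(f"JointDMX mass must have shape (2,2,2), got {p.shape}")
        if np.any(p < 0) or not math.isfinite(p.sum()):
            raise FeasibilityError("JointDMX masses must be finite and >= 0")
        if abs(p.sum() - 1.0) > 1e-12:
            raise FeasibilityError(
                f"JointDMX masses sum to {p.sum()!r}, not 1 (tolerance 1e-12)"
            )
        object.__setattr__(self, "p", p)

    def pr_mx(self, m: int, x: int) -> float:
        """Marginal Pr(M=m, X=x)."""
        return float(self.p[:, m, x].sum())

    def pr_d_given_mx(self, m: int, x: int) -> np.ndarray:
        """Conditional distribution of D given (M=m, X=x)."""
        cell = self.p[:, m, x]
        tot = cell.sum()
        if tot <= 0:
            raise UndefinedStratumError(
                f"stratum (M={m}, X={x}) has zero probability mass"
            )
        return cell / tot

    def pr_d_given_x(self, x: int) -> np.ndarray:
        sl = self.p[:, :, x]
        tot = sl.sum()
        if tot <= 0:
            raise UndefinedStratumError(f"exposure stratum X={x} has zero mass")
        return sl.sum(axis=1) / tot

    def pr_d_given_m(self, m: int) -> np.ndarray:
        sl = self.p[:, m, :]
        tot = sl.sum()
        if tot <= 0:
            raise UndefinedStratumError(f"marker stratum M={m} has zero mass")
        return sl.sum(axis=1) / tot


@dataclass(frozen=True)
class EtaGrid:
    """Marker-level linear predictors eta[m][x] and derived coefficients."""

    eta: np.ndarray = field(repr=False)  # eta[m, x]
    link: LinkFunction = LOG

    @property
    def beta0(self) -> float:
        return float(self.eta[0, 0])

    @property
    def beta_m(self) -> float:
        return float(self.eta[1, 0] - self.eta[0, 0])

    @property
    def beta_x(self) -> float:
        return float(self.eta[0, 1] - self.eta[0, 0])

    @property
    def beta_mx(self) -> float:
        """Interaction tetrad eta11 - eta01 - eta10 + eta00."""
        e = self.eta
        return float(e[1, 1] - e[0, 1] - e[1, 0] + e[0, 0])

    def to_dict(self) -> dict:
        return {
            "link": self.link.name,
            "eta": {f"eta_{m}{x}": float(self.eta[m, x])
                    for m in (0, 1) for x in (0, 1)},
            "beta0": self.beta0,
            "beta_m": self.beta_m,
            "beta_x": self.beta_x,
            "beta_mx": self.beta_mx,
        }


def build_joint_dmx(
    joint: HaplotypeJoint,
    theta: float,
    exposure_prev: float | None = None,
    convention: str = "baseline_unexposed",
) -> JointDMX:
    """Couple the haplotype joint to a binary exposure with per-allele tilt theta.

    Two stratification conventions are supported:

    ``baseline_unexposed``
        The supplied joint describes *unexposed* chromosomes:
        Pr(d, m | X=0) = joint and Pr(d, m | X=1) ∝ joint * theta**d.  Only
        the per-stratum conditionals are pinned down; the exposure marginal
        (``exposure_prev``, default 0.5) merely weights the strata and
        cancels from every conditional Pr(d | m, x).

    ``marginal``
        The supplied joint is the *population* marginal of (d, m) and
        exposure is assigned per chromosome as Pr(X=1 | d) = kappa * theta**d
        with kappa solved so that Pr(X=1) = ``exposure_prev``.

    Raises
    ------
    FeasibilityError
        Under ``marginal`` when kappa * theta > 1 (requested prevalence
        unattainable with the given tilt).
    """
    if theta <= 0:
        raise ValueError(f"exposure tilt theta={theta!r} must be > 0")
    a = joint.as_array()  # a[d, m]
    p = np.empty((2, 2, 2))

    if convention == "baseline_unexposed":
        w1 = 0.5 if exposure_prev is None else float(exposure_prev)
        if not (0.0 < w1 < 1.0):
            raise ValueError(f"exposure_prev={w1!r} must lie in (0, 1)")
        tilt = a * np.array([[1.0], [theta]])
        p[:, :, 0] = (1 - w1) * a
        p[:, :, 1] = w1 * tilt / tilt.sum()
    elif convention == "marginal":
        if exposure_prev is None:
            raise ValueError("marginal convention requires exposure_prev")
        prev = float(exposure_prev)
        if not (0.0 < prev < 1.0):
            raise ValueError(f"exposure_prev={prev!r} must lie in (0, 1)")
        p_d = a.sum(axis=1)  # Pr(D=d)
        kappa = prev / (p_d[0] + p_d[1] * theta)
        if kappa * max(1.0, theta) > 1.0 + 1e-12:
            raise FeasibilityError(
                f"marginal convention infeasible: kappa*theta="
                f"{kappa * theta!r} > 1 for prevalence {prev} and theta {theta}"
            )
        tilt = np.array([kappa, kappa * theta])  # Pr(X=1 | d)
        p[:, :, 1] = a * tilt[:, None]
        p[:, :, 0] = a * (1.0 - tilt)[:, None]
    else:
        raise ValueError(f"unknown convention {convention!r}")

    return JointDMX(p=p)


def marker_eta_grid(model: CausalGLM, jdmx: JointDMX) -> EtaGrid:
    """Marginalize the causal GLM over Pr(D | M, X) to the marker scale.

    Raises
    ------
    UndefinedStratumError
        If any (m, x) cell has zero mass.
    LinkDomainError
        If a causal-cell mean or a mixed mean leaves the link's domain.
    """
    eta = np.empty((2, 2))
    for m in (0, 1):
        for x in (0, 1):
            cond = jdmx.pr_d_given_mx(m, x)
            mu = sum(cond[d] * model.mean(d, x) for d in (0, 1))
            model.link.check_mean(mu)
            eta[m, x] = model.link.forward(mu)
    return EtaGrid(eta=eta, link=model.link)


@dataclass(frozen=True)
class LemmaReport:
    """Which sufficient no-interaction conditions hold for a configuration.

    ``cond4_link_guaranteed`` records whether the link is identity or log,
    the cases in which condition (4) alone forces beta_MX = 0 (for logit it
    only does so in the rare-outcome limit).
    """

    cond1_no_causal_main_effect: bool
    cond2_marker_is_causal: bool
    cond3_d_indep_m_given_x: bool
    cond4_d_indep_x_given_m: bool
    cond4_link_guaranteed: bool
    beta_mx: float

    def any_guaranteed(self) -> bool:
        return (
            self.cond1_no_causal_main_effect
            or self.cond2_marker_is_causal
            or self.cond3_d_indep_m_given_x
            or (self.cond4_d_indep_x_given_m and self.cond4_link_guaranteed)
        )

    def to_dict(self) -> dict:
        return {
            "cond1_no_causal_main_effect": self.cond1_no_causal_main_effect,
            "cond2_marker_is_causal": self.cond2_marker_is_causal,
            "cond3_d_indep_m_given_x": self.cond3_d_indep_m_given_x,
            "cond4_d_indep_x_given_m": self.cond4_d_indep_x_given_m,
            "cond4_link_guaranteed": self.cond4_link_guaranteed,
            "beta_mx": self.beta_mx,
        }


def lemma_conditions(
    model: CausalGLM, jdmx: JointDMX, tol: float = 1e-9
) -> LemmaReport:
    """Check the four sufficient conditions for a null marker interaction.

    Assumes no causal-scale interaction (``model.beta_dx = 0``); the report
    is still produced otherwise, but the guarantee only applies when the
    causal interaction is zero.
    """
    cond1 = bool(abs(model.beta_d) <= tol)

    # Pr(D == M): mass on the diagonal of the (d, m) marginal
    dm = jdmx.p.sum(axis=2)
    cond2 = bool(abs(dm[0, 1]) + abs(dm[1, 0]) <= tol)

    dev3 = max(
        abs(jdmx.pr_d_given_mx(m, x)[1] - jdmx.pr_d_given_x(x)[1])
        for m in (0, 1)
        for x in (0, 1)
    )
    cond3 = bool(dev3 <= tol)

    dev4 = max(
        abs(jdmx.pr_d_given_mx(m, x)[1] - jdmx.pr_d_given_m(m)[1])
        for m in (0, 1)
        for x in (0, 1)
    )
    cond4 = bool(dev4 <= tol)

    beta_mx = marker_eta_grid(model, jdmx).beta_mx
    return LemmaReport(
        cond1_no_causal_main_effect=cond1,
        cond2_marker_is_causal=cond2,
        cond3_d_indep_m_given_x=cond3,
        cond4_d_indep_x_given_m=cond4,
        cond4_link_guaranteed=model.link.name in ("identity", "log"),
        beta_mx=beta_mx,
    )
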