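"""Inverse sensitivity analysis: from observed marker effects to causal space.

Given stratum-specific marker effects (ratio scale) observed in the two
levels of a binary exposure, an assumed causal-variant MAF and LD (D') with
the marker, solve for the causal per-allele risk ratio on disease, R, and on
exposure, theta, that exactly reproduce the observed marker effects under
the forward machinery of :mod:`tagbias.risk`.  Scanning the assumed causal
MAF shows which causal-variant configurations — typically rarer variants
with stronger effects and *no* interaction — are compatible with an observed
marker-by-exposure interaction.

With D' = 1 and causal MAF <= marker MAF, every copy of the causal allele
rides on a marker-allele chromosome (``h_Dm = 0``), so the system is solved
sequentially in closed form: the baseline-stratum equation involves only R
(the M=0 class then carries no causal alleles), after which the
tilted-stratum equation is linear in theta.  For incomplete LD a damped
2-D Newton iteration is used, with a bisection (Brent) fallback exploiting
the triangular structure: the baseline-stratum marker RR never involves
theta.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .exceptions import InfeasibleObservationError, NonIdentifiableError
from .haplotypes import HaplotypeJoint, haplotypes_from_ld
from .risk import marker_rr, stratum_marker_rrs, tilted_masses

__all__ = [
    "ObservedMarkerEffects",
    "SensitivitySolution",
    "invert_marker_effects",
    "sensitivity_scan",
]

_TOL = 1e-12
_MAX_ITER = 200


@dataclass(frozen=True)
class ObservedMarkerEffects:
    """Observed per-stratum marker effects, ratio scale.

    ``rr_stratum0`` is the effect in the baseline (untilted) exposure
    stratum, ``rr_stratum1`` in the tilted stratum.  Published odds ratios
    are entered directly and treated on the risk-ratio scale (rare-outcome
    convention).
    """

    p_M: float
    rr_stratum0: float
    rr_stratum1: float

    def __post_init__(self) -> None:
        if not (0.0 < self.p_M < 1.0):
            raise ValueError(f"p_M={self.p_M!r} must lie in (0, 1)")
        if self.rr_stratum0 <= 0 or self.rr_stratum1 <= 0:
            raise ValueError("stratum effects must be positive ratios")

    @property
    def interaction_ratio(self) -> float:
        """Observed multiplicative interaction, tilted over baseline stratum."""
        return self.rr_stratum1 / self.rr_stratum0


@dataclass(frozen=True)
class SensitivitySolution:
    """Causal risk ratios reproducing the observed marker effects.

    ``residual`` is the maximum absolute error of the two forward equations
    at the solution; ``method`` records the solve path (closed_form, newton,
    or bisection).  ``status`` is "converged", "infeasible" or
    "non_identifiable".

    With incomplete LD (D' < 1) the tilted-stratum equation is non-monotone
    in theta and exposure-side solutions come in pairs related by
    ``theta <-> h_dM h_dm / (R h_DM h_Dm theta)``; both reproduce the
    observations exactly.  ``rr_exposure_alt`` carries the partner root when
    it exists and differs (it never does at D' = 1, where the inversion is
    unique).
    """

    p_D: float
    rr_disease: float
    rr_exposure: float
    converged: bool
    residual: float
    status: str = "converged"
    method: str = "closed_form"
    rr_exposure_alt: float | None = None


def _forward(joint_arr: np.ndarray, R: float, theta: float) -> tuple[float, float]:
    eff = stratum_marker_rrs(joint_arr, R, theta)
    return eff.rr_unexposed, eff.rr_exposed


def _solve_closed_form(
    joint: HaplotypeJoint, obs: ObservedMarkerEffects
) -> SensitivitySolution:
    """Sequential closed form for h_Dm = 0 (D' = 1, p_D <= p_M)."""
    h_DM, h_dM = joint.h_DM, joint.h_dM
    # baseline stratum: rr0 = (h_dM + h_DM R) / p_M  (M=0 ratio is 1)
    R = (obs.rr_stratum0 * joint.p_M - h_dM) / h_DM
    if R <= 0:
        raise InfeasibleObservationError(
            f"no positive disease risk ratio reproduces rr_stratum0="
            f"{obs.rr_stratum0} at causal MAF {joint.p_D}"
        )
    if h_dM <= 0:
        # perfect proxy (r2 = 1): theta drops out of the tilted equation
        if abs(obs.rr_stratum1 - R) <= 1e-9:
            raise NonIdentifiableError(
                "perfect proxy: exposure tilt undetermined (both stratum "
                "effects equal the causal risk ratio)"
            )
        raise InfeasibleObservationError(
            "perfect proxy cannot show differing stratum effects "
            f"({obs.rr_stratum0} vs {obs.rr_stratum1})"
        )
    if abs(R - 1.0) <= 1e-12:
        # tilted equation is identically 1: theta cannot move the marker RR
        if abs(obs.rr_stratum1 - 1.0) <= 1e-9:
            raise NonIdentifiableError(
                "null marker effects: exposure tilt undetermined when the "
                "causal disease risk ratio is 1"
            )
        raise InfeasibleObservationError(
            "rr_stratum0 = 1 forces a null causal effect, which cannot "
            f"produce rr_stratum1 = {obs.rr_stratum1}"
        )
    # tilted stratum: rr1 = (h_dM + h_DM theta R) / (h_dM + h_DM theta)
    denom = h_DM * (R - obs.rr_stratum1)
    if denom == 0:
        raise InfeasibleObservationError(
            "tilted-stratum equation degenerate (rr_stratum1 equals the "
            "causal risk ratio)"
        )
    theta = h_dM * (obs.rr_stratum1 - 1.0) / denom
    if theta <= 0:
        raise InfeasibleObservationError(
            f"no positive exposure tilt reproduces rr_stratum1="
            f"{obs.rr_stratum1} at causal MAF {joint.p_D}"
        )
    f0, f1 = _forward(joint.as_array(), R, theta)
    residual = max(abs(f0 - obs.rr_stratum0), abs(f1 - obs.rr_stratum1))
    return SensitivitySolution(
        p_D=joint.p_D, rr_disease=R, rr_exposure=theta,
        converged=residual < 1e-10, residual=residual, method="closed_form",
    )


def _bracket_root(f, lo: float = 1e-9, hi: float = 1e9) -> float:
    """Brent root of f on a log-spaced bracket scan over (lo, hi)."""
    grid = np.logspace(math.log10(lo), math.log10(hi), 121)
    vals = [f(g) for g in grid]
    for a, b, fa, fb in zip(grid[:-1], grid[1:], vals[:-1], vals[1:]):
        if fa == 0.0:
            return float(a)
        if fa * fb < 0:
            return float(brentq(f, a, b, xtol=1e-15, rtol=8.9e-16))
    raise InfeasibleObservationError(
        "no positive root found for the observed marker effects"
    )


def _solve_newton(
    joint: HaplotypeJoint, obs: ObservedMarkerEffects
) -> SensitivitySolution:
    """Damped 2-D Newton in (log R, log theta) with Brent fallback."""
    arr = joint.as_array()
    target = np.array([obs.rr_stratum0, obs.rr_stratum1])

    def resid(u: np.ndarray) -> np.ndarray:
        with np.errstate(over="ignore", invalid="ignore"):
            R, theta = np.exp(u[0]), np.exp(u[1])
            if not (np.isfinite(R) and np.isfinite(theta)) or R <= 0 or theta <= 0:
                return np.array([np.inf, np.inf])
            return np.array(_forward(arr, R, theta)) - target

    u = np.array([
        math.log(obs.rr_stratum0),
        math.log(max(obs.rr_stratum1 / obs.rr_stratum0, 1e-6)),
    ])
    f = resid(u)
    method = "newton"
    for _ in range(_MAX_ITER):
        if np.max(np.abs(f)) < _TOL:
            break
        h = 1e-7
        J = np.empty((2, 2))
        for j in range(2):
            du = np.zeros(2)
            du[j] = h
            J[:, j] = (resid(u + du) - resid(u - du)) / (2 * h)
        try:
            step = np.linalg.solve(J, -f)
        except np.linalg.LinAlgError:
            break
        # damping: halve until the residual norm decreases
        lam, ok = 1.0, False
        for _ in range(40):
            f_new = resid(u + lam * step)
            if np.linalg.norm(f_new) < np.linalg.norm(f):
                u, f, ok = u + lam * step, f_new, True
                break
            lam *= 0.5
        if not ok:
            break

    if np.max(np.abs(f)) >= _TOL:
        # sequential Brent fallback: rr_unexposed involves only R
        method = "bisection"
        R = _bracket_root(lambda r: marker_rr(arr, r) - obs.rr_stratum0)
        theta = _bracket_root(
            lambda t: marker_rr(tilted_masses(arr, t), R) - obs.rr_stratum1
        )
        u = np.array([math.log(R), math.log(theta)])
        f = resid(u)

    R, theta = math.exp(u[0]), math.exp(u[1])
    residual = float(np.max(np.abs(f)))

    # partner root of the (non-monotone) tilted-stratum equation
    theta_alt = None
    if joint.h_Dm > 0 and joint.h_DM > 0 and R > 0:
        cand = (joint.h_dM * joint.h_dm) / (R * joint.h_DM * joint.h_Dm * theta)
        if cand > 0 and abs(cand - theta) > 1e-8 * max(1.0, theta):
            f0, f1 = _forward(arr, R, cand)
            if max(abs(f0 - obs.rr_stratum0), abs(f1 - obs.rr_stratum1)) < 1e-8:
                theta_alt = cand

    return SensitivitySolution(
        p_D=joint.p_D, rr_disease=R, rr_exposure=theta,
        converged=residual < 1e-10, residual=residual, method=method,
        rr_exposure_alt=theta_alt,
    )


def invert_marker_effects(
    obs: ObservedMarkerEffects, p_D: float, d_prime: float = 1.0
) -> SensitivitySolution:
    """Recover causal risk ratios (R, theta) from stratum marker effects.

    Parameters
    ----------
    obs:
        Observed marker MAF and per-stratum marker effects.
    p_D:
        Assumed causal-variant MAF, in (0, 1).
    d_prime:
        Assumed LD between causal variant and marker (default 1, the
        maximum-correlation assumption).

    Returns
    -------
    SensitivitySolution
        Such that the forward stratum marker RRs at (R, theta) reproduce the
        observations with residual below 1e-10 when converged.

    Raises
    ------
    InfeasibleObservationError
        When no positive (R, theta) solves the system.
    NonIdentifiableError
        When theta drops out of the equations (e.g. null marker effects).
    """
    joint = haplotypes_from_ld(p_D, obs.p_M, "d_prime", d_prime, "+")
    if joint.h_Dm <= 1e-15:
        return _solve_closed_form(joint, obs)
    return _solve_newton(joint, obs)


def sensitivity_scan(
    obs: ObservedMarkerEffects,
    p_D_grid: Sequence[float],
    d_prime: float = 1.0,
) -> pd.DataFrame:
    """Run the inversion over a grid of assumed causal MAFs.

    Returns one row per MAF with the recovered ratios, their reciprocals
    (convenient for protective alleles), the forward residual and a status
    column; infeasible MAFs are flagged, not dropped.
    """
    rows = []
    for p_D in p_D_grid:
        row: dict = {"maf_causal": p_D}
        try:
            sol = invert_marker_effects(obs, p_D, d_prime)
            row.update(
                rr_disease=sol.rr_disease,
                rr_exposure=sol.rr_exposure,
                inv_rr_disease=1.0 / sol.rr_disease,
                inv_rr_exposure=1.0 / sol.rr_exposure,
                residual=sol.residual,
                status=sol.status if sol.converged else "not_converged",
            )
        except NonIdentifiableError:
            row.update(
                rr_disease=np.nan, rr_exposure=np.nan,
                inv_rr_disease=np.nan, inv_rr_exposure=np.nan,
                residual=np.nan, status="non_identifiable",
            )
        except InfeasibleObservationError:
            row.update(
                rr_disease=np.nan, rr_exposure=np.nan,
                inv_rr_disease=np.nan, inv_rr_exposure=np.nan,
                residual=np.nan, status="infeasible",
            )
        rows.append(row)
    cols = [
        "maf_causal", "rr_disease", "rr_exposure",
        "inv_rr_disease", "inv_rr_exposure", "residual", "status",
    ]
    return pd.DataFrame(rows, columns=cols)
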