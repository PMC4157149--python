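"""Forward bias machinery on the risk-ratio scale.

Given the haplotype joint of a causal variant D and marker M, a per-allele
disease risk ratio ``rr_disease`` for D, and a per-allele exposure tilt
``theta`` (the risk ratio of D on a binary exposure), this module computes
the per-allele marker risk ratio overall and within each exposure stratum.
With multiplicative risks the marker RR in a stratum is

    RR(M | stratum) = E[rr^D | M=1, stratum] / E[rr^D | M=0, stratum],

and the exposed-stratum haplotype masses are the baseline masses tilted
cell-wise by ``theta**d``.  The ratio of the two stratum RRs is the induced
multiplicative marker-by-exposure interaction: nonzero G-E dependence plus
imperfect LD makes it differ from 1 even though the causal variant has no
interaction with the exposure at all.

All ratios are computed from unnormalized masses; baselines and
normalizations cancel, so the results do not depend on disease or exposure
prevalence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import UndefinedStratumError
from .haplotypes import HaplotypeJoint

__all__ = [
    "StratumEffects",
    "risk_weighted_masses",
    "marker_rr",
    "stratum_marker_rrs",
]


@dataclass(frozen=True)
class StratumEffects:
    """Per-allele marker risk ratio in each exposure stratum.

    Attributes
    ----------
    rr_unexposed, rr_exposed:
        Marker RR among unexposed (X=0) and exposed (X=1) chromosomes.
    interaction_ratio:
        ``rr_exposed / rr_unexposed`` — the multiplicative marker-by-exposure
        interaction induced by LD plus gene-environment dependence.
    """

    rr_unexposed: float
    rr_exposed: float

    @property
    def interaction_ratio(self) -> float:
        return self.rr_exposed / self.rr_unexposed

    def to_dict(self) -> dict:
        return {
            "rr_unexposed": self.rr_unexposed,
            "rr_exposed": self.rr_exposed,
            "interaction_ratio": self.interaction_ratio,
        }


def _as_masses(joint) -> np.ndarray:
    if isinstance(joint, HaplotypeJoint):
        return joint.as_array()
    return np.asarray(joint, dtype=float)


def risk_weighted_masses(joint, rr_disease: float) -> np.ndarray:
    """Masses proportional to Pr(Y=1, d, m): cell (d, m) times rr**d.

    No normalization is applied — the baseline disease risk cancels in every
    ratio downstream.  Accepts a :class:`HaplotypeJoint` or a raw (2, 2)
    ``[d, m]`` mass array (not necessarily normalized).
    """
    if rr_disease <= 0:
        raise ValueError(f"rr_disease={rr_disease!r} must be > 0")
    a = _as_masses(joint)
    return a * np.array([[1.0], [rr_disease]])


def marker_rr(joint, rr_disease: float) -> float:
    """Per-allele marker risk ratio under a multiplicative causal effect.

    Equals ``E[rr^D | M=1] / E[rr^D | M=0]`` — the ratio of risk-weighted to
    unweighted marker-allele masses, M=1 vs M=0.
    """
    a = _as_masses(joint)
    w = risk_weighted_masses(a, rr_disease)
    m1, m0 = a[:, 1].sum(), a[:, 0].sum()
    if m1 <= 0 or m0 <= 0:
        raise UndefinedStratumError(
            f"marker class empty (mass M=1: {m1}, M=0: {m0})"
        )
    return float((w[:, 1].sum() / m1) / (w[:, 0].sum() / m0))


def tilted_masses(joint, theta: float) -> np.ndarray:
    """Exposed-stratum haplotype masses: cell (d, m) times theta**d.

    Unnormalized; the exposure-stratum normalization cancels in marker RRs.
    """
    if theta <= 0:
        raise ValueError(f"theta={theta!r} must be > 0")
    a = _as_masses(joint)
    return a * np.array([[1.0], [theta]])


def stratum_marker_rrs(joint, rr_disease: float, theta: float) -> StratumEffects:
    """Marker RR per exposure stratum and the induced interaction ratio.

    The unexposed stratum uses the baseline haplotype masses; the exposed
    stratum uses the theta-tilted masses.
    """
    a = _as_masses(joint)
    return StratumEffects(
        rr_unexposed=marker_rr(a, rr_disease),
        rr_exposed=marker_rr(tilted_masses(a, theta), rr_disease),
    )
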