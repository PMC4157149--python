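"""Haplotype-frequency algebra for a biallelic causal variant and marker.

The canonical object is the joint distribution of the *alleles* carried by a
single chromosome at two loci: ``D`` (the unmeasured causal variant) and
``M`` (the genotyped marker).  Four haplotype masses fully describe it:

===========  =======================================
``h_DM``     Pr(D = 1, M = 1)  — risk allele with minor marker allele
``h_Dm``     Pr(D = 1, M = 0)
``h_dM``     Pr(D = 0, M = 1)
``h_dm``     Pr(D = 0, M = 0)
===========  =======================================

Linkage disequilibrium (LD) is quantified by the covariance
``delta = h_DM - p_D * p_M``, its Fréchet-normalized form D' and the squared
allelic correlation r².  Diploid genotypes are derived views obtained by two
independent haplotype draws (Hardy–Weinberg equilibrium); they are never the
stored representation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np

from .exceptions import FeasibilityError, MonomorphicLocusError

__all__ = [
    "HaplotypeJoint",
    "LDStats",
    "haplotypes_from_ld",
    "ld_stats",
    "max_r2",
    "diploid_expansion",
]

#: tolerance for the sum-to-one check on user-supplied masses
_SUM_TOL = 1e-9


@dataclass(frozen=True)
class HaplotypeJoint:
    """Joint allele-level distribution over (causal allele, marker allele).

    Masses are validated, never silently clipped: they must be nonnegative
    and sum to one within 1e-9.

    Attributes
    ----------
    h_DM, h_Dm, h_dM, h_dm:
        Probability masses of the four haplotypes (D, M) = (1,1), (1,0),
        (0,1), (0,0).
    """

    h_DM: float
    h_Dm: float
    h_dM: float
    h_dm: float

    def __post_init__(self) -> None:
        masses = (self.h_DM, self.h_Dm, self.h_dM, self.h_dm)
        for name, h in zip(("h_DM", "h_Dm", "h_dM", "h_dm"), masses):
            if not math.isfinite(h) or h < 0:
                raise FeasibilityError(
                    f"haplotype mass {name}={h!r} must be finite and >= 0"
                )
        total = sum(masses)
        if abs(total - 1.0) > _SUM_TOL:
            raise FeasibilityError(
                f"haplotype masses sum to {total!r}, not 1 (tolerance {_SUM_TOL})"
            )

    @property
    def p_D(self) -> float:
        """Causal-variant allele frequency Pr(D = 1)."""
        return self.h_DM + self.h_Dm

    @property
    def p_M(self) -> float:
        """Marker allele frequency Pr(M = 1)."""
        return self.h_DM + self.h_dM

    def as_array(self) -> np.ndarray:
        """Return a (2, 2) array ``a[d, m]`` of haplotype masses."""
        return np.array([[self.h_dm, self.h_dM], [self.h_Dm, self.h_DM]])

    @classmethod
    def from_array(cls, a: np.ndarray) -> "HaplotypeJoint":
        """Build from a (2, 2) array indexed ``a[d, m]``."""
        a = np.asarray(a, dtype=float)
        return cls(h_DM=a[1, 1], h_Dm=a[1, 0], h_dM=a[0, 1], h_dm=a[0, 0])

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "h_DM": self.h_DM,
            "h_Dm": self.h_Dm,
            "h_dM": self.h_dM,
            "h_dm": self.h_dm,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HaplotypeJoint":
        return cls(**{k: float(d[k]) for k in ("h_DM", "h_Dm", "h_dM", "h_dm")})

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "HaplotypeJoint":
        return cls.from_dict(json.loads(s))

    def to_tsv(self) -> str:
        """Two-line TSV record (header + full-precision values)."""
        keys = ("h_DM", "h_Dm", "h_dM", "h_dm")
        vals = (self.h_DM, self.h_Dm, self.h_dM, self.h_dm)
        return "\t".join(keys) + "\n" + "\t".join(repr(v) for v in vals) + "\n"

    @classmethod
    def from_tsv(cls, s: str) -> "HaplotypeJoint":
        lines = [ln for ln in s.splitlines() if ln.strip() and not ln.startswith("#")]
        header = lines[0].split("\t")
        values = [float(x) for x in lines[1].split("\t")]
        return cls.from_dict(dict(zip(header, values)))


@dataclass(frozen=True)
class LDStats:
    """LD summary of a haplotype joint.

    Attributes
    ----------
    delta:
        Covariance-scale LD coefficient, ``h_DM - p_D * p_M``.
    d_prime:
        ``delta`` normalized by its sign-appropriate Fréchet bound, in
        [-1, 1].
    r2:
        Squared allelic correlation
        ``delta**2 / (p_D (1-p_D) p_M (1-p_M))``, in [0, 1].
    """

    delta: float
    d_prime: float
    r2: float


def _delta_bounds(p_D: float, p_M: float) -> tuple[float, float]:
    """(most negative, most positive) admissible covariance delta."""
    lo = -min(p_D * p_M, (1 - p_D) * (1 - p_M))
    hi = min(p_D * (1 - p_M), (1 - p_D) * p_M)
    return lo, hi


def max_r2(p_D: float, p_M: float, sign: str = "+") -> float:
    """Largest attainable r² for given allele frequencies and delta sign.

    The bound follows from the Fréchet bounds on ``h_DM``; it equals 1 only
    when the two allele frequencies match (positive sign) or are
    complementary (negative sign).
    """
    lo, hi = _delta_bounds(p_D, p_M)
    d = hi if sign == "+" else lo
    return d * d / (p_D * (1 - p_D) * p_M * (1 - p_M))


def _check_freq(name: str, p: float) -> None:
    if not (0.0 < p < 1.0):
        raise FeasibilityError(f"{name}={p!r} must lie strictly in (0, 1)")


def haplotypes_from_ld(
    p_D: float,
    p_M: float,
    measure: str = "d_prime",
    value: float = 1.0,
    sign: str = "+",
) -> HaplotypeJoint:
    """Construct the haplotype joint from allele frequencies and one LD measure.

    Parameters
    ----------
    p_D, p_M:
        Allele frequencies of the causal variant and marker, in (0, 1).
    measure:
        ``"d_prime"`` or ``"r2"``.
    value:
        The LD value.  D' carries its own sign in [-1, 1]; r² is sign-blind
        and must be in [0, r²_max] for the chosen ``sign``.
    sign:
        ``"+"`` or ``"-"``: orientation of delta when ``measure="r2"``
        (positive means the causal allele is enriched on the minor-marker
        background).  Ignored for D'.

    Returns
    -------
    HaplotypeJoint
        Joint with ``h_DM = p_D * p_M + delta``.  Recomputing the requested
        measure from the result returns ``value`` to 1e-12.

    Raises
    ------
    FeasibilityError
        If the (p_D, p_M, value) combination violates a Fréchet bound; the
        message names the violated bound.
    """
    _check_freq("p_D", p_D)
    _check_freq("p_M", p_M)
    lo, hi = _delta_bounds(p_D, p_M)

    if measure == "d_prime":
        if not -1.0 <= value <= 1.0:
            raise FeasibilityError(f"d_prime={value!r} must lie in [-1, 1]")
        delta = value * (hi if value >= 0 else -lo)
    elif measure == "r2":
        if sign not in ("+", "-"):
            raise ValueError(f"sign must be '+' or '-', got {sign!r}")
        if value < 0:
            raise FeasibilityError(f"r2={value!r} must be >= 0")
        r2_cap = max_r2(p_D, p_M, sign)
        # small headroom so the boundary value itself is accepted
        if value > r2_cap * (1 + 1e-12) + 1e-15:
            raise FeasibilityError(
                f"r2={value!r} exceeds the Fréchet-bound maximum "
                f"r2_max={r2_cap!r} for p_D={p_D}, p_M={p_M}, sign={sign!r}"
            )
        mag = math.sqrt(value * p_D * (1 - p_D) * p_M * (1 - p_M))
        delta = mag if sign == "+" else -mag
        delta = min(max(delta, lo), hi)  # absorb sqrt round-off at the boundary
    else:
        raise ValueError(f"unknown LD measure {measure!r}")

    return HaplotypeJoint(
        h_DM=p_D * p_M + delta,
        h_Dm=p_D * (1 - p_M) - delta,
        h_dM=(1 - p_D) * p_M - delta,
        h_dm=(1 - p_D) * (1 - p_M) + delta,
    )


def ld_stats(joint: HaplotypeJoint) -> LDStats:
    """Compute delta, D' and r² for a haplotype joint.

    Raises
    ------
    MonomorphicLocusError
        If either allele frequency is 0 or 1 (LD undefined).
    """
    p_D, p_M = joint.p_D, joint.p_M
    if not (0.0 < p_D < 1.0) or not (0.0 < p_M < 1.0):
        raise MonomorphicLocusError(
            f"LD undefined for monomorphic locus (p_D={p_D}, p_M={p_M})"
        )
    delta = joint.h_DM - p_D * p_M
    lo, hi = _delta_bounds(p_D, p_M)
    if delta >= 0:
        d_prime = 0.0 if hi == 0 else delta / hi
    else:
        d_prime = delta / -lo
    r2 = delta * delta / (p_D * (1 - p_D) * p_M * (1 - p_M))
    return LDStats(delta=delta, d_prime=d_prime, r2=r2)


def diploid_expansion(joint: HaplotypeJoint) -> np.ndarray:
    """Genotype-pair distribution from two independent haplotype draws.

    Returns
    -------
    numpy.ndarray
        (3, 3) array ``P[g_D, g_M]`` over causal and marker allele dosages
        0/1/2.  Marginals are Hardy–Weinberg at each locus.
    """
    a = joint.as_array()  # a[d, m]
    out = np.zeros((3, 3))
    for d1 in range(2):
        for m1 in range(2):
            for d2 in range(2):
                for m2 in range(2):
                    out[d1 + d2, m1 + m2] += a[d1, m1] * a[d2, m2]
    return out
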