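"""Seeded individual-level simulator and GLM fitter.

This is the brute-force empirical counterpart of the analytic machinery:
draw diploid subjects (two independent haplotypes per subject), assign a
binary exposure that depends on the causal dosage, draw a binary outcome
from the causal GLM, and fit the marker-level interaction model

    E(Y | M, X) = h^{-1}(b0 + bM M + bX X + bMX M X)

by iteratively reweighted least squares (IRLS).  The fitter is implemented
in-package so the oracle carries no statistical dependency of its own; a
library fit can serve as a second opinion in tests.

Exposure conventions
--------------------
``marginal`` (default)
    Haplotypes are drawn first from the population joint; exposure follows
    Pr(X=1 | d) = kappa * theta**d with d the causal *dosage* (0/1/2) and
    kappa solved so the population exposure prevalence matches the target.
``baseline_unexposed``
    Exposure is drawn first with the target prevalence; the subject's two
    haplotypes are then drawn iid from the stratum-specific distribution
    (baseline masses if unexposed, theta-tilted if exposed).  Within-stratum
    haplotype independence makes the allele-level stratum marker RRs exactly
    the analytic ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .exceptions import ConfigError, SamplingBudgetError
from .glm import CausalGLM, LinkFunction, get_link
from .haplotypes import HaplotypeJoint

__all__ = [
    "SimConfig",
    "FitResult",
    "simulate_cohort",
    "simulate_case_control",
    "fit_interaction_glm",
    "expected_diploid_cells",
]

_COLUMNS = ["causal_dosage", "marker_dosage", "exposure", "outcome"]


@dataclass(frozen=True)
class SimConfig:
    """Scenario plus sampling settings for the individual-level simulator.

    The causal GLM is evaluated at the diploid dosage (0/1/2), i.e. the
    per-allele coefficients act multiplicatively across the two chromosomes
    on the link scale.
    """

    joint: HaplotypeJoint
    model: CausalGLM
    theta: float = 1.0
    exposure_prev: float = 0.5
    convention: Literal["marginal", "baseline_unexposed"] = "marginal"
    n: int = 10_000
    seed: int = 0
    n_cases: int | None = None
    n_controls: int | None = None

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ConfigError(f"n={self.n!r} must be > 0")
        if self.theta <= 0:
            raise ConfigError(f"theta={self.theta!r} must be > 0")
        if not (0.0 < self.exposure_prev < 1.0):
            raise ConfigError(
                f"exposure_prev={self.exposure_prev!r} must lie in (0, 1)"
            )
        if self.convention not in ("marginal", "baseline_unexposed"):
            raise ConfigError(f"unknown convention {self.convention!r}")
        # validate all attainable (dosage, exposure) risks before sampling
        for d in (0, 1, 2):
            self.model.link.check_mean(self._mean(d, 0))
            self.model.link.check_mean(self._mean(d, 1))

    def _mean(self, d: int, x: int) -> float:
        m = self.model
        return m.link.inverse(
            m.beta0 + m.beta_d * d + m.beta_x * x + m.beta_dx * d * x
        )

    def dosage_exposure_prob(self) -> np.ndarray:
        """Pr(X=1 | causal dosage) under the marginal convention."""
        hwe_d = self._hwe_causal()
        kappa = self.exposure_prev / (hwe_d @ self.theta ** np.arange(3))
        probs = kappa * self.theta ** np.arange(3)
        if probs.max() > 1.0 + 1e-12:
            raise ConfigError(
                f"exposure model infeasible: Pr(X=1|dosage 2)={probs.max()!r} > 1"
            )
        return np.minimum(probs, 1.0)

    def _hwe_causal(self) -> np.ndarray:
        p = self.joint.p_D
        return np.array([(1 - p) ** 2, 2 * p * (1 - p), p * p])


def _draw_haplotypes(
    rng: np.random.Generator, masses: np.ndarray, n: int
) -> tuple[np.ndarray, np.ndarray]:
    """Two independent haplotype draws per subject -> (causal, marker) dosages."""
    flat = masses.ravel() / masses.sum()  # order (d,m): 00,01,10,11
    idx = rng.choice(4, size=(n, 2), p=flat)
    d = (idx >= 2).sum(axis=1)
    m = (idx % 2).sum(axis=1)
    return d, m


def simulate_cohort(cfg: SimConfig) -> pd.DataFrame:
    """Simulate a cohort of ``cfg.n`` subjects; reproducible given seed.

    Returns a DataFrame with integer columns causal_dosage, marker_dosage,
    exposure, outcome.
    """
    rng = np.random.default_rng(cfg.seed)
    return _simulate_cohort_rng(cfg, rng, cfg.n)


def _simulate_cohort_rng(
    cfg: SimConfig, rng: np.random.Generator, n: int
) -> pd.DataFrame:
    a = cfg.joint.as_array()
    if cfg.convention == "marginal":
        d, m = _draw_haplotypes(rng, a, n)
        px = cfg.dosage_exposure_prob()[d]
        x = (rng.random(n) < px).astype(np.int64)
    else:  # baseline_unexposed
        x = (rng.random(n) < cfg.exposure_prev).astype(np.int64)
        tilted = a * np.array([[1.0], [cfg.theta]])
        d = np.empty(n, dtype=np.int64)
        m = np.empty(n, dtype=np.int64)
        for stratum, masses in ((0, a), (1, tilted)):
            sel = np.flatnonzero(x == stratum)
            if sel.size:
                d[sel], m[sel] = _draw_haplotypes(rng, masses, sel.size)
    mu = np.array([[cfg._mean(dd, xx) for xx in (0, 1)] for dd in (0, 1, 2)])
    y = (rng.random(n) < mu[d, x]).astype(np.int64)
    return pd.DataFrame(
        {"causal_dosage": d, "marker_dosage": m, "exposure": x, "outcome": y}
    )


def simulate_case_control(cfg: SimConfig, max_batches: int = 1000) -> pd.DataFrame:
    """Rejection-sample a case-control study of the cohort model.

    Draws cohort batches until ``cfg.n_cases`` cases and ``cfg.n_controls``
    controls have accumulated (cases first in the returned table).

    Raises
    ------
    SamplingBudgetError
        If the quotas are not met within ``max_batches`` cohort batches.
    """
    if cfg.n_cases is None or cfg.n_controls is None:
        raise ConfigError("case-control design requires n_cases and n_controls")
    rng = np.random.default_rng(cfg.seed)
    batch = max(cfg.n, 4 * (cfg.n_cases + cfg.n_controls))
    cases: list[pd.DataFrame] = []
    controls: list[pd.DataFrame] = []
    got_cases = got_controls = 0
    for _ in range(max_batches):
        tab = _simulate_cohort_rng(cfg, rng, batch)
        if got_cases < cfg.n_cases:
            sub = tab[tab["outcome"] == 1]
            cases.append(sub.iloc[: cfg.n_cases - got_cases])
            got_cases += len(cases[-1])
        if got_controls < cfg.n_controls:
            sub = tab[tab["outcome"] == 0]
            controls.append(sub.iloc[: cfg.n_controls - got_controls])
            got_controls += len(controls[-1])
        if got_cases >= cfg.n_cases and got_controls >= cfg.n_controls:
            return pd.concat(cases + controls, ignore_index=True)
    raise SamplingBudgetError(
        f"failed to collect {cfg.n_cases} cases / {cfg.n_controls} controls "
        f"within {max_batches} batches of {batch}"
    )


@dataclass(frozen=True)
class FitResult:
    """IRLS fit of the marker-level interaction GLM.

    ``params`` and ``se`` are in design order (intercept, marker, exposure,
    marker:exposure); ``cov`` is the inverse expected information at the
    optimum.
    """

    params: np.ndarray
    se: np.ndarray
    cov: np.ndarray = field(repr=False)
    converged: bool
    n_iter: int
    link: str
    coding: str

    @property
    def beta_mx(self) -> float:
        return float(self.params[3])

    @property
    def se_mx(self) -> float:
        return float(self.se[3])

    def to_dict(self) -> dict:
        names = ["beta0", "beta_m", "beta_x", "beta_mx"]
        return {
            "params": dict(zip(names, map(float, self.params))),
            "se": dict(zip(names, map(float, self.se))),
            "converged": self.converged,
            "n_iter": self.n_iter,
            "link": self.link,
            "coding": self.coding,
        }


def _aggregate_cells(
    m_code: np.ndarray, x: np.ndarray, y: np.ndarray, w: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Collapse subject rows to unique (m, x) cells with weights and mean y."""
    key = m_code * 2 + x
    cells = np.unique(key)
    W = np.empty(cells.size)
    Ybar = np.empty(cells.size)
    M = np.empty(cells.size)
    X = np.empty(cells.size)
    for i, c in enumerate(cells):
        sel = key == c
        W[i] = w[sel].sum()
        Ybar[i] = np.average(y[sel], weights=w[sel])
        M[i] = m_code[sel][0]
        X[i] = x[sel][0]
    design = np.column_stack([np.ones(cells.size), M, X, M * X])
    return design, W, Ybar


def fit_interaction_glm(
    data: pd.DataFrame,
    link: str | LinkFunction = "log",
    coding: Literal["allele_dosage", "carrier"] = "allele_dosage",
    weights: np.ndarray | None = None,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> FitResult:
    """Fit outcome ~ marker + exposure + marker:exposure by binomial IRLS.

    Parameters
    ----------
    data:
        Table with columns marker_dosage, exposure, outcome.  ``outcome``
        may hold fractional cell means when ``weights`` carries the cell
        masses (expected-data fits).
    link:
        identity, log or logit (name or :class:`LinkFunction`).
    coding:
        ``allele_dosage`` uses the marker dosage 0/1/2; ``carrier`` codes
        dosage > 0 as 1.
    weights:
        Optional frequency weights, one per row (default all 1).

    Notes
    -----
    Rows are aggregated to unique (marker, exposure) cells, so the fit cost
    is independent of sample size.  Separation or a diverging iteration is
    reported via ``converged=False``, never silently returned as converged.
    """
    lk = get_link(link) if isinstance(link, str) else link
    m_raw = data["marker_dosage"].to_numpy(dtype=float)
    m_code = (m_raw > 0).astype(float) if coding == "carrier" else m_raw
    if coding not in ("allele_dosage", "carrier"):
        raise ValueError(f"unknown coding {coding!r}")
    x = data["exposure"].to_numpy(dtype=float)
    y = data["outcome"].to_numpy(dtype=float)
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)

    design, W, Ybar = _aggregate_cells(m_code, x, y, w)
    return _irls(design, W, Ybar, lk, coding, tol, max_iter)


def _irls(
    design: np.ndarray,
    W: np.ndarray,
    Ybar: np.ndarray,
    lk: LinkFunction,
    coding: str,
    tol: float,
    max_iter: int,
) -> FitResult:
    k = design.shape[1]
    if design.shape[0] < k or np.linalg.matrix_rank(design) < k:
        raise ConfigError(
            "design is rank-deficient: not all (marker, exposure) cells "
            "observed"
        )
    # starting values: adjusted cell means pushed through the link
    mu = np.clip(Ybar, 1e-6, 1 - 1e-6) if lk.name != "identity" else np.clip(
        Ybar, 1e-6, None
    )
    eta = np.array([lk.forward(m) for m in mu])
    beta, _, _, _ = np.linalg.lstsq(design, eta, rcond=None)

    converged = False
    it = 0
    info = np.eye(k)
    for it in range(1, max_iter + 1):
        eta = design @ beta
        mu, dmu = _mean_and_deriv(eta, lk)
        if np.any(~np.isfinite(mu)) or np.any(mu <= 0) or (
            lk.name != "identity" and np.any(mu >= 1)
        ):
            break  # separation / domain escape
        var = mu * (1 - mu)
        wirls = W * dmu * dmu / var
        z = eta + (Ybar - mu) / dmu
        info = design.T @ (design * wirls[:, None])
        try:
            beta_new = np.linalg.solve(info, design.T @ (wirls * z))
        except np.linalg.LinAlgError:
            break
        shift = np.max(np.abs(beta_new - beta))
        beta = beta_new
        if shift < tol:
            converged = True
            break

    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        cov = np.full((k, k), np.nan)
        se = np.full(k, np.nan)
        converged = False
    return FitResult(
        params=beta, se=se, cov=cov, converged=converged, n_iter=it,
        link=lk.name, coding=coding,
    )


def _mean_and_deriv(eta: np.ndarray, lk: LinkFunction) -> tuple[np.ndarray, np.ndarray]:
    if lk.name == "identity":
        return eta.copy(), np.ones_like(eta)
    if lk.name == "log":
        mu = np.exp(eta)
        return mu, mu
    mu = 0.5 * (1.0 + np.tanh(0.5 * eta))
    return mu, mu * (1 - mu)


def expected_diploid_cells(cfg: SimConfig) -> pd.DataFrame:
    """Exact expected (marker_dosage, exposure) cells of the cohort model.

    Returns a table with fractional ``weight`` (cell probability) and
    ``outcome`` (true cell mean risk) suitable for an expected-data fit;
    the IRLS fit on these cells is the exact probability limit of the fit
    to simulated data from the same configuration.
    """
    a = cfg.joint.as_array()
    # joint over (d1,m1,d2,m2,x)
    rows = []
    cells: dict[tuple[int, int], tuple[float, float]] = {}
    if cfg.convention == "marginal":
        px_d = cfg.dosage_exposure_prob()

        def pr_x_given_d(d: int, x: int) -> float:
            return px_d[d] if x == 1 else 1 - px_d[d]

        def hap_mass(d1, m1, d2, m2, x):
            return a[d1, m1] * a[d2, m2] * pr_x_given_d(d1 + d2, x)
    else:
        tilted = a * np.array([[1.0], [cfg.theta]])
        tilted = tilted / tilted.sum()

        def hap_mass(d1, m1, d2, m2, x):
            b = tilted if x == 1 else a
            w = cfg.exposure_prev if x == 1 else 1 - cfg.exposure_prev
            return w * b[d1, m1] * b[d2, m2]

    for d1 in range(2):
        for m1 in range(2):
            for d2 in range(2):
                for m2 in range(2):
                    for x in (0, 1):
                        mass = hap_mass(d1, m1, d2, m2, x)
                        key = (m1 + m2, x)
                        wt, ym = cells.get(key, (0.0, 0.0))
                        cells[key] = (
                            wt + mass,
                            ym + mass * cfg._mean(d1 + d2, x),
                        )
    for (g, x), (wt, ysum) in sorted(cells.items()):
        rows.append(
            {
                "marker_dosage": g,
                "exposure": x,
                "weight": wt,
                "outcome": ysum / wt if wt > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)
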