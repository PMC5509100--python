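"""Reproducibility model: P(bound | ranks) from two bound-condition replicates.

A genuine binding site produces high, positively correlated footprint
scores in both replicates, while noise produces uncorrelated background
scores. Following the irreproducible-discovery-rate (IDR) mixture idea, the
probit-transformed replicate ranks (z1, z2) are modelled as a two-component
bivariate normal mixture:

* irreproducible component (weight 1 - pi1): standard bivariate normal,
  correlation 0;
* reproducible component (weight pi1): mean (mu, mu) with mu >= 0,
  covariance sigma2 * [[1, rho], [rho, 1]] with rho in [0, 1).

The EM fit below estimates (pi1, mu, sigma2, rho); the posterior of the
reproducible component is the per-site reproducibility score. The binding
probability used downstream, P(A | R), is that posterior expressed as a
monotone function of the mean bound-condition rank via isotonic regression
(deterministic, monotone by construction, no bin-width parameter).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from scipy.special import logsumexp
from sklearn.isotonic import IsotonicRegression

__all__ = [
    "ReproducibilityModel",
    "PACurve",
    "ReproInit",
    "fit_repro",
    "posterior_repro",
    "pA_from_mean_rank",
    "mixture_loglik",
    "simulate_repro_pairs",
    "DegenerateFitError",
]

_LOG_2PI = np.log(2.0 * np.pi)


class DegenerateFitError(RuntimeError):
    """Raised when EM collapses onto a single component.

    The ``model`` attribute carries the boundary parameter estimates (e.g.
    the perfect-correlation limit drives rho to its cap while the mixing
    weight escapes to 1), so the failure is inspectable.
    """

    def __init__(self, message: str, model: "ReproducibilityModel | None" = None):
        super().__init__(message)
        self.model = model


_RHO_MAX = 0.999  # keeps the reproducible-cluster density bounded


@dataclasses.dataclass
class ReproInit:
    """EM starting point (fixed defaults, logged with every fit)."""

    pi1: float = 0.5
    mu: float = 1.0
    sigma2: float = 1.0
    rho: float = 0.5


@dataclasses.dataclass
class PACurve:
    """Monotone map mean bound-condition rank -> P(bound), as interp knots."""

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if np.any(np.diff(self.x) < 0) or np.any(np.diff(self.y) < -1e-12):
            raise ValueError("PACurve knots must be nondecreasing")

    def __call__(self, mean_ranks: np.ndarray) -> np.ndarray:
        # np.interp clips outside the knot range, keeping the curve bounded
        return np.interp(np.asarray(mean_ranks, dtype=float), self.x, self.y)


@dataclasses.dataclass
class ReproducibilityModel:
    pi1: float
    mu: float
    sigma2: float
    rho: float
    loglik_trace: list[float] = dataclasses.field(default_factory=list)
    converged: bool = True
    n_sites: int | None = None
    pa_curve: PACurve | None = None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "pi1": self.pi1,
            "mu": self.mu,
            "sigma2": self.sigma2,
            "rho": self.rho,
            "loglik_trace": list(self.loglik_trace),
            "converged": self.converged,
            "n_sites": self.n_sites,
        }
        if self.pa_curve is not None:
            payload["pa_curve"] = {
                "x": self.pa_curve.x.tolist(),
                "y": self.pa_curve.y.tolist(),
            }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "ReproducibilityModel":
        payload = json.loads(Path(path).read_text())
        curve = payload.pop("pa_curve", None)
        model = cls(**payload)
        if curve is not None:
            model.pa_curve = PACurve(np.array(curve["x"]), np.array(curve["y"]))
        return model


def _component_logpdfs(
    z1: np.ndarray, z2: np.ndarray, mu: float, sigma2: float, rho: float
) -> tuple[np.ndarray, np.ndarray]:
    """(log f0, log f1): background and reproducible bivariate-normal logpdfs."""
    log_f0 = -_LOG_2PI - 0.5 * (z1 * z1 + z2 * z2)
    d1 = z1 - mu
    d2 = z2 - mu
    one_m_r2 = 1.0 - rho * rho
    log_det = 2.0 * np.log(sigma2) + np.log(one_m_r2)
    quad = (d1 * d1 + d2 * d2 - 2.0 * rho * d1 * d2) / (sigma2 * one_m_r2)
    log_f1 = -_LOG_2PI - 0.5 * log_det - 0.5 * quad
    return log_f0, log_f1


def mixture_loglik(
    z1: np.ndarray,
    z2: np.ndarray,
    pi1: float,
    mu: float,
    sigma2: float,
    rho: float,
) -> float:
    """Observed-data log-likelihood of the two-component mixture."""
    log_f0, log_f1 = _component_logpdfs(z1, z2, mu, sigma2, rho)
    with np.errstate(divide="ignore"):
        terms = np.stack(
            [np.log1p(-pi1) + log_f0, np.log(pi1) + log_f1], axis=0
        )
    return float(logsumexp(terms, axis=0).sum())


def fit_repro(
    z1: np.ndarray,
    z2: np.ndarray,
    init: ReproInit | None = None,
    max_iter: int = 500,
    tol: float = 1e-6,
    min_sites: int = 100,
) -> ReproducibilityModel:
    """EM fit of the reproducible/irreproducible mixture on probit ranks.

    The observed-data log-likelihood is recorded every iteration and is
    nondecreasing; convergence is declared when its relative change falls
    below ``tol``. Raises :class:`DegenerateFitError` when the reproducible
    weight collapses to 0 or 1.
    """
    z1 = np.asarray(z1, dtype=float)
    z2 = np.asarray(z2, dtype=float)
    if z1.shape != z2.shape or z1.ndim != 1:
        raise ValueError("z1 and z2 must be 1-D arrays of equal length")
    if len(z1) < min_sites:
        raise ValueError(f"need at least {min_sites} sites to fit the mixture")
    if not (np.isfinite(z1).all() and np.isfinite(z2).all()):
        raise ValueError("probit columns must be finite")

    init = init or ReproInit()
    pi1, mu, sigma2, rho = init.pi1, init.mu, init.sigma2, init.rho
    trace: list[float] = []
    converged = False
    for _ in range(max_iter):
        log_f0, log_f1 = _component_logpdfs(z1, z2, mu, sigma2, rho)
        lw1 = np.log(pi1) + log_f1
        lw0 = np.log1p(-pi1) + log_f0
        norm = np.logaddexp(lw0, lw1)
        trace.append(float(norm.sum()))
        gamma = np.exp(lw1 - norm)

        s = gamma.sum()
        if 1e-8 < s < len(z1) - 1e-8:
            pi1 = s / len(z1)
            mu = max(0.0, float((gamma * (z1 + z2)).sum() / (2.0 * s)))
            d1 = z1 - mu
            d2 = z2 - mu
            sigma2 = max(1e-8, float((gamma * (d1 * d1 + d2 * d2)).sum() / (2.0 * s)))
            rho = float((gamma * d1 * d2).sum() / (s * sigma2))
            rho = min(max(rho, 0.0), _RHO_MAX)

        if len(trace) >= 2:
            prev, cur = trace[-2], trace[-1]
            if abs(cur - prev) <= tol * abs(prev):
                converged = True
                break
    if not (1e-4 < pi1 < 1.0 - 1e-4):
        boundary = ReproducibilityModel(
            pi1=pi1, mu=mu, sigma2=sigma2, rho=rho,
            loglik_trace=trace, converged=converged, n_sites=len(z1),
        )
        raise DegenerateFitError(
            f"degenerate mixing weight pi1={pi1:.3g}; provide more data or a "
            "different init",
            model=boundary,
        )
    return ReproducibilityModel(
        pi1=pi1,
        mu=mu,
        sigma2=sigma2,
        rho=rho,
        loglik_trace=trace,
        converged=converged,
        n_sites=len(z1),
    )


def posterior_repro(
    model: ReproducibilityModel, z1: np.ndarray, z2: np.ndarray
) -> np.ndarray:
    """Bayes posterior of the reproducible component, per site, in [0, 1]."""
    z1 = np.asarray(z1, dtype=float)
    z2 = np.asarray(z2, dtype=float)
    if model.pi1 <= 0.0:
        return np.zeros_like(z1)
    if model.pi1 >= 1.0:
        return np.ones_like(z1)
    log_f0, log_f1 = _component_logpdfs(z1, z2, model.mu, model.sigma2, model.rho)
    lw1 = np.log(model.pi1) + log_f1
    lw0 = np.log1p(-model.pi1) + log_f0
    return np.exp(lw1 - np.logaddexp(lw0, lw1))


def pA_from_mean_rank(
    posteriors: np.ndarray, mean_ranks: np.ndarray
) -> PACurve:
    """Monotone P(bound) as a function of mean bound-condition rank.

    Isotonic (nondecreasing) regression of the reproducibility posterior on
    the mean rank; the pooled-adjacent-violators solution is returned as
    interpolation knots evaluable at any rank.
    """
    posteriors = np.asarray(posteriors, dtype=float)
    mean_ranks = np.asarray(mean_ranks, dtype=float)
    if posteriors.shape != mean_ranks.shape:
        raise ValueError("posterior and mean-rank columns must be aligned")
    ok = np.isfinite(posteriors) & np.isfinite(mean_ranks)
    iso = IsotonicRegression(y_min=0.0, y_max=1.0, increasing=True)
    iso.fit(mean_ranks[ok], posteriors[ok])
    return PACurve(iso.X_thresholds_, iso.y_thresholds_)


def simulate_repro_pairs(
    pi1: float,
    mu: float,
    sigma2: float,
    rho: float,
    n: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw (z1, z2, is_reproducible) from the mixture model itself."""
    is_repro = rng.random(n) < pi1
    z = rng.standard_normal((n, 2))
    # correlate the reproducible rows: z2 <- rho*z1 + sqrt(1-rho^2)*z2
    sd = np.sqrt(sigma2)
    z1 = np.where(is_repro, mu + sd * z[:, 0], z[:, 0])
    z2_rep = mu + sd * (rho * z[:, 0] + np.sqrt(1.0 - rho * rho) * z[:, 1])
    z2 = np.where(is_repro, z2_rep, z[:, 1])
    return z1, z2, is_repro
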