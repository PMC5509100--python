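"""Three-category mixture on rank differences: P(weaker unbound | bound, ranks).

Among reproducibly bound sites, the difference of per-condition mean ranks
D = R_bound - R_unbound separates three behaviours: no significant
difference, significantly weaker in the unbound condition (D >> 0; the
event of interest) and significantly stronger (D << 0). Within sliding
windows of bound-condition mean rank, D is modelled as a three-component
Gaussian mixture with constrained means (0, +delta, -delta), a null spread
sigma0 and a tied shifted-component spread sigma1. Conditioning on the site
being bound is soft: every site enters the weighted EM with its
reproducibility posterior as case weight, so no arbitrary bound/unbound
cutoff is introduced.

Window scheme: ``n_windows`` windows over the sites sorted by
bound-condition mean rank, each holding ``window_frac`` of the sites, with
starts spaced so that consecutive windows overlap by about half. Posterior
evaluation blends the two windows whose centers bracket a site's mean rank.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
from scipy.special import logsumexp

from .rank_transform import RankTable

__all__ = [
    "WindowConfig",
    "DiffEMConfig",
    "WindowParams",
    "DiffMixtureModel",
    "fit_three_component",
    "fit_diff_mixture",
    "posterior_categories",
    "posterior_B",
]

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)

#: category order used throughout: same, weaker unbound (+delta), stronger
#: unbound (-delta)
CATEGORIES = ("same", "lower_unbound", "higher_unbound")


@dataclasses.dataclass
class WindowConfig:
    n_windows: int = 20
    window_frac: float = 0.10
    min_effective: float = 50.0  # minimum summed case weight to fit a window


@dataclasses.dataclass
class DiffEMConfig:
    weights_init: tuple[float, float, float] = (0.8, 0.1, 0.1)
    max_iter: int = 500
    tol: float = 1e-6
    sigma_floor: float = 1.0  # rank units; guards degenerate components


@dataclasses.dataclass
class WindowParams:
    center: float
    weights: tuple[float, float, float]  # (pi_same, pi_lower, pi_higher)
    delta: float
    sigma0: float
    sigma1: float
    n_effective: float
    borrowed: bool = False


@dataclasses.dataclass
class DiffMixtureModel:
    windows: list[WindowParams]
    n_sites: int | None = None

    @property
    def centers(self) -> np.ndarray:
        return np.array([w.center for w in self.windows])

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_sites": self.n_sites,
            "windows": [dataclasses.asdict(w) for w in self.windows],
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "DiffMixtureModel":
        payload = json.loads(Path(path).read_text())
        windows = [
            WindowParams(**{**w, "weights": tuple(w["weights"])})
            for w in payload["windows"]
        ]
        return cls(windows=windows, n_sites=payload.get("n_sites"))


def _norm_logpdf(x: np.ndarray, mean: float, sigma: float) -> np.ndarray:
    z = (x - mean) / sigma
    return -_LOG_SQRT_2PI - np.log(sigma) - 0.5 * z * z


def _weighted_sd(d: np.ndarray, w: np.ndarray) -> float:
    m = float((w * d).sum() / w.sum())
    return float(np.sqrt((w * (d - m) ** 2).sum() / w.sum()))


def fit_three_component(
    d: np.ndarray,
    case_weights: np.ndarray | None = None,
    em: DiffEMConfig | None = None,
) -> tuple[tuple[float, float, float], float, float, float, list[float]]:
    """Weighted EM for the constrained three-Gaussian mixture on D.

    Returns ``(weights, delta, sigma0, sigma1, loglik_trace)`` with
    component means fixed at (0, +delta, -delta). The weighted
    log-likelihood is nondecreasing across iterations.
    """
    em = em or DiffEMConfig()
    d = np.asarray(d, dtype=float)
    w = np.ones_like(d) if case_weights is None else np.asarray(case_weights, float)
    if d.shape != w.shape:
        raise ValueError("d and case_weights must be aligned")
    if w.sum() <= 0:
        raise ValueError("total case weight must be positive")

    pis = np.array(em.weights_init, dtype=float)
    pis = pis / pis.sum()
    sd = _weighted_sd(d, w)
    delta = max(sd, em.sigma_floor)
    sigma0 = max(0.5 * sd, em.sigma_floor)
    sigma1 = max(0.5 * sd, em.sigma_floor)

    trace: list[float] = []
    for _ in range(em.max_iter):
        means = (0.0, delta, -delta)
        sigmas = (sigma0, sigma1, sigma1)
        with np.errstate(divide="ignore"):
            log_comp = np.stack(
                [
                    np.log(pis[c]) + _norm_logpdf(d, means[c], sigmas[c])
                    for c in range(3)
                ],
                axis=0,
            )
        norm = logsumexp(log_comp, axis=0)
        trace.append(float((w * norm).sum()))
        resp = np.exp(log_comp - norm)  # 3 x N

        wr = resp * w  # weighted responsibilities
        totals = wr.sum(axis=1)
        pis = totals / totals.sum()

        shifted = totals[1] + totals[2]
        if shifted > 0:
            delta = float((wr[1] * d - wr[2] * d).sum() / shifted)
            # a shift below the spread floor is not a significant difference
            delta = max(delta, em.sigma_floor)
        if totals[0] > 0:
            sigma0 = float(np.sqrt((wr[0] * d * d).sum() / totals[0]))
        if shifted > 0:
            sq = (wr[1] * (d - delta) ** 2 + wr[2] * (d + delta) ** 2).sum()
            sigma1 = float(np.sqrt(sq / shifted))
        sigma0 = max(sigma0, em.sigma_floor)
        sigma1 = max(sigma1, em.sigma_floor)

        if len(trace) >= 2 and abs(trace[-1] - trace[-2]) <= em.tol * abs(trace[-2]):
            break
    return tuple(float(p) for p in pis), delta, sigma0, sigma1, trace


def _window_slices(n: int, cfg: WindowConfig) -> list[tuple[int, int]]:
    """Start/stop index pairs over the rank-sorted sites."""
    width = max(2, int(round(cfg.window_frac * n)))
    width = min(width, n)
    if cfg.n_windows == 1 or width == n:
        return [(0, n)]
    starts = np.linspace(0, n - width, cfg.n_windows)
    return [(int(round(s)), int(round(s)) + width) for s in starts]


def fit_diff_mixture(
    rank_table: RankTable,
    repro_posteriors: np.ndarray,
    window: WindowConfig | None = None,
    em: DiffEMConfig | None = None,
) -> DiffMixtureModel:
    """Fit the per-window three-category mixture on mean-rank differences.

    Sites are weighted by their reproducibility posterior, implementing the
    conditioning on the bound event without a hard threshold. Windows whose
    summed weight falls below ``window.min_effective`` borrow parameters
    from the nearest fitted window (with a warning).
    """
    window = window or WindowConfig()
    em = em or DiffEMConfig()
    repro_posteriors = np.asarray(repro_posteriors, dtype=float)
    if len(repro_posteriors) != rank_table.n_sites:
        raise ValueError("posterior column length does not match rank table")

    complete = rank_table.complete_mask
    d_all = rank_table.rank_diff[complete]
    mean_bound = rank_table.mean_bound[complete]
    w_all = repro_posteriors[complete]
    order = np.argsort(mean_bound, kind="stable")
    d_sorted = d_all[order]
    w_sorted = w_all[order]
    r_sorted = mean_bound[order]

    windows: list[WindowParams] = []
    pending: list[int] = []
    for lo, hi in _window_slices(len(d_sorted), window):
        d_win = d_sorted[lo:hi]
        w_win = w_sorted[lo:hi]
        center = float(r_sorted[lo:hi].mean())
        n_eff = float(w_win.sum())
        if n_eff < window.min_effective:
            windows.append(
                WindowParams(center, (1.0, 0.0, 0.0), 1.0, 1.0, 1.0, n_eff, True)
            )
            pending.append(len(windows) - 1)
            continue
        pis, delta, s0, s1, _ = fit_three_component(d_win, w_win, em)
        windows.append(WindowParams(center, pis, delta, s0, s1, n_eff))

    fitted = [i for i, w in enumerate(windows) if not w.borrowed]
    if not fitted:
        raise ValueError(
            "no window reached the minimum effective weight "
            f"({window.min_effective}); nothing to fit"
        )
    for i in pending:
        j = min(fitted, key=lambda k: abs(windows[k].center - windows[i].center))
        src = windows[j]
        windows[i] = WindowParams(
            windows[i].center,
            src.weights,
            src.delta,
            src.sigma0,
            src.sigma1,
            windows[i].n_effective,
            borrowed=True,
        )
        warnings.warn(
            f"window at mean rank {windows[i].center:.1f} had effective weight "
            f"{windows[i].n_effective:.1f} < {window.min_effective}; borrowed "
            f"parameters from window at {src.center:.1f}",
            stacklevel=2,
        )
    return DiffMixtureModel(windows=windows, n_sites=rank_table.n_sites)


def _window_posterior(params: WindowParams, d: np.ndarray) -> np.ndarray:
    """N x 3 category posteriors for values ``d`` under one window's mixture."""
    means = (0.0, params.delta, -params.delta)
    sigmas = (params.sigma0, params.sigma1, params.sigma1)
    with np.errstate(divide="ignore"):
        log_comp = np.stack(
            [
                (np.log(params.weights[c]) if params.weights[c] > 0 else -np.inf)
                + _norm_logpdf(d, means[c], sigmas[c])
                for c in range(3)
            ],
            axis=1,
        )
    return np.exp(log_comp - logsumexp(log_comp, axis=1, keepdims=True))


def posterior_categories(
    model: DiffMixtureModel, rank_table: RankTable
) -> np.ndarray:
    """Per-site three-category posteriors (columns: same, lower, higher).

    Each site is evaluated under the windows whose centers bracket its
    bound-condition mean rank, blending the two posteriors linearly; sites
    outside the center range use the nearest window. Rows with missing
    ranks are NaN.
    """
    if model.n_sites is not None and model.n_sites != rank_table.n_sites:
        raise ValueError(
            f"model fitted on {model.n_sites} sites, table has "
            f"{rank_table.n_sites}"
        )
    d = rank_table.rank_diff
    r = rank_table.mean_bound
    out = np.full((rank_table.n_sites, 3), np.nan)
    ok = np.isfinite(d) & np.isfinite(r)

    centers = model.centers
    order = np.argsort(centers)
    centers = centers[order]
    wins = [model.windows[i] for i in order]

    idx = np.searchsorted(centers, r[ok])  # first center >= r
    lo = np.clip(idx - 1, 0, len(wins) - 1)
    hi = np.clip(idx, 0, len(wins) - 1)
    span = centers[hi] - centers[lo]
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(span > 0, (r[ok] - centers[lo]) / np.where(span > 0, span, 1), 0.0)
    t = np.clip(t, 0.0, 1.0)

    post = np.zeros((ok.sum(), 3))
    d_ok = d[ok]
    for k, w in enumerate(wins):
        sel_lo = lo == k
        sel_hi = hi == k
        if sel_lo.any() or sel_hi.any():
            pk = _window_posterior(w, d_ok)
            post += np.where(sel_lo[:, None], (1.0 - t)[:, None] * pk, 0.0)
            post += np.where(sel_hi[:, None], t[:, None] * pk, 0.0)
    out[ok] = post
    return out


def posterior_B(model: DiffMixtureModel, rank_table: RankTable) -> np.ndarray:
    """P(significantly weaker in the unbound condition | bound, ranks)."""
    return posterior_categories(model, rank_table)[:, 1]
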