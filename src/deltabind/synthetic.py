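"""Synthetic data with the statistical structure the method assumes.

The generator plants three latent site states at study-condition rates —
unbound (background), bound in both conditions, and bound only in the
bound condition (the differential class, prevalence 0.4% by default, the
average rate observed across factors; the per-factor range is roughly
0.1-1.3%). Replicate scores are drawn on a latent probit scale: bound
states produce correlated draws from the reproducible cluster
N((mu, mu), sigma2 [[1, rho], [rho, 1]]), background produces independent
standard normals, and the unbound-condition mean of differential sites is
shifted down by ``delta``. Per-site read counts for the count-difference
baseline are drawn as Poisson variates whose rate mixes the binding signal
with a large site-specific accessibility term, mimicking why aggregate
counts rank differential sites poorly.

Because the generator simulates the model's own assumptions, parameter
recovery on its output is a test of the implementation, not of the model's
biological adequacy (see docs/methods.md).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .sites_io import CandidateSite, ScoreSchema, ScoreTable, TruthLabels

__all__ = ["SimConfig", "simulate_scores", "simulate_sitestats"]

STATE_UNBOUND = "unbound"
STATE_BOUND_BOTH = "bound_both"
STATE_DIFFERENTIAL = "bound_K_only"


@dataclasses.dataclass
class SimConfig:
    """Study conditions for the generator (defaults = the emulated setting)."""

    n_sites: int = 100_000
    prevalence_differential: float = 0.004
    frac_bound: float = 0.10  # fraction of sites bound in the bound condition
    mu: float = 2.0  # reproducible-cluster mean shift (probit units)
    sigma2: float = 1.0  # reproducible-cluster marginal variance
    rho: float = 0.8  # reproducible-cluster replicate correlation
    delta: float = 2.0  # latent down-shift of differential sites, unbound cond.
    n_replicates_unbound: int = 2  # 1 or 2
    motif_width: int = 19
    site_spacing: int = 1_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 100:
            raise ValueError("n_sites must be at least 100")
        for name in ("prevalence_differential", "frac_bound"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.prevalence_differential > self.frac_bound:
            raise ValueError(
                "prevalence_differential exceeds frac_bound: differential "
                "sites must be bound in the bound condition"
            )
        if self.n_replicates_unbound not in (1, 2):
            raise ValueError("n_replicates_unbound must be 1 or 2")


def _make_sites(cfg: SimConfig) -> pd.DataFrame:
    start = np.arange(cfg.n_sites, dtype=int) * cfg.site_spacing + 100
    return pd.DataFrame(
        {
            "chrom": "chrS",
            "start": start,
            "end": start + cfg.motif_width,
            "strand": ".",
        }
    )


def simulate_scores(
    config: SimConfig,
) -> tuple[ScoreTable, TruthLabels, pd.DataFrame]:
    """Draw a score table, its truth labels, and the latent-state table.

    The latent table records every draw: the planted state, the latent
    replicate scores per condition, and the per-condition read counts used
    by the count-difference baseline.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_sites

    u = rng.random(n)
    state = np.where(
        u < cfg.prevalence_differential,
        STATE_DIFFERENTIAL,
        np.where(u < cfg.frac_bound, STATE_BOUND_BOTH, STATE_UNBOUND),
    )
    bound_any = state != STATE_UNBOUND
    diff = state == STATE_DIFFERENTIAL

    # Bound sites carry one latent strength shared by all replicates and,
    # for bound-both sites, by both conditions. Decomposing the
    # reproducible cluster as strength ~ N(mu, rho*sigma2) plus replicate
    # noise N(0, (1-rho)*sigma2) yields exactly the cluster the
    # reproducibility model assumes: marginal N(mu, sigma2), replicate
    # correlation rho. Sharing the strength across conditions is what makes
    # "no significant rank difference" the typical bound-both behaviour.
    strength = cfg.mu + np.sqrt(cfg.rho * cfg.sigma2) * rng.standard_normal(n)
    rep_sd = np.sqrt((1.0 - cfg.rho) * cfg.sigma2)

    noise_bound = rng.standard_normal((n, 2))
    z_bound = np.where(
        bound_any[:, None],
        strength[:, None] + rep_sd * noise_bound,
        rng.standard_normal((n, 2)),
    )

    # unbound condition: bound-both keeps the same strength, differential
    # sites are shifted down by delta on the latent scale, background stays
    # independent standard normal
    strength_unbound = np.where(diff, strength - cfg.delta, strength)
    noise_unbound = rng.standard_normal((n, 2))
    z_unbound = np.where(
        bound_any[:, None],
        strength_unbound[:, None] + rep_sd * noise_unbound,
        rng.standard_normal((n, 2)),
    )

    # Window read counts: dominated by a per-site accessibility term plus
    # condition-level accessibility noise unrelated to factor binding; the
    # footprint occupies a small part of the window, so binding contributes
    # only weakly. This is what makes aggregate count differences a poor
    # differential-binding ranker even though counts do respond to binding.
    access = rng.normal(3.0, 1.0, size=n)
    cond_noise = rng.normal(0.0, 0.4, size=(n, 2))
    mean_bound_lat = np.where(bound_any, strength, 0.0)
    mean_unbound_lat = np.where(bound_any, strength_unbound, 0.0)
    lam_bound = np.exp(access + cond_noise[:, 0] + 0.15 * mean_bound_lat)
    lam_unbound = np.exp(access + cond_noise[:, 1] + 0.15 * mean_unbound_lat)
    counts_bound = rng.poisson(lam_bound)
    counts_unbound = rng.poisson(lam_unbound)

    sites = _make_sites(cfg)
    schema = ScoreSchema(bound="K", unbound="G")
    scores = pd.DataFrame({"K_rep1": z_bound[:, 0], "K_rep2": z_bound[:, 1]})
    scores["G_rep1"] = z_unbound[:, 0]
    if cfg.n_replicates_unbound == 2:
        scores["G_rep2"] = z_unbound[:, 1]
    table = ScoreTable(sites, scores, schema)

    labels = TruthLabels(pd.Series(diff, index=list(table.site_ids)))
    latent = pd.DataFrame(
        {
            "site_id": table.site_ids,
            "state": state,
            "z_K1": z_bound[:, 0],
            "z_K2": z_bound[:, 1],
            "z_G1": z_unbound[:, 0],
            "z_G2": z_unbound[:, 1],
            "counts_K": counts_bound,
            "counts_G": counts_unbound,
        }
    )
    return table, labels, latent


@dataclasses.dataclass
class StatsSimConfig:
    """Distributions of the per-site statistics around the planted truth.

    Nulls carry uniform count-test p-values, small exponential -log10
    q-values in both conditions and a standard-normal differential score.
    Planted differential sites carry Beta-skewed p-values, a significant
    bound-condition q-value and a well-separated differential score, so
    that they tend to pass every stage of the truth pipeline.
    """

    p_beta_a: float = 0.05
    p_beta_b: float = 20.0
    q_null_scale: float = 0.5  # exponential scale of null -log10 q
    q_pos_unbound_scale: float = 0.3
    q_pos_bound_offset: float = 3.2
    q_pos_bound_scale: float = 1.0
    diff_score_mean: float = 6.0  # positives' differential score, N(mean, 1)
    event_jitter: int = 10  # bp, |event center - motif center|


def simulate_sitestats(
    config: SimConfig,
    truth: TruthLabels,
    stats_config: StatsSimConfig | None = None,
) -> pd.DataFrame:
    """Draw the statistics table consumed by the ground-truth pipeline.

    Seeded from ``config.seed`` (offset so draws are independent of
    :func:`simulate_scores`); two calls with the same configs are
    byte-identical when written.
    """
    sc = stats_config or StatsSimConfig()
    rng = np.random.default_rng((config.seed, 1))
    ids = list(truth.labels.index)
    pos = truth.labels.to_numpy()
    n = len(ids)

    p = np.where(
        pos,
        rng.beta(sc.p_beta_a, sc.p_beta_b, size=n),
        rng.uniform(size=n),
    )
    p = np.clip(p, 1e-300, 1.0)
    q_un = np.where(
        pos,
        rng.exponential(sc.q_pos_unbound_scale, size=n),
        rng.exponential(sc.q_null_scale, size=n),
    )
    q_bd = np.where(
        pos,
        sc.q_pos_bound_offset + rng.exponential(sc.q_pos_bound_scale, size=n),
        rng.exponential(sc.q_null_scale, size=n),
    )
    diff_score = rng.standard_normal(n) + np.where(pos, sc.diff_score_mean, 0.0)
    order = np.argsort(-diff_score, kind="stable")
    diff_rank = np.empty(n, dtype=int)
    diff_rank[order] = np.arange(1, n + 1)

    sites = _make_sites(config)
    jitter = rng.integers(-sc.event_jitter, sc.event_jitter + 1, size=n)
    center = ((sites["start"] + sites["end"]) // 2).to_numpy() + jitter
    half = config.motif_width // 2

    return pd.DataFrame(
        {
            "site_id": ids,
            "chrom": sites["chrom"],
            "start": center - half,
            "end": center + half + 1,
            "neglog10_q_unbound": q_un,
            "neglog10_q_bound": q_bd,
            "p_count": p,
            "diff_rank": diff_rank,
            "in_count_set": p < 0.05,
        }
    )


def candidate_sites_from_table(table: ScoreTable) -> list[CandidateSite]:
    """The score table's sites as CandidateSite objects (for motif matching)."""
    return [
        CandidateSite(r.chrom, int(r.start), int(r.end), r.strand)
        for r in table.sites.itertuples(index=False)
    ]
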