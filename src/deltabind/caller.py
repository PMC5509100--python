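"""Final differential-binding calls and the two comparison rankers.

The differential-binding probability of a site is the product of the two
conditional pieces estimated upstream:

    P(differential | ranks) = P(bound | ranks) * P(weaker unbound | bound, ranks)

Also implemented here are the two reference rankers the method is compared
against: the raw score difference between conditions and the read-count
difference over a fixed window around each site (counts arrive precomputed).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .diff_mixture import (
    DiffEMConfig,
    DiffMixtureModel,
    WindowConfig,
    fit_diff_mixture,
    posterior_B,
)
from .rank_transform import RankTable, probit, to_ranks
from .reproducibility import (
    ReproInit,
    ReproducibilityModel,
    fit_repro,
    pA_from_mean_rank,
    posterior_repro,
)
from .sites_io import ScoreTable

__all__ = [
    "DifferentialCallSet",
    "call_differential",
    "baseline_score_diff",
    "baseline_readcount_diff",
    "PipelineResult",
    "fit_and_call",
]


@dataclasses.dataclass
class DifferentialCallSet:
    """Per-site probabilities and the resulting ranked call list.

    ``table`` columns: site coordinates, p_bound, p_weaker_unbound, score
    (their exact product) and call_rank (1 = strongest call; ties broken by
    site_id for platform-independent determinism). Row order matches the
    input site order; ranking is a separate column.
    """

    table: pd.DataFrame
    provenance: dict = dataclasses.field(default_factory=dict)

    @property
    def scores(self) -> np.ndarray:
        return self.table["score"].to_numpy()

    def top(self, k: int) -> pd.DataFrame:
        return self.table.sort_values("call_rank").head(k)

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def _call_ranks(scores: np.ndarray, site_ids: pd.Series) -> np.ndarray:
    """Descending-score competition order, ties by site_id; NaN scores last."""
    keys = np.where(np.isfinite(scores), scores, -np.inf)
    order = np.lexsort((site_ids.to_numpy(), -keys))
    ranks = np.empty(len(scores), dtype=int)
    ranks[order] = np.arange(1, len(scores) + 1)
    return ranks


def call_differential(
    rank_table: RankTable,
    repro_model: ReproducibilityModel,
    diff_model: DiffMixtureModel,
    sites: pd.DataFrame | None = None,
) -> DifferentialCallSet:
    """Combine the two fitted models into per-site differential calls."""
    if repro_model.pa_curve is None:
        raise ValueError(
            "repro_model has no fitted P(bound) curve; run pA_from_mean_rank "
            "(or fit_and_call) first"
        )
    if repro_model.n_sites is not None and diff_model.n_sites is not None:
        if diff_model.n_sites != rank_table.n_sites:
            raise ValueError(
                f"diff model fitted on {diff_model.n_sites} sites, rank table "
                f"has {rank_table.n_sites}"
            )
    p_a = repro_model.pa_curve(rank_table.mean_bound)
    p_a = np.where(np.isfinite(rank_table.mean_bound), p_a, np.nan)
    p_b = posterior_B(diff_model, rank_table)
    score = p_a * p_b

    table = pd.DataFrame({"site_id": rank_table.site_ids})
    if sites is not None:
        table = sites.reset_index(drop=True).copy()
    table["p_bound"] = p_a
    table["p_weaker_unbound"] = p_b
    table["score"] = score
    table["call_rank"] = _call_ranks(score, rank_table.site_ids)
    return DifferentialCallSet(table=table)


def baseline_score_diff(scores: ScoreTable) -> np.ndarray:
    """Raw-score difference ranker: mean bound score minus mean unbound score."""
    return scores.bound_scores.mean(axis=1) - scores.unbound_scores.mean(axis=1)


def baseline_readcount_diff(
    counts_bound: np.ndarray, counts_unbound: np.ndarray
) -> np.ndarray:
    """Read-count difference ranker over the fixed per-site window.

    The counts are extracted upstream (600 bp window centered on the motif)
    and arrive as table columns; this op only forms the difference.
    """
    counts_bound = np.asarray(counts_bound, dtype=float)
    counts_unbound = np.asarray(counts_unbound, dtype=float)
    if counts_bound.shape != counts_unbound.shape:
        raise ValueError("count columns must be aligned")
    if (counts_bound < 0).any() or (counts_unbound < 0).any():
        raise ValueError("read counts must be nonnegative")
    return counts_bound - counts_unbound


@dataclasses.dataclass
class PipelineResult:
    calls: DifferentialCallSet
    rank_table: RankTable
    repro_model: ReproducibilityModel
    diff_model: DiffMixtureModel
    repro_posteriors: np.ndarray


def fit_and_call(
    scores: ScoreTable,
    repro_init: ReproInit | None = None,
    window: WindowConfig | None = None,
    em: DiffEMConfig | None = None,
) -> PipelineResult:
    """Run the full unsupervised pipeline on one score table.

    rank transform -> probit -> reproducibility EM on the two bound-condition
    replicates -> isotonic P(bound | mean rank) -> windowed three-category
    mixture on rank differences -> product score.
    """
    rank_table = to_ranks(scores)
    n = rank_table.n_ranked
    rep = rank_table.replicate_ranks(rank_table.bound)
    complete = rank_table.complete_mask
    z1 = probit(rep[complete, 0], n)
    z2 = probit(rep[complete, 1], n)
    repro_model = fit_repro(z1, z2, init=repro_init)

    posteriors = np.full(rank_table.n_sites, np.nan)
    posteriors[complete] = posterior_repro(repro_model, z1, z2)
    repro_model.pa_curve = pA_from_mean_rank(
        posteriors[complete], rank_table.mean_bound[complete]
    )

    diff_model = fit_diff_mixture(
        rank_table, np.nan_to_num(posteriors), window=window, em=em
    )
    calls = call_differential(rank_table, repro_model, diff_model, sites=scores.sites)
    return PipelineResult(calls, rank_table, repro_model, diff_model, posteriors)
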