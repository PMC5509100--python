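"""Rank-space standardisation of binding scores.

All downstream modelling operates on ranks rather than raw footprint
scores: each replicate column is replaced by its within-column rank (rank N
= strongest signal, ties averaged), which makes every later step invariant
to any strictly increasing distortion of the score scale and lets the same
machinery consume scores from any footprint caller.

The reproducibility fit additionally needs the ranks mapped to an
approximately standard-normal scale; :func:`probit` applies the normal
quantile function at the plotting position r/(N+1), which is symmetric and
finite at both extremes.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .sites_io import ScoreTable

__all__ = ["RankTable", "to_ranks", "probit"]


class RankTable:
    """Per-site ranks for every replicate plus per-condition mean ranks.

    ``ranks`` has one column ``rank_{condition}{r}`` per replicate and
    ``meanrank_{condition}`` per condition, aligned to the master site
    order. Rows with missing raw scores carry NaN ranks and are skipped by
    the model fits; ``n_ranked`` is the number of complete rows (the N that
    ranks run over).
    """

    def __init__(
        self,
        site_ids: pd.Series,
        ranks: pd.DataFrame,
        bound: str,
        unbound: str,
        n_ranked: int,
    ):
        self.site_ids = site_ids.reset_index(drop=True)
        self.ranks = ranks.reset_index(drop=True)
        self.bound = bound
        self.unbound = unbound
        self.n_ranked = n_ranked

    @property
    def n_sites(self) -> int:
        return len(self.ranks)

    @property
    def complete_mask(self) -> np.ndarray:
        return np.isfinite(self.ranks.to_numpy()).all(axis=1)

    def replicate_columns(self, condition: str) -> list[str]:
        prefix = f"rank_{condition}"
        return [c for c in self.ranks.columns if c.startswith(prefix)]

    def replicate_ranks(self, condition: str) -> np.ndarray:
        return self.ranks[self.replicate_columns(condition)].to_numpy()

    @property
    def mean_bound(self) -> np.ndarray:
        return self.ranks[f"meanrank_{self.bound}"].to_numpy()

    @property
    def mean_unbound(self) -> np.ndarray:
        return self.ranks[f"meanrank_{self.unbound}"].to_numpy()

    @property
    def rank_diff(self) -> np.ndarray:
        """Mean-rank difference bound - unbound; positive = weaker unbound."""
        return self.mean_bound - self.mean_unbound


def to_ranks(scores: ScoreTable) -> RankTable:
    """Rank each replicate column (average ties, rank N = strongest score).

    Only rows with a complete set of finite replicate scores participate in
    the ranking; incomplete rows receive NaN throughout.
    """
    if scores.n_sites < 2:
        raise ValueError("need at least 2 sites to rank")
    complete = scores.complete_mask
    n = int(complete.sum())
    if n < 2:
        raise ValueError("fewer than 2 complete rows after missing-data policy")
    out = pd.DataFrame(index=np.arange(scores.n_sites), dtype=float)
    schema = scores.schema
    for cond, cols in (
        (schema.bound, schema.bound_columns),
        (schema.unbound, schema.unbound_columns),
    ):
        rep_ranks = []
        for r, col in enumerate(cols, start=1):
            vals = scores.scores[col].to_numpy()[complete]
            if np.all(vals == vals[0]):
                warnings.warn(
                    f"score column {col!r} is constant; all ranks tied at (N+1)/2",
                    stacklevel=2,
                )
            ranked = np.full(scores.n_sites, np.nan)
            ranked[complete] = rankdata(vals, method="average")
            out[f"rank_{cond}{r}"] = ranked
            rep_ranks.append(ranked)
        out[f"meanrank_{cond}"] = np.nanmean(np.column_stack(rep_ranks), axis=1)
    return RankTable(scores.site_ids, out, schema.bound, schema.unbound, n)


def probit(ranks: np.ndarray, n: int) -> np.ndarray:
    """Normal-quantile transform of ranks: z = Phi^-1(r / (N+1)).

    Strictly increasing in rank and finite over the whole valid range
    [1, N]; the median rank maps to exactly 0.
    """
    r = np.asarray(ranks, dtype=float)
    valid = np.isnan(r) | ((r >= 1) & (r <= n))
    if not valid.all():
        bad = r[~valid][0]
        raise ValueError(f"rank {bad} outside [1, {n}]")
    return norm.ppf(r / (n + 1))
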