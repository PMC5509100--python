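"""High-confidence differential-event construction from per-site statistics.

The truth set is built from precomputed outputs of two independent callers
run on condition-matched ChIP-seq: a multi-condition peak caller that
yields per-condition binding q-values and an ordered differential-site
list, and a count-based test that yields a per-site p-value. Three stages,
applied in fixed order and each only removing sites:

1. agreement stopping rule: walk down the multi-condition caller's
   differential ranking and stop once the local (trailing-window)
   agreement with the count test drops below max-observed-proportion / 1.6;
2. threshold filter: keep sites with count-test p < 0.05, insignificant
   binding in the unbound condition (-log10 Q_unbound < 2.5), significant
   binding in the bound condition (-log10 Q_bound > 2.5) and a q-value
   contrast above 0.5;
3. motif proximity: keep events whose center lies within 20 bp of a
   candidate motif site's center, transferring the label to that site.

Running the upstream callers is out of scope here; their outputs arrive as
TSV tables (see :func:`deltabind.sites_io.read_stats_table`).
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .sites_io import CandidateSite, TruthLabels

logger = logging.getLogger(__name__)

__all__ = [
    "TruthSet",
    "agreement_cutoff",
    "threshold_filter",
    "match_to_motifs",
    "build_truth_set",
    "Q_UNBOUND_MAX",
    "Q_BOUND_MIN",
    "Q_CONTRAST_MIN",
    "P_COUNT_MAX",
    "AGREEMENT_DIVISOR",
    "MOTIF_MAX_DIST",
]

# filter constants (strict inequalities, as applied)
Q_UNBOUND_MAX = 2.5
Q_BOUND_MIN = 2.5
Q_CONTRAST_MIN = 0.5
P_COUNT_MAX = 0.05
AGREEMENT_DIVISOR = 1.6
MOTIF_MAX_DIST = 20


@dataclasses.dataclass
class TruthSet:
    """Surviving site_ids plus a per-site trace of which filters passed."""

    site_ids: list[str]
    trace: pd.DataFrame  # one row per input site, boolean filter columns

    def __len__(self) -> int:
        return len(self.site_ids)


def agreement_cutoff(
    agreement: np.ndarray | Sequence[float],
    local_window: int = 200,
) -> int:
    """Stopping rank for the caller-agreement walk.

    ``agreement`` is given in differential-rank order (rank 1 first) and
    holds, per site, its agreement with the count test — a boolean or a
    local proportion in [0, 1]. Walking down the list, the trailing mean
    over ``local_window`` entries is compared against (global max so far)
    / 1.6; the first rank where it falls below is returned, and sites from
    that rank on are to be excluded. The rule is only evaluated once a full
    window is available. If the proportion never drops, ``M + 1`` is
    returned (keep everything) and the event is logged.
    """
    x = np.asarray(agreement, dtype=float)
    if x.ndim != 1:
        raise ValueError("agreement must be a 1-D column")
    m = len(x)
    if m < local_window:
        raise ValueError(f"need at least local_window={local_window} sites, got {m}")
    if np.any((x < 0) | (x > 1)):
        raise ValueError("agreement values must lie in [0, 1]")

    csum = np.concatenate([[0.0], np.cumsum(x)])
    ks = np.arange(local_window, m + 1)
    trailing = (csum[ks] - csum[ks - local_window]) / local_window
    running_max = np.maximum.accumulate(trailing)
    below = trailing < running_max / AGREEMENT_DIVISOR
    if below.any():
        return int(ks[np.argmax(below)])
    logger.info(
        "agreement proportion never dropped below max/%s; keeping all %d sites",
        AGREEMENT_DIVISOR,
        m,
    )
    return m + 1


def apply_agreement_cutoff(
    stats: pd.DataFrame, local_window: int = 200
) -> tuple[pd.DataFrame, int]:
    """Drop the tail of the differential ranking past the agreement cutoff."""
    ordered = stats.sort_values("diff_rank", kind="stable")
    cutoff = agreement_cutoff(
        ordered["in_count_set"].to_numpy(dtype=float), local_window=local_window
    )
    keep_ids = set(ordered["site_id"].iloc[: cutoff - 1])
    return stats[stats["site_id"].isin(keep_ids)], cutoff


def threshold_filter(stats: pd.DataFrame) -> TruthSet:
    """Apply the four per-site statistic thresholds (all strict).

    Keeps sites with count-test p < 0.05, -log10 Q_unbound < 2.5,
    -log10 Q_bound > 2.5 and (-log10 Q_bound) - (-log10 Q_unbound) > 0.5.
    The returned trace records each filter per input site.
    """
    q_un = stats["neglog10_q_unbound"].to_numpy(float)
    q_bd = stats["neglog10_q_bound"].to_numpy(float)
    p = stats["p_count"].to_numpy(float)
    trace = pd.DataFrame(
        {
            "site_id": stats["site_id"].to_numpy(),
            "pass_p_count": p < P_COUNT_MAX,
            "pass_q_unbound": q_un < Q_UNBOUND_MAX,
            "pass_q_bound": q_bd > Q_BOUND_MIN,
            "pass_q_contrast": (q_bd - q_un) > Q_CONTRAST_MIN,
        }
    )
    keep = (
        trace["pass_p_count"]
        & trace["pass_q_unbound"]
        & trace["pass_q_bound"]
        & trace["pass_q_contrast"]
    )
    trace["kept"] = keep
    return TruthSet(site_ids=list(trace.loc[keep, "site_id"]), trace=trace)


def match_to_motifs(
    events: pd.DataFrame,
    motifs: Sequence[CandidateSite],
    max_dist: float = MOTIF_MAX_DIST,
) -> tuple[TruthLabels, pd.DataFrame]:
    """Match differential events to candidate motif sites within ``max_dist``.

    Distances are center-to-center; an event survives iff some motif center
    lies within ``max_dist`` bp on the same chromosome, the nearest motif
    wins and equal-distance ties break deterministically toward the
    lexicographically smaller site_id (with a warning). Returns the labels
    over all motif site_ids plus an event -> motif assignment table.
    """
    by_chrom: dict[str, list[CandidateSite]] = {}
    for m in motifs:
        by_chrom.setdefault(m.chrom, []).append(m)
    index = {}
    for chrom, ms in by_chrom.items():
        ms_sorted = sorted(ms, key=lambda s: (s.center, s.site_id))
        index[chrom] = (np.array([s.center for s in ms_sorted]), ms_sorted)

    rows = []
    for rec in events.itertuples(index=False):
        center = 0.5 * (rec.start + rec.end)
        matched_id = None
        dist = np.nan
        if rec.chrom in index:
            centers, ms_sorted = index[rec.chrom]
            i = int(np.searchsorted(centers, center))
            close = sorted(
                (abs(centers[j] - center), ms_sorted[j].site_id)
                for j in (i - 1, i, i + 1)
                if 0 <= j < len(ms_sorted) and abs(centers[j] - center) <= max_dist
            )
            if close:
                if len(close) > 1 and close[0][0] == close[1][0]:
                    warnings.warn(
                        f"event {rec.chrom}:{rec.start}-{rec.end} is equidistant "
                        f"from two motif sites; keeping {close[0][1]}",
                        stacklevel=2,
                    )
                dist, matched_id = close[0]
        rows.append(
            {
                "chrom": rec.chrom,
                "start": rec.start,
                "end": rec.end,
                "matched_site_id": matched_id,
                "distance": dist,
            }
        )
    assign = pd.DataFrame(rows)
    matched = sorted({s for s in assign["matched_site_id"] if s is not None})
    labels = TruthLabels.from_positive_ids([m.site_id for m in motifs], matched)
    return labels, assign


def build_truth_set(
    stats: pd.DataFrame,
    motifs: Sequence[CandidateSite],
    local_window: int = 200,
    max_dist: float = MOTIF_MAX_DIST,
) -> tuple[TruthLabels, dict]:
    """Full truth pipeline: agreement cutoff -> thresholds -> motif match.

    ``stats`` must carry event coordinates (chrom/start/end) in addition to
    the statistic columns. Returns labels over the motif site_ids and a
    summary of per-stage survivor counts.
    """
    for col in ("chrom", "start", "end"):
        if col not in stats.columns:
            raise ValueError(f"stats table lacks event coordinate column {col!r}")
    after_cut, cutoff = apply_agreement_cutoff(stats, local_window=local_window)
    truth = threshold_filter(after_cut)
    events = after_cut[after_cut["site_id"].isin(set(truth.site_ids))]
    labels, assign = match_to_motifs(
        events[["chrom", "start", "end"]], motifs, max_dist=max_dist
    )
    summary = {
        "n_input": len(stats),
        "agreement_cutoff_rank": cutoff,
        "n_after_agreement": len(after_cut),
        "n_after_thresholds": len(truth),
        "n_matched_to_motifs": labels.n_positive,
    }
    logger.info("truth-set construction: %s", summary)
    return labels, summary
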