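"""Ranking metrics under extreme class imbalance.

With roughly 400 true events per 100,000 candidate sites, accuracy is
meaningless and even AUROC is forgiving; the informative summaries are the
precision-recall curve (a random ranker's expected AUPR equals the
prevalence), precision at a fixed recall, and permutation p-values for the
observed metrics. Curve and area computations are delegated to
scikit-learn; the surrounding conventions (first-crossing precision at
recall, add-one permutation p-values, contingency summaries, group
comparison) live here.
"""

from __future__ import annotations

import dataclasses
from importlib import resources

import numpy as np
import pandas as pd
from scipy.stats import permutation_test
from sklearn.metrics import (
    average_precision_score,
    precision_recall_curve,
    roc_auc_score,
)

__all__ = [
    "PRCurve",
    "EvalResult",
    "ContingencyCounts",
    "precision_recall",
    "precision_at_recall",
    "auroc",
    "bootstrap_pvalue",
    "evaluate_ranking",
    "contingency_stats",
    "load_ctcf_snp_counts",
    "group_compare",
]


def _check_labels(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be aligned 1-D columns")
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    if labels.sum() == 0:
        raise ValueError("no positive labels")
    if labels.sum() == labels.size:
        raise ValueError("no negative labels")
    return scores, labels


@dataclasses.dataclass
class PRCurve:
    """Step-wise precision-recall curve over all score thresholds.

    Arrays follow scikit-learn's convention: ``thresholds`` increasing,
    ``precision``/``recall`` one element longer with a final (1, 0) point;
    tied scores form a single threshold. ``aupr`` is average precision (the
    un-interpolated estimator: mean over positives of the precision at
    their threshold).
    """

    precision: np.ndarray
    recall: np.ndarray
    thresholds: np.ndarray
    aupr: float
    n_pos: int
    n_neg: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"recall": self.recall[:-1], "precision": self.precision[:-1]}
        )


def precision_recall(scores: np.ndarray, labels: np.ndarray) -> PRCurve:
    scores, labels = _check_labels(scores, labels)
    precision, recall, thresholds = precision_recall_curve(labels, scores)
    aupr = float(average_precision_score(labels, scores))
    return PRCurve(
        precision=precision,
        recall=recall,
        thresholds=thresholds,
        aupr=aupr,
        n_pos=int(labels.sum()),
        n_neg=int((~labels).sum()),
    )


def precision_at_recall(curve: PRCurve, recall_level: float = 0.10) -> float:
    """Precision where the curve first reaches the requested recall.

    Scanning thresholds from strict to permissive, recall is nondecreasing;
    the precision reported is the one at the first (strictest) threshold
    whose recall is >= ``recall_level``. At recall 0 this is the precision
    of the top-ranked block alone.
    """
    if not 0.0 <= recall_level <= 1.0:
        raise ValueError("recall level must be in [0, 1]")
    # exclude the appended (precision=1, recall=0) end point
    rec = curve.recall[:-1]
    prec = curve.precision[:-1]
    ok = np.flatnonzero(rec >= recall_level)
    if len(ok) == 0:
        raise ValueError(
            f"recall level {recall_level} exceeds the maximum achievable "
            f"recall {rec.max():.4g}"
        )
    # thresholds increase along the array; the last qualifying index is the
    # strictest threshold reaching the recall level
    return float(prec[ok[-1]])


def auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve (Mann-Whitney with tie correction)."""
    scores, labels = _check_labels(scores, labels)
    return float(roc_auc_score(labels, scores))


def bootstrap_pvalue(
    scores: np.ndarray,
    labels: np.ndarray,
    metric: str = "aupr",
    n_resamples: int = 999,
    seed: int | np.random.Generator | None = None,
) -> float:
    """Label-permutation p-value for an observed AUPR or AUROC.

    p = (1 + #{permuted metric >= observed}) / (1 + n_resamples); the
    add-one estimator never returns 0 and attains its minimum
    1/(1 + n_resamples) when no permutation matches the observed ranking.
    """
    if n_resamples < 100:
        raise ValueError("n_resamples must be at least 100")
    scores, labels = _check_labels(scores, labels)
    if metric == "aupr":
        stat = lambda y: float(average_precision_score(y, scores))  # noqa: E731
    elif metric == "auroc":
        stat = lambda y: float(roc_auc_score(y, scores))  # noqa: E731
    else:
        raise ValueError(f"unknown metric {metric!r} (use 'aupr' or 'auroc')")
    observed = stat(labels)
    rng = np.random.default_rng(seed)
    hits = 0
    y = labels.copy()
    for _ in range(n_resamples):
        rng.shuffle(y)
        if stat(y) >= observed:
            hits += 1
    return (1 + hits) / (1 + n_resamples)


@dataclasses.dataclass
class EvalResult:
    aupr: float
    auroc: float
    precision_at: dict[float, float]
    n_pos: int
    n_neg: int
    bootstrap_p: dict[str, float] | None = None

    @property
    def prevalence(self) -> float:
        return self.n_pos / (self.n_pos + self.n_neg)

    def to_dict(self) -> dict:
        return {
            "aupr": self.aupr,
            "auroc": self.auroc,
            "precision_at": {str(k): v for k, v in self.precision_at.items()},
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
            "prevalence": self.prevalence,
            "bootstrap_p": self.bootstrap_p,
        }


def evaluate_ranking(
    scores: np.ndarray,
    labels: np.ndarray,
    recall_levels: tuple[float, ...] = (0.10,),
    n_resamples: int | None = None,
    seed: int | np.random.Generator | None = None,
) -> EvalResult:
    """One-stop summary: AUPR, AUROC, precision at recall, optional p-values."""
    curve = precision_recall(scores, labels)
    result = EvalResult(
        aupr=curve.aupr,
        auroc=auroc(scores, labels),
        precision_at={r: precision_at_recall(curve, r) for r in recall_levels},
        n_pos=curve.n_pos,
        n_neg=curve.n_neg,
    )
    if n_resamples:
        result.bootstrap_p = {
            m: bootstrap_pvalue(scores, labels, m, n_resamples, seed)
            for m in ("aupr", "auroc")
        }
    return result


# ---------------------------------------------------------------------------
# Contingency statistics (accessibility imbalance vs differential binding)
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class ContingencyCounts:
    """2x2 co-occurrence of an accessibility signal and a binding event.

    ``n_signal`` sites show differential accessibility, ``n_event`` show
    differential binding, ``n_both`` show both, out of ``n_total``.
    """

    n_total: int
    n_signal: int
    n_event: int
    n_both: int

    def __post_init__(self) -> None:
        if min(self.n_total, self.n_signal, self.n_event, self.n_both) < 0:
            raise ValueError("counts must be nonnegative")
        if self.n_both > min(self.n_signal, self.n_event):
            raise ValueError("n_both cannot exceed n_signal or n_event")
        if max(self.n_signal, self.n_event) > self.n_total:
            raise ValueError("marginal counts cannot exceed n_total")

    @property
    def n_nosignal(self) -> int:
        return self.n_total - self.n_signal

    @property
    def n_nosignal_noevent(self) -> int:
        return self.n_nosignal - (self.n_event - self.n_both)


def contingency_stats(counts: ContingencyCounts) -> dict[str, float]:
    """PPV/NPV of the accessibility signal for the binding event, plus
    marginal prevalences; fractions in [0, 1] (multiply by 100 to report)."""
    if counts.n_signal == 0:
        raise ValueError("n_signal is zero; PPV undefined")
    if counts.n_nosignal == 0:
        raise ValueError("n_nosignal is zero; NPV undefined")
    if counts.n_total == 0:
        raise ValueError("n_total is zero")
    return {
        "ppv": counts.n_both / counts.n_signal,
        "npv": counts.n_nosignal_noevent / counts.n_nosignal,
        "prevalence_event": counts.n_event / counts.n_total,
        "prevalence_signal": counts.n_signal / counts.n_total,
    }


def load_ctcf_snp_counts() -> ContingencyCounts:
    """The packaged CTCF/SNP co-occurrence table (see data/ for provenance)."""
    path = resources.files("deltabind.data").joinpath("ctcf_snp_contingency.tsv")
    with resources.as_file(path) as p:
        df = pd.read_csv(p, sep="\t", comment="#")
    counts = dict(zip(df["field"], df["count"]))
    return ContingencyCounts(
        n_total=int(counts["n_total"]),
        n_signal=int(counts["n_signal"]),
        n_event=int(counts["n_event"]),
        n_both=int(counts["n_both"]),
    )


# ---------------------------------------------------------------------------
# Two-group factor-class comparison
# ---------------------------------------------------------------------------

def group_compare(
    values_a: np.ndarray,
    values_b: np.ndarray,
    n_resamples: int = 100_000,
    seed: int | np.random.Generator | None = None,
) -> tuple[float, float]:
    """One-sided permutation test that group A's mean exceeds group B's.

    Returns (mean_a - mean_b, p-value). The test is exact whenever the
    number of distinct regroupings does not exceed ``n_resamples``.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    res = permutation_test(
        (a, b),
        statistic=lambda x, y, axis=-1: np.mean(x, axis=axis) - np.mean(y, axis=axis),
        permutation_type="independent",
        alternative="greater",
        n_resamples=n_resamples,
        rng=np.random.default_rng(seed),
        vectorized=True,
    )
    return float(a.mean() - b.mean()), float(res.pvalue)
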