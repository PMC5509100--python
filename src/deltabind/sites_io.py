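"""Candidate sites, score tables, statistics tables and their TSV/BED forms.

Conventions shared by every other module:

* Genomic coordinates are 0-based, half-open (BED convention).
* All tables join on ``site_id = "{chrom}:{start}-{end}:{strand}"``; nothing
  downstream ever reorders the master site list.
* A score table carries exactly two replicate columns for the bound
  condition and one or two for the unbound condition.
* Missing score cells do not abort a run: the affected rows are excluded
  from model fitting (with a logged count) but remain in every output with
  null probabilities.
"""

from __future__ import annotations

import dataclasses
import logging
import re
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CandidateSite",
    "ScoreSchema",
    "ScoreTable",
    "TruthLabels",
    "make_site_id",
    "read_sites_bed",
    "write_sites_bed",
    "read_score_table",
    "write_score_table",
    "read_stats_table",
    "write_stats_table",
    "STATS_COLUMNS",
]

VALID_STRANDS = ("+", "-", ".")
COORD_COLUMNS = ["chrom", "start", "end", "strand"]

#: required columns of a per-site statistics table (ground-truth inputs):
#: peak-caller q-values per condition (as -log10), the count-test p-value and
#: the multi-condition caller's differential rank (1 = most differential).
STATS_COLUMNS = [
    "site_id",
    "neglog10_q_unbound",
    "neglog10_q_bound",
    "p_count",
    "diff_rank",
]

_FLOAT_FMT = "%.10g"


def make_site_id(chrom: str, start: int, end: int, strand: str) -> str:
    """Canonical stable key for a site; round-trips through every writer."""
    return f"{chrom}:{start}-{end}:{strand}"


@dataclasses.dataclass(frozen=True)
class CandidateSite:
    """A candidate motif match in 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    motif_score: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(
                f"invalid strand {self.strand!r} (must be one of {VALID_STRANDS})"
            )

    @property
    def site_id(self) -> str:
        return make_site_id(self.chrom, self.start, self.end, self.strand)

    @property
    def center(self) -> float:
        return 0.5 * (self.start + self.end)


@dataclasses.dataclass
class ScoreSchema:
    """Names the conditions and replicate columns of a score table.

    When the column lists are left as ``None`` they are auto-detected from
    header names of the form ``{condition}_rep{r}`` (e.g. ``K_rep1``).
    """

    bound: str = "K"
    unbound: str = "G"
    bound_columns: list[str] | None = None
    unbound_columns: list[str] | None = None

    def detect(self, columns: Iterable[str]) -> "ScoreSchema":
        cols = list(columns)

        def matching(cond: str) -> list[str]:
            pat = re.compile(rf"^{re.escape(cond)}_rep(\d+)$")
            found = [(int(m.group(1)), c) for c in cols if (m := pat.match(c))]
            return [c for _, c in sorted(found)]

        return ScoreSchema(
            bound=self.bound,
            unbound=self.unbound,
            bound_columns=self.bound_columns or matching(self.bound),
            unbound_columns=self.unbound_columns or matching(self.unbound),
        )


class ScoreTable:
    """Per-site raw binding scores for two conditions.

    ``sites`` is a DataFrame with columns chrom/start/end/strand (plus a
    derived ``site_id``); ``scores`` holds one float column per
    (condition, replicate). Row order is preserved by every operation.
    """

    def __init__(self, sites: pd.DataFrame, scores: pd.DataFrame, schema: ScoreSchema):
        if len(sites) != len(scores):
            raise ValueError("sites and scores must have the same number of rows")
        sites = sites.reset_index(drop=True).copy()
        if "site_id" not in sites.columns:
            sites["site_id"] = [
                make_site_id(c, s, e, st)
                for c, s, e, st in zip(
                    sites["chrom"], sites["start"], sites["end"], sites["strand"]
                )
            ]
        dup = sites["site_id"][sites["site_id"].duplicated()]
        if len(dup):
            raise ValueError(f"duplicate site_id: {dup.iloc[0]!r}")
        if schema.bound_columns is None or schema.unbound_columns is None:
            schema = schema.detect(scores.columns)
        if len(schema.bound_columns) != 2:
            raise ValueError(
                f"bound condition {schema.bound!r} has "
                f"{len(schema.bound_columns)} replicate column(s); exactly two "
                "replicate experiments are required for the bound condition"
            )
        if len(schema.unbound_columns) not in (1, 2):
            raise ValueError(
                f"unbound condition {schema.unbound!r} has "
                f"{len(schema.unbound_columns)} replicate column(s); at least "
                "one (and at most two) is required"
            )
        self.sites = sites
        self.scores = scores.reset_index(drop=True).astype(float)
        self.schema = schema

    # -- basic accessors -------------------------------------------------
    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def site_ids(self) -> pd.Series:
        return self.sites["site_id"]

    @property
    def score_columns(self) -> list[str]:
        return list(self.schema.bound_columns) + list(self.schema.unbound_columns)

    @property
    def bound_scores(self) -> np.ndarray:
        return self.scores[self.schema.bound_columns].to_numpy()

    @property
    def unbound_scores(self) -> np.ndarray:
        return self.scores[self.schema.unbound_columns].to_numpy()

    @property
    def complete_mask(self) -> np.ndarray:
        """True where every replicate score is finite (rows used for fitting)."""
        return np.isfinite(self.scores[self.score_columns].to_numpy()).all(axis=1)


class TruthLabels:
    """Binary differential / non_differential labels keyed by site_id."""

    POSITIVE = "differential"
    NEGATIVE = "non_differential"

    def __init__(self, labels: pd.Series):
        if labels.index.has_duplicates:
            raise ValueError("duplicate site_id in truth labels")
        self.labels = labels.astype(bool)

    @classmethod
    def from_positive_ids(
        cls, site_ids: Sequence[str], positive_ids: Iterable[str]
    ) -> "TruthLabels":
        pos = set(positive_ids)
        unknown = pos.difference(site_ids)
        if unknown:
            raise ValueError(
                f"{len(unknown)} positive site_id(s) not in the site list, "
                f"e.g. {sorted(unknown)[0]!r}"
            )
        return cls(pd.Series([s in pos for s in site_ids], index=list(site_ids)))

    @property
    def n_positive(self) -> int:
        return int(self.labels.sum())

    def aligned_to(self, site_ids: Sequence[str]) -> np.ndarray:
        """Boolean vector over ``site_ids``; sites without a label are negative."""
        return self.labels.reindex(list(site_ids), fill_value=False).to_numpy()

    def write(self, path: str | Path) -> None:
        out = pd.DataFrame(
            {
                "site_id": self.labels.index,
                "label": np.where(self.labels.values, self.POSITIVE, self.NEGATIVE),
            }
        )
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path) -> "TruthLabels":
        df = pd.read_csv(path, sep="\t", dtype={"site_id": str})
        bad = set(df["label"]) - {cls.POSITIVE, cls.NEGATIVE}
        if bad:
            raise ValueError(f"unknown label value(s): {sorted(bad)}")
        return cls(pd.Series(df["label"].eq(cls.POSITIVE).values, index=df["site_id"]))


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_sites_bed(path: str | Path) -> list[CandidateSite]:
    """Read a 3-6 column BED file of candidate sites.

    Strand defaults to ``"."`` for BED3/4; column 5 (score) is stored as
    ``motif_score``. Raises with the 1-based line number on malformed lines.
    """
    sites: list[CandidateSite] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if not 3 <= len(fields) <= 6:
                raise ValueError(f"{path}:{lineno}: expected 3-6 BED columns")
            chrom, start_s, end_s = fields[:3]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise ValueError(
                    f"{path}:{lineno}: start >= end ({start} >= {end})"
                )
            score = None
            if len(fields) >= 5 and fields[4] not in (".", ""):
                score = float(fields[4])
            strand = fields[5] if len(fields) >= 6 else "."
            try:
                sites.append(CandidateSite(chrom, start, end, strand, score))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return sites


def write_sites_bed(sites: Iterable[CandidateSite], path: str | Path) -> None:
    """Write BED6; name = site_id, score = motif_score (0 when absent)."""
    with open(path, "w") as fh:
        for s in sites:
            score = 0.0 if s.motif_score is None else s.motif_score
            fh.write(
                f"{s.chrom}\t{s.start}\t{s.end}\t{s.site_id}\t"
                f"{_FLOAT_FMT % score}\t{s.strand}\n"
            )


# ---------------------------------------------------------------------------
# Score tables
# ---------------------------------------------------------------------------

def read_score_table(path: str | Path, schema: ScoreSchema | None = None) -> ScoreTable:
    """Read a TSV score table (coordinate columns + one column per replicate)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "strand": str})
    missing = [c for c in COORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing coordinate column(s) {missing}")
    schema = (schema or ScoreSchema()).detect(df.columns)
    if not schema.bound_columns and not schema.unbound_columns:
        raise ValueError(
            f"{path}: no replicate score columns found (expected e.g. "
            f"'{(schema or ScoreSchema()).bound}_rep1')"
        )
    sites = df[COORD_COLUMNS].copy()
    sites["start"] = sites["start"].astype(int)
    sites["end"] = sites["end"].astype(int)
    score_cols = list(schema.bound_columns) + list(schema.unbound_columns)
    table = ScoreTable(sites, df[score_cols], schema)
    n_incomplete = int((~table.complete_mask).sum())
    if n_incomplete:
        logger.warning(
            "%s: %d row(s) with missing scores; excluded from model fitting",
            path,
            n_incomplete,
        )
    return table


def write_score_table(table: ScoreTable, path: str | Path) -> None:
    """Write the canonical TSV form (coordinates, then replicate columns)."""
    out = table.sites[COORD_COLUMNS].copy()
    for col in table.score_columns:
        out[col] = table.scores[col].values
    out.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# Statistics tables (ground-truth construction inputs)
# ---------------------------------------------------------------------------

def read_stats_table(path: str | Path) -> pd.DataFrame:
    """Read a per-site statistics table used by the ground-truth pipeline.

    Requires :data:`STATS_COLUMNS`; event coordinates (chrom/start/end) are
    optional and only needed for motif-proximity matching. ``in_count_set``
    (count-test p below 0.05) is derived when absent.
    """
    df = pd.read_csv(path, sep="\t", dtype={"site_id": str})
    missing = [c for c in STATS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing statistics column(s) {missing}")
    for col in ("neglog10_q_unbound", "neglog10_q_bound"):
        vals = df[col].to_numpy(float)
        if not np.all(np.isfinite(vals)) or (vals < 0).any():
            raise ValueError(f"{path}: {col} must be finite and >= 0")
    p = df["p_count"].to_numpy(float)
    if ((p <= 0) | (p > 1)).any():
        raise ValueError(f"{path}: p_count must lie in (0, 1]")
    ranks = np.sort(df["diff_rank"].to_numpy(int))
    if not np.array_equal(ranks, np.arange(1, len(df) + 1)):
        raise ValueError(f"{path}: diff_rank must be a permutation of 1..M")
    if "in_count_set" not in df.columns:
        df = df.copy()
        df["in_count_set"] = df["p_count"] < 0.05
    return df


def write_stats_table(stats: pd.DataFrame, path: str | Path) -> None:
    stats.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
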