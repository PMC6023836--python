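"""Collation of miRNA->gene interactions from multiple resources.

Interaction tables are pandas frames with columns
``mirna_id, gene_id, resource, score, evidence, percentile, reference_ids``.
Predicted records carry resource-native scores filtered by creator-style
cutoffs and converted to percentiles (1 = top 1%); experimental records are
exempt from scoring.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

INTERACTION_COLUMNS = [
    "mirna_id", "gene_id", "resource", "score", "evidence", "percentile", "reference_ids",
]


@dataclass(frozen=True)
class ScoreCutoff:
    """Per-resource score threshold; ``direction`` says which scores are better."""

    threshold: float
    direction: Literal["higher", "lower"]

    def passes(self, score: float) -> bool:
        if self.direction == "higher":
            return score >= self.threshold
        return score <= self.threshold


def _empty_frame() -> pd.DataFrame:
    return pd.DataFrame(columns=INTERACTION_COLUMNS)


def _normalize(frame: pd.DataFrame) -> pd.DataFrame:
    for col in INTERACTION_COLUMNS:
        if col not in frame.columns:
            frame[col] = np.nan if col in ("score", "percentile") else ""
    return frame[INTERACTION_COLUMNS]


def read_interactions(
    path: str | Path,
    resource: str,
    evidence: Literal["predicted", "experimental"],
    direction: Literal["higher", "lower"] = "higher",
) -> pd.DataFrame:
    """Read one resource's interaction TSV.

    Requires ``mirna_id`` and ``gene_id`` columns; ``score`` and
    ``reference_ids`` are optional.  Duplicate (mirna, gene) pairs keep the
    best score (direction-aware) and are logged.
    """
    frame = pd.read_csv(path, sep="\t")
    missing = {"mirna_id", "gene_id"} - set(frame.columns)
    if missing:
        raise ValueError(f"interaction file {path} missing columns: {sorted(missing)}")
    frame = frame.copy()
    frame["resource"] = resource
    frame["evidence"] = evidence
    if "score" not in frame.columns:
        frame["score"] = np.nan

    dup_mask = frame.duplicated(subset=["mirna_id", "gene_id"], keep=False)
    if dup_mask.any():
        n_before = len(frame)
        ascending = direction == "lower"
        frame = (
            frame.sort_values("score", ascending=ascending, kind="stable")
            .drop_duplicates(subset=["mirna_id", "gene_id"], keep="first")
            .sort_index()
        )
        logger.info(
            "%s: collapsed %d duplicate pairs keeping best score", resource, n_before - len(frame)
        )
    return _normalize(frame).reset_index(drop=True)


def split_unified_table(
    frame: pd.DataFrame, directions: Mapping[str, str] | None = None
) -> dict[str, pd.DataFrame]:
    """Split a unified table (with a ``resource`` column) into per-resource frames."""
    if "resource" not in frame.columns:
        raise ValueError("unified interaction table needs a 'resource' column")
    out = {}
    for resource, sub in frame.groupby("resource", sort=True):
        out[resource] = _normalize(sub.copy()).reset_index(drop=True)
    return out


def filter_by_score(
    records: pd.DataFrame, cutoffs: Mapping[str, ScoreCutoff]
) -> pd.DataFrame:
    """Drop predicted records failing their resource cutoff; experimental
    records are always retained."""
    if records.empty:
        return records.copy()
    keep = np.ones(len(records), dtype=bool)
    for i, row in enumerate(records.itertuples(index=False)):
        if row.evidence == "experimental":
            continue
        cutoff = cutoffs.get(row.resource)
        if cutoff is None:
            raise ValueError(f"no score cutoff configured for predicted resource {row.resource!r}")
        keep[i] = cutoff.passes(row.score)
    out = records.loc[keep].reset_index(drop=True)
    logger.info("score filter: kept %d of %d records", len(out), len(records))
    return out


def score_to_percentile(
    records: pd.DataFrame, direction_of: Mapping[str, str]
) -> pd.DataFrame:
    """Attach integer percentiles 1..100 per resource (1 = top 1% of scores).

    Records are ranked best-to-worst; ties share the minimum rank of their
    group; percentile = ceil(100 * rank / N).  Experimental records keep no
    percentile.
    """
    out = records.copy()
    out["percentile"] = np.nan
    for resource, sub in records.groupby("resource"):
        if (sub["evidence"] == "experimental").all():
            continue
        scores = sub["score"].to_numpy(dtype=float)
        if np.isnan(scores).any():
            bad = sub.loc[sub["score"].isna()].iloc[0]
            raise ValueError(
                f"unscored predicted record in {resource!r}: "
                f"{bad['mirna_id']} -> {bad['gene_id']}"
            )
        direction = direction_of.get(resource, "higher")
        keyed = -scores if direction == "higher" else scores
        ranks = rankdata(keyed, method="min")
        pct = np.ceil(100.0 * ranks / len(ranks)).astype(int)
        out.loc[sub.index, "percentile"] = pct
    return out


def restrict_to_expressed(
    records: pd.DataFrame,
    expressed_genes: Iterable[str],
    expressed_mirnas: Iterable[str],
    mode: Literal["both", "either"] = "both",
) -> pd.DataFrame:
    """Keep interactions whose partners pass the expression filter.

    ``mode="both"`` (default) requires both partners expressed — the setting
    under which downstream correlations are computable.
    """
    genes = set(expressed_genes)
    mirnas = set(expressed_mirnas)
    g_ok = records["gene_id"].isin(genes)
    m_ok = records["mirna_id"].isin(mirnas)
    mask = (g_ok & m_ok) if mode == "both" else (g_ok | m_ok)
    out = records.loc[mask].reset_index(drop=True)
    logger.info("expression restriction (%s): kept %d of %d", mode, len(out), len(records))
    return out


def merge_resources(*record_frames: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Union per-resource records and summarize support per (mirna, gene) pair.

    Returns (unified records keyed by (mirna, gene, resource), per-pair
    summary with supporting resources, best percentile and an experimental
    flag).  Output order is canonical, so the merge is order-insensitive.
    """
    frames = [f for f in record_frames if f is not None and not f.empty]
    if not frames:
        empty_summary = pd.DataFrame(
            columns=["mirna_id", "gene_id", "n_resources", "resources",
                     "best_percentile", "has_experimental"]
        )
        return _empty_frame(), empty_summary
    unified = pd.concat([_normalize(f.copy()) for f in frames], ignore_index=True)
    unified = unified.drop_duplicates(subset=["mirna_id", "gene_id", "resource"])
    unified = unified.sort_values(["mirna_id", "gene_id", "resource"]).reset_index(drop=True)

    def summarize(group: pd.DataFrame) -> pd.Series:
        return pd.Series(
            {
                "n_resources": group["resource"].nunique(),
                "resources": ",".join(sorted(group["resource"].unique())),
                "best_percentile": group["percentile"].min(),
                "has_experimental": bool((group["evidence"] == "experimental").any()),
            }
        )

    summary = (
        unified.groupby(["mirna_id", "gene_id"], sort=True)
        .apply(summarize, include_groups=False)
        .reset_index()
    )
    logger.info("merged %d records into %d pairs", len(unified), len(summary))
    return unified, summary
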