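"""miRNA prioritization: DETG/DETGNC counting, anti-correlated regulator
counting, the stringent candidate filter, and template matching.

DETG = differentially expressed target gene of a miRNA; DETGNC = the
anti-correlated subset (Kendall tau below threshold, embryonic-only by
default).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .io import StageProfiles
from .network import DEFAULT_ANTICORR_THRESHOLD, kendall_tau

logger = logging.getLogger(__name__)

HEART_DEV = "heart_dev"
TX_REGULATOR = "tx_regulator"


def read_annotations(path: str | Path) -> dict[str, set[str]]:
    """Load a flat ``gene_id <tab> category`` table into a gene -> categories map."""
    frame = pd.read_csv(path, sep="\t")
    missing = {"gene_id", "category"} - set(frame.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    table: dict[str, set[str]] = {}
    for rec in frame.itertuples(index=False):
        table.setdefault(rec.gene_id, set()).add(rec.category)
    return table


def annotations_from_frame(frame: pd.DataFrame) -> dict[str, set[str]]:
    table: dict[str, set[str]] = {}
    for rec in frame.itertuples(index=False):
        table.setdefault(rec.gene_id, set()).add(rec.category)
    return table


def detg_stats(
    mirna_id: str, de_gene_ids: set[str], correlated: pd.DataFrame
) -> dict:
    """DETG/DETGNC counts for one miRNA.

    Zero-DETG miRNAs get an undefined (NaN) percentage and a flag rather
    than an error.
    """
    sub = correlated.loc[correlated["mirna_id"] == mirna_id]
    detg = set(sub["gene_id"]) & de_gene_ids
    detgnc = set(sub.loc[sub["is_anticorrelated"], "gene_id"]) & de_gene_ids
    n_detg, n_detgnc = len(detg), len(detgnc)
    pct = 100.0 * n_detgnc / n_detg if n_detg else float("nan")
    return {
        "mirna_id": mirna_id,
        "n_DETG": n_detg,
        "n_DETGNC": n_detgnc,
        "pct_DETGNC": pct,
        "pct_defined": n_detg > 0,
    }


def prioritization_table(
    correlated: pd.DataFrame,
    de_gene_ids: Iterable[str],
    annotations: Mapping[str, set[str]] | None = None,
    min_regulators: int = 10,
) -> pd.DataFrame:
    """One row per miRNA with all prioritization statistics."""
    de_gene_ids = set(de_gene_ids)
    annotations = annotations or {}
    rows = []
    for mirna_id in sorted(correlated["mirna_id"].unique()):
        record = detg_stats(mirna_id, de_gene_ids, correlated)
        sub = correlated.loc[
            (correlated["mirna_id"] == mirna_id) & correlated["is_anticorrelated"]
        ]
        anti_targets = set(sub["gene_id"])
        record["n_anticorr_regulators"] = sum(
            1 for g in anti_targets if TX_REGULATOR in annotations.get(g, ())
        )
        record["n_anticorr_heart_dev"] = sum(
            1 for g in anti_targets if HEART_DEV in annotations.get(g, ())
        )
        rows.append(record)
    table = pd.DataFrame(rows)
    if not table.empty:
        table["regulator_shortlisted"] = table["n_anticorr_regulators"] >= min_regulators
    return table


def count_anticorr_regulators(
    correlated: pd.DataFrame,
    annotations: Mapping[str, set[str]],
    min_count: int = 10,
) -> tuple[pd.DataFrame, list[str]]:
    """Per-miRNA counts of anti-correlated transcription-regulator targets,
    plus the shortlist of miRNAs with at least ``min_count`` of them."""
    table = prioritization_table(correlated, set(), annotations, min_regulators=min_count)
    if table.empty:
        return table, []
    counts = table[["mirna_id", "n_anticorr_regulators", "n_anticorr_heart_dev"]]
    shortlist = list(table.loc[table["regulator_shortlisted"], "mirna_id"])
    logger.info("%d miRNAs with >= %d anti-correlated regulators", len(shortlist), min_count)
    return counts, shortlist


def stringent_filter(
    correlated: pd.DataFrame,
    mirna_max_lfc: Mapping[str, float] | pd.Series,
    gene_max_lfc: Mapping[str, float] | pd.Series,
    annotations: Mapping[str, set[str]],
    lfc_threshold: float = 2.0,
    tau_threshold: float = DEFAULT_ANTICORR_THRESHOLD,
    tau_column: str = "tau_dev",
) -> pd.DataFrame:
    """Strictest candidate rule: both partners change at least
    ``2**lfc_threshold``-fold at some time point, tau below ``tau_threshold``,
    and the target carries the heart-development annotation."""
    mirna_max_lfc = dict(mirna_max_lfc)
    gene_max_lfc = dict(gene_max_lfc)
    rows = []
    for rec in correlated.itertuples(index=False):
        tau = getattr(rec, tau_column)
        if not np.isfinite(tau) or not tau < tau_threshold:
            continue
        m_lfc = mirna_max_lfc.get(rec.mirna_id, 0.0)
        g_lfc = gene_max_lfc.get(rec.gene_id, 0.0)
        if m_lfc < lfc_threshold or g_lfc < lfc_threshold:
            continue
        if HEART_DEV not in annotations.get(rec.gene_id, ()):
            continue
        rows.append(
            {
                "mirna_id": rec.mirna_id,
                "gene_id": rec.gene_id,
                "tau": tau,
                "mirna_max_abs_lfc": m_lfc,
                "gene_max_abs_lfc": g_lfc,
            }
        )
    out = pd.DataFrame(
        rows, columns=["mirna_id", "gene_id", "tau", "mirna_max_abs_lfc", "gene_max_abs_lfc"]
    )
    logger.info(
        "stringent filter: %d interactions across %d miRNAs",
        len(out), out["mirna_id"].nunique() if len(out) else 0,
    )
    return out


def template_match(
    template_mirna_id: str,
    mirna_profiles: StageProfiles,
    similarity_threshold: float = 0.6,
    include_self: bool = False,
) -> pd.DataFrame:
    """Rank miRNAs by Kendall tau of their profile against a template miRNA's.

    Matches with tau >= threshold are returned sorted descending; the
    template itself is excluded unless ``include_self`` is set.
    """
    values = mirna_profiles.values
    if template_mirna_id not in values.index:
        raise KeyError(f"unknown template miRNA {template_mirna_id!r}")
    template = values.loc[template_mirna_id].to_numpy()
    rows = []
    for mirna_id in values.index:
        if mirna_id == template_mirna_id and not include_self:
            continue
        tau = kendall_tau(template, values.loc[mirna_id].to_numpy())
        if np.isfinite(tau) and tau >= similarity_threshold:
            rows.append({"mirna_id": mirna_id, "tau": tau})
    out = pd.DataFrame(rows, columns=["mirna_id", "tau"])
    return out.sort_values("tau", ascending=False, kind="stable").reset_index(drop=True)
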