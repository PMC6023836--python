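"""Kendall anti-correlation of miRNA/target profiles and cluster-level link matrices."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Literal, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .io import StageProfiles

logger = logging.getLogger(__name__)

DEFAULT_ANTICORR_THRESHOLD = -0.4


def kendall_tau(x: np.ndarray, y: np.ndarray) -> float:
    """Tie-corrected Kendall rank correlation (tau-b).

    Returns NaN (with a warning) when either vector has zero variance, where
    the coefficient is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("zero-variance input: Kendall tau undefined", stacklevel=2)
        return float("nan")
    tau = stats.kendalltau(x, y, variant="b").statistic
    return float(tau)


def annotate_correlations(
    interactions: pd.DataFrame,
    mirna_profiles: StageProfiles,
    gene_profiles: StageProfiles,
    mirna_dev_profiles: StageProfiles | None = None,
    gene_dev_profiles: StageProfiles | None = None,
    threshold: float = DEFAULT_ANTICORR_THRESHOLD,
    mode: Literal["full", "dev"] = "dev",
) -> pd.DataFrame:
    """Attach tau_full / tau_dev and the anti-correlation flag to interactions.

    ``tau_full`` uses all stages of the given profiles; ``tau_dev`` uses the
    embryonic-only profiles (derived from the full ones when not supplied).
    The flag applies a strict ``tau < threshold`` on the mode-selected tau.
    Interactions with a missing profile are skipped and counted in the log.
    """
    if mirna_dev_profiles is None:
        from .stages import embryonic_subset

        dev_cols = embryonic_subset(mirna_profiles.stages)
        mirna_dev_profiles = StageProfiles(mirna_profiles.values[dev_cols], dev_only=True)
    if gene_dev_profiles is None:
        from .stages import embryonic_subset

        dev_cols = embryonic_subset(gene_profiles.stages)
        gene_dev_profiles = StageProfiles(gene_profiles.values[dev_cols], dev_only=True)

    rows = []
    n_skipped = 0
    mir_full = mirna_profiles.values
    gene_full = gene_profiles.values
    mir_dev = mirna_dev_profiles.values
    gene_dev = gene_dev_profiles.values
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant profiles yield NaN tau, flagged below
        for rec in interactions.itertuples(index=False):
            if rec.mirna_id not in mir_full.index or rec.gene_id not in gene_full.index:
                n_skipped += 1
                continue
            tau_full = kendall_tau(
                mir_full.loc[rec.mirna_id].to_numpy(), gene_full.loc[rec.gene_id].to_numpy()
            )
            tau_dev = kendall_tau(
                mir_dev.loc[rec.mirna_id].to_numpy(), gene_dev.loc[rec.gene_id].to_numpy()
            )
            row = rec._asdict()
            row["tau_full"] = tau_full
            row["tau_dev"] = tau_dev
            selected = tau_dev if mode == "dev" else tau_full
            row["is_anticorrelated"] = bool(selected < threshold) if np.isfinite(selected) else False
            rows.append(row)
    if n_skipped:
        logger.info("skipped %d interactions lacking expression profiles", n_skipped)
    out = pd.DataFrame(rows)
    if out.empty:
        out = pd.DataFrame(
            columns=list(interactions.columns) + ["tau_full", "tau_dev", "is_anticorrelated"]
        )
    return out


@dataclass
class ClusterLinkMatrix:
    """Cluster-pair interaction counts.

    ``m_all`` counts every cluster-labeled interaction; ``m_neg`` the
    anti-correlated subset; ``m_neg_targets`` the unique anti-correlated
    target genes per cluster pair (arrow-width count).
    """

    m_all: pd.DataFrame
    m_neg: pd.DataFrame
    m_neg_targets: pd.DataFrame
    n_skipped: int


def build_link_matrices(
    correlated: pd.DataFrame,
    mir_labels: Mapping[str, int] | pd.Series,
    gene_labels: Mapping[str, int] | pd.Series,
) -> ClusterLinkMatrix:
    """Count interactions between each (miRNA cluster, gene cluster) pair.

    Interactions with an unlabeled partner are skipped and counted.
    """
    mir_labels = dict(mir_labels)
    gene_labels = dict(gene_labels)
    mir_clusters = sorted(set(mir_labels.values())) or [0]
    gene_clusters = sorted(set(gene_labels.values())) or [0]
    m_all = pd.DataFrame(0, index=mir_clusters, columns=gene_clusters)
    m_neg = pd.DataFrame(0, index=mir_clusters, columns=gene_clusters)
    neg_targets: dict[tuple[int, int], set[str]] = {}
    n_skipped = 0
    for rec in correlated.itertuples(index=False):
        mi = mir_labels.get(rec.mirna_id)
        gi = gene_labels.get(rec.gene_id)
        if mi is None or gi is None:
            n_skipped += 1
            continue
        m_all.loc[mi, gi] += 1
        if rec.is_anticorrelated:
            m_neg.loc[mi, gi] += 1
            neg_targets.setdefault((mi, gi), set()).add(rec.gene_id)
    m_neg_targets = pd.DataFrame(0, index=mir_clusters, columns=gene_clusters)
    for (mi, gi), genes in neg_targets.items():
        m_neg_targets.loc[mi, gi] = len(genes)
    if n_skipped:
        logger.info("link matrices: skipped %d interactions without cluster labels", n_skipped)
    return ClusterLinkMatrix(m_all=m_all, m_neg=m_neg, m_neg_targets=m_neg_targets, n_skipped=n_skipped)


def dominant_links(
    matrix: ClusterLinkMatrix, rule_fraction: float = 0.5
) -> list[tuple[int, int]]:
    """Cluster pairs where anti-correlated interactions strictly dominate:
    M_neg/M_all > rule_fraction (and M_all > 0)."""
    links = []
    for mi in matrix.m_all.index:
        for gi in matrix.m_all.columns:
            total = matrix.m_all.loc[mi, gi]
            if total > 0 and matrix.m_neg.loc[mi, gi] / total > rule_fraction:
                links.append((mi, gi))
    return links
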