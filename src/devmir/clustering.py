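"""Fuzzy c-means clustering of standardized temporal profiles.

Profiles are standardized per feature (mean 0, SD 1); the cluster count is
advised by the minimum-centroid-distance curve and clusters are relabeled so
downregulated trends come first.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .io import StageProfiles

logger = logging.getLogger(__name__)


def standardize_profiles(
    profiles: StageProfiles | pd.DataFrame, ddof: int = 0
) -> tuple[pd.DataFrame, list[str]]:
    """Scale each profile to mean 0, SD 1 (population SD by default).

    Zero-SD (constant) profiles cannot be standardized; they are excluded
    and returned as the second element.
    """
    values = profiles.values if isinstance(profiles, StageProfiles) else profiles
    if values.shape[1] < 2:
        raise ValueError("profiles need at least 2 stages")
    sd = values.std(axis=1, ddof=ddof)
    excluded = list(values.index[sd == 0])
    kept = values.loc[sd > 0]
    if kept.empty:
        raise ValueError("all profiles are constant; nothing to standardize")
    standardized = kept.sub(kept.mean(axis=1), axis=0).div(sd[sd > 0], axis=0)
    if excluded:
        logger.info("excluded %d constant profiles from standardization", len(excluded))
    return standardized, excluded


@dataclass
class ClusterModel:
    """Fitted fuzzy c-means model."""

    membership: pd.DataFrame  # features x clusters, rows sum to 1
    centroids: pd.DataFrame  # clusters x stages
    fuzzifier: float
    objective: float
    objective_history: list[float]
    seed: int
    restarts: int

    @property
    def n_clusters(self) -> int:
        return self.centroids.shape[0]

    @property
    def feature_ids(self) -> list[str]:
        return list(self.membership.index)

    def hard_labels(self) -> pd.Series:
        """Argmax membership per feature; ties go to the lowest cluster index."""
        return pd.Series(
            np.argmax(self.membership.to_numpy(), axis=1),
            index=self.membership.index,
            name="cluster",
        )


def _memberships(d2: np.ndarray, m: float) -> np.ndarray:
    """U from squared distances; a point coincident with a centroid gets
    full membership there (split equally among coincident centroids)."""
    n, c = d2.shape
    u = np.zeros((n, c))
    zero = d2 <= 0
    has_zero = zero.any(axis=1)
    if has_zero.any():
        z = zero[has_zero]
        u[has_zero] = z / z.sum(axis=1, keepdims=True)
    rest = ~has_zero
    if rest.any():
        inv = d2[rest] ** (-1.0 / (m - 1.0))
        u[rest] = inv / inv.sum(axis=1, keepdims=True)
    return u


def _sq_distances(x: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    diff = x[:, None, :] - centroids[None, :, :]
    return np.einsum("ijk,ijk->ij", diff, diff)


def _objective(u: np.ndarray, d2: np.ndarray, m: float) -> float:
    return float(np.sum(u**m * d2))


def _init_centroids(x: np.ndarray, c: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++-style seeding: spread initial centroids over the data."""
    n = x.shape[0]
    idx = [int(rng.integers(n))]
    for _ in range(c - 1):
        d2 = np.min(_sq_distances(x, x[idx]), axis=1)
        total = d2.sum()
        if total <= 0:
            idx.append(int(rng.integers(n)))
            continue
        idx.append(int(rng.choice(n, p=d2 / total)))
    return x[idx].copy()


def fuzzy_cmeans(
    profiles: pd.DataFrame,
    c: int,
    m: float = 2.0,
    tol: float = 1e-8,
    max_iter: int = 500,
    restarts: int = 5,
    seed: int = 0,
) -> ClusterModel:
    """Fit fuzzy c-means on standardized profiles; best of ``restarts`` by
    objective value wins."""
    x = profiles.to_numpy(dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("profiles contain non-finite values")
    n = x.shape[0]
    if c > n:
        raise ValueError(f"c={c} exceeds number of features ({n})")
    if c < 1:
        raise ValueError("c must be >= 1")
    if m <= 1:
        raise ValueError("fuzzifier m must be > 1")

    rng = np.random.default_rng(seed)
    best: tuple[float, np.ndarray, np.ndarray, list[float]] | None = None
    for _ in range(max(1, restarts)):
        centroids = _init_centroids(x, c, rng)
        u = _memberships(_sq_distances(x, centroids), m)
        history: list[float] = []
        for _ in range(max_iter):
            um = u**m
            centroids = (um.T @ x) / um.sum(axis=0)[:, None]
            d2 = _sq_distances(x, centroids)
            history.append(_objective(u, d2, m))
            u_new = _memberships(d2, m)
            delta = np.max(np.abs(u_new - u))
            u = u_new
            if delta < tol:
                break
        d2 = _sq_distances(x, centroids)
        final_j = _objective(u, d2, m)
        history.append(final_j)
        if best is None or final_j < best[0]:
            best = (final_j, u, centroids, history)

    assert best is not None
    final_j, u, centroids, history = best
    model = ClusterModel(
        membership=pd.DataFrame(u, index=profiles.index, columns=range(c)),
        centroids=pd.DataFrame(centroids, columns=profiles.columns),
        fuzzifier=m,
        objective=final_j,
        objective_history=history,
        seed=seed,
        restarts=restarts,
    )
    logger.info("fuzzy c-means: c=%d, J=%.4g after %d iterations", c, final_j, len(history))
    return model


def dmin_curve(
    profiles: pd.DataFrame,
    c_range: Sequence[int] = range(2, 11),
    m: float = 2.0,
    seed: int = 0,
    **fit_kwargs,
) -> pd.DataFrame:
    """Minimum pairwise centroid distance per candidate cluster count.

    The curve is advisory: an elbow/drop suggests the cluster number, but
    final selection stays with the user.
    """
    rows = []
    for c in c_range:
        model = fuzzy_cmeans(profiles, c=c, m=m, seed=seed, **fit_kwargs)
        cent = model.centroids.to_numpy()
        if c < 2:
            raise ValueError("Dmin is defined for c >= 2")
        dists = [
            float(np.linalg.norm(cent[i] - cent[j]))
            for i in range(c)
            for j in range(i + 1, c)
        ]
        rows.append({"c": c, "dmin": min(dists)})
    return pd.DataFrame(rows)


def order_clusters(model: ClusterModel) -> ClusterModel:
    """Relabel clusters by increasing end-minus-start centroid trend, so
    downregulated clusters come first; ties broken by centroid mean."""
    cent = model.centroids.to_numpy()
    trend = cent[:, -1] - cent[:, 0]
    means = cent.mean(axis=1)
    order = np.lexsort((means, trend))
    new_centroids = model.centroids.iloc[order].reset_index(drop=True)
    new_membership = model.membership.iloc[:, order]
    new_membership.columns = range(model.n_clusters)
    return replace(model, centroids=new_centroids, membership=new_membership)


def cluster_overlap_table(
    model_a: ClusterModel, model_b: ClusterModel
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Contingency counts of shared features between two clusterings.

    Features present in only one model are reported separately rather than
    counted.
    """
    labels_a = model_a.hard_labels()
    labels_b = model_b.hard_labels()
    common = labels_a.index.intersection(labels_b.index)
    table = pd.DataFrame(
        0, index=range(model_a.n_clusters), columns=range(model_b.n_clusters)
    )
    for fid in common:
        table.loc[labels_a[fid], labels_b[fid]] += 1
    unmatched = {
        "only_in_a": sorted(set(labels_a.index) - set(labels_b.index)),
        "only_in_b": sorted(set(labels_b.index) - set(labels_a.index)),
    }
    return table, unmatched
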