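"""Empirical-Bayes moderated differential expression.

Per-feature variances are shrunk toward a prior (d0, s0_sq) estimated by
closed-form moment matching on the log sample variances (digamma/trigamma
inversion), and moderated t statistics are referred to a t distribution with
d0 + d_g degrees of freedom.  Benjamini-Hochberg adjustment is applied across
features within each contrast.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

#: prior df above this value is treated as infinite (homogeneous variances)
PRIOR_DF_CAP = 1e6

_VAR_FLOOR = 1e-12


@dataclass
class ModeratedStats:
    """Variance-shrinkage bookkeeping for one fit."""

    prior_df: float  # d0
    prior_var: float  # s0_sq
    sample_var: np.ndarray  # s_g_sq per feature
    shrunken_var: np.ndarray  # s_tilde_sq per feature
    residual_df: float  # d_g (common to all features here)


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration on 1/trigamma."""
    if y <= 0:
        raise ValueError("trigamma is positive; cannot invert non-positive value")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if -dif / x < 1e-8:
            break
    return float(x)


def estimate_variance_prior(sample_var: np.ndarray, residual_df: float) -> tuple[float, float]:
    """Moment-matching estimate of (d0, s0_sq) from per-feature sample variances.

    Fits a scaled-F model for the variances using the mean and variance of
    log(s_g_sq) corrected by digamma/trigamma terms.  Returns d0 = inf when
    the observed spread of log variances is no larger than expected under a
    common variance.
    """
    sample_var = np.asarray(sample_var, dtype=float)
    if sample_var.size < 2:
        return np.inf, float(max(sample_var.mean(), _VAR_FLOOR)) if sample_var.size else (np.inf, 1.0)
    if sample_var.size < 10:
        warnings.warn(
            "fewer than 10 features: variance-prior estimate is unstable", stacklevel=2
        )
    z = np.log(np.maximum(sample_var, _VAR_FLOOR))
    half_df = residual_df / 2.0
    e = z - special.digamma(half_df) + np.log(half_df)
    e_mean = float(e.mean())
    e_var = float(e.var(ddof=1)) - float(special.polygamma(1, half_df))
    if e_var > 0:
        d0 = 2.0 * trigamma_inverse(e_var)
        if d0 > PRIOR_DF_CAP:
            d0 = np.inf
    else:
        d0 = np.inf
    if np.isfinite(d0):
        s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        s0_sq = float(np.exp(e_mean))
    return d0, max(s0_sq, _VAR_FLOOR)


def shrink_variances(
    sample_var: np.ndarray, residual_df: float, prior_df: float | None = None
) -> ModeratedStats:
    """Shrink per-feature variances toward the (estimated or forced) prior."""
    sample_var = np.asarray(sample_var, dtype=float)
    d0_est, s0_sq = estimate_variance_prior(sample_var, residual_df)
    d0 = d0_est if prior_df is None else float(prior_df)
    if d0 == 0:
        shrunken = sample_var.copy()
    elif np.isinf(d0):
        shrunken = np.full_like(sample_var, s0_sq)
    else:
        shrunken = (d0 * s0_sq + residual_df * sample_var) / (d0 + residual_df)
    return ModeratedStats(
        prior_df=d0,
        prior_var=s0_sq,
        sample_var=sample_var,
        shrunken_var=shrunken,
        residual_df=residual_df,
    )


def _t_pvalues(t: np.ndarray, df: float) -> np.ndarray:
    if np.isinf(df):
        return 2.0 * stats.norm.sf(np.abs(t))
    return 2.0 * stats.t.sf(np.abs(t), df)


def fit_moderated_t(
    matrix: ExpressionMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    contrast: str = "a_vs_b",
    prior_df: float | None = None,
) -> tuple[pd.DataFrame, ModeratedStats]:
    """Moderated two-group comparison; log2FC = mean(group_a) - mean(group_b).

    ``prior_df`` overrides the estimated d0 (0 recovers the classical pooled
    t; inf uses the prior variance for every feature).
    """
    group_a, group_b = list(group_a), list(group_b)
    overlap = set(group_a) & set(group_b)
    if overlap:
        raise ValueError(f"groups overlap: {sorted(overlap)}")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 samples")
    missing = (set(group_a) | set(group_b)) - set(matrix.values.columns)
    if missing:
        raise ValueError(f"samples not in matrix: {sorted(missing)}")

    a = matrix.values[group_a].to_numpy()
    b = matrix.values[group_b].to_numpy()
    n_a, n_b = a.shape[1], b.shape[1]
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    lfc = mean_a - mean_b
    d_g = n_a + n_b - 2
    pooled = (a.var(axis=1, ddof=1) * (n_a - 1) + b.var(axis=1, ddof=1) * (n_b - 1)) / d_g
    mod = shrink_variances(pooled, d_g, prior_df=prior_df)
    se = np.sqrt(np.maximum(mod.shrunken_var, _VAR_FLOOR) * (1.0 / n_a + 1.0 / n_b))
    t = lfc / se
    df_total = mod.prior_df + d_g if np.isfinite(mod.prior_df) else np.inf
    p = _t_pvalues(t, df_total)
    result = pd.DataFrame(
        {
            "feature_id": matrix.feature_ids,
            "contrast": contrast,
            "log2FC": lfc,
            "t_mod": t,
            "p_raw": p,
        }
    )
    return result, mod


def moderated_one_sample_t(
    diffs: pd.DataFrame, contrast: str = "paired", prior_df: float | None = None
) -> tuple[pd.DataFrame, ModeratedStats]:
    """Moderated one-sample t on per-feature difference vectors (rows)."""
    x = diffs.to_numpy(dtype=float)
    n = x.shape[1]
    if n < 2:
        raise ValueError("need at least 2 paired differences")
    mean = x.mean(axis=1)
    d_g = n - 1
    var = x.var(axis=1, ddof=1)
    mod = shrink_variances(var, d_g, prior_df=prior_df)
    se = np.sqrt(np.maximum(mod.shrunken_var, _VAR_FLOOR) / n)
    t = mean / se
    df_total = mod.prior_df + d_g if np.isfinite(mod.prior_df) else np.inf
    p = _t_pvalues(t, df_total)
    result = pd.DataFrame(
        {
            "feature_id": list(diffs.index),
            "contrast": contrast,
            "log2FC": mean,
            "t_mod": t,
            "p_raw": p,
        }
    )
    return result, mod


def adjust_bh(p_values: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values, clipped to 1."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    # guard against 1-ulp rounding of p*m/rank dipping below p itself
    adjusted = np.maximum(adjusted, p[order])
    out = np.empty(m)
    out[order] = adjusted
    return out


def call_de(
    results: pd.DataFrame, p_threshold: float = 1e-5, lfc_threshold: float = 2.0
) -> pd.DataFrame:
    """Flag features with p_adj <= p_threshold and |log2FC| >= lfc_threshold."""
    out = results.copy()
    if "p_adj" not in out.columns:
        raise ValueError("run adjust_bh first: p_adj column missing")
    out["is_DE"] = (out["p_adj"] <= p_threshold) & (out["log2FC"].abs() >= lfc_threshold)
    return out


def de_vs_reference(
    matrix: ExpressionMatrix,
    reference_stage: str,
    p_threshold: float = 1e-5,
    lfc_threshold: float = 2.0,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """One moderated contrast per non-reference stage, BH within each contrast.

    Returns the concatenated per-contrast result frames; contrast labels are
    ``"<stage>_vs_<reference>"``.
    """
    present = matrix.stages_present()
    if reference_stage not in present:
        raise ValueError(f"reference stage {reference_stage!r} not present in data")
    ref_samples = matrix.samples_for(stage=reference_stage)
    frames = []
    for stage in present:
        if stage == reference_stage:
            continue
        label = f"{stage}_vs_{reference_stage}"
        res, _ = fit_moderated_t(
            matrix, matrix.samples_for(stage=stage), ref_samples, contrast=label,
            prior_df=prior_df,
        )
        res["p_adj"] = adjust_bh(res["p_raw"])
        frames.append(call_de(res, p_threshold, lfc_threshold))
    result = pd.concat(frames, ignore_index=True)
    n_de = int(result["is_DE"].sum())
    logger.info("DE vs %s: %d significant feature-contrasts", reference_stage, n_de)
    return result


DEFAULT_SEX_EXCLUDED_STAGES = frozenset({"E10.5", "E11.5", "E12.5"})


def _sex_difference_frame(
    matrix: ExpressionMatrix, excluded_stages: Iterable[str]
) -> pd.DataFrame:
    """Per-stage male-minus-female log2 differences (features x stages)."""
    excluded = set(excluded_stages)
    stages = [s for s in matrix.stages_present() if s not in excluded]
    diffs = {}
    for stage in stages:
        males = matrix.samples_for(stage=stage, sex="M")
        females = matrix.samples_for(stage=stage, sex="F")
        if not males or not females:
            raise ValueError(f"stage {stage!r} lacks a male or female sample")
        diffs[stage] = matrix.values[males].mean(axis=1) - matrix.values[females].mean(axis=1)
    if not diffs:
        raise ValueError("no stages left for the paired sex contrast")
    return pd.DataFrame(diffs)


def paired_sex_contrast(
    matrix: ExpressionMatrix,
    excluded_stages: Iterable[str] = DEFAULT_SEX_EXCLUDED_STAGES,
    p_threshold: float = 1e-5,
    lfc_threshold: float = 2.0,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Overall male-vs-female contrast from per-stage paired differences.

    Stages with incomplete sex differentiation are excluded by default;
    mixed-sex replicates are ignored.
    """
    diffs = _sex_difference_frame(matrix, excluded_stages)
    res, _ = moderated_one_sample_t(diffs, contrast="M_vs_F", prior_df=prior_df)
    res["p_adj"] = adjust_bh(res["p_raw"])
    return call_de(res, p_threshold, lfc_threshold)


def sex_fold_change_counts(
    matrix: ExpressionMatrix, log2_threshold: float = 1.0
) -> pd.DataFrame:
    """Per-stage counts of features changed more than ``log2_threshold``
    between the sexes (strict inequality), split by sign (up = higher in male)."""
    rows = []
    for stage in matrix.stages_present():
        males = matrix.samples_for(stage=stage, sex="M")
        females = matrix.samples_for(stage=stage, sex="F")
        if not males or not females:
            continue
        diff = matrix.values[males].mean(axis=1) - matrix.values[females].mean(axis=1)
        rows.append(
            {
                "stage": stage,
                "n_up_in_male": int((diff > log2_threshold).sum()),
                "n_down_in_male": int((diff < -log2_threshold).sum()),
            }
        )
    return pd.DataFrame(rows, columns=["stage", "n_up_in_male", "n_down_in_male"])


def de_feature_ids(results: pd.DataFrame) -> set[str]:
    """Features flagged DE in at least one contrast."""
    return set(results.loc[results["is_DE"], "feature_id"])


def max_abs_lfc(results: pd.DataFrame) -> pd.Series:
    """Per feature, the maximum |log2FC| over all contrasts."""
    return results.groupby("feature_id")["log2FC"].apply(lambda s: s.abs().max())


def compare_de_sets(
    set_a: Mapping[str, set[str]] | set[str], set_b: Mapping[str, set[str]] | set[str]
) -> dict[str, set[str]]:
    """Intersect/diff DE id sets, either pooled or per matching contrast key."""
    if isinstance(set_a, Mapping) != isinstance(set_b, Mapping):
        raise ValueError("both inputs must be pooled sets or both per-contrast maps")
    if isinstance(set_a, Mapping):
        pooled_a = set().union(*set_a.values()) if set_a else set()
        pooled_b = set().union(*set_b.values()) if set_b else set()
    else:
        pooled_a, pooled_b = set(set_a), set(set_b)
    common = pooled_a & pooled_b
    logger.info(
        "DE-set comparison: %d common, %d unique to A, %d unique to B",
        len(common), len(pooled_a - pooled_b), len(pooled_b - pooled_a),
    )
    return {
        "common": common,
        "unique_to_a": pooled_a - pooled_b,
        "unique_to_b": pooled_b - pooled_a,
    }
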