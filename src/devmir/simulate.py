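"""Synthetic paired gene/miRNA time-course generator with planted regulation.

Produces log2 expression matrices over a staged design (embryonic days plus
two mature stages), an interaction table mixing planted repressive
miRNA->gene links with decoys, a flat category-annotation table, and a truth
object for recovery benchmarks.  Noise is additive Gaussian on the log2
scale; postnatal effect sizes are drawn larger than embryonic stage-to-stage
changes (configurable ratio).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .io import ExpressionMatrix
from .stages import DEFAULT_STAGES, MIXED_ONLY_STAGES, embryonic_subset, validate_stages

ARCHETYPES = ("monotone_down", "monotone_up", "transient_peak", "postnatal_switch", "flat")


@dataclass(frozen=True)
class ResourceSpec:
    """A pseudo target-prediction resource with a native score distribution."""

    name: str
    evidence: Literal["predicted", "experimental"]
    direction: Literal["higher", "lower"] | None = None  # which scores are better
    cutoff: float | None = None
    score_lo: float = 0.0
    score_hi: float = 1.0

    def passing_interval(self) -> tuple[float, float]:
        """Score interval that survives the recommended cutoff."""
        if self.evidence == "experimental":
            raise ValueError("experimental resources carry no scores")
        assert self.cutoff is not None and self.direction is not None
        if self.direction == "higher":
            return (self.cutoff, self.score_hi)
        return (self.score_lo, self.cutoff)


DEFAULT_RESOURCES: tuple[ResourceSpec, ...] = (
    ResourceSpec("miranda_like", "predicted", "lower", cutoff=-0.10, score_lo=-1.0, score_hi=0.0),
    ResourceSpec("pita_like", "predicted", "lower", cutoff=-10.0, score_lo=-30.0, score_hi=0.0),
    ResourceSpec("mirdb_like", "predicted", "higher", cutoff=60.0, score_lo=0.0, score_hi=100.0),
    ResourceSpec("targetscan_like", "predicted", "lower", cutoff=-0.2, score_lo=-1.5, score_hi=0.0),
    ResourceSpec("curated_db", "experimental"),
)

DEFAULT_ARCHETYPE_MIX = {
    "monotone_down": 0.25,
    "monotone_up": 0.25,
    "transient_peak": 0.20,
    "postnatal_switch": 0.15,
    "flat": 0.15,
}


@dataclass
class SyntheticConfig:
    """Parameters of one synthetic dataset."""

    n_genes: int = 600
    n_mirnas: int = 200
    stages: list[str] = field(default_factory=lambda: list(DEFAULT_STAGES))
    n_replicates_per_stage: int = 3
    archetype_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_ARCHETYPE_MIX))
    n_planted_repressors: int = 30
    targets_per_repressor: int = 5
    repression_strength: float = 0.85
    decoy_interactions: int = 1200
    noise_sd: float = 0.3
    baseline_mean: float = 8.0
    baseline_sd: float = 0.5
    amplitude: float = 4.0
    profile_wiggle_sd: float = 1.5
    mature_ratio: float = 2.0
    n_sex_specific_genes: int = 3
    annotation_heart_dev_fraction: float = 0.5
    annotation_tx_regulator_fraction: float = 0.5
    background_annotation_rate: float = 0.10
    resources: tuple[ResourceSpec, ...] = DEFAULT_RESOURCES
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_genes": self.n_genes,
            "n_mirnas": self.n_mirnas,
            "n_replicates_per_stage": self.n_replicates_per_stage,
            "n_planted_repressors": self.n_planted_repressors,
            "targets_per_repressor": self.targets_per_repressor,
        }
        for name, value in counts.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")
        if self.decoy_interactions < 0:
            raise ValueError("decoy_interactions must be non-negative")
        validate_stages(self.stages)
        unknown = set(self.archetype_mix) - set(ARCHETYPES)
        if unknown:
            raise ValueError(f"unknown archetypes in mix: {sorted(unknown)}")
        total = sum(self.archetype_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"archetype_mix proportions must sum to 1, got {total}")
        if not 0.0 <= self.repression_strength <= 1.0:
            raise ValueError("repression_strength must lie in [0, 1]")
        if self.n_planted_repressors > self.n_mirnas:
            raise ValueError("n_planted_repressors cannot exceed n_mirnas")
        n_targets = self.n_planted_repressors * self.targets_per_repressor
        if n_targets + self.n_sex_specific_genes > self.n_genes:
            raise ValueError(
                "n_genes too small for planted targets plus sex-specific genes "
                f"({n_targets} + {self.n_sex_specific_genes} > {self.n_genes})"
            )


@dataclass
class SyntheticTruth:
    """Ground truth of one generated dataset."""

    planted_interactions: list[tuple[str, str, float]]
    archetype_of_feature: dict[str, str]
    sex_specific_genes: list[str]
    expressed_flags: dict[str, bool]
    planted_repressors: list[str]
    heart_dev_genes: set[str]
    tx_regulator_genes: set[str]


def make_archetype_profile(
    archetype: str,
    stages: Sequence[str],
    amplitude: float,
    peak_index: int | None = None,
    mature_ratio: float = 2.0,
) -> np.ndarray:
    """Return one log2 offset per stage for a named temporal archetype.

    ``monotone_down``/``monotone_up`` span exactly ``amplitude`` log2 units
    from first to last stage, with steps into the mature stages scaled by
    ``mature_ratio``.  ``transient_peak`` is a bump of height ``amplitude``
    at an interior embryonic stage.  ``postnatal_switch`` is zero during
    development and elevated by at least ``amplitude`` in mature stages.
    """
    if archetype not in ARCHETYPES:
        raise ValueError(f"unknown archetype {archetype!r}; valid: {list(ARCHETYPES)}")
    stages = list(stages)
    n = len(stages)
    embryonic = embryonic_subset(stages)
    n_emb = len(embryonic)

    if archetype == "flat":
        return np.zeros(n)

    if archetype in ("monotone_down", "monotone_up"):
        # per-transition weights; postnatal transitions are larger
        weights = np.ones(n - 1)
        for i in range(n - 1):
            if stages[i + 1] not in embryonic:
                weights[i] = mature_ratio
        cum = np.concatenate([[0.0], np.cumsum(weights)])
        ramp = amplitude * cum / cum[-1]  # 0 .. amplitude, strictly increasing
        return ramp if archetype == "monotone_up" else amplitude - ramp

    if archetype == "transient_peak":
        if n_emb < 3:
            raise ValueError("transient_peak requires at least 3 embryonic stages")
        if peak_index is None:
            peak_index = n_emb // 2
        if not 1 <= peak_index <= n_emb - 2:
            raise ValueError(f"peak_index must be interior (1..{n_emb - 2})")
        idx = np.arange(n, dtype=float)
        width = max(n_emb / 5.0, 1.0)
        profile = amplitude * np.exp(-0.5 * ((idx - peak_index) / width) ** 2)
        profile[n_emb:] = 0.0  # mature stages stay at baseline
        return profile

    # postnatal_switch
    profile = np.zeros(n)
    profile[n_emb:] = amplitude * max(1.0, mature_ratio)
    return profile


def plant_repression(
    mirna_profile: np.ndarray,
    strength: float,
    noise_sd: float,
    rng: np.random.Generator,
    stages: Sequence[str],
    amplitude: float = 4.0,
) -> np.ndarray:
    """Derive a target profile repressed by the given miRNA profile.

    The target is a mixture of an independent archetype draw and the exact
    anti-profile of the miRNA: at ``strength`` 1 with no noise the result is
    a strictly decreasing affine function of the miRNA profile.
    """
    if not 0.0 <= strength <= 1.0:
        raise ValueError(f"strength must lie in [0, 1], got {strength}")
    mirna_profile = np.asarray(mirna_profile, dtype=float)
    n_emb = len(embryonic_subset(stages))
    archetype = ["monotone_down", "monotone_up", "transient_peak", "postnatal_switch"][
        rng.integers(4)
    ]
    peak = int(rng.integers(1, max(2, n_emb - 1))) if archetype == "transient_peak" else None
    base = make_archetype_profile(archetype, stages, amplitude, peak_index=peak)
    anti = -(mirna_profile - mirna_profile.mean())
    profile = (1.0 - strength) * base + strength * anti
    if noise_sd > 0:
        profile = profile + rng.normal(0.0, noise_sd, size=len(profile))
    return profile


def _sample_sheet(stages: Sequence[str], n_replicates: int, kind_prefix: str) -> pd.DataFrame:
    """Replicate design: one female, one male, rest mixed — mixed-only where
    sex differentiation is incomplete."""
    rows = []
    for stage in stages:
        for rep in range(1, n_replicates + 1):
            if stage in MIXED_ONLY_STAGES:
                sex = "mixed"
            else:
                sex = {1: "F", 2: "M"}.get(rep, "mixed")
            rows.append(
                {
                    "sample_id": f"{kind_prefix}_{stage}_r{rep}",
                    "stage": stage,
                    "sex": sex,
                    "replicate": rep,
                }
            )
    return pd.DataFrame(rows, columns=["sample_id", "stage", "sex", "replicate"])


def _draw_archetypes(
    rng: np.random.Generator, n: int, mix: dict[str, float]
) -> list[str]:
    names = [a for a in ARCHETYPES if a in mix]
    probs = np.array([mix[a] for a in names], dtype=float)
    probs = probs / probs.sum()
    return [names[i] for i in rng.choice(len(names), size=n, p=probs)]


def _smooth_wiggle(rng: np.random.Generator, n: int, sd: float) -> np.ndarray:
    """Centered random-walk component that decorrelates independent profiles
    sharing an archetype."""
    if sd <= 0:
        return np.zeros(n)
    walk = np.cumsum(rng.normal(0.0, sd, size=n))
    return walk - walk.mean()


def _feature_profile(
    rng: np.random.Generator, archetype: str, cfg: SyntheticConfig
) -> np.ndarray:
    n_emb = len(embryonic_subset(cfg.stages))
    amp = cfg.amplitude * rng.uniform(0.75, 1.25)
    peak = int(rng.integers(1, max(2, n_emb - 1))) if archetype == "transient_peak" else None
    profile = make_archetype_profile(
        archetype, cfg.stages, amp, peak_index=peak, mature_ratio=cfg.mature_ratio
    )
    return profile + _smooth_wiggle(rng, len(profile), cfg.profile_wiggle_sd)


def generate_dataset(
    config: SyntheticConfig,
) -> tuple[ExpressionMatrix, ExpressionMatrix, pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Generate the full synthetic bundle.

    Returns (gene matrix, miRNA matrix, interaction table, annotation table,
    truth).  Identical configs (including seed) reproduce identical outputs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    stages = list(config.stages)
    n_emb = len(embryonic_subset(stages))

    gene_ids = [f"gene{idx:04d}" for idx in range(config.n_genes)]
    mirna_ids = [f"mir-{idx:04d}" for idx in range(config.n_mirnas)]
    repressors = mirna_ids[: config.n_planted_repressors]

    # --- miRNA profiles ---------------------------------------------------
    archetype_of: dict[str, str] = {}
    mirna_profiles: dict[str, np.ndarray] = {}
    # planted repressors must vary during embryonic development, otherwise
    # the dev-mode correlation against their targets is uninformative
    signal_archetypes = ["monotone_down", "monotone_up", "transient_peak"]
    n_emb_interior = max(2, len(embryonic_subset(config.stages)) - 1)
    for i, mid in enumerate(mirna_ids):
        if mid in repressors:
            # clean archetype (no wiggle): targets must track it with a
            # large, differentially expressed amplitude
            arch = signal_archetypes[i % len(signal_archetypes)]
            amp = config.amplitude * rng.uniform(0.9, 1.25)
            peak = int(rng.integers(1, n_emb_interior)) if arch == "transient_peak" else None
            profile = make_archetype_profile(
                arch, config.stages, amp, peak_index=peak, mature_ratio=config.mature_ratio
            )
        else:
            arch = _draw_archetypes(rng, 1, config.archetype_mix)[0]
            profile = _feature_profile(rng, arch, config)
        archetype_of[mid] = arch
        mirna_profiles[mid] = profile

    # --- gene profiles ----------------------------------------------------
    n_targets = config.n_planted_repressors * config.targets_per_repressor
    target_ids = gene_ids[:n_targets]
    sex_ids = gene_ids[n_targets : n_targets + config.n_sex_specific_genes]
    free_ids = gene_ids[n_targets + config.n_sex_specific_genes :]

    planted: list[tuple[str, str, float]] = []
    gene_profiles: dict[str, np.ndarray] = {}
    it = iter(target_ids)
    for mid in repressors:
        for _ in range(config.targets_per_repressor):
            gid = next(it)
            gene_profiles[gid] = plant_repression(
                mirna_profiles[mid],
                config.repression_strength,
                0.0,
                rng,
                stages,
                amplitude=config.amplitude,
            )
            archetype_of[gid] = "planted_target"
            planted.append((mid, gid, config.repression_strength))

    for gid in free_ids:
        arch = _draw_archetypes(rng, 1, config.archetype_mix)[0]
        archetype_of[gid] = arch
        gene_profiles[gid] = _feature_profile(rng, arch, config)

    # sex-specific genes: expression confined to one sex (X-inactivation /
    # Y-linked style); profile flat otherwise
    sex_mode: dict[str, str] = {}
    for k, gid in enumerate(sex_ids):
        sex_mode[gid] = "F" if k == 0 else "M"
        archetype_of[gid] = "flat"
        gene_profiles[gid] = np.zeros(len(stages))

    # --- baselines (clipped at 3 sd so planted links stay expressed) ------
    def draw_baselines(ids: list[str]) -> dict[str, float]:
        raw = rng.normal(config.baseline_mean, config.baseline_sd, size=len(ids))
        lo = config.baseline_mean - 3.0 * config.baseline_sd
        hi = config.baseline_mean + 3.0 * config.baseline_sd
        return dict(zip(ids, np.clip(raw, lo, hi)))

    gene_base = draw_baselines(gene_ids)
    mirna_base = draw_baselines(mirna_ids)

    # --- assemble matrices ------------------------------------------------
    gene_sheet = _sample_sheet(stages, config.n_replicates_per_stage, "g")
    mirna_sheet = _sample_sheet(stages, config.n_replicates_per_stage, "m")

    def build_matrix(
        ids: list[str],
        profiles: dict[str, np.ndarray],
        baselines: dict[str, float],
        sheet: pd.DataFrame,
        kind: str,
    ) -> ExpressionMatrix:
        stage_index = {s: i for i, s in enumerate(stages)}
        n_rows, n_cols = len(ids), len(sheet)
        data = np.empty((n_rows, n_cols))
        col_stage = [stage_index[s] for s in sheet["stage"]]
        col_sex = list(sheet["sex"])
        for r, fid in enumerate(ids):
            base = baselines[fid] + profiles[fid]
            for c in range(n_cols):
                value = base[col_stage[c]]
                mode = sex_mode.get(fid)
                if mode is not None:
                    sex = col_sex[c]
                    if sex == mode:
                        pass  # full expression
                    elif sex == "mixed":
                        value -= 1.0  # half dose
                    else:
                        value -= 6.0  # effectively absent
                data[r, c] = value
        if config.noise_sd > 0:
            data = data + rng.normal(0.0, config.noise_sd, size=data.shape)
        values = pd.DataFrame(data, index=pd.Index(ids, name="feature_id"), columns=list(sheet["sample_id"]))
        return ExpressionMatrix(values=values, samples=sheet, feature_kind=kind, stages=stages)

    gene_matrix = build_matrix(gene_ids, gene_profiles, gene_base, gene_sheet, "gene")
    mirna_matrix = build_matrix(mirna_ids, mirna_profiles, mirna_base, mirna_sheet, "miRNA")

    # --- interaction table ------------------------------------------------
    predicted = [r for r in config.resources if r.evidence == "predicted"]
    rows = []
    for mid, gid, _strength in planted:
        res = config.resources[rng.integers(len(config.resources))]
        if res.evidence == "experimental":
            rows.append((mid, gid, res.name, np.nan, "experimental", "PMID:0"))
        else:
            lo, hi = res.passing_interval()
            rows.append((mid, gid, res.name, float(rng.uniform(lo, hi)), "predicted", ""))

    planted_pairs = {(m, g) for m, g, _ in planted}
    n_decoys = 0
    while n_decoys < config.decoy_interactions:
        mid = mirna_ids[rng.integers(config.n_mirnas)]
        gid = gene_ids[rng.integers(config.n_genes)]
        if (mid, gid) in planted_pairs:
            continue
        planted_pairs.add((mid, gid))  # avoid duplicate decoys too
        res = predicted[rng.integers(len(predicted))]
        score = float(rng.uniform(res.score_lo, res.score_hi))
        rows.append((mid, gid, res.name, score, "predicted", ""))
        n_decoys += 1

    interactions = pd.DataFrame(
        rows, columns=["mirna_id", "gene_id", "resource", "score", "evidence", "reference_ids"]
    )

    # --- annotations ------------------------------------------------------
    heart_dev: set[str] = set()
    tx_reg: set[str] = set()
    for gid in target_ids:
        if rng.random() < config.annotation_heart_dev_fraction:
            heart_dev.add(gid)
        if rng.random() < config.annotation_tx_regulator_fraction:
            tx_reg.add(gid)
    for gid in free_ids:
        if rng.random() < config.background_annotation_rate:
            heart_dev.add(gid)
        if rng.random() < config.background_annotation_rate:
            tx_reg.add(gid)
    ann_rows = [(g, "heart_dev") for g in sorted(heart_dev)]
    ann_rows += [(g, "tx_regulator") for g in sorted(tx_reg)]
    annotations = pd.DataFrame(ann_rows, columns=["gene_id", "category"])

    # --- truth ------------------------------------------------------------
    expressed: dict[str, bool] = {}
    for fid in gene_ids:
        expressed[fid] = bool(gene_base[fid] + gene_profiles[fid].max() > 5.0)
    for fid in mirna_ids:
        expressed[fid] = bool(mirna_base[fid] + mirna_profiles[fid].max() > 5.0)

    truth = SyntheticTruth(
        planted_interactions=planted,
        archetype_of_feature=archetype_of,
        sex_specific_genes=list(sex_ids),
        expressed_flags=expressed,
        planted_repressors=list(repressors),
        heart_dev_genes=heart_dev,
        tx_regulator_genes=tx_reg,
    )
    return gene_matrix, mirna_matrix, interactions, annotations, truth


def write_dataset(
    out_dir: str | Path,
    gene_matrix: ExpressionMatrix,
    mirna_matrix: ExpressionMatrix,
    interactions: pd.DataFrame,
    annotations: pd.DataFrame,
    truth: SyntheticTruth,
) -> dict[str, Path]:
    """Write the bundle as TSVs; returns the paths written."""
    from .io import write_expression

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "gene_matrix": out / "genes.tsv",
        "gene_samples": out / "gene_samples.tsv",
        "mirna_matrix": out / "mirnas.tsv",
        "mirna_samples": out / "mirna_samples.tsv",
        "interactions": out / "interactions.tsv",
        "annotations": out / "annotations.tsv",
        "truth_interactions": out / "truth_planted_interactions.tsv",
        "truth_features": out / "truth_features.tsv",
    }
    write_expression(gene_matrix, paths["gene_matrix"], paths["gene_samples"])
    write_expression(mirna_matrix, paths["mirna_matrix"], paths["mirna_samples"])
    interactions.to_csv(paths["interactions"], sep="\t", index=False, float_format="%.6f")
    annotations.to_csv(paths["annotations"], sep="\t", index=False)
    pd.DataFrame(
        truth.planted_interactions, columns=["mirna_id", "gene_id", "strength"]
    ).to_csv(paths["truth_interactions"], sep="\t", index=False)
    feats = pd.DataFrame(
        {
            "feature_id": list(truth.archetype_of_feature),
            "archetype": list(truth.archetype_of_feature.values()),
        }
    )
    feats["expressed"] = [truth.expressed_flags.get(f, True) for f in feats["feature_id"]]
    feats["sex_specific"] = feats["feature_id"].isin(truth.sex_specific_genes)
    feats["planted_repressor"] = feats["feature_id"].isin(truth.planted_repressors)
    feats["heart_dev"] = feats["feature_id"].isin(truth.heart_dev_genes)
    feats["tx_regulator"] = feats["feature_id"].isin(truth.tx_regulator_genes)
    feats.to_csv(paths["truth_features"], sep="\t", index=False)
    return paths
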