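"""Expression-matrix I/O, probe collapsing, the expression filter and stage profiles.

Matrices are log2 intensities with features on rows and samples on columns;
no normalization is performed here (arrays are assumed RMA-processed upstream).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .stages import DEFAULT_STAGES, embryonic_subset

logger = logging.getLogger(__name__)

VALID_SEXES = {"M", "F", "mixed"}

SAMPLE_SHEET_COLUMNS = ["sample_id", "stage", "sex", "replicate"]


@dataclass(frozen=True)
class SampleAnnotation:
    """Metadata for one array sample."""

    sample_id: str
    stage: str
    sex: Literal["M", "F", "mixed"]
    replicate: int

    def __post_init__(self) -> None:
        if self.sex not in VALID_SEXES:
            raise ValueError(
                f"sex must be one of {sorted(VALID_SEXES)}, got {self.sex!r}"
            )


@dataclass
class ExpressionMatrix:
    """Log2 expression values (features x samples) with aligned sample metadata.

    Attributes
    ----------
    values : pandas.DataFrame
        Index = feature ids, columns = sample ids, entries = log2 intensities.
    samples : pandas.DataFrame
        One row per sample with columns ``sample_id, stage, sex, replicate``,
        in the same order as ``values.columns``.
    feature_kind : str
        ``"gene"`` or ``"miRNA"``.
    stages : list of str
        Ordered stage labels present in the design.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    feature_kind: Literal["gene", "miRNA"]
    stages: list[str] = field(default_factory=lambda: list(DEFAULT_STAGES))

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicated feature_ids: {list(dups[:5])}")
        if list(self.values.columns) != list(self.samples["sample_id"]):
            raise ValueError("matrix columns and sample sheet must align")
        if self.samples["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_ids in sample sheet")
        vals = self.values.to_numpy()
        if vals.size and not np.all(np.isfinite(vals)):
            raise ValueError("expression matrix contains non-finite values")
        unknown = set(self.samples["stage"]) - set(self.stages)
        if unknown:
            raise ValueError(f"sample stages not in configured stage list: {sorted(unknown)}")
        bad_sex = set(self.samples["sex"]) - VALID_SEXES
        if bad_sex:
            raise ValueError(f"invalid sex labels: {sorted(bad_sex)}")

    # -- convenience -------------------------------------------------------

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def stages_present(self) -> list[str]:
        present = set(self.samples["stage"])
        return [s for s in self.stages if s in present]

    def samples_for(self, stage: str | None = None, sex: str | None = None) -> list[str]:
        """Sample ids matching the given stage and/or sex."""
        mask = pd.Series(True, index=self.samples.index)
        if stage is not None:
            mask &= self.samples["stage"] == stage
        if sex is not None:
            mask &= self.samples["sex"] == sex
        return list(self.samples.loc[mask, "sample_id"])

    def subset_features(self, ids: Iterable[str]) -> "ExpressionMatrix":
        ids = [i for i in ids if i in self.values.index]
        return replace(self, values=self.values.loc[ids])


def read_expression(
    matrix_path: str | Path,
    sample_sheet_path: str | Path,
    feature_kind: Literal["gene", "miRNA"],
    stages: Sequence[str] | None = None,
) -> ExpressionMatrix:
    """Read an expression TSV and its sample sheet into an aligned matrix.

    The matrix TSV has a ``feature_id`` first column and one column per
    sample; the sheet has columns ``sample_id, stage, sex, replicate``.
    Samples present in only one of the two files raise an error naming them.
    """
    values = pd.read_csv(matrix_path, sep="\t", index_col="feature_id")
    sheet = pd.read_csv(sample_sheet_path, sep="\t", dtype={"sample_id": str})
    missing_cols = set(SAMPLE_SHEET_COLUMNS) - set(sheet.columns)
    if missing_cols:
        raise ValueError(f"sample sheet missing columns: {sorted(missing_cols)}")

    matrix_samples = list(values.columns)
    sheet_samples = list(sheet["sample_id"])
    only_matrix = sorted(set(matrix_samples) - set(sheet_samples))
    only_sheet = sorted(set(sheet_samples) - set(matrix_samples))
    if only_matrix or only_sheet:
        raise ValueError(
            "sample mismatch between matrix and sheet; "
            f"only in matrix: {only_matrix}; only in sheet: {only_sheet}"
        )

    non_numeric = values.columns[
        [not pd.api.types.is_numeric_dtype(values[c]) for c in values.columns]
    ]
    if len(non_numeric):
        for col in non_numeric:
            bad = values[col][pd.to_numeric(values[col], errors="coerce").isna()]
            if len(bad):
                raise ValueError(
                    f"non-numeric value in column {col!r}, feature {bad.index[0]!r}"
                )

    # align sheet order to matrix column order
    sheet = sheet.set_index("sample_id").loc[matrix_samples].reset_index()
    stage_list = list(stages) if stages is not None else _infer_stages(sheet["stage"])
    mat = ExpressionMatrix(
        values=values.astype(float),
        samples=sheet,
        feature_kind=feature_kind,
        stages=stage_list,
    )
    logger.info(
        "read %s matrix: %d features x %d samples", feature_kind, mat.n_features, mat.n_samples
    )
    return mat


def _infer_stages(stage_col: pd.Series) -> list[str]:
    present = list(dict.fromkeys(stage_col))
    known = [s for s in DEFAULT_STAGES if s in present]
    extra = [s for s in present if s not in DEFAULT_STAGES]
    return known + extra


def write_expression(
    matrix: ExpressionMatrix, matrix_path: str | Path, sample_sheet_path: str | Path | None = None
) -> None:
    """Write a matrix (and optionally its sample sheet) as TSV."""
    out = matrix.values.copy()
    out.index.name = "feature_id"
    out.to_csv(matrix_path, sep="\t", float_format="%.6f")
    if sample_sheet_path is not None:
        matrix.samples.to_csv(sample_sheet_path, sep="\t", index=False)


def collapse_features(
    matrix: ExpressionMatrix,
    mapping: Mapping[str, str],
    rule: Literal["max_mean", "max_variance"] = "max_mean",
) -> ExpressionMatrix:
    """Collapse probe-level rows to one row per mapped entity.

    The representative probe for each entity is the one with the highest
    mean intensity across all samples (``max_mean``, default) or the highest
    variance (``max_variance``).  Unmapped probes are dropped.
    """
    if not mapping:
        raise ValueError("empty feature mapping")
    mapped = {f: e for f, e in mapping.items() if f in matrix.values.index}
    if not mapped:
        raise ValueError("mapping covers no features present in the matrix")

    if rule == "max_mean":
        stat = matrix.values.mean(axis=1)
    elif rule == "max_variance":
        stat = matrix.values.var(axis=1, ddof=0)
    else:
        raise ValueError(f"unknown collapse rule {rule!r}")

    chosen: dict[str, str] = {}
    for probe, entity in mapped.items():
        best = chosen.get(entity)
        if best is None or (stat[probe], probe) > (stat[best], best):
            chosen[entity] = probe
    entities = sorted(chosen)
    new_values = matrix.values.loc[[chosen[e] for e in entities]].copy()
    new_values.index = pd.Index(entities, name="feature_id")
    logger.info("collapsed %d probes to %d entities", len(mapped), len(entities))
    return replace(matrix, values=new_values)


@dataclass
class StageProfiles:
    """Per-stage replicate-mean log2 profiles, one row per feature."""

    values: pd.DataFrame  # features x stages
    dev_only: bool

    @property
    def stages(self) -> list[str]:
        return list(self.values.columns)

    def profile(self, feature_id: str) -> np.ndarray:
        return self.values.loc[feature_id].to_numpy()


def stage_means(matrix: ExpressionMatrix, dev_only: bool = False) -> StageProfiles:
    """Average replicates within each stage; optionally restrict to embryonic stages."""
    selected = matrix.stages_present()
    if dev_only:
        selected = embryonic_subset(selected)
    if not selected:
        raise ValueError("no stages selected")
    cols = {}
    for stage in selected:
        ids = matrix.samples_for(stage=stage)
        if not ids:
            raise ValueError(f"stage {stage!r} has zero samples")
        cols[stage] = matrix.values[ids].mean(axis=1)
    profiles = pd.DataFrame(cols, columns=selected)
    return StageProfiles(values=profiles, dev_only=dev_only)


def filter_expressed(
    matrix: ExpressionMatrix, threshold: float = 5.0
) -> tuple[ExpressionMatrix, list[str]]:
    """Keep features whose maximum per-stage mean exceeds ``threshold`` (strict).

    Returns the filtered matrix and the list of dropped feature ids.
    """
    profiles = stage_means(matrix)
    max_means = profiles.values.max(axis=1)
    keep = max_means > threshold
    kept_ids = list(max_means.index[keep])
    dropped = list(max_means.index[~keep])
    logger.info(
        "expression filter (> %g): kept %d, dropped %d", threshold, len(kept_ids), len(dropped)
    )
    return matrix.subset_features(kept_ids), dropped
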