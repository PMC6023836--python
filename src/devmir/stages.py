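"""Stage label conventions shared across the pipeline.

The default design has twelve ordered stages: ten embryonic days followed by
two mature stages ("young", "old").  Embryonic stages are the "developmental"
subset used by dev-only profiles and correlations.
"""

from __future__ import annotations

from typing import Sequence

EMBRYONIC_STAGES: tuple[str, ...] = tuple(
    f"E{d}.5" for d in range(10, 20)
)
MATURE_STAGES: tuple[str, ...] = ("young", "old")
DEFAULT_STAGES: tuple[str, ...] = EMBRYONIC_STAGES + MATURE_STAGES

#: Stages with incomplete sex differentiation: replicates are mixed-only.
MIXED_ONLY_STAGES: tuple[str, ...] = ("E10.5", "E11.5")


def embryonic_subset(stages: Sequence[str]) -> list[str]:
    """Return the embryonic (developmental) stages, preserving order."""
    mature = set(MATURE_STAGES)
    return [s for s in stages if s not in mature]


def validate_stages(stages: Sequence[str]) -> list[str]:
    stages = list(stages)
    if len(stages) != len(set(stages)):
        raise ValueError("stage labels must be unique")
    if not stages:
        raise ValueError("at least one stage label required")
    return stages
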