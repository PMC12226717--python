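"""Visual-field severity staging from the mean deviation (MD) index.

Implements the MD-threshold staging used throughout the toolkit, an
adaptation of the Hodapp-Anderson-Parrish system: early (MD >= -6 dB),
moderate (-12 <= MD < -6), advanced (-20 < MD < -12), severe
(MD <= -20).  Boundary convention: the explicit "MD >= -6" and
"MD <= -20" rules win at their boundaries, and MD = -12 exactly is
assigned to moderate (moderate is the half-open interval [-12, -6)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core.types import SeverityStage

__all__ = ["StagingRule", "stage_from_md", "binarize_stage", "stages_from_md"]


@dataclass(frozen=True)
class StagingRule:
    """MD cut points in dB; must be strictly decreasing."""

    cut_early: float = -6.0
    cut_moderate: float = -12.0
    cut_advanced: float = -20.0

    def __post_init__(self) -> None:
        if not (self.cut_early > self.cut_moderate > self.cut_advanced):
            raise ValueError("staging cuts must satisfy cut_early > cut_moderate > cut_advanced")


DEFAULT_RULE = StagingRule()


def stage_from_md(md: float, rule: StagingRule = DEFAULT_RULE) -> SeverityStage:
    """Map one MD value (dB) to a severity stage.

    The mapping partitions the real line: early iff md >= cut_early;
    moderate iff cut_moderate <= md < cut_early; advanced iff
    cut_advanced < md < cut_moderate; severe iff md <= cut_advanced.
    """
    md = float(md)
    if math.isnan(md):
        raise ValueError("md must not be NaN")
    if md >= rule.cut_early:
        return SeverityStage.EARLY
    if md >= rule.cut_moderate:
        return SeverityStage.MODERATE
    if md > rule.cut_advanced:
        return SeverityStage.ADVANCED
    return SeverityStage.SEVERE


def stages_from_md(md: np.ndarray, rule: StagingRule = DEFAULT_RULE) -> np.ndarray:
    """Vectorised :func:`stage_from_md`; returns integer stage codes."""
    md = np.asarray(md, dtype=float)
    if np.isnan(md).any():
        raise ValueError("md must not contain NaN")
    out = np.full(md.shape, int(SeverityStage.SEVERE), dtype=int)
    out[md > rule.cut_advanced] = int(SeverityStage.ADVANCED)
    out[md >= rule.cut_moderate] = int(SeverityStage.MODERATE)
    out[md >= rule.cut_early] = int(SeverityStage.EARLY)
    return out


def binarize_stage(stage: SeverityStage) -> str:
    """Collapse the four stages to the pre-diagnosis binary target.

    Early stays "early"; moderate, advanced and severe collapse to
    "serious".
    """
    stage = SeverityStage(stage)
    return "early" if stage == SeverityStage.EARLY else "serious"
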