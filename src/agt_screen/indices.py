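"""Tolerance indices and categorical classification of screened genotypes.

Two composite indices summarize performance under early-stage submergence:

* the anaerobic vigor index, ``AVI = AGP x (shoot length + root length)``,
  combining germination success with seedling growth; and
* the response index, ``RI = SL(submerged) - SL(control)``, positive when
  hypoxia stimulates shoot elongation (the escape strategy) and negative
  when it suppresses it.

Genotypes are binned into four tolerance classes on AGP, and into grain
types on kernel length and the length-to-breadth ratio.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from typing import Iterable

import pandas as pd

from .errors import ValidationError


class ToleranceClass(IntEnum):
    """Ordered tolerance classes; higher value = more tolerant."""

    susceptible = 0
    moderately_susceptible = 1
    moderately_tolerant = 2
    tolerant = 3

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


TOLERANCE_ORDER = [
    ToleranceClass.tolerant,
    ToleranceClass.moderately_tolerant,
    ToleranceClass.moderately_susceptible,
    ToleranceClass.susceptible,
]


def anaerobic_vigor_index(agp: float, shoot_length: float, root_length: float) -> float:
    """AVI = AGP x (shoot length + root length).

    AGP is on the percent scale; the product is treated as a dimensionless
    vigor score (zero germination or zero growth gives zero vigor).
    """
    if not 0.0 <= agp <= 100.0:
        raise ValidationError(f"AGP outside [0,100]: {agp}")
    if shoot_length < 0 or root_length < 0:
        raise ValidationError("seedling lengths must be non-negative")
    return agp * (shoot_length + root_length)


def response_index(shoot_submerged: float, shoot_control: float) -> float:
    """Signed shoot-elongation response to submergence, in cm."""
    if shoot_submerged < 0 or shoot_control < 0:
        raise ValidationError("shoot lengths must be non-negative")
    return shoot_submerged - shoot_control


def classify_tolerance(agp: float) -> ToleranceClass:
    """Bin AGP into the four tolerance classes.

    >=90 tolerant; (70, 90) moderately tolerant; (40, 70] moderately
    susceptible; <=40 susceptible. The interior bounds are half-open so the
    partition is total for fractional AGP values.
    """
    if not 0.0 <= agp <= 100.0:
        raise ValidationError(f"AGP outside [0,100]: {agp}")
    if agp >= 90.0:
        return ToleranceClass.tolerant
    if agp > 70.0:
        return ToleranceClass.moderately_tolerant
    if agp > 40.0:
        return ToleranceClass.moderately_susceptible
    return ToleranceClass.susceptible


@dataclass(frozen=True)
class GrainTypeRule:
    """Kernel-dimension thresholds for grain-type classification.

    Kernels of length >= ``long_threshold`` mm are 'long'; an LBR of at
    least ``slender_threshold`` makes a kernel 'slender'. Short kernels with
    LBR in [``medium_slender_lbr_floor``, ``slender_threshold``) are
    'medium-slender'. When ``merge_short_slender`` is set, short-slender
    kernels are reported in the short-bold group (the convention used when
    either short group is small).
    """

    long_threshold: float = 6.0
    slender_threshold: float = 3.0
    medium_slender_lbr_floor: float = 2.5
    merge_short_slender: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.medium_slender_lbr_floor < self.slender_threshold:
            raise ValidationError(
                "require 0 < medium_slender_lbr_floor < slender_threshold"
            )


DEFAULT_GRAIN_RULE = GrainTypeRule()


def classify_grain_type(
    kernel_length: float, lbr: float, rule: GrainTypeRule = DEFAULT_GRAIN_RULE
) -> str:
    """Classify a kernel by length (mm) and length-to-breadth ratio."""
    if kernel_length <= 0 or lbr <= 0:
        raise ValidationError("kernel dimensions must be positive")
    if kernel_length >= rule.long_threshold:
        return "long-slender" if lbr >= rule.slender_threshold else "long-bold"
    if lbr >= rule.slender_threshold:
        return "short-bold" if rule.merge_short_slender else "short-slender"
    if lbr >= rule.medium_slender_lbr_floor:
        return "medium-slender"
    return "short-bold"


def score_panel(
    frame: pd.DataFrame, rule: GrainTypeRule = DEFAULT_GRAIN_RULE
) -> pd.DataFrame:
    """Annotate a genotype-mean table with tolerance and grain-type classes.

    Parameters
    ----------
    frame : pandas.DataFrame
        Genotype-indexed trait means; must contain AGP, and KL/LBR for the
        rule-derived grain type.

    Returns
    -------
    pandas.DataFrame
        Copy of ``frame`` with ``tolerance_class`` and (when KL and LBR are
        present) ``grain_type_rule`` columns appended.
    """
    scored = frame.copy()
    if len(scored) == 0:
        scored["tolerance_class"] = pd.Series(dtype=object)
        return scored
    if "AGP" not in scored.columns:
        raise ValidationError("score_panel requires an AGP column")
    try:
        scored["tolerance_class"] = [
            classify_tolerance(a).name for a in scored["AGP"]
        ]
        if "KL" in scored.columns and "LBR" in scored.columns:
            scored["grain_type_rule"] = [
                classify_grain_type(kl, lbr, rule)
                for kl, lbr in zip(scored["KL"], scored["LBR"])
            ]
    except ValidationError as exc:
        raise ValidationError(f"while scoring panel: {exc}") from exc
    return scored


def tolerance_counts(scored: pd.DataFrame) -> dict[str, int]:
    """Number of genotypes per tolerance class (all four classes reported)."""
    counts = scored["tolerance_class"].value_counts() if len(scored) else {}
    return {c.name: int(counts.get(c.name, 0)) for c in TOLERANCE_ORDER}


def grain_type_counts(scored: pd.DataFrame, column: str = "grain_type") -> dict[str, int]:
    counts = scored[column].value_counts()
    return {k: int(v) for k, v in counts.items()}


def response_index_per_replicate(
    shoot_submerged: Iterable[float], shoot_control: Iterable[float]
) -> list[float]:
    """Replicate-wise RI; the per-genotype mean-based form is the default
    elsewhere because pooled tables carry one shoot length per genotype."""
    return [response_index(s, c) for s, c in zip(shoot_submerged, shoot_control)]
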