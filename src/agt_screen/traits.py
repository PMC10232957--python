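"""Canonical trait registry for the anaerobic-germination screening panel.

The screening records fourteen traits per genotype: germination and vigor
under submergence (AGP, AVI, RI), seedling architecture (SL, RL, SRR, NOL,
NOR), seedling biomass (FW, DW), and kernel morphology (KL, KB, LBR, HSW).
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class TraitSpec:
    """Static description of one measured trait.

    Attributes
    ----------
    code : str
        Short identifier used in file headers and result tables.
    name : str
        Human-readable trait name.
    unit : str
        Measurement unit ('%', 'index', 'cm', 'count', 'g', 'mm', 'ratio').
    higher_is_better : bool
        Whether larger values indicate stronger submergence tolerance or
        more desirable grain morphology.
    """

    code: str
    name: str
    unit: str
    higher_is_better: bool = True


_SPECS = [
    TraitSpec("AGP", "anaerobic germination percentage", "%"),
    TraitSpec("AVI", "anaerobic vigor index", "index"),
    TraitSpec("SL", "shoot length", "cm"),
    TraitSpec("RL", "root length", "cm"),
    TraitSpec("RI", "response index", "cm"),
    TraitSpec("SRR", "shoot-to-root ratio", "ratio"),
    TraitSpec("NOL", "number of leaves", "count"),
    TraitSpec("NOR", "number of roots", "count"),
    TraitSpec("FW", "fresh weight", "g"),
    TraitSpec("DW", "dry weight", "g"),
    TraitSpec("KL", "kernel length", "mm"),
    TraitSpec("KB", "kernel breadth", "mm"),
    TraitSpec("LBR", "kernel length-to-breadth ratio", "ratio"),
    TraitSpec("HSW", "hundred-seed weight", "g"),
]

#: Registry of the fourteen canonical traits, keyed by code.
CANONICAL_TRAITS: dict[str, TraitSpec] = {s.code: s for s in _SPECS}

#: Canonical column order for trait tables.
TRAIT_ORDER: tuple[str, ...] = tuple(s.code for s in _SPECS)

#: Traits that must be non-negative (lengths, weights, counts, indices).
NON_NEGATIVE_TRAITS = frozenset(
    c for c in TRAIT_ORDER if c not in ("RI",)
)

#: Traits bounded on [0, 100].
PERCENT_TRAITS = frozenset({"AGP"})


def is_canonical(code: str) -> bool:
    return code in CANONICAL_TRAITS
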