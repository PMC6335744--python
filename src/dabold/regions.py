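"""Region vocabulary and the hierarchical dopamine factor structure.

Sixteen regional BP_ND indicators (8 bilateral regions x 2 hemispheres) load
on 8 first-order bilateral factors, which in turn load on three correlated
second-order factors following the anatomy of the dopaminergic systems:
striatum (putamen, caudate), limbic (hippocampus, amygdala) and neocortex
(frontal, occipital, temporal, parietal). One loading per factor is fixed
to 1 to set its metric.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

__all__ = ["BILATERAL_REGIONS", "HEMISPHERES", "REGIONS", "SECOND_ORDER_MAP",
           "FactorStructure", "default_structure"]

BILATERAL_REGIONS: Tuple[str, ...] = (
    "putamen", "caudate", "hippocampus", "amygdala",
    "frontal", "occipital", "temporal", "parietal",
)
HEMISPHERES: Tuple[str, ...] = ("L", "R")

#: The 16 indicator names, e.g. "putamen_L".
REGIONS: Tuple[str, ...] = tuple(
    f"{r}_{h}" for r in BILATERAL_REGIONS for h in HEMISPHERES
)

SECOND_ORDER_MAP: Dict[str, Tuple[str, ...]] = {
    "striatal": ("putamen", "caudate"),
    "limbic": ("hippocampus", "amygdala"),
    "neocortical": ("frontal", "occipital", "temporal", "parietal"),
}


@dataclass(frozen=True)
class FactorStructure:
    """Mapping of indicators to first- and second-order factors.

    Invariants: every indicator loads on exactly one first-order factor, and
    each factor (either order) has exactly one loading fixed to 1 — the first
    indicator / first child in declaration order.
    """

    indicators: Tuple[str, ...] = REGIONS
    first_order: Dict[str, Tuple[str, ...]] = field(
        default_factory=lambda: {r: (f"{r}_L", f"{r}_R") for r in BILATERAL_REGIONS}
    )
    second_order: Dict[str, Tuple[str, ...]] = field(
        default_factory=lambda: dict(SECOND_ORDER_MAP)
    )

    def __post_init__(self) -> None:
        seen: List[str] = []
        for inds in self.first_order.values():
            seen.extend(inds)
        if sorted(seen) != sorted(self.indicators):
            raise ValueError("each indicator must load on exactly one first-order factor")
        children: List[str] = []
        for kids in self.second_order.values():
            children.extend(kids)
        if sorted(children) != sorted(self.first_order):
            raise ValueError("each first-order factor must load on exactly one second-order factor")

    @property
    def first_order_factors(self) -> Tuple[str, ...]:
        return tuple(self.first_order)

    @property
    def second_order_factors(self) -> Tuple[str, ...]:
        return tuple(self.second_order)

    def fixed_indicator(self, factor: str) -> str:
        """The indicator whose loading on ``factor`` is fixed to 1."""
        return self.first_order[factor][0]

    def fixed_child(self, factor2: str) -> str:
        """The first-order factor whose second-order loading is fixed to 1."""
        return self.second_order[factor2][0]


def default_structure() -> FactorStructure:
    return FactorStructure()
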