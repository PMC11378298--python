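"""Per-residue interaction records and the interaction map container."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .energy import EnergyComponents
from .errors import ArgumentError


@dataclass
class PairInteraction:
    """Interaction of the ligand with one pocket residue."""

    residue_label: str
    components: EnergyComponents
    closest_contact: float            # Å
    refined: bool = False
    chain: str = ""
    resnum: Optional[int] = None

    def __post_init__(self):
        if not (self.closest_contact > 0):
            raise ArgumentError("closest_contact must be positive")

    @property
    def sort_key(self):
        return (self.chain, self.resnum if self.resnum is not None else 1 << 30,
                self.residue_label)


@dataclass
class InteractionMap:
    """Per-residue interaction energies for one binding mode."""

    mode_label: str
    pairs: list = field(default_factory=list)   # list[PairInteraction]
    summed: EnergyComponents = field(default_factory=EnergyComponents)

    def recompute_sum(self) -> None:
        total = EnergyComponents()
        for p in self.pairs:
            total = total + p.components
        self.summed = total

    def validate(self, tol: float = 1e-9) -> None:
        expect = EnergyComponents()
        for p in self.pairs:
            expect = expect + p.components
        for f in EnergyComponents.FIELDS + ("total",):
            if abs(getattr(expect, f) - getattr(self.summed, f)) > tol:
                raise ArgumentError(
                    f"summed {f} inconsistent with per-residue records")

    def by_residue(self) -> dict:
        return {p.residue_label: p for p in self.pairs}
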