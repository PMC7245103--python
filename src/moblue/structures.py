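"""Registry of known molybdenum-oxide cluster structures.

Bookkeeping layer for the polyoxometalate family that frames the assembly
model: the Keggin ion {PMo12}, the {Mo36} template, the giant reduced
clusters ({Mo132} Keplerate ball, {Mo150}/{Mo154} wheels, {Mo248}, {Mo368})
and the {PMo12}-templated {Mo124Ce4} nanoring.  Records carry formula-level
facts only — building-block composition where published, Mo(VI)/Mo(V)
oxidation splits, heteroatom counts — and the module provides the small
pieces of arithmetic that connect them: nuclearity from composition,
reduced-electron counts, and reductant stoichiometry.

No crystallographic data or 3-D geometry is handled here; clusters whose
internal breakdown is not published are stored nuclearity-only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping


class RegistryError(KeyError):
    """An unknown building-block or cluster label was referenced."""


@dataclass(frozen=True)
class BuildingBlock:
    """A coarse structural unit clusters are assembled from."""

    label: str
    mo_count: int
    note: str = ""

    def __post_init__(self) -> None:
        if self.mo_count < 0:
            raise ValueError(f"mo_count must be >= 0, got {self.mo_count}")


@dataclass(frozen=True)
class ClusterRecord:
    """Formula-level facts about one named cluster.

    ``composition`` maps building-block labels to counts and may be omitted
    when no published breakdown exists.  ``mo_vi``/``mo_v`` are the counts of
    Mo(VI) and Mo(V) centers; each Mo(V) center carries one added electron.
    """

    name: str
    nuclearity: int | None = None
    composition: Mapping[str, int] | None = None
    mo_vi: int | None = None
    mo_v: int | None = None
    heteroatoms: Mapping[str, int] = field(default_factory=dict)
    note: str = ""


def reduced_electron_count(record: ClusterRecord) -> int:
    """Number of reducing electrons stored in a cluster (one per Mo(V))."""
    if record.mo_v is None:
        raise ValueError(
            f"{record.name}: Mo(V) count unspecified; cannot count electrons"
        )
    return record.mo_v


def reduction_fraction_percent(
    mo_molar: float,
    reductant_molar: float,
    electrons_per_reductant: int = 2,
) -> float:
    """Percent of Mo(VI) centers a reductant charge can reduce to Mo(V).

    Assumes one electron reduces one Mo center.  The default of two
    electrons per reductant anion is the dithionite (S2O4^2-) stoichiometry.
    The result is capped at 100%.

    >>> round(reduction_fraction_percent(0.075, 0.023), 2)
    61.33
    """
    if mo_molar <= 0:
        raise ValueError(f"mo_molar must be > 0, got {mo_molar}")
    if reductant_molar < 0:
        raise ValueError(f"reductant_molar must be >= 0, got {reductant_molar}")
    return min(100.0, 100.0 * electrons_per_reductant * reductant_molar / mo_molar)


class ClusterRegistry:
    """Lookup table of building blocks and cluster records."""

    def __init__(
        self,
        blocks: Mapping[str, BuildingBlock],
        records: Mapping[str, ClusterRecord],
    ) -> None:
        self.blocks = dict(blocks)
        self.records = dict(records)

    @classmethod
    def from_dict(cls, payload: Mapping) -> "ClusterRegistry":
        blocks = {}
        for raw in payload.get("building_blocks", []):
            blk = BuildingBlock(raw["label"], raw["mo_count"], raw.get("note", ""))
            if blk.label in blocks:
                raise ValueError(f"duplicate building-block label {blk.label!r}")
            blocks[blk.label] = blk
        records = {}
        for raw in payload.get("clusters", []):
            rec = ClusterRecord(
                name=raw["name"],
                nuclearity=raw.get("nuclearity"),
                composition=raw.get("composition"),
                mo_vi=raw.get("mo_vi"),
                mo_v=raw.get("mo_v"),
                heteroatoms=raw.get("heteroatoms", {}),
                note=raw.get("note", ""),
            )
            if rec.name in records:
                raise ValueError(f"duplicate cluster name {rec.name!r}")
            records[rec.name] = rec
        return cls(blocks, records)

    @classmethod
    def default(cls) -> "ClusterRegistry":
        """The registry shipped with the package."""
        text = resources.files("moblue.data").joinpath("registry.json").read_text()
        return cls.from_dict(json.loads(text))

    def __getitem__(self, name: str) -> ClusterRecord:
        try:
            return self.records[name]
        except KeyError:
            raise RegistryError(f"unknown cluster {name!r}") from None

    def nuclearity_from_composition(self, composition: Mapping[str, int]) -> int:
        """Total Mo atoms implied by a building-block composition.

        >>> ClusterRegistry.default().nuclearity_from_composition(
        ...     {"Mo8": 12, "Mo2": 8, "Mo1": 12})
        124
        """
        total = 0
        for label, count in composition.items():
            if count < 0:
                raise ValueError(f"negative count for {label!r}")
            if label not in self.blocks:
                raise RegistryError(f"unknown building block {label!r}")
            total += count * self.blocks[label].mo_count
        return total

    def validate(self) -> list[str]:
        """Check every record's internal consistency.

        Returns a list of human-readable violations (empty on success):
        composition labels must resolve, counts must be non-negative, and
        where both an oxidation split and a nuclearity are given they must
        agree, as must a composition-implied nuclearity.
        """
        violations: list[str] = []
        for rec in self.records.values():
            comp_nuc: int | None = None
            if rec.composition is not None:
                try:
                    comp_nuc = self.nuclearity_from_composition(rec.composition)
                except (RegistryError, ValueError) as exc:
                    violations.append(f"{rec.name}: {exc}")
            if (rec.mo_vi is not None and rec.mo_vi < 0) or (
                rec.mo_v is not None and rec.mo_v < 0
            ):
                violations.append(f"{rec.name}: negative oxidation-state count")
                continue
            if rec.mo_vi is not None and rec.mo_v is not None:
                split = rec.mo_vi + rec.mo_v
                for label, value in (
                    ("declared nuclearity", rec.nuclearity),
                    ("composition nuclearity", comp_nuc),
                ):
                    if value is not None and value != split:
                        violations.append(
                            f"{rec.name}: mo_vi+mo_v = {split} != {label} {value}"
                        )
            if (
                rec.nuclearity is not None
                and comp_nuc is not None
                and comp_nuc != rec.nuclearity
            ):
                violations.append(
                    f"{rec.name}: composition implies {comp_nuc} Mo, "
                    f"declared {rec.nuclearity}"
                )
        return violations


def validate_registry(registry: ClusterRegistry) -> list[str]:
    """Functional alias for :meth:`ClusterRegistry.validate`."""
    return registry.validate()
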