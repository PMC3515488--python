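"""Core containers for multilocus codominant genotypes.

Alleles are integer fragment lengths (base pairs); a single-locus genotype
is an unordered allele pair stored canonically as ``(min, max)``, or ``None``
for missing data.  Partial calls (one known allele) are not represented:
anything short of a full diploid call is treated as missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

__all__ = [
    "Genotype",
    "genotype",
    "is_heterozygous",
    "MarkerPanel",
    "Individual",
    "GenotypeDataset",
    "CrossDesign",
    "MassCrossError",
]

#: A diploid single-locus genotype: canonical ordered pair, or None (missing).
Genotype = Optional[tuple[int, int]]

SEXES = ("male", "female", "unknown")
ROLES = ("parent", "offspring")


class MassCrossError(ValueError):
    """Domain error (malformed input, violated invariant)."""


def genotype(a: int, b: int) -> tuple[int, int]:
    """Canonicalize an unordered allele pair so that a/b == b/a.

    >>> genotype(288, 276)
    (276, 288)
    """
    if a <= 0 or b <= 0:
        raise MassCrossError(f"allele sizes must be positive, got {a}/{b}")
    return (a, b) if a <= b else (b, a)


def is_heterozygous(g: tuple[int, int]) -> bool:
    return g[0] != g[1]


@dataclass
class MarkerPanel:
    """Ordered marker loci plus the per-locus registry of observed alleles."""

    loci: list[str]
    registry: dict[str, set[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.loci)) != len(self.loci):
            raise MassCrossError("duplicate locus names in panel")
        for locus in self.loci:
            self.registry.setdefault(locus, set())

    def observe(self, locus: str, g: Genotype) -> None:
        if g is not None:
            self.registry[locus].update(g)

    def __len__(self) -> int:
        return len(self.loci)


@dataclass
class Individual:
    """A genotyped fish: candidate parent (sexed) or offspring."""

    id: str
    sex: str
    role: str
    genotype: dict[str, Genotype]

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise MassCrossError(f"unknown sex {self.sex!r} for {self.id!r}")
        if self.role not in ROLES:
            raise MassCrossError(f"unknown role {self.role!r} for {self.id!r}")

    def at(self, locus: str) -> Genotype:
        return self.genotype.get(locus)

    def n_typed(self) -> int:
        """Number of loci with a non-missing call."""
        return sum(1 for g in self.genotype.values() if g is not None)


@dataclass
class GenotypeDataset:
    """A marker panel plus all genotyped individuals (parents and offspring)."""

    panel: MarkerPanel
    individuals: list[Individual]

    def __post_init__(self) -> None:
        ids = [ind.id for ind in self.individuals]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise MassCrossError(f"duplicate individual ids: {dupes}")
        if not self.panel.loci:
            raise MassCrossError("panel has no loci")
        for ind in self.individuals:
            extra = set(ind.genotype) - set(self.panel.loci)
            if extra:
                raise MassCrossError(f"{ind.id}: loci not in panel: {sorted(extra)}")
            for locus, g in ind.genotype.items():
                self.panel.observe(locus, g)

    def __getitem__(self, ind_id: str) -> Individual:
        for ind in self.individuals:
            if ind.id == ind_id:
                return ind
        raise KeyError(ind_id)

    @property
    def parents(self) -> list[Individual]:
        return [i for i in self.individuals if i.role == "parent"]

    @property
    def offspring(self) -> list[Individual]:
        return [i for i in self.individuals if i.role == "offspring"]


@dataclass
class CrossDesign:
    """Full-factorial cross: every listed sire × dam pair is a candidate family."""

    sire_ids: list[str]
    dam_ids: list[str]

    def __post_init__(self) -> None:
        if set(self.sire_ids) & set(self.dam_ids):
            raise MassCrossError("sire and dam id lists overlap")
        if len(set(self.sire_ids)) != len(self.sire_ids) or len(set(self.dam_ids)) != len(self.dam_ids):
            raise MassCrossError("duplicate parent ids in design")

    def validate_against(self, dataset: GenotypeDataset) -> None:
        """Check that every design parent exists with the matching sex."""
        for ids, sex in ((self.sire_ids, "male"), (self.dam_ids, "female")):
            for pid in ids:
                try:
                    ind = dataset[pid]
                except KeyError:
                    raise MassCrossError(f"design parent {pid!r} absent from dataset") from None
                if ind.role != "parent":
                    raise MassCrossError(f"{pid!r} is not a parent in the dataset")
                if ind.sex != sex:
                    raise MassCrossError(f"{pid!r} listed as {sex} but has sex {ind.sex!r}")

    @property
    def n_pairs(self) -> int:
        return len(self.sire_ids) * len(self.dam_ids)
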