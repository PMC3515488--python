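"""Maximum-likelihood parent-pair assignment under error-free Mendelian segregation.

Each candidate sire×dam pair is scored by the product over loci of the
Mendelian transmission probability of the offspring genotype; the offspring
is assigned to the unique pair maximizing the log-likelihood.  The model
assumes codominant markers, no genotyping error, no mutation and no null
alleles, so a single incompatible locus excludes a pair outright.  Ties
within a relative tolerance are reported as ambiguous, never silently
broken.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional

from .genotypes import CrossDesign, Genotype, GenotypeDataset, Individual, MarkerPanel, MassCrossError

__all__ = [
    "transmission_probability",
    "pair_loglikelihood",
    "assign_all",
    "assignment_rate",
    "AssignmentRecord",
    "AssignmentResult",
    "PairScore",
]


@lru_cache(maxsize=None)
def _transmission(gs: tuple[int, int], gd: tuple[int, int], go: tuple[int, int]) -> float:
    # The four equiprobable gamete combinations (one allele from each parent).
    hits = 0
    for a in gs:
        for b in gd:
            if (a, b) == go or (b, a) == go:
                hits += 1
    return hits / 4.0


def transmission_probability(g_sire: Genotype, g_dam: Genotype, g_off: Genotype) -> float:
    """P(offspring genotype | sire genotype, dam genotype) at one locus.

    Sums the 2×2 equiprobable gamete combinations (weight 1/4 each) that
    produce the offspring's unordered pair; 0 if none can.

    >>> transmission_probability((1, 2), (3, 4), (1, 3))
    0.25
    >>> transmission_probability((1, 1), (1, 1), (1, 1))
    1.0
    """
    if g_sire is None or g_dam is None or g_off is None:
        raise MassCrossError("transmission_probability requires non-missing genotypes")
    return _transmission(g_sire, g_dam, g_off)


@dataclass(frozen=True)
class PairScore:
    """Log-likelihood of one candidate pair, or incompatibility with a reason."""

    loglik: Optional[float]  # None when incompatible
    n_loci_used: int
    reason: Optional[str] = None

    @property
    def compatible(self) -> bool:
        return self.loglik is not None


def pair_loglikelihood(
    offspring: Individual,
    sire: Individual,
    dam: Individual,
    panel: MarkerPanel,
    min_loci: int = 5,
) -> PairScore:
    """Score one sire×dam pair for one offspring.

    Loci where any of the trio is missing are skipped (contribute factor 1).
    A single used locus with transmission probability 0 makes the pair
    incompatible; fewer than ``min_loci`` usable loci is reported as
    ``insufficient loci``.
    """
    loglik = 0.0
    n_used = 0
    for locus in panel.loci:
        go, gs, gd = offspring.at(locus), sire.at(locus), dam.at(locus)
        if go is None or gs is None or gd is None:
            continue
        p = _transmission(gs, gd, go)
        if p == 0.0:
            return PairScore(None, n_used + 1, reason=f"incompatible at {locus}")
        loglik += math.log(p)
        n_used += 1
    if n_used < min_loci:
        return PairScore(None, n_used, reason="insufficient loci")
    return PairScore(loglik, n_used)


@dataclass
class AssignmentRecord:
    offspring_id: str
    status: str  # assigned | ambiguous | unassigned
    pair: Optional[tuple[str, str]]  # (sire_id, dam_id)
    loglik: Optional[float]
    n_loci_used: int
    n_compatible_pairs: int
    ties: list[tuple[str, str]] = field(default_factory=list)
    reason: Optional[str] = None


@dataclass
class AssignmentResult:
    records: list[AssignmentRecord]
    design: CrossDesign

    def counts(self) -> dict[str, int]:
        out = {"assigned": 0, "ambiguous": 0, "unassigned": 0}
        for r in self.records:
            out[r.status] += 1
        return out

    def __len__(self) -> int:
        return len(self.records)


def assign_all(
    dataset: GenotypeDataset,
    design: CrossDesign,
    min_loci: int = 5,
    tie_tol: float = 1e-9,
) -> AssignmentResult:
    """Assign every offspring to its maximum-likelihood candidate pair.

    Status is ``assigned`` for a unique maximal compatible pair, ``ambiguous``
    when ≥2 pairs lie within relative tolerance ``tie_tol`` of the maximum
    log-likelihood, and ``unassigned`` when no pair is compatible.
    """
    if not design.sire_ids or not design.dam_ids:
        raise MassCrossError("empty cross design")
    design.validate_against(dataset)
    sires = [dataset[s] for s in design.sire_ids]
    dams = [dataset[d] for d in design.dam_ids]
    panel = dataset.panel

    records: list[AssignmentRecord] = []
    for off in dataset.offspring:
        if off.n_typed() == 0:
            records.append(
                AssignmentRecord(off.id, "unassigned", None, None, 0, 0, reason="all loci missing")
            )
            continue
        scored: list[tuple[float, int, tuple[str, str]]] = []
        for sire in sires:
            for dam in dams:
                sc = pair_loglikelihood(off, sire, dam, panel, min_loci=min_loci)
                if sc.compatible:
                    scored.append((sc.loglik, sc.n_loci_used, (sire.id, dam.id)))
        if not scored:
            records.append(
                AssignmentRecord(off.id, "unassigned", None, None, 0, 0, reason="no compatible pair")
            )
            continue
        best = max(ll for ll, _, _ in scored)
        # relative tolerance on log-likelihoods (all ≤ 0 here)
        ties = [(ll, n, pair) for ll, n, pair in scored if ll >= best - tie_tol * max(1.0, abs(best))]
        if len(ties) == 1:
            ll, n, pair = ties[0]
            records.append(AssignmentRecord(off.id, "assigned", pair, ll, n, len(scored)))
        else:
            ll, n, pair = max(ties)
            records.append(
                AssignmentRecord(
                    off.id, "ambiguous", None, ll, n, len(scored),
                    ties=[p for _, _, p in ties], reason="tied maximum likelihood",
                )
            )
    return AssignmentResult(records=records, design=design)


def assignment_rate(result: AssignmentResult) -> float:
    """Fraction of offspring with status ``assigned`` (in [0, 1])."""
    if not result.records:
        raise MassCrossError("empty assignment result")
    return result.counts()["assigned"] / len(result.records)
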