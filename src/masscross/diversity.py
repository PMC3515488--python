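"""Allele frequencies, heterozygosity and parent→offspring diversity change.

Per locus the module reports the allele count A, observed heterozygosity Ho
(fraction of non-missing genotypes that are heterozygous), Nei's unbiased
gene diversity He = (2n/(2n−1))·(1−Σp²) with n the number of non-missing
individuals, and the fixation index f = 1 − Ho/He (undefined at monomorphic
loci).  Means over loci are unweighted; mean f averages polymorphic loci
only.  Retention analysis compares a parental and an offspring set:
allelic loss (A_p − A_o)/A_p and gene-diversity loss (He_p − He_o)/He_p,
with the list of parental alleles absent from the offspring.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genotypes import Individual, MarkerPanel, MassCrossError, is_heterozygous

__all__ = [
    "allele_frequencies",
    "diversity_stats",
    "allele_retention",
    "loss_fraction",
    "DiversityStats",
]


def allele_frequencies(individuals: Sequence[Individual], locus: str) -> dict:
    """Allele frequency spectrum at one locus over non-missing gene copies."""
    counts: dict[int, int] = {}
    n_ind = 0
    for ind in individuals:
        g = ind.at(locus)
        if g is None:
            continue
        n_ind += 1
        for a in g:
            counts[a] = counts.get(a, 0) + 1
    n_copies = 2 * n_ind
    if n_copies == 0:
        raise MassCrossError(f"all genotypes missing at locus {locus!r}")
    freqs = {a: c / n_copies for a, c in sorted(counts.items())}
    return {"locus": locus, "frequencies": freqs, "n_individuals": n_ind, "n_gene_copies": n_copies}


@dataclass
class DiversityStats:
    """Per-locus table and means of A, Ho, He, f for one set of individuals."""

    per_locus: pd.DataFrame  # index: locus; columns: n, A, Ho, He, f
    n_individuals: int

    @property
    def means(self) -> dict[str, float]:
        m = {
            "A": float(self.per_locus["A"].mean()),
            "Ho": float(self.per_locus["Ho"].mean()),
            "He": float(self.per_locus["He"].mean()),
            # f is undefined (NaN) at monomorphic loci; average the rest
            "f": float(self.per_locus["f"].mean(skipna=True)),
        }
        return m


def diversity_stats(individuals: Sequence[Individual], panel: MarkerPanel) -> DiversityStats:
    """Compute A, Ho, He (Nei unbiased) and f per locus plus unweighted means."""
    if len(individuals) < 2:
        raise MassCrossError("diversity statistics need at least two individuals")
    rows = []
    for locus in panel.loci:
        genos = [ind.at(locus) for ind in individuals if ind.at(locus) is not None]
        n = len(genos)
        if n == 0:
            rows.append({"locus": locus, "n": 0, "A": np.nan, "Ho": np.nan, "He": np.nan, "f": np.nan})
            continue
        spec = allele_frequencies(individuals, locus)
        p = np.array(list(spec["frequencies"].values()))
        a_count = p.size
        ho = sum(is_heterozygous(g) for g in genos) / n
        if a_count == 1:
            he = 0.0
            f = np.nan
        else:
            he = (2 * n / (2 * n - 1)) * (1.0 - float(np.sum(p**2)))
            f = 1.0 - ho / he if he > 0 else np.nan
        rows.append({"locus": locus, "n": n, "A": a_count, "Ho": ho, "He": he, "f": f})
    table = pd.DataFrame(rows).set_index("locus")
    return DiversityStats(per_locus=table, n_individuals=len(individuals))


def loss_fraction(before: float, after: float) -> float:
    """Relative loss (before − after)/before; 0 when both are 0."""
    if before == 0:
        return 0.0
    return (before - after) / before


def allele_retention(
    parents: Sequence[Individual],
    offspring: Sequence[Individual],
    panel: MarkerPanel,
) -> dict:
    """Parent→offspring diversity retention/loss per locus and on the means."""
    if not parents or not offspring:
        raise MassCrossError("both parent and offspring sets must be non-empty")
    stats_p = diversity_stats(parents, panel)
    stats_o = diversity_stats(offspring, panel)
    per_locus = []
    for locus in panel.loci:
        alleles_p = set(allele_frequencies(parents, locus)["frequencies"])
        alleles_o = set(allele_frequencies(offspring, locus)["frequencies"])
        lost = sorted(alleles_p - alleles_o)
        ap, ao = stats_p.per_locus.loc[locus, "A"], stats_o.per_locus.loc[locus, "A"]
        hp, ho_ = stats_p.per_locus.loc[locus, "He"], stats_o.per_locus.loc[locus, "He"]
        per_locus.append(
            {
                "locus": locus,
                "allelic_loss": loss_fraction(ap, ao),
                "gene_diversity_loss": loss_fraction(hp, ho_),
                "lost_alleles": lost,
            }
        )
    mp, mo = stats_p.means, stats_o.means
    return {
        "per_locus": per_locus,
        "mean_allelic_loss": loss_fraction(mp["A"], mo["A"]),
        "mean_gene_diversity_loss": loss_fraction(mp["He"], mo["He"]),
        "parents": stats_p,
        "offspring": stats_o,
    }
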