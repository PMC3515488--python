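"""Family matrices, parental contribution percentages and chi-square skew tests.

The central object is the dam×sire matrix of assigned-offspring counts.  Its
marginals give per-parent contributions; equality of contribution among ALL
candidate parents of a sex (zero contributors included, d.f. = k−1) is tested
with a chi-square goodness-of-fit against the uniform expectation N/k.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import MassCrossError
from .parentage import AssignmentResult

__all__ = [
    "FamilyMatrix",
    "family_matrix",
    "percent_contribution",
    "chi_square_uniform",
    "count_contributing",
    "count_families",
    "contribution_summary",
    "ChiSquareResult",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal round-half-up (0.05 at 1 dp → 0.1), matching printed tables."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class FamilyMatrix:
    """Dam×sire assigned-offspring counts with marginals."""

    counts: pd.DataFrame  # index: dam ids, columns: sire ids

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise MassCrossError("negative family counts")

    @property
    def dam_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sire_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n(self) -> int:
        return int(self.counts.to_numpy().sum())

    def totals(self, sex: str) -> pd.Series:
        """Per-parent marginal counts for ``sire`` (columns) or ``dam`` (rows)."""
        if sex == "sire":
            return self.counts.sum(axis=0)
        if sex == "dam":
            return self.counts.sum(axis=1)
        raise MassCrossError(f"sex must be 'sire' or 'dam', got {sex!r}")


def family_matrix(result: AssignmentResult) -> FamilyMatrix:
    """Tabulate assigned offspring into the dam×sire family matrix.

    Ambiguous and unassigned records are excluded (never fractionally
    allocated).
    """
    counts = pd.DataFrame(
        0, index=pd.Index(result.design.dam_ids, name="dam"), columns=result.design.sire_ids, dtype=int
    )
    n_assigned = 0
    for rec in result.records:
        if rec.status == "assigned":
            sire_id, dam_id = rec.pair
            counts.loc[dam_id, sire_id] += 1
            n_assigned += 1
    if n_assigned == 0:
        raise MassCrossError("no assigned offspring: cannot build a family matrix")
    return FamilyMatrix(counts=counts)


def percent_contribution(matrix: FamilyMatrix, sex: str) -> pd.DataFrame:
    """Per-parent contribution: count, exact fraction, and percent at 1 dp."""
    totals = matrix.totals(sex)
    n = matrix.n
    if n == 0:
        raise MassCrossError("empty family matrix")
    frac = totals / n
    return pd.DataFrame(
        {
            "count": totals,
            "fraction": frac,
            "percent": [round_half_up(100 * f, 1) for f in frac],
        }
    )


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    dof: int
    pvalue: float


def chi_square_uniform(totals: Sequence[float] | pd.Series) -> ChiSquareResult:
    """Chi-square goodness-of-fit of per-parent counts against equal sharing.

    All k candidates (including zero contributors) enter, so the expectation
    is N/k and d.f. = k−1.
    """
    arr = np.asarray(totals, dtype=float)
    if arr.size < 2:
        raise MassCrossError("need at least two candidate parents")
    if arr.sum() <= 0:
        raise MassCrossError("no offspring counted")
    stat, p = stats.chisquare(arr)
    return ChiSquareResult(statistic=float(stat), dof=arr.size - 1, pvalue=float(p))


def count_contributing(matrix: FamilyMatrix, sex: str) -> int:
    """Number of candidates of one sex with at least one assigned offspring."""
    return int((matrix.totals(sex) > 0).sum())


def count_families(matrix: FamilyMatrix) -> int:
    """Number of realized families (strictly positive cells)."""
    return int((matrix.counts.to_numpy() > 0).sum())


def contribution_summary(matrix: FamilyMatrix) -> dict:
    """Full per-cross contribution report (JSON-serializable)."""
    out: dict = {"n_offspring": matrix.n, "n_families": count_families(matrix)}
    for sex in ("sire", "dam"):
        table = percent_contribution(matrix, sex)
        chi = chi_square_uniform(table["count"])
        out[sex] = {
            "totals": {str(k): int(v) for k, v in table["count"].items()},
            "percent": {str(k): float(v) for k, v in table["percent"].items()},
            "n_contributing": count_contributing(matrix, sex),
            "chi_square": {"statistic": chi.statistic, "dof": chi.dof, "pvalue": chi.pvalue},
        }
    return out
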