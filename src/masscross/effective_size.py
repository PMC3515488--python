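"""Effective population size from the family-size distribution.

For an offspring cohort of size N with per-sire family sizes of mean Ks and
variance Vs (and Kd, Vd for dams):

    Ne = 4 (N − 2) / ((Ks + Vs/Ks) + (Kd + Vd/Kd) − 2)

Variances are population variances over the full candidate lists (divisor =
number of candidates, zero contributors included).  With that convention
K + V/K = Σx²/Σx, so Ne is invariant to padding a candidate list with
non-contributors — only realized family sizes matter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .contribution import FamilyMatrix
from .genotypes import MassCrossError

__all__ = ["NeResult", "effective_size", "ne_report"]


@dataclass(frozen=True)
class NeResult:
    n: int          # offspring sampled (assigned cohort)
    ks: float       # mean offspring per candidate sire
    vs: float       # population variance of sire family sizes
    kd: float
    vd: float
    ne: float


def effective_size(sire_totals: Sequence[float], dam_totals: Sequence[float]) -> NeResult:
    """Evaluate the family-size-variance Ne formula on per-candidate counts."""
    s = np.asarray(sire_totals, dtype=float)
    d = np.asarray(dam_totals, dtype=float)
    if s.size == 0 or d.size == 0:
        raise MassCrossError("need at least one candidate per sex")
    if not np.isclose(s.sum(), d.sum()):
        raise MassCrossError(f"sire totals sum {s.sum()} != dam totals sum {d.sum()}")
    n = s.sum()
    if n <= 2:
        raise MassCrossError("Ne formula requires more than 2 offspring")
    ks, vs = s.mean(), s.var()  # population variance (divisor = k)
    kd, vd = d.mean(), d.var()
    denom = (ks + vs / ks) + (kd + vd / kd) - 2.0
    ne = 4.0 * (n - 2.0) / denom
    return NeResult(n=int(n), ks=float(ks), vs=float(vs), kd=float(kd), vd=float(vd), ne=float(ne))


def ne_report(matrices: Mapping[str, FamilyMatrix]) -> pd.DataFrame:
    """One Ne row per cross, with the Ne / census-size ratio.

    Census size is the number of candidate parents in the cross design
    (sires + dams), not just the contributors.
    """
    rows = []
    for name, matrix in matrices.items():
        res = effective_size(matrix.totals("sire"), matrix.totals("dam"))
        census = len(matrix.sire_ids) + len(matrix.dam_ids)
        rows.append(
            {
                "cross": name,
                "N": res.n,
                "Ks": res.ks,
                "Vs": res.vs,
                "Kd": res.kd,
                "Vd": res.vd,
                "Ne": res.ne,
                "census": census,
                "Ne_over_census": res.ne / census,
            }
        )
    return pd.DataFrame(rows).set_index("cross")
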