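"""Packaged offspring-count matrices from four Asian seabass mass crosses.

Each fixture is the dam×sire table of offspring assigned by
nine-microsatellite parentage analysis of one full-factorial mass spawning
(10 sires × 10 dams).  Crosses 1–2 used brooders screened for reproductive
readiness; crosses 3–4 used unscreened brooders and collapsed onto one
dominant dam.  Marginals are recomputed from the cells on load.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from ..contribution import FamilyMatrix

CROSS_NAMES = ("cross1", "cross2", "cross3", "cross4")

__all__ = ["CROSS_NAMES", "load_family_matrix", "load_all_crosses"]


def load_family_matrix(name: str) -> FamilyMatrix:
    """Load one packaged cross matrix by name (``cross1`` … ``cross4``)."""
    if name not in CROSS_NAMES:
        raise KeyError(f"unknown cross fixture {name!r}; choose from {CROSS_NAMES}")
    with resources.files(__package__).joinpath(f"{name}.tsv").open("r", encoding="utf-8") as fh:
        df = pd.read_csv(fh, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return FamilyMatrix(counts=df.astype(int))


def load_all_crosses() -> dict[str, FamilyMatrix]:
    return {name: load_family_matrix(name) for name in CROSS_NAMES}
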