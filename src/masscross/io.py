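"""Readers and writers for genotype tables, Genepop files, designs and matrices.

Two genotype formats are supported:

* a CSV matrix with header ``id,sex,role,<locus1>,...,<locusK>`` and cells
  ``a/b`` (``a/a`` for homozygotes, empty for missing), and
* the Genepop dialect with 3-digit allele codes, where the first ``Pop``
  block holds the candidate parents and the second the offspring.

Serialization is canonical ("smaller/larger" allele order) so that
write ∘ read round-trips bit-stably.
"""

from __future__ import annotations

import csv
import re
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from .genotypes import (
    CrossDesign,
    Genotype,
    GenotypeDataset,
    Individual,
    MarkerPanel,
    MassCrossError,
    ROLES,
    SEXES,
    genotype,
)

__all__ = [
    "read_genotype_table",
    "write_genotype_table",
    "read_genepop",
    "write_genepop",
    "read_cross_design",
    "write_cross_design",
    "read_family_counts",
    "write_family_counts",
]

_CELL_RE = re.compile(r"^\s*(\d+)\s*/\s*(\d+)\s*$")


def _parse_cell(cell: str, row: int, column: str) -> Genotype:
    if cell is None or cell.strip() == "":
        return None
    m = _CELL_RE.match(cell)
    if not m:
        raise MassCrossError(f"malformed genotype cell {cell!r} at row {row}, locus {column!r}")
    return genotype(int(m.group(1)), int(m.group(2)))


def _format_cell(g: Genotype) -> str:
    return "" if g is None else f"{g[0]}/{g[1]}"


def read_genotype_table(path: str | Path, panel_spec: Optional[Sequence[str]] = None) -> GenotypeDataset:
    """Load a CSV genotype matrix.

    Parameters
    ----------
    path
        CSV file with header ``id,sex,role,<locus1>,...``.
    panel_spec
        Optional explicit locus list; must match the header loci when given.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise MassCrossError(f"{path}: empty file") from None
        if len(header) < 4 or [h.strip().lower() for h in header[:3]] != ["id", "sex", "role"]:
            raise MassCrossError(f"{path}: header must start with id,sex,role followed by loci")
        loci = [h.strip() for h in header[3:]]
        if panel_spec is not None and list(panel_spec) != loci:
            raise MassCrossError(f"{path}: header loci {loci} do not match panel_spec {list(panel_spec)}")
        panel = MarkerPanel(loci=loci)
        individuals: list[Individual] = []
        seen: set[str] = set()
        for rownum, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != 3 + len(loci):
                raise MassCrossError(f"{path}: row {rownum} has {len(row)} fields, expected {3 + len(loci)}")
            ind_id, sex, role = (c.strip() for c in row[:3])
            if ind_id in seen:
                raise MassCrossError(f"{path}: duplicate id {ind_id!r} at row {rownum}")
            seen.add(ind_id)
            if sex not in SEXES:
                raise MassCrossError(f"{path}: unknown sex {sex!r} at row {rownum}")
            if role not in ROLES:
                raise MassCrossError(f"{path}: unknown role {role!r} at row {rownum}")
            geno = {locus: _parse_cell(cell, rownum, locus) for locus, cell in zip(loci, row[3:])}
            individuals.append(Individual(id=ind_id, sex=sex, role=role, genotype=geno))
    return GenotypeDataset(panel=panel, individuals=individuals)


def write_genotype_table(dataset: GenotypeDataset, path: str | Path) -> None:
    """Write the canonical CSV genotype matrix (round-trips with the reader)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["id", "sex", "role", *dataset.panel.loci])
        for ind in dataset.individuals:
            writer.writerow(
                [ind.id, ind.sex, ind.role, *(_format_cell(ind.at(l)) for l in dataset.panel.loci)]
            )


# ---------------------------------------------------------------------------
# Genepop (3-digit dialect)
# ---------------------------------------------------------------------------

def _genepop_code(g: Genotype) -> str:
    if g is None:
        return "000000"
    if g[1] > 999:
        raise MassCrossError(f"allele {g[1]} too large for 3-digit Genepop coding")
    return f"{g[0]:03d}{g[1]:03d}"


def write_genepop(dataset: GenotypeDataset, path: str | Path, title: str = "masscross export") -> None:
    """Write a 3-digit Genepop file: Pop 1 = parents, Pop 2 = offspring.

    Parent sex cannot be carried in Genepop; a round-trip restores it from the
    id prefix written here (``M:``/``F:`` for parents).
    """
    path = Path(path)
    lines = [title]
    lines += dataset.panel.loci
    for group in (dataset.parents, dataset.offspring):
        lines.append("Pop")
        for ind in group:
            prefix = {"male": "M:", "female": "F:", "unknown": "U:"}[ind.sex]
            codes = " ".join(_genepop_code(ind.at(l)) for l in dataset.panel.loci)
            lines.append(f"{prefix}{ind.id} , {codes}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def _decode_genepop(code: str, lineno: int) -> Genotype:
    if len(code) == 6:
        a, b = int(code[:3]), int(code[3:])
    elif len(code) == 4:
        raise MassCrossError(f"line {lineno}: 2-digit Genepop coding not supported (mixed coding?)")
    else:
        raise MassCrossError(f"line {lineno}: malformed allele code {code!r}")
    if a == 0 or b == 0:
        return None  # 000 encodes missing
    return genotype(a, b)


def read_genepop(path: str | Path) -> GenotypeDataset:
    """Read a 3-digit Genepop file (first Pop = parents, second = offspring)."""
    path = Path(path)
    raw = [ln.rstrip() for ln in path.read_text(encoding="utf-8").splitlines()]
    if len(raw) < 3:
        raise MassCrossError(f"{path}: truncated Genepop file")
    body = raw[1:]
    loci: list[str] = []
    i = 0
    while i < len(body) and body[i].strip().lower() != "pop":
        # locus names may be one per line or comma-separated
        loci.extend(l.strip() for l in body[i].split(",") if l.strip())
        i += 1
    if i == len(body):
        raise MassCrossError(f"{path}: no Pop separator found")
    panel = MarkerPanel(loci=loci)
    individuals: list[Individual] = []
    pop_index = -1
    for lineno, line in enumerate(body[i:], start=i + 2):
        if line.strip().lower() == "pop":
            pop_index += 1
            continue
        if not line.strip():
            continue
        if "," not in line:
            raise MassCrossError(f"{path}: line {lineno}: expected 'id , codes'")
        name, codes_str = line.split(",", 1)
        name = name.strip()
        sex = "unknown"
        if name[:2] in ("M:", "F:", "U:"):
            sex = {"M": "male", "F": "female", "U": "unknown"}[name[0]]
            name = name[2:]
        codes = codes_str.split()
        if len(codes) != len(loci):
            raise MassCrossError(f"{path}: line {lineno}: {len(codes)} codes for {len(loci)} loci")
        geno = {locus: _decode_genepop(code, lineno) for locus, code in zip(loci, codes)}
        role = "parent" if pop_index == 0 else "offspring"
        individuals.append(Individual(id=name, sex=sex, role=role, genotype=geno))
    if pop_index < 1:
        raise MassCrossError(f"{path}: expected two Pop blocks (parents, offspring)")
    return GenotypeDataset(panel=panel, individuals=individuals)


# ---------------------------------------------------------------------------
# Cross designs (YAML) and family-count matrices (TSV)
# ---------------------------------------------------------------------------

def read_cross_design(path: str | Path) -> CrossDesign:
    """Load a YAML cross design: ``{sires: [...], dams: [...]}``."""
    with Path(path).open(encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "sires" not in doc or "dams" not in doc:
        raise MassCrossError(f"{path}: design YAML needs 'sires' and 'dams' lists")
    return CrossDesign(sire_ids=[str(s) for s in doc["sires"]], dam_ids=[str(d) for d in doc["dams"]])


def write_cross_design(design: CrossDesign, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        yaml.safe_dump({"sires": design.sire_ids, "dams": design.dam_ids}, fh, sort_keys=False)


def read_family_counts(path: str | Path) -> pd.DataFrame:
    """Read a dam×sire offspring-count matrix (TSV; dams as rows)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    counts = df.to_numpy()
    if (counts < 0).any():
        raise MassCrossError(f"{path}: negative family counts")
    return df.astype(int)


def write_family_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t")
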