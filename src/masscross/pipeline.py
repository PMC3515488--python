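"""End-to-end orchestration: load/simulate → assign → contribution → diversity → Ne.

``run_pipeline`` accepts exactly one input source — a genotype table plus a
cross design, a simulation config, or a bare family-count matrix (the
"matrix-only" mode for published count tables without genotypes) — and
writes a consolidated per-cross report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from . import io as mio
from .contribution import FamilyMatrix, contribution_summary, family_matrix
from .diversity import allele_retention
from .effective_size import effective_size
from .genotypes import CrossDesign, GenotypeDataset, MassCrossError
from .parentage import AssignmentResult, assign_all, assignment_rate
from .simulate import SimConfig, simulate_dataset

logger = logging.getLogger("masscross")

__all__ = ["PipelineConfig", "run_pipeline", "write_assignment_report", "design_from_dataset"]


@dataclass
class PipelineConfig:
    """One input source (genotypes+design | simulation | family matrix) + options."""

    genotypes: Optional[Path] = None
    design: Optional[Path] = None
    sim: Optional[SimConfig] = None
    matrix: Optional[Path] = None
    min_loci: int = 5
    tie_tol: float = 1e-9
    outdir: Path = Path("masscross_out")

    def __post_init__(self) -> None:
        sources = [self.genotypes is not None, self.sim is not None, self.matrix is not None]
        if sum(sources) != 1:
            raise MassCrossError("exactly one input source required: genotypes, sim or matrix")


def design_from_dataset(dataset: GenotypeDataset) -> CrossDesign:
    """Full-factorial design over every sexed parent in the dataset."""
    sires = [p.id for p in dataset.parents if p.sex == "male"]
    dams = [p.id for p in dataset.parents if p.sex == "female"]
    return CrossDesign(sire_ids=sires, dam_ids=dams)


def write_assignment_report(result: AssignmentResult, path: Path) -> None:
    """TSV: offspring_id, status, sire_id, dam_id, loglik, n_loci_used, n_compatible_pairs."""
    lines = ["offspring_id\tstatus\tsire_id\tdam_id\tloglik\tn_loci_used\tn_compatible_pairs"]
    for r in result.records:
        sire, dam = r.pair if r.pair else ("", "")
        ll = f"{r.loglik:.6f}" if r.loglik is not None else ""
        lines.append(f"{r.offspring_id}\t{r.status}\t{sire}\t{dam}\t{ll}\t{r.n_loci_used}\t{r.n_compatible_pairs}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def _jsonable(obj):
    """Strict-JSON view: numpy scalars to native, NaN (undefined f) to null."""
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (float, np.floating)):
        f = float(obj)
        return None if np.isnan(f) else f
    if isinstance(obj, np.integer):
        return int(obj)
    return obj


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise MassCrossError(f"stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every applicable stage; returns (and writes) the report bundle."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {}

    dataset: Optional[GenotypeDataset] = None
    pedigree = None
    if config.sim is not None:
        logger.info("simulating cross: %d sires × %d dams, %d offspring",
                    config.sim.n_sires, config.sim.n_dams, config.sim.n_offspring)
        dataset, pedigree = simulate_dataset(config.sim)
        mio.write_genotype_table(dataset, outdir / "genotypes.csv")
        truth_lines = ["offspring_id\tsire_id\tdam_id"] + [
            f"{o}\t{s}\t{d}" for o, (s, d) in pedigree.items()
        ]
        (outdir / "pedigree_truth.tsv").write_text("\n".join(truth_lines) + "\n", encoding="utf-8")
    elif config.genotypes is not None:
        dataset = _stage("load")(mio.read_genotype_table)(config.genotypes)
        logger.info("loaded %d individuals (%d parents, %d offspring)",
                    len(dataset.individuals), len(dataset.parents), len(dataset.offspring))

    if dataset is not None:
        if not dataset.offspring:
            raise MassCrossError("stage 'assignment' failed: no offspring in dataset")
        if config.design is not None:
            design = _stage("load")(mio.read_cross_design)(config.design)
        else:
            design = design_from_dataset(dataset)
        result = _stage("assignment")(assign_all)(dataset, design, config.min_loci, config.tie_tol)
        counts = result.counts()
        logger.info("assignment: %(assigned)d assigned, %(ambiguous)d ambiguous, %(unassigned)d unassigned", counts)
        write_assignment_report(result, outdir / "assignments.tsv")
        report["assignment"] = {**counts, "rate": assignment_rate(result)}
        matrix = _stage("contribution")(family_matrix)(result)

        parents = dataset.parents
        offspring = [dataset[r.offspring_id] for r in result.records if r.status == "assigned"]
        retention = _stage("diversity")(allele_retention)(parents, offspring, dataset.panel)
        report["diversity"] = {
            "parents": {"per_locus": retention["parents"].per_locus.reset_index().to_dict("records"),
                        "means": retention["parents"].means},
            "offspring": {"per_locus": retention["offspring"].per_locus.reset_index().to_dict("records"),
                          "means": retention["offspring"].means},
            "mean_allelic_loss": retention["mean_allelic_loss"],
            "mean_gene_diversity_loss": retention["mean_gene_diversity_loss"],
        }
    else:
        matrix = FamilyMatrix(counts=mio.read_family_counts(config.matrix))
        logger.info("matrix-only mode: %d offspring in %d×%d design",
                    matrix.n, len(matrix.dam_ids), len(matrix.sire_ids))

    mio.write_family_counts(matrix.counts, outdir / "family_matrix.tsv")
    report["contribution"] = _stage("contribution")(contribution_summary)(matrix)
    ne = _stage("effective_size")(effective_size)(matrix.totals("sire"), matrix.totals("dam"))
    census = len(matrix.sire_ids) + len(matrix.dam_ids)
    report["effective_size"] = {
        "N": ne.n, "Ks": ne.ks, "Vs": ne.vs, "Kd": ne.kd, "Vd": ne.vd,
        "Ne": ne.ne, "census": census, "Ne_over_census": ne.ne / census,
    }

    (outdir / "report.json").write_text(
        json.dumps(_jsonable(report), indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    logger.info("report written to %s", outdir / "report.json")
    return report
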