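import pytest
from hypothesis import HealthCheck, settings

from masscross.genotypes import CrossDesign, GenotypeDataset, Individual, MarkerPanel
from masscross.parentage import assign_all
from masscross.simulate import SimConfig, simulate_dataset

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("ci")

# study-shaped simulation used across tests: 9 loci × 7 alleles, 10 sires ×
# 10 dams, 500 offspring, equal contributions, no noise
STUDY_SIM = dict(
    seed=20260, n_loci=9, alleles_per_locus=7, n_sires=10, n_dams=10,
    n_offspring=500, contribution_model="equal",
)


def make_individual(ind_id, genotype, sex="unknown", role="offspring"):
    return Individual(id=ind_id, sex=sex, role=role, genotype=genotype)


def make_trio_dataset(loci, sire_geno, dam_geno, offspring_genos):
    """One sire, one dam, n offspring over the given loci."""
    panel = MarkerPanel(loci=list(loci))
    inds = [
        Individual(id="S1", sex="male", role="parent", genotype=dict(sire_geno)),
        Individual(id="D1", sex="female", role="parent", genotype=dict(dam_geno)),
    ]
    for i, g in enumerate(offspring_genos):
        inds.append(Individual(id=f"O{i+1}", sex="unknown", role="offspring", genotype=dict(g)))
    return GenotypeDataset(panel=panel, individuals=inds), CrossDesign(sire_ids=["S1"], dam_ids=["D1"])


@pytest.fixture(scope="session")
def study_cross():
    """(dataset, pedigree) for the error-free study-shaped simulation."""
    return simulate_dataset(SimConfig(**STUDY_SIM))


@pytest.fixture(scope="session")
def study_assignment(study_cross):
    dataset, pedigree = study_cross
    design = CrossDesign(
        sire_ids=[p.id for p in dataset.parents if p.sex == "male"],
        dam_ids=[p.id for p in dataset.parents if p.sex == "female"],
    )
    return assign_all(dataset, design), pedigree
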