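import numpy as np
import pytest

from funcgsr import (
    build_table,
    compute_functionome,
    default_eaoc_design,
    gen_cohort,
    gen_gene_sets,
    integrate_common_genes,
)


@pytest.fixture(scope="session")
def small_cohort():
    """One-disease synthetic cohort with two planted deregulated sets."""
    from funcgsr.synthetic_data import DiseaseArm, SimulationDesign

    design = SimulationDesign(
        n_genes=300,
        n_sets=30,
        set_size_range=(6, 10),
        diseases=[DiseaseArm("D", 20, 30, "tissue")],
        deregulation_plan={"D": [("GO_SET_0000", 0.8), ("GO_SET_0001", 0.8)]},
        platform_plan={},
        noise_sd=1.0,
        seed=11,
    )
    collection = gen_gene_sets(300, 30, (6, 10), seed=11)
    cohorts = gen_cohort(design, collection)
    case, ctrl = cohorts["D"]
    cohort = integrate_common_genes([case, ctrl], min_common_genes=2)
    return design, collection, cohort


@pytest.fixture(scope="session")
def small_functionome(small_cohort):
    design, collection, cohort = small_cohort
    return compute_functionome(cohort, collection)


def run_default_design(seed, **kwargs):
    """Full tri-disease analysis for one seed of the default study design."""
    design = default_eaoc_design(seed=seed, **kwargs)
    collection = gen_gene_sets(
        design.n_genes, design.n_sets, design.set_size_range, seed=design.seed
    )
    cohorts = gen_cohort(design, collection)
    functionomes, tables = {}, {}
    for d, (case, ctrl) in cohorts.items():
        cohort = integrate_common_genes([case, ctrl], min_common_genes=2)
        fm = compute_functionome(cohort, collection)
        functionomes[d] = fm
        tables[d] = build_table(fm, d)
    return design, collection, cohorts, functionomes, tables


@pytest.fixture(scope="session")
def default_design_runs():
    """Cached tri-disease runs of the default design over a seed sweep.

    Shared by the deregulation-recovery, clustering-topology and
    progression-filter checks so the cohort simulations are done once.
    """
    return {seed: run_default_design(seed) for seed in range(20)}
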