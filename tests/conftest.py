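"""Shared fixtures: one small simulated scenario reused across test modules."""
import pytest

from polyploidkit import phasing, simulate


#: census role of each (genome, subgenome) copy in the default scenarios
ROLE_OF_COPY = {
    ("outgroup", "outgroup"): "O",
    ("tetraploid", "A"): "T1",
    ("tetraploid", "C"): "T2",
    ("octoploid", "A"): "P1",
    ("octoploid", "B"): "P2",
    ("octoploid", "C"): "P3",
    ("octoploid", "D"): "P4",
}


def anchor_copies(result):
    """family -> {(genome, subgenome): truth gene row} for anchor families."""
    by = {}
    for t in result.truth.genes:
        if t["kind"] == "anchor":
            by.setdefault(t["family"], {})[(t["genome"], t["subgenome"])] = t
    return by


def gene_seq(result, row):
    return result.genomes[row["genome"]][row["chrom"]][row["start"] : row["end"]]


@pytest.fixture(scope="session")
def small_scenario():
    return simulate.reticulate_scenario(
        n_chromosomes_per_subgenome=2,
        chrom_length=150_000,
        n_gene_families=40,
        n_single_copy_families=5,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_result(small_scenario):
    return simulate.simulate_scenario(small_scenario)


@pytest.fixture(scope="session")
def phased_octoploid(small_result):
    return phasing.phase_genome(
        small_result.genomes["octoploid"],
        n_subgenomes=4,
        k=15,
        min_total=10,
        seed=0,
        window_size=20_000,
        min_exchange_length=100_000,
    )
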