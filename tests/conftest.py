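import numpy as np
import pytest

from exoload import genotypes as gt
from exoload import synthetic_data as sd


@pytest.fixture(scope="session")
def genomes_small():
    seqs, truth = sd.make_genomes(
        host_len=20_000, pest_specs={"aphid": 9000, "mildew": 8000},
        conserved_len=2000, divergence=0.05, seed=1,
    )
    return seqs, truth


@pytest.fixture(scope="session")
def alignment_fixture(genomes_small, tmp_path_factory):
    seqs, gtruth = genomes_small
    out = tmp_path_factory.mktemp("sams")
    counts = {"s0": {"aphid": 15, "mildew": 4}, "s1": {"aphid": 0, "mildew": 6},
              "s2": {"aphid": 30, "mildew": 0}}
    truth = sd.simulate_alignments(
        seqs, gtruth, counts, ambiguous_fraction=0.1, out_dir=out, seed=7,
        n_host_pairs=120,
    )
    return truth


@pytest.fixture(scope="session")
def population_small():
    table, pops = sd.make_population(
        n_samples=80, n_pops=2, fst=0.1, n_variants=400, seed=11,
    )
    return table, pops


@pytest.fixture(scope="session")
def kinship_small(population_small):
    table, _ = population_small
    return gt.scale_kinship(gt.ibs_kinship(table))


@pytest.fixture(scope="session")
def methylation_fixture():
    samples = [f"s{i:02d}" for i in range(40)]
    loads = np.r_[np.ones(20), -np.ones(20)]
    ub, truth = sd.simulate_methylation(
        n_sites_per_context=1500, samples=samples, loads=loads, n_dmr=6,
        dmr_effect=0.15, seed=5, contexts=("CG",),
    )
    return ub, truth, samples
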