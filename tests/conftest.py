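import numpy as np
import pytest

from reinforcescan.io import GenotypeMatrix, PopulationAssignment


def make_matrix(dosage, positions=None, is_variant=None, chrom="chr1",
                sample_ids=None, ref=None, alt=None) -> GenotypeMatrix:
    """Assemble a GenotypeMatrix from a dosage array with sane defaults."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n_sites, n_samples = dosage.shape
    if positions is None:
        positions = np.arange(1, n_sites + 1) * 10
    if is_variant is None:
        is_variant = np.ones(n_sites, dtype=bool)
    is_variant = np.asarray(is_variant, dtype=bool)
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(n_samples)]
    if ref is None:
        ref = np.array(["A"] * n_sites, dtype=object)
    if alt is None:
        alt = np.array(["C" if v else "" for v in is_variant], dtype=object)
    return GenotypeMatrix(chrom=chrom, positions=np.asarray(positions),
                          ref_alleles=np.asarray(ref, dtype=object),
                          alt_alleles=np.asarray(alt, dtype=object),
                          dosage=dosage, sample_ids=list(sample_ids),
                          is_variant=is_variant)


def make_popmap(n_per_pop=(2, 2, 2, 2)) -> PopulationAssignment:
    labels = ("ALLO_MUL", "PARA_MUL", "ALLO_FAS", "PARA_FAS")
    prefix = ("am", "pm", "af", "pf")
    mapping = {}
    for lab, pre, n in zip(labels, prefix, n_per_pop):
        for i in range(n):
            mapping[f"{pre}{i}"] = lab
    return PopulationAssignment(mapping)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """A small simulated bundle shared by pipeline-level tests."""
    from reinforcescan.simulate import SimulationParams, generate_dataset

    out = tmp_path_factory.mktemp("simbundle")
    params = SimulationParams(n_sites=4000, sites_per_window=100,
                              n_planted=3, seed=7)
    ds = generate_dataset(params, out_dir=out)
    return ds, out
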