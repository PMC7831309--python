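import numpy as np
import pandas as pd
import pytest

from rohscan.genotype_io import GenotypeDataset


def make_dataset(genotypes, positions=None, chrom="1", sample_ids=None,
                 breed="test"):
    """Build a GenotypeDataset from a (samples x snps) array."""
    genotypes = np.asarray(genotypes, dtype=np.int8)
    if genotypes.ndim == 1:
        genotypes = genotypes[None, :]
    n_samples, n_snps = genotypes.shape
    if positions is None:
        positions = np.arange(1, n_snps + 1) * 10_000
    if np.isscalar(chrom):
        chroms = [str(chrom)] * n_snps
    else:
        chroms = [str(c) for c in chrom]
    if sample_ids is None:
        sample_ids = [f"s{i + 1}" for i in range(n_samples)]
    markers = pd.DataFrame({
        "chrom": chroms,
        "snp_id": [f"snp{i}" for i in range(n_snps)],
        "cm": 0.0, "bp": np.asarray(positions, dtype=np.int64),
        "allele1": "A", "allele2": "B"})
    samples = pd.DataFrame({"sample_id": sample_ids, "breed": breed,
                            "als": 2.0, "group": "unassigned"})
    return GenotypeDataset(markers, samples, genotypes)


def plant_run(genotypes, sample, lo, hi, flank_het=True):
    """Make [lo, hi] homozygous for one sample, optionally het-flanked."""
    genotypes[sample, lo:hi + 1] = 2
    if flank_het:
        genotypes[sample, max(lo - 2, 0):lo] = 1
        genotypes[sample, hi + 1:hi + 3] = 1
    return genotypes


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def tiny_fixture(tmp_path_factory):
    """On-disk tiny PLINK fileset shared across CLI tests."""
    from rohscan.synthetic_data import make_fixture
    out = tmp_path_factory.mktemp("tiny")
    dataset, truth, paths = make_fixture("tiny", out, seed=11)
    return {"dir": out, "dataset": dataset, "truth": truth, "paths": paths}
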