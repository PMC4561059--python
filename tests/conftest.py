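import numpy as np
import pandas as pd
import pytest

import famscan as fs


@pytest.fixture(scope="session")
def default_pedigree():
    """One default-mixture family sample (3690 families), shared read-only."""
    return fs.sample_family_structures(fs.FamilyMixture(), seed=11)


@pytest.fixture(scope="session")
def toy_pedigree():
    """Two families: a sib-pair with both parents, and a couple."""
    rows = [
        ("F1", "F1_P1", "0", "0", 1, "-9", "founder"),
        ("F1", "F1_P2", "0", "0", 2, "-9", "founder"),
        ("F1", "F1_S1", "F1_P1", "F1_P2", 1, "-9", "offspring"),
        ("F1", "F1_S2", "F1_P1", "F1_P2", 2, "-9", "offspring"),
        ("F2", "F2_P1", "0", "0", 1, "-9", "spouse"),
        ("F2", "F2_P2", "0", "0", 2, "-9", "spouse"),
    ]
    table = pd.DataFrame(rows, columns=["family_id", "individual_id", "father_id",
                                        "mother_id", "sex", "phenotype", "role"])
    return fs.Pedigree(table)


def make_genotypes(dosages, mafs=None, infos=None, chromosome=1):
    """Small GenotypeDataset from a dosage matrix (individuals x SNPs)."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n, m = dosages.shape
    if mafs is None:
        mafs = dosages.mean(axis=0) / 2.0
    if infos is None:
        infos = np.ones(m)
    snps = pd.DataFrame({
        "snp_id": [f"s{j+1}" for j in range(m)],
        "chromosome": chromosome,
        "position": 1000 * (np.arange(m) + 1),
        "allele_freq": np.asarray(mafs, dtype=float),
        "info_score": np.asarray(infos, dtype=float),
    })
    return fs.GenotypeDataset(individuals=[f"i{k+1}" for k in range(n)],
                              snps=snps, dosages=dosages)
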