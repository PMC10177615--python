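import numpy as np
import pandas as pd
import pytest

from pcmlm import (
    GenotypeMatrix,
    PhenotypeTable,
    SimConfig,
    simulate_phenotype,
    simulate_structured_genotypes,
)

VCF_5_SITES = """\
##fileformat=VCFv4.2
##contig=<ID=chr1>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3
chr1\t100\trs1\tA\tG\t.\t.\t.\tGT\t0/0\t0/1\t1/1
chr1\t200\trs2\tC\tT\t.\t.\t.\tGT\t0/0\t0/0\t0/1
chr1\t300\trs3\tG\tA,C\t.\t.\t.\tGT\t0/1\t0/2\t1/1
chr1\t400\trs4\tT\tC\t.\t.\t.\tGT\t./.\t0/1\t1/1
chr1\t500\trs5\tA\tC\t.\t.\t.\tGT\t1/1\t1/1\t0/0
"""


@pytest.fixture
def vcf_file(tmp_path):
    path = tmp_path / "toy.vcf"
    path.write_text(VCF_5_SITES)
    return path


@pytest.fixture
def toy_genotypes():
    """4 samples x 3 markers with two missing cells."""
    codes = np.array(
        [
            [0.0, 1.0, 2.0],
            [2.0, np.nan, 0.0],
            [0.0, 1.0, np.nan],
            [2.0, 2.0, 2.0],
        ]
    )
    return GenotypeMatrix(["a", "b", "c", "d"], codes)


@pytest.fixture(scope="session")
def structured_sim():
    """Seven-population, FST 0.1 dataset with one 20%-variance QTL."""
    cfg = SimConfig(
        fst=0.1,
        m_markers=600,
        n_qtl=1,
        qtl_variance_fraction=0.2,
        h2_polygenic=0.3,
        seed=11,
    )
    g, markers, pops = simulate_structured_genotypes(cfg)
    y, truth = simulate_phenotype(g, pops, cfg)
    phen = PhenotypeTable(pd.DataFrame({"BH": y}, index=g.sample_ids))
    return g, markers, pops, phen, truth


def make_small_dataset(seed=0, n_per_pop=20, n_pops=3, m=120, **kwargs):
    cfg = SimConfig(
        n_pops=n_pops,
        pop_sizes=tuple([n_per_pop] * n_pops),
        fst=kwargs.pop("fst", 0.1),
        m_markers=m,
        seed=seed,
        **kwargs,
    )
    return cfg, *simulate_structured_genotypes(cfg)
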