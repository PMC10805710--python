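"""Shared fixtures: small synthetic maps and a low-noise pedigree.

Everything is generated at test time; fixture sizes are kept small so the
unit suite stays fast, while the acceptance tests build their own
full-scale inputs.
"""

import numpy as np
import pandas as pd
import pytest

from haplarith.karyotype import Karyotype
from haplarith.phasing import phase_parents
from haplarith.sample import GT_NC, SampleArray
from haplarith.scenarios import simulate_family
from haplarith.snp_map import SnpMap, build_snp_map


@pytest.fixture(scope="session")
def tiny_map() -> SnpMap:
    """Ten SNPs on one 100 Mbp chromosome, for table/QC tests."""
    kt = Karyotype({"1": 100_000_000})
    df = pd.DataFrame(
        {
            "snp_id": [f"SNP{i:06d}" for i in range(10)],
            "chrom": "1",
            "pos_bp": np.arange(1, 11) * 9_000_000,
            "b_freq": 0.5,
        }
    )
    return SnpMap(df, kt)


@pytest.fixture(scope="session")
def small_map() -> SnpMap:
    """Four chromosomes, 4000 SNPs: enough for segmentation/recovery tests."""
    kt = Karyotype({"1": 150_000_000, "2": 100_000_000, "3": 60_000_000, "X": 120_000_000})
    return build_snp_map(kt, n_snps=4000, seed=11)


@pytest.fixture(scope="session")
def family(small_map):
    """A noise-free pedigree on the small map (exact bulk genotypes)."""
    from haplarith.simulate import NoiseConfig

    return simulate_family(
        small_map, seed=7, bulk_noise=NoiseConfig.none(), sibling_noise=NoiseConfig.none()
    )


@pytest.fixture(scope="session")
def phased(family):
    return phase_parents(
        family.samples["mother"],
        family.samples["father"],
        sibling=family.samples["sibling"],
        snp_map=family.snp_map,
    )


def make_sample(gtypes, bafs=None, logrs=None, sample_id="s", role="embryo"):
    """Build a SampleArray from genotype codes with sensible BAF/LogR."""
    g = np.asarray(gtypes, dtype=np.int8)
    if bafs is None:
        bafs = np.where(g == GT_NC, np.nan, g / 2.0)
    if logrs is None:
        logrs = np.zeros(len(g))
    return SampleArray(sample_id, role, g, np.asarray(bafs, float), np.asarray(logrs, float))
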