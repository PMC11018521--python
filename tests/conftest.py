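import numpy as np
import pytest

from haplocnv.simcohort import CohortConfig, plant_cnvs, sim_haplotype_panel, sim_read_counts


@pytest.fixture(scope="session")
def small_cfg():
    return CohortConfig(
        n_founders=12,
        n_samples=60,
        n_sites=120,
        n_bins=30,
        bin_bp=100,
        copy_tract_mean=40.0,
        seed=11,
        lot_fraction=0.5,
        depth_mean=30.0,
        nb_dispersion=10.0,
    )


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    panel, genealogy = sim_haplotype_panel(small_cfg)
    return small_cfg, panel, genealogy


@pytest.fixture(scope="session")
def small_counts(small_cohort):
    cfg, panel, genealogy = small_cohort
    truth = plant_cnvs(panel, genealogy, [], cfg)
    return sim_read_counts(truth, panel, cfg)


def brute_suffix_match_lengths(alleles: np.ndarray) -> np.ndarray:
    """Longest common suffix ending at each site for every haplotype pair.

    O(N^2 M) dynamic program used as the independent oracle for PBWT
    divergence recovery: out[a, b, k] = length of the allele match between
    haplotypes a and b over sites ending at (and including) k.
    """
    n, m = alleles.shape
    eq = alleles[:, None, :] == alleles[None, :, :]
    out = np.zeros((n, n, m), dtype=np.int32)
    out[:, :, 0] = eq[:, :, 0]
    for k in range(1, m):
        out[:, :, k] = np.where(eq[:, :, k], out[:, :, k - 1] + 1, 0)
    return out
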