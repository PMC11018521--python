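import numpy as np
import pytest

from haplocnv.simcohort import (
    CNVEvent,
    CohortConfig,
    HaplotypePanel,
    plant_cnvs,
    sim_haplotype_panel,
    sim_psv_pileups,
    sim_read_counts,
    sim_trios,
)


def test_config_validation_rejects_bad_values():
    with pytest.raises(ValueError):
        CohortConfig(n_samples=0).validate()
    with pytest.raises(ValueError):
        CohortConfig(lot_fraction=1.5).validate()
    with pytest.raises(ValueError):
        CohortConfig(nb_dispersion=-1).validate()


def test_panel_deterministic_given_seed(small_cfg):
    p1, g1 = sim_haplotype_panel(small_cfg)
    p2, g2 = sim_haplotype_panel(small_cfg)
    assert np.array_equal(p1.alleles, p2.alleles)
    assert np.array_equal(g1, g2)


def test_no_recombination_limit_copies_founders_verbatim():
    cfg = CohortConfig(
        n_founders=40, n_samples=20, n_sites=50, n_bins=20, copy_tract_mean=50, seed=3
    )
    panel, gen = sim_haplotype_panel(cfg)
    assert np.all(gen == gen[:, :1])  # one founder per haplotype, no breakpoints


def test_excess_founders_warn_about_missing_sharing():
    cfg = CohortConfig(
        n_founders=50, n_samples=20, n_sites=50, n_bins=20, copy_tract_mean=10, seed=3
    )
    with pytest.warns(UserWarning, match="sharing"):
        sim_haplotype_panel(cfg)


def test_single_founder_makes_all_haplotypes_identical():
    cfg = CohortConfig(n_founders=1, n_samples=10, n_sites=80, n_bins=20, copy_tract_mean=10, seed=5)
    panel, _ = sim_haplotype_panel(cfg)
    assert np.all(panel.alleles == panel.alleles[0])


def test_tract_length_recovered_from_genealogy_breakpoints():
    cfg = CohortConfig(
        n_founders=20, n_samples=200, n_sites=500, n_bins=500, copy_tract_mean=100, seed=7
    )
    panel, gen = sim_haplotype_panel(cfg)
    breaks = int((np.diff(gen, axis=1) != 0).sum())
    est = (cfg.n_sites - 1) * panel.n_haplotypes / breaks
    assert abs(est - 100) / 100 < 0.15


def _toy_panel(n_samples, n_sites, founder_ids):
    alleles = np.zeros((2 * n_samples, n_sites), dtype=np.uint8)
    pos = np.arange(n_sites, dtype=np.int64) * 10 + 5
    cm = np.arange(n_sites, dtype=float) * 0.01
    ids = [f"S{i:05d}" for i in range(n_samples)]
    gen = np.broadcast_to(np.asarray(founder_ids)[:, None], (2 * n_samples, n_sites)).copy()
    return HaplotypePanel(alleles, pos, cm, ids), gen


def test_plant_cnvs_homozygous_deletion_gives_copy_number_zero():
    cfg = CohortConfig(n_founders=2, n_samples=2, n_sites=40, n_bins=4, bin_bp=100, seed=0)
    panel, gen = _toy_panel(2, 40, [0, 0, 1, 1])  # sample 0 carries founder 0 on both haps
    truth = plant_cnvs(panel, gen, [CNVEvent(0, 1, 3, -1)], cfg)
    assert truth.cn[0, 1] == 0 and truth.cn[0, 2] == 0
    assert truth.cn[1, 1] == 2
    assert set(truth.carrier_haps[0]) == {0, 1}


def test_plant_cnvs_no_descendants_means_no_carriers():
    cfg = CohortConfig(n_founders=5, n_samples=3, n_sites=40, n_bins=4, seed=0)
    panel, gen = _toy_panel(3, 40, [0, 0, 1, 1, 2, 2])
    truth = plant_cnvs(panel, gen, [CNVEvent(4, 0, 2, -1)], cfg)
    assert len(truth.carrier_haps[0]) == 0
    assert np.all(truth.cn == 2)


def test_plant_cnvs_rejects_overlapping_events_on_one_founder():
    cfg = CohortConfig(n_founders=5, n_samples=3, n_sites=40, n_bins=10, seed=0)
    panel, gen = _toy_panel(3, 40, [0, 0, 1, 1, 2, 2])
    with pytest.raises(ValueError, match="overlapping"):
        plant_cnvs(panel, gen, [CNVEvent(0, 1, 5, -1), CNVEvent(0, 4, 8, 1)], cfg)


def test_carrier_frequency_matches_genealogy_tract_frequency():
    cfg = CohortConfig(
        n_founders=10, n_samples=200, n_sites=200, n_bins=50, copy_tract_mean=60, seed=19
    )
    panel, gen = sim_haplotype_panel(cfg)
    truth = plant_cnvs(panel, gen, [CNVEvent(0, 20, 24, -1)], cfg)
    # independent recount of haplotype tracts covering the event interval
    lo, hi = 20 * cfg.bin_bp, 24 * cfg.bin_bp
    sites = np.flatnonzero((panel.site_pos >= lo) & (panel.site_pos < hi))
    q = np.mean(np.all(gen[:, sites] == 0, axis=1))
    expected_carrier_freq = 1 - (1 - q) ** 2
    observed = len(truth.carriers_of(0)) / cfg.n_samples
    ci = 3 * np.sqrt(expected_carrier_freq * (1 - expected_carrier_freq) / cfg.n_samples)
    assert abs(observed - expected_carrier_freq) <= ci + 1e-9


def test_read_counts_zero_copy_number_yields_zero_counts():
    cfg = CohortConfig(n_founders=2, n_samples=2, n_sites=40, n_bins=4, seed=0)
    panel, gen = _toy_panel(2, 40, [0, 0, 1, 1])
    truth = plant_cnvs(panel, gen, [CNVEvent(0, 1, 3, -1)], cfg)
    matrix = sim_read_counts(truth, panel, cfg)
    assert matrix.counts[0, 1] == 0 and matrix.counts[0, 2] == 0


def test_read_count_means_match_configured_model():
    cfg = CohortConfig(
        n_founders=4, n_samples=10_000, n_sites=80, n_bins=6, copy_tract_mean=40, seed=23
    )
    panel, gen = sim_haplotype_panel(cfg)
    truth = plant_cnvs(panel, gen, [], cfg)
    matrix = sim_read_counts(truth, panel, cfg)
    emp = matrix.counts.mean(axis=0)
    expected = matrix.true_mean.mean(axis=0)
    assert np.all(np.abs(emp / expected - 1) < 0.02)


def test_deletion_carriers_show_half_depth():
    cfg = CohortConfig(
        n_founders=8, n_samples=2000, n_sites=100, n_bins=10, copy_tract_mean=60, seed=29
    )
    panel, gen = sim_haplotype_panel(cfg)
    truth = plant_cnvs(panel, gen, [CNVEvent(0, 4, 6, -1)], cfg)
    matrix = sim_read_counts(truth, panel, cfg)
    carriers = truth.carriers_of(0)
    non = np.setdiff1d(np.arange(cfg.n_samples), carriers)
    emp_ratio = matrix.counts[carriers, 4].mean() / matrix.counts[non, 4].mean()
    expected_ratio = truth.cn[carriers, 4].mean() / 2.0
    assert abs(emp_ratio - expected_ratio) < 0.06


def test_trios_are_mendelian_consistent(small_cohort):
    cfg, panel, gen = small_cohort
    truth = plant_cnvs(panel, gen, [CNVEvent(0, 5, 8, -1)], cfg)
    trios = sim_trios(panel, gen, truth, cfg, n_trios=20)
    for i in range(trios.n_trios):
        f, m = trios.father_idx[i], trios.mother_idx[i]
        pat = trios.child_alleles[2 * i]
        mat = trios.child_alleles[2 * i + 1]
        assert np.all((pat == panel.alleles[2 * f]) | (pat == panel.alleles[2 * f + 1]))
        assert np.all((mat == panel.alleles[2 * m]) | (mat == panel.alleles[2 * m + 1]))


def test_trios_reject_too_small_parent_pool(small_cohort):
    cfg, panel, gen = small_cohort
    truth = plant_cnvs(panel, gen, [], cfg)
    with pytest.raises(ValueError, match="parental pool"):
        sim_trios(panel, gen, truth, cfg, n_trios=cfg.n_samples)


def test_psv_pileups_edge_cases_and_binomial_mean():
    n = 5000
    k_tot = np.full(n, 4)
    zeros = sim_psv_pileups(k_tot, np.zeros(n, dtype=int), depth=30, seed=1)
    assert (zeros["alt_count"] == 0).all()
    fixed = sim_psv_pileups(k_tot, k_tot, depth=30, seed=2)
    assert (fixed["alt_count"] == fixed["total_count"]).all()
    half = sim_psv_pileups(k_tot, np.full(n, 2), depth=30, seed=3)
    ok = half["total_count"] > 0
    frac = (half.loc[ok, "alt_count"] / half.loc[ok, "total_count"]).mean()
    assert abs(frac - 0.5) < 0.005
    with pytest.raises(ValueError):
        sim_psv_pileups(k_tot, k_tot + 1, depth=30, seed=4)
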