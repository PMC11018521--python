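import numpy as np
import pytest

from conftest import brute_suffix_match_lengths
from haplocnv.hapmatch import (
    PBWTIndex,
    build_pbwt,
    match_interval_brute_force,
    neighbors_at,
    neighbors_brute_force,
)
from haplocnv.pipeline import two_class_panel
from haplocnv.simcohort import HaplotypePanel


def _random_panel(rng, n_hap, n_sites):
    alleles = rng.integers(0, 2, size=(n_hap, n_sites)).astype(np.uint8)
    pos = np.arange(n_sites, dtype=np.int64) * 7 + 3
    cm = np.arange(n_sites, dtype=float) * 0.01
    ids = [f"S{i:05d}" for i in range(n_hap // 2)]
    return HaplotypePanel(alleles, pos, cm, ids)


def test_build_pbwt_rejects_non_binary():
    panel = _random_panel(np.random.default_rng(0), 8, 20)
    panel.alleles[0, 0] = 2
    with pytest.raises(ValueError, match="binary"):
        build_pbwt(panel)


def test_identical_haplotypes_share_full_matches():
    n_hap, n_sites = 8, 30
    panel = HaplotypePanel(
        np.zeros((n_hap, n_sites), dtype=np.uint8),
        np.arange(n_sites, dtype=np.int64),
        np.arange(n_sites, dtype=float) * 0.01,
        [f"S{i}" for i in range(n_hap // 2)],
    )
    index = build_pbwt(panel)
    # every adjacent pair matches from site 0 at every position
    assert np.all(index.divergence[1:, 1:] == 0)


def test_complementary_haplotypes_never_match():
    alleles = np.array([[0, 1] * 10, [1, 0] * 10], dtype=np.uint8)
    panel = HaplotypePanel(
        alleles,
        np.arange(20, dtype=np.int64),
        np.arange(20, dtype=float) * 0.01,
        ["S0"],
    )
    index = build_pbwt(panel)
    # divergence k+1 == sentinel: zero-length match at every site
    assert np.all(index.divergence[1:, 1] == np.arange(1, 21))


@pytest.mark.parametrize("n_hap,n_sites,seed", [(16, 40, 0), (50, 200, 1), (64, 256, 2)])
def test_pbwt_divergence_equals_brute_force_suffix_lengths(n_hap, n_sites, seed):
    """Adjacent-pair match lengths recovered from divergence arrays equal the
    O(N^2 M) longest-common-suffix dynamic program at every site."""
    panel = _random_panel(np.random.default_rng(seed), n_hap, n_sites)
    index = build_pbwt(panel)
    brute = brute_suffix_match_lengths(panel.alleles)
    for k in range(n_sites):
        order = index.orderings[k + 1]
        div = index.divergence[k + 1]
        for i in range(1, n_hap):
            a, b = order[i - 1], order[i]
            assert k + 1 - div[i] == brute[a, b, k]


@pytest.mark.parametrize("unit,thresholds", [("sites", (5, 10, 20)), ("cm", (0.05, 0.1))])
def test_neighbors_match_brute_force_on_random_probes(unit, thresholds):
    rng = np.random.default_rng(42)
    panel = _random_panel(rng, 40, 120)
    index = build_pbwt(panel)
    for _ in range(30):
        hap = int(rng.integers(panel.n_haplotypes))
        site = int(rng.integers(panel.n_sites))
        for thr in thresholds:
            got = neighbors_at(index, panel, hap, site, thr, unit=unit)
            want = neighbors_brute_force(panel, hap, site, thr, unit=unit)
            assert [(n.hap, n.start, n.end) for n in got.neighbors] == [
                (n.hap, n.start, n.end) for n in want.neighbors
            ]


def test_threshold_beyond_panel_gives_empty_set():
    panel = _random_panel(np.random.default_rng(7), 20, 50)
    index = build_pbwt(panel)
    assert neighbors_at(index, panel, 0, 25, 1000, unit="sites").neighbors == []


def test_single_founder_panel_gives_full_length_matches():
    n_hap, n_sites = 30, 60
    panel = HaplotypePanel(
        np.tile(np.random.default_rng(1).integers(0, 2, n_sites).astype(np.uint8), (n_hap, 1)),
        np.arange(n_sites, dtype=np.int64),
        np.arange(n_sites, dtype=float) * 0.01,
        [f"S{i}" for i in range(n_hap // 2)],
    )
    index = build_pbwt(panel)
    ns = neighbors_at(index, panel, 0, 30, n_sites, unit="sites")
    assert len(ns.neighbors) == 10
    assert all(n.length_sites == n_sites for n in ns.neighbors)
    assert all(n.hap not in (0, 1) for n in ns.neighbors)


def test_match_length_is_symmetric():
    panel = _random_panel(np.random.default_rng(3), 24, 80)
    rng = np.random.default_rng(4)
    for _ in range(50):
        a, b = rng.choice(panel.n_haplotypes, size=2, replace=False)
        site = int(rng.integers(panel.n_sites))
        assert match_interval_brute_force(panel.alleles, a, b, site) == (
            match_interval_brute_force(panel.alleles, b, a, site)
        )


def test_neighbor_sets_shrink_as_threshold_grows():
    panel, _ = two_class_panel(9, n_samples=50, n_sites=100, tract_mean=30)
    index = build_pbwt(panel)
    rng = np.random.default_rng(10)
    for _ in range(20):
        hap = int(rng.integers(panel.n_haplotypes))
        site = int(rng.integers(panel.n_sites))
        sizes = [
            len(neighbors_at(index, panel, hap, site, t, max_neighbors=100, unit="sites").neighbors)
            for t in (5, 15, 30, 60)
        ]
        assert sizes == sorted(sizes, reverse=True)


def test_neighbors_equal_genealogy_truth_on_complement_founder_panel():
    """On a two-complement-founder mosaic panel, allele identity coincides
    with genealogy identity, so PBWT neighbor sets must equal the sets of
    haplotypes whose genealogy-identical tract spanning the probe site passes
    the threshold."""
    panel, gen = two_class_panel(17, n_samples=60, n_sites=150, tract_mean=40)
    index = build_pbwt(panel)
    rng = np.random.default_rng(18)
    for _ in range(100):
        hap = int(rng.integers(panel.n_haplotypes))
        site = int(rng.integers(panel.n_sites))
        thr = int(rng.integers(10, 60))
        got = neighbors_at(index, panel, hap, site, thr, unit="sites")
        # genealogy-truth oracle: maximal run of founder identity around site
        rows = []
        for h in range(panel.n_haplotypes):
            if h // 2 == hap // 2:
                continue
            if gen[h, site] != gen[hap, site]:
                continue
            eq = gen[h] == gen[hap]
            s = site
            while s > 0 and eq[s - 1]:
                s -= 1
            e = site + 1
            while e < panel.n_sites and eq[e]:
                e += 1
            if e - s >= thr:
                rows.append((h, s, e))
        rows.sort(key=lambda r: (-(r[2] - r[1]), r[0]))
        assert [(n.hap, n.start, n.end) for n in got.neighbors] == rows[:10]


def test_index_dump_restore_roundtrip(tmp_path):
    panel = _random_panel(np.random.default_rng(5), 12, 30)
    index = build_pbwt(panel)
    path = str(tmp_path / "index.pbwt")
    index.dump(path)
    back = PBWTIndex.restore(path)
    assert np.array_equal(back.orderings, index.orderings)
    assert np.array_equal(back.divergence, index.divergence)
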