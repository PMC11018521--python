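"""Synthetic cohorts with known haplotype sharing, planted CNVs, trios and PSVs.

The generator uses a founder-mosaic copying model: every sample haplotype is a
mosaic of a small set of founder haplotypes, with geometrically distributed
tract lengths.  The genealogy (founder id per haplotype per site) is recorded
exactly, which gives queryable ground truth for identity-by-descent (IBD)
sharing — the structure exploited downstream by haplotype-neighbor pooling.

Exome read counts are drawn from negative binomial distributions whose means
combine a per-bin capture efficiency, a per-bin batch ("oligo lot") effect, a
per-sample coverage scale, and the sample's integer copy number at the bin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CohortConfig",
    "HaplotypePanel",
    "CNVEvent",
    "SimTruth",
    "ReadCountMatrix",
    "TrioSet",
    "sim_haplotype_panel",
    "plant_cnvs",
    "sim_read_counts",
    "sim_trios",
    "sim_psv_pileups",
    "sim_psv_haplotype_cohort",
]


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort.

    Lengths are in sites for haplotype tracts and in base pairs for bins.
    ``copy_tract_mean`` is the mean IBD tract length in sites; a value of at
    least ``n_sites`` disables recombination entirely, so each haplotype copies
    a single founder verbatim.  ``cm_per_site`` defines a linear genetic map
    (default 1 cM per 100 sites) used to express match lengths in cM.
    """

    n_founders: int = 100
    n_samples: int = 2000
    n_sites: int = 300
    n_bins: int = 40
    bin_bp: int = 100
    copy_tract_mean: float = 100.0
    seed: int = 0
    lot_fraction: float = 0.1
    depth_mean: float = 30.0
    nb_dispersion: float = 10.0
    capture_sd: float = 0.3
    lot_effect_sd: float = 0.1
    sample_scale_sd: float = 0.1
    cm_per_site: float = 0.01
    chrom: str = "chr1"

    def validate(self) -> None:
        for name in ("n_founders", "n_samples", "n_sites", "n_bins", "bin_bp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 <= self.lot_fraction <= 1.0):
            raise ValueError("lot_fraction must lie in [0, 1]")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.copy_tract_mean <= 0:
            raise ValueError("copy_tract_mean must be positive")

    @property
    def span_bp(self) -> int:
        return self.n_bins * self.bin_bp


@dataclass
class HaplotypePanel:
    """Phased biallelic haplotypes: row ``2*s`` and ``2*s + 1`` belong to sample ``s``."""

    alleles: np.ndarray          # (n_haplotypes, n_sites) uint8 in {0, 1}
    site_pos: np.ndarray         # bp coordinates, strictly increasing
    site_cm: np.ndarray          # genetic-map coordinates (cM)
    sample_ids: list[str]
    chrom: str = "chr1"

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.uint8)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be a 2-D matrix")
        if not np.all((self.alleles == 0) | (self.alleles == 1)):
            raise ValueError("alleles must be binary")
        if self.alleles.shape[0] != 2 * len(self.sample_ids):
            raise ValueError("need exactly two haplotypes per sample")
        if np.any(np.diff(self.site_pos) <= 0):
            raise ValueError("site_pos must be strictly increasing")

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    def sample_of(self, hap: int) -> int:
        return hap // 2

    def partner_of(self, hap: int) -> int:
        return hap ^ 1


@dataclass(frozen=True)
class CNVEvent:
    founder_hap: int
    start_bin: int
    end_bin: int               # half-open
    copy_change: int           # -1 deletion, +1 duplication

    def __post_init__(self) -> None:
        if self.copy_change not in (-1, 1):
            raise ValueError("copy_change must be -1 or +1")
        if self.end_bin <= self.start_bin:
            raise ValueError("empty event interval")


@dataclass
class SimTruth:
    """Ground truth for a simulated cohort."""

    events: list[CNVEvent]
    carrier_haps: list[np.ndarray]       # per event: haplotype ids carrying it
    cn: np.ndarray                       # (n_samples, n_bins) integer copy number
    config: CohortConfig
    psv_truth: dict | None = None
    trio_index: list[tuple[str, str, str]] = field(default_factory=list)

    def carriers_of(self, event_idx: int) -> np.ndarray:
        """Sample indices carrying event ``event_idx`` on at least one haplotype."""
        return np.unique(self.carrier_haps[event_idx] // 2)


@dataclass
class ReadCountMatrix:
    """Integer WES read counts per (sample, 100-bp bin) with batch labels."""

    counts: np.ndarray          # (n_samples, n_bins) int64
    sample_ids: list[str]
    bin_ids: list[str]
    lots: np.ndarray            # per-sample lot label ("lot1"/"lot2")
    true_mean: np.ndarray | None = None    # NB means used by the simulator
    capture_eff: np.ndarray | None = None  # per-bin e(b)
    lot_mult: np.ndarray | None = None     # per-bin lot1 multiplier
    sample_scale: np.ndarray | None = None # per-sample g(s)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_bins(self) -> int:
        return self.counts.shape[1]


@dataclass
class TrioSet:
    """Father/mother/child trios with child haplotypes, copy numbers and counts."""

    trio_index: list[tuple[str, str, str]]
    father_idx: np.ndarray
    mother_idx: np.ndarray
    child_alleles: np.ndarray      # (2*n_trios, n_sites)
    child_genealogy: np.ndarray    # (2*n_trios, n_sites) founder ids
    child_cn: np.ndarray           # (n_trios, n_bins)
    child_counts: np.ndarray       # (n_trios, n_bins)

    @property
    def n_trios(self) -> int:
        return len(self.trio_index)


# ---------------------------------------------------------------------------
# haplotype panel
# ---------------------------------------------------------------------------

def _rng(config: CohortConfig, stream: int) -> np.random.Generator:
    # independent substreams so each operation is deterministic given the seed,
    # regardless of call order
    return np.random.default_rng([config.seed, stream])


def _mosaic_genealogy(
    rng: np.random.Generator, n_hap: int, n_sites: int, tract_mean: float, n_founders: int
) -> np.ndarray:
    """Founder id per (haplotype, site) with geometric tract lengths."""
    if tract_mean >= n_sites:
        # no-recombination limit: each haplotype copies one founder verbatim
        founders = rng.integers(0, n_founders, size=n_hap)
        return np.broadcast_to(founders[:, None], (n_hap, n_sites)).copy()
    p_break = 1.0 / tract_mean
    breaks = rng.random((n_hap, n_sites)) < p_break
    breaks[:, 0] = True  # every haplotype starts a segment at site 0
    draws = rng.integers(0, n_founders, size=(n_hap, n_sites))
    cols = np.arange(n_sites)
    seg_start = np.maximum.accumulate(np.where(breaks, cols, 0), axis=1)
    return np.take_along_axis(draws, seg_start, axis=1).astype(np.int32)


def sim_haplotype_panel(config: CohortConfig) -> tuple[HaplotypePanel, np.ndarray]:
    """Simulate a phased panel plus its genealogy record.

    Returns
    -------
    panel : HaplotypePanel
    genealogy : (2*n_samples, n_sites) int array of founder ids
    """
    config.validate()
    if config.n_founders > 2 * config.n_samples:
        warnings.warn(
            "n_founders exceeds the number of haplotypes; little or no "
            "haplotype sharing is expected",
            stacklevel=2,
        )
    rng = _rng(config, 1)
    freqs = rng.uniform(0.05, 0.95, size=config.n_sites)
    founder_alleles = (rng.random((config.n_founders, config.n_sites)) < freqs).astype(np.uint8)
    genealogy = _mosaic_genealogy(
        rng, 2 * config.n_samples, config.n_sites, config.copy_tract_mean, config.n_founders
    )
    alleles = founder_alleles[genealogy, np.arange(config.n_sites)[None, :]]

    # sites spread evenly across the binned span; bp positions strictly increasing
    if config.span_bp < config.n_sites:
        raise ValueError("binned span shorter than the site count; increase n_bins*bin_bp")
    site_pos = np.unique(
        np.round((np.arange(config.n_sites) + 0.5) * config.span_bp / config.n_sites)
    ).astype(np.int64)
    if site_pos.size != config.n_sites:  # collisions after rounding: fall back to 1-bp grid
        site_pos = np.arange(config.n_sites, dtype=np.int64)
    site_cm = np.arange(config.n_sites, dtype=float) * config.cm_per_site
    sample_ids = [f"S{i:05d}" for i in range(config.n_samples)]
    panel = HaplotypePanel(alleles, site_pos, site_cm, sample_ids, chrom=config.chrom)
    return panel, genealogy


def sites_in_bins(panel: HaplotypePanel, config: CohortConfig, start_bin: int, end_bin: int) -> np.ndarray:
    """Indices of panel sites falling inside the bp interval of a bin range.

    If no site falls inside the interval, the nearest site to the interval
    midpoint is returned, so descent over an event interval is always defined.
    """
    lo = start_bin * config.bin_bp
    hi = end_bin * config.bin_bp
    idx = np.flatnonzero((panel.site_pos >= lo) & (panel.site_pos < hi))
    if idx.size == 0:
        mid = 0.5 * (lo + hi)
        idx = np.array([int(np.argmin(np.abs(panel.site_pos - mid)))])
    return idx


# ---------------------------------------------------------------------------
# planted CNVs
# ---------------------------------------------------------------------------

def plant_cnvs(
    panel: HaplotypePanel,
    genealogy: np.ndarray,
    event_specs: list[CNVEvent],
    config: CohortConfig,
) -> SimTruth:
    """Attach CNV events to founder haplotypes and derive per-sample copy numbers.

    A sample haplotype carries an event iff its genealogy equals the event's
    founder haplotype over the whole event interval.  Per-sample copy number
    per bin is ``2 + sum of carried copy changes``.
    """
    by_founder: dict[int, list[CNVEvent]] = {}
    for ev in event_specs:
        if not (0 <= ev.start_bin < ev.end_bin <= config.n_bins):
            raise ValueError(f"event interval {ev.start_bin}:{ev.end_bin} outside bin range")
        if not (0 <= ev.founder_hap < config.n_founders):
            raise ValueError(f"invalid founder haplotype id {ev.founder_hap}")
        for prev in by_founder.get(ev.founder_hap, []):
            if ev.start_bin < prev.end_bin and prev.start_bin < ev.end_bin:
                raise ValueError(
                    f"overlapping events on founder haplotype {ev.founder_hap}"
                )
        by_founder.setdefault(ev.founder_hap, []).append(ev)

    n_samples, n_bins = len(panel.sample_ids), config.n_bins
    cn = np.full((n_samples, n_bins), 2, dtype=np.int64)
    carrier_haps: list[np.ndarray] = []
    for ev in event_specs:
        sites = sites_in_bins(panel, config, ev.start_bin, ev.end_bin)
        carries = np.all(genealogy[:, sites] == ev.founder_hap, axis=1)
        haps = np.flatnonzero(carries)
        carrier_haps.append(haps)
        if haps.size:
            add = np.bincount(haps // 2, minlength=n_samples) * ev.copy_change
            cn[:, ev.start_bin:ev.end_bin] += add[:, None]
    if np.any(cn < 0):
        raise ValueError("copy number fell below zero; conflicting deletions planted")
    return SimTruth(events=list(event_specs), carrier_haps=carrier_haps, cn=cn, config=config)


# ---------------------------------------------------------------------------
# read counts
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mean: np.ndarray, size_param: float) -> np.ndarray:
    """NB(mean, size) draws; a zero mean yields a zero count."""
    mean = np.asarray(mean, dtype=float)
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p)


def _lot_labels(config: CohortConfig, n: int) -> np.ndarray:
    n_lot1 = int(round(config.lot_fraction * n))
    return np.array(["lot1"] * n_lot1 + ["lot2"] * (n - n_lot1))


def sim_read_counts(truth: SimTruth, panel: HaplotypePanel, config: CohortConfig) -> ReadCountMatrix:
    """Draw NB-distributed WES read counts for the cohort.

    The NB mean for sample ``s`` at bin ``b`` is
    ``depth_mean * e(b) * lot(s, b) * g(s) * cn(s, b) / 2`` with per-bin
    log-normal capture efficiency ``e``, a per-bin multiplicative batch effect
    for lot-1 samples, and a per-sample log-normal coverage scale ``g``.
    """
    if config is None:
        raise ValueError("config is required")
    if truth.cn.shape != (config.n_samples, config.n_bins):
        raise ValueError("truth inconsistent with config dimensions")
    rng = _rng(config, 2)
    e_b = np.exp(rng.normal(0.0, config.capture_sd, size=config.n_bins))
    lot1_mult = np.exp(rng.normal(0.0, config.lot_effect_sd, size=config.n_bins))
    g_s = np.exp(rng.normal(0.0, config.sample_scale_sd, size=config.n_samples))
    lots = _lot_labels(config, config.n_samples)
    lot_factor = np.where((lots == "lot1")[:, None], lot1_mult[None, :], 1.0)
    mean = config.depth_mean * e_b[None, :] * lot_factor * g_s[:, None] * truth.cn / 2.0
    counts = _nb_draw(rng, mean, config.nb_dispersion).astype(np.int64)
    bin_ids = [f"bin{b:05d}" for b in range(config.n_bins)]
    return ReadCountMatrix(
        counts=counts,
        sample_ids=list(panel.sample_ids),
        bin_ids=bin_ids,
        lots=lots,
        true_mean=mean,
        capture_eff=e_b,
        lot_mult=lot1_mult,
        sample_scale=g_s,
    )


# ---------------------------------------------------------------------------
# trios
# ---------------------------------------------------------------------------

def _transmit(
    rng: np.random.Generator,
    alleles: np.ndarray,
    genealogy: np.ndarray,
    parent_sample: np.ndarray,
    tract_mean: float,
) -> tuple[np.ndarray, np.ndarray]:
    """One recombined gamete per parent: alleles and genealogy."""
    n, m = len(parent_sample), alleles.shape[1]
    if tract_mean >= m:
        src_is_second = np.broadcast_to(
            (rng.random(n) < 0.5)[:, None], (n, m)
        ).copy()
    else:
        switch = rng.random((n, m)) < 1.0 / tract_mean
        switch[:, 0] = rng.random(n) < 0.5
        # cumulative parity of switches selects between the two parental haplotypes
        src_is_second = np.cumsum(switch, axis=1) % 2 == 1
    hap_a = 2 * parent_sample
    hap_b = 2 * parent_sample + 1
    src = np.where(src_is_second, hap_b[:, None], hap_a[:, None])
    cols = np.arange(m)[None, :]
    return alleles[src, cols], genealogy[src, cols]


def sim_trios(
    panel: HaplotypePanel,
    genealogy: np.ndarray,
    truth: SimTruth,
    config: CohortConfig,
    n_trios: int,
) -> TrioSet:
    """Simulate trios whose parents are cohort samples.

    Parents are taken pairwise from the start of the cohort (samples ``2*i``
    and ``2*i + 1`` form trio ``i``); each child haplotype is a recombined
    gamete of one parent, so Mendelian consistency holds at every site.
    Child read counts are drawn under the same NB depth model.
    """
    if 2 * n_trios > config.n_samples:
        raise ValueError("parental pool too small: need 2 parents per trio")
    rng = _rng(config, 3)
    fathers = np.arange(n_trios) * 2
    mothers = fathers + 1
    pat_alleles, pat_gen = _transmit(rng, panel.alleles, genealogy, fathers, config.copy_tract_mean)
    mat_alleles, mat_gen = _transmit(rng, panel.alleles, genealogy, mothers, config.copy_tract_mean)

    child_alleles = np.empty((2 * n_trios, config.n_sites), dtype=np.uint8)
    child_gen = np.empty((2 * n_trios, config.n_sites), dtype=np.int32)
    child_alleles[0::2], child_alleles[1::2] = pat_alleles, mat_alleles
    child_gen[0::2], child_gen[1::2] = pat_gen, mat_gen

    child_cn = np.full((n_trios, config.n_bins), 2, dtype=np.int64)
    for ev, _ in zip(truth.events, truth.carrier_haps):
        sites = sites_in_bins(panel, config, ev.start_bin, ev.end_bin)
        carries = np.all(child_gen[:, sites] == ev.founder_hap, axis=1)
        add = carries[0::2].astype(np.int64) + carries[1::2].astype(np.int64)
        child_cn[:, ev.start_bin:ev.end_bin] += (add * ev.copy_change)[:, None]

    e_b = truth_counts_capture(truth, panel, config)
    g_child = np.exp(rng.normal(0.0, config.sample_scale_sd, size=n_trios))
    mean = config.depth_mean * e_b[None, :] * g_child[:, None] * child_cn / 2.0
    child_counts = _nb_draw(rng, mean, config.nb_dispersion).astype(np.int64)

    trio_index = [
        (panel.sample_ids[f], panel.sample_ids[m], f"child{i:05d}")
        for i, (f, m) in enumerate(zip(fathers, mothers))
    ]
    truth.trio_index = trio_index
    return TrioSet(
        trio_index=trio_index,
        father_idx=fathers,
        mother_idx=mothers,
        child_alleles=child_alleles,
        child_genealogy=child_gen,
        child_cn=child_cn,
        child_counts=child_counts,
    )


def truth_counts_capture(truth: SimTruth, panel: HaplotypePanel, config: CohortConfig) -> np.ndarray:
    """Per-bin capture efficiencies matching those used in sim_read_counts."""
    rng = _rng(config, 2)
    return np.exp(rng.normal(0.0, config.capture_sd, size=config.n_bins))


# ---------------------------------------------------------------------------
# PSV pileups
# ---------------------------------------------------------------------------

def sim_psv_pileups(
    k_tot: np.ndarray,
    k_psv: np.ndarray,
    depth: float,
    seed: int,
    psv_site: int = 0,
) -> pd.DataFrame:
    """Simulate WGS pileup counts at a PSV site on a collapsed reference.

    Total reads ``t ~ Poisson(depth * k_tot / 2)``; PSV-supporting reads
    ``a ~ Binomial(t, k_psv / k_tot)`` (``a = 0`` when ``k_tot = 0``).
    """
    k_tot = np.asarray(k_tot)
    k_psv = np.asarray(k_psv)
    if np.any(k_tot < 0):
        raise ValueError("repeat copy number must be non-negative")
    if np.any(k_psv > k_tot) or np.any(k_psv < 0):
        raise ValueError("PSV-bearing copies must satisfy 0 <= k_psv <= k_tot")
    rng = np.random.default_rng(seed)
    t = rng.poisson(depth * k_tot / 2.0)
    frac = np.divide(k_psv, k_tot, out=np.zeros(len(k_tot), dtype=float), where=k_tot > 0)
    a = rng.binomial(t, frac)
    return pd.DataFrame(
        {
            "sample": [f"S{i:05d}" for i in range(len(k_tot))],
            "psv_site": psv_site,
            "alt_count": a,
            "total_count": t,
        }
    )


def sim_psv_haplotype_cohort(
    panel: HaplotypePanel,
    genealogy: np.ndarray,
    anchor_site: int,
    founder_psv_copies: np.ndarray,
    depth: float,
    seed: int,
    copies_per_hap: int = 2,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Haplotype-structured PSV truth plus pileups.

    Each haplotype contributes ``copies_per_hap`` repeat units; the number of
    PSV-bearing units on a haplotype is determined by its founder at the
    anchor site.  Returns (pileups, diploid k_tot, diploid k_psv).
    """
    founder_psv_copies = np.asarray(founder_psv_copies)
    hap_psv = founder_psv_copies[genealogy[:, anchor_site]]
    k_psv = hap_psv[0::2] + hap_psv[1::2]
    k_tot = np.full(len(panel.sample_ids), 2 * copies_per_hap, dtype=np.int64)
    pileups = sim_psv_pileups(k_tot, k_psv, depth, seed)
    return pileups, k_tot, k_psv
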