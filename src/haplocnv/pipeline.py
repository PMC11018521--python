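"""End-to-end orchestration and simulation experiments.

``run_pipeline`` executes configured stages (simulate -> normalize -> match ->
call-rare -> screen-common) on a synthetic cohort, writing standard-format
artifacts plus a machine-readable JSON-lines run log; reruns with the same
configuration are bit-identical.

The experiment functions at the bottom reproduce the package's validation
studies — haplotype-pooling sensitivity gain and the null false-call rate —
and are shared by the test suite and the acceptance script.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import depthnorm, io, rarecnv
from .commondosage import trio_screen
from .hapmatch import PBWTIndex, build_pbwt, neighbors_at
from .rarecnv import BayesFactorTrack, HMMConfig
from .simcohort import (
    CNVEvent,
    CohortConfig,
    HaplotypePanel,
    ReadCountMatrix,
    SimTruth,
    plant_cnvs,
    sim_haplotype_panel,
    sim_read_counts,
    sim_trios,
)

__all__ = [
    "make_bins_table",
    "dosage_matrix",
    "neighbor_masks_for_sample",
    "call_sample",
    "run_pipeline",
    "pooling_replicate",
    "pooling_experiment",
    "null_false_call_rate",
]


def make_bins_table(config: CohortConfig, mappable_fraction: float = 1.0) -> pd.DataFrame:
    starts = np.arange(config.n_bins) * config.bin_bp
    return pd.DataFrame(
        {
            "chrom": config.chrom,
            "start": starts,
            "end": starts + config.bin_bp,
            "bin_id": [f"bin{b:05d}" for b in range(config.n_bins)],
            "mappable_fraction": mappable_fraction,
        }
    )


def dosage_matrix(counts: np.ndarray, mu: np.ndarray, sample_ids, bin_ids) -> pd.DataFrame:
    """Copy-number-scale dosage: 2 * count / expected diploid count."""
    return pd.DataFrame(2.0 * counts / mu, index=sample_ids, columns=bin_ids)


# ---------------------------------------------------------------------------
# haplotype-informed calling of one sample
# ---------------------------------------------------------------------------

def _bin_anchor_sites(panel: HaplotypePanel, bins: pd.DataFrame) -> np.ndarray:
    mids = 0.5 * (bins["start"].to_numpy() + bins["end"].to_numpy())
    return np.searchsorted(panel.site_pos, mids).clip(0, panel.n_sites - 1)


def neighbor_masks_for_sample(
    panel: HaplotypePanel,
    index: PBWTIndex,
    target_sample: int,
    bins: pd.DataFrame,
    threshold: float,
    max_neighbors: int = 10,
    unit: str = "cm",
) -> dict[int, np.ndarray]:
    """Per-neighbor-sample boolean bin masks for one target individual.

    At each bin's anchor site, both target haplotypes' neighbor lists are
    merged (deduplicated by sample, keeping the longest match) and capped at
    ``max_neighbors`` samples; a neighbor therefore contributes only at bins
    inside its matching IBD tract.
    """
    anchors = _bin_anchor_sites(panel, bins)
    n_bins = len(bins)
    masks: dict[int, np.ndarray] = {}
    cache: dict[int, list] = {}
    for b in range(n_bins):
        site = int(anchors[b])
        if site in cache:
            merged = cache[site]
        else:
            cands = []
            for hap in (2 * target_sample, 2 * target_sample + 1):
                ns = neighbors_at(index, panel, hap, site, threshold, max_neighbors, unit)
                cands.extend(ns.neighbors)
            cands.sort(key=lambda n: (-n.length_sites, n.hap))
            best: dict[int, object] = {}
            for n in cands:
                best.setdefault(n.hap // 2, n)
            merged = list(best.keys())[:max_neighbors]
            cache[site] = merged
        for q in merged:
            if q not in masks:
                masks[q] = np.zeros(n_bins, dtype=bool)
            masks[q][b] = True
    return masks


def call_sample(
    sample_idx: int,
    matrix: ReadCountMatrix,
    norm: depthnorm.NormModel,
    panel: HaplotypePanel,
    index: PBWTIndex | None,
    bins: pd.DataFrame,
    hmm_cfg: HMMConfig,
    threshold: float,
    max_neighbors: int = 10,
    unit: str = "cm",
    track_cache: dict[int, BayesFactorTrack] | None = None,
) -> list[rarecnv.CNVCall]:
    """Combined-BF HMM calls for one sample at one IBD threshold.

    ``max_neighbors = 0`` (or no index) gives the single-sample analysis.
    """
    def _track(s: int) -> BayesFactorTrack:
        if track_cache is not None and s in track_cache:
            return track_cache[s]
        t = rarecnv.emission_logbf_track(
            matrix.counts[s], norm.mu[s], norm.phi[s], sample=matrix.sample_ids[s]
        )
        if track_cache is not None:
            track_cache[s] = t
        return t

    target = _track(sample_idx)
    if max_neighbors > 0 and index is not None:
        masks = neighbor_masks_for_sample(
            panel, index, sample_idx, bins, threshold, max_neighbors, unit
        )
        neighbor_tracks = [(_track(q), mask) for q, mask in masks.items()]
        track = rarecnv.combined_bf(target, neighbor_tracks)
    else:
        track = target
    post, path = rarecnv.hmm_segment(track, hmm_cfg)
    return rarecnv.call_cnvs(track, post, path, hmm_cfg, bins, ibd_threshold=threshold)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: io.RunConfig, outdir: str | None = None) -> dict[str, str]:
    """Execute the configured stages in dependency order.

    Returns a mapping from artifact name to path.  Every output carries the
    stage name and config hash; a ``run_log.jsonl`` records one entry per
    stage with input sizes and counts.
    """
    outdir = outdir or config.outdir
    os.makedirs(outdir, exist_ok=True)
    chash = io.config_hash(config)
    log_path = os.path.join(outdir, "run_log.jsonl")
    artifacts: dict[str, str] = {"run_log": log_path}
    log_entries: list[dict] = []
    config.to_yaml(os.path.join(outdir, "config.yaml"))
    artifacts["config"] = os.path.join(outdir, "config.yaml")

    ccfg = config.cohort
    events = [CNVEvent(*spec) for spec in getattr(config, "events", [])]
    state: dict = {}

    for stage in config.stages:
        try:
            if stage == "simulate":
                panel, genealogy = sim_haplotype_panel(ccfg)
                truth = plant_cnvs(panel, genealogy, events, ccfg)
                matrix = sim_read_counts(truth, panel, ccfg)
                state.update(panel=panel, genealogy=genealogy, truth=truth, matrix=matrix)
                io.write_panel_vcf(panel, os.path.join(outdir, "panel.vcf"), stage, chash)
                io.write_counts_tsv(matrix, os.path.join(outdir, "counts.tsv.gz"), stage, chash)
                io.write_truth_json(truth, os.path.join(outdir, "truth.json"), stage, chash)
                artifacts.update(
                    panel=os.path.join(outdir, "panel.vcf"),
                    counts=os.path.join(outdir, "counts.tsv.gz"),
                    truth=os.path.join(outdir, "truth.json"),
                )
                if config.n_trios:
                    trios = sim_trios(panel, genealogy, truth, ccfg, config.n_trios)
                    state["trios"] = trios
                    io.write_trios_fam(trios, os.path.join(outdir, "trios.fam"), stage, chash)
                    artifacts["trios"] = os.path.join(outdir, "trios.fam")
                log_entries.append(
                    {
                        "stage": stage, "seed": ccfg.seed,
                        "n_samples": ccfg.n_samples, "n_bins": ccfg.n_bins,
                        "n_events": len(events),
                        "n_carriers": [int(len(c)) for c in truth.carrier_haps],
                    }
                )
            elif stage == "normalize":
                bins = make_bins_table(ccfg)
                norm = depthnorm.normalize(state["matrix"], bins, k=config.k_reference, thresholds=config.qc)
                state["norm"], state["bins"] = norm, bins
                mu_df = pd.DataFrame(
                    norm.mu, index=state["matrix"].sample_ids, columns=state["matrix"].bin_ids
                )
                with open(os.path.join(outdir, "norm_mu.tsv"), "w") as fh:
                    fh.write(io._header(stage, chash))
                    mu_df.to_csv(fh, sep="\t", index_label="sample")
                phi_df = pd.DataFrame(
                    {"sample": state["matrix"].sample_ids, "phi": norm.phi}
                )
                with open(os.path.join(outdir, "norm_phi.tsv"), "w") as fh:
                    fh.write(io._header(stage, chash))
                    phi_df.to_csv(fh, sep="\t", index=False)
                artifacts["norm_mu"] = os.path.join(outdir, "norm_mu.tsv")
                artifacts["norm_phi"] = os.path.join(outdir, "norm_phi.tsv")
                log_entries.append(
                    {"stage": stage, "n_retained_bins": int(norm.retained.sum())}
                )
            elif stage == "match":
                state["index"] = build_pbwt(state["panel"])
                log_entries.append(
                    {"stage": stage, "n_haplotypes": state["panel"].n_haplotypes}
                )
            elif stage == "call-rare":
                matrix, norm, bins = state["matrix"], state["norm"], state["bins"]
                retained = norm.retained
                sub = ReadCountMatrix(
                    counts=matrix.counts[:, retained],
                    sample_ids=matrix.sample_ids,
                    bin_ids=[b for b, r in zip(matrix.bin_ids, retained) if r],
                    lots=matrix.lots,
                )
                sub_norm = depthnorm.NormModel(
                    mu=norm.mu[:, retained], phi=norm.phi, reference_ids=norm.reference_ids,
                    sample_scale=norm.sample_scale, retained=np.ones(int(retained.sum()), bool),
                )
                sub_bins = bins.loc[retained].reset_index(drop=True)
                cache: dict[int, BayesFactorTrack] = {}
                by_thr: dict[float, list[rarecnv.CNVCall]] = {}
                for thr in config.hmm.ibd_thresholds:
                    calls_t: list[rarecnv.CNVCall] = []
                    for s in range(matrix.n_samples):
                        calls_t.extend(
                            call_sample(
                                s, sub, sub_norm, state["panel"], state.get("index"),
                                sub_bins, config.hmm, thr, track_cache=cache,
                            )
                        )
                    by_thr[thr] = calls_t
                compiled = rarecnv.compile_thresholds(by_thr)
                kept, excluded, reasons = rarecnv.filter_calls(
                    compiled, per_sample_cap=config.hmm.per_sample_cap,
                    score_min=config.hmm.score_min,
                )
                state["calls"] = kept
                io.write_calls_bed(kept, os.path.join(outdir, "calls.bed"), stage, chash)
                io.write_calls_vcf(kept, os.path.join(outdir, "calls.vcf"), stage=stage, chash=chash)
                artifacts["calls_bed"] = os.path.join(outdir, "calls.bed")
                artifacts["calls_vcf"] = os.path.join(outdir, "calls.vcf")
                log_entries.append(
                    {
                        "stage": stage, "n_compiled": len(compiled), "n_kept": len(kept),
                        "n_excluded_samples": len(excluded), "removals": reasons,
                    }
                )
            elif stage == "screen-common":
                if "trios" not in state:
                    raise RuntimeError("screen-common requires trios (set n_trios)")
                matrix, norm, trios = state["matrix"], state["norm"], state["trios"]
                dose = dosage_matrix(
                    matrix.counts, norm.mu, matrix.sample_ids, matrix.bin_ids
                )
                mu_bin = norm.mu.mean(axis=0)
                child_scale = (
                    trios.child_counts.sum(axis=1, keepdims=True)
                    / max(float(np.mean(matrix.counts.sum(axis=1))), 1.0)
                )
                child_dose = 2.0 * trios.child_counts / (mu_bin[None, :] * child_scale)
                results = trio_screen(dose, trios, child_dose)
                df = pd.DataFrame([vars(r) for r in results])
                with open(os.path.join(outdir, "trio_screen.tsv"), "w") as fh:
                    fh.write(io._header(stage, chash))
                    df.to_csv(fh, sep="\t", index=False)
                artifacts["trio_screen"] = os.path.join(outdir, "trio_screen.tsv")
                log_entries.append(
                    {"stage": stage, "n_regions": len(df), "n_retained": int(df["retained"].sum())}
                )
            else:
                raise ValueError(f"unknown stage {stage!r}")
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(log_path, "w") as fh:
        for entry in log_entries:
            entry["config"] = chash
            fh.write(json.dumps(entry, sort_keys=True) + "\n")
    return artifacts


# ---------------------------------------------------------------------------
# validation experiments
# ---------------------------------------------------------------------------

@dataclass
class PoolingReplicate:
    seed: int
    n_carriers: int
    carrier_freq: float
    sensitivity_solo: float
    sensitivity_pooled: float


def _pooling_config(seed: int) -> CohortConfig:
    # study conditions for the pooling benefit experiment: 2,000 samples,
    # 30x depth, NB size 10, ~1 cM IBD tracts over a 16-kb / 3-cM region
    return CohortConfig(
        n_founders=200,
        n_samples=2000,
        n_sites=300,
        n_bins=160,
        bin_bp=100,
        copy_tract_mean=100.0,
        seed=seed,
        lot_fraction=0.1,
        depth_mean=30.0,
        nb_dispersion=10.0,
        capture_sd=0.3,
        lot_effect_sd=0.1,
    )


def _pick_founder(genealogy: np.ndarray, sites: np.ndarray, n_founders: int, target_freq: float) -> int:
    """Founder whose full-interval descendants give the carrier frequency
    closest to the target (ties to the lowest id)."""
    n_samples = genealogy.shape[0] // 2
    best, best_gap = 0, np.inf
    for f in range(n_founders):
        hap_carries = np.all(genealogy[:, sites] == f, axis=1)
        freq = np.count_nonzero(hap_carries[0::2] | hap_carries[1::2]) / n_samples
        gap = abs(freq - target_freq)
        if 0 < freq and gap < best_gap:
            best, best_gap = f, gap
    return best


def pooling_replicate(
    seed: int,
    event_bins: tuple[int, int] = (76, 82),
    carrier_freq: float = 0.01,
    threshold_cm: float = 0.5,
    max_neighbors: int = 10,
    hmm_cfg: HMMConfig | None = None,
) -> PoolingReplicate:
    """One replicate of the haplotype-pooling sensitivity experiment.

    A heterozygous deletion is planted on the founder haplotype whose descent
    gives a carrier frequency nearest ``carrier_freq``; every true carrier is
    then analyzed twice — alone, and pooled with up to ``max_neighbors`` IBD
    neighbors — and sensitivity is the fraction of carriers recovered by a
    deletion call overlapping the event at the default score threshold.
    """
    from .simcohort import sites_in_bins

    cfg = _pooling_config(seed)
    hmm_cfg = hmm_cfg or HMMConfig(ibd_thresholds=(threshold_cm,))
    panel, genealogy = sim_haplotype_panel(cfg)
    sites = sites_in_bins(panel, cfg, *event_bins)
    founder = _pick_founder(genealogy, sites, cfg.n_founders, carrier_freq)
    event = CNVEvent(founder, event_bins[0], event_bins[1], -1)
    truth = plant_cnvs(panel, genealogy, [event], cfg)
    matrix = sim_read_counts(truth, panel, cfg)
    bins = make_bins_table(cfg)

    retained, _ = depthnorm.qc_bins(matrix, bins)
    sub = ReadCountMatrix(
        counts=matrix.counts[:, retained],
        sample_ids=matrix.sample_ids,
        bin_ids=[b for b, r in zip(matrix.bin_ids, retained) if r],
        lots=matrix.lots,
    )
    all_ret = np.ones(sub.n_bins, dtype=bool)
    refs = depthnorm.select_reference_panels(sub, 20, all_ret)
    mu = np.empty_like(sub.counts, dtype=float)
    scale = np.empty(sub.n_samples)
    for s in range(sub.n_samples):
        mu[s], scale[s], _ = depthnorm.estimate_expected_depth(s, refs[s], sub, all_ret)
    phi = depthnorm.fit_dispersion(sub, mu, all_ret)
    norm = depthnorm.NormModel(mu=mu, phi=phi, reference_ids=refs, sample_scale=scale, retained=all_ret)
    sub_bins = bins.loc[retained].reset_index(drop=True)

    index = build_pbwt(panel)
    carriers = truth.carriers_of(0)
    ev_lo, ev_hi = event_bins[0] * cfg.bin_bp, event_bins[1] * cfg.bin_bp
    cache: dict[int, BayesFactorTrack] = {}

    def _detected(calls: list[rarecnv.CNVCall]) -> bool:
        return any(
            c.type == "DEL" and c.start < ev_hi and ev_lo < c.end and c.score >= hmm_cfg.score_min
            for c in calls
        )

    hit_solo = hit_pooled = 0
    for s in carriers:
        solo = call_sample(
            int(s), sub, norm, panel, None, sub_bins, hmm_cfg, threshold_cm,
            max_neighbors=0, track_cache=cache,
        )
        pooled = call_sample(
            int(s), sub, norm, panel, index, sub_bins, hmm_cfg, threshold_cm,
            max_neighbors=max_neighbors, track_cache=cache,
        )
        hit_solo += _detected(solo)
        hit_pooled += _detected(pooled)
    n_car = len(carriers)
    return PoolingReplicate(
        seed=seed,
        n_carriers=n_car,
        carrier_freq=n_car / cfg.n_samples,
        sensitivity_solo=hit_solo / max(n_car, 1),
        sensitivity_pooled=hit_pooled / max(n_car, 1),
    )


def pooling_experiment(n_replicates: int, seed: int) -> pd.DataFrame:
    """Replicated pooling experiment; rows are per-replicate sensitivities."""
    seeds = np.random.SeedSequence(seed).generate_state(n_replicates) % (2**31)
    rows = [pooling_replicate(int(s)) for s in seeds]
    return pd.DataFrame([vars(r) for r in rows])


def two_class_panel(
    seed: int, n_samples: int, n_sites: int = 120, tract_mean: float = 60.0,
    bin_bp: int = 100, cm_per_site: float = 0.01,
) -> tuple[HaplotypePanel, np.ndarray]:
    """Mosaic panel over two complementary founders.

    The two founder haplotypes are bitwise complements, so allele identity
    coincides exactly with genealogy identity — IBD neighbor clusters found
    from alleles are exactly the founder classes, which makes this panel the
    reference construction for haplotype-structured dosage experiments.
    """
    rng = np.random.default_rng([seed, 11])
    founder0 = (rng.random(n_sites) < 0.5).astype(np.uint8)
    founders = np.stack([founder0, 1 - founder0])
    p_break = 1.0 / tract_mean
    breaks = rng.random((2 * n_samples, n_sites)) < p_break
    breaks[:, 0] = True
    draws = rng.integers(0, 2, size=(2 * n_samples, n_sites))
    cols = np.arange(n_sites)
    seg_start = np.maximum.accumulate(np.where(breaks, cols, 0), axis=1)
    genealogy = np.take_along_axis(draws, seg_start, axis=1).astype(np.int32)
    alleles = founders[genealogy, cols[None, :]]
    n_bins_equiv = max(n_sites // 2, 1)
    span = n_bins_equiv * bin_bp
    site_pos = np.round((np.arange(n_sites) + 0.5) * span / n_sites).astype(np.int64)
    if len(np.unique(site_pos)) != n_sites:
        site_pos = np.arange(n_sites, dtype=np.int64)
    site_cm = np.arange(n_sites, dtype=float) * cm_per_site
    sample_ids = [f"S{i:05d}" for i in range(n_samples)]
    panel = HaplotypePanel(alleles, site_pos, site_cm, sample_ids)
    return panel, genealogy


def denoise_experiment(
    seed: int,
    n_samples: int = 500,
    noise_sd: float = 0.5,
    hap_values: tuple[float, float] = (1.0, 2.0),
    threshold: float = 30.0,
    holdout_frac: float = 0.1,
    max_neighbors: int = 30,
) -> dict[str, float]:
    """Two-class dosage phasing/denoising plus hold-out imputation.

    Haplotypes belong to one of two classes (complementary founders) with
    true per-haplotype dosage values ``hap_values``; diploid measurements add
    N(0, noise_sd) noise.  Denoising accuracy (RMSE, class means, mass
    conservation) is evaluated on the fully measured cohort; a second run
    leaves a random ``holdout_frac`` of samples unmeasured and imputes them
    from measured IBD neighbors.  Thresholds are in sites (genealogy ==
    allele identity on this panel).
    """
    from .commondosage import impute_dosage, phase_denoise

    panel, genealogy = two_class_panel(seed, n_samples)
    anchor = panel.n_sites // 2
    rng = np.random.default_rng([seed, 13])
    hv = np.asarray(hap_values)[genealogy[:, anchor]]
    true_diploid = hv[0::2] + hv[1::2]
    meas = true_diploid + rng.normal(0.0, noise_sd, n_samples)
    index = build_pbwt(panel)

    # denoising on the fully measured cohort
    values_all = pd.Series(meas, index=panel.sample_ids)
    phased = phase_denoise(
        values_all, panel, index, threshold, anchor, max_neighbors=max_neighbors, unit="sites"
    )
    den = phased.denoised.to_numpy()
    rmse_raw = float(np.sqrt(np.mean((meas - true_diploid) ** 2)))
    rmse_den = float(np.sqrt(np.mean((den - true_diploid) ** 2)))
    class_mean = [
        float(np.nanmean(phased.hap_values[genealogy[:, anchor] == cls])) for cls in (0, 1)
    ]

    # hold-out imputation from a partially measured cohort
    n_hold = int(round(holdout_frac * n_samples))
    holdout = rng.choice(n_samples, size=n_hold, replace=False)
    measured = np.setdiff1d(np.arange(n_samples), holdout)
    values = pd.Series(meas[measured], index=[panel.sample_ids[i] for i in measured])
    phased_part = phase_denoise(
        values, panel, index, threshold, anchor, max_neighbors=max_neighbors, unit="sites"
    )
    imputed, _ = impute_dosage(
        phased_part, panel, index, [panel.sample_ids[i] for i in holdout], threshold,
        max_neighbors=max_neighbors, unit="sites", anchor_site=anchor,
    )
    imp = imputed.to_numpy()
    ok = ~np.isnan(imp)
    corr_imp = float(np.corrcoef(imp[ok], true_diploid[holdout][ok])[0, 1])
    corr_raw = float(np.corrcoef(meas[holdout], true_diploid[holdout])[0, 1])
    return {
        "rmse_raw": rmse_raw,
        "rmse_denoised": rmse_den,
        "class_mean_low": class_mean[0],
        "class_mean_high": class_mean[1],
        "corr_imputed": corr_imp,
        "corr_raw_noise": corr_raw,
        "n_holdout_imputed": int(ok.sum()),
        "n_holdout": n_hold,
        "mean_measured": float(np.mean(meas)),
        "mean_denoised": float(np.mean(den)),
        "change_history": phased.change_history,
    }


def trio_heritability_experiment(seed: int, n_trios: int = 2000) -> dict[str, float]:
    """Mid-parent/child correlation of a noiseless additive copy-number region.

    Deletions are planted on half the founder haplotypes at a single-site
    locus, so the per-haplotype dosage contribution is a Bernoulli variable
    copied intact to the transmitted gamete; with the child inheriting one
    haplotype from each parent, the analytic correlation between child and
    mid-parent values is 1/sqrt(2): Cov = v, Var(child) = 2v,
    Var(mid-parent) = v for haplotype variance v.  (A multi-site event
    interval would attenuate the correlation: a gamete recombining inside the
    interval breaks the carried tract.)
    """
    cfg = CohortConfig(
        n_founders=40, n_samples=2 * n_trios, n_sites=12, n_bins=12,
        copy_tract_mean=6.0, seed=seed, depth_mean=30.0,
    )
    panel, genealogy = sim_haplotype_panel(cfg)
    events = [CNVEvent(f, 5, 6, -1) for f in range(20)]
    truth = plant_cnvs(panel, genealogy, events, cfg)
    trios = sim_trios(panel, genealogy, truth, cfg, n_trios)
    parents = pd.DataFrame({"region": truth.cn[:, 5].astype(float)})
    children = trios.child_cn[:, 5].astype(float)[:, None]
    res = trio_screen(parents, trios, children)[0]
    return {"r": res.r, "p": res.p_value, "n_trios": n_trios}


def trio_null_screen(seed: int, n_trios: int = 704, n_regions: int = 1000) -> dict[str, float]:
    """Type-I behavior of the trio screen on pure-noise regions."""
    rng = np.random.default_rng([seed, 31])
    parents = pd.DataFrame(
        rng.standard_normal((2 * n_trios, n_regions)),
        columns=[f"r{j}" for j in range(n_regions)],
    )
    children = rng.standard_normal((n_trios, n_regions))
    trios = [(i, n_trios + i, None) for i in range(n_trios)]
    results = trio_screen(parents, trios, children)
    n_retained = sum(r.retained for r in results)
    p05 = np.mean([r.p_value < 0.05 for r in results])
    return {
        "bonferroni_retained": n_retained,
        "p05_rate": float(p05),
        "n_regions": n_regions,
        "n_trios": n_trios,
    }


def association_null_pvalues(n_draws: int = 500, n: int = 10_000, seed: int = 0) -> np.ndarray:
    """P-values of the OLS association test on independent null draws."""
    from .assoc import test_association

    rng = np.random.default_rng([seed, 21])
    ps = np.empty(n_draws)
    for i in range(n_draws):
        x = rng.standard_normal(n)
        y = rng.standard_normal(n)
        ps[i] = test_association(x, y).p_value
    return ps


def deletion_effect_coverage(
    n_replicates: int = 100,
    n: int = 50_000,
    allele_freq: float = 0.005,
    beta: float = -0.4,
    seed: int = 0,
) -> dict[str, float]:
    """95% CI coverage of a planted rare-deletion effect on a prepared trait.

    Genotypes are allele dosages (0/1/2) at the given allele frequency; the
    phenotype is ``beta`` per allele plus standard normal noise.
    """
    from .assoc import test_association

    rng = np.random.default_rng([seed, 22])
    covered = 0
    betas = np.empty(n_replicates)
    for i in range(n_replicates):
        g = rng.binomial(2, allele_freq, n).astype(float)
        y = beta * g + rng.standard_normal(n)
        res = test_association(g, y)
        betas[i] = res.beta
        covered += abs(res.beta - beta) <= 1.96 * res.se
    return {
        "coverage": covered / n_replicates,
        "mean_beta": float(betas.mean()),
        "n_replicates": n_replicates,
        "n": n,
    }


def ld_filter_accuracy(n_replicates: int = 100, n: int = 5000, seed: int = 0) -> dict[str, float]:
    """Fraction of correct LD-filter verdicts over paired tag/causal scenarios.

    Even replicates plant a causal CNV partially tagged (r^2 ~ 0.66) by a
    nearby SNP: the filter should pass the CNV.  Odd replicates make the SNP
    causal and the CNV a mere tag: the filter should fail the CNV.
    """
    import pandas as pd

    from .assoc import ld_filter

    rng = np.random.default_rng([seed, 23])
    q = np.sqrt(0.66)
    correct = 0
    for i in range(n_replicates):
        g = rng.binomial(1, 0.2, n).astype(float)
        redraw = rng.random(n) >= q
        tag = np.where(redraw, rng.binomial(1, 0.2, n).astype(float), g)
        causal_is_target = i % 2 == 0
        driver = g if causal_is_target else tag
        y = 0.25 * driver + rng.standard_normal(n)
        res = ld_filter(pd.Series(g), pd.DataFrame({"snp": tag}), pd.Series(y))
        correct += res.passed == causal_is_target
    return {"accuracy": correct / n_replicates, "n_replicates": n_replicates}


def _max_subarray(x: np.ndarray) -> float:
    """Maximum contiguous-segment sum (empty segment excluded)."""
    c = np.cumsum(x)
    running_min = np.minimum.accumulate(np.concatenate([[0.0], c[:-1]]))
    return float(np.max(c - running_min))


def null_false_call_rate(
    seed: int, n_samples: int = 2000, n_bins: int = 640, hmm_cfg: HMMConfig | None = None
) -> dict[str, float]:
    """False-call rate of the single-sample HMM on a CNV-free cohort.

    Returns per-(sample, bin) rates of called CNV bins and of emitted call
    segments, with the prior rates implied by the transition parameters.  A
    cheap upper bound on the achievable path-score gain skips samples that
    provably cannot produce a Viterbi CNV segment.
    """
    hmm_cfg = hmm_cfg or HMMConfig(ibd_thresholds=(1.0,))
    cfg = CohortConfig(
        n_founders=50, n_samples=n_samples, n_sites=100, n_bins=n_bins,
        bin_bp=100, seed=seed, depth_mean=30.0, nb_dispersion=10.0,
    )
    panel, genealogy = sim_haplotype_panel(cfg)
    truth = plant_cnvs(panel, genealogy, [], cfg)
    matrix = sim_read_counts(truth, panel, cfg)
    bins = make_bins_table(cfg)
    retained, _ = depthnorm.qc_bins(matrix, bins)
    sub_counts = matrix.counts[:, retained]
    sub = ReadCountMatrix(
        counts=sub_counts, sample_ids=matrix.sample_ids,
        bin_ids=[b for b, r in zip(matrix.bin_ids, retained) if r], lots=matrix.lots,
    )
    all_ret = np.ones(sub.n_bins, dtype=bool)
    refs = depthnorm.select_reference_panels(sub, 20, all_ret)
    mu = np.empty_like(sub.counts, dtype=float)
    for s in range(sub.n_samples):
        mu[s], _, _ = depthnorm.estimate_expected_depth(s, refs[s], sub, all_ret)
    phi = depthnorm.fit_dispersion(sub, mu, all_ret)
    sub_bins = bins.loc[retained].reset_index(drop=True)

    # evidence bound: a Viterbi CNV segment over bins [i, j) must beat the
    # all-diploid path, whose transition advantage is at least
    # -ln(tau_enter) - ln(exit); the best achievable evidence is the maximum
    # contiguous-segment sum of the log Bayes factors
    tau, ex = hmm_cfg.tau_enter, 1.0 / hmm_cfg.expected_len_bins
    need = -(np.log(tau) + np.log(ex)) - 0.5
    cnv_bins = 0
    n_calls = 0
    for s in range(sub.n_samples):
        track = rarecnv.emission_logbf_track(sub.counts[s], mu[s], phi[s], sub.sample_ids[s])
        gain = max(_max_subarray(track.log_bf_del), _max_subarray(track.log_bf_dup))
        if gain < need:
            continue
        post, path = rarecnv.hmm_segment(track, hmm_cfg)
        calls = rarecnv.call_cnvs(track, post, path, hmm_cfg, sub_bins)
        n_calls += len(calls)
        cnv_bins += int(np.sum(path != rarecnv.DIP))
    total = sub.n_samples * sub.n_bins
    x = tau / (ex + 2 * tau)
    return {
        "false_cnv_bin_rate": cnv_bins / total,
        "false_call_rate": n_calls / total,
        "prior_cnv_bin_rate": 2 * x,
        "prior_entry_rate": 2 * tau,
        "sample_bins": total,
    }
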