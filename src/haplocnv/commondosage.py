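"""Common copy-variable regions: trio heritability screen, haplotype phasing /
denoising of continuous dosage, and imputation into unmeasured samples.

Common CNVs and segmental-duplication copy variation resist discrete
genotyping from short reads, so copy number is carried as a continuous,
read-depth-derived dosage.  Regions are screened for heritability via
mid-parent versus child correlations of normalized depth in trios; dosage in
retained regions is then phased onto haplotypes and simultaneously denoised
by iterative averaging over IBD-sharing haplotype clusters, which also lets
values be imputed into samples with haplotypes but no sequencing measurement.
A WES-versus-WGS consistency filter guards against exome-capture bias
masquerading as heritable copy variation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .hapmatch import PBWTIndex, neighbors_at
from .simcohort import HaplotypePanel, TrioSet

__all__ = [
    "HeritabilityResult",
    "PhasedDosage",
    "trio_screen",
    "region_anchor_site",
    "phase_denoise",
    "impute_dosage",
    "wes_wgs_consistency",
]


@dataclass
class HeritabilityResult:
    region_id: str
    r: float
    p_value: float
    n_trios: int
    retained: bool
    reason: str = ""


@dataclass
class PhasedDosage:
    """Per-haplotype dosage values and their diploid sums."""

    hap_values: np.ndarray          # value per panel haplotype (NaN if unmeasured)
    denoised: pd.Series             # per measured sample: v(2s) + v(2s+1)
    iterations_run: int
    converged: bool
    change_history: list[float] | None = None   # max abs update per sweep


def trio_screen(
    dosage: pd.DataFrame,
    trios: TrioSet | list[tuple[int, int, np.ndarray]],
    child_dosage: pd.DataFrame | np.ndarray,
    alpha: float = 0.05,
    known_cnv: set[str] | None = None,
) -> list[HeritabilityResult]:
    """Retain regions whose dosage is heritable in trios.

    Per region, the Pearson correlation between the child value and the
    mid-parent value (mean of the two parents) is tested one-sided (r > 0);
    retention requires p below the Bonferroni-adjusted ``alpha`` across the
    screened regions.  Regions listed in ``known_cnv`` (a previously reported
    CNV catalog) are retained unconditionally and do not count toward the
    correction.

    ``dosage``: (samples x regions) parent measurements, positionally indexed;
    ``child_dosage``: (trios x regions) child measurements.
    """
    known = known_cnv or set()
    if isinstance(trios, TrioSet):
        fathers, mothers = trios.father_idx, trios.mother_idx
    else:
        fathers = np.array([t[0] for t in trios])
        mothers = np.array([t[1] for t in trios])
    n_trios = len(fathers)
    if n_trios < 30:
        raise ValueError("need at least 30 trios")
    parents = dosage.to_numpy() if isinstance(dosage, pd.DataFrame) else np.asarray(dosage)
    children = (
        child_dosage.to_numpy() if isinstance(child_dosage, pd.DataFrame) else np.asarray(child_dosage)
    )
    region_ids = (
        list(dosage.columns) if isinstance(dosage, pd.DataFrame) else [str(i) for i in range(parents.shape[1])]
    )
    midparent = 0.5 * (parents[fathers] + parents[mothers])

    screened = [rid for rid in region_ids if rid not in known]
    n_tests = max(len(screened), 1)
    thresh = alpha / n_tests
    results: list[HeritabilityResult] = []
    for j, rid in enumerate(region_ids):
        if rid in known:
            results.append(HeritabilityResult(rid, np.nan, np.nan, n_trios, True, "known_cnv"))
            continue
        mp, ch = midparent[:, j], children[:, j]
        if np.std(mp) == 0 or np.std(ch) == 0:
            results.append(
                HeritabilityResult(rid, np.nan, np.nan, n_trios, False, "zero_variance")
            )
            continue
        r, p = pearsonr(ch, mp, alternative="greater")
        results.append(
            HeritabilityResult(rid, float(r), float(p), n_trios, bool(p < thresh))
        )
    return results


def region_anchor_site(panel: HaplotypePanel, region_start: int, region_end: int) -> int:
    """Panel site nearest the midpoint of a bp region."""
    mid = 0.5 * (region_start + region_end)
    return int(np.argmin(np.abs(panel.site_pos - mid)))


def _neighbor_clusters(
    panel: HaplotypePanel,
    index: PBWTIndex,
    haps: np.ndarray,
    measured_haps: set[int],
    anchor_site: int,
    threshold: float,
    max_neighbors: int,
    unit: str,
) -> dict[int, np.ndarray]:
    clusters: dict[int, np.ndarray] = {}
    for h in haps:
        ns = neighbors_at(
            index, panel, int(h), anchor_site, threshold, max_neighbors=max_neighbors, unit=unit
        )
        members = [int(h)] + [n.hap for n in ns.neighbors if n.hap in measured_haps]
        clusters[int(h)] = np.array(members, dtype=np.int64)
    return clusters


def phase_denoise(
    values: pd.Series,
    panel: HaplotypePanel,
    index: PBWTIndex,
    threshold: float,
    anchor_site: int,
    max_iter: int = 50,
    tol: float = 1e-6,
    max_neighbors: int = 30,
    unit: str = "cm",
) -> PhasedDosage:
    """Phase a diploid dosage onto haplotypes while denoising it.

    Starting from half the diploid measurement per haplotype, each haplotype's
    value is repeatedly replaced by the mean, over its IBD neighbor cluster at
    the region anchor (including itself), of the cluster members'
    measurements minus their partner haplotypes' current values.  Updates run
    in fixed haplotype-id order (Gauss-Seidel) for determinism and stop when
    the largest change drops below ``tol``.  Haplotypes with no neighbors keep
    their running value.

    Clusters here are larger than the ten-neighbor cap of the rare-CNV HMM:
    the scheme carries a weakly damped antisymmetric mode whose residual noise
    shrinks with the cluster-mean noise, so denoising benefits from more
    neighbors.
    """
    sample_index = {sid: i for i, sid in enumerate(panel.sample_ids)}
    measured_samples = [sample_index[s] for s in values.index]
    meas = np.full(len(panel.sample_ids), np.nan)
    meas[measured_samples] = values.to_numpy(dtype=float)

    haps = np.sort(
        np.concatenate([[2 * s, 2 * s + 1] for s in measured_samples]).astype(np.int64)
    )
    measured_set = set(int(h) for h in haps)
    clusters = _neighbor_clusters(
        panel, index, haps, measured_set, anchor_site, threshold, max_neighbors, unit
    )

    v = np.full(panel.n_haplotypes, np.nan)
    v[haps] = meas[haps // 2] / 2.0
    iterations = 0
    converged = False
    history: list[float] = []
    for iterations in range(1, max_iter + 1):
        max_change = 0.0
        for h in haps:
            members = clusters[int(h)]
            new = float(np.mean(meas[members // 2] - v[members ^ 1]))
            max_change = max(max_change, abs(new - v[h]))
            v[h] = new
        history.append(max_change)
        if max_change < tol:
            converged = True
            break
    denoised = pd.Series(
        v[2 * np.asarray(measured_samples)] + v[2 * np.asarray(measured_samples) + 1],
        index=values.index,
    )
    return PhasedDosage(
        hap_values=v, denoised=denoised, iterations_run=iterations,
        converged=converged, change_history=history,
    )


def impute_dosage(
    phased: PhasedDosage,
    panel: HaplotypePanel,
    index: PBWTIndex,
    targets: list[str],
    threshold: float,
    max_neighbors: int = 10,
    unit: str = "cm",
    anchor_site: int | None = None,
) -> tuple[pd.Series, dict[str, str]]:
    """Impute diploid dosage into samples without measurements.

    Each target haplotype takes the mean value of its measured IBD neighbors
    at the anchor; the diploid value is the sum over the two haplotypes.
    Targets with any haplotype lacking a measured neighbor at the threshold
    are returned as missing with a reason.
    """
    if anchor_site is None:
        raise ValueError("anchor_site is required")
    sample_index = {sid: i for i, sid in enumerate(panel.sample_ids)}
    measured_haps = set(np.flatnonzero(~np.isnan(phased.hap_values)).tolist())
    out: dict[str, float] = {}
    reasons: dict[str, str] = {}
    for sid in targets:
        s = sample_index[sid]
        hap_vals = []
        for h in (2 * s, 2 * s + 1):
            ns = neighbors_at(
                index, panel, h, anchor_site, threshold, max_neighbors=max_neighbors, unit=unit
            )
            vals = [phased.hap_values[n.hap] for n in ns.neighbors if n.hap in measured_haps]
            if not vals:
                hap_vals = None
                break
            hap_vals.append(float(np.mean(vals)))
        if hap_vals is None:
            out[sid] = np.nan
            reasons[sid] = "no_measured_neighbor"
        else:
            out[sid] = hap_vals[0] + hap_vals[1]
    return pd.Series(out), reasons


def wes_wgs_consistency(
    dosage_wes: pd.DataFrame,
    dosage_wgs: pd.DataFrame,
    r_min: float = 0.3,
    min_shared: int = 50,
) -> pd.DataFrame:
    """Retain regions whose WES and WGS read-depth signals agree.

    A region passes iff the Pearson correlation of WES and WGS dosage over
    shared samples is at least ``r_min``; regions with fewer than
    ``min_shared`` shared samples are undetermined and not retained.
    """
    shared = dosage_wes.index.intersection(dosage_wgs.index)
    rows = []
    for region in dosage_wes.columns.intersection(dosage_wgs.columns):
        x = dosage_wes.loc[shared, region].to_numpy(dtype=float)
        y = dosage_wgs.loc[shared, region].to_numpy(dtype=float)
        ok = ~(np.isnan(x) | np.isnan(y))
        if ok.sum() < min_shared:
            rows.append({"region_id": region, "r": np.nan, "retained": False, "reason": "undetermined"})
            continue
        if np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
            rows.append({"region_id": region, "r": np.nan, "retained": False, "reason": "zero_variance"})
            continue
        r = float(pearsonr(x[ok], y[ok])[0])
        rows.append({"region_id": region, "r": r, "retained": bool(r >= r_min), "reason": ""})
    return pd.DataFrame(rows)
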