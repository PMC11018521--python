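"""Bin-level QC and read-depth normalization against matched reference panels.

Technical variation in exome capture (per-bin efficiency, reagent-lot batch
effects, per-sample coverage) is absorbed by normalizing each sample against a
reference panel of samples with the most similar exome-wide coverage profile,
rather than by explicit covariate modeling.  Negative-binomial overdispersion
is then estimated per sample by the method of moments on the normalized
residuals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simcohort import ReadCountMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "QCThresholds",
    "NormModel",
    "qc_bins",
    "select_reference_panel",
    "select_reference_panels",
    "estimate_expected_depth",
    "fit_dispersion",
    "normalize",
]

PHI_MIN, PHI_MAX = 1.0, 1e6


@dataclass
class QCThresholds:
    """Bin-retention thresholds.

    ``min_cov``: minimum mean count required in each lot.
    ``lot_tol``: maximum |log2 ratio| of lot mean coverages.
    ``mappability_min``: minimum fraction of reads with positive mapping
    quality ("most aligned reads" read literally as a majority).
    Calibration: a bin is calibratable if cross-sample normalized depth either
    has robust CV <= ``calib_cv_max`` (rare-CNV regime) or clusters within
    ``calib_halfint_tol`` of half-integer multiples of 0.5 for at least
    ``calib_halfint_frac`` of samples (discrete copy-number regime).  The CV
    ceiling must sit above the intrinsic NB sampling noise of a diploid bin
    (CV ~ sqrt(1/mu + 1/phi), ~0.37 at 30x depth with size 10), so that bins
    rarely touched by CNVs pass while common multiallelic CNV bins, whose
    copy-number variance adds to the sampling noise, fail.
    """

    min_cov: float = 5.0
    lot_tol: float = 0.2
    mappability_min: float = 0.5
    calib_cv_max: float = 0.5
    calib_halfint_tol: float = 0.12
    calib_halfint_frac: float = 0.90


@dataclass
class NormModel:
    mu: np.ndarray                       # (n_samples, n_bins) expected diploid count
    phi: np.ndarray                      # per-sample NB size
    reference_ids: list[np.ndarray]      # per-sample reference sample indices
    sample_scale: np.ndarray             # per-sample total-coverage factor
    retained: np.ndarray                 # boolean bin mask
    non_calibratable: np.ndarray | None = None  # (n_samples, n_bins) flags


def _fractional_coverage(counts: np.ndarray) -> np.ndarray:
    totals = counts.sum(axis=1, keepdims=True).astype(float)
    totals[totals == 0] = 1.0
    return counts / totals


def _normalized_depth(counts: np.ndarray) -> np.ndarray:
    """Cross-sample normalized depth with cohort diploid level at 1."""
    f = _fractional_coverage(counts)
    med = np.median(f, axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(med > 0, f / med, np.nan)
    return d


def qc_bins(
    matrix: ReadCountMatrix,
    bins: pd.DataFrame,
    thresholds: QCThresholds | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Retain bins with coverage in both lots, similar lot coverage, sufficient
    mappability and a calibratable normalized-depth distribution.

    ``bins`` must provide a ``mappable_fraction`` column aligned with the count
    matrix columns.  Returns the boolean retention mask and a per-bin report
    with semicolon-joined failure reasons.
    """
    thr = thresholds or QCThresholds()
    counts = matrix.counts
    lot1 = matrix.lots == "lot1"
    lot2 = ~lot1
    if lot1.sum() < 2 or lot2.sum() < 2:
        raise ValueError("need at least 2 samples per lot")
    mean1 = counts[lot1].mean(axis=0)
    mean2 = counts[lot2].mean(axis=0)

    reasons: list[list[str]] = [[] for _ in range(matrix.n_bins)]
    cov_ok = (mean1 > thr.min_cov) & (mean2 > thr.min_cov)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_ratio = np.log2(np.where(mean2 > 0, mean1 / np.where(mean2 > 0, mean2, 1.0), np.inf))
    ratio_ok = cov_ok & (np.abs(log_ratio) <= thr.lot_tol)
    mapp = bins["mappable_fraction"].to_numpy()
    mapp_ok = mapp >= thr.mappability_min

    d = _normalized_depth(counts)
    med = np.nanmedian(d, axis=0)
    mad = np.nanmedian(np.abs(d - med[None, :]), axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        robust_cv = np.where(med > 0, 1.4826 * mad / med, np.inf)
    halfint_dev = np.abs(d - 0.5 * np.round(d / 0.5))
    halfint_frac = np.nanmean(halfint_dev <= thr.calib_halfint_tol, axis=0)
    calib_ok = (robust_cv <= thr.calib_cv_max) | (halfint_frac >= thr.calib_halfint_frac)

    for b in range(matrix.n_bins):
        if not cov_ok[b]:
            reasons[b].append("lot coverage")
        elif not ratio_ok[b]:
            reasons[b].append("lot ratio")
        if not mapp_ok[b]:
            reasons[b].append("mappability")
        if not calib_ok[b]:
            reasons[b].append("calibration")
    retained = cov_ok & ratio_ok & mapp_ok & calib_ok
    if not retained.any():
        raise ValueError("all bins failed QC")
    report = pd.DataFrame(
        {
            "bin_id": matrix.bin_ids,
            "retained": retained,
            "reason": ["" if ok else ";".join(r) for ok, r in zip(retained, reasons)],
        }
    )
    return retained, report


def _profiles(counts: np.ndarray, retained: np.ndarray) -> np.ndarray:
    p = np.log1p(_fractional_coverage(counts)[:, retained])
    p = p - p.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(p, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return p / norms


def select_reference_panel(
    target: int,
    matrix: ReadCountMatrix,
    k: int,
    retained: np.ndarray,
) -> np.ndarray:
    """The ``k`` same-lot samples with exome-wide coverage profiles closest to
    the target (distance = 1 - Pearson r of log1p fractional coverage)."""
    same_lot = np.flatnonzero((matrix.lots == matrix.lots[target]))
    cands = same_lot[same_lot != target]
    if k >= len(cands) + 1:
        raise ValueError("k must be smaller than the number of same-lot samples")
    prof = _profiles(matrix.counts, retained)
    dist = 1.0 - prof[cands] @ prof[target]
    order = np.lexsort((cands, dist))
    return cands[order[:k]]


def select_reference_panels(
    matrix: ReadCountMatrix, k: int, retained: np.ndarray
) -> list[np.ndarray]:
    """Reference panels for every sample at once (shared profile matrix)."""
    prof = _profiles(matrix.counts, retained)
    refs: list[np.ndarray | None] = [None] * matrix.n_samples
    for lot in np.unique(matrix.lots):
        members = np.flatnonzero(matrix.lots == lot)
        if k >= len(members):
            raise ValueError("k must be smaller than the number of same-lot samples")
        corr = prof[members] @ prof[members].T
        dist = 1.0 - corr
        np.fill_diagonal(dist, np.inf)
        for row, s in enumerate(members):
            order = np.lexsort((members, dist[row]))
            refs[s] = members[order[:k]]
    return [r for r in refs]  # type: ignore[misc]


def estimate_expected_depth(
    target: int,
    reference_ids: np.ndarray,
    matrix: ReadCountMatrix,
    retained: np.ndarray,
    mu_min: float = 0.01,
) -> tuple[np.ndarray, float, np.ndarray]:
    """Expected diploid count per bin for one sample.

    The baseline is the median, over the reference panel, of coverage-scaled
    counts; the target's own total-coverage factor rescales it.  A final
    recalibration makes the expected counts sum to the observed total over
    retained bins, so normalized depth is calibrated to copy number 2 on
    average despite the skew of the NB median.  Returns (mu over all bins,
    sample_scale, non-calibratable flags).
    """
    if len(reference_ids) == 0:
        raise ValueError("reference panel is empty")
    counts = matrix.counts.astype(float)
    totals = counts[:, retained].sum(axis=1)
    panel_mean = totals[reference_ids].mean()
    if panel_mean <= 0:
        raise ValueError("reference panel has zero coverage")
    scale_refs = totals[reference_ids] / panel_mean
    scale_refs[scale_refs == 0] = 1.0
    scale_t = totals[target] / panel_mean
    base = np.median(counts[reference_ids] / scale_refs[:, None], axis=0)
    non_calib = base <= 0
    mu = scale_t * base
    denom = mu[retained].sum()
    if denom > 0:
        mu = mu * (totals[target] / denom)
    mu = np.maximum(mu, mu_min)
    return mu, float(scale_t), non_calib


def fit_dispersion(
    matrix: ReadCountMatrix,
    mu: np.ndarray,
    retained: np.ndarray,
    diploid_mask: np.ndarray | None = None,
    eps: float = 1e-9,
) -> np.ndarray:
    """Per-sample NB size by the method of moments on retained diploid bins.

    Var(n) = mu + mu^2/phi pooled over bins gives
    phi = mean(mu^2) / max(eps, Var_hat(n) - mean(mu)), clipped to
    [1, 1e6].  Overdispersion is only declared when the variance excess
    exceeds twice the standard error of the pooled variance estimate
    (~ sqrt(2/n_bins) * Var_hat); below that the data are consistent with
    Poisson noise and phi is pinned at the upper clip.
    """
    n_retained = int(np.sum(retained))
    if n_retained < 100:
        raise ValueError("need at least 100 retained bins to estimate dispersion")
    use = np.asarray(retained, dtype=bool)
    phi = np.empty(matrix.n_samples)
    n_clipped = 0
    for s in range(matrix.n_samples):
        mask = use if diploid_mask is None else use & diploid_mask[s]
        n = matrix.counts[s, mask].astype(float)
        m = mu[s, mask]
        var_hat = np.mean((n - m) ** 2)
        excess = var_hat - np.mean(m)
        min_excess = max(eps, 2.0 * np.sqrt(2.0 / n.size) * var_hat)
        if excess <= min_excess:
            phi[s] = PHI_MAX
            n_clipped += 1
            continue
        phi[s] = np.clip(np.mean(m**2) / excess, PHI_MIN, PHI_MAX)
    if n_clipped:
        logger.warning(
            "%d samples showed no overdispersion; dispersion clipped to the "
            "Poisson limit", n_clipped
        )
    return phi


def normalize(
    matrix: ReadCountMatrix,
    bins: pd.DataFrame,
    k: int = 20,
    thresholds: QCThresholds | None = None,
    mu_min: float = 0.01,
) -> NormModel:
    """QC bins, select reference panels, and fit mu and phi for every sample."""
    retained, _ = qc_bins(matrix, bins, thresholds)
    refs = select_reference_panels(matrix, k, retained)
    mu = np.empty_like(matrix.counts, dtype=float)
    scale = np.empty(matrix.n_samples)
    non_calib = np.zeros_like(matrix.counts, dtype=bool)
    for s in range(matrix.n_samples):
        mu[s], scale[s], non_calib[s] = estimate_expected_depth(
            s, refs[s], matrix, retained, mu_min=mu_min
        )
    phi = fit_dispersion(matrix, mu, retained)
    return NormModel(
        mu=mu,
        phi=phi,
        reference_ids=refs,
        sample_scale=scale,
        retained=retained,
        non_calibratable=non_calib,
    )
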