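"""Haplotype-informed rare CNV calling.

Per 100-bp bin, a negative-binomial Bayes factor compares the likelihood of a
sample's read count under a deletion (copy number 1) or duplication (copy
number 3) against the diploid expectation.  Evidence is pooled across the
target individual and up to ten haplotype neighbors (individuals sharing a
long IBD tract spanning the bin) by multiplying Bayes factors, then a 3-state
hidden Markov model segments the pooled track into calls.  The analysis runs
at several IBD length thresholds, trading sensitivity to recent versus older
mutations, and the per-threshold call sets are compiled into one.

An exhaustive path-enumeration reference for the HMM posteriors and Viterbi
path is provided for validation on short tracks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import nbinom

__all__ = [
    "HMMConfig",
    "BayesFactorTrack",
    "CNVCall",
    "emission_bf",
    "emission_logbf_track",
    "combined_bf",
    "hmm_segment",
    "enumerate_posteriors",
    "call_cnvs",
    "compile_thresholds",
    "filter_calls",
    "annotate_plof",
]

DEL, DIP, DUP = 0, 1, 2
STATE_NAMES = ("DEL", "DIP", "DUP")
LN10 = np.log(10.0)


@dataclass
class HMMConfig:
    """Transition/calling parameters for the 3-state copy-number HMM.

    ``tau_enter`` is the per-bin prior probability of entering a CNV state and
    ``expected_len_bins`` the mean CNV length in bins (exit probability is its
    reciprocal); both were tuned on simulation, not taken from data.
    ``ibd_thresholds`` (cM, descending) are the IBD sharing thresholds at
    which the analysis is repeated.
    """

    tau_enter: float = 1e-4
    expected_len_bins: float = 10.0
    call_posterior_min: float = 0.9
    ibd_thresholds: tuple[float, ...] = (10.0, 4.0, 2.0, 1.0)
    score_min: float = 2.0
    per_sample_cap: int = 300
    mu_floor_frac: float = 0.05

    def validate(self) -> None:
        if not (0.0 < self.tau_enter < 0.5):
            raise ValueError("tau_enter must lie in (0, 0.5)")
        if self.expected_len_bins < 1:
            raise ValueError("expected_len_bins must be >= 1")
        if list(self.ibd_thresholds) != sorted(self.ibd_thresholds, reverse=True):
            raise ValueError("ibd_thresholds must be sorted descending")

    def transition_matrix(self) -> np.ndarray:
        tau, ex = self.tau_enter, 1.0 / self.expected_len_bins
        return np.array(
            [
                [1.0 - ex, ex, 0.0],
                [tau, 1.0 - 2.0 * tau, tau],
                [0.0, ex, 1.0 - ex],
            ]
        )

    def start_probs(self) -> np.ndarray:
        # stationary distribution: flow balance (1-2x) tau = x / expected_len
        tau, ex = self.tau_enter, 1.0 / self.expected_len_bins
        x = tau / (ex + 2.0 * tau)
        return np.array([x, 1.0 - 2.0 * x, x])


@dataclass
class BayesFactorTrack:
    """Per-bin log Bayes factors (natural log) versus the diploid state."""

    sample: str
    log_bf_del: np.ndarray
    log_bf_dup: np.ndarray
    combined: bool = False
    n_neighbors_used: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not (np.all(np.isfinite(self.log_bf_del)) and np.all(np.isfinite(self.log_bf_dup))):
            raise ValueError("Bayes factors must be positive and finite")

    @property
    def n_bins(self) -> int:
        return len(self.log_bf_del)


@dataclass
class CNVCall:
    sample: str
    chrom: str
    start: int                     # bp, 0-based half-open, bin-aligned
    end: int
    type: str                      # "DEL" or "DUP"
    score: float                   # summed per-bin log10 combined BF
    ibd_threshold: float | None
    n_bins: int
    thresholds: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("call interval must be non-empty")
        if self.type not in ("DEL", "DUP"):
            raise ValueError("type must be DEL or DUP")
        if not self.thresholds and self.ibd_threshold is not None:
            self.thresholds = [self.ibd_threshold]

    @property
    def length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# emission Bayes factors
# ---------------------------------------------------------------------------

def _nb_logpmf(count, mean, phi):
    mean = np.asarray(mean, dtype=float)
    return nbinom.logpmf(count, phi, phi / (phi + mean))


def emission_bf(
    count: float,
    mu: float,
    phi: float,
    state: str,
    copy: int | None = None,
    mu_floor_frac: float = 0.05,
) -> float:
    """Bayes factor for one bin: NB likelihood of ``count`` under ``state``
    relative to the diploid likelihood.

    DEL evaluates copy number 1 and DUP copy number 3 by default; ``copy``
    overrides the altered copy number, with the mean floored at
    ``mu_floor_frac * mu`` so a homozygous deletion (copy 0) keeps a proper
    likelihood.  BF(DIP) is identically 1.
    """
    if not (np.isfinite(count) and np.isfinite(mu) and np.isfinite(phi)):
        raise ValueError("non-finite input to emission_bf")
    if mu <= 0 or phi <= 0 or count < 0:
        raise ValueError("require mu > 0, phi > 0, count >= 0")
    if state == "DIP":
        return 1.0
    if state == "DEL":
        c = 1 if copy is None else copy
    elif state == "DUP":
        c = 3 if copy is None else copy
    else:
        raise ValueError(f"unknown state {state!r}")
    alt_mean = max(mu * c / 2.0, mu_floor_frac * mu)
    return float(np.exp(_nb_logpmf(count, alt_mean, phi) - _nb_logpmf(count, mu, phi)))


def emission_logbf_track(
    counts: np.ndarray, mu: np.ndarray, phi: float, sample: str = ""
) -> BayesFactorTrack:
    """Vectorised per-bin log Bayes factors for one sample."""
    counts = np.asarray(counts)
    mu = np.asarray(mu, dtype=float)
    if np.any(mu <= 0) or phi <= 0:
        raise ValueError("require mu > 0 and phi > 0")
    base = _nb_logpmf(counts, mu, phi)
    log_del = _nb_logpmf(counts, mu / 2.0, phi) - base
    log_dup = _nb_logpmf(counts, 1.5 * mu, phi) - base
    return BayesFactorTrack(sample=sample, log_bf_del=log_del, log_bf_dup=log_dup)


def combined_bf(
    target_track: BayesFactorTrack,
    neighbor_tracks: list[tuple[BayesFactorTrack, np.ndarray]],
) -> BayesFactorTrack:
    """Multiply Bayes factors across the target and its haplotype neighbors.

    Each neighbor contributes only over the bins inside its matching IBD
    tract (its boolean mask); outside the tract its BF is treated as 1.
    """
    n = target_track.n_bins
    log_del = target_track.log_bf_del.copy()
    log_dup = target_track.log_bf_dup.copy()
    used = np.zeros(n, dtype=np.int64)
    for track, mask in neighbor_tracks:
        if track.n_bins != n or len(mask) != n:
            raise ValueError("neighbor track not aligned to target bins")
        m = np.asarray(mask, dtype=bool)
        log_del[m] += track.log_bf_del[m]
        log_dup[m] += track.log_bf_dup[m]
        used[m] += 1
    return BayesFactorTrack(
        sample=target_track.sample,
        log_bf_del=log_del,
        log_bf_dup=log_dup,
        combined=True,
        n_neighbors_used=used,
    )


# ---------------------------------------------------------------------------
# HMM segmentation
# ---------------------------------------------------------------------------

def _emission_log_odds(track: BayesFactorTrack) -> np.ndarray:
    em = np.stack([track.log_bf_del, np.zeros(track.n_bins), track.log_bf_dup], axis=1)
    if np.any(np.isnan(em)):
        raise ValueError("NaN in Bayes factor track")
    return em


def hmm_segment(
    track: BayesFactorTrack, cfg: HMMConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Forward-backward posteriors and Viterbi path for one track.

    Emission odds are the diploid-normalized Bayes factors (DIP emission = 1),
    equivalent to full likelihoods up to a per-bin constant that cancels in
    both the posteriors and the Viterbi arg-max.  All recursions run in log
    space.
    """
    cfg.validate()
    em = _emission_log_odds(track)
    with np.errstate(divide="ignore"):
        log_t = np.log(cfg.transition_matrix())
    log_start = np.log(cfg.start_probs())
    n = track.n_bins

    fwd = np.empty((n, 3))
    fwd[0] = log_start + em[0]
    for i in range(1, n):
        fwd[i] = em[i] + logsumexp(fwd[i - 1][:, None] + log_t, axis=0)
    bwd = np.empty((n, 3))
    bwd[-1] = 0.0
    for i in range(n - 2, -1, -1):
        bwd[i] = logsumexp(log_t + (em[i + 1] + bwd[i + 1])[None, :], axis=1)
    log_post = fwd + bwd
    log_post -= logsumexp(log_post, axis=1, keepdims=True)
    post = np.exp(log_post)

    vit = np.empty((n, 3))
    back = np.zeros((n, 3), dtype=np.int8)
    vit[0] = log_start + em[0]
    for i in range(1, n):
        cand = vit[i - 1][:, None] + log_t
        back[i] = np.argmax(cand, axis=0)
        vit[i] = em[i] + np.max(cand, axis=0)
    path = np.empty(n, dtype=np.int8)
    path[-1] = int(np.argmax(vit[-1]))
    for i in range(n - 2, -1, -1):
        path[i] = back[i + 1][path[i + 1]]
    return post, path


def enumerate_posteriors(
    track: BayesFactorTrack, cfg: HMMConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Exhaustive 3^L reference for posteriors and the Viterbi path (L <= ~12)."""
    cfg.validate()
    em = _emission_log_odds(track)
    with np.errstate(divide="ignore"):
        log_t = np.log(cfg.transition_matrix())
    log_start = np.log(cfg.start_probs())
    n = track.n_bins
    states = np.indices((3,) * n).reshape(n, -1).T      # (3^n, n)
    logw = log_start[states[:, 0]] + em[np.arange(n)[None, :], states].sum(axis=1)
    if n > 1:
        logw = logw + log_t[states[:, :-1], states[:, 1:]].sum(axis=1)
    post = np.empty((n, 3))
    for i in range(n):
        for s in range(3):
            sel = states[:, i] == s
            post[i, s] = logsumexp(logw[sel]) if sel.any() else -np.inf
    post = np.exp(post - logsumexp(logw))
    path = states[int(np.argmax(logw))].astype(np.int8)
    return post, path


# ---------------------------------------------------------------------------
# call emission, compilation, filtering
# ---------------------------------------------------------------------------

def call_cnvs(
    track: BayesFactorTrack,
    posteriors: np.ndarray,
    path: np.ndarray,
    cfg: HMMConfig,
    bins: pd.DataFrame,
    ibd_threshold: float | None = None,
) -> list[CNVCall]:
    """Maximal Viterbi CNV runs with sufficient mean posterior become calls.

    ``bins`` provides chrom/start/end per bin (0-based half-open).  The call
    score is the summed per-bin log10 combined Bayes factor of the called
    state over the run; non-positive-score runs are discarded.
    """
    calls: list[CNVCall] = []
    n = len(path)
    i = 0
    starts = bins["start"].to_numpy()
    ends = bins["end"].to_numpy()
    chroms = bins["chrom"].to_numpy()
    while i < n:
        s = path[i]
        if s == DIP:
            i += 1
            continue
        j = i
        while j < n and path[j] == s:
            j += 1
        mean_post = posteriors[i:j, s].mean()
        log_bf = track.log_bf_del if s == DEL else track.log_bf_dup
        score = float(log_bf[i:j].sum() / LN10)
        if mean_post >= cfg.call_posterior_min and score > 0:
            calls.append(
                CNVCall(
                    sample=track.sample,
                    chrom=str(chroms[i]),
                    start=int(starts[i]),
                    end=int(ends[j - 1]),
                    type=STATE_NAMES[s],
                    score=score,
                    ibd_threshold=ibd_threshold,
                    n_bins=j - i,
                )
            )
        i = j
    return calls


def _reciprocal_overlap(a: CNVCall, b: CNVCall) -> float:
    ov = min(a.end, b.end) - max(a.start, b.start)
    if ov <= 0:
        return 0.0
    return min(ov / a.length, ov / b.length)


def compile_thresholds(calls_by_threshold: dict[float, list[CNVCall]]) -> list[CNVCall]:
    """Merge per-threshold call sets into one compiled set.

    Calls from the same sample with the same type and reciprocal overlap
    >= 0.5 are merged into the union interval with the max score, recording
    every contributing threshold.  Thresholds are processed in descending
    order for determinism; a final sweep unions any residual same-type
    overlaps and resolves cross-type overlaps in favor of the higher score,
    so compiled intervals are non-overlapping per sample.
    """
    merged: list[CNVCall] = []
    for thr in sorted(calls_by_threshold, reverse=True):
        for call in calls_by_threshold[thr]:
            hit = None
            for m in merged:
                if (
                    m.sample == call.sample
                    and m.chrom == call.chrom
                    and m.type == call.type
                    and _reciprocal_overlap(m, call) >= 0.5
                ):
                    hit = m
                    break
            if hit is None:
                merged.append(
                    CNVCall(
                        sample=call.sample,
                        chrom=call.chrom,
                        start=call.start,
                        end=call.end,
                        type=call.type,
                        score=call.score,
                        ibd_threshold=None,
                        n_bins=call.n_bins,
                        thresholds=[thr],
                    )
                )
            else:
                new_start = min(hit.start, call.start)
                new_end = max(hit.end, call.end)
                bin_bp = max(hit.length // max(hit.n_bins, 1), 1)
                hit.start, hit.end = new_start, new_end
                hit.n_bins = max(hit.n_bins, call.n_bins, round((new_end - new_start) / bin_bp))
                hit.score = max(hit.score, call.score)
                if thr not in hit.thresholds:
                    hit.thresholds.append(thr)
    return _resolve_overlaps(merged)


def _resolve_overlaps(calls: list[CNVCall]) -> list[CNVCall]:
    out: list[CNVCall] = []
    by_key: dict[tuple[str, str], list[CNVCall]] = {}
    for c in calls:
        by_key.setdefault((c.sample, c.chrom), []).append(c)
    for group in by_key.values():
        group.sort(key=lambda c: (c.start, c.end))
        kept: list[CNVCall] = []
        for c in group:
            if kept and c.start < kept[-1].end:
                prev = kept[-1]
                if prev.type == c.type:
                    prev.end = max(prev.end, c.end)
                    prev.score = max(prev.score, c.score)
                    prev.thresholds = sorted(set(prev.thresholds) | set(c.thresholds), reverse=True)
                elif c.score > prev.score:
                    kept[-1] = c
                continue
            kept.append(c)
        out.extend(kept)
    out.sort(key=lambda c: (c.sample, c.chrom, c.start))
    return out


def filter_calls(
    calls: list[CNVCall],
    per_sample_cap: int = 300,
    masks: list[tuple[str, int, int]] | None = None,
    score_min: float = 2.0,
) -> tuple[list[CNVCall], list[str], dict[str, int]]:
    """Remove hyper-called samples, masked regions and low-score calls.

    Samples with more than ``per_sample_cap`` calls are removed entirely.
    Returns (kept calls, excluded samples, per-reason removal counts).
    """
    counts: dict[str, int] = {}
    for c in calls:
        counts[c.sample] = counts.get(c.sample, 0) + 1
    excluded = sorted(s for s, n in counts.items() if n > per_sample_cap)
    excluded_set = set(excluded)
    reasons = {"sample_cap": 0, "mask": 0, "low_score": 0}
    kept: list[CNVCall] = []
    for c in calls:
        if c.sample in excluded_set:
            reasons["sample_cap"] += 1
            continue
        if masks and any(
            c.chrom == chrom and c.start < end and start < c.end for chrom, start, end in masks
        ):
            reasons["mask"] += 1
            continue
        if c.score < score_min:
            reasons["low_score"] += 1
            continue
        kept.append(c)
    return kept, excluded, reasons


# ---------------------------------------------------------------------------
# pLOF annotation
# ---------------------------------------------------------------------------

def annotate_plof(
    calls: list[CNVCall],
    genes: pd.DataFrame,
    exons: pd.DataFrame,
) -> pd.DataFrame:
    """Classify calls by predicted effect on coding sequence.

    ``genes``: columns gene, chrom, start, end (gene body, 0-based half-open).
    ``exons``: columns gene, start, end (coding exon intervals).

    A deletion overlapping any coding base is ``pLOF_del``.  A duplication
    with both endpoints strictly inside one gene body that overlaps coding
    sequence is ``internal_dup_pLOF`` (presumed tandem, reading-frame
    disrupting); a duplication containing an entire gene is
    ``whole_gene_dup``.  Calls touching no gene body are ``intergenic``.
    """
    for df, cols in ((genes, ("gene", "chrom", "start", "end")), (exons, ("gene", "start", "end"))):
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise ValueError(f"malformed gene model: missing columns {missing}")
    if (genes["end"] <= genes["start"]).any() or (exons["end"] <= exons["start"]).any():
        raise ValueError("malformed gene model: empty intervals")

    rows = []
    for c in calls:
        g = genes[(genes["chrom"] == c.chrom) & (genes["start"] < c.end) & (c.start < genes["end"])]
        hit_genes = list(g["gene"])
        ex = exons[exons["gene"].isin(hit_genes)]
        ex_hit = ex[(ex["start"] < c.end) & (c.start < ex["end"])]
        n_exons = len(ex_hit)
        coding = n_exons > 0
        if not hit_genes:
            cls = "intergenic"
        elif c.type == "DEL":
            cls = "pLOF_del" if coding else "other"
        else:
            whole = g[(g["start"] >= c.start) & (g["end"] <= c.end)]
            inside = g[(g["start"] < c.start) & (c.end < g["end"])]
            if len(whole):
                cls = "whole_gene_dup"
            elif len(inside) and coding:
                cls = "internal_dup_pLOF"
            else:
                cls = "other"
        rows.append(
            {
                "sample": c.sample,
                "chrom": c.chrom,
                "start": c.start,
                "end": c.end,
                "type": c.type,
                "classification": cls,
                "genes": ",".join(hit_genes),
                "n_exons": n_exons,
            }
        )
    return pd.DataFrame(rows)
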