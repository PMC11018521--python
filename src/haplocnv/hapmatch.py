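"""Positional Burrows-Wheeler transform (PBWT) haplotype matching.

At every site the PBWT keeps haplotypes sorted by reversed prefix together
with divergence values, so the set of haplotypes sharing a long tract with a
target around an anchor site can be recovered in time linear in the panel
size.  Matches are maximal set-theoretic allele matches (no error model); the
match length, in sites or in cM via the panel's genetic map, acts as a proxy
for the age of the shared ancestor: longer IBD implies a more recent common
ancestor.

A quadratic brute-force matcher is included as an independent reference
implementation used for validation.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass

import numpy as np

from .simcohort import HaplotypePanel

__all__ = [
    "PBWTIndex",
    "Neighbor",
    "NeighborSet",
    "build_pbwt",
    "neighbors_at",
    "match_interval_brute_force",
    "neighbors_brute_force",
]


@dataclass
class PBWTIndex:
    """Prefix orderings and divergence arrays for every site.

    ``orderings[k]`` sorts haplotypes by reversed prefix over sites ``[0, k)``;
    ``divergence[k][i]`` is the start of the match between ``orderings[k][i]``
    and ``orderings[k][i-1]`` (the two match over sites ``[divergence, k)``).
    ``ranks[k]`` is the inverse permutation of ``orderings[k]``.
    """

    orderings: np.ndarray   # (n_sites + 1, H) int32
    divergence: np.ndarray  # (n_sites + 1, H) int32
    ranks: np.ndarray       # (n_sites + 1, H) int32

    @property
    def n_sites(self) -> int:
        return self.orderings.shape[0] - 1

    @property
    def n_haplotypes(self) -> int:
        return self.orderings.shape[1]

    def dump(self, path: str) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def restore(path: str) -> "PBWTIndex":
        with open(path, "rb") as fh:
            obj = pickle.load(fh)
        if not isinstance(obj, PBWTIndex):
            raise ValueError("not a PBWT index file")
        return obj


@dataclass(frozen=True)
class Neighbor:
    hap: int
    start: int            # match interval [start, end) in sites
    end: int
    length_sites: int
    length_cm: float


@dataclass
class NeighborSet:
    target_hap: int
    anchor_site: int
    threshold: float
    unit: str
    neighbors: list[Neighbor]

    def hap_ids(self) -> list[int]:
        return [n.hap for n in self.neighbors]


def _segment_max(d: np.ndarray, pos: np.ndarray, sentinel: int) -> np.ndarray:
    """Divergence update for one allele class (vectorised Durbin update).

    For the ``j``-th class member at old-ordering position ``pos[j]``, the new
    divergence is the max of ``d`` over positions ``(pos[j-1], pos[j]]``; the
    first member gets the sentinel (no predecessor in its class matches
    through the current site).
    """
    if pos.size == 0:
        return np.empty(0, dtype=d.dtype)
    starts = np.empty(pos.size, dtype=np.intp)
    starts[0] = 0
    starts[1:] = pos[:-1] + 1
    out = np.maximum.reduceat(d[: pos[-1] + 1], starts)
    out[0] = sentinel
    return out


def build_pbwt(panel: HaplotypePanel) -> PBWTIndex:
    """Build the PBWT index in O(haplotypes x sites) time."""
    alleles = panel.alleles
    if alleles.size == 0:
        raise ValueError("empty panel")
    if not np.all((alleles == 0) | (alleles == 1)):
        raise ValueError("non-binary allele in panel")
    n_hap, n_sites = alleles.shape
    orderings = np.empty((n_sites + 1, n_hap), dtype=np.int32)
    divergence = np.empty((n_sites + 1, n_hap), dtype=np.int32)
    ranks = np.empty((n_sites + 1, n_hap), dtype=np.int32)

    a = np.arange(n_hap, dtype=np.int32)
    d = np.zeros(n_hap, dtype=np.int32)
    orderings[0], divergence[0] = a, d
    ranks[0, a] = np.arange(n_hap, dtype=np.int32)
    for k in range(n_sites):
        al = alleles[a, k]
        idx0 = np.flatnonzero(al == 0)
        idx1 = np.flatnonzero(al == 1)
        a = np.concatenate([a[idx0], a[idx1]])
        d = np.concatenate(
            [_segment_max(d, idx0, k + 1), _segment_max(d, idx1, k + 1)]
        ).astype(np.int32)
        orderings[k + 1], divergence[k + 1] = a, d
        ranks[k + 1, a] = np.arange(n_hap, dtype=np.int32)
    return PBWTIndex(orderings=orderings, divergence=divergence, ranks=ranks)


def _forward_extension(alleles: np.ndarray, target: int, cands: np.ndarray, site: int) -> np.ndarray:
    """Number of matching sites strictly after ``site`` for each candidate."""
    n_sites = alleles.shape[1]
    if site + 1 >= n_sites:
        return np.zeros(cands.size, dtype=np.int64)
    diff = alleles[cands, site + 1:] != alleles[target, site + 1:]
    first = np.argmax(diff, axis=1)
    full = ~diff.any(axis=1)
    return np.where(full, n_sites - site - 1, first)


def _match_length(panel: HaplotypePanel, start: np.ndarray, end: np.ndarray, unit: str) -> np.ndarray:
    if unit == "sites":
        return (end - start).astype(float)
    if unit == "cm":
        return panel.site_cm[np.maximum(end - 1, start)] - panel.site_cm[start]
    raise ValueError("unit must be 'sites' or 'cm'")


def neighbors_at(
    index: PBWTIndex,
    panel: HaplotypePanel,
    target_hap: int,
    site: int,
    threshold: float,
    max_neighbors: int = 10,
    unit: str = "cm",
) -> NeighborSet:
    """Up to ``max_neighbors`` haplotypes whose match with the target spans ``site``.

    The search scans outward from the target's position in the prefix ordering
    at the anchor site: running maxima of the divergence array give every
    candidate's backward match start in one linear pass, and forward
    extensions are computed directly on the allele matrix.  Candidates are
    ranked by decreasing match length (in the threshold unit), ties broken by
    haplotype id; both haplotypes of the target's own sample are excluded.
    """
    if not (0 <= site < index.n_sites):
        raise ValueError("anchor site out of range")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    a = index.orderings[site + 1]
    d = index.divergence[site + 1]
    pos = int(index.ranks[site + 1, target_hap])
    n_hap = index.n_haplotypes

    # backward match starts via running maxima of divergence away from target
    starts = np.empty(n_hap, dtype=np.int64)
    starts[pos] = site + 1  # self; excluded below
    if pos > 0:
        up = np.maximum.accumulate(d[1: pos + 1][::-1])
        starts[pos - 1:: -1][: pos] = up
    if pos + 1 < n_hap:
        starts[pos + 1:] = np.maximum.accumulate(d[pos + 1:])

    cand_mask = starts <= site            # matches the target at the anchor site
    cand_mask[pos] = False
    own = panel.sample_of(target_hap)
    cand_mask[index.ranks[site + 1, 2 * own]] = False
    cand_mask[index.ranks[site + 1, 2 * own + 1]] = False
    cand_pos = np.flatnonzero(cand_mask)
    if cand_pos.size == 0:
        return NeighborSet(target_hap, site, threshold, unit, [])

    cand_haps = a[cand_pos].astype(np.int64)
    cand_start = starts[cand_pos]
    fwd = _forward_extension(panel.alleles, target_hap, cand_haps, site)
    cand_end = site + 1 + fwd
    lengths = _match_length(panel, cand_start, cand_end, unit)

    keep = lengths >= threshold
    cand_haps, cand_start, cand_end, lengths = (
        cand_haps[keep], cand_start[keep], cand_end[keep], lengths[keep]
    )
    order = np.lexsort((cand_haps, -lengths))[:max_neighbors]
    neighbors = [
        Neighbor(
            hap=int(cand_haps[i]),
            start=int(cand_start[i]),
            end=int(cand_end[i]),
            length_sites=int(cand_end[i] - cand_start[i]),
            length_cm=float(
                panel.site_cm[max(cand_end[i] - 1, cand_start[i])] - panel.site_cm[cand_start[i]]
            ),
        )
        for i in order
    ]
    return NeighborSet(target_hap, site, threshold, unit, neighbors)


# ---------------------------------------------------------------------------
# brute-force reference (independent of the PBWT code path)
# ---------------------------------------------------------------------------

def match_interval_brute_force(
    alleles: np.ndarray, hap_a: int, hap_b: int, site: int
) -> tuple[int, int]:
    """Maximal allele-match interval [start, end) containing ``site``; empty if mismatched."""
    if alleles[hap_a, site] != alleles[hap_b, site]:
        return site, site
    eq = alleles[hap_a] == alleles[hap_b]
    start = site
    while start > 0 and eq[start - 1]:
        start -= 1
    end = site + 1
    while end < alleles.shape[1] and eq[end]:
        end += 1
    return start, end


def neighbors_brute_force(
    panel: HaplotypePanel,
    target_hap: int,
    site: int,
    threshold: float,
    max_neighbors: int = 10,
    unit: str = "cm",
) -> NeighborSet:
    """Quadratic reference neighbor search scanning every other haplotype."""
    own = panel.sample_of(target_hap)
    rows = []
    for h in range(panel.n_haplotypes):
        if h // 2 == own:
            continue
        s, e = match_interval_brute_force(panel.alleles, target_hap, h, site)
        if e <= s:
            continue
        length = float(e - s) if unit == "sites" else float(
            panel.site_cm[max(e - 1, s)] - panel.site_cm[s]
        )
        if length >= threshold:
            rows.append((h, s, e, length))
    rows.sort(key=lambda r: (-r[3], r[0]))
    neighbors = [
        Neighbor(
            hap=h,
            start=s,
            end=e,
            length_sites=e - s,
            length_cm=float(panel.site_cm[max(e - 1, s)] - panel.site_cm[s]),
        )
        for h, s, e, _ in rows[:max_neighbors]
    ]
    return NeighborSet(target_hap, site, threshold, unit, neighbors)
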