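"""Recombination-hotspot break points and per-triad fragment plans.

A *boundary* ``b`` on a chromosome with ``n`` markers is an integer in
``1..n-1`` separating marker ``b-1`` from marker ``b`` (markers 0-based,
fragments half-open).  A hotspot interval nominates the boundary whose
inter-marker bp gap contains its midpoint; a fragment plan draws ``k``
boundaries uniformly without replacement from the candidates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io_plink import MarkerMap

__all__ = [
    "HotspotTrack",
    "FragmentPlan",
    "hotspots_to_boundaries",
    "uniform_track",
    "draw_fragment_plan",
    "resolve_k",
]

logger = logging.getLogger(__name__)


@dataclass
class HotspotTrack:
    """Candidate break-point boundaries per chromosome (sorted, deduplicated)."""

    boundaries: dict[str, np.ndarray]
    n_markers: dict[str, int]

    def __post_init__(self) -> None:
        for chrom, b in self.boundaries.items():
            b = np.unique(np.asarray(b, dtype=np.int64))
            n = self.n_markers[chrom]
            if b.size and (b[0] < 1 or b[-1] > n - 1):
                raise ValueError(f"chromosome {chrom}: boundaries must lie in 1..{n - 1}")
            self.boundaries[chrom] = b


@dataclass
class FragmentPlan:
    """Chosen boundaries per chromosome; implied half-open fragments cover
    ``0..n_chr`` disjointly and in order."""

    chosen: dict[str, np.ndarray]
    n_markers: dict[str, int]

    def fragments(self, chrom: str) -> list[tuple[int, int]]:
        edges = np.concatenate([[0], self.chosen[chrom], [self.n_markers[chrom]]])
        return [(int(a), int(b)) for a, b in zip(edges[:-1], edges[1:])]


def uniform_track(marker_map: MarkerMap) -> HotspotTrack:
    """Fallback track with every inter-marker boundary as a candidate."""
    slices = marker_map.chrom_slices()
    return HotspotTrack(
        boundaries={c: np.arange(1, sl.stop - sl.start) for c, sl in slices.items()},
        n_markers={c: sl.stop - sl.start for c, sl in slices.items()},
    )


def hotspots_to_boundaries(track_bed, marker_map: MarkerMap) -> HotspotTrack:
    """Map a BED-like hotspot table (chrom, start, end; 0-based half-open)
    to candidate boundaries.

    A hotspot contributes boundary ``b`` when its midpoint lies strictly
    between ``bp_pos[b-1]`` and ``bp_pos[b]``; hotspots outside the marker
    span or hitting no gap are discarded, duplicates collapse.
    """
    if isinstance(track_bed, (str, Path)):
        bed = pd.read_csv(
            track_bed, sep=r"\s+", header=None, comment="#",
            names=["chrom", "start", "end"], dtype={"chrom": str},
        )
    else:
        bed = pd.DataFrame(track_bed, columns=["chrom", "start", "end"])
        bed["chrom"] = bed["chrom"].astype(str)
    slices = marker_map.chrom_slices()
    boundaries: dict[str, np.ndarray] = {c: np.empty(0, dtype=np.int64) for c in slices}
    for chrom, grp in bed.groupby("chrom", sort=False):
        if chrom not in slices:
            logger.warning("hotspot chromosome %s absent from the marker map; skipped", chrom)
            continue
        sl = slices[chrom]
        bp = marker_map.bp_pos[sl]
        mid = (grp["start"].to_numpy(np.float64) + grp["end"].to_numpy(np.float64)) / 2.0
        # boundary b iff bp[b-1] < mid < bp[b]
        b = np.searchsorted(bp, mid, side="left")
        strict = (b >= 1) & (b <= len(bp) - 1)
        strict &= np.where(strict, mid != bp[np.clip(b - 1, 0, None)], False)
        # searchsorted(left) already guarantees mid <= bp[b]; exclude equality
        strict &= np.where(strict, mid != bp[np.clip(b, 0, len(bp) - 1)], False)
        boundaries[chrom] = np.unique(b[strict].astype(np.int64))
    return HotspotTrack(
        boundaries=boundaries,
        n_markers={c: sl.stop - sl.start for c, sl in slices.items()},
    )


def resolve_k(track: HotspotTrack, k_per_chromosome) -> dict[str, int]:
    """Normalize an ``int`` or ``{chrom: int}`` break-point request."""
    if isinstance(k_per_chromosome, int):
        k = {c: k_per_chromosome for c in track.boundaries}
    else:
        k = {c: int(k_per_chromosome.get(c, 0)) for c in track.boundaries}
    for c, v in k.items():
        if v < 0:
            raise ValueError(f"negative break-point count for chromosome {c}")
    return k


def draw_fragment_plan(
    track: HotspotTrack, k_per_chromosome, rng: np.random.Generator
) -> FragmentPlan:
    """Draw ``k`` boundaries per chromosome uniformly without replacement.

    When a chromosome has fewer than ``k`` candidates all of them are used
    (with a warning).  The same plan is applied jointly to the mother,
    father, and child of every pool member for one simulated triad.
    """
    k = resolve_k(track, k_per_chromosome)
    chosen: dict[str, np.ndarray] = {}
    for chrom in track.boundaries:
        cand = track.boundaries[chrom]
        kk = k[chrom]
        if kk > cand.size:
            logger.warning(
                "chromosome %s: %d break points requested but only %d candidates",
                chrom, kk, cand.size,
            )
            kk = cand.size
        if kk == 0:
            chosen[chrom] = np.empty(0, dtype=np.int64)
        else:
            chosen[chrom] = np.sort(rng.choice(cand, size=kk, replace=False))
    return FragmentPlan(chosen=chosen, n_markers=dict(track.n_markers))


def draw_boundary_matrix(
    cand: np.ndarray, k: int, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized plan drawing for one chromosome: (n, k) sorted boundary
    indices, each row a without-replacement uniform draw from ``cand``."""
    k = min(k, cand.size)
    if k == 0:
        return np.empty((n, 0), dtype=np.int64)
    u = rng.random((n, cand.size))
    pick = np.argpartition(u, k - 1, axis=1)[:, :k]
    return np.sort(cand[pick], axis=1)
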