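"""Null-genotype generation by triplicate-fragment resampling.

Each simulated triad draws a fresh fragment plan, samples one pool triad
(uniformly, with replacement) per fragment, splices the mother/father/child
slices jointly, and finally exchanges the mother and father labels with
probability 1/2 (removing any parental asymmetry in the source).  Because
the mother-father-child triple is the resampling unit, LD and transmission
patterns inside each fragment are carried over verbatim and no random-mating
assumption is imposed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .complementer import ComplementedPool
from .fragmenter import FragmentPlan, HotspotTrack, draw_boundary_matrix, resolve_k
from .io_plink import MarkerMap, SampleTable

__all__ = ["SimulatedTriad", "NullStudy", "simulate_triad", "simulate_null_study"]


@dataclass
class SimulatedTriad:
    mother: np.ndarray
    father: np.ndarray
    child: np.ndarray
    plan: FragmentPlan
    provenance: dict[str, np.ndarray]  # chromosome -> pool row per fragment
    parent_swap: bool


@dataclass
class NullStudy:
    """A set of simulated triads with no phenotype attached."""

    marker_map: MarkerMap
    mothers: np.ndarray
    fathers: np.ndarray
    children: np.ndarray

    @property
    def n_triads(self) -> int:
        return self.mothers.shape[0]

    def founder_allele_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """Allele1 copies and called-allele totals over the simulated parents."""
        from .io_plink import MISSING

        m, f = self.mothers, self.fathers
        called = ((m != MISSING).sum(0) + (f != MISSING).sum(0)) * 2
        copies = np.where(m != MISSING, m, 0).sum(0) + np.where(f != MISSING, f, 0).sum(0)
        return copies.astype(np.int64), called.astype(np.int64)

    def all_genotypes(self) -> np.ndarray:
        """(3n, markers) matrix ordered mother, father, child per triad."""
        n, p = self.mothers.shape
        out = np.empty((3 * n, p), dtype=self.mothers.dtype)
        out[0::3] = self.mothers
        out[1::3] = self.fathers
        out[2::3] = self.children
        return out

    def sample_table(self, phenotype: np.ndarray | None = None) -> SampleTable:
        return _triad_sample_table(self.n_triads, phenotype)


def _triad_sample_table(n: int, phenotype: np.ndarray | None = None) -> SampleTable:
    """Synthetic family ids/pedigree rows for n triads (mother, father, child)."""
    recs = []
    for i in range(n):
        fam = f"sim{i + 1:06d}"
        pheno = -9.0 if phenotype is None else float(phenotype[i])
        recs.append((fam, "mother", "0", "0", 2, -9.0))
        recs.append((fam, "father", "0", "0", 1, -9.0))
        recs.append((fam, "child", "father", "mother", 0, pheno))
    return SampleTable(pd.DataFrame(recs, columns=list(SampleTable.COLUMNS)))


def _fragment_row_matrix(
    boundaries: np.ndarray, rows: np.ndarray, n_markers: int
) -> np.ndarray:
    """Expand per-fragment pool-row choices to a per-marker row matrix.

    ``boundaries``: (n, k) sorted boundary indices; ``rows``: (n, k+1) pool
    rows per fragment.  Returns (n, n_markers) pool-row index per marker.
    """
    if boundaries.shape[1] == 0:
        return np.broadcast_to(rows[:, :1], (rows.shape[0], n_markers))
    marker_idx = np.arange(n_markers)
    # fragment id of marker j = number of boundaries <= j
    frag = (boundaries[:, :, None] <= marker_idx[None, None, :]).sum(axis=1)
    return np.take_along_axis(rows, frag, axis=1)


def splice_batch(
    pool: ComplementedPool,
    marker_map: MarkerMap,
    boundaries: dict[str, np.ndarray],
    rows: dict[str, np.ndarray],
    swap: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Materialize (mothers, fathers, children) for a batch of simulated
    triads from pre-drawn plans and pool-row choices."""
    n = swap.shape[0]
    p = marker_map.n_markers
    mothers = np.empty((n, p), dtype=np.int8)
    fathers = np.empty((n, p), dtype=np.int8)
    children = np.empty((n, p), dtype=np.int8)
    for chrom, sl in marker_map.chrom_slices().items():
        nm = sl.stop - sl.start
        rowmat = _fragment_row_matrix(boundaries[chrom], rows[chrom], nm)
        col = np.arange(sl.start, sl.stop)[None, :]
        mothers[:, sl] = pool.mothers[rowmat, col]
        fathers[:, sl] = pool.fathers[rowmat, col]
        children[:, sl] = pool.children[rowmat, col]
    if swap.any():
        sw = swap.astype(bool)
        mothers[sw], fathers[sw] = fathers[sw].copy(), mothers[sw].copy()
    return mothers, fathers, children


def draw_batch_plans(
    track: HotspotTrack,
    k_per_chromosome,
    n: int,
    pool_size: int,
    rng: np.random.Generator,
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray], np.ndarray]:
    """Draw fragment plans, per-fragment pool rows, and parent swaps for a
    batch of ``n`` simulated triads.  Draw order is fixed (chromosomes in
    map order), so output is reproducible for a given generator state."""
    k = resolve_k(track, k_per_chromosome)
    boundaries: dict[str, np.ndarray] = {}
    rows: dict[str, np.ndarray] = {}
    for chrom, cand in track.boundaries.items():
        b = draw_boundary_matrix(cand, k[chrom], n, rng)
        boundaries[chrom] = b
        rows[chrom] = rng.integers(0, pool_size, size=(n, b.shape[1] + 1))
    swap = rng.random(n) < 0.5
    return boundaries, rows, swap


def simulate_triad(
    pool: ComplementedPool,
    marker_map: MarkerMap,
    track: HotspotTrack,
    k_per_chromosome,
    rng: np.random.Generator,
) -> SimulatedTriad:
    """Simulate a single triad (convenience scalar path over the batch core)."""
    boundaries, rows, swap = draw_batch_plans(track, k_per_chromosome, 1, pool.size, rng)
    mothers, fathers, children = splice_batch(pool, marker_map, boundaries, rows, swap)
    plan = FragmentPlan(
        chosen={c: b[0] for c, b in boundaries.items()},
        n_markers=dict(track.n_markers),
    )
    return SimulatedTriad(
        mother=mothers[0],
        father=fathers[0],
        child=children[0],
        plan=plan,
        provenance={c: r[0] for c, r in rows.items()},
        parent_swap=bool(swap[0]),
    )


def simulate_null_study(
    pool: ComplementedPool,
    marker_map: MarkerMap,
    n_triads: int,
    track: HotspotTrack,
    k_per_chromosome,
    rng: np.random.Generator,
) -> NullStudy:
    """Simulate ``n_triads`` independent triads under the global null."""
    if n_triads < 1:
        raise ValueError("n_triads must be >= 1")
    boundaries, rows, swap = draw_batch_plans(
        track, k_per_chromosome, n_triads, pool.size, rng
    )
    mothers, fathers, children = splice_batch(pool, marker_map, boundaries, rows, swap)
    return NullStudy(marker_map=marker_map, mothers=mothers, fathers=fathers, children=children)
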