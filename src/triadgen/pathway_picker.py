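"""Pathway SNP selection — explicit lists or frequency-targeted picking."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .complementer import ComplementedPool
from .io_plink import MISSING, MarkerMap, TriadSet
from .traits import PathwaySpec

__all__ = ["founder_maf", "founder_maf_from_source", "pick_snps", "read_snp_list"]


def founder_maf(pool: ComplementedPool, markers=None) -> np.ndarray:
    """Counted-allele frequency over the 4N parental alleles of the N source
    families (each parent counted once, not per pool row).

    All-missing markers yield NaN (flagged, excluded downstream).
    """
    copies, called = pool.founder_allele_counts()
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(called > 0, copies / np.maximum(called, 1), np.nan)
    if markers is None:
        return freq
    return freq[np.asarray(markers)]


def founder_maf_from_source(
    genotypes: np.ndarray, triads: TriadSet
) -> np.ndarray:
    """Founder frequency straight from a source dataset (parents of triads)."""
    triads = np.asarray(triads)
    parents = np.vstack([genotypes[triads[:, 0]], genotypes[triads[:, 1]]])
    called = (parents != MISSING).sum(0) * 2
    copies = np.where(parents != MISSING, parents, 0).sum(0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(called > 0, copies / np.maximum(called, 1), np.nan)


def read_snp_list(path: str | Path, marker_map: MarkerMap) -> PathwaySpec:
    """Explicit pathway file: one pathway per line, whitespace-separated snp ids."""
    pathways = []
    for line in Path(path).read_text().splitlines():
        ids = line.split()
        if ids:
            pathways.append(marker_map.index_of(ids))
    if not pathways:
        raise ValueError(f"{path}: no pathways found")
    return PathwaySpec(pathways)


def pick_snps(
    marker_map: MarkerMap,
    maf: np.ndarray,
    sizes,
    target_mafs,
    tolerance: float = 0.02,
    min_gap_bp: int = 1_000_000,
    rng: np.random.Generator | None = None,
) -> PathwaySpec:
    """Pick disjoint pathways of SNPs with founder MAF near per-pathway
    targets, pairwise bp gap >= ``min_gap_bp`` among picked SNPs on the same
    chromosome, spread round-robin across chromosomes with eligible SNPs.
    """
    rng = np.random.default_rng() if rng is None else rng
    sizes = list(sizes)
    target_mafs = list(target_mafs)
    if len(sizes) != len(target_mafs):
        raise ValueError("sizes and target_mafs must align")
    maf = np.asarray(maf, float)
    chrom = marker_map.chromosome
    bp = marker_map.bp_pos
    chroms = marker_map.chromosomes()

    picked: list[int] = []
    pathways: list[np.ndarray] = []
    for pw, (size, target) in enumerate(zip(sizes, target_mafs)):
        eligible = np.flatnonzero(
            ~np.isnan(maf) & (np.abs(maf - target) <= tolerance)
        )
        eligible = np.array([i for i in eligible if i not in set(picked)])
        if eligible.size < size:
            raise ValueError(
                f"pathway {pw + 1}: only {eligible.size} SNPs with |MAF - "
                f"{target}| <= {tolerance}; need {size} (binding constraint: "
                "allele-frequency window)"
            )
        chosen: list[int] = []
        by_chrom = {c: list(rng.permutation(eligible[chrom[eligible] == c])) for c in chroms}
        order = [c for c in chroms if by_chrom[c]]
        attempts = 0
        ci = 0
        while len(chosen) < size:
            attempts += 1
            if attempts > 10_000 or not order:
                raise ValueError(
                    f"pathway {pw + 1}: cannot place {size} SNPs with pairwise "
                    f"gap >= {min_gap_bp} bp (binding constraint: min_gap_bp)"
                )
            c = order[ci % len(order)]
            ci += 1
            placed = False
            while by_chrom[c]:
                cand = int(by_chrom[c].pop())
                same = [j for j in chosen + picked if chrom[j] == c]
                if all(abs(int(bp[cand]) - int(bp[j])) >= min_gap_bp for j in same):
                    chosen.append(cand)
                    placed = True
                    break
            if not by_chrom[c]:
                order = [cc for cc in order if by_chrom[cc]]
                ci = 0
            if not placed and not order:
                raise ValueError(
                    f"pathway {pw + 1}: cannot place {size} SNPs with pairwise "
                    f"gap >= {min_gap_bp} bp (binding constraint: min_gap_bp)"
                )
        picked.extend(chosen)
        pathways.append(np.array(sorted(chosen), dtype=np.int64))
    return PathwaySpec(pathways)
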