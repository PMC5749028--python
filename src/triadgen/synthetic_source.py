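"""Synthetic Mendelian-consistent triad GWAS fixtures with block LD.

Each chromosome is a sequence of haplotype blocks.  A block holds H
haplotypes over {0,1} alleles with fixed frequencies; parental chromosomes
are built by walking the blocks, keeping the current haplotype rank with
probability ``1 - r`` at each block boundary and redrawing it from the block
frequencies otherwise.  Children inherit one recombinant haplotype per
parent with crossovers only at block boundaries (probability ``r``), so the
fixture's own hotspot track — its block boundaries — is exactly the
recombination geography the fragment resampler should use.

Per-SNP allele frequencies are controlled by assigning the variant allele
to a subset of haplotype ranks whose total frequency best matches the
target (exact subset-sum enumeration over the small rank set, ties broken
at random); the default rank weights make the frequencies used by the
study scenarios (0.15, 0.30, 0.50) and rare frequencies down to 0.005
exactly attainable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io_plink import MarkerMap, SampleTable, write_plink
from .traits import PathwaySpec, TraitModel, assign_dichotomous, pathway_indicator_matrix

__all__ = [
    "BlockSpec",
    "SourceDataset",
    "default_weights",
    "make_chromosomes",
    "generate_source",
    "generate_ascertained_source",
]

#: default haplotype-rank frequencies; subset sums realize 0.15, 0.30, 0.50
#: exactly and rare frequencies at 0.005 resolution
DEFAULT_WEIGHTS = (0.30, 0.20, 0.15, 0.14, 0.10, 0.05, 0.03, 0.02, 0.005, 0.005)


def default_weights() -> np.ndarray:
    return np.array(DEFAULT_WEIGHTS)


@dataclass
class BlockSpec:
    """One LD block: (H, n_snps) haplotype alleles, rank frequencies, bp
    positions, and the recombination probability r to the NEXT block."""

    haplotypes: np.ndarray
    freqs: np.ndarray
    bp_pos: np.ndarray
    recomb_prob: float = 0.0

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.haplotypes.ndim != 2 or self.haplotypes.shape[0] != self.freqs.size:
            raise ValueError("haplotypes must be (H, n_snps) aligned with freqs")
        if not np.isclose(self.freqs.sum(), 1.0):
            raise ValueError("haplotype frequencies must sum to 1")
        if not 0.0 <= self.recomb_prob <= 0.5:
            raise ValueError("recomb_prob must lie in [0, 0.5]")
        if len(self.bp_pos) != self.haplotypes.shape[1]:
            raise ValueError("bp_pos length must equal n_snps")

    @property
    def n_snps(self) -> int:
        return self.haplotypes.shape[1]

    def implied_freqs(self) -> np.ndarray:
        """Haplotype-implied variant-allele frequency per SNP."""
        return self.freqs @ self.haplotypes


@dataclass
class SourceDataset:
    """A generated triad panel plus its hotspot track and truth tables."""

    marker_map: MarkerMap
    samples: SampleTable
    genotypes: np.ndarray
    hotspots: pd.DataFrame  # chrom, start, end (0-based half-open)
    truth: pd.DataFrame  # snp_id, chrom, block, target_freq, implied_freq

    def write(self, prefix: str | Path, dialect: str = "bed") -> list[Path]:
        prefix = Path(prefix)
        paths = write_plink(prefix, self.marker_map, self.samples, self.genotypes, dialect)
        hs = prefix.parent / (prefix.name + ".hotspots.bed")
        self.hotspots.to_csv(hs, sep="\t", header=False, index=False)
        tr = prefix.parent / (prefix.name + ".truth.tsv")
        self.truth.to_csv(tr, sep="\t", index=False)
        return paths + [hs, tr]


_SUBSET_CACHE: dict[bytes, tuple[np.ndarray, np.ndarray]] = {}


def _subset_table(weights: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All 2^H subset indicator rows and their weight sums (H is small)."""
    key = weights.tobytes()
    if key not in _SUBSET_CACHE:
        h = len(weights)
        if h > 16:
            raise ValueError("at most 16 haplotype ranks are supported")
        masks = np.arange(2**h, dtype=np.uint32)
        rows = ((masks[:, None] >> np.arange(h)) & 1).astype(np.int8)
        _SUBSET_CACHE[key] = (rows, rows @ weights)
    return _SUBSET_CACHE[key]


def _alleles_for_target(
    weights: np.ndarray, target: float, rng: np.random.Generator
) -> np.ndarray:
    """Assign the variant allele to a subset of haplotype ranks whose total
    frequency best matches the target; ties broken uniformly at random so
    repeated SNPs at one frequency land on varied haplotype subsets."""
    rows, sums = _subset_table(np.asarray(weights, float))
    dist = np.abs(sums - target)
    best = dist.min()
    choices = np.flatnonzero(dist <= best + 1e-12)
    return rows[rng.choice(choices)].copy()


def make_chromosomes(
    n_chromosomes: int = 4,
    n_snps_per_chrom: int = 500,
    block_size: int = 25,
    weights: np.ndarray | None = None,
    target_freqs: np.ndarray | None = None,
    recomb_prob: float = 0.35,
    rare_fraction: float = 0.15,
    bp_spacing: int = 2_000,
    block_gap_bp: int = 10_000,
    rng: np.random.Generator | None = None,
) -> list[list[BlockSpec]]:
    """Build block specs for a fixture panel.

    By default per-SNP target frequencies mix common (uniform 0.1-0.5) and
    rare (<0.02) SNPs; pass ``target_freqs`` (total length n_chromosomes *
    n_snps_per_chrom) to pin every SNP, e.g. to place scenario loci.
    """
    rng = np.random.default_rng() if rng is None else rng
    w = default_weights() if weights is None else np.asarray(weights, float)
    total = n_chromosomes * n_snps_per_chrom
    if target_freqs is None:
        rare = rng.random(total) < rare_fraction
        target_freqs = np.where(
            rare,
            rng.choice([0.005, 0.01, 0.015], size=total),
            np.round(rng.uniform(0.10, 0.50, size=total), 3),
        )
    else:
        target_freqs = np.asarray(target_freqs, float)
        if target_freqs.size != total:
            raise ValueError("target_freqs length must equal the panel size")
    if n_snps_per_chrom % block_size:
        raise ValueError("n_snps_per_chrom must be a multiple of block_size")
    chroms: list[list[BlockSpec]] = []
    s = 0
    for _c in range(n_chromosomes):
        blocks: list[BlockSpec] = []
        pos = 1
        for _b in range(n_snps_per_chrom // block_size):
            tf = target_freqs[s : s + block_size]
            s += block_size
            haps = np.stack(
                [_alleles_for_target(w, t, rng) for t in tf], axis=1
            )  # (H, block_size)
            bp = pos + bp_spacing * np.arange(block_size)
            pos = int(bp[-1]) + block_gap_bp
            blocks.append(
                BlockSpec(haplotypes=haps, freqs=w.copy(), bp_pos=bp, recomb_prob=recomb_prob)
            )
        blocks[-1].recomb_prob = 0.0  # no boundary after the last block
        chroms.append(blocks)
    return chroms


def _chrom_meta(chromosomes: list[list[BlockSpec]]):
    """Marker map + hotspot intervals + block bookkeeping for the specs."""
    snp_id, chrom_lab, bp, blk_lab = [], [], [], []
    hotspot_rows = []
    for ci, blocks in enumerate(chromosomes):
        chrom = str(ci + 1)
        for bi, blk in enumerate(blocks):
            for j in range(blk.n_snps):
                snp_id.append(f"snp{chrom}_{bi:03d}_{j:02d}")
                chrom_lab.append(chrom)
                bp.append(int(blk.bp_pos[j]))
                blk_lab.append(bi)
            if bi < len(blocks) - 1:
                lo = int(blk.bp_pos[-1])
                hi = int(blocks[bi + 1].bp_pos[0])
                mid = (lo + hi) // 2
                hotspot_rows.append((chrom, mid - 1, mid + 1))
    mm = MarkerMap(
        snp_id=np.array(snp_id, dtype=object),
        chromosome=np.array(chrom_lab, dtype=object),
        genetic_pos=np.zeros(len(snp_id)),
        bp_pos=np.array(bp, dtype=np.int64),
        allele1=np.array(["A"] * len(snp_id), dtype=object),
        allele2=np.array(["G"] * len(snp_id), dtype=object),
    )
    hotspots = pd.DataFrame(hotspot_rows, columns=["chrom", "start", "end"])
    return mm, hotspots, np.array(blk_lab)


def _draw_parent_haplotypes(
    blocks: list[BlockSpec], n: int, rng: np.random.Generator
) -> np.ndarray:
    """(n, n_snps) haplotypes for one chromosome: rank walk with redraw
    probability r at each block boundary."""
    n_snps = sum(b.n_snps for b in blocks)
    out = np.empty((n, n_snps), dtype=np.int8)
    rank = None
    col = 0
    for bi, blk in enumerate(blocks):
        cum = np.cumsum(blk.freqs)
        fresh = rng.random(n)
        new_rank = np.searchsorted(cum, fresh * cum[-1], side="right").clip(0, len(blk.freqs) - 1)
        if rank is None:
            rank = new_rank
        else:
            redraw = rng.random(n) < prev_r
            rank = np.where(redraw, new_rank, rank)
        out[:, col : col + blk.n_snps] = blk.haplotypes[rank]
        col += blk.n_snps
        prev_r = blk.recomb_prob
    return out


def _recombine(
    hap_a: np.ndarray, hap_b: np.ndarray, blocks: list[BlockSpec], rng: np.random.Generator
) -> np.ndarray:
    """Transmit one recombinant haplotype: block-wise switches at prob r."""
    n = hap_a.shape[0]
    out = np.empty_like(hap_a)
    use_b = rng.random(n) < 0.5
    col = 0
    for bi, blk in enumerate(blocks):
        seg = np.where(use_b[:, None], hap_b[:, col : col + blk.n_snps], hap_a[:, col : col + blk.n_snps])
        out[:, col : col + blk.n_snps] = seg
        col += blk.n_snps
        if bi < len(blocks) - 1:
            flip = rng.random(n) < blk.recomb_prob
            use_b = use_b ^ flip
    return out


def _generate_families(
    chromosomes: list[list[BlockSpec]], n: int, rng: np.random.Generator
):
    """Genotype-count matrices (mothers, fathers, children), each (n, M)."""
    mothers, fathers, children = [], [], []
    for blocks in chromosomes:
        m1 = _draw_parent_haplotypes(blocks, n, rng)
        m2 = _draw_parent_haplotypes(blocks, n, rng)
        f1 = _draw_parent_haplotypes(blocks, n, rng)
        f2 = _draw_parent_haplotypes(blocks, n, rng)
        cm = _recombine(m1, m2, blocks, rng)
        cf = _recombine(f1, f2, blocks, rng)
        mothers.append(m1 + m2)
        fathers.append(f1 + f2)
        children.append(cm + cf)
    return (
        np.hstack(mothers).astype(np.int8),
        np.hstack(fathers).astype(np.int8),
        np.hstack(children).astype(np.int8),
    )


def _assemble(chromosomes, mothers, fathers, children, prefix_tag="fam") -> SourceDataset:
    mm, hotspots, blk = _chrom_meta(chromosomes)
    n = mothers.shape[0]
    recs = []
    for i in range(n):
        fam = f"{prefix_tag}{i + 1:06d}"
        recs.append((fam, "mother", "0", "0", 2, -9.0))
        recs.append((fam, "father", "0", "0", 1, -9.0))
        recs.append((fam, "child", "father", "mother", 0, 2.0))
    samples = SampleTable(pd.DataFrame(recs, columns=list(SampleTable.COLUMNS)))
    geno = np.empty((3 * n, mm.n_markers), dtype=np.int8)
    geno[0::3] = mothers
    geno[1::3] = fathers
    geno[2::3] = children
    implied = np.concatenate(
        [blk_spec.implied_freqs() for blocks in chromosomes for blk_spec in blocks]
    )
    founder = (mothers.sum(0) + fathers.sum(0)) / (4.0 * n)
    truth = pd.DataFrame(
        {
            "snp_id": mm.snp_id,
            "chromosome": mm.chromosome,
            "block": blk,
            "implied_freq": implied,
            "founder_freq": founder,
        }
    )
    return SourceDataset(mm, samples, geno, hotspots, truth)


def generate_source(
    n_families: int,
    chromosomes: list[list[BlockSpec]],
    seed: int | np.random.Generator,
) -> SourceDataset:
    """Generate ``n_families`` Mendelian-consistent triads from block specs."""
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mothers, fathers, children = _generate_families(chromosomes, n_families, rng)
    return _assemble(chromosomes, mothers, fathers, children)


def generate_ascertained_source(
    n_families: int,
    chromosomes: list[list[BlockSpec]],
    planted_model: TraitModel,
    planted_pathways: PathwaySpec,
    seed: int | np.random.Generator,
    batch: int = 4096,
    max_draws: int = 10_000_000,
) -> SourceDataset:
    """Generate triads ascertained on an affected child under a planted risk
    model, producing genuine transmission distortion at the planted loci."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if planted_model.trait_kind != "dichotomous":
        raise ValueError("planted model must be dichotomous")
    kept_m, kept_f, kept_c = [], [], []
    kept = 0
    drawn = 0
    while kept < n_families:
        if drawn >= max_draws:
            raise RuntimeError(
                "ascertainment did not reach the target family count; "
                "is the planted penetrance zero?"
            )
        m, f, c = _generate_families(chromosomes, batch, rng)
        drawn += batch
        X = pathway_indicator_matrix(c, planted_pathways)
        affected = assign_dichotomous(planted_model, X, 0, rng).astype(bool)
        kept_m.append(m[affected])
        kept_f.append(f[affected])
        kept_c.append(c[affected])
        kept += int(affected.sum())
    mothers = np.vstack(kept_m)[:n_families]
    fathers = np.vstack(kept_f)[:n_families]
    children = np.vstack(kept_c)[:n_families]
    return _assemble(chromosomes, mothers, fathers, children, prefix_tag="asc")
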