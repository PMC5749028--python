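"""Complement-triad construction and the 2N-triad resampling pool.

For each observed mother-father-child triad the *complement* triad keeps the
parental genotypes but gives the offspring the parental alleles that were
NOT transmitted to the observed child.  At the genotype-count level this is
simply ``m + f - c``, which is well defined without phasing (even when all
three are heterozygous, both phase resolutions leave a heterozygous
complement).  Pooling observed and complement triads is what destroys any
risk signal carried by the source families.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_plink import MISSING, MarkerMap, SampleTable, TriadSet

__all__ = [
    "ComplementedPool",
    "QCReport",
    "mendel_consistent",
    "mendel_consistent_array",
    "complement_genotype",
    "build_pool",
]

logger = logging.getLogger(__name__)

# _MENDEL_OK[m, f, c]: child count c is compatible with parent counts m, f
# (transmissible allele counts: T(0)={0}, T(1)={0,1}, T(2)={1})
_MENDEL_OK = np.zeros((3, 3, 3), dtype=bool)
_T = {0: (0,), 1: (0, 1), 2: (1,)}
for _m in range(3):
    for _f in range(3):
        for _tm in _T[_m]:
            for _tf in _T[_f]:
                _MENDEL_OK[_m, _f, _tm + _tf] = True


def mendel_consistent(m: int, f: int, c: int) -> bool:
    """True iff child count ``c`` can arise from parents ``m`` and ``f``."""
    return bool(_MENDEL_OK[m, f, c])


def mendel_consistent_array(m: np.ndarray, f: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Vectorized :func:`mendel_consistent`; MISSING anywhere counts as consistent."""
    mm, ff, cc = np.broadcast_arrays(*(np.asarray(a) for a in (m, f, c)))
    complete = (mm != MISSING) & (ff != MISSING) & (cc != MISSING)
    out = np.ones(mm.shape, dtype=bool)
    out[complete] = _MENDEL_OK[mm[complete], ff[complete], cc[complete]]
    return out


def complement_genotype(m: int, f: int, c: int) -> int:
    """Non-transmitted-allele child count ``m + f - c``; self-inverse."""
    if not mendel_consistent(m, f, c):
        raise ValueError(f"Mendelian-inconsistent triple (m={m}, f={f}, c={c})")
    return m + f - c


@dataclass
class QCReport:
    """Mendelian-error tallies produced while building a pool."""

    per_snp: pd.DataFrame  # snp_id, n_errors
    per_family: pd.DataFrame  # family_id, n_errors, dropped
    dropped_families: list[str] = field(default_factory=list)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# per-SNP Mendelian errors\n")
            self.per_snp.to_csv(fh, sep="\t", index=False)
            fh.write("# per-family Mendelian errors\n")
            self.per_family.to_csv(fh, sep="\t", index=False)


@dataclass
class ComplementedPool:
    """2N aligned mother/father/child genotype rows (N observed + N complement).

    Rows ``j`` and ``j + n_families`` share parents: the first block holds the
    observed triads, the second their complements.
    """

    mothers: np.ndarray
    fathers: np.ndarray
    children: np.ndarray
    origin: np.ndarray  # "observed" | "complement"
    source_family: np.ndarray

    def __post_init__(self) -> None:
        if not (self.mothers.shape == self.fathers.shape == self.children.shape):
            raise ValueError("pool matrices must share a shape")

    @property
    def size(self) -> int:
        return self.mothers.shape[0]

    @property
    def n_families(self) -> int:
        return self.size // 2

    @property
    def n_markers(self) -> int:
        return self.mothers.shape[1]

    def founder_allele_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """(count of allele1 copies, count of called alleles) over the 4N
        parental alleles, each parent counted once."""
        n = self.n_families
        m = self.mothers[:n]
        f = self.fathers[:n]
        called = ((m != MISSING).sum(0) + (f != MISSING).sum(0)) * 2
        copies = np.where(m != MISSING, m, 0).sum(0) + np.where(f != MISSING, f, 0).sum(0)
        return copies.astype(np.int64), called.astype(np.int64)


def build_pool(
    marker_map: MarkerMap,
    samples: SampleTable,
    genotypes: np.ndarray,
    triads: TriadSet,
    qc_policy: str = "set_missing",
    max_inconsistent_fraction: float = 0.01,
) -> tuple[ComplementedPool, QCReport]:
    """Build the observed + complement resampling pool with Mendelian QC.

    ``qc_policy`` routes locus-level Mendelian inconsistencies:

    - ``"error"``: raise on the first inconsistency, naming locus and family;
    - ``"drop_triad"``: drop the whole family from the pool;
    - ``"set_missing"`` (default): set the locus MISSING in both child rows.

    Independently of the policy, a family whose fraction of inconsistent
    loci exceeds ``max_inconsistent_fraction`` (evident nonpaternity) is
    dropped entirely.  The complement child is MISSING wherever any of
    (m, f, c) is MISSING.
    """
    if qc_policy not in ("error", "drop_triad", "set_missing"):
        raise ValueError(f"unknown qc_policy {qc_policy!r}")
    triads = np.asarray(triads)
    n = len(triads)
    geno = np.asarray(genotypes, dtype=np.int8)
    m = geno[triads[:, 0]]
    f = geno[triads[:, 1]]
    c = geno[triads[:, 2]].copy()
    fam_ids = samples.df["family_id"].to_numpy(dtype=object)[triads[:, 2]]

    ok = mendel_consistent_array(m, f, c)
    bad = ~ok
    if qc_policy == "error" and bad.any():
        fi, si = np.argwhere(bad)[0]
        raise ValueError(
            f"Mendelian inconsistency at marker {marker_map.snp_id[si]} "
            f"in family {fam_ids[fi]}"
        )
    per_snp_errors = bad.sum(axis=0)
    per_family_errors = bad.sum(axis=1)
    n_loci_checked = np.maximum(
        ((m != MISSING) & (f != MISSING) & (c != MISSING)).sum(axis=1), 1
    )
    drop = per_family_errors / n_loci_checked > max_inconsistent_fraction
    if qc_policy == "drop_triad":
        drop |= per_family_errors > 0
    if drop.any():
        logger.warning("dropping %d triad(s) failing Mendelian QC", int(drop.sum()))

    complete = (m != MISSING) & (f != MISSING) & (c != MISSING)
    comp = np.where(complete & ok, m + f - c, MISSING).astype(np.int8)
    if qc_policy == "set_missing":
        c = np.where(complete & ~ok, MISSING, c).astype(np.int8)

    keep = ~drop
    pool = ComplementedPool(
        mothers=np.vstack([m[keep], m[keep]]),
        fathers=np.vstack([f[keep], f[keep]]),
        children=np.vstack([c[keep], comp[keep]]),
        origin=np.array(["observed"] * int(keep.sum()) + ["complement"] * int(keep.sum()), dtype=object),
        source_family=np.concatenate([fam_ids[keep], fam_ids[keep]]),
    )
    report = QCReport(
        per_snp=pd.DataFrame(
            {"snp_id": marker_map.snp_id, "n_errors": per_snp_errors}
        ),
        per_family=pd.DataFrame(
            {"family_id": fam_ids, "n_errors": per_family_errors, "dropped": drop}
        ),
        dropped_families=list(fam_ids[drop]),
    )
    return pool, report
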