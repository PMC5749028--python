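"""PLINK pedigree-format input/output and triad assembly.

Genotypes are held as counts of a designated *counted allele* (allele1) in
``{0, 1, 2}`` with :data:`MISSING` (``-1``) for no-calls.  Both the text
dialect (.ped/.map) and the binary SNP-major dialect (.bed/.bim/.fam, magic
bytes ``6C 1B`` and mode byte ``01``) are supported, and writing followed by
reading reproduces the genotype matrix exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "MarkerMap",
    "SampleTable",
    "TriadSet",
    "PlinkFormatError",
    "read_plink",
    "write_plink",
    "build_triads",
]

logger = logging.getLogger(__name__)

MISSING: int = -1
"""Sentinel for a missing genotype count (stored in int8 matrices)."""

_VALID_ALLELES = set("ACGT120")


class PlinkFormatError(ValueError):
    """Raised on malformed PLINK input."""


@dataclass
class MarkerMap:
    """Ordered marker panel: ids, chromosome labels, positions, alleles.

    ``allele1`` is the counted allele (genotype values are copies of it);
    markers must be grouped contiguously by chromosome with strictly
    increasing bp position within each chromosome.
    """

    snp_id: np.ndarray
    chromosome: np.ndarray
    genetic_pos: np.ndarray
    bp_pos: np.ndarray
    allele1: np.ndarray
    allele2: np.ndarray

    def __post_init__(self) -> None:
        self.snp_id = np.asarray(self.snp_id, dtype=object)
        self.chromosome = np.asarray(self.chromosome, dtype=object)
        self.genetic_pos = np.asarray(self.genetic_pos, dtype=float)
        self.bp_pos = np.asarray(self.bp_pos, dtype=np.int64)
        self.allele1 = np.asarray(self.allele1, dtype=object)
        self.allele2 = np.asarray(self.allele2, dtype=object)
        if len(set(self.snp_id)) != self.n_markers:
            raise ValueError("snp_ids must be unique")
        if np.any(self.allele1 == self.allele2):
            bad = self.snp_id[self.allele1 == self.allele2][0]
            raise ValueError(f"allele1 == allele2 at marker {bad}")
        seen = set()
        for chrom, sl in self.chrom_slices().items():
            if chrom in seen:  # pragma: no cover - guarded by dict build
                raise ValueError(f"chromosome {chrom} not contiguous")
            seen.add(chrom)
            bp = self.bp_pos[sl]
            if np.any(np.diff(bp) <= 0):
                raise ValueError(
                    f"bp positions not strictly increasing on chromosome {chrom}"
                )

    @property
    def n_markers(self) -> int:
        return len(self.snp_id)

    def chromosomes(self) -> list[str]:
        """Chromosome labels in order of first appearance."""
        out: list[str] = []
        for c in self.chromosome:
            if not out or out[-1] != c:
                if c in out:
                    raise ValueError(f"chromosome {c} not contiguous in map")
                out.append(c)
        return out

    def chrom_slices(self) -> dict[str, slice]:
        """Map chromosome label -> slice of marker indices (contiguous)."""
        out: dict[str, slice] = {}
        start = 0
        chroms = self.chromosome
        for i in range(1, self.n_markers + 1):
            if i == self.n_markers or chroms[i] != chroms[start]:
                out[chroms[start]] = slice(start, i)
                start = i
        return out

    def index_of(self, snp_ids: Iterable[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.snp_id)}
        return np.array([lookup[s] for s in snp_ids], dtype=np.int64)


@dataclass
class SampleTable:
    """Per-individual pedigree fields following PLINK .fam conventions."""

    df: pd.DataFrame = field(repr=False)

    COLUMNS = ("family_id", "individual_id", "paternal_id", "maternal_id", "sex", "phenotype")

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"SampleTable missing columns {missing}")
        self.df = self.df.reset_index(drop=True)
        for c in self.COLUMNS[:4]:
            self.df[c] = self.df[c].astype(str)
        self.df["sex"] = self.df["sex"].astype(int)
        self.df["phenotype"] = self.df["phenotype"].astype(float)
        keys = list(zip(self.df["family_id"], self.df["individual_id"]))
        if len(set(keys)) != len(keys):
            raise ValueError("(family_id, individual_id) pairs must be unique")

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def from_records(cls, records: Sequence[tuple]) -> "SampleTable":
        return cls(pd.DataFrame(records, columns=list(cls.COLUMNS)))


#: list of (mother_row, father_row, child_row) indices into the SampleTable
TriadSet = np.ndarray


def _infer_dialect(prefix: Path) -> str:
    if prefix.with_suffix(".bed").exists():
        return "bed"
    if prefix.with_suffix(".ped").exists():
        return "ped"
    raise FileNotFoundError(f"no .bed or .ped file with prefix {prefix}")


def read_plink(
    prefix: str | Path,
    dialect: str | None = None,
    counted_alleles: Mapping[str, str] | None = None,
) -> tuple[MarkerMap, SampleTable, np.ndarray]:
    """Read a PLINK fileset into (MarkerMap, SampleTable, genotype matrix).

    Genotype values are counts of allele1 in {0,1,2} or :data:`MISSING`.
    For the text dialect allele1 is the minor allele computed over founders
    (ties broken lexicographically) unless ``counted_alleles`` maps a snp_id
    to an explicit counted allele.
    """
    prefix = Path(prefix)
    if dialect is None:
        dialect = _infer_dialect(prefix)
    if dialect == "bed":
        return _read_bed(prefix)
    if dialect == "ped":
        return _read_ped(prefix, counted_alleles or {})
    raise ValueError(f"unknown dialect {dialect!r}")


def write_plink(
    prefix: str | Path,
    marker_map: MarkerMap,
    samples: SampleTable,
    genotypes: np.ndarray,
    dialect: str = "bed",
) -> list[Path]:
    """Write a PLINK fileset; returns the paths written."""
    prefix = Path(prefix)
    genotypes = np.asarray(genotypes, dtype=np.int8)
    if genotypes.shape != (len(samples), marker_map.n_markers):
        raise ValueError("genotype matrix shape does not match samples/map")
    prefix.parent.mkdir(parents=True, exist_ok=True)
    if dialect == "bed":
        return _write_bed(prefix, marker_map, samples, genotypes)
    if dialect == "ped":
        return _write_ped(prefix, marker_map, samples, genotypes)
    raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# text dialect

def _fam_fields(samples: SampleTable) -> list[str]:
    lines = []
    for r in samples.df.itertuples(index=False):
        pheno = r.phenotype
        ptxt = str(int(pheno)) if float(pheno).is_integer() else repr(pheno)
        lines.append(f"{r.family_id} {r.individual_id} {r.paternal_id} {r.maternal_id} {r.sex} {ptxt}")
    return lines


def _write_ped(prefix, marker_map, samples, genotypes) -> list[Path]:
    map_path = prefix.with_suffix(".map")
    ped_path = prefix.with_suffix(".ped")
    with open(map_path, "w") as fh:
        for i in range(marker_map.n_markers):
            gp = marker_map.genetic_pos[i]
            gtxt = str(int(gp)) if float(gp).is_integer() else repr(gp)
            fh.write(
                f"{marker_map.chromosome[i]} {marker_map.snp_id[i]} {gtxt} {marker_map.bp_pos[i]}\n"
            )
    a1 = marker_map.allele1
    a2 = marker_map.allele2
    fam_lines = _fam_fields(samples)
    with open(ped_path, "w") as fh:
        for row, head in zip(genotypes, fam_lines):
            parts = [head]
            for g, x, y in zip(row, a1, a2):
                if g == MISSING:
                    parts.append("0 0")
                elif g == 2:
                    parts.append(f"{x} {x}")
                elif g == 1:
                    parts.append(f"{x} {y}")  # counted allele written first
                else:
                    parts.append(f"{y} {y}")
            fh.write(" ".join(parts) + "\n")
    return [ped_path, map_path]


def _read_map(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=r"\s+", header=None, dtype=str)
    if df.shape[1] != 4:
        raise PlinkFormatError(f"{path}: expected 4 columns, found {df.shape[1]}")
    df.columns = ["chromosome", "snp_id", "genetic_pos", "bp_pos"]
    return df


def _read_ped(prefix: Path, counted_alleles: Mapping[str, str]):
    map_df = _read_map(prefix.with_suffix(".map"))
    n_markers = len(map_df)
    fam_rows = []
    allele_pairs: list[list[tuple[str, str]]] = []
    with open(prefix.with_suffix(".ped")) as fh:
        for ln, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * n_markers:
                raise PlinkFormatError(
                    f"{prefix}.ped line {ln}: expected {6 + 2 * n_markers} fields, got {len(fields)}"
                )
            fam_rows.append(tuple(fields[:6]))
            pairs = []
            for m in range(n_markers):
                x, y = fields[6 + 2 * m], fields[7 + 2 * m]
                if x not in _VALID_ALLELES or y not in _VALID_ALLELES:
                    raise PlinkFormatError(
                        f"{prefix}.ped line {ln}: invalid allele pair '{x} {y}'"
                    )
                pairs.append((x, y))
            allele_pairs.append(pairs)
    samples = SampleTable.from_records(fam_rows)
    n = len(samples)
    founder = (samples.df["paternal_id"] == "0") & (samples.df["maternal_id"] == "0")
    if not founder.any():
        founder = pd.Series(True, index=samples.df.index)

    a1_list, a2_list = [], []
    geno = np.full((n, n_markers), MISSING, dtype=np.int8)
    for m in range(n_markers):
        counts: dict[str, int] = {}
        observed: list[tuple[str, str]] = [allele_pairs[i][m] for i in range(n)]
        for i, (x, y) in enumerate(observed):
            if (x == "0") != (y == "0"):
                raise PlinkFormatError(f"half-missing genotype at marker {m}")
            if x != "0" and founder.iloc[i]:
                counts[x] = counts.get(x, 0) + 1
                counts[y] = counts.get(y, 0) + 1
        if not counts:  # all-missing or no founder calls: count any calls at all
            for x, y in observed:
                if x != "0":
                    counts[x] = counts.get(x, 0) + 1
                    counts[y] = counts.get(y, 0) + 1
        alleles = sorted(counts)
        if len(alleles) > 2:
            raise PlinkFormatError(
                f"marker {map_df['snp_id'][m]}: more than two alleles {alleles}"
            )
        snp = map_df["snp_id"][m]
        if snp in counted_alleles:
            a1 = counted_alleles[snp]
            others = [a for a in alleles if a != a1]
            a2 = others[0] if others else ("N" if a1 != "N" else "M")
        elif not alleles:
            a1, a2 = "0", "N"  # no information; column stays MISSING
        elif len(alleles) == 1:
            a1, a2 = alleles[0], "N"
        else:
            # minor allele first, lexicographic tie-break
            x, y = alleles
            a1, a2 = (x, y) if (counts[x], x) <= (counts[y], y) else (y, x)
        a1_list.append(a1)
        a2_list.append(a2)
        for i, (x, y) in enumerate(observed):
            if x == "0":
                continue
            for a in (x, y):
                if a not in (a1, a2):
                    raise PlinkFormatError(
                        f"marker {snp}: allele {a} absent from the map/override"
                    )
            geno[i, m] = (x == a1) + (y == a1)

    mm = MarkerMap(
        snp_id=map_df["snp_id"].to_numpy(),
        chromosome=map_df["chromosome"].to_numpy(),
        genetic_pos=map_df["genetic_pos"].astype(float).to_numpy(),
        bp_pos=map_df["bp_pos"].astype(np.int64).to_numpy(),
        allele1=np.array(a1_list, dtype=object),
        allele2=np.array(a2_list, dtype=object),
    )
    return mm, samples, geno


# ---------------------------------------------------------------------------
# binary dialect (SNP-major .bed)

_BED_MAGIC = b"\x6c\x1b\x01"
# two-bit code -> allele1 count: 00=hom A1 (2), 01=missing, 10=het (1), 11=hom A2 (0)
_BED_DECODE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_BED_ENCODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}


def _read_bed(prefix: Path):
    bim = pd.read_csv(prefix.with_suffix(".bim"), sep=r"\s+", header=None, dtype=str)
    if bim.shape[1] != 6:
        raise PlinkFormatError(f"{prefix}.bim: expected 6 columns")
    bim.columns = ["chromosome", "snp_id", "genetic_pos", "bp_pos", "allele1", "allele2"]
    fam = pd.read_csv(prefix.with_suffix(".fam"), sep=r"\s+", header=None, dtype=str)
    if fam.shape[1] != 6:
        raise PlinkFormatError(f"{prefix}.fam: expected 6 columns")
    fam.columns = list(SampleTable.COLUMNS)
    samples = SampleTable(fam)
    n, p = len(samples), len(bim)
    raw = Path(prefix.with_suffix(".bed")).read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise PlinkFormatError(
            f"{prefix}.bed: bad magic/mode bytes {raw[:3]!r} (need SNP-major 6c 1b 01)"
        )
    bpm = (n + 3) // 4  # bytes per marker
    body = np.frombuffer(raw[3:], dtype=np.uint8)
    if len(body) != bpm * p:
        raise PlinkFormatError(f"{prefix}.bed: wrong length for {n} samples x {p} markers")
    body = body.reshape(p, bpm)
    # unpack two-bit fields, samples from the low-order bits of each byte
    shifts = np.arange(4, dtype=np.uint8) * 2
    codes = (body[:, :, None] >> shifts[None, None, :]) & 0b11
    codes = codes.reshape(p, bpm * 4)[:, :n]
    geno = _BED_DECODE[codes].T.copy()  # (n, p), int8
    mm = MarkerMap(
        snp_id=bim["snp_id"].to_numpy(),
        chromosome=bim["chromosome"].to_numpy(),
        genetic_pos=bim["genetic_pos"].astype(float).to_numpy(),
        bp_pos=bim["bp_pos"].astype(np.int64).to_numpy(),
        allele1=bim["allele1"].to_numpy(),
        allele2=bim["allele2"].to_numpy(),
    )
    return mm, samples, geno


def _write_bed(prefix, marker_map, samples, genotypes) -> list[Path]:
    n, p = genotypes.shape
    bim_path = prefix.with_suffix(".bim")
    with open(bim_path, "w") as fh:
        for i in range(p):
            gp = marker_map.genetic_pos[i]
            gtxt = str(int(gp)) if float(gp).is_integer() else repr(gp)
            fh.write(
                f"{marker_map.chromosome[i]}\t{marker_map.snp_id[i]}\t{gtxt}\t"
                f"{marker_map.bp_pos[i]}\t{marker_map.allele1[i]}\t{marker_map.allele2[i]}\n"
            )
    fam_path = prefix.with_suffix(".fam")
    fam_path.write_text("\n".join(_fam_fields(samples)) + "\n")
    # encode: counts -> two-bit codes, padding bits 0 (code 00)
    code_of = np.zeros(4, dtype=np.uint8)
    for count, code in _BED_ENCODE.items():
        code_of[count] = code  # MISSING=-1 wraps to index 3
    codes = code_of[genotypes.T]  # (p, n)
    bpm = (n + 3) // 4
    padded = np.zeros((p, bpm * 4), dtype=np.uint8)
    padded[:, :n] = codes
    padded = padded.reshape(p, bpm, 4)
    shifts = np.arange(4, dtype=np.uint8) * 2
    packed = (padded << shifts[None, None, :]).sum(axis=2).astype(np.uint8)
    bed_path = prefix.with_suffix(".bed")
    with open(bed_path, "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())
    return [bed_path, bim_path, fam_path]


# ---------------------------------------------------------------------------
# triad assembly

def build_triads(samples: SampleTable, on_inconsistent_sex: str = "warn") -> TriadSet:
    """Assemble every complete (mother, father, child) row-index triple.

    Families lacking a genotyped parent are skipped with a warning; a family
    with two or more children sharing the same parents is an error (the
    resampling pool requires one case child per family — pre-split such
    families).  ``on_inconsistent_sex``: ``"warn"`` skips a child whose
    parent ids point at individuals with the wrong sex codes, ``"error"``
    raises.
    """
    df = samples.df
    idx = {(f, i): k for k, (f, i) in enumerate(zip(df["family_id"], df["individual_id"]))}
    triads: list[tuple[int, int, int]] = []
    seen_parent_pairs: dict[tuple[str, str, str], str] = {}
    used: set[int] = set()
    for k, row in enumerate(df.itertuples(index=False)):
        if row.paternal_id == "0" or row.maternal_id == "0":
            continue
        fk = idx.get((row.family_id, row.paternal_id))
        mk = idx.get((row.family_id, row.maternal_id))
        if fk is None or mk is None:
            logger.warning(
                "family %s: child %s has ungenotyped parent(s); skipped",
                row.family_id, row.individual_id,
            )
            continue
        if df["sex"].iloc[fk] == 2 or df["sex"].iloc[mk] == 1:
            msg = (f"family {row.family_id}: parent sex codes inconsistent for child "
                   f"{row.individual_id}")
            if on_inconsistent_sex == "error":
                raise ValueError(msg)
            logger.warning("%s; skipped", msg)
            continue
        key = (row.family_id, row.maternal_id, row.paternal_id)
        if key in seen_parent_pairs:
            raise ValueError(
                f"family {row.family_id}: multiple children share parents "
                f"({seen_parent_pairs[key]}, {row.individual_id}); one case child per "
                "family is required — pre-split the family"
            )
        seen_parent_pairs[key] = row.individual_id
        if mk in used or fk in used or k in used:
            raise ValueError(f"individual reused across triads in family {row.family_id}")
        used.update((mk, fk, k))
        triads.append((mk, fk, k))
    return np.array(triads, dtype=np.int64).reshape(-1, 3)
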