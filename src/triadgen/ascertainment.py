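"""Study generation: stratified sampling, trait assignment, retention.

The generation loop repeatedly (1) draws a subpopulation by its proportion,
(2) draws a fragment plan and one pool row per fragment, (3) assembles the
candidate offspring's *pathway* genotypes only, computes the pathway
indicators, draws exposure and phenotype, and (4) materializes the full
triad genome only when the candidate is retained under the study design.
Because the phenotype depends on the offspring genotype solely through the
pathway loci — which are fixed at stage 1 along with every fragment's pool
row — deferring the rest of the genome to stage 2 is distributionally
identical to generating whole genomes and filtering, while making
rare-disease ascertainment (baseline risk ~10^-3) tractable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .complementer import ComplementedPool
from .fragmenter import HotspotTrack
from .io_plink import MarkerMap, SampleTable, write_plink
from .resampler import _triad_sample_table, draw_batch_plans, splice_batch
from .traits import (
    PathwaySpec,
    TraitModel,
    assign_dichotomous,
    assign_exposure,
    assign_quantitative,
    pathway_indicator_matrix,
)

__all__ = [
    "SubpopulationSpec",
    "StudyDesign",
    "SimulatedStudy",
    "retention_rule",
    "generate_study",
    "strip_parents",
]

logger = logging.getLogger(__name__)

_DESIGNS = ("case_parents", "control_parents", "case_only", "case_control", "population_qt")


@dataclass
class SubpopulationSpec:
    """One source subpopulation: its resampling pool, its share of the
    simulated population, and its baseline (log risk or trait mean)."""

    pool: ComplementedPool
    proportion: float
    alpha: float
    exposure_prevalence: float = 0.0
    label: str = ""


@dataclass
class StudyDesign:
    kind: str
    n_target: int
    control_ratio: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in _DESIGNS:
            raise ValueError(f"unknown design {self.kind!r}")
        if self.n_target < 1:
            raise ValueError("n_target must be >= 1")
        if self.kind == "case_control" and self.control_ratio <= 0:
            raise ValueError("control_ratio must be positive")


def retention_rule(design: StudyDesign, affected: bool, quotas: dict | None = None) -> bool:
    """Single-candidate retention decision (vectorized internally elsewhere).

    ``quotas``: remaining {"cases": int, "controls": int} for case_control.
    """
    if design.kind in ("case_parents", "case_only"):
        return bool(affected)
    if design.kind == "control_parents":
        return not affected
    if design.kind == "population_qt":
        return True
    quotas = quotas or {}
    if affected:
        return quotas.get("cases", 0) > 0
    return quotas.get("controls", 0) > 0


@dataclass
class SimulatedStudy:
    """Retained simulated records with phenotype/exposure/subpop labels."""

    marker_map: MarkerMap
    mothers: np.ndarray | None
    fathers: np.ndarray | None
    children: np.ndarray
    phenotype: np.ndarray
    exposure: np.ndarray
    subpop: np.ndarray
    design: StudyDesign
    trait_kind: str
    candidates_used: int = 0

    @property
    def has_parents(self) -> bool:
        return self.mothers is not None

    @property
    def n_records(self) -> int:
        return self.children.shape[0]

    def sample_table(self) -> SampleTable:
        if self.trait_kind == "dichotomous":
            pheno = np.where(self.phenotype > 0, 2.0, 1.0)
        else:
            pheno = np.full(self.n_records, -9.0)
        if self.has_parents:
            return _triad_sample_table(self.n_records, pheno)
        recs = [
            (f"sim{i + 1:06d}", "child", "0", "0", 0, float(pheno[i]))
            for i in range(self.n_records)
        ]
        return SampleTable(pd.DataFrame(recs, columns=list(SampleTable.COLUMNS)))

    def genotype_matrix(self) -> np.ndarray:
        if not self.has_parents:
            return self.children
        n, p = self.children.shape
        out = np.empty((3 * n, p), dtype=self.children.dtype)
        out[0::3] = self.mothers
        out[1::3] = self.fathers
        out[2::3] = self.children
        return out

    def write(self, prefix: str | Path, dialect: str = "bed") -> list[Path]:
        """PLINK files plus a tab-separated phenotype/exposure sidecar."""
        prefix = Path(prefix)
        paths = write_plink(prefix, self.marker_map, self.sample_table(),
                            self.genotype_matrix(), dialect)
        side = prefix.parent / (prefix.name + ".pheno.tsv")
        pd.DataFrame(
            {
                "family_id": [f"sim{i + 1:06d}" for i in range(self.n_records)],
                "individual_id": ["child"] * self.n_records,
                "phenotype": self.phenotype,
                "exposure": self.exposure,
                "subpop": self.subpop,
            }
        ).to_csv(side, sep="\t", index=False)
        return paths + [side]


def strip_parents(study: SimulatedStudy) -> SimulatedStudy:
    """Offspring-only view (case-only / case-control samples); idempotent."""
    if not study.has_parents:
        return study
    return replace(study, mothers=None, fathers=None)


def _subpop_model(model: TraitModel, sp: SubpopulationSpec) -> TraitModel:
    m = model.with_alpha(sp.alpha)
    return replace(m, exposure_prevalence=sp.exposure_prevalence)


def _gather_pathway_genotypes(
    pool: ComplementedPool,
    marker_map: MarkerMap,
    loci: np.ndarray,
    boundaries: dict[str, np.ndarray],
    rows: dict[str, np.ndarray],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Child/mother/father genotypes at ``loci`` for a candidate batch,
    using the pool row drawn for the fragment containing each locus."""
    slices = marker_map.chrom_slices()
    n = next(iter(rows.values())).shape[0]
    child = np.empty((n, loci.size), dtype=np.int8)
    mother = np.empty((n, loci.size), dtype=np.int8)
    father = np.empty((n, loci.size), dtype=np.int8)
    for li, locus in enumerate(loci):
        chrom = marker_map.chromosome[locus]
        local = int(locus - slices[chrom].start)
        b = boundaries[chrom]
        frag = (b <= local).sum(axis=1) if b.shape[1] else np.zeros(n, dtype=np.int64)
        r = rows[chrom][np.arange(n), frag]
        child[:, li] = pool.children[r, locus]
        mother[:, li] = pool.mothers[r, locus]
        father[:, li] = pool.fathers[r, locus]
    return child, mother, father


def generate_study(
    subpops: list[SubpopulationSpec],
    pathways: PathwaySpec,
    model: TraitModel,
    design: StudyDesign,
    track: HotspotTrack,
    k_per_chromosome,
    rng: np.random.Generator,
    marker_map: MarkerMap = None,
    candidate_cap: int = 10_000_000,
    full_generation: bool = False,
) -> SimulatedStudy:
    """Run the stratified generation loop until the design's quota is met.

    ``marker_map`` is the shared marker panel (identical across
    subpopulations).  ``full_generation=True`` materializes every
    candidate's whole genome before filtering (the reference path used to
    validate the two-stage optimization); default is causal-first.
    """
    if marker_map is None:
        raise ValueError("marker_map is required")
    props = np.array([sp.proportion for sp in subpops], dtype=float)
    if not np.isclose(props.sum(), 1.0):
        raise ValueError("subpopulation proportions must sum to 1")
    for sp in subpops:
        if sp.pool.n_markers != marker_map.n_markers:
            raise ValueError("marker panels must be identical across subpopulations")
    if design.kind == "population_qt" and model.trait_kind != "quantitative":
        raise ValueError("population_qt requires a quantitative trait model")
    if design.kind != "population_qt" and model.trait_kind != "dichotomous":
        raise ValueError(f"design {design.kind} requires a dichotomous trait model")
    models = [_subpop_model(model, sp) for sp in subpops]
    loci = pathways.all_loci

    need_cases = design.n_target
    need_controls = (
        int(round(design.n_target * design.control_ratio))
        if design.kind == "case_control" else 0
    )
    total_needed = need_cases + need_controls if design.kind == "case_control" else design.n_target

    out_m, out_f, out_c = [], [], []
    out_pheno, out_expo, out_sub = [], [], []
    retained = 0
    candidates_used = 0
    batch = total_needed if design.kind == "population_qt" else max(256, 2 * total_needed)
    rate_est = None
    while retained < total_needed:
        if candidates_used >= candidate_cap:
            raise RuntimeError(
                f"candidate cap {candidate_cap} reached with {retained}/{total_needed} "
                "records retained — is the retention probability zero under this design?"
            )
        batch = min(batch, candidate_cap - candidates_used)
        sub = rng.choice(len(subpops), size=batch, p=props)
        pheno = np.empty(batch, dtype=float)
        expo = np.empty(batch, dtype=np.int64)
        stage: dict[int, dict] = {}
        for si in range(len(subpops)):
            members = np.flatnonzero(sub == si)
            if members.size == 0:
                continue
            sp, m_si = subpops[si], models[si]
            boundaries, rows, swap = draw_batch_plans(
                track, k_per_chromosome, members.size, sp.pool.size, rng
            )
            if full_generation:
                mm_, ff_, cc_ = splice_batch(sp.pool, marker_map, boundaries, rows, swap)
                X = pathway_indicator_matrix(cc_, pathways)
                stage[si] = {"members": members, "full": (mm_, ff_, cc_)}
            else:
                child_g, _, _ = _gather_pathway_genotypes(
                    sp.pool, marker_map, loci, boundaries, rows
                )
                if np.any(child_g < 0):
                    raise ValueError("missing genotype at a pathway locus in the pool")
                split = np.cumsum([p.size for p in pathways.pathways])[:-1]
                X = np.column_stack(
                    [np.all(g >= 1, axis=1) for g in np.hsplit(child_g >= 1, split)]
                ).astype(np.int64)
                stage[si] = {
                    "members": members,
                    "boundaries": boundaries,
                    "rows": rows,
                    "swap": swap,
                }
            E = assign_exposure(m_si, members.size, rng)
            if model.trait_kind == "dichotomous":
                y = assign_dichotomous(m_si, X, E, rng).astype(float)
            else:
                y = assign_quantitative(m_si, X, E, rng)
            pheno[members] = y
            expo[members] = E
        candidates_used += batch

        keep = _vector_retention(design, model.trait_kind, pheno,
                                 need_cases, need_controls)
        # cap in candidate order so a quota never overshoots (the retained
        # subpopulation mix must not depend on output assembly order)
        excess = retained + int(keep.sum()) - total_needed
        if excess > 0:
            keep[np.flatnonzero(keep)[-excess:]] = False
        if design.kind == "case_control":
            kept_cases = int((pheno[keep] > 0).sum())
            need_cases -= kept_cases
            need_controls -= int(keep.sum()) - kept_cases

        for si, st in stage.items():
            members = st["members"]
            local_keep = keep[members]
            if not local_keep.any():
                continue
            if full_generation:
                mm_, ff_, cc_ = st["full"]
                out_m.append(mm_[local_keep])
                out_f.append(ff_[local_keep])
                out_c.append(cc_[local_keep])
            else:
                idx = np.flatnonzero(local_keep)
                boundaries = {c: b[idx] for c, b in st["boundaries"].items()}
                rows = {c: r[idx] for c, r in st["rows"].items()}
                mm_, ff_, cc_ = splice_batch(
                    subpops[si].pool, marker_map, boundaries, rows, st["swap"][idx]
                )
                out_m.append(mm_)
                out_f.append(ff_)
                out_c.append(cc_)
            out_pheno.append(pheno[members][local_keep])
            out_expo.append(expo[members][local_keep])
            lab = subpops[si].label or str(si)
            out_sub.append(np.full(int(local_keep.sum()), lab, dtype=object))
        retained += int(keep.sum())

        if rate_est is None:
            rate = max(keep.mean(), 1.0 / batch)
            rate_est = rate
        remaining = total_needed - retained
        if remaining > 0:
            batch = int(min(500_000, max(256, math.ceil(1.2 * remaining / rate_est))))

    study = SimulatedStudy(
        marker_map=marker_map,
        mothers=np.vstack(out_m),
        fathers=np.vstack(out_f),
        children=np.vstack(out_c),
        phenotype=np.concatenate(out_pheno),
        exposure=np.concatenate(out_expo),
        subpop=np.concatenate(out_sub),
        design=design,
        trait_kind=model.trait_kind,
        candidates_used=candidates_used,
    )
    logger.info(
        "design=%s retained=%d candidates=%d retention_rate=%.4g",
        design.kind, study.n_records, candidates_used,
        study.n_records / max(candidates_used, 1),
    )
    return study


def _vector_retention(
    design: StudyDesign, trait_kind: str, pheno: np.ndarray,
    need_cases: int, need_controls: int,
) -> np.ndarray:
    if design.kind == "population_qt":
        return np.ones(pheno.shape[0], dtype=bool)
    affected = pheno > 0
    if design.kind in ("case_parents", "case_only"):
        return affected
    if design.kind == "control_parents":
        return ~affected
    # case_control: fill both quotas from the single candidate stream
    keep = np.zeros(pheno.shape[0], dtype=bool)
    case_pos = np.flatnonzero(affected)[:max(need_cases, 0)]
    ctrl_pos = np.flatnonzero(~affected)[:max(need_controls, 0)]
    keep[case_pos] = True
    keep[ctrl_pos] = True
    return keep
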