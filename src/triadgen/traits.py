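"""Pathway indicators, penetrance / quantitative trait models, exposure.

A *pathway* is a set of SNP loci; its indicator X is 1 when the offspring
carries at least one variant (counted) allele at every locus in the set
(dominant coding per SNP; single SNPs are 1-SNP pathways).  With p pathways
and a dichotomous exposure E, the models are log-linear in the indicators:

- dichotomous:   log P(affected | X, E) = alpha + beta'X + theta*E + gamma'(E*X)
- quantitative:  Y = alpha + beta'X + theta*E + gamma'(E*X) + eps,
                 eps ~ Normal(0, sigma)

so pathway contributions to risk combine multiplicatively on the relative
risk scale, and additively on the original scale for quantitative traits.
Effects may be supplied as odds ratios instead of relative risks; each
effect cell is then converted against the baseline risk before use.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, replace

import numpy as np

from .io_plink import MISSING

__all__ = [
    "PathwaySpec",
    "TraitModel",
    "pathway_indicator",
    "pathway_indicator_matrix",
    "linear_predictor",
    "penetrance",
    "or_to_rr",
    "assign_exposure",
    "assign_dichotomous",
    "assign_quantitative",
]


@dataclass
class PathwaySpec:
    """p ordered pathways of marker indices; indices globally distinct."""

    pathways: list[np.ndarray]

    def __post_init__(self) -> None:
        self.pathways = [np.asarray(p, dtype=np.int64) for p in self.pathways]
        if any(p.size < 1 for p in self.pathways):
            raise ValueError("every pathway needs at least one locus")
        flat = np.concatenate(self.pathways)
        if len(np.unique(flat)) != flat.size:
            raise ValueError("pathway loci must be globally distinct")

    @property
    def n_pathways(self) -> int:
        return len(self.pathways)

    @property
    def all_loci(self) -> np.ndarray:
        return np.concatenate(self.pathways)


@dataclass
class TraitModel:
    """Parameters of the trait-assignment models.

    ``alpha`` is the log baseline risk (dichotomous) or the baseline trait
    mean (quantitative) among unexposed non-carriers; ``beta``/``gamma`` are
    per-pathway log relative risks / interaction log relative risks on the
    dichotomous scale, or additive mean shifts on the quantitative scale;
    ``theta`` is the exposure main effect on the same scale.  With
    ``effect_scale="OR"`` the dichotomous effects are interpreted as odds
    ratios and converted cellwise against ``exp(alpha)``.
    """

    trait_kind: str  # "dichotomous" | "quantitative"
    alpha: float
    beta: np.ndarray
    theta: float = 0.0
    gamma: np.ndarray | None = None
    effect_scale: str = "RR"
    sigma: float = 1.0
    exposure_prevalence: float = 0.0

    def __post_init__(self) -> None:
        if self.trait_kind not in ("dichotomous", "quantitative"):
            raise ValueError(f"unknown trait_kind {self.trait_kind!r}")
        if self.effect_scale not in ("RR", "OR"):
            raise ValueError(f"unknown effect_scale {self.effect_scale!r}")
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        if self.gamma is None:
            self.gamma = np.zeros_like(self.beta)
        self.gamma = np.atleast_1d(np.asarray(self.gamma, dtype=float))
        if self.gamma.shape != self.beta.shape:
            raise ValueError("beta and gamma must have equal length")
        if not 0.0 <= self.exposure_prevalence <= 1.0:
            raise ValueError("exposure_prevalence must lie in [0, 1]")
        if self.trait_kind == "quantitative" and self.sigma <= 0:
            raise ValueError("sigma must be positive for a quantitative trait")
        if self.trait_kind == "dichotomous":
            self.validate_penetrance()

    @property
    def n_pathways(self) -> int:
        return len(self.beta)

    # -- OR -> RR conversion -------------------------------------------------
    def _converted_to_rr(self) -> "TraitModel":
        p0 = math.exp(self.alpha)
        conv = lambda lo: math.log(or_to_rr(math.exp(lo), p0))  # noqa: E731
        return replace(
            self,
            beta=np.array([conv(b) for b in self.beta]),
            theta=conv(self.theta),
            gamma=np.array([conv(g) for g in self.gamma]),
            effect_scale="RR",
        )

    def as_rr(self) -> "TraitModel":
        """The model with all effects on the (log) relative-risk scale."""
        if self.effect_scale == "RR":
            return self
        return self._converted_to_rr()

    def with_alpha(self, alpha: float) -> "TraitModel":
        """Copy with a different baseline (used per subpopulation).  OR
        effects are re-converted against the new baseline."""
        return replace(self, alpha=alpha)

    def validate_penetrance(self) -> None:
        """Reject dichotomous models whose penetrance exceeds 1 at any
        realizable (X, E) cell."""
        m = self.as_rr()
        p = m.n_pathways
        exposures = (0, 1) if (m.theta != 0 or np.any(m.gamma != 0)
                               or m.exposure_prevalence > 0) else (0,)
        for xs in itertools.product((0, 1), repeat=p):
            for e in exposures:
                pr = math.exp(linear_predictor(m, np.array(xs, float), e))
                if pr > 1.0 + 1e-12:
                    raise ValueError(
                        f"penetrance {pr:.4g} > 1 at X={xs}, E={e}; "
                        "lower the baseline or the effect sizes"
                    )


def or_to_rr(or_value: float, baseline_risk: float) -> float:
    """The relative risk giving odds ratio ``or_value`` against baseline
    risk ``p0``: RR = OR / (1 - p0 + p0*OR).  For a rare disease OR ~ RR."""
    if or_value <= 0:
        raise ValueError("odds ratio must be positive")
    if not 0.0 < baseline_risk < 1.0:
        raise ValueError("baseline risk must lie strictly in (0, 1)")
    rr = or_value / (1.0 - baseline_risk + baseline_risk * or_value)
    if rr * baseline_risk > 1.0 + 1e-12:
        raise ValueError("conversion yields risk > 1")
    return rr


def pathway_indicator(child_genotypes: np.ndarray, pathway: np.ndarray) -> int:
    """1 iff the offspring carries >=1 counted allele at every pathway locus."""
    g = np.asarray(child_genotypes)[np.asarray(pathway, dtype=np.int64)]
    if np.any(g == MISSING):
        raise ValueError("missing genotype at a pathway locus")
    return int(np.all(g >= 1))


def pathway_indicator_matrix(children: np.ndarray, pathways: PathwaySpec) -> np.ndarray:
    """(n, p) indicator matrix for a block of offspring genotype rows."""
    children = np.atleast_2d(children)
    cols = []
    for pw in pathways.pathways:
        g = children[:, pw]
        if np.any(g == MISSING):
            raise ValueError("missing genotype at a pathway locus")
        cols.append(np.all(g >= 1, axis=1))
    return np.column_stack(cols).astype(np.int64)


def linear_predictor(model: TraitModel, X: np.ndarray, E) -> np.ndarray | float:
    """alpha + beta'X + theta*E + gamma'(E*X); rows of X may be batched."""
    m = model.as_rr() if model.trait_kind == "dichotomous" else model
    X = np.asarray(X, dtype=float)
    E = np.asarray(E, dtype=float)
    eta = m.alpha + X @ m.beta + m.theta * E + (X * E[..., None] if X.ndim > 1 else X * E) @ m.gamma
    return float(eta) if np.ndim(eta) == 0 else eta


def penetrance(model: TraitModel, X: np.ndarray, E=0) -> np.ndarray | float:
    """exp(linear predictor); errors if any cell exceeds 1."""
    if model.trait_kind != "dichotomous":
        raise ValueError("penetrance is defined for dichotomous models only")
    pr = np.exp(linear_predictor(model, X, E))
    if np.any(np.asarray(pr) > 1.0 + 1e-12):
        bad = np.argmax(np.atleast_1d(pr))
        raise ValueError(f"penetrance > 1 for record {bad}; invalid configuration")
    return pr


def assign_exposure(model: TraitModel, n: int, rng: np.random.Generator) -> np.ndarray:
    """Bernoulli(exposure_prevalence) draws, independent of genotype."""
    return (rng.random(n) < model.exposure_prevalence).astype(np.int64)


def assign_dichotomous(
    model: TraitModel, X: np.ndarray, E, rng: np.random.Generator
) -> np.ndarray:
    """Affected indicator ~ Bernoulli(penetrance(X, E))."""
    pr = np.atleast_1d(np.asarray(penetrance(model, X, E), dtype=float))
    return (rng.random(pr.shape[0]) < pr).astype(np.int64)


def assign_quantitative(
    model: TraitModel, X: np.ndarray, E, rng: np.random.Generator
) -> np.ndarray:
    """Trait value = linear predictor + Normal(0, sigma) error."""
    if model.trait_kind != "quantitative":
        raise ValueError("model is not quantitative")
    eta = np.atleast_1d(np.asarray(linear_predictor(model, X, E), dtype=float))
    return eta + rng.normal(0.0, model.sigma, size=eta.shape[0])
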