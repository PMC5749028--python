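"""Evaluation battery and analytic-recovery estimators.

Covers: pairwise genotype correlation (LD) comparison between a source
panel and simulated replicates, LD-decay curves, exact binomial prediction
intervals for minor allele frequencies and their empirical coverage, the
transmission disequilibrium test (TDT), the matched case-complement
conditional logistic estimator for case-parent studies, and cohort fits
(least squares / log-binomial / logistic) for population samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_plink import MISSING, MarkerMap

__all__ = [
    "genotype_correlation",
    "pairwise_r",
    "ld_comparison",
    "LDReport",
    "ld_decay_curve",
    "maf_prediction_interval",
    "maf_coverage_report",
    "tdt_test",
    "fit_case_complement",
    "CaseComplementFit",
    "fit_cohort",
]


def genotype_correlation(g1: np.ndarray, g2: np.ndarray) -> float:
    """Pearson correlation of genotype counts over pairwise-complete entries.

    NaN (flagged, to be excluded) when either vector is constant or fewer
    than two complete pairs remain.
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    ok = (g1 != MISSING) & (g2 != MISSING)
    if ok.sum() < 2:
        raise ValueError("fewer than two complete pairs")
    a, b = g1[ok], g2[ok]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def _qualifying_pairs(marker_map: MarkerMap, window_bp: int):
    """Same-chromosome marker-index pairs (i < j) with bp distance <= window,
    organized per chromosome as (start_offset, list of (lag, j_indices))."""
    out = {}
    for chrom, sl in marker_map.chrom_slices().items():
        bp = marker_map.bp_pos[sl]
        n = len(bp)
        lags = []
        for lag in range(1, n):
            dist = bp[lag:] - bp[:-lag]
            sel = np.flatnonzero(dist <= window_bp)
            if sel.size == 0:
                break
            lags.append((lag, sel))
        out[chrom] = (sl.start, lags)
    return out


def _standardize(G: np.ndarray) -> np.ndarray:
    """Column z-scores (population SD); constant columns become all-NaN."""
    G = np.asarray(G, dtype=np.float64)
    mu = G.mean(axis=0)
    sd = G.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = (G - mu) / sd
    Z[:, sd == 0] = np.nan
    return Z


def pairwise_r(
    genotypes: np.ndarray, marker_map: MarkerMap, window_bp: int = 200_000
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Genotype correlations for all same-chromosome pairs within the bp
    window.  Returns (i, j, r); r is NaN for pairs with a constant member.
    Assumes a complete (no-missing) matrix — the generated panels are.
    """
    Z = np.ascontiguousarray(_standardize(genotypes))
    n = genotypes.shape[0]
    slices = marker_map.chrom_slices()
    ii, jj, rr = [], [], []
    for chrom, (start, lags) in _qualifying_pairs(marker_map, window_bp).items():
        stop = slices[chrom].stop
        for lag, sel in lags:
            # contiguous views keep the banded products cache-friendly
            prod = np.einsum("ni,ni->i", Z[:, start : stop - lag], Z[:, start + lag : stop])
            ii.append(start + sel)
            jj.append(start + sel + lag)
            rr.append(prod[sel] / n)
    if not ii:
        return (np.empty(0, np.int64),) * 2 + (np.empty(0),)
    return np.concatenate(ii), np.concatenate(jj), np.concatenate(rr)


@dataclass
class LDReport:
    pairs: pd.DataFrame  # i, j, r_source, r_sim_mean, abs_diff
    summary_correlation: float
    frac_within_tol: float  # mean per-replicate fraction with |dr| < tol
    frac_exceed_rare: float  # fraction of exceedances involving a rare SNP
    n_pairs: int


def ld_comparison(
    source_genotypes: np.ndarray,
    simulated_replicates,
    marker_map: MarkerMap,
    window_bp: int = 200_000,
    tol: float = 0.1,
    source_maf: np.ndarray | None = None,
    rare_threshold: float = 0.02,
) -> LDReport:
    """Compare source pairwise LD with simulated replicates.

    ``simulated_replicates`` is an iterable of genotype matrices on the same
    marker panel.  Reports the correlation between source r and the
    across-replicate mean r, the average per-replicate fraction of pairs
    with |r_sim - r_source| < ``tol``, and the share of exceedances (of the
    mean-r difference) involving a SNP rarer than ``rare_threshold``.
    """
    ii, jj, r_src = pairwise_r(source_genotypes, marker_map, window_bp)
    sum_r = np.zeros_like(r_src)
    cnt_r = np.zeros_like(r_src)
    frac_within = []
    n_rep = 0
    for rep in simulated_replicates:
        _, _, r_sim = pairwise_r(rep, marker_map, window_bp)
        ok = ~np.isnan(r_sim) & ~np.isnan(r_src)
        sum_r[ok] += r_sim[ok]
        cnt_r[ok] += 1
        frac_within.append(np.mean(np.abs(r_sim[ok] - r_src[ok]) < tol))
        n_rep += 1
    if n_rep == 0:
        raise ValueError("at least one simulated replicate is required")
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_r = np.where(cnt_r > 0, sum_r / np.maximum(cnt_r, 1), np.nan)
    ok = ~np.isnan(mean_r) & ~np.isnan(r_src)
    summary = float(np.corrcoef(r_src[ok], mean_r[ok])[0, 1])
    exceed = ok & (np.abs(mean_r - r_src) >= tol)
    if source_maf is not None and exceed.any():
        rare = (source_maf[ii] < rare_threshold) | (source_maf[jj] < rare_threshold)
        frac_rare = float(rare[exceed].mean())
    else:
        frac_rare = 0.0 if not exceed.any() else float("nan")
    pairs = pd.DataFrame(
        {"i": ii, "j": jj, "r_source": r_src, "r_sim_mean": mean_r,
         "abs_diff": np.abs(mean_r - r_src)}
    )
    return LDReport(
        pairs=pairs,
        summary_correlation=summary,
        frac_within_tol=float(np.mean(frac_within)),
        frac_exceed_rare=frac_rare,
        n_pairs=int(ok.sum()),
    )


def ld_decay_curve(
    genotypes: np.ndarray,
    marker_map: MarkerMap,
    window_bp: int = 200_000,
    n_bins: int = 20,
) -> pd.DataFrame:
    """Mean squared genotype correlation (r^2) binned by inter-SNP distance.

    Equal-width bins over (0, window_bp]; empty bins carry NaN (flagged) and
    their occupancy is reported.
    """
    ii, jj, r = pairwise_r(genotypes, marker_map, window_bp)
    if ii.size == 0:
        raise ValueError("no qualifying pairs")
    dist = marker_map.bp_pos[jj] - marker_map.bp_pos[ii]
    ok = ~np.isnan(r)
    edges = np.linspace(0, window_bp, n_bins + 1)
    which = np.clip(np.digitize(dist, edges[1:], right=True), 0, n_bins - 1)
    mean_r2 = np.full(n_bins, np.nan)
    count = np.zeros(n_bins, dtype=np.int64)
    for b in range(n_bins):
        sel = ok & (which == b)
        count[b] = int(sel.sum())
        if count[b]:
            mean_r2[b] = float(np.mean(r[sel] ** 2))
    return pd.DataFrame(
        {"bin_lo": edges[:-1], "bin_hi": edges[1:], "mean_r2": mean_r2, "n_pairs": count}
    )


def maf_prediction_interval(
    maf0: float, n_alleles: int, level: float = 0.95
) -> tuple[float, float]:
    """Exact binomial prediction interval for an observed MAF in a fresh
    sample of ``n_alleles`` alleles, treating ``maf0`` as the true MAF."""
    if not 0.0 <= maf0 <= 1.0:
        raise ValueError("maf0 must lie in [0, 1]")
    if n_alleles < 1:
        raise ValueError("n_alleles must be >= 1")
    a = (1.0 - level) / 2.0
    lo = stats.binom.ppf(a, n_alleles, maf0)
    hi = stats.binom.ppf(1.0 - a, n_alleles, maf0)
    if maf0 == 0.0:
        lo = hi = 0.0
    elif maf0 == 1.0:
        lo = hi = n_alleles
    return float(lo) / n_alleles, float(hi) / n_alleles


def maf_coverage_report(
    source_maf: np.ndarray,
    replicate_mafs: np.ndarray,
    n_alleles: int,
    level: float = 0.95,
) -> dict:
    """Per-SNP empirical coverage of the exact binomial prediction interval.

    ``replicate_mafs``: (n_replicates, n_snps) founder MAFs of simulated
    samples.  Coverage of a SNP is the fraction of replicates whose MAF lies
    inside the interval built from ``source_maf`` and ``n_alleles``.
    """
    replicate_mafs = np.atleast_2d(replicate_mafs)
    if replicate_mafs.shape[0] < 2:
        raise ValueError("at least two replicates are required")
    lo = np.empty(source_maf.size)
    hi = np.empty(source_maf.size)
    for s, p0 in enumerate(source_maf):
        lo[s], hi[s] = maf_prediction_interval(float(p0), n_alleles, level)
    eps = 0.5 / n_alleles  # half-allele slack absorbs float roundoff
    inside = (replicate_mafs >= lo[None, :] - eps) & (replicate_mafs <= hi[None, :] + eps)
    per_snp = inside.mean(axis=0)
    return {
        "per_snp": per_snp,
        "mean": float(np.mean(per_snp)),
        "median": float(np.median(per_snp)),
        "lo": lo,
        "hi": hi,
    }


def tdt_test(
    mothers: np.ndarray, fathers: np.ndarray, children: np.ndarray
) -> tuple[float, float, int, int]:
    """Transmission disequilibrium test at one marker.

    Counts transmissions ``b`` (variant transmitted) vs ``c`` (variant not
    transmitted) from heterozygous parents; chi-square = (b-c)^2/(b+c) on 1
    df.  Returns (chi2, p, b, c); (nan, nan, 0, 0) when no heterozygous
    parents are available.
    """
    m = np.asarray(mothers, dtype=np.int64)
    f = np.asarray(fathers, dtype=np.int64)
    c = np.asarray(children, dtype=np.int64)
    ok = (m != MISSING) & (f != MISSING) & (c != MISSING)
    m, f, c = m[ok], f[ok], c[ok]
    n_het = (m == 1).astype(np.int64) + (f == 1).astype(np.int64)
    # variant copies the child received from het parents
    b_fam = c - (m == 2).astype(np.int64) - (f == 2).astype(np.int64)
    use = n_het > 0
    b = int(b_fam[use].sum())
    n_trans = int(n_het[use].sum())
    c_count = n_trans - b
    if n_trans == 0:
        return float("nan"), float("nan"), 0, 0
    chi2 = (b - c_count) ** 2 / n_trans
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p, b, c_count


@dataclass
class CaseComplementFit:
    """Matched conditional-logistic estimates on the log-RR scale."""

    names: list[str]
    coef: np.ndarray
    se: np.ndarray
    rr: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    cov: np.ndarray
    n_pairs: int
    n_informative: int
    converged: bool

    def covers(self, truth_rr: np.ndarray) -> np.ndarray:
        """Whether each Wald 95% CI covers the given true RRs."""
        t = np.asarray(truth_rr, float)
        return (self.ci_low <= t) & (t <= self.ci_high)


def fit_case_complement(
    x_case: np.ndarray,
    x_comp: np.ndarray,
    exposure: np.ndarray | None = None,
    firth: bool = True,
    max_iter: int = 200,
    tol: float = 1e-10,
) -> CaseComplementFit:
    """Matched case-complement conditional logistic fit.

    Maximizes the pairwise conditional likelihood
    ``prod exp(eta_case) / (exp(eta_case) + exp(eta_comp))`` with
    ``eta = beta'X + gamma'(E*X)``; the baseline and the exposure main
    effect cancel within a pair, so only within-pair differences of X (and
    E*X) identify the model.  Pairs with identical features are dropped from
    the informative count.  Wald 95% CIs are formed on the log scale and
    reported exponentiated.

    By default Firth's bias-reduced score (Jeffreys-prior penalty) is used:
    with multi-SNP pathways the informative pairs for an interaction term
    can number only a few dozen per study, where the unpenalized maximum
    conditional likelihood estimate carries a first-order upward bias and
    may not exist under separation.  ``firth=False`` gives the plain
    maximum conditional likelihood fit.
    """
    x_case = np.atleast_2d(np.asarray(x_case, dtype=float))
    x_comp = np.atleast_2d(np.asarray(x_comp, dtype=float))
    if x_case.shape != x_comp.shape:
        raise ValueError("case and complement feature matrices must align")
    p = x_case.shape[1]
    d = x_case - x_comp
    names = [f"pathway{i + 1}" for i in range(p)]
    if exposure is not None:
        e = np.asarray(exposure, dtype=float)[:, None]
        d = np.hstack([d, e * d])
        names += [f"pathway{i + 1}:E" for i in range(p)]
    informative = np.any(d != 0, axis=1)
    n_inf = int(informative.sum())
    if n_inf == 0:
        raise ValueError("no informative pairs (all case/complement features concordant)")
    D = d[informative]
    beta = np.zeros(D.shape[1])
    converged = False
    for _ in range(max_iter):
        eta = D @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        grad = D.T @ (1.0 - mu)
        W = mu * (1.0 - mu)
        H = (D * W[:, None]).T @ D
        try:
            if firth:
                # hat diagonals h_i = w_i d_i' I^{-1} d_i; the modified
                # score adds h_i (1/2 - mu_i) per observation (y_i = 1)
                Hinv_D = np.linalg.solve(H, D.T)
                h = W * np.einsum("ij,ji->i", D, Hinv_D)
                grad = grad + D.T @ (h * (0.5 - mu))
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError as err:
            raise RuntimeError("singular information matrix (separation or "
                               "collinear pathway features)") from err
        # dampen very large steps for stability on sparse data
        if np.max(np.abs(step)) > 5.0:
            step *= 5.0 / np.max(np.abs(step))
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    if not converged:
        raise RuntimeError(f"no convergence after {max_iter} Newton iterations")
    eta = D @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    W = mu * (1.0 - mu)
    cov = np.linalg.inv((D * W[:, None]).T @ D)
    se = np.sqrt(np.diag(cov))
    z = stats.norm.ppf(0.975)
    return CaseComplementFit(
        names=names,
        coef=beta,
        se=se,
        rr=np.exp(beta),
        ci_low=np.exp(beta - z * se),
        ci_high=np.exp(beta + z * se),
        cov=cov,
        n_pairs=x_case.shape[0],
        n_informative=n_inf,
        converged=converged,
    )


def fit_cohort(
    X: np.ndarray,
    Y: np.ndarray,
    exposure: np.ndarray | None = None,
    subpop: np.ndarray | None = None,
    model_kind: str = "quantitative",
):
    """Cohort fits for population samples.

    quantitative: least squares of Y on the pathway indicators (plus E and
    E*X when exposure is given), with subpopulation intercepts when labels
    are present.  ``rr``: log-link binomial regression (relative risks);
    ``or``: logistic regression (odds ratios).  Returns a statsmodels
    results object; pathway coefficients are named ``pathway1..p``.
    """
    import statsmodels.api as sm

    X = np.atleast_2d(np.asarray(X, dtype=float))
    p = X.shape[1]
    cols = {f"pathway{i + 1}": X[:, i] for i in range(p)}
    if exposure is not None:
        e = np.asarray(exposure, dtype=float)
        cols["E"] = e
        for i in range(p):
            cols[f"pathway{i + 1}:E"] = X[:, i] * e
    df = pd.DataFrame(cols)
    if subpop is not None:
        labels = pd.Categorical(subpop)
        for lev in labels.categories[1:]:
            df[f"subpop[{lev}]"] = (labels == lev).astype(float)
    design = sm.add_constant(df, prepend=True)
    if model_kind == "quantitative":
        return sm.OLS(np.asarray(Y, float), design).fit()
    if model_kind == "rr":
        import warnings

        with warnings.catch_warnings():
            # log link on the binomial family is intentional (risk ratios)
            warnings.simplefilter("ignore")
            return sm.GLM(np.asarray(Y, float), design,
                          family=sm.families.Binomial(link=sm.families.links.Log())).fit()
    if model_kind == "or":
        return sm.Logit(np.asarray(Y, float), design).fit(disp=False)
    raise ValueError(f"unknown model_kind {model_kind!r}")
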