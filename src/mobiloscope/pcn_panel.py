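"""Proxy copy numbers (pCN) from coverage, and their association with climate.

A family's proxy copy number is the mean read depth over its consensus
sequence divided by the genome-wide mean depth of the same sample:

    pCN_f = mean_depth(consensus_f) / mean_depth(genome)

The ratio of mean depths is invariant to read length and sequencing depth and
already corrects for consensus length. Reads are aligned *all-hits*, so every
reported location contributes coverage; for a consensus whose two LTRs are
identical this counts LTR-derived reads at both LTR positions, a documented
mild upward bias.

Associations between per-family pCNs and bioclimatic variables are quantified
with a random-intercept linear mixed model (clade of origin as the grouping
factor, one covariate at a time as fixed effect), fitted by REML through a
profiled one-dimensional optimization over the variance ratio. The variance
explained by the fixed effects is summarized as the Nakagawa–Schielzeth
marginal R²:

    R²m = Var(Xβ) / (Var(Xβ) + σ²_clade + σ²_resid)
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io_align import AlignmentRecord

__all__ = [
    "LmmFit",
    "AssociationResult",
    "consensus_depth",
    "genome_mean_depth",
    "estimate_pcn",
    "pcn_table",
    "fit_random_intercept_lmm",
    "fit_ols",
    "marginal_r2",
    "associate_bioclim",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# coverage-based pCN
# ---------------------------------------------------------------------------

def _aligned_bases_by_reference(alignments: Sequence[AlignmentRecord]) -> dict[str, int]:
    totals: dict[str, int] = {}
    for rec in alignments:
        n = rec.aligned_len
        totals[rec.reference_name] = totals.get(rec.reference_name, 0) + n
    return totals


def consensus_depth(
    alignments: Sequence[AlignmentRecord],
    consensus_lengths: Mapping[str, int],
) -> dict[str, float]:
    """Mean per-base depth over each consensus; all-hits alignments all count.

    Families with no alignments get depth 0.0 (not an error).
    """
    totals = _aligned_bases_by_reference(alignments)
    unknown = set(totals) - set(consensus_lengths)
    if unknown:
        raise ValueError(f"alignments reference unknown consensus: {sorted(unknown)}")
    return {
        fam: totals.get(fam, 0) / length
        for fam, length in consensus_lengths.items()
    }


def genome_mean_depth(
    alignments: Sequence[AlignmentRecord],
    genome_length: int | Mapping[str, int],
) -> float:
    """Genome-wide mean depth (zero-depth positions included in the mean)."""
    L = (
        sum(genome_length.values())
        if isinstance(genome_length, Mapping)
        else int(genome_length)
    )
    if L <= 0:
        raise ValueError("genome length must be positive")
    total = sum(rec.aligned_len for rec in alignments)
    return total / L


def estimate_pcn(consensus_depth_f: float, genome_mean_depth: float) -> float:
    """pCN as the mean-depth ratio (copies per haploid genome equivalent)."""
    if genome_mean_depth <= 0:
        raise ValueError("genome mean depth must be positive to normalize pCN")
    if consensus_depth_f < 0:
        raise ValueError("consensus depth must be non-negative")
    return consensus_depth_f / genome_mean_depth


def pcn_table(
    depths: Mapping[str, float], genome_depth: float
) -> dict[str, float]:
    return {fam: estimate_pcn(d, genome_depth) for fam, d in depths.items()}


# ---------------------------------------------------------------------------
# random-intercept LMM via profiled REML
# ---------------------------------------------------------------------------

@dataclass
class LmmFit:
    beta: np.ndarray
    se: np.ndarray
    p_values: np.ndarray
    sigma2_clade: float
    sigma2_resid: float
    loglik_reml: float
    n: int
    n_groups: int


def _reml_pieces(y, X, group_idx, sizes, lam):
    """GLS quantities under V = sigma2 * (I + lam * Z Z')."""
    shrink = lam / (1.0 + lam * sizes)  # per-group
    def W(v):
        if v.ndim == 1:
            gs = np.bincount(group_idx, weights=v, minlength=sizes.size)
            return v - (shrink * gs)[group_idx]
        return np.column_stack([W(v[:, j]) for j in range(v.shape[1])])
    WX = W(X)
    Wy = W(y)
    XtWX = X.T @ WX
    beta = np.linalg.solve(XtWX, X.T @ Wy)
    r = y - X @ beta
    q = float(r @ W(r))
    return beta, XtWX, q


def _neg2_reml(y, X, group_idx, sizes, lam):
    n, p = X.shape
    _, XtWX, q = _reml_pieces(y, X, group_idx, sizes, lam)
    # floor guards the noiseless limit (q -> 0) against log(0)
    sigma2 = max(q / (n - p), np.finfo(float).tiny)
    logdet_v = float(np.sum(np.log1p(lam * sizes)))
    sign, logdet_xwx = np.linalg.slogdet(XtWX)
    if sign <= 0:
        return np.inf
    return (
        (n - p) * np.log(sigma2)
        + logdet_v
        + logdet_xwx
        + (n - p) * (1.0 + np.log(2.0 * np.pi))
    )


def fit_random_intercept_lmm(
    y: Sequence[float],
    x: Sequence[float],
    groups: Sequence,
) -> LmmFit:
    """REML fit of ``y ~ 1 + x + (1 | group)``.

    The criterion is profiled down to the single variance ratio
    ``lambda = sigma2_group / sigma2_resid`` and minimized on a log grid plus
    bounded scalar optimization; variance estimates are floored at zero.
    Fixed-effect p-values are two-sided Wald tests.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    labels, group_idx = np.unique(np.asarray(groups), return_inverse=True)
    n = y.size
    g = labels.size
    if x.size != n or group_idx.size != n:
        raise ValueError("y, x and groups must have equal length")
    if g < 2:
        raise ValueError("need at least 2 groups for a random intercept")
    if n <= g:
        raise ValueError("need more observations than groups")
    if np.ptp(x) == 0:
        raise ValueError("covariate is constant")
    X = np.column_stack([np.ones(n), x])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular fixed-effect design")
    sizes = np.bincount(group_idx).astype(float)

    def crit(log_lam):
        return _neg2_reml(y, X, group_idx, sizes, np.exp(log_lam))

    # coarse log-grid bracket, then Brent refinement; also test the boundary
    grid = np.linspace(-12.0, 8.0, 21)
    vals = [crit(t) for t in grid]
    t0 = grid[int(np.argmin(vals))]
    res = optimize.minimize_scalar(
        crit, bounds=(t0 - 2.0, t0 + 2.0), method="bounded",
        options={"xatol": 1e-6},
    )
    lam = float(np.exp(res.x))
    best = float(res.fun)
    at_zero = _neg2_reml(y, X, group_idx, sizes, 0.0)
    if at_zero <= best:
        lam, best = 0.0, at_zero

    beta, XtWX, q = _reml_pieces(y, X, group_idx, sizes, lam)
    p = X.shape[1]
    sigma2_resid = max(q / (n - p), 0.0)
    sigma2_clade = max(lam * sigma2_resid, 0.0)
    cov_beta = sigma2_resid * np.linalg.inv(XtWX)
    se = np.sqrt(np.diag(cov_beta))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, np.inf)
    p_values = 2.0 * stats.norm.sf(np.abs(z))
    return LmmFit(
        beta=beta,
        se=se,
        p_values=p_values,
        sigma2_clade=sigma2_clade,
        sigma2_resid=sigma2_resid,
        loglik_reml=-0.5 * best,
        n=n,
        n_groups=g,
    )


def fit_ols(y: Sequence[float], x: Sequence[float]) -> LmmFit:
    """Ordinary least squares ``y ~ 1 + x`` in the same result container.

    Used as the no-random-effect variant (no population-structure correction)
    and as the degenerate-input fallback when only one clade is present.
    ``sigma2_resid`` is the ML residual variance so that ``marginal_r2`` on
    this fit reduces to the classical R².
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    n = y.size
    if np.ptp(x) == 0:
        raise ValueError("covariate is constant")
    X = np.column_stack([np.ones(n), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    rss = float(r @ r)
    dof = n - X.shape[1]
    cov = (rss / dof) * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, np.inf)
    p_values = 2.0 * stats.norm.sf(np.abs(z))
    return LmmFit(
        beta=beta,
        se=se,
        p_values=p_values,
        sigma2_clade=0.0,
        sigma2_resid=rss / n,
        loglik_reml=float("nan"),
        n=n,
        n_groups=1,
    )


def marginal_r2(fit: LmmFit, x: Sequence[float]) -> float:
    """Nakagawa–Schielzeth marginal R²: fixed-effect variance over total."""
    x = np.asarray(x, dtype=float)
    fixed = fit.beta[0] + fit.beta[1] * x
    var_fixed = float(np.var(fixed))
    denom = var_fixed + fit.sigma2_clade + fit.sigma2_resid
    if denom == 0:
        raise ValueError("total variance is zero; marginal R2 undefined")
    return var_fixed / denom


# ---------------------------------------------------------------------------
# panel-wide association scan
# ---------------------------------------------------------------------------

@dataclass
class AssociationResult:
    family: str
    variable: str
    marginal_r2: float
    p_value: float
    significant: bool


def associate_bioclim(
    pcn: pd.DataFrame,
    bioclim: pd.DataFrame,
    clades: pd.Series | Sequence,
    alpha: float = 0.05,
    use_random_effect: bool = True,
) -> pd.DataFrame:
    """One mixed-model fit per (family, variable); variables entered separately.

    ``pcn`` is accessions x families, ``bioclim`` accessions x variables, both
    indexed by accession. Accessions with missing covariate values are dropped
    with a logged count. ``significant`` is a per-test p < alpha flag (no
    multiplicity correction by default, matching the per-test convention).
    With ``use_random_effect=False``, or when only one clade is present
    (degenerate mixed fit), an ordinary linear model is used instead.
    """
    clades = pd.Series(np.asarray(clades), index=pcn.index)
    common = pcn.index.intersection(bioclim.index)
    if len(common) < len(pcn):
        log.warning("dropping %d accessions absent from covariates", len(pcn) - len(common))
    results: list[AssociationResult] = []
    for variable in bioclim.columns:
        xv = bioclim.loc[common, variable]
        ok = xv.notna()
        if (~ok).any():
            log.warning("variable %s: dropped %d accessions with missing values",
                        variable, int((~ok).sum()))
        idx = common[ok.to_numpy()]
        x = bioclim.loc[idx, variable].to_numpy(dtype=float)
        grp = clades.loc[idx].to_numpy()
        for family in pcn.columns:
            yv = pcn.loc[idx, family].to_numpy(dtype=float)
            single_clade = len(np.unique(grp)) < 2
            if use_random_effect and not single_clade:
                fit = fit_random_intercept_lmm(yv, x, grp)
            else:
                if use_random_effect and single_clade:
                    warnings.warn(
                        f"single clade for family {family}; falling back to a "
                        "linear model without random effect",
                        stacklevel=2,
                    )
                fit = fit_ols(yv, x)
            r2 = marginal_r2(fit, x)
            p = float(fit.p_values[1])
            results.append(AssociationResult(family, variable, r2, p, p < alpha))
    return pd.DataFrame([vars(r) for r in results])
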