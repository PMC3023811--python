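"""Per-timepoint GFP+ vs GFP- differential expression.

The test statistic is an empirical-Bayes moderated t: per-gene pooled sample
variances s^2 (df residual degrees of freedom) are shrunk toward a prior
variance s0^2 with prior degrees of freedom d0,

    s2_shrunk = (d0*s0^2 + df*s^2) / (d0 + df)
    t_mod     = log2fc / sqrt(s2_shrunk * (1/n+ + 1/n-))

with p-values from a t distribution on d0 + df degrees of freedom. The prior
(d0, s0^2) is fitted by the method of moments on log s^2 under a scaled
inverse-chi-square prior for the true gene variances: the marginal of s^2 is
s0^2 * F(df, d0), so

    E[log s^2]   = log s0^2 + psi(df/2) - log(df/2) - psi(d0/2) + log(d0/2)
    Var[log s^2] = psi'(df/2) + psi'(d0/2)

which we solve with a Newton trigamma inverse. Log-scale moments are used
because raw moments of the F marginal diverge for small d0. When the observed
log-variance dispersion does not exceed the chi-square sampling component the
fit degenerates to full pooling (d0 = +inf, every gene assigned the common
variance, normal-theory p-values).

"Enriched" calls are one-directional (GFP+ above GFP-): two-sided p gated by
linear fold change >= fc_threshold and BH q <= fdr_threshold, both inclusive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .study import ExpressionStudy


class DEError(ValueError):
    pass


class DegenerateDataError(DEError):
    pass


@dataclass(frozen=True)
class ShrinkagePrior:
    """Scaled inverse-chi-square variance prior; d0 = +inf means full pooling."""

    d0: float
    s0_2: float

    def __post_init__(self) -> None:
        if self.d0 < 0:
            raise DEError("d0 must be >= 0")
        if self.s0_2 <= 0:
            raise DEError("s0_2 must be positive")


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every column onto the mean of the column order statistics.

    Ties within a column receive the average of the reference values at
    their tied ranks. Single-column input is returned unchanged.
    """
    if matrix.isna().any().any():
        raise DEError("quantile_normalize requires complete data")
    if matrix.shape[1] <= 1:
        return matrix.copy()
    values = matrix.to_numpy(dtype=float)
    reference = np.sort(values, axis=0).mean(axis=1)
    ranks = pd.DataFrame(values).rank(method="average").to_numpy()
    out = np.interp(ranks, np.arange(1, len(reference) + 1), reference)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def _trigamma_inverse(y: float, tol: float = 1e-10, max_iter: int = 100) -> float:
    """Solve psi'(x) = y for x > 0 by Newton iteration on the monotone map."""
    if y <= 0:
        return math.inf
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif) < tol * x:
            break
    return x


def estimate_prior(s2: np.ndarray, df: float) -> ShrinkagePrior:
    """Fit (d0, s0^2) from observed per-gene variances by log-scale moments.

    Falls back to full pooling (d0 = +inf, s0^2 = mean variance) when fewer
    than 10 genes are supplied or the variances are underdispersed relative
    to pure chi-square sampling noise.
    """
    s2 = np.asarray(s2, dtype=float)
    if df < 1:
        raise DEError("need residual df >= 1")
    if np.all(s2 <= 0):
        raise DegenerateDataError("all variances are zero")
    positive = s2[s2 > 0]
    if np.ptp(positive) == 0 and len(positive) == len(s2):
        return ShrinkagePrior(math.inf, float(positive[0]))
    if len(positive) < 10:
        return ShrinkagePrior(math.inf, float(np.mean(s2)))
    z = np.log(positive)
    evar = float(np.var(z, ddof=1)) - float(special.polygamma(1, df / 2))
    if evar <= 0:
        return ShrinkagePrior(math.inf, float(np.mean(s2)))
    d0 = 2.0 * _trigamma_inverse(evar)
    if not math.isfinite(d0):
        return ShrinkagePrior(math.inf, float(np.mean(s2)))
    log_s0_2 = (float(np.mean(z))
                - float(special.digamma(df / 2)) + math.log(df / 2)
                + float(special.digamma(d0 / 2)) - math.log(d0 / 2))
    return ShrinkagePrior(d0, math.exp(log_s0_2))


def moderated_t(study: ExpressionStudy, timepoint: str,
                prior: ShrinkagePrior | None = None,
                genotype: str = "wt") -> pd.DataFrame:
    """Moderated-t table for one timepoint's GFP+ vs GFP- contrast.

    Returns one row per gene with columns ``gene_id, timepoint, log2fc, fc,
    s2, s2_shrunk, t_mod, p`` (no multiplicity adjustment; see
    :func:`bh_fdr` / :func:`differential_expression`). ``prior=None`` fits
    the shrinkage prior from this contrast's variances;
    ``ShrinkagePrior(0, ...)`` reproduces the ordinary pooled two-sample t.
    """
    pos = study.sample_ids(timepoint=timepoint, gfp="+", genotype=genotype)
    neg = study.sample_ids(timepoint=timepoint, gfp="-", genotype=genotype)
    if len(pos) < 2 or len(neg) < 2:
        raise DEError(f"need >=2 replicates per group at {timepoint} ({genotype})")
    xp = study.matrix[pos].to_numpy(dtype=float)
    xn = study.matrix[neg].to_numpy(dtype=float)
    n_pos, n_neg = xp.shape[1], xn.shape[1]
    df = n_pos + n_neg - 2

    log2fc = xp.mean(axis=1) - xn.mean(axis=1)
    ssq = ((xp - xp.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) \
        + ((xn - xn.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    s2 = ssq / df

    if prior is None:
        prior = estimate_prior(s2, df)
    if math.isinf(prior.d0):
        s2_shrunk = np.full_like(s2, prior.s0_2)
        df_total = math.inf
    else:
        s2_shrunk = (prior.d0 * prior.s0_2 + df * s2) / (prior.d0 + df)
        df_total = prior.d0 + df

    se = np.sqrt(s2_shrunk * (1.0 / n_pos + 1.0 / n_neg))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = np.where(se > 0, log2fc / se, np.sign(log2fc) * np.inf)
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)

    return pd.DataFrame({
        "gene_id": study.genes,
        "timepoint": timepoint,
        "log2fc": log2fc,
        "fc": np.exp2(log2fc),
        "s2": s2,
        "s2_shrunk": s2_shrunk,
        "t_mod": t_mod,
        "p": p,
    }).reset_index(drop=True)


def bh_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise DEError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_enriched(records: pd.DataFrame, fc_threshold: float = 1.5,
                  fdr_threshold: float = 0.01,
                  universe: set[str] | None = None) -> list[str]:
    """Genes with fc >= fc_threshold and q <= fdr_threshold (inclusive).

    Optionally restricted to a trusted universe; ordered by descending fold
    change with ties broken by gene id.
    """
    if records.empty:
        return []
    if "q" not in records.columns:
        raise DEError("records need a q column; run bh_fdr first")
    keep = (records["fc"] >= fc_threshold) & (records["q"] <= fdr_threshold)
    sub = records.loc[keep, ["gene_id", "fc"]]
    if universe is not None:
        sub = sub[sub["gene_id"].isin(universe)]
    sub = sub.sort_values(["fc", "gene_id"], ascending=[False, True],
                          kind="mergesort")
    return list(sub["gene_id"])


def differential_expression(study: ExpressionStudy, timepoint: str,
                            fc_threshold: float = 1.5,
                            fdr_threshold: float = 0.01,
                            prior: ShrinkagePrior | None = None,
                            genotype: str = "wt",
                            universe: set[str] | None = None) -> pd.DataFrame:
    """Full DE table for one timepoint: moderated t, BH q, enriched flag.

    Rows are ranked by descending fold change (ties by gene id), the shape
    of a per-timepoint ranked report.
    """
    records = moderated_t(study, timepoint, prior=prior, genotype=genotype)
    records["q"] = bh_fdr(records["p"].to_numpy())
    enriched = set(call_enriched(records, fc_threshold, fdr_threshold, universe))
    records["enriched"] = records["gene_id"].isin(enriched)
    return records.sort_values(["fc", "gene_id"], ascending=[False, True],
                               kind="mergesort").reset_index(drop=True)
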