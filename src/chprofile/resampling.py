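"""Resampling null distributions for gene-list enrichment.

Random gene lists of equal size to an observed list are drawn uniformly
without replacement from the analysis universe and scored by a pluggable
statistic (e.g. "number of list genes with an X box upstream", "number of
distinct PNS-related annotation terms hit"). The null scores are fitted by a
normal (sample mean and SD, n-1 denominator), the observed score is assessed
by a one-sided upper-tail single-location z-test, and enrichment is reported
as observed / null mean. An empirical rank-based p is carried alongside the
normal-theory p as a distribution-free cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .motifs import MotifHitTable


class ResamplingError(ValueError):
    pass


#: A list scorer maps a gene-id list to a non-negative score, deterministically.
ListScorer = Callable[[Sequence[str]], float]


@dataclass
class NullDistribution:
    """Fitted resampling null for one observed list and scorer."""

    observed: float
    samples: np.ndarray
    mu: float
    sigma: float
    z: float | None          # None when the null is degenerate (sigma == 0)
    p: float | None          # one-sided upper-tail normal p
    p_empirical: float       # (1 + #{samples >= observed}) / (n_iter + 1)
    enrichment_factor: float | None  # observed / mu, None when mu == 0
    n_iter: int
    seed: int
    degenerate: bool

    def to_dict(self, include_samples: bool = False) -> dict:
        out = {
            "observed": self.observed, "mu": self.mu, "sigma": self.sigma,
            "z": self.z, "p": self.p, "p_empirical": self.p_empirical,
            "enrichment_factor": self.enrichment_factor,
            "n_iter": self.n_iter, "seed": self.seed, "degenerate": self.degenerate,
        }
        if include_samples:
            out["samples"] = self.samples.tolist()
        return out


def z_test(observed: float, mu: float, sigma: float) -> tuple[float, float]:
    """Single-location z-test, one-sided upper tail (over-representation)."""
    if sigma <= 0:
        raise ResamplingError("sigma must be positive for a z-test")
    z = (observed - mu) / sigma
    return z, float(stats.norm.sf(z))


def resample_null(gene_list: Sequence[str], universe: Sequence[str],
                  scorer: ListScorer, n_iter: int = 1000,
                  seed: int = 0) -> NullDistribution:
    """Score ``n_iter`` random same-size lists and fit the null.

    Sampling is uniform without replacement from the full universe (the
    observed list is not excluded). Fully reproducible from ``seed``. A
    constant null (sigma = 0) is flagged degenerate with z and p undefined.
    """
    gene_list = list(gene_list)
    universe_arr = np.asarray(list(universe), dtype=object)
    if len(gene_list) > len(universe_arr):
        raise ResamplingError("list larger than universe")
    if n_iter < 100:
        raise ResamplingError("need n_iter >= 100 for a usable null fit")
    rng = np.random.default_rng(seed)
    size = len(gene_list)
    samples = np.empty(n_iter)
    for i in range(n_iter):
        draw = universe_arr[rng.choice(len(universe_arr), size=size, replace=False)]
        samples[i] = scorer(list(draw))
    observed = float(scorer(gene_list))
    mu = float(samples.mean())
    sigma = float(samples.std(ddof=1))
    p_emp = float((1 + np.sum(samples >= observed)) / (n_iter + 1))
    if sigma == 0:
        return NullDistribution(observed, samples, mu, sigma, None, None,
                                p_emp, observed / mu if mu > 0 else None,
                                n_iter, seed, degenerate=True)
    z, p = z_test(observed, mu, sigma)
    return NullDistribution(observed, samples, mu, sigma, z, p, p_emp,
                            observed / mu if mu > 0 else None,
                            n_iter, seed, degenerate=False)


def xbox_scorer(hit_table: MotifHitTable | pd.DataFrame) -> ListScorer:
    """Scorer: number of list genes with >=1 upstream motif match.

    Genes absent from the hit table are counted as motif-free (collected on
    the scorer's ``missing`` attribute for inspection).
    """
    counts = hit_table.counts if isinstance(hit_table, MotifHitTable) else hit_table
    with_motif = set(counts.loc[counts["has_motif"], "gene_id"])
    known = set(counts["gene_id"])
    missing: set[str] = set()

    def score(genes: Sequence[str]) -> float:
        missing.update(g for g in genes if g not in known)
        return float(sum(1 for g in genes if g in with_motif))

    score.missing = missing  # type: ignore[attr-defined]
    score.__name__ = "xbox_scorer"
    return score


def pns_go_scorer(annotation: pd.DataFrame,
                  flag_column: str = "is_pns_related") -> ListScorer:
    """Scorer: distinct flagged terms annotating >=1 list member."""
    if flag_column not in annotation.columns:
        raise ResamplingError(f"annotation lacks {flag_column!r} column")
    flagged = annotation.loc[annotation[flag_column].astype(bool)]
    gene_to_terms: dict[str, frozenset[str]] = {
        g: frozenset(grp["term_id"])
        for g, grp in flagged.groupby("gene_id", sort=False)
    }

    def score(genes: Sequence[str]) -> float:
        terms: set[str] = set()
        for g in genes:
            terms |= gene_to_terms.get(g, frozenset())
        return float(len(terms))

    score.__name__ = "pns_go_scorer"
    return score
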