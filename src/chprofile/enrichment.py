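"""Gene-set over-representation: Fisher exact and EASE-corrected statistics.

Each test is a 2x2 contingency of a gene list (size n) against a gene set
(size m) within a trusted universe (size N) with overlap k:

    fold     = (k/m) / (n/N)
    p_fisher = P(X >= k),  X ~ Hypergeometric(N, m, n)   (one-sided, upper)
    p_ease   = P(X >= k-1)                               (EASE correction)

The hypergeometric upper tail is summed in log space (gammaln + logsumexp) so
that tails of order 1e-20 at N ~ 14,000 are computed accurately. The EASE
statistic removes one gene from the observed overlap before testing, a
conservative variant that damps significance driven by a single gene; k = 0
yields p_ease = 1.

Gene-set members that do not resolve against the declared universe are
dropped before m is counted (and reported), because the percentage reports
use resolved set totals as denominators.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp


class EnrichmentError(ValueError):
    pass


@dataclass(frozen=True)
class ContingencyResult:
    """One 2x2 over-representation test."""

    k: int       # list ∩ set overlap
    m: int       # set size within universe
    n: int       # list size within universe
    N: int       # universe size
    fold: float  # (k/m) / (n/N)
    p_fisher: float
    p_ease: float
    significant: bool  # p_fisher < alpha at construction time

    @property
    def percent(self) -> float:
        """100*k/m, the share of the set found in the list."""
        return 100.0 * self.k / self.m if self.m else float("nan")


def log_hypergeom_upper_tail(k: int, m: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, m, n), exact in log space."""
    if not (0 <= m <= N and 0 <= n <= N):
        raise EnrichmentError("need 0 <= m, n <= N")
    lo = max(0, n + m - N)
    hi = min(m, n)
    if k <= lo:
        return 1.0
    if k > hi:
        return 0.0
    j = np.arange(k, hi + 1)
    logpmf = (gammaln(m + 1) - gammaln(j + 1) - gammaln(m - j + 1)
              + gammaln(N - m + 1) - gammaln(n - j + 1) - gammaln(N - m - n + j + 1)
              - (gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1)))
    return float(min(1.0, np.exp(logsumexp(logpmf))))


def fisher_enrichment(gene_list: Iterable[str], gene_set: Iterable[str],
                      universe: Iterable[str], alpha: float = 0.05) -> ContingencyResult:
    """One-sided upper-tail Fisher exact over-representation test.

    List and set are resolved against (intersected with) the universe before
    counting; the significance flag is raw ``p_fisher < alpha``.
    """
    uni = set(universe)
    if not uni:
        raise EnrichmentError("empty universe")
    lst = set(gene_list) & uni
    st = set(gene_set) & uni
    k, m, n, N = len(lst & st), len(st), len(lst), len(uni)
    fold = (k / m) / (n / N) if m and n else 0.0
    p_fisher = log_hypergeom_upper_tail(k, m, n, N)
    p_ease = 1.0 if k == 0 else log_hypergeom_upper_tail(k - 1, m, n, N)
    return ContingencyResult(k, m, n, N, fold, p_fisher, p_ease, p_fisher < alpha)


def ease_fisher(gene_list: Iterable[str], gene_set: Iterable[str],
                universe: Iterable[str], alpha: float = 0.05) -> ContingencyResult:
    """As :func:`fisher_enrichment` but flag significance on the EASE p."""
    res = fisher_enrichment(gene_list, gene_set, universe, alpha)
    return ContingencyResult(res.k, res.m, res.n, res.N, res.fold,
                             res.p_fisher, res.p_ease, res.p_ease < alpha)


def format_percent(value: float, digits: int = 1) -> str:
    """Round-half-up percentage formatting (matches printed-table style)."""
    q = Decimal(10) ** -digits
    return str(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def enrichment_table(lists: Mapping[str, Iterable[str]],
                     collections: Mapping[str, Iterable[str]],
                     universe: Iterable[str],
                     alpha: float = 0.05) -> pd.DataFrame:
    """Summary table: one row per gene set, per-timepoint overlap cells.

    Each timepoint contributes columns ``{tp}_k``, ``{tp}_percent`` (100*k/m,
    one decimal, round-half-up), ``{tp}_p`` and ``{tp}_star`` (raw
    ``p_fisher < alpha``; no cross-row multiplicity correction) plus a
    ``{tp}_cell`` rendering ``"k* (pct%)"``. The leading ``All genes`` row
    reports list sizes n and 100*n/N. Sets with no resolvable member are
    flagged untestable.
    """
    uni = set(universe)
    if not uni:
        raise EnrichmentError("empty universe")
    resolved_lists = {tp: set(lst) & uni for tp, lst in lists.items()}
    rows = []

    genome_row: dict[str, object] = {"gene_group": "All genes", "total": len(uni),
                                     "testable": True}
    for tp, lst in resolved_lists.items():
        pct = format_percent(100.0 * len(lst) / len(uni))
        genome_row[f"{tp}_k"] = len(lst)
        genome_row[f"{tp}_percent"] = pct
        genome_row[f"{tp}_p"] = np.nan
        genome_row[f"{tp}_star"] = False
        genome_row[f"{tp}_cell"] = f"{len(lst)} ({pct}%)"
    rows.append(genome_row)

    for name, members in collections.items():
        resolved = set(members) & uni
        dropped = len(set(members)) - len(resolved)
        row: dict[str, object] = {"gene_group": name, "total": len(resolved),
                                  "testable": bool(resolved), "unresolved": dropped}
        for tp, lst in resolved_lists.items():
            if not resolved:
                row[f"{tp}_k"] = 0
                row[f"{tp}_percent"] = ""
                row[f"{tp}_p"] = np.nan
                row[f"{tp}_star"] = False
                row[f"{tp}_cell"] = "untestable"
                continue
            res = fisher_enrichment(lst, resolved, uni, alpha)
            pct = format_percent(res.percent)
            star = res.significant
            row[f"{tp}_k"] = res.k
            row[f"{tp}_percent"] = pct
            row[f"{tp}_p"] = res.p_fisher
            row[f"{tp}_star"] = star
            row[f"{tp}_fold"] = res.fold
            row[f"{tp}_cell"] = f"{res.k}{'*' if star else ''} ({pct}%)"
        rows.append(row)
    return pd.DataFrame(rows)


def term_enrichment(gene_list: Iterable[str], annotation: pd.DataFrame,
                    universe: Iterable[str], top: int = 50,
                    alpha: float = 0.05) -> pd.DataFrame:
    """Ranked annotation-term over-representation using the EASE statistic.

    ``annotation`` columns: ``gene_id, term_id, term_name`` and optionally
    ``is_pns_related`` (0/1 flag carried through for resampling analyses).
    Terms are ranked ascending by p_ease (ties by term id); the ``top`` most
    significant rows are returned without further multiplicity correction.
    """
    required = {"gene_id", "term_id", "term_name"}
    missing = required - set(annotation.columns)
    if missing:
        raise EnrichmentError(f"annotation missing columns: {sorted(missing)}")
    uni = set(universe)
    lst = set(gene_list) & uni
    if annotation.loc[annotation["gene_id"].isin(lst)].empty:
        raise EnrichmentError("annotation covers no gene of the list")
    rows = []
    for term_id, grp in annotation.groupby("term_id", sort=True):
        members = set(grp["gene_id"]) & uni
        if not members:
            continue
        res = ease_fisher(lst, members, uni, alpha)
        rows.append({
            "term_id": term_id,
            "term_name": grp["term_name"].iloc[0],
            "is_pns_related": bool(grp["is_pns_related"].iloc[0])
            if "is_pns_related" in grp.columns else False,
            "k": res.k, "m": res.m, "n": res.n, "N": res.N,
            "fold": res.fold, "p_fisher": res.p_fisher, "p_ease": res.p_ease,
        })
    report = pd.DataFrame(rows).sort_values(["p_ease", "term_id"],
                                            kind="mergesort").reset_index(drop=True)
    return report.head(top)
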