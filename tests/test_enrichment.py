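"""Fisher/EASE over-representation statistics and table reports."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import hypergeom

from chprofile import ease_fisher, enrichment_table, fisher_enrichment, term_enrichment
from chprofile.enrichment import (EnrichmentError, format_percent,
                                  log_hypergeom_upper_tail)


def exact_upper_tail(k, m, n, N):
    """Exhaustive rational-arithmetic enumeration of P(X >= k)."""
    lo, hi = max(0, n + m - N), min(m, n)
    total = Fraction(0)
    for j in range(max(k, lo), hi + 1):
        total += Fraction(comb(m, j) * comb(N - m, n - j), comb(N, n))
    return float(min(total, Fraction(1)))


def _universe(N):
    return [f"u{i}" for i in range(N)]


def _table(k, m, n, N):
    uni = _universe(N)
    return uni[:n], uni[:k] + uni[n:n + m - k], uni


# --- printed-table arithmetic --------------------------------------------

@pytest.mark.parametrize("k,m,fold_1dp,pct", [
    (23, 28, 27.0, "82.1"),   # compartmentalised-ciliogenesis subset at t3
    (18, 83, 7.1, "21.7"),    # stringent conserved X-box gene set at t3
    (42, 174, 7.9, "24.1"),   # comparative-genomics ciliogenesis set at t3
    (76, 750, 3.3, "10.1"),   # cilia & basal body database at t3
])
def test_t3_marginals_reproduce_published_folds_and_percents(k, m, fold_1dp, pct):
    lst, gene_set, uni = _table(k, m, 429, 14075)
    res = fisher_enrichment(lst, gene_set, uni)
    assert round(res.fold, 1) == pytest.approx(fold_1dp)
    assert format_percent(res.percent) == pct
    assert res.significant


def test_genome_wide_list_share():
    assert format_percent(100 * 429 / 14075) == "3.0"


def test_zero_overlap_gives_fold_zero_and_p_one():
    lst, gene_set, uni = _table(0, 5, 4, 30)
    res = fisher_enrichment(lst, gene_set, uni)
    assert res.fold == 0.0 and res.p_fisher == 1.0 and res.p_ease == 1.0


def test_small_table_matches_enumeration():
    lst, gene_set, uni = _table(2, 5, 4, 20)
    res = fisher_enrichment(lst, gene_set, uni)
    assert res.p_fisher == pytest.approx(exact_upper_tail(2, 5, 4, 20), rel=1e-12)


def test_log_space_tail_matches_scipy_in_deep_tail():
    mine = log_hypergeom_upper_tail(23, 28, 429, 14075)
    ref = float(hypergeom.sf(22, 14075, 28, 429))
    assert mine == pytest.approx(ref, rel=1e-9)
    assert mine < 1e-25


def test_empty_universe_rejected():
    with pytest.raises(EnrichmentError):
        fisher_enrichment(["a"], ["a"], [])


# --- EASE -----------------------------------------------------------------

def test_ease_overlap_one_gives_p_one():
    lst, gene_set, uni = _table(1, 5, 4, 30)
    assert fisher_enrichment(lst, gene_set, uni).p_ease == 1.0


def test_ease_equals_fisher_on_decremented_overlap():
    lst, gene_set, uni = _table(10, 20, 50, 1000)
    res = fisher_enrichment(lst, gene_set, uni)
    lst9, set9, uni9 = _table(9, 20, 50, 1000)
    # same marginals, overlap k-1
    ref = log_hypergeom_upper_tail(9, 20, 50, 1000)
    assert res.p_ease == pytest.approx(ref, rel=1e-12)


@given(st.integers(1, 60).flatmap(
    lambda N: st.tuples(st.just(N), st.integers(0, N), st.integers(0, N))))
def test_ease_never_below_fisher(tab):
    N, m, n = tab
    for k in range(0, min(m, n) + 1):
        pf = log_hypergeom_upper_tail(k, m, n, N)
        pe = 1.0 if k == 0 else log_hypergeom_upper_tail(k - 1, m, n, N)
        assert pe >= pf - 1e-15


def test_ease_fisher_flags_on_ease_p():
    lst, gene_set, uni = _table(2, 2, 2, 40)
    plain = fisher_enrichment(lst, gene_set, uni)
    corrected = ease_fisher(lst, gene_set, uni)
    assert plain.p_fisher == corrected.p_fisher
    assert corrected.significant == (corrected.p_ease < 0.05)


# --- definitional identity ------------------------------------------------

@given(st.integers(2, 80).flatmap(
    lambda N: st.tuples(st.just(N), st.integers(1, N), st.integers(1, N))))
def test_fold_identity(tab):
    N, m, n = tab
    lst, gene_set, uni = _table(min(m, n), m, n, N)
    res = fisher_enrichment(lst, gene_set, uni)
    assert res.fold * (res.n / res.N) * res.m == pytest.approx(res.k)


# --- reports --------------------------------------------------------------

def test_enrichment_table_shape_and_stars():
    uni = _universe(1000)
    lists = {"t1": uni[:50], "t3": uni[:80]}
    collections = {
        "planted": uni[:30] + uni[900:910],   # heavy overlap with both lists
        "cold": uni[500:540],                 # none
        "ghost": ["not_in_universe"],
    }
    rep = enrichment_table(lists, collections, uni)
    assert rep.iloc[0]["gene_group"] == "All genes"
    planted = rep[rep["gene_group"] == "planted"].iloc[0]
    assert planted["t1_star"] and planted["t1_k"] == 30
    assert planted["t1_cell"] == "30* (75.0%)"
    ghost = rep[rep["gene_group"] == "ghost"].iloc[0]
    assert not ghost["testable"] and ghost["t1_cell"] == "untestable"
    cold = rep[rep["gene_group"] == "cold"].iloc[0]
    assert not cold["t1_star"]


def test_enrichment_table_false_star_rate_near_alpha():
    rng = np.random.default_rng(23)
    uni = _universe(2000)
    lists = {"t1": list(rng.choice(uni, 100, replace=False))}
    collections = {
        f"rand{i}": list(rng.choice(uni, 40, replace=False)) for i in range(300)
    }
    rep = enrichment_table(lists, collections, uni)
    rate = rep["t1_star"].iloc[1:].mean()
    assert rate <= 0.1  # one-sided test at alpha=0.05 on random sets


def test_percent_rounding_half_up():
    assert format_percent(28.25) == "28.3"
    assert format_percent(6 / 28 * 100) == "21.4"
    assert format_percent(23 / 28 * 100) == "82.1"


# --- term enrichment ------------------------------------------------------

def _annotation(terms):
    rows = []
    for term, (genes, flag) in terms.items():
        for g in genes:
            rows.append({"gene_id": g, "term_id": term, "term_name": term.upper(),
                         "is_pns_related": flag})
    return pd.DataFrame(rows)


def test_term_equal_to_list_ranks_first():
    uni = _universe(200)
    lst = uni[:20]
    annot = _annotation({
        "self": (lst, 1),
        "broad": (uni[:100], 0),
        "offlist": (uni[100:140], 0),
    })
    rep = term_enrichment(lst, annot, uni)
    assert rep.iloc[0]["term_id"] == "self"
    assert rep.iloc[0]["is_pns_related"]


def test_planted_term_found_and_lost_after_shuffle():
    rng = np.random.default_rng(5)
    uni = _universe(500)
    lst = uni[:40]
    terms = {f"t{i}": (list(rng.choice(uni, 25, replace=False)), 0) for i in range(20)}
    terms["planted"] = (lst[:15] + uni[450:460], 0)
    annot = _annotation(terms)
    rep = term_enrichment(lst, annot, uni, top=5)
    assert "planted" in set(rep["term_id"])

    lost = 0
    n_shuffles = 20
    for i in range(n_shuffles):
        shuffled = list(rng.permutation(uni))
        mapping = dict(zip(uni, shuffled))
        annot_s = annot.assign(gene_id=annot["gene_id"].map(mapping))
        rep_s = term_enrichment(lst, annot_s, uni, top=len(terms))
        row = rep_s[rep_s["term_id"] == "planted"]
        if row.empty or row.iloc[0]["p_ease"] > 0.05:
            lost += 1
    assert lost >= 0.9 * n_shuffles


def test_term_enrichment_needs_list_coverage():
    uni = _universe(50)
    annot = _annotation({"t": (uni[40:45], 0)})
    with pytest.raises(EnrichmentError):
        term_enrichment(uni[:10], annot, uni)
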