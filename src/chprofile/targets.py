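"""Candidate proneural target screen: wild-type vs mutant fold-change contrast.

A gene is a first-tier candidate when it is strongly differentially expressed
in reporter-positive cells from wild-type embryos (fold change >= threshold
at the FDR bound) but not in the mutant (mutant fold change below threshold),
and a second-tier candidate when additionally the ratio of wild-type to
mutant fold changes is itself >= a ratio threshold, removing genes whose
difference straddles the threshold without a robust expression difference.
"""

from __future__ import annotations

import logging

import pandas as pd

logger = logging.getLogger(__name__)


class ScreenError(ValueError):
    pass


def screen_targets(wt_records: pd.DataFrame, mut_records: pd.DataFrame,
                   fc_threshold: float = 2.0, ratio_threshold: float = 2.0,
                   fdr_threshold: float = 0.01,
                   require_mut_nonsig: bool = False) -> pd.DataFrame:
    """Contrast wild-type and mutant fold-change profiles.

    Both inputs are per-gene DE tables (columns ``gene_id, fc, q``) for the
    same timepoint over the same universe. Returns one row per shared gene
    with columns ``gene_id, fc_wt, fc_mut, ratio, passes_s11, passes_s12``,
    sorted by descending ratio (ties by gene id):

    * ``passes_s11``: fc_wt >= fc_threshold with q_wt <= fdr_threshold, and
      fc_mut < fc_threshold. By default the mutant side is a fold-change
      magnitude gate only; ``require_mut_nonsig`` additionally demands the
      mutant contrast be non-significant.
    * ``passes_s12``: passes_s11 and fc_wt/fc_mut >= ratio_threshold.

    Genes present in only one genotype's records are excluded and logged.
    """
    for name, df in (("wild-type", wt_records), ("mutant", mut_records)):
        missing = {"gene_id", "fc", "q"} - set(df.columns)
        if missing:
            raise ScreenError(f"{name} records missing columns: {sorted(missing)}")
    merged = wt_records[["gene_id", "fc", "q"]].merge(
        mut_records[["gene_id", "fc", "q"]], on="gene_id",
        suffixes=("_wt", "_mut"), how="inner")
    dropped = (set(wt_records["gene_id"]) ^ set(mut_records["gene_id"]))
    if dropped:
        logger.warning("target screen: %d genes present in only one genotype, excluded",
                       len(dropped))
    if (merged["fc_wt"] <= 0).any() or (merged["fc_mut"] <= 0).any():
        raise ScreenError("fold changes must be positive (linear scale)")

    merged["ratio"] = merged["fc_wt"] / merged["fc_mut"]
    s11 = ((merged["fc_wt"] >= fc_threshold)
           & (merged["q_wt"] <= fdr_threshold)
           & (merged["fc_mut"] < fc_threshold))
    if require_mut_nonsig:
        s11 &= merged["q_mut"] > fdr_threshold
    merged["passes_s11"] = s11
    merged["passes_s12"] = s11 & (merged["ratio"] >= ratio_threshold)
    out = merged[["gene_id", "fc_wt", "fc_mut", "ratio", "passes_s11", "passes_s12"]]
    return out.sort_values(["ratio", "gene_id"], ascending=[False, True],
                           kind="mergesort").reset_index(drop=True)
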