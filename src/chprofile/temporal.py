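"""Temporal set analysis: three-way Venn partition and ranked reports."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

REGIONS = ("100", "010", "001", "110", "101", "011", "111")


class TemporalError(ValueError):
    pass


@dataclass
class TemporalPartition:
    """Disjoint Venn regions over three per-timepoint gene lists.

    Region labels are membership bitstrings over (t1, t2, t3): ``"101"`` is
    the set of genes in the t1 and t3 lists but not the t2 list.
    """

    region_sets: dict[str, set[str]]
    totals: dict[str, int]

    def counts(self) -> dict[str, int]:
        return {r: len(self.region_sets[r]) for r in REGIONS}

    def unique_counts(self) -> tuple[int, int, int]:
        """Sizes of the three single-timepoint regions."""
        return (len(self.region_sets["100"]), len(self.region_sets["010"]),
                len(self.region_sets["001"]))

    def validate(self) -> None:
        union: set[str] = set()
        total = 0
        for r in REGIONS:
            total += len(self.region_sets[r])
            union |= self.region_sets[r]
        if total != len(union):
            raise TemporalError("Venn regions are not disjoint")
        for i, tp in enumerate(("t1", "t2", "t3")):
            per_tp = sum(len(self.region_sets[r]) for r in REGIONS if r[i] == "1")
            if per_tp != self.totals[tp]:
                raise TemporalError(f"{tp}: region sum {per_tp} != list size {self.totals[tp]}")


def venn_partition(list_t1: Iterable[str], list_t2: Iterable[str],
                   list_t3: Iterable[str]) -> TemporalPartition:
    """Exact set-algebra partition of three gene lists into 7 Venn regions."""
    s1, s2, s3 = set(list_t1), set(list_t2), set(list_t3)
    regions: dict[str, set[str]] = {r: set() for r in REGIONS}
    for g in s1 | s2 | s3:
        label = f"{int(g in s1)}{int(g in s2)}{int(g in s3)}"
        regions[label].add(g)
    part = TemporalPartition(regions, {"t1": len(s1), "t2": len(s2), "t3": len(s3)})
    part.validate()
    return part


def rank_report(records: pd.DataFrame, top_n: int = 100,
                annotations: Mapping[str, Iterable[str]] | None = None) -> pd.DataFrame:
    """Top ``top_n`` genes of one timepoint by descending fold change.

    Ties broken lexicographically by gene id. ``annotations`` maps flag-column
    names to gene-id sets (e.g. a cilia-database membership flag) joined as
    boolean columns.
    """
    if top_n <= 0:
        raise TemporalError("top_n must be positive")
    ranked = records.sort_values(["fc", "gene_id"], ascending=[False, True],
                                 kind="mergesort").head(top_n).reset_index(drop=True)
    ranked.insert(0, "rank", range(1, len(ranked) + 1))
    if annotations:
        for name, members in annotations.items():
            ranked[name] = ranked["gene_id"].isin(set(members))
    return ranked


def partition_to_frames(part: TemporalPartition) -> dict[str, pd.DataFrame]:
    """One single-column gene-id table per region, for TSV export."""
    return {
        r: pd.DataFrame({"gene_id": sorted(part.region_sets[r])})
        for r in REGIONS
    }


def brute_force_partition(list_t1: Sequence[str], list_t2: Sequence[str],
                          list_t3: Sequence[str]) -> dict[str, set[str]]:
    """Independent per-gene membership oracle (linear scans, no set algebra)."""
    regions: dict[str, set[str]] = {r: set() for r in REGIONS}
    every = list(dict.fromkeys([*list_t1, *list_t2, *list_t3]))
    for g in every:
        label = "".join(
            "1" if any(g == x for x in lst) else "0"
            for lst in (list_t1, list_t2, list_t3)
        )
        regions[label].add(g)
    return regions
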