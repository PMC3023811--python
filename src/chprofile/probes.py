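"""Trusted-gene probe-set filter.

A probe set is *trusted* for gene g when g is the only gene to which at least
``min_fraction`` (default 50%) of the set's oligomers align; sets where two or
more genes reach the fraction are *promiscuous*, all others *unmapped*. The
union of trusted genes is the analysis universe for every downstream
enrichment test.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd


class AlignmentError(ValueError):
    """Malformed probe-set alignment record."""


@dataclass(frozen=True)
class ProbeSetAlignment:
    probeset_id: str
    per_gene_oligo_counts: Mapping[str, int]
    total_oligos: int

    def __post_init__(self) -> None:
        if self.total_oligos <= 0:
            raise AlignmentError(f"{self.probeset_id}: total_oligos must be positive")
        if any(c < 0 for c in self.per_gene_oligo_counts.values()):
            raise AlignmentError(f"{self.probeset_id}: negative oligo count")


@dataclass(frozen=True)
class ProbeSetStatus:
    probeset_id: str
    status: str  # "trusted" | "promiscuous" | "unmapped"
    gene_id: str | None  # set only when trusted


def classify_probeset(aln: ProbeSetAlignment, min_fraction: float = 0.5) -> ProbeSetStatus:
    """Classify one probe set. The fraction threshold is inclusive (>=)."""
    qualifying = sorted(
        g for g, c in aln.per_gene_oligo_counts.items()
        if c / aln.total_oligos >= min_fraction
    )
    if len(qualifying) == 1:
        return ProbeSetStatus(aln.probeset_id, "trusted", qualifying[0])
    if len(qualifying) >= 2:
        return ProbeSetStatus(aln.probeset_id, "promiscuous", None)
    return ProbeSetStatus(aln.probeset_id, "unmapped", None)


def classify_all(alignments: Iterable[ProbeSetAlignment],
                 min_fraction: float = 0.5) -> list[ProbeSetStatus]:
    return [classify_probeset(a, min_fraction) for a in alignments]


def trusted_universe(alignments: Iterable[ProbeSetAlignment],
                     min_fraction: float = 0.5) -> set[str]:
    """Deduplicated union of genes from trusted probe sets."""
    out: set[str] = set()
    for aln in alignments:
        st = classify_probeset(aln, min_fraction)
        if st.status == "trusted":
            out.add(st.gene_id)  # type: ignore[arg-type]
    return out


def alignments_from_table(table: pd.DataFrame) -> list[ProbeSetAlignment]:
    """Build alignment records from a long-form table.

    Expects columns ``probeset_id, gene_id, n_oligos_aligned, total_oligos``
    (one row per probeset x gene).
    """
    required = {"probeset_id", "gene_id", "n_oligos_aligned", "total_oligos"}
    missing = required - set(table.columns)
    if missing:
        raise AlignmentError(f"alignment table missing columns: {sorted(missing)}")
    out = []
    for ps, grp in table.groupby("probeset_id", sort=True):
        totals = grp["total_oligos"].unique()
        if len(totals) != 1:
            raise AlignmentError(f"{ps}: inconsistent total_oligos")
        out.append(ProbeSetAlignment(
            probeset_id=str(ps),
            per_gene_oligo_counts=dict(zip(grp["gene_id"], grp["n_oligos_aligned"])),
            total_oligos=int(totals[0]),
        ))
    return out


def read_alignments(path: str | Path) -> list[ProbeSetAlignment]:
    return alignments_from_table(pd.read_csv(path, sep="\t"))


def statuses_to_table(statuses: Iterable[ProbeSetStatus]) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.probeset_id, s.status, s.gene_id or "") for s in statuses],
        columns=["probeset_id", "status", "gene_id"],
    )


def collapse_to_genes(matrix: pd.DataFrame,
                      statuses: Iterable[ProbeSetStatus]) -> pd.DataFrame:
    """Collapse a probeset x sample matrix to trusted genes.

    When several probe sets are trusted to one gene, their per-sample log2
    intensities are averaged (the collapse rule this package adopts; the
    upstream convention only defines which probe sets are trusted).
    """
    trusted = [(s.probeset_id, s.gene_id) for s in statuses if s.status == "trusted"]
    if not trusted:
        return pd.DataFrame(columns=matrix.columns)
    mapping = pd.DataFrame(trusted, columns=["probeset_id", "gene_id"])
    mapping = mapping[mapping["probeset_id"].isin(matrix.index)]
    sub = matrix.loc[mapping["probeset_id"]]
    sub.index = pd.Index(mapping["gene_id"], name="gene_id")
    return sub.groupby(level=0).mean()
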