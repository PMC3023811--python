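"""Readers and writers for the plain-text formats the pipeline exchanges.

Expression matrices and sample sheets are TSV (see :mod:`chprofile.study`),
gene sets are GMT, promoters FASTA, TSS annotations BED6, annotations and
reports TSV, ground truth JSON.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT: one set per line — name, description, then tab-separated ids."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"GMT line has fewer than 3 fields: {line[:60]!r}")
        sets[fields[0]] = {g for g in fields[2:] if g}
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path,
              descriptions: Mapping[str, str] | None = None) -> None:
    lines = []
    for name, members in sets.items():
        desc = (descriptions or {}).get(name, "na")
        lines.append("\t".join([name, desc, *sorted(set(members))]))
    Path(path).write_text("\n".join(lines) + "\n")


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_bed(bed: pd.DataFrame, path: str | Path) -> None:
    bed.to_csv(path, sep="\t", header=False, index=False)


def read_gene_list(path: str | Path, column: str = "gene_id") -> list[str]:
    """Gene ids from a TSV report (or a headerless single-column file)."""
    df = pd.read_csv(path, sep="\t")
    if column in df.columns:
        return list(df[column].astype(str))
    return [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Gene→term table: gene_id, term_id, term_name[, is_pns_related]."""
    df = pd.read_csv(path, sep="\t")
    if "is_pns_related" in df.columns:
        df["is_pns_related"] = df["is_pns_related"].astype(int)
    return df
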