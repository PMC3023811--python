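"""Core containers for an expression-profiling study.

An :class:`ExpressionStudy` couples a log2 intensity matrix (genes x samples)
with a sample sheet describing the experimental design: developmental
timepoint (t1/t2/t3), GFP sort status (reporter-positive precursor cells vs
the reporter-negative remainder of the embryo), genotype (wild type vs
proneural mutant), and replicate index.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

SAMPLE_COLUMNS = ["sample_id", "timepoint", "gfp", "genotype", "replicate"]


class StudyError(ValueError):
    """Raised for malformed study inputs."""


@dataclass
class ExpressionStudy:
    """Log2 expression matrix plus sample annotations.

    Parameters
    ----------
    matrix
        DataFrame of log2 intensities, genes as rows (index = gene ids),
        samples as columns (column names = sample ids).
    samples
        Sample sheet with columns ``sample_id, timepoint, gfp, genotype,
        replicate``. ``gfp`` is ``"+"`` or ``"-"``; ``genotype`` is ``"wt"``
        or ``"mut"``.
    """

    matrix: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SAMPLE_COLUMNS if c not in self.samples.columns]
        if missing:
            raise StudyError(f"sample sheet missing columns: {missing}")
        unknown = set(self.samples["sample_id"]) - set(self.matrix.columns)
        if unknown:
            raise StudyError(f"sample ids absent from matrix: {sorted(unknown)[:5]}")

    @property
    def genes(self) -> pd.Index:
        return self.matrix.index

    @property
    def timepoints(self) -> list[str]:
        return list(pd.unique(self.samples["timepoint"]))

    def sample_ids(self, timepoint: str | None = None, gfp: str | None = None,
                   genotype: str | None = None) -> list[str]:
        """Sample ids matching the given design cell (None = no constraint)."""
        mask = pd.Series(True, index=self.samples.index)
        if timepoint is not None:
            mask &= self.samples["timepoint"] == timepoint
        if gfp is not None:
            mask &= self.samples["gfp"] == gfp
        if genotype is not None:
            mask &= self.samples["genotype"] == genotype
        return list(self.samples.loc[mask, "sample_id"])

    def subset(self, gene_ids: Iterable[str]) -> "ExpressionStudy":
        return ExpressionStudy(self.matrix.loc[list(gene_ids)], self.samples)

    def to_dir(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.matrix.to_csv(outdir / "matrix.tsv", sep="\t", index_label="gene_id")
        self.samples.to_csv(outdir / "samples.tsv", sep="\t", index=False)

    @classmethod
    def from_dir(cls, indir: str | Path) -> "ExpressionStudy":
        indir = Path(indir)
        matrix = pd.read_csv(indir / "matrix.tsv", sep="\t", index_col="gene_id")
        samples = pd.read_csv(indir / "samples.tsv", sep="\t",
                              dtype={"gfp": str, "timepoint": str, "genotype": str})
        return cls(matrix, samples)


@dataclass
class GroundTruth:
    """Planted signal of a synthetic study, the oracle for recovery tests."""

    de_genes_by_timepoint: dict[str, set[str]] = field(default_factory=dict)
    planted_set_members: dict[str, set[str]] = field(default_factory=dict)
    planted_motif_positions: dict[str, list[tuple[int, str]]] = field(default_factory=dict)
    mutant_dependent_genes: set[str] = field(default_factory=set)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "de_genes_by_timepoint": {k: sorted(v) for k, v in self.de_genes_by_timepoint.items()},
            "planted_set_members": {k: sorted(v) for k, v in self.planted_set_members.items()},
            "planted_motif_positions": {
                g: [[o, s] for o, s in hits] for g, hits in self.planted_motif_positions.items()
            },
            "mutant_dependent_genes": sorted(self.mutant_dependent_genes),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            de_genes_by_timepoint={k: set(v) for k, v in payload["de_genes_by_timepoint"].items()},
            planted_set_members={k: set(v) for k, v in payload["planted_set_members"].items()},
            planted_motif_positions={
                g: [(int(o), s) for o, s in hits]
                for g, hits in payload["planted_motif_positions"].items()
            },
            mutant_dependent_genes=set(payload["mutant_dependent_genes"]),
        )


def make_sample_sheet(rows: Iterable[Mapping[str, object]]) -> pd.DataFrame:
    df = pd.DataFrame(list(rows))
    return df[SAMPLE_COLUMNS]
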