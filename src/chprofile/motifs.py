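"""Strand-aware IUPAC consensus scanning of promoter windows.

Degenerate single-sequence consensus matching (no position-weight scoring):
the E box CANNTG and the Scute site GCAGSTG are printed consensi; X-box and
E_ATO consensi are user-supplied configuration because their sequences are
taken from the primary literature rather than fixed here.

Coordinates are 0-based half-open throughout. Match offsets are reported
window-relative, 5'->3' on the gene's sense strand. A genomic site matching
in both orientations (e.g. under a self-reverse-complementary pattern) is
counted once.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


class MotifError(ValueError):
    pass


def reverse_complement(seq: str) -> str:
    """Reverse complement preserving IUPAC ambiguity codes."""
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class MotifPattern:
    name: str
    iupac: str
    both_strands: bool = True

    def __post_init__(self) -> None:
        if not self.iupac:
            raise MotifError("empty pattern")
        bad = [ch for ch in self.iupac.upper() if ch not in IUPAC]
        if bad:
            raise MotifError(f"invalid IUPAC characters {bad} in {self.iupac!r}")


@dataclass(frozen=True)
class CompiledMotif:
    pattern: MotifPattern
    length: int
    _fwd: re.Pattern
    _rev: re.Pattern | None

    def find(self, sequence: str) -> list[tuple[int, str]]:
        """All (offset, strand) matches; overlapping matches all counted.

        An offset matching in both orientations is reported once, as '+'.
        """
        text = sequence.upper()
        fwd = {m.start() for m in self._fwd.finditer(text)}
        hits = [(o, "+") for o in fwd]
        if self._rev is not None:
            hits += [(m.start(), "-") for m in self._rev.finditer(text)
                     if m.start() not in fwd]
        return sorted(hits)


def _regex(iupac: str) -> re.Pattern:
    body = "".join(
        ch if len(IUPAC[ch]) == 1 else f"[{IUPAC[ch]}]" for ch in iupac.upper()
    )
    return re.compile(f"(?=({body}))")  # lookahead: overlapping matches


def compile_pattern(pattern: MotifPattern) -> CompiledMotif:
    rev = _regex(reverse_complement(pattern.iupac)) if pattern.both_strands else None
    return CompiledMotif(pattern, len(pattern.iupac), _regex(pattern.iupac), rev)


@dataclass(frozen=True)
class PromoterWindow:
    """Upstream window on the gene's sense strand, reading toward the TSS."""

    gene_id: str
    window_bp: int
    strand: str
    sequence: str


@dataclass
class MotifHitTable:
    """Per-gene match counts and (offset, strand) site lists."""

    pattern: MotifPattern
    counts: pd.DataFrame  # columns: gene_id, n_hits, has_motif
    sites: dict[str, list[tuple[int, str]]] = field(default_factory=dict)

    def hit_genes(self) -> set[str]:
        return set(self.counts.loc[self.counts["has_motif"], "gene_id"])

    def sites_bed(self) -> pd.DataFrame:
        rows = [
            {"chrom": g, "start": o, "end": o + len(self.pattern.iupac),
             "name": self.pattern.name, "score": 0, "strand": s}
            for g, hits in self.sites.items() for o, s in hits
        ]
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "name",
                                           "score", "strand"])


def read_tss_bed(path: str | Path) -> pd.DataFrame:
    bed = pd.read_csv(path, sep="\t", header=None, comment="#",
                      names=["chrom", "start", "end", "name", "score", "strand"])
    return bed


def extract_windows(fasta: str | Path | Mapping[str, str],
                    tss_bed: str | Path | pd.DataFrame,
                    window_bp: int = 1000) -> list[PromoterWindow]:
    """Cut upstream windows from contigs around annotated TSSs.

    For a + strand gene the window is ``[tss - window_bp, tss)``; for a -
    strand gene ``(tss, tss + window_bp]`` reverse-complemented, so every
    window reads 5'->3' toward the TSS on the gene's sense strand. Windows
    are clipped at contig edges.
    """
    if isinstance(fasta, (str, Path)):
        contigs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta), "fasta")}
    else:
        contigs = dict(fasta)
    bed = tss_bed if isinstance(tss_bed, pd.DataFrame) else read_tss_bed(tss_bed)
    out = []
    for row in bed.itertuples(index=False):
        if row.chrom not in contigs:
            raise MotifError(f"BED record {row.name!r}: contig {row.chrom!r} not in FASTA")
        contig = contigs[row.chrom]
        tss = int(row.start)
        if row.strand == "-":
            seq = reverse_complement(contig[tss + 1:min(len(contig), tss + 1 + window_bp)])
        else:
            seq = contig[max(0, tss - window_bp):tss]
        out.append(PromoterWindow(str(row.name), window_bp, str(row.strand), seq))
    return out


def scan(windows: Iterable[PromoterWindow],
         pattern: MotifPattern | CompiledMotif) -> MotifHitTable:
    """Scan windows for a compiled IUPAC pattern."""
    motif = pattern if isinstance(pattern, CompiledMotif) else compile_pattern(pattern)
    sites: dict[str, list[tuple[int, str]]] = {}
    rows = []
    for w in windows:
        hits = motif.find(w.sequence)
        sites[w.gene_id] = hits
        rows.append({"gene_id": w.gene_id, "n_hits": len(hits),
                     "has_motif": bool(hits)})
    return MotifHitTable(motif.pattern, pd.DataFrame(rows), sites)


_EBOX = re.compile("CA[ACGT][ACGT]TG")


def mutate_ebox(sequence: str) -> str:
    """Disable every plus-strand E box: CANNTG -> AANNTT.

    Left to right; after rewriting a site, scanning resumes at the next base
    so that hexamers newly exposed by a rewrite (the two inner N bases can
    themselves spell the start of an E box) are also disabled. The result
    contains no plus-strand CANNTG match (the site-directed mutagenesis rule
    for reporter constructs, applied exhaustively).
    """
    seq = list(sequence)
    i = 0
    upper = sequence.upper()
    while i <= len(seq) - 6:
        if _EBOX.match(upper, i):
            seq[i] = "A" if seq[i].isupper() else "a"
            seq[i + 5] = "T" if seq[i + 5].isupper() else "t"
            upper = "".join(seq).upper()
        i += 1
    return "".join(seq)


def load_motif_config(path: str | Path) -> dict[str, MotifPattern]:
    """Load named patterns from YAML: ``motifs: {name: {iupac, both_strands}}``."""
    import yaml

    payload = yaml.safe_load(Path(path).read_text())
    motifs = payload.get("motifs", payload)
    out = {}
    for name, spec in motifs.items():
        out[name] = MotifPattern(name=name, iupac=spec["iupac"],
                                 both_strands=bool(spec.get("both_strands", True)))
    return out
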