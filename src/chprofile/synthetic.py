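"""Synthetic study generator with planted, recoverable ground truth.

Emulates the design of a FACS-sorted, GFP+/GFP- two-channel microarray time
course over three timepoints of sensory-precursor development: a ~14,075-gene
universe probed in quadruplicate, a subset of genes planted as differentially
expressed with early/mid/late onset, gene-set collections with planted overlap
into the DE genes, promoter sequences with planted degenerate motif instances,
and an optional proneural-mutant genotype in which a subset of the planted
effects is abolished.

The generator is the oracle for every downstream stage: the emitted
:class:`~chprofile.study.GroundTruth` records exactly which genes, set members
and motif positions were planted, so recall/calibration of the real analysis
code can be measured against known truth.

Model notes
-----------
* Noise is additive Gaussian on the log2 scale (RMA-style summaries are log2).
* Onset is cumulative by default: a gene planted from t1 stays differentially
  expressed at t2 and t3. A ``transient`` mode plants each gene at exactly one
  timepoint.
* Background promoter sequence is i.i.d. uniform A/C/G/T; composition bias is
  out of scope (adequate for enrichment calibration).
* The default motif is a synthetic RFX-like degenerate 14-mer; the real X-box
  and E_ATO consensus sequences are configuration inputs elsewhere in the
  package, never invented here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .study import ExpressionStudy, GroundTruth, make_sample_sheet

#: Synthetic RFX-like degenerate motif planted by default (NOT a published
#: consensus; palindrome-flavoured 14-mer with low random-match probability).
DEFAULT_MOTIF = "GTTNCCATRGNAAC"

IUPAC_CHOICES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class ConfigError(ValueError):
    """Invalid synthetic-study configuration."""


@dataclass
class SyntheticConfig:
    """Parameters of a synthetic study.

    Defaults mirror the scale of the emulated design: a 14,075-gene universe,
    quadruplicate GFP+/GFP- hybridisations at three timepoints, planted log2
    effects of 2 (4-fold), and onset fractions sized so per-timepoint DE list
    sizes land in the few-hundred range.
    """

    n_genes: int = 14075
    n_replicates: int = 4
    timepoints: tuple[str, ...] = ("t1", "t2", "t3")
    #: fraction of genes planted DE with onset at each timepoint
    onset_fractions: tuple[float, ...] = (0.023, 0.010, 0.007)
    onset_model: str = "cumulative"  # or "transient"
    effect_size: float = 2.0         # mean planted log2 fold change
    effect_size_sd: float = 0.0      # gene-to-gene spread of planted effects
    noise_sd: float = 0.5            # per-observation Gaussian SD, log2 scale
    variance_heterogeneity: float = 0.1  # log-normal spread of per-gene SDs
    #: (set size, planted overlap rate with DE genes) per emitted gene set
    geneset_spec: tuple[tuple[int, float], ...] = ((28, 0.8), (750, 0.1))
    promoter_length: int = 1000
    motif_iupac: str = DEFAULT_MOTIF
    motif_plant_rate: float = 0.5        # P(member promoter carries >=1 instance)
    background_motif_rate: float = 0.05  # per-kb P(background promoter carries one)
    include_mutant: bool = False
    mutant_dependent_fraction: float = 0.8
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0 or self.n_replicates <= 0 or self.promoter_length <= 0:
            raise ConfigError("counts must be positive")
        if len(self.onset_fractions) != len(self.timepoints):
            raise ConfigError("need one onset fraction per timepoint")
        if any(f < 0 for f in self.onset_fractions) or sum(self.onset_fractions) > 1:
            raise ConfigError("onset fractions must be non-negative and sum to <= 1")
        for r in (self.motif_plant_rate, self.background_motif_rate,
                  self.mutant_dependent_fraction):
            if not 0 <= r <= 1:
                raise ConfigError("rates must lie in [0, 1]")
        if self.onset_model not in ("cumulative", "transient"):
            raise ConfigError(f"unknown onset model {self.onset_model!r}")
        if any(ch not in IUPAC_CHOICES for ch in self.motif_iupac.upper()):
            raise ConfigError(f"invalid IUPAC motif {self.motif_iupac!r}")
        for size, rate in self.geneset_spec:
            if size <= 0 or not 0 <= rate <= 1:
                raise ConfigError("gene-set spec entries must be (positive size, rate in [0,1])")


@dataclass
class PromoterSet:
    """Promoter contigs plus the extraction convention used to emit them.

    ``windows`` holds, per gene, the upstream window on the gene's sense
    strand reading toward the TSS -- exactly what window extraction over
    ``contigs``/``tss`` should return.
    """

    contigs: dict[str, str]
    tss: pd.DataFrame  # BED6 columns: chrom, start, end, name, score, strand
    windows: dict[str, str]
    planted: dict[str, list[tuple[int, str]]]


def _gene_ids(n: int) -> list[str]:
    return [f"g{i:05d}" for i in range(n)]


def generate_study(config: SyntheticConfig) -> tuple[ExpressionStudy, GroundTruth]:
    """Generate a complete synthetic study and its ground truth.

    Planted genes have expected GFP+ minus GFP- log2 difference equal to
    their per-gene effect (mean ``config.effect_size``) from their onset
    timepoint onward (cumulative mode); unplanted genes have expected
    difference zero. In the mutant genotype the planted effect of
    mutant-dependent genes is zeroed, modelling precursors that fail to be
    specified.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = _gene_ids(config.n_genes)
    tps = list(config.timepoints)

    # Assign onset groups from a single permutation.
    counts = [int(round(f * config.n_genes)) for f in config.onset_fractions]
    perm = rng.permutation(config.n_genes)
    onset = np.full(config.n_genes, -1)  # -1 = never DE
    start = 0
    for i, c in enumerate(counts):
        onset[perm[start:start + c]] = i
        start += c

    effects = rng.normal(config.effect_size, config.effect_size_sd, config.n_genes)
    if config.effect_size != 0:
        effects = np.clip(effects, 0.25 * config.effect_size, None)
    else:
        effects = np.zeros(config.n_genes)
    base = rng.normal(7.0, 2.0, config.n_genes)
    vh = config.variance_heterogeneity
    gene_sd = config.noise_sd * np.exp(rng.normal(-vh ** 2 / 2, vh, config.n_genes))

    planted = onset >= 0
    mutant_dep = np.zeros(config.n_genes, dtype=bool)
    if config.include_mutant:
        idx = np.flatnonzero(planted)
        n_dep = int(round(config.mutant_dependent_fraction * len(idx)))
        mutant_dep[rng.choice(idx, size=n_dep, replace=False)] = True

    def active(tp_index: int) -> np.ndarray:
        if config.onset_model == "cumulative":
            return planted & (onset <= tp_index)
        return onset == tp_index

    genotypes = ["wt", "mut"] if config.include_mutant else ["wt"]
    columns: dict[str, np.ndarray] = {}
    rows = []
    for genotype in genotypes:
        for ti, tp in enumerate(tps):
            act = active(ti)
            for gfp in "+-":
                for rep in range(1, config.n_replicates + 1):
                    sid = f"{genotype}_{tp}_{'pos' if gfp == '+' else 'neg'}_{rep}"
                    mean = base.copy()
                    if gfp == "+":
                        eff = np.where(act, effects, 0.0)
                        if genotype == "mut":
                            eff = np.where(mutant_dep, 0.0, eff)
                        mean = mean + eff
                    columns[sid] = mean + rng.normal(0.0, gene_sd)
                    rows.append({"sample_id": sid, "timepoint": tp, "gfp": gfp,
                                 "genotype": genotype, "replicate": rep})

    matrix = pd.DataFrame(columns, index=pd.Index(genes, name="gene_id"))
    study = ExpressionStudy(matrix, make_sample_sheet(rows))

    gene_arr = np.asarray(genes)
    de_by_tp = {tp: set(gene_arr[active(ti)]) for ti, tp in enumerate(tps)}

    # Gene-set collections with planted overlap into the DE union.
    de_union = sorted(set().union(*de_by_tp.values())) if de_by_tp else []
    non_de = sorted(set(genes) - set(de_union))
    set_members: dict[str, set[str]] = {}
    for i, (size, rate) in enumerate(config.geneset_spec):
        n_in = min(int(round(size * rate)), len(de_union))
        n_out = min(size - n_in, len(non_de))
        members = set(rng.choice(de_union, n_in, replace=False)) if n_in else set()
        members |= set(rng.choice(non_de, n_out, replace=False)) if n_out else set()
        set_members[f"set{i + 1}_n{size}"] = members

    truth = GroundTruth(
        de_genes_by_timepoint=de_by_tp,
        planted_set_members=set_members,
        mutant_dependent_genes=set(gene_arr[mutant_dep]),
    )
    return study, truth


def generate_promoters(
    config: SyntheticConfig,
    genes: Sequence[str] | None = None,
    members: Mapping[str, Iterable[str]] | None = None,
    pad: int = 60,
) -> PromoterSet:
    """Emit per-gene promoter contigs with planted motif instances.

    One contig per gene (record id = gene id). Genes are assigned random
    strands; the TSS BED row and contig layout follow the extraction
    convention: for ``+`` genes the window is ``[tss - L, tss)``, for ``-``
    genes ``(tss, tss + L]`` reverse-complemented. Members of the supplied
    gene sets carry a planted instance with probability
    ``config.motif_plant_rate``; other promoters carry a spurious instance
    with per-kb probability ``config.background_motif_rate``. Minus-strand
    instances appear reverse-complemented in the emitted sequence.
    """
    config.validate()
    pattern = config.motif_iupac.upper()
    if len(pattern) > config.promoter_length:
        raise ConfigError("motif longer than promoter window")
    rng = np.random.default_rng([config.seed, 1])
    if genes is None:
        genes = _gene_ids(config.n_genes)
    planted_union: set[str] = set()
    if members:
        for ids in members.values():
            planted_union.update(ids)

    L = config.promoter_length
    bases = np.array(list("ACGT"))
    contigs: dict[str, str] = {}
    windows: dict[str, str] = {}
    planted: dict[str, list[tuple[int, str]]] = {}
    bed_rows = []
    bg_p = config.background_motif_rate * (L / 1000.0)

    for gene in genes:
        window = rng.choice(bases, size=L)
        if gene in planted_union:
            plant = rng.random() < config.motif_plant_rate
        else:
            plant = rng.random() < bg_p
        if plant:
            offset = int(rng.integers(0, L - len(pattern) + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            concrete = "".join(rng.choice(list(IUPAC_CHOICES[ch])) for ch in pattern)
            inserted = concrete if strand == "+" else _revcomp(concrete)
            window[offset:offset + len(pattern)] = list(inserted)
            planted[gene] = [(offset, strand)]
        wseq = "".join(window)
        windows[gene] = wseq
        gene_strand = "+" if rng.random() < 0.5 else "-"
        if gene_strand == "+":
            tail = "".join(rng.choice(bases, size=pad))
            contigs[gene] = wseq + tail
            tss = L
        else:
            head = "".join(rng.choice(bases, size=pad))
            contigs[gene] = head + _revcomp(wseq)
            tss = pad - 1
        bed_rows.append({"chrom": gene, "start": tss, "end": tss + 1,
                         "name": gene, "score": 0, "strand": gene_strand})

    tss_bed = pd.DataFrame(bed_rows, columns=["chrom", "start", "end", "name", "score", "strand"])
    return PromoterSet(contigs=contigs, tss=tss_bed, windows=windows, planted=planted)


def generate_probe_alignments(
    n_probesets: int,
    oligos_per_set: int = 14,
    corruption_spec: Mapping[str, int] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Emit a probe-alignment table with designed classification outcomes.

    ``corruption_spec`` maps ``{"promiscuous": k1, "low_coverage": k2}``;
    the remaining probe sets are clean (unique gene, all oligomers aligned).
    Returns ``(alignments, truth)`` where ``alignments`` has one row per
    probeset x gene (columns ``probeset_id, gene_id, n_oligos_aligned,
    total_oligos``) and ``truth`` records the expected classification.
    """
    if n_probesets <= 0 or oligos_per_set <= 0:
        raise ConfigError("counts must be positive")
    spec = dict(corruption_spec or {})
    n_prom = spec.pop("promiscuous", 0)
    n_low = spec.pop("low_coverage", 0)
    if spec:
        raise ConfigError(f"unknown corruption classes: {sorted(spec)}")
    if n_prom + n_low > n_probesets:
        raise ConfigError("corruption counts exceed probe-set count")

    rng = np.random.default_rng(seed)
    half = -(-oligos_per_set // 2)  # ceil, the >=50% boundary
    rows, truth_rows = [], []
    gene_counter = 0

    def next_gene() -> str:
        nonlocal gene_counter
        gene_counter += 1
        return f"pg{gene_counter:05d}"

    for i in range(n_probesets):
        ps = f"ps{i:05d}"
        if i < n_prom:
            g1, g2 = next_gene(), next_gene()
            for g in (g1, g2):
                rows.append((ps, g, int(rng.integers(half, oligos_per_set + 1)), oligos_per_set))
            truth_rows.append((ps, "promiscuous", ""))
        elif i < n_prom + n_low:
            g = next_gene()
            rows.append((ps, g, int(rng.integers(1, half)), oligos_per_set))
            truth_rows.append((ps, "unmapped", ""))
        else:
            g = next_gene()
            rows.append((ps, g, int(rng.integers(half, oligos_per_set + 1)), oligos_per_set))
            truth_rows.append((ps, "trusted", g))

    alignments = pd.DataFrame(rows, columns=["probeset_id", "gene_id",
                                             "n_oligos_aligned", "total_oligos"])
    truth = pd.DataFrame(truth_rows, columns=["probeset_id", "expected_status", "expected_gene"])
    return alignments, truth
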