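"""Generate the synthetic study that all downstream analyses consume.

Emits, under results/data/:
  matrix.tsv / samples.tsv   log2 expression study (wild type + mutant)
  ground_truth.json          planted DE genes, set members, mutant-dependents
  planted_sets.gmt           gene-set collection with planted DE overlap
  promoters.fa / tss.bed     per-gene promoter contigs and TSS annotation
  planted_motifs.json        planted motif instances (window offset, strand)
  alignments.tsv (+truth)    probe-set alignment fixture

The study emulates a GFP+/GFP- sorted time course: 6,000 genes (a scaled-down
universe keeping every statistical structure intact), quadruplicate arrays at
three timepoints, cumulative DE onset, and a mutant genotype in which 80% of
planted effects are abolished.
"""

import argparse
import json
from pathlib import Path

from chprofile import generate_probe_alignments, generate_promoters, generate_study
from chprofile.io import write_bed, write_fasta, write_gmt

from analysis_config import study_config

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args()

    out = RESULTS / "data"
    out.mkdir(parents=True, exist_ok=True)
    config = study_config(args.seed)

    study, truth = generate_study(config)
    study.to_dir(out)
    truth.to_json(out / "ground_truth.json")
    write_gmt(truth.planted_set_members, out / "planted_sets.gmt")

    promoters = generate_promoters(config, genes=list(study.genes),
                                   members=truth.planted_set_members)
    write_fasta(promoters.contigs, out / "promoters.fa")
    write_bed(promoters.tss, out / "tss.bed")
    (out / "planted_motifs.json").write_text(json.dumps(
        {g: [[o, s] for o, s in hits] for g, hits in promoters.planted.items()},
        indent=1))

    alignments, aln_truth = generate_probe_alignments(
        200, 14, {"promiscuous": 10, "low_coverage": 10}, seed=args.seed)
    alignments.to_csv(out / "alignments.tsv", sep="\t", index=False)
    aln_truth.to_csv(out / "alignments_truth.tsv", sep="\t", index=False)

    n_de = {tp: len(g) for tp, g in truth.de_genes_by_timepoint.items()}
    print(f"study: {study.matrix.shape[0]} genes x {study.matrix.shape[1]} arrays")
    print(f"planted DE genes per timepoint (cumulative onset): {n_de}")
    print(f"planted motif carriers: {len(promoters.planted)}")
    print(f"mutant-dependent genes: {len(truth.mutant_dependent_genes)}")
    print(f"outputs under {out}")


if __name__ == "__main__":
    main()
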