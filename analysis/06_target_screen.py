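"""Candidate proneural target genes: wild-type vs mutant fold-change screen.

Contrasts the t1 GFP+/GFP- fold changes between genotypes: first-tier
candidates are >=2-fold enriched (1% FDR) in wild type but <2-fold in the
mutant; second-tier candidates additionally show a >=2-fold ratio between the
two fold changes. Reports recall of the generator's mutant-dependent genes.
Writes results/targets/screen_t1.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

from chprofile import GroundTruth, screen_targets

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--fc", type=float, default=2.0)
    parser.add_argument("--ratio", type=float, default=2.0)
    args = parser.parse_args()

    out = RESULTS / "targets"
    out.mkdir(parents=True, exist_ok=True)
    wt = pd.read_csv(RESULTS / "de" / "de_wt_t1.tsv", sep="\t")
    mut = pd.read_csv(RESULTS / "de" / "de_mut_t1.tsv", sep="\t")
    table = screen_targets(wt, mut, fc_threshold=args.fc,
                           ratio_threshold=args.ratio)
    table.to_csv(out / "screen_t1.tsv", sep="\t", index=False)

    truth = GroundTruth.from_json(RESULTS / "data" / "ground_truth.json")
    called = set(table.loc[table["passes_s11"], "gene_id"])
    recoverable = truth.mutant_dependent_genes & truth.de_genes_by_timepoint["t1"]
    recall = len(called & recoverable) / len(recoverable) if recoverable else float("nan")
    n11 = int(table["passes_s11"].sum())
    n12 = int(table["passes_s12"].sum())
    print(f"{n11} first-tier candidates; {n12} with >=2-fold wt/mut ratio")
    print(f"recall of planted mutant-dependent genes: {recall:.3f} "
          f"({len(called & recoverable)}/{len(recoverable)})")
    print(f"output: {out / 'screen_t1.tsv'}")


if __name__ == "__main__":
    main()
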