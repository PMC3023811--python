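"""Partition the per-timepoint enriched lists into Venn regions; rank reports.

Writes region counts (JSON), per-region gene lists, and top-100
fold-change-ranked reports per timepoint (annotated with planted-set
membership flags) under results/temporal/.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from chprofile import GroundTruth, rank_report, venn_partition
from chprofile.temporal import partition_to_frames

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--top-n", type=int, default=100)
    args = parser.parse_args()

    truth = GroundTruth.from_json(RESULTS / "data" / "ground_truth.json")
    out = RESULTS / "temporal"
    out.mkdir(parents=True, exist_ok=True)

    records, lists = {}, {}
    for tp in ("t1", "t2", "t3"):
        df = pd.read_csv(RESULTS / "de" / f"de_wt_{tp}.tsv", sep="\t")
        records[tp] = df
        lists[tp] = list(df.loc[df["enriched"], "gene_id"])

    part = venn_partition(lists["t1"], lists["t2"], lists["t3"])
    part.validate()
    (out / "venn_counts.json").write_text(
        json.dumps({"regions": part.counts(), "totals": part.totals}, indent=1))
    for region, frame in partition_to_frames(part).items():
        frame.to_csv(out / f"region_{region}.tsv", sep="\t", index=False)

    annotations = {f"in_{name}": members
                   for name, members in truth.planted_set_members.items()}
    for tp in ("t1", "t2", "t3"):
        enriched = records[tp][records[tp]["enriched"]]
        report = rank_report(enriched, top_n=args.top_n, annotations=annotations)
        report.to_csv(out / f"top{args.top_n}_{tp}.tsv", sep="\t", index=False)

    u1, u2, u3 = part.unique_counts()
    print(f"enriched per timepoint: {part.totals}")
    print(f"unique to t1/t2/t3: {u1}/{u2}/{u3}; shared by all three: "
          f"{len(part.region_sets['111'])}")
    print(f"outputs under {out}")


if __name__ == "__main__":
    main()
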