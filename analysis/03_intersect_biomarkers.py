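"""Intersect the per-cohort DEG sets into shared biomarkers.

Mirrors the study's cross-dataset comparison: the genes called in every
cohort are the candidate shared biomarkers, and a per-gene attribution
table records which cohorts support each candidate. Also demonstrates the
miRNA-target join on a synthetic target map.
"""

import argparse
from pathlib import Path

import pandas as pd

from il17sys.crossdata import DegSet, intersect_degs, intersection_report, map_mirna_targets
from il17sys.synth import generate_mirna_map


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--de", type=Path, default=Path("results/de"))
    parser.add_argument("--out", type=Path, default=Path("results/intersect"))
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    sets = []
    for de_file in sorted(args.de.glob("microarray_*_de.tsv")):
        res = pd.read_csv(de_file, sep="\t")
        genes = set(res.loc[res["is_deg"], "gene"])
        sets.append(DegSet(de_file.stem, "synthetic", "lesional_vs_normal", genes))
    common = intersect_degs(sets)
    pd.DataFrame({"gene": sorted(common)}).to_csv(
        args.out / "common_degs.tsv", sep="\t", index=False)
    intersection_report(sets).to_csv(args.out / "attribution.tsv", sep="\t", index=False)
    print(f"{len(sets)} DEG sets of sizes {[len(s.genes) for s in sets]}; "
          f"{len(common)} genes shared by all cohorts")

    # miRNA arm: a synthetic target map joined against a miRNA hit list
    pool = sorted(set().union(*(s.genes for s in sets))) or ["G00000"]
    mapping = generate_mirna_map(5, min(10, len(pool)), pool, seed=args.seed)
    targets, missing = map_mirna_targets(set(mapping) | {"mir-absent"}, mapping)
    pd.DataFrame({"gene": sorted(targets)}).to_csv(
        args.out / "mirna_targets.tsv", sep="\t", index=False)
    print(f"miRNA join: {len(targets)} target genes; unmapped miRNAs: {missing}")


if __name__ == "__main__":
    main()
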