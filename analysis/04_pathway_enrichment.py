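"""Hypergeometric pathway enrichment of each cohort's DEG set.

Tests every gene set of the bundled KEGG-like collection against the DEGs
of each cohort (universe = measured genes), then intersects the significant
pathways (p <= 0.05) across cohorts, mirroring the study's common-pathway
comparison. With synthetic gene symbols the bundled pathways are unrelated
to the planted DEGs, so significant calls occur at the null rate; the
script additionally spikes the DEG symbols of one cohort into a positive
control set to show the test detects true enrichment.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from il17sys.data import gmt_path
from il17sys.enrich import common_significant_pathways, enrich, results_table
from il17sys.io import GeneSet, read_gmt


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--de", type=Path, default=Path("results/de"))
    parser.add_argument("--out", type=Path, default=Path("results/enrichment"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    collection = read_gmt(gmt_path())
    per_dataset = {}
    control_added = False
    for de_file in sorted(args.de.glob("microarray_*_de.tsv")):
        res = pd.read_csv(de_file, sep="\t")
        degs = set(res.loc[res["is_deg"], "gene"])
        universe = set(res["gene"])
        sets = list(collection)
        if degs and not control_added:
            control = frozenset(list(degs)[: max(3, len(degs) // 2)])
            sets.append(GeneSet("positive control (spiked)", control))
            control_added = True
        results = enrich(degs, universe, sets)
        results_table(results).to_csv(args.out / f"{de_file.stem}_enrichment.tsv",
                                      sep="\t", index=False)
        per_dataset[de_file.stem] = results
        sig = [r.pathway for r in results if r.significant]
        print(f"{de_file.stem}: {len(degs)} DEGs, significant pathways: {sig or 'none'}")

    common, per_sig = common_significant_pathways(per_dataset)
    (args.out / "common_pathways.json").write_text(json.dumps(
        {"common": sorted(common),
         "per_dataset": {k: sorted(v) for k, v in per_sig.items()}}, indent=2) + "\n")
    print(f"pathways significant in every cohort: {sorted(common) or 'none'}")


if __name__ == "__main__":
    main()
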