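"""Call differentially expressed genes in every synthetic cohort.

Fits per-gene two-group linear models, moderates the variances with the
empirical-Bayes prior estimated from all genes, and applies the stringent
regime (p < 0.005 and |log2FC| > 1). Reports planted-DEG recovery and the
false-discovery count against the known truth.
"""

import argparse
from pathlib import Path

import pandas as pd

from il17sys.destats import ContrastSpec, call_degs, de_table, volcano_table
from il17sys.io import read_expression_tsv


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--cohorts", type=Path, default=Path("results/cohorts"))
    parser.add_argument("--out", type=Path, default=Path("results/de"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    contrast = ContrastSpec("lesional", "normal", "stringent")
    for expr in sorted(args.cohorts.glob("*[0-9].tsv")) + [args.cohorts / "rnaseq.tsv"]:
        stem = expr.stem
        matrix = read_expression_tsv(expr, expr.with_name(f"{stem}_pheno.tsv"))
        res = de_table(matrix, contrast)
        res.to_csv(args.out / f"{stem}_de.tsv", sep="\t", index=False)
        volcano_table(res).to_csv(args.out / f"{stem}_volcano.tsv", sep="\t", index=False)
        degs = call_degs(res, contrast)
        truth = pd.read_csv(expr.with_name(f"{stem}_truth.tsv"), sep="\t")
        planted = set(truth.loc[truth["is_deg"], "gene"])
        recovered = len(degs & planted)
        print(f"{stem}: {len(degs)} DEGs called; recovered {recovered}/{len(planted)} "
              f"planted ({recovered / len(planted):.1%}); "
              f"{len(degs - planted)} false discoveries; "
              f"prior d0={res.attrs['hyper'].d0:.2f}")


if __name__ == "__main__":
    main()
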