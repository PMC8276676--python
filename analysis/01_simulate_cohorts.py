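"""Generate the synthetic expression cohorts used by the downstream stages.

Three microarray-like cohorts (Gaussian log2 intensities, 5 disease vs 5
normal samples, 5% planted DEGs at log2 shift 2, noise SD 0.5) and one
RNA-seq-like cohort (negative-binomial counts on the log2(count+1) scale),
each with its ground-truth table, written under results/cohorts/.
"""

import argparse
import dataclasses
from pathlib import Path

from il17sys.io import write_expression_tsv
from il17sys.synth import SyntheticSpec, generate_counts, generate_microarray


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--out", type=Path, default=Path("results/cohorts"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    base = SyntheticSpec(n_genes=2000, deg_fraction=0.05, effect_size=2.0,
                         sigma=0.5, seed=args.seed)
    for d in range(3):
        spec = dataclasses.replace(base, seed=args.seed + 1000 * d)
        matrix, truth = generate_microarray(spec)
        write_expression_tsv(matrix, args.out / f"microarray_{d}.tsv",
                             args.out / f"microarray_{d}_pheno.tsv")
        truth.to_csv(args.out / f"microarray_{d}_truth.tsv", sep="\t", index=False)
        print(f"microarray cohort {d}: {spec.n_genes} genes, "
              f"{truth['is_deg'].sum()} planted DEGs")

    rnaseq = dataclasses.replace(base, groups=[("lesional", 8), ("normal", 8)],
                                 seed=args.seed + 9000)
    matrix, truth = generate_counts(rnaseq, dispersion=0.1)
    write_expression_tsv(matrix, args.out / "rnaseq.tsv", args.out / "rnaseq_pheno.tsv")
    truth.to_csv(args.out / "rnaseq_truth.tsv", sep="\t", index=False)
    print(f"RNA-seq cohort: {rnaseq.n_genes} genes, {truth['is_deg'].sum()} planted DEGs")


if __name__ == "__main__":
    main()
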