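"""Cross-dataset biomarker logic: DEG intersection, miRNA target joins, and
the per-gene average expressions that seed the pathway models."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .io import ExpressionMatrix, normalize_symbol


class ArityError(ValueError):
    """Raised when an intersection is requested over fewer than two sets."""


@dataclass
class DegSet:
    dataset_id: str
    disease: str
    contrast: str
    genes: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.genes = {normalize_symbol(g) for g in self.genes}


def intersect_degs(sets: list[DegSet | set[str]]) -> set[str]:
    """Exact intersection of DEG sets after symbol normalization."""
    if len(sets) < 2:
        raise ArityError(f"need >= 2 DEG sets to intersect, got {len(sets)}")
    norm = [
        {normalize_symbol(g) for g in (s.genes if isinstance(s, DegSet) else s)}
        for s in sets
    ]
    out = norm[0]
    for s in norm[1:]:
        out = out & s
    return out


def map_mirna_targets(
    mirnas: set[str], mapping: dict[str, set[str]]
) -> tuple[set[str], list[str]]:
    """Union of target sets over the supplied miRNAs.

    Returns (targets, missing) where ``missing`` lists miRNAs absent from the
    map — reported rather than fatal, mirroring a partial lookup table.
    """
    targets: set[str] = set()
    missing: list[str] = []
    for mirna in sorted(mirnas):
        if mirna in mapping:
            targets |= {normalize_symbol(g) for g in mapping[mirna]}
        else:
            missing.append(mirna)
    return targets, missing


def average_expression(
    matrices: list[ExpressionMatrix],
    genes: list[str],
    disease_groups: set[str],
    disease: str = "disease",
) -> tuple[pd.DataFrame, list[str]]:
    """Mean log2 expression per gene over all disease-group samples.

    Samples are pooled across matrices (one grand mean per gene), not
    averaged per dataset. Genes absent from every matrix are returned in the
    skipped list instead of raising.
    """
    rows = []
    skipped = []
    for gene in genes:
        sym = normalize_symbol(gene)
        total, count = 0.0, 0
        for m in matrices:
            cols = [s for s in m.samples if m.phenotype[s] in disease_groups]
            if sym in m.values.index and cols:
                vals = m.values.loc[sym, cols]
                total += float(vals.sum())
                count += len(cols)
        if count == 0:
            skipped.append(sym)
        else:
            rows.append({"gene": sym, "disease": disease, "avg_expr": total / count})
    return pd.DataFrame(rows, columns=["gene", "disease", "avg_expr"]), skipped


def intersection_report(sets: list[DegSet]) -> pd.DataFrame:
    """Per-gene dataset-attribution table for every gene in >= 1 set.

    The same report shape as a shared-biomarker attribution matrix: one row
    per gene, one boolean column per dataset/contrast, plus a count.
    """
    all_genes = sorted(set().union(*(s.genes for s in sets)) if sets else set())
    cols = [f"{s.dataset_id}:{s.contrast}" for s in sets]
    data = {
        col: [g in s.genes for g in all_genes] for col, s in zip(cols, sets)
    }
    out = pd.DataFrame(data, index=pd.Index(all_genes, name="gene"))
    out["n_datasets"] = out.sum(axis=1).astype(int)
    return out.reset_index()
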