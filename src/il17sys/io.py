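"""Readers, writers and the core expression-matrix container.

All tabular interchange is plain TSV (UTF-8, '.' decimal). Gene symbols are
upper-cased at ingest so that intersections across datasets are well defined.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd


class ParseError(ValueError):
    """Raised when an input file violates the expected format."""


def normalize_symbol(symbol: str) -> str:
    return str(symbol).strip().upper()


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix on log2 scale with a sample -> group map.

    ``values`` is a DataFrame indexed by gene symbol with one column per
    sample; ``phenotype`` maps every sample to its group label.
    """

    values: pd.DataFrame
    phenotype: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = self.values.copy()
        self.values.index = [normalize_symbol(g) for g in self.values.index]
        missing = [s for s in self.values.columns if s not in self.phenotype]
        if missing:
            raise ParseError(f"samples without phenotype label: {missing}")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ParseError("expression matrix contains non-finite values")
        if self.values.index.duplicated().any():
            self.values = collapse_duplicate_genes(self.values)

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def groups(self) -> set[str]:
        return set(self.phenotype[s] for s in self.samples)

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.samples if self.phenotype[s] == group]


def collapse_duplicate_genes(values: pd.DataFrame) -> pd.DataFrame:
    """Collapse duplicated gene symbols keeping the max-IQR row per symbol."""
    q3 = values.quantile(0.75, axis=1)
    q1 = values.quantile(0.25, axis=1)
    iqr = (q3 - q1).to_numpy()
    order = np.lexsort((-iqr, np.arange(len(values))))  # stable on ties
    keep: dict[str, int] = {}
    best: dict[str, float] = {}
    for pos in range(len(values)):
        sym = values.index[pos]
        if sym not in keep or iqr[pos] > best[sym]:
            keep[sym] = pos
            best[sym] = iqr[pos]
    rows = sorted(keep.values())
    return values.iloc[rows]


def read_expression_tsv(path: str | Path, phenotype_path: str | Path) -> ExpressionMatrix:
    """Read an expression TSV (first column ``gene``) plus a phenotype TSV."""
    path, phenotype_path = Path(path), Path(phenotype_path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric expression value ({exc})") from exc
    pheno = read_phenotype_tsv(phenotype_path)
    missing = [s for s in df.columns if s not in pheno]
    if missing:
        raise ParseError(f"{phenotype_path}: no phenotype for sample(s) {missing}")
    return ExpressionMatrix(values=df, phenotype=pheno)


def read_phenotype_tsv(path: str | Path) -> dict[str, str]:
    pheno_df = pd.read_csv(path, sep="\t", dtype=str)
    if list(pheno_df.columns[:2]) != ["sample", "group"]:
        raise ParseError(f"{path}: expected columns 'sample' and 'group'")
    return dict(zip(pheno_df["sample"], pheno_df["group"]))


def write_expression_tsv(
    matrix: ExpressionMatrix, path: str | Path, phenotype_path: str | Path
) -> None:
    out = matrix.values.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t")
    pd.DataFrame(
        {"sample": matrix.samples, "group": [matrix.phenotype[s] for s in matrix.samples]}
    ).to_csv(phenotype_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# miRNA target maps


def read_mirna_map(path: str | Path) -> dict[str, set[str]]:
    """Read a two-column ``mirna<TAB>gene`` table into mirna -> target set."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["mirna", "gene"]:
        raise ParseError(f"{path}: expected columns 'mirna' and 'gene'")
    out: dict[str, set[str]] = {}
    for mirna, gene in zip(df["mirna"], df["gene"]):
        out.setdefault(mirna, set()).add(normalize_symbol(gene))
    return out


def write_mirna_map(mapping: Mapping[str, set[str]], path: str | Path) -> None:
    rows = [(m, g) for m in sorted(mapping) for g in sorted(mapping[m])]
    pd.DataFrame(rows, columns=["mirna", "gene"]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GMT gene-set collections


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: frozenset[str]
    source: str = ""


def read_gmt(path: str | Path) -> list[GeneSet]:
    sets: list[GeneSet] = []
    for line_no, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ParseError(f"{path}:{line_no}: GMT line needs name, description, genes")
        name, _desc, *genes = parts
        members = frozenset(normalize_symbol(g) for g in genes if g.strip())
        if not members:
            raise ParseError(f"{path}:{line_no}: gene set {name!r} is empty")
        sets.append(GeneSet(name=name, genes=members, source=line))
    return sets


def write_gmt(sets: list[GeneSet], path: str | Path, description: str = "na") -> None:
    lines = [
        "\t".join([s.name, description, *sorted(s.genes)]) for s in sets
    ]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# run manifests


def file_checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(out_dir: str | Path, stages: list[str], config: Mapping) -> Path:
    """Record every artifact in ``out_dir`` with a checksum, plus the config."""
    out_dir = Path(out_dir)
    manifest_path = out_dir / "manifest.json"
    artifacts = {
        str(p.relative_to(out_dir)): file_checksum(p)
        for p in sorted(out_dir.rglob("*"))
        if p.is_file() and p.name != "manifest.json"
    }
    config_blob = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "stages": stages,
        "config": json.loads(config_blob),
        "config_sha256": hashlib.sha256(config_blob.encode()).hexdigest(),
        "artifacts": artifacts,
    }
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest_path
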