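"""Shipped data: the two disease pathway models, the average-expression
table used to seed them, and a small KEGG-like gene-set collection."""

from __future__ import annotations

from importlib.resources import files
from pathlib import Path

import pandas as pd


def _path(name: str) -> Path:
    return Path(str(files(__package__) / name))


def table5_path() -> Path:
    return _path("avg_expr_table5.tsv")


def load_table5() -> pd.DataFrame:
    """Average log2 expression of the pathway DEGs per disease."""
    return pd.read_csv(table5_path(), sep="\t")


def psoriasis_model_path() -> Path:
    return _path("psoriasis_il17.json")


def cscc_model_path() -> Path:
    return _path("cscc_il17.json")


def gmt_path() -> Path:
    return _path("kegg_subset.gmt")
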