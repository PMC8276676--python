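"""Hypergeometric gene-set over-representation analysis.

A local replacement for a web enrichment service: for each pathway set the
upper-tail hypergeometric p-value of the DEG overlap is computed against the
measured universe (the genes on the array / in the count matrix, not the
union of the collection). Raw p <= 0.05 defines significance, matching the
study design; a Benjamini-Hochberg column is emitted for information.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .destats import bh_fdr
from .io import GeneSet, normalize_symbol

DEFAULT_ALPHA = 0.05


class UniverseError(ValueError):
    """Raised when the DEG set is not contained in the universe."""


@dataclass(frozen=True)
class EnrichmentResult:
    pathway: str
    overlap: int
    set_size: int
    deg_count: int
    universe_size: int
    p: float
    significant: bool


def hypergeom_upper_tail(x: int, N: int, K: int, n: int) -> float:
    """P(X >= x) for X ~ Hypergeom(N, K, n); exactly 1 when x == 0."""
    if x <= 0:
        return 1.0
    return float(stats.hypergeom.sf(x - 1, N, K, n))


def enrich(
    degs: set[str],
    universe: set[str],
    collection: list[GeneSet],
    alpha: float = DEFAULT_ALPHA,
) -> list[EnrichmentResult]:
    """Over-representation of ``degs`` in each pathway of ``collection``.

    Pathway sets are intersected with the universe before testing, so the
    null conditions on what could have been called. Results are sorted by p
    ascending with ties broken by pathway label.
    """
    degs = {normalize_symbol(g) for g in degs}
    universe = {normalize_symbol(g) for g in universe}
    offenders = sorted(degs - universe)
    if offenders:
        raise UniverseError(f"DEGs outside universe: {offenders}")
    N, n = len(universe), len(degs)
    results = []
    for gs in collection:
        members = gs.genes & universe
        K = len(members)
        x = len(members & degs)
        p = hypergeom_upper_tail(x, N, K, n)
        results.append(
            EnrichmentResult(
                pathway=gs.name,
                overlap=x,
                set_size=K,
                deg_count=n,
                universe_size=N,
                p=p,
                significant=p <= alpha,
            )
        )
    return sorted(results, key=lambda r: (r.p, r.pathway))


def results_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    out = pd.DataFrame(
        [
            {
                "pathway": r.pathway,
                "overlap": r.overlap,
                "set_size": r.set_size,
                "deg_count": r.deg_count,
                "universe_size": r.universe_size,
                "p": r.p,
                "significant": r.significant,
            }
            for r in results
        ]
    )
    if len(out):
        out["bh_fdr"] = bh_fdr(out["p"].to_numpy())
    return out


def common_significant_pathways(
    per_dataset: dict[str, list[EnrichmentResult]],
) -> tuple[set[str], dict[str, set[str]]]:
    """Pathways significant in every dataset, plus the per-dataset sets."""
    if len(per_dataset) < 2:
        raise ValueError("need enrichment results from >= 2 datasets")
    per_sig = {
        ds: {r.pathway for r in results if r.significant}
        for ds, results in per_dataset.items()
    }
    common = set.intersection(*per_sig.values())
    return common, per_sig
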