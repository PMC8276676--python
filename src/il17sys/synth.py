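"""Synthetic expression data with planted ground truth.

Two generators are provided: a Gaussian log2-intensity generator emulating
post-normalization microarray matrices, and a negative-binomial count
generator emulating RNA-seq abundances (returned on the log2(count+1) scale
used by the shared differential-expression stage). Both plant a known set of
differentially expressed genes whose true log2 shift is recorded in a truth
table, so every downstream stage can be tested against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionMatrix

# fixed offsets carving independent substreams out of one user-facing seed
_SUBSTREAM_MICROARRAY = 11
_SUBSTREAM_COUNTS = 23
_SUBSTREAM_MIRNA = 37


class SpecValidationError(ValueError):
    """Raised when a synthetic-data specification is inconsistent."""


@dataclass
class SyntheticSpec:
    """Parameters of a two-or-three-group synthetic expression experiment.

    ``effect_size`` is the mean log2 shift planted into DEGs of the first
    (disease) group; ``sigma`` the per-gene Gaussian noise SD on log2 scale.
    """

    n_genes: int = 2000
    groups: list[tuple[str, int]] = field(
        default_factory=lambda: [("lesional", 5), ("normal", 5)]
    )
    deg_fraction: float = 0.05
    effect_size: float = 2.0
    sigma: float = 0.5
    baseline_mean: float = 7.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise SpecValidationError("n_genes must be positive")
        if not 0.0 <= self.deg_fraction <= 1.0:
            raise SpecValidationError("deg_fraction must be in [0, 1]")
        if self.sigma < 0:
            raise SpecValidationError("sigma must be non-negative")
        if len(self.groups) < 2:
            raise SpecValidationError("need at least two groups")
        for label, n in self.groups:
            if n < 2:
                raise SpecValidationError(
                    f"group {label!r} has {n} samples; need >= 2 for variance estimation"
                )

    @property
    def n_deg(self) -> int:
        return int(round(self.deg_fraction * self.n_genes))


def _gene_names(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def _sample_names(groups: list[tuple[str, int]]) -> tuple[list[str], dict[str, str]]:
    samples, pheno = [], {}
    for label, n in groups:
        for i in range(n):
            name = f"{label}_{i}"
            samples.append(name)
            pheno[name] = label
    return samples, pheno


def _plant_truth(spec: SyntheticSpec, rng: np.random.Generator) -> pd.DataFrame:
    genes = _gene_names(spec.n_genes)
    is_deg = np.zeros(spec.n_genes, dtype=bool)
    is_deg[: spec.n_deg] = True
    signs = rng.choice([1.0, -1.0], size=spec.n_genes)
    shift = np.where(is_deg, signs * spec.effect_size, 0.0)
    return pd.DataFrame({"gene": genes, "is_deg": is_deg, "true_shift": shift})


def generate_microarray(spec: SyntheticSpec) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Gaussian log2-intensity matrix with planted group shifts.

    The first listed group is the disease group and receives the planted
    shift; remaining groups sit at baseline.
    """
    rng = np.random.default_rng(spec.seed + _SUBSTREAM_MICROARRAY)
    truth = _plant_truth(spec, rng)
    samples, pheno = _sample_names(spec.groups)
    disease = spec.groups[0][0]
    means = np.full((spec.n_genes, len(samples)), spec.baseline_mean)
    for j, s in enumerate(samples):
        if pheno[s] == disease:
            means[:, j] += truth["true_shift"].to_numpy()
    values = means + rng.normal(0.0, spec.sigma, size=means.shape)
    df = pd.DataFrame(values, index=truth["gene"], columns=samples)
    return ExpressionMatrix(values=df, phenotype=pheno), truth


def generate_counts(
    spec: SyntheticSpec, dispersion: float
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Negative-binomial counts with group means 2**(baseline + shift).

    ``dispersion`` is the NB overdispersion alpha (var = mu + alpha*mu^2);
    the returned matrix is on the log2(count+1) scale expected by the DE
    stage. alpha -> 0 recovers Poisson sampling.
    """
    if dispersion <= 0:
        raise SpecValidationError("dispersion must be > 0")
    rng = np.random.default_rng(spec.seed + _SUBSTREAM_COUNTS)
    truth = _plant_truth(spec, rng)
    samples, pheno = _sample_names(spec.groups)
    disease = spec.groups[0][0]
    log2_mu = np.full((spec.n_genes, len(samples)), spec.baseline_mean)
    for j, s in enumerate(samples):
        if pheno[s] == disease:
            log2_mu[:, j] += truth["true_shift"].to_numpy()
    mu = np.exp2(log2_mu)
    size = 1.0 / dispersion  # NB shape parameter
    p = size / (size + mu)
    counts = rng.negative_binomial(size, p)
    df = pd.DataFrame(np.log2(counts + 1.0), index=truth["gene"], columns=samples)
    return ExpressionMatrix(values=df, phenotype=pheno), truth


def generate_mirna_map(
    n_mirnas: int, targets_per_mirna: int, gene_pool: list[str], seed: int
) -> dict[str, set[str]]:
    """Uniform random miRNA -> target-set map drawn without replacement."""
    if targets_per_mirna > len(gene_pool):
        raise SpecValidationError(
            f"targets_per_mirna={targets_per_mirna} exceeds pool size {len(gene_pool)}"
        )
    rng = np.random.default_rng(seed + _SUBSTREAM_MIRNA)
    pool = np.asarray(sorted(gene_pool))
    out: dict[str, set[str]] = {}
    for i in range(n_mirnas):
        chosen = rng.choice(pool, size=targets_per_mirna, replace=False)
        out[f"mir-{i:03d}"] = set(map(str, chosen))
    return out
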