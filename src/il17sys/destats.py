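"""Per-gene differential expression with empirical-Bayes variance moderation.

The statistic is the classic moderated t: per-gene two-group linear fits give
log2 fold change and pooled residual variance s2 with df = n_a + n_b - 2; the
variances are shrunk toward a prior (d0, s0^2) estimated from all genes by
moment matching on log s2, and the moderated t is referred to a t
distribution on d0 + df degrees of freedom (normal in the d0 -> inf limit).

Two threshold regimes call DEGs, both with strict inequalities:

* stringent: p < 0.005 and |log2FC| > 1 (disease vs normal contrasts)
* relaxed:   p < 0.05  and |log2FC| > 0.5 (subtype or non-lesional contrasts)

No multiple-testing correction is applied in the calling path; a
Benjamini-Hochberg FDR column is emitted for information only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .io import ExpressionMatrix

REGIMES = {
    "stringent": {"p_threshold": 0.005, "fc_threshold": 1.0},
    "relaxed": {"p_threshold": 0.05, "fc_threshold": 0.5},
}


class ContrastError(ValueError):
    """Raised when a contrast cannot be formed from the matrix phenotypes."""


class DegenerateVarianceError(ValueError):
    """Raised when every residual variance is zero."""


@dataclass(frozen=True)
class ContrastSpec:
    group_a: str
    group_b: str
    regime: str = "stringent"

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}")

    @property
    def p_threshold(self) -> float:
        return REGIMES[self.regime]["p_threshold"]

    @property
    def fc_threshold(self) -> float:
        return REGIMES[self.regime]["fc_threshold"]


@dataclass(frozen=True)
class EBayesHyper:
    """Prior degrees of freedom (may be inf) and prior variance."""

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if not (self.d0 > 0):
            raise ValueError("d0 must be positive")
        if not (self.s0_sq > 0):
            raise ValueError("s0_sq must be positive")


def fit_gene_models(matrix: ExpressionMatrix, contrast: ContrastSpec) -> pd.DataFrame:
    """Per-gene two-group fit: log2fc, pooled variance s2, df and 1/na+1/nb."""
    for group in (contrast.group_a, contrast.group_b):
        n = len(matrix.samples_in(group))
        if n == 0:
            raise ContrastError(f"group {group!r} absent from matrix")
        if n < 2:
            raise ContrastError(f"group {group!r} has a single sample")
    a = matrix.values[matrix.samples_in(contrast.group_a)].to_numpy()
    b = matrix.values[matrix.samples_in(contrast.group_b)].to_numpy()
    na, nb = a.shape[1], b.shape[1]
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    ss = ((a - a.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (b - b.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    df = na + nb - 2
    s2 = ss / df
    return pd.DataFrame(
        {
            "gene": matrix.genes,
            "log2fc": log2fc,
            "s2": s2,
            "df": df,
            "v": 1.0 / na + 1.0 / nb,
        }
    )


def trigamma_inverse(y: float, tol: float = 1e-12, max_iter: int = 100) -> float:
    """Solve trigamma(x) = y for x > 0 by monotone Newton iteration."""
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < tol * x:
            break
    return float(x)


def estimate_hyperparameters(s2: np.ndarray, df: int) -> EBayesHyper:
    """Moment-match (d0, s0^2) from the spread of log residual variances.

    With s2_g ~ s0^2 * chi2_df / df scaled by a chi2_{d0} prior, the excess
    variance of e_g = log s2_g - psi(df/2) + log(df/2) over trigamma(df/2)
    identifies d0 through the trigamma function; zero or negative excess
    clamps d0 at infinity (all variances shrunk fully to s0^2).
    """
    s2 = np.asarray(s2, dtype=float)
    positive = s2 > 0
    if not positive.any():
        raise DegenerateVarianceError("all residual variances are zero")
    z = np.log(s2[positive])
    e = z - special.digamma(df / 2.0) + math.log(df / 2.0)
    excess = float(np.var(e, ddof=1) - special.polygamma(1, df / 2.0))
    if excess <= 0:
        d0 = math.inf
        s0_sq = float(np.exp(np.mean(e)))
    else:
        d0 = 2.0 * trigamma_inverse(excess)
        s0_sq = float(
            np.exp(np.mean(e) + special.digamma(d0 / 2.0) - math.log(d0 / 2.0))
        )
    return EBayesHyper(d0=d0, s0_sq=s0_sq)


def moderated_test(
    log2fc: np.ndarray,
    s2: np.ndarray,
    df: int,
    v: float | np.ndarray,
    hyper: EBayesHyper,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Moderated t and two-sided p on d0 + df degrees of freedom."""
    log2fc = np.asarray(log2fc, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    if math.isinf(hyper.d0):
        s2_tilde = np.full_like(s2, hyper.s0_sq)
        t_mod = log2fc / np.sqrt(s2_tilde * v)
        p = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        s2_tilde = (hyper.d0 * hyper.s0_sq + df * s2) / (hyper.d0 + df)
        t_mod = log2fc / np.sqrt(s2_tilde * v)
        p = 2.0 * stats.t.sf(np.abs(t_mod), df=hyper.d0 + df)
    return t_mod, p, s2_tilde


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (informational column only)."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def de_table(matrix: ExpressionMatrix, contrast: ContrastSpec) -> pd.DataFrame:
    """Full DE pipeline for one contrast: fit, moderate, test, flag DEGs."""
    fits = fit_gene_models(matrix, contrast)
    hyper = estimate_hyperparameters(fits["s2"].to_numpy(), int(fits["df"].iloc[0]))
    t_mod, p, s2_tilde = moderated_test(
        fits["log2fc"].to_numpy(),
        fits["s2"].to_numpy(),
        int(fits["df"].iloc[0]),
        fits["v"].to_numpy(),
        hyper,
    )
    out = fits.copy()
    out["s2_tilde"] = s2_tilde
    out["t_mod"] = t_mod
    out["p"] = p
    out["bh_fdr"] = bh_fdr(p)
    out["is_deg"] = (p < contrast.p_threshold) & (
        np.abs(out["log2fc"].to_numpy()) > contrast.fc_threshold
    )
    out.attrs["hyper"] = hyper
    return out


def call_degs(results: pd.DataFrame, contrast: ContrastSpec) -> set[str]:
    """DEG symbols under the contrast regime (strict thresholds on p and FC)."""
    flag = (results["p"] < contrast.p_threshold) & (
        results["log2fc"].abs() > contrast.fc_threshold
    )
    return set(results.loc[flag, "gene"])


def volcano_table(results: pd.DataFrame) -> pd.DataFrame:
    """gene, log2fc, -log10 p — the table behind a volcano plot."""
    with np.errstate(divide="ignore"):
        neglog = -np.log10(results["p"].to_numpy())
    return pd.DataFrame(
        {"gene": results["gene"], "log2fc": results["log2fc"], "neg_log10_p": neglog}
    )
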