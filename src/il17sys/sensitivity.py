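"""Local sensitivity of the biological-process outputs to species initial
values, with full normalization.

For output Y and input X with initial value X0 > 0, a central finite
difference on the initial value gives s(t) = [Y(t; X0(1+h)) - Y(t; X0(1-h))]
/ (2*h*X0); the fully normalized sensitivity n(t) = s(t) * X0 / Y(t) is
dimensionless, and the reported matrix entry is max |n(t)| over the output
grid, excluding times where Y is still numerically zero. Inputs are initial
values only — a gene enters the model solely through its initial state, so
this is the natural reading of "genes as inputs".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pathway import (
    DEFAULT_ATOL,
    DEFAULT_N_POINTS,
    DEFAULT_RTOL,
    DEFAULT_T_END,
    PathwayModel,
    simulate,
)

DEFAULT_H_REL = 1e-3
DEFAULT_H_ABS = 1e-3
HIGH_SENSITIVITY_THRESHOLD = 1.5


@dataclass
class SensitivityMatrix:
    outputs: list[str]
    inputs: list[str]
    S: np.ndarray  # outputs x inputs, max-|n(t)| summary
    evaluable: np.ndarray  # False where the output never left zero

    def entry(self, output: str, input_: str) -> float:
        return float(self.S[self.outputs.index(output), self.inputs.index(input_)])

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.S, index=self.outputs, columns=self.inputs)


@dataclass
class HighSensitivitySet:
    threshold: float
    pairs: list[tuple[str, str]]  # (output, input) with S > threshold
    inputs_flagged: list[str]  # inputs high for >= 1 output


def _perturbed(model: PathwayModel, species_id: str, value: float) -> PathwayModel:
    out = model.copy()
    out.get(species_id).initial = value
    return out


def compute_sensitivities(
    model: PathwayModel,
    outputs: list[str] | None = None,
    inputs: list[str] | None = None,
    t_end: float = DEFAULT_T_END,
    h_rel: float = DEFAULT_H_REL,
    h_abs: float = DEFAULT_H_ABS,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    n_points: int = DEFAULT_N_POINTS,
) -> SensitivityMatrix:
    """Normalized initial-value sensitivities of process outputs.

    Defaults: outputs = the model's process species, inputs = its gene-level
    species. Zero-initial inputs are perturbed by the absolute step, and
    their fully normalized sensitivity is zero by construction.
    """
    outputs = list(outputs if outputs is not None else model.processes)
    inputs = list(inputs if inputs is not None else model.gene_inputs)
    base = simulate(model, t_end=t_end, rtol=rtol, atol=atol, n_points=n_points)
    y_base = {o: base[o] for o in outputs}
    defined = {o: y_base[o] > atol for o in outputs}
    S = np.zeros((len(outputs), len(inputs)))
    evaluable = np.zeros((len(outputs), len(inputs)), dtype=bool)
    for j, x in enumerate(inputs):
        x0 = model.get(x).initial
        h = h_rel * x0 if x0 > 0 else h_abs
        up = simulate(_perturbed(model, x, x0 + h), t_end=t_end, rtol=rtol, atol=atol, n_points=n_points)
        dn = simulate(_perturbed(model, x, max(x0 - h, 0.0)), t_end=t_end, rtol=rtol, atol=atol, n_points=n_points)
        for i, o in enumerate(outputs):
            mask = defined[o]
            if not mask.any():
                continue  # output never leaves zero: not evaluable
            evaluable[i, j] = True
            if x0 <= 0:
                continue  # full normalization multiplies by X0 = 0
            s_t = (up[o][mask] - dn[o][mask]) / (2.0 * h)
            n_t = s_t * x0 / y_base[o][mask]
            S[i, j] = float(np.max(np.abs(n_t)))
    return SensitivityMatrix(outputs=outputs, inputs=inputs, S=S, evaluable=evaluable)


def classify_high(
    S: SensitivityMatrix, threshold: float = HIGH_SENSITIVITY_THRESHOLD
) -> HighSensitivitySet:
    """Strictly-greater-than classification of high-sensitivity pairs."""
    pairs = [
        (o, x)
        for i, o in enumerate(S.outputs)
        for j, x in enumerate(S.inputs)
        if S.S[i, j] > threshold
    ]
    flagged = sorted({x for _o, x in pairs}, key=S.inputs.index)
    return HighSensitivitySet(threshold=threshold, pairs=pairs, inputs_flagged=flagged)


def sensitivity_report(S: SensitivityMatrix, H: HighSensitivitySet) -> pd.DataFrame:
    """Long-format (output, input, sensitivity, flagged) table, sorted by
    sensitivity descending with ties broken by input id."""
    flagged_pairs = set(H.pairs)
    rows = [
        {
            "output": o,
            "input": x,
            "sensitivity": float(S.S[i, j]),
            "flagged": (o, x) in flagged_pairs,
        }
        for i, o in enumerate(S.outputs)
        for j, x in enumerate(S.inputs)
    ]
    out = pd.DataFrame(rows)
    return out.sort_values(
        ["sensitivity", "input"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
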