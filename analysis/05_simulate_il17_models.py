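"""Simulate the psoriasis and cSCC IL-17 signaling models.

Loads the shipped reaction-network fixtures, seeds gene species with the
published per-disease average expression values (non-measured genes at the
0.5 default, biological processes at zero), integrates the mass-action
system for 10 time units, and reports the peak concentration and plateau
onset of the three biological-process outputs.
"""

import argparse
import json
from pathlib import Path

from il17sys.data import cscc_model_path, load_table5, psoriasis_model_path
from il17sys.pathway import apply_initial_values, load_model, peak, simulate


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--out", type=Path, default=Path("results/model"))
    parser.add_argument("--t-end", type=float, default=10.0)
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    table = load_table5()
    for path in (psoriasis_model_path(), cscc_model_path()):
        model = apply_initial_values(load_model(path), table)
        traj = simulate(model, t_end=args.t_end)
        traj.save(args.out / f"trajectory_{model.disease}.tsv")
        peaks = {}
        for p in model.processes:
            t_peak, value = peak(traj, p)
            peaks[p] = {"t_peak": round(t_peak, 3), "value": round(value, 3)}
            print(f"{model.disease:10s} {p:36s} peak {value:6.2f} at t={t_peak:5.2f}")
        (args.out / f"peaks_{model.disease}.json").write_text(
            json.dumps(peaks, indent=2) + "\n")


if __name__ == "__main__":
    main()
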