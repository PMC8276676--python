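"""Activation/inhibition reaction-network model of the IL-17 signaling
sub-pathway, with deterministic mass-action simulation.

Semantics
---------
Species carry non-negative concentrations in arbitrary units. Two reaction
kinds connect them:

* activation ``S -> T`` (rate constant k): mass-action conversion; flux
  ``k*[S]`` leaves S and enters T. When S has m > 1 outbound activation
  edges, each edge carries ``k_e*[S]/m`` so branching does not inflate total
  outflow.
* inhibition ``I -| T`` (rate constant k): catalytic second-order removal;
  flux ``k*[I]*[T]`` leaves T while I is unchanged.

Activation-only networks are therefore linear, conserve total mass, and
plateau as upstream pools drain into terminal species; inhibition introduces
the only nonlinearity and only ever removes mass.

The two disease models (psoriasis, cSCC) encode the figure-level topology:
ligands through the receptor/adaptor complex and TRAF6 to the TAK1 complex,
branching into NF-kB and MAPK/AP-1 arms that drive effector families
(chemokines, antimicrobial peptides, tissue-remodeling MMPs, cytokines),
which feed three terminal biological-process species: autoimmune pathology,
neutrophil recruitment, and immunity to extracellular pathogens.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .io import normalize_symbol

ROLES = {"gene", "deg", "complex", "inhibitor", "process"}

DEFAULT_NON_DEG_INITIAL = 0.5
DEFAULT_T_END = 10.0
DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10
DEFAULT_N_POINTS = 201
PLATEAU_TOLERANCE = 0.005  # "within 0.5% of the maximum"

PROCESS_IDS = (
    "autoimmune_pathology",
    "neutrophil_recruitment",
    "immunity_extracellular_pathogens",
)

# Grouped species fixed by the figure captions.
CAPTION_GROUPS = {
    "psoriasis": {
        "MAPKs": {"MAPK13", "MAPK14"},
        "chemokines": {"CXCL1", "CXCL2", "CXCL5", "CXCL8", "CXCL10", "CCL2", "CCL7", "CCL20"},
        "antimicrobial": {"S100A7", "S100A8", "S100A9", "LCN2"},
        "tissue_remodeling": {"MMP1", "MMP9"},
        "C1": {"HSP90", "ACT1"},
        "C2": {"TAB2", "TAB3", "TAK1"},
        "C3": {"ANAPC5", "A20"},
        "AP1": {"FOSL1", "FOS"},
    },
    "cSCC": {
        "MAPKs": {"MAPK3", "MAPK9", "MAPK10", "MAPK11", "MAPK14"},
        "chemokines": {"CXCL1", "CXCL2", "CXCL8", "CCL20"},
        "antimicrobial": {"DEFB4A", "DEFB4B", "S100A7", "S100A8", "S100A9", "LCN2"},
        "tissue_remodeling": {"MMP1", "MMP3", "MMP9", "MMP13"},
        "AP1": {"FOSL1", "JUN"},
    },
}

# Table-symbol aliases for complex members (gene symbols as printed in the
# average-expression table).
MEMBER_ALIASES = {"HSP90": "HSP90AA1", "ACT1": "TRAF3IP2", "TAK1": "MAP3K7", "A20": "TNFAIP3"}


class ModelSchemaError(ValueError):
    """Raised when a model file or object violates the schema."""


class SolverError(RuntimeError):
    """Raised when ODE integration fails."""


@dataclass
class Species:
    id: str
    role: str
    members: list[str] = field(default_factory=list)
    initial: float = DEFAULT_NON_DEG_INITIAL

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ModelSchemaError(f"species {self.id!r}: unknown role {self.role!r}")
        if not self.members:
            self.members = [self.id]
        self.members = [normalize_symbol(m) for m in self.members]
        if self.initial < 0:
            raise ModelSchemaError(f"species {self.id!r}: negative initial {self.initial}")
        if self.role == "process" and self.initial != 0:
            raise ModelSchemaError(
                f"process species {self.id!r} must start at 0, got {self.initial}"
            )


@dataclass
class Edge:
    source: str
    target: str
    kind: str  # activation | inhibition
    k: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("activation", "inhibition"):
            raise ModelSchemaError(f"edge {self.source}->{self.target}: kind {self.kind!r}")
        if self.source == self.target:
            raise ModelSchemaError(f"self-loop on {self.source!r}")
        if not (self.k > 0):
            raise ModelSchemaError(f"edge {self.source}->{self.target}: k must be > 0")


@dataclass
class PathwayModel:
    disease: str
    species: list[Species]
    edges: list[Edge]
    notes: str = ""

    def __post_init__(self) -> None:
        self.validate()

    # -- structure ---------------------------------------------------------
    def index(self) -> dict[str, int]:
        return {s.id: i for i, s in enumerate(self.species)}

    def get(self, species_id: str) -> Species:
        for s in self.species:
            if s.id == species_id:
                return s
        raise KeyError(species_id)

    @property
    def processes(self) -> list[str]:
        return [s.id for s in self.species if s.role == "process"]

    @property
    def gene_inputs(self) -> list[str]:
        """Default sensitivity inputs: gene-level species, not processes or
        pure inhibitors."""
        return [s.id for s in self.species if s.role in ("gene", "deg", "complex")]

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(s.id for s in self.species)
        for e in self.edges:
            g.add_edge(e.source, e.target, kind=e.kind, k=e.k)
        return g

    def validate(self) -> None:
        ids = [s.id for s in self.species]
        if len(ids) != len(set(ids)):
            raise ModelSchemaError("duplicate species ids")
        known = set(ids)
        for e in self.edges:
            for endpoint in (e.source, e.target):
                if endpoint not in known:
                    raise ModelSchemaError(
                        f"edge {e.source}->{e.target}: unknown species {endpoint!r}"
                    )
        # every process must be reachable from a ligand (a species with no
        # inbound activation edge)
        g = self.graph()
        inbound_activation = {
            e.target for e in self.edges if e.kind == "activation"
        }
        ligands = [
            s.id
            for s in self.species
            if s.role != "process" and s.id not in inbound_activation
        ]
        for proc in self.processes:
            if not any(nx.has_path(g, lig, proc) for lig in ligands):
                raise ModelSchemaError(f"process {proc!r} unreachable from any ligand")
        if self.disease in CAPTION_GROUPS:
            self._check_caption_groups()

    def _check_caption_groups(self) -> None:
        for sid, members in CAPTION_GROUPS[self.disease].items():
            try:
                sp = self.get(sid)
            except KeyError:
                raise ModelSchemaError(
                    f"{self.disease} model must contain grouped species {sid!r}"
                ) from None
            if set(sp.members) != {normalize_symbol(m) for m in members}:
                raise ModelSchemaError(
                    f"{self.disease} species {sid!r} members {sorted(sp.members)} "
                    f"differ from the figure caption {sorted(members)}"
                )

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "disease": self.disease,
            "notes": self.notes,
            "species": [asdict(s) for s in self.species],
            "edges": [asdict(e) for e in self.edges],
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1) + "\n")

    def copy(self) -> "PathwayModel":
        return PathwayModel(
            disease=self.disease,
            species=[Species(**asdict(s)) for s in self.species],
            edges=[Edge(**asdict(e)) for e in self.edges],
            notes=self.notes,
        )


def load_model(path: str | Path) -> PathwayModel:
    """Load and validate a pathway-model JSON file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = json.loads(path.read_text())
    for key in ("disease", "species", "edges"):
        if key not in raw:
            raise ModelSchemaError(f"{path}: missing field {key!r}")
    species = [Species(**s) for s in raw["species"]]
    edges = [Edge(**e) for e in raw["edges"]]
    return PathwayModel(
        disease=raw["disease"], species=species, edges=edges, notes=raw.get("notes", "")
    )


def apply_initial_values(
    model: PathwayModel,
    table: pd.DataFrame,
    default: float = DEFAULT_NON_DEG_INITIAL,
) -> PathwayModel:
    """Seed species initial values from an average-expression table.

    Singleton species take their table value when present, else ``default``;
    grouped species take the mean over members with absent members
    contributing ``default``; processes stay at zero. Table rows for a
    different disease are ignored; rows never matched are reported via the
    returned model's ``notes``.
    """
    lookup = {
        normalize_symbol(g): float(v)
        for g, d, v in zip(table["gene"], table["disease"], table["avg_expr"])
        if str(d) == model.disease
    }
    used: set[str] = set()
    seeded = model.copy()
    for sp in seeded.species:
        if sp.role == "process":
            sp.initial = 0.0
            continue
        vals = []
        for member in sp.members:
            key = member if member in lookup else MEMBER_ALIASES.get(member, member)
            if key in lookup:
                vals.append(lookup[key])
                used.add(key)
            else:
                vals.append(default)
        sp.initial = float(np.mean(vals))
    unmatched = sorted(set(lookup) - used)
    if unmatched:
        seeded.notes = (seeded.notes + f" unmatched table rows: {unmatched}").strip()
    return seeded


def build_odes(model: PathwayModel):
    """Compile the model into a vectorized rate function f(t, y).

    Returns (rhs, species_ids). Activation fluxes are split equally across a
    source's outbound activation edges; inhibition removes ``k*[I]*[T]``
    from the target only.
    """
    ids = [s.id for s in model.species]
    idx = {sid: i for i, sid in enumerate(ids)}
    act = [(idx[e.source], idx[e.target], e.k) for e in model.edges if e.kind == "activation"]
    inh = [(idx[e.source], idx[e.target], e.k) for e in model.edges if e.kind == "inhibition"]
    out_count = np.zeros(len(ids))
    for s, _t, _k in act:
        out_count[s] += 1
    act_src = np.array([a[0] for a in act], dtype=int)
    act_tgt = np.array([a[1] for a in act], dtype=int)
    act_k = np.array([a[2] for a in act], dtype=float)
    act_share = act_k / np.maximum(out_count[act_src], 1.0)
    inh_src = np.array([a[0] for a in inh], dtype=int)
    inh_tgt = np.array([a[1] for a in inh], dtype=int)
    inh_k = np.array([a[2] for a in inh], dtype=float)
    n = len(ids)

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        dy = np.zeros(n)
        if len(act_src):
            flux = act_share * y[act_src]
            np.add.at(dy, act_tgt, flux)
            np.subtract.at(dy, act_src, flux)
        if len(inh_src):
            loss = inh_k * y[inh_src] * y[inh_tgt]
            np.subtract.at(dy, inh_tgt, loss)
        return dy

    return rhs, ids


@dataclass
class Trajectory:
    times: np.ndarray
    values: np.ndarray  # time x species
    species: list[str]

    def __getitem__(self, species_id: str) -> np.ndarray:
        return self.values[:, self.species.index(species_id)]

    def frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.species)
        df.insert(0, "time", self.times)
        return df

    def save(self, path: str | Path) -> None:
        self.frame().to_csv(path, sep="\t", index=False)


def simulate(
    model: PathwayModel,
    t_end: float = DEFAULT_T_END,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    n_points: int = DEFAULT_N_POINTS,
) -> Trajectory:
    """Integrate the model on a uniform grid with a stiff-capable solver."""
    rhs, ids = build_odes(model)
    y0 = np.array([s.initial for s in model.species], dtype=float)
    times = np.linspace(0.0, t_end, n_points)
    sol = solve_ivp(
        rhs, (0.0, t_end), y0, method="LSODA", t_eval=times, rtol=rtol, atol=atol
    )
    if not sol.success:
        raise SolverError(f"integration failed for {model.disease} model: {sol.message}")
    return Trajectory(times=times, values=sol.y.T, species=ids)


def peak(trajectory: Trajectory, species_id: str) -> tuple[float, float]:
    """(t_peak, value): grid maximum, with plateau onset for monotone curves.

    ``t_peak`` is the earliest grid time at which the curve is within 0.5% of
    its maximum, which for plateaued monotone trajectories reads off the
    plateau onset rather than the last grid point.
    """
    y = trajectory[species_id]
    vmax = float(np.max(y))
    if vmax <= 0:
        return float(trajectory.times[0]), vmax
    within = np.nonzero(y >= (1.0 - PLATEAU_TOLERANCE) * vmax)[0]
    return float(trajectory.times[within[0]]), vmax


def total_mass(trajectory: Trajectory) -> np.ndarray:
    return trajectory.values.sum(axis=1)
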