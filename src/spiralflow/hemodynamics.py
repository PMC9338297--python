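"""Network-Poiseuille hemodynamics of the spiral-artery subnetwork.

Each segment behaves as a chain of laminar Hagen-Poiseuille resistors
(``R_i = 8 mu l_i / (pi r_i^4)`` per consecutive node pair, with the
pairwise-mean radius); the network flow problem is the standard linear
circuit analogy: conductances on edges, pressure unknowns on nodes, mass
conservation at interior nodes, Dirichlet pressures at the flow inlets
(radial-adjacent spiral terminals) and outlets (canal-adjacent terminals).
The total network resistance is ``R = delta_p / Q`` with ``Q`` the total
outflow; being a linear model, ``R`` is independent of the applied
pressure gradient.  Conductance ``G = 1/R`` is reported (higher G, easier
flow).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.linalg import spsolve

from .graph import VascularGraph
from .voxelio import CANAL, RADIAL, SPIRAL, LabelVolume

#: default dynamic viscosity of blood, Pa·s
DEFAULT_VISCOSITY = 3.5e-3
UM_TO_M = 1e-6


def segment_conductance(
    positions_um: np.ndarray, radii_um: np.ndarray, viscosity: float = DEFAULT_VISCOSITY
) -> float:
    """Poiseuille conductance (m^3 Pa^-1 s^-1) of one segment chain.

    The chain is a series of sub-element resistances
    ``8 mu l_i / (pi rbar_i^4)`` with ``rbar_i`` the mean of the bounding
    node radii.
    """
    pos = np.asarray(positions_um, dtype=float) * UM_TO_M
    rad = np.asarray(radii_um, dtype=float) * UM_TO_M
    steps = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    rbar = 0.5 * (rad[:-1] + rad[1:])
    if np.any(rbar <= 0):
        raise ValueError("segment has non-positive radii")
    keep = steps > 0  # coincident nodes contribute zero resistance
    if not keep.any():
        raise ValueError("segment has zero total length")
    resistance = float(np.sum(8.0 * viscosity * steps[keep] / (np.pi * rbar[keep] ** 4)))
    return 1.0 / resistance


@dataclass
class FlowProblem:
    graph: VascularGraph  # spiral subnetwork, measured and radius-annotated
    inlets: list
    outlets: list
    delta_p: float = 1000.0  # Pa
    viscosity: float = DEFAULT_VISCOSITY  # Pa·s

    def __post_init__(self):
        if set(self.inlets) & set(self.outlets):
            raise ValueError("inlet and outlet sets must be disjoint")
        if self.delta_p <= 0:
            raise ValueError("delta_p must be positive")
        if self.viscosity <= 0:
            raise ValueError("viscosity must be positive")


@dataclass
class FlowSolution:
    node_pressures: dict  # Pa
    segment_flows: dict  # m^3/s, signed by chain orientation
    total_outflow: float  # Q, m^3/s
    resistance: float  # R = delta_p / Q, Pa·s/m^3
    conductance: float  # G = 1/R
    delta_p: float
    viscosity: float
    inlets: list
    outlets: list
    max_interior_residual: float = 0.0
    diagnostic: str = ""

    def to_json(self, path=None):
        payload = {
            "Q_m3_per_s": self.total_outflow,
            "R_Pa_s_per_m3": self.resistance,
            "G_m3_per_Pa_s": self.conductance,
            "delta_p_Pa": self.delta_p,
            "viscosity_Pa_s": self.viscosity,
            "inlets": list(self.inlets),
            "outlets": list(self.outlets),
            "max_interior_residual": self.max_interior_residual,
            "diagnostic": self.diagnostic,
        }
        if path is None:
            return json.dumps(payload, sort_keys=True)
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))
        return path

    def flows_to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"segment_id": sid, "flow_m3_per_s": q} for sid, q in sorted(self.segment_flows.items())]
        )


def classify_terminals(
    g: VascularGraph,
    labels: LabelVolume,
    proximity_um: float | None = None,
    spiral_classes=(SPIRAL,),
) -> tuple[list, list, dict]:
    """Classify spiral-subnetwork terminals as flow inlets or outlets.

    A terminal is an inlet when a radial-class voxel lies within
    ``proximity_um`` of it, an outlet when a canal-class voxel does; when
    both classes are in range the nearer one wins (tie -> inlet); with
    neither it is a sealed wall (role ``"none"``).  Default proximity is 2
    voxels.  Raises when no inlet or no outlet is found (flow problem
    ill-posed).
    """
    h = float(labels.voxel_size_um)
    if proximity_um is None:
        proximity_um = 2.0 * h
    spiral = g.spiral_subgraph(spiral_classes)
    terms = spiral.terminals()
    if not terms:
        raise ValueError("spiral subnetwork has no terminals")
    dist = {}
    for cls in (RADIAL, CANAL):
        if np.any(labels.labels == cls):
            dist[cls] = ndimage.distance_transform_edt(labels.labels != cls) * h
        else:
            dist[cls] = None
    shape = np.asarray(labels.shape)

    def dist_at(cls, nid):
        if dist[cls] is None:
            return np.inf
        idx = np.clip(
            np.round(spiral.nodes[nid].position / h - 0.5).astype(int), 0, shape - 1
        )
        return float(dist[cls][tuple(idx)])

    roles = {}
    for nid in terms:
        d_r, d_c = dist_at(RADIAL, nid), dist_at(CANAL, nid)
        if d_r <= proximity_um and (d_r <= d_c or d_c > proximity_um):
            roles[nid] = "inlet"
        elif d_c <= proximity_um:
            roles[nid] = "outlet"
        else:
            roles[nid] = "none"
    inlets = sorted(n for n, r in roles.items() if r == "inlet")
    outlets = sorted(n for n, r in roles.items() if r == "outlet")
    if not inlets or not outlets:
        raise ValueError(
            f"flow problem ill-posed: {len(inlets)} inlet(s), {len(outlets)} outlet(s) "
            f"within {proximity_um:g} μm of radial/canal vessels"
        )
    return inlets, outlets, roles


def solve_flow(problem: FlowProblem) -> FlowSolution:
    """Solve the network-Poiseuille pressure/flow problem.

    Dirichlet pressures ``delta_p`` at every inlet and 0 at every outlet;
    mass conservation elsewhere (symmetric positive-definite sparse system,
    direct factorization).  Components without both an inlet and an outlet
    carry zero flow; if no component has both, the solution reports G = 0
    with a diagnostic instead of raising.
    """
    from .morphometry import coarsen_chain  # local import: avoid cycle

    g = problem.graph
    step_um = 2.0 * g.voxel_size_um  # same integration spacing as morphometry
    edges = []  # (u, v, conductance, sid)
    for sid in sorted(g.segments):
        seg = g.segments[sid]
        u, v = seg.chain[0], seg.chain[-1]
        pos, rad = coarsen_chain(
            g.segment_positions(sid), g.segment_radii(sid), step_um
        )
        cond = segment_conductance(pos, rad, problem.viscosity)
        edges.append((u, v, cond, sid))

    nxg = nx.Graph()
    nxg.add_nodes_from(g.nodes)
    for u, v, cond, sid in edges:
        if u != v:
            nxg.add_edge(u, v)
    inlets, outlets = set(problem.inlets), set(problem.outlets)
    active_nodes: set = set()
    for comp in nx.connected_components(nxg):
        if comp & inlets and comp & outlets:
            active_nodes |= comp

    pressures = {}
    for nid in g.nodes:
        if nid in inlets:
            pressures[nid] = problem.delta_p
        elif nid in outlets:
            pressures[nid] = 0.0

    diagnostic = ""
    if not active_nodes:
        diagnostic = "no inlet-outlet path: network carries no flow"
        for nid in g.nodes:
            pressures.setdefault(nid, float("nan"))
        flows = {sid: 0.0 for _, _, _, sid in edges}
        return FlowSolution(
            pressures, flows, 0.0, float("inf"), 0.0, problem.delta_p,
            problem.viscosity, sorted(inlets), sorted(outlets), 0.0, diagnostic,
        )

    free = sorted(n for n in active_nodes if n not in inlets and n not in outlets)
    index = {n: i for i, n in enumerate(free)}
    rows, cols, vals = [], [], []
    rhs = np.zeros(len(free))
    for u, v, cond, _sid in edges:
        if u == v or u not in active_nodes:
            continue
        for a, b in ((u, v), (v, u)):
            if a in index:
                i = index[a]
                rows.append(i)
                cols.append(i)
                vals.append(cond)
                if b in index:
                    rows.append(i)
                    cols.append(index[b])
                    vals.append(-cond)
                else:
                    rhs[i] += cond * pressures[b]
    if free:
        lap = coo_matrix((vals, (rows, cols)), shape=(len(free), len(free))).tocsc()
        sol = spsolve(lap, rhs)
        for n, i in index.items():
            pressures[n] = float(sol[i])
    for nid in g.nodes:
        pressures.setdefault(nid, float("nan"))

    flows = {}
    for u, v, cond, sid in edges:
        if u == v or u not in active_nodes:
            flows[sid] = 0.0
        else:
            flows[sid] = cond * (pressures[u] - pressures[v])

    q_out = 0.0
    for u, v, cond, sid in edges:
        if u == v or u not in active_nodes:
            continue
        if v in outlets:
            q_out += flows[sid]
        if u in outlets:
            q_out -= flows[sid]

    # conservation residual at interior (non-Dirichlet) nodes
    net = {n: 0.0 for n in free}
    for u, v, cond, sid in edges:
        if u == v or u not in active_nodes:
            continue
        if u in net:
            net[u] -= flows[sid]
        if v in net:
            net[v] += flows[sid]
    residual = max((abs(x) for x in net.values()), default=0.0)

    if q_out <= 0:
        diagnostic = diagnostic or "zero net outflow"
        return FlowSolution(
            pressures, flows, 0.0, float("inf"), 0.0, problem.delta_p,
            problem.viscosity, sorted(inlets), sorted(outlets), residual, diagnostic,
        )
    resistance = problem.delta_p / q_out
    return FlowSolution(
        node_pressures=pressures,
        segment_flows=flows,
        total_outflow=q_out,
        resistance=resistance,
        conductance=1.0 / resistance,
        delta_p=problem.delta_p,
        viscosity=problem.viscosity,
        inlets=sorted(inlets),
        outlets=sorted(outlets),
        max_interior_residual=residual,
        diagnostic=diagnostic,
    )
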