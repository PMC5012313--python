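"""Steady-state current-conduction solve on a voxel conductivity map.

The electric potential V satisfies div(sigma grad V) = 0 with insulating
outer boundaries, equipotential electrode terminals driven by a current
source, and a thin resistive contact layer under the skin patches.

Discretization is a 7-point finite-volume scheme on the voxel grid: the
conductance of the face between voxels a and b is the harmonic mean of
their conductivities times face area over center distance (exact for
series composition of piecewise-constant sigma, and discretely
conservative).  Faces touching excluded voxels (exterior, internal air,
catheter balloon) carry zero conductance, i.e. a no-flux boundary.
Terminal voxels of one group are collapsed into a single equipotential
node.  The current-source condition is realized by a unit-Dirichlet solve
(1 V / 0 V between the groups) followed by exact linear rescaling of
V, E, J to the requested total current — identical to a constrained
current solve for this two-terminal linear problem, but keeps the system
symmetric positive definite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse import csgraph
from scipy.sparse.linalg import cg

from .grid import ConductivityVolume, LabelVolume, VoxelGrid
from . import phantom as _ph

__all__ = [
    "Terminal",
    "TerminalSet",
    "AssembledSystem",
    "FieldSolution",
    "TopologyError",
    "SolverError",
    "assemble_system",
    "solve_potential",
    "compute_fields",
    "check_current_conservation",
    "terminals_from_phantom",
    "solve_emda",
]

MM = 1e-3  # mm -> m


class TopologyError(ValueError):
    """The conductive domain does not connect the two terminal groups."""


class SolverError(RuntimeError):
    """Iterative solve failed to reach the requested residual."""


@dataclass
class Terminal:
    """One electrode: a named voxel mask tied to a terminal group."""

    name: str
    mask: np.ndarray
    group: str  # "source" or "return"
    contact_layer: bool = False  # thin resistive layer on faces to tissue


@dataclass
class TerminalSet:
    """Electrode terminals, injected current and skin-contact parameters.

    All terminals of a group are tied to one generator pole.  The contact
    conductance per area g = sigma_layer / thickness (S/m^2) models the
    resistive skin film under the surface patches; it raises the terminal
    voltage at fixed current but cannot change interior fields (linear
    rescaling makes them functions of the injected current only).
    """

    terminals: list[Terminal]
    injected_current_A: float = 0.020
    contact_conductance_S_per_m2: float = 2.0

    def __post_init__(self) -> None:
        if self.injected_current_A <= 0:
            raise ValueError("injected current must be > 0")
        if self.contact_conductance_S_per_m2 <= 0:
            raise ValueError("contact conductance must be > 0")
        groups = {t.group for t in self.terminals}
        if groups != {"source", "return"}:
            raise ValueError(
                f"need exactly the two groups 'source' and 'return', got {sorted(groups)}"
            )
        agg = None
        for t in self.terminals:
            m = np.asarray(t.mask, dtype=bool)
            if agg is None:
                agg = np.zeros_like(m)
            if np.any(agg & m):
                raise ValueError("terminal masks must be disjoint")
            agg |= m

    def group_mask(self, group: str, shape) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        for t in self.terminals:
            if t.group == group:
                m |= t.mask
        return m


@dataclass
class AssembledSystem:
    """Sparse finite-volume operator plus the face list used to build it."""

    grid: VoxelGrid
    matrix: sparse.csr_matrix  # (n_interior + 2) square, groups are last two nodes
    face_i: np.ndarray  # node ids
    face_j: np.ndarray
    face_g: np.ndarray  # face conductances, S
    node_id: np.ndarray  # per voxel: interior index, group index, or -1 (excluded)
    n_interior: int
    source_node: int
    return_node: int
    terminal_mask: np.ndarray = field(repr=False, default=None)


def _face_arrays(cond: ConductivityVolume, node_id, contact_mask, plain_mask, g_contact):
    """Yield (i, j, G) node-index arrays for all conductive faces."""
    grid = cond.grid
    sig = cond.sigma
    ex = cond.excluded
    sp = np.asarray(grid.spacing) * MM
    for axis in range(3):
        area = np.prod(np.delete(sp, axis))
        h = sp[axis]
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[axis] = slice(None, -1)
        sl_b[axis] = slice(1, None)
        sl_a, sl_b = tuple(sl_a), tuple(sl_b)
        ok = ~ex[sl_a] & ~ex[sl_b]
        na, nb = node_id[sl_a][ok], node_id[sl_b][ok]
        sa, sb = sig[sl_a][ok], sig[sl_b][ok]
        G = (area / h) * 2.0 * sa * sb / (sa + sb)
        # thin resistive contact layer in series on patch<->tissue faces
        ca = contact_mask[sl_a][ok] & plain_mask[sl_b][ok]
        cb = contact_mask[sl_b][ok] & plain_mask[sl_a][ok]
        cl = ca | cb
        if np.any(cl):
            Gc = g_contact * area
            G = np.where(cl, G * Gc / (G + Gc), G)
        keep = na != nb  # drop faces internal to one equipotential node
        yield na[keep], nb[keep], G[keep]


def assemble_system(cond: ConductivityVolume, terminals: TerminalSet) -> AssembledSystem:
    """Build the SPD finite-volume operator with collapsed terminal nodes.

    Raises :class:`TopologyError` if the conductive domain does not
    connect the source and return groups.  Interior voxels in components
    attached to neither terminal are dropped from the unknown set (their
    potential is undefined and reported as NaN).
    """
    grid = cond.grid
    src = terminals.group_mask("source", grid.shape)
    ret = terminals.group_mask("return", grid.shape)
    if np.any((src | ret) & cond.excluded):
        raise ValueError("terminal voxels must not be excluded")
    term = src | ret
    contact = np.zeros(grid.shape, dtype=bool)
    for t in terminals.terminals:
        if t.contact_layer:
            contact |= t.mask
    plain = ~cond.excluded & ~term

    interior = plain
    n_int = int(interior.sum())
    node_id = np.full(grid.shape, -1, dtype=np.int64)
    node_id[interior] = np.arange(n_int)
    node_id[src] = n_int
    node_id[ret] = n_int + 1
    n_nodes = n_int + 2

    fi, fj, fg = [], [], []
    for a, b, g in _face_arrays(cond, node_id, contact, plain, terminals.contact_conductance_S_per_m2):
        fi.append(a)
        fj.append(b)
        fg.append(g)
    fi = np.concatenate(fi) if fi else np.empty(0, dtype=np.int64)
    fj = np.concatenate(fj) if fj else np.empty(0, dtype=np.int64)
    fg = np.concatenate(fg) if fg else np.empty(0, dtype=float)

    rows = np.concatenate([fi, fj, fi, fj])
    cols = np.concatenate([fi, fj, fj, fi])
    vals = np.concatenate([fg, fg, -fg, -fg])
    A = sparse.coo_matrix((vals, (rows, cols)), shape=(n_nodes, n_nodes)).tocsr()

    # connectivity: source and return must share a component
    adj = sparse.coo_matrix((np.ones(len(fi)), (fi, fj)), shape=(n_nodes, n_nodes))
    n_comp, comp = csgraph.connected_components(adj, directed=False)
    if comp[n_int] != comp[n_int + 1]:
        sizes = np.bincount(comp)
        raise TopologyError(
            "source and return terminals lie in disconnected conductive regions "
            f"({n_comp} components, sizes {sorted(sizes, reverse=True)[:4]}...)"
        )
    # drop stray components (unknowns unreachable from the terminals)
    main = comp == comp[n_int]
    if not main.all():
        keep_vox = main[node_id[interior]]
        new_node = np.full(grid.shape, -1, dtype=np.int64)
        idx = np.flatnonzero(interior.ravel())[keep_vox]
        n_int = len(idx)
        new_node.ravel()[idx] = np.arange(n_int)
        new_node[src] = n_int
        new_node[ret] = n_int + 1
        cond2 = ConductivityVolume(grid=grid, sigma=cond.sigma,
                                   excluded=cond.excluded | (interior & (new_node < 0)))
        return assemble_system(cond2, terminals)

    return AssembledSystem(
        grid=grid, matrix=A, face_i=fi, face_j=fj, face_g=fg, node_id=node_id,
        n_interior=n_int, source_node=n_int, return_node=n_int + 1,
        terminal_mask=term,
    )


def _node_potentials_unit(system: AssembledSystem, tol: float):
    """Solve the unit-Dirichlet problem (source 1 V, return 0 V)."""
    A = system.matrix
    n = system.n_interior
    if n == 0:
        return np.array([1.0, 0.0]), {"iterations": 0, "final_residual": 0.0}
    Auu = A[:n, :n]
    rhs = -A[:n, n:].toarray() @ np.array([1.0, 0.0])
    diag = Auu.diagonal()
    if np.any(diag <= 0):
        raise SolverError("singular interior system (isolated unknowns)")
    M = sparse.diags(1.0 / diag)
    it = {"count": 0}

    def cb(xk):
        it["count"] += 1

    maxiter = int(1000 * max(10.0, n ** (1.0 / 3.0)))
    x, info = cg(Auu, rhs, rtol=tol, atol=0.0, maxiter=maxiter, M=M, callback=cb)
    res = float(np.linalg.norm(Auu @ x - rhs) / np.linalg.norm(rhs))
    if info != 0:
        raise SolverError(
            f"CG failed to converge (info={info}, {it['count']} iterations, "
            f"relative residual {res:.2e}, target {tol:.2e})"
        )
    return np.concatenate([x, [1.0, 0.0]]), {"iterations": it["count"], "final_residual": res}


def _group_current(system: AssembledSystem, node_v: np.ndarray, node: int) -> float:
    """Net current out of one terminal node, from the assembled faces."""
    on_i = system.face_i == node
    on_j = system.face_j == node
    out = np.sum(system.face_g[on_i] * (node_v[node] - node_v[system.face_j[on_i]]))
    out += np.sum(system.face_g[on_j] * (node_v[node] - node_v[system.face_i[on_j]]))
    return float(out)


@dataclass
class FieldSolution:
    """Potential and derived fields of one converged solve.

    V is in volts, E in V/m, J in A/m^2; all are NaN on excluded voxels
    and (for E, J) on terminal voxels, where the fields are undefined.
    """

    grid: VoxelGrid
    V: np.ndarray
    E: np.ndarray  # (..., 3)
    J: np.ndarray  # (..., 3)
    valid: np.ndarray  # voxels where E/J are defined
    terminal_report: dict
    solver_report: dict
    node_v: np.ndarray = field(repr=False, default=None)  # scaled node potentials

    @property
    def E_mag(self) -> np.ndarray:
        return np.linalg.norm(self.E, axis=-1)

    @property
    def J_mag(self) -> np.ndarray:
        return np.linalg.norm(self.J, axis=-1)


def compute_fields(V: np.ndarray, cond: ConductivityVolume,
                   terminal_mask: np.ndarray | None = None):
    """E = -grad V (central differences) and J = sigma E.

    One-sided differences are used at the domain boundary and next to
    excluded or terminal voxels, so a linear potential ramp yields the
    exact constant field everywhere it is defined.  Spacing is converted
    from mm so E is in V/m.
    """
    grid = cond.grid
    if terminal_mask is None:
        terminal_mask = np.zeros(grid.shape, dtype=bool)
    valid = ~cond.excluded & ~terminal_mask & np.isfinite(V)
    E = np.zeros(grid.shape + (3,), dtype=float)
    for axis in range(3):
        h = grid.spacing[axis] * MM
        vp = np.roll(V, -1, axis=axis)  # value at i+1
        vm = np.roll(V, 1, axis=axis)  # value at i-1
        has_p = np.roll(valid, -1, axis=axis)
        has_m = np.roll(valid, 1, axis=axis)
        edge = [slice(None)] * 3
        edge[axis] = -1
        has_p[tuple(edge)] = False
        edge[axis] = 0
        has_m[tuple(edge)] = False
        dv = np.zeros_like(V)
        both = has_p & has_m
        only_p = has_p & ~has_m
        only_m = has_m & ~has_p
        with np.errstate(invalid="ignore"):
            dv[both] = (vp[both] - vm[both]) / (2 * h)
            dv[only_p] = (vp[only_p] - V[only_p]) / h
            dv[only_m] = (V[only_m] - vm[only_m]) / h
        E[..., axis] = -dv
    E[~valid] = np.nan
    J = E * cond.sigma[..., None]
    return E, J, valid


def solve_potential(system: AssembledSystem, cond: ConductivityVolume,
                    terminals: TerminalSet, tol: float = 1e-8) -> FieldSolution:
    """Converge the potential and rescale to the requested injected current.

    Solves the unit-Dirichlet problem with preconditioned CG (deterministic
    zero initial guess), measures the resulting source current I1, and
    scales V, E, J by I/I1 — exact for this linear problem.
    """
    node_v, rep = _node_potentials_unit(system, tol)
    i_unit = _group_current(system, node_v, system.source_node)
    if i_unit <= 0:
        raise SolverError("non-positive unit-solve current; system is degenerate")
    k = terminals.injected_current_A / i_unit
    node_v = node_v * k

    V = np.full(system.grid.shape, np.nan)
    mapped = system.node_id >= 0
    V[mapped] = node_v[system.node_id[mapped]]
    E, J, valid = compute_fields(V, cond, system.terminal_mask)

    i_src = _group_current(system, node_v, system.source_node)
    i_ret = _group_current(system, node_v, system.return_node)
    report = {
        "source": {"potential_V": float(node_v[system.source_node]),
                   "net_current_A": i_src},
        "return": {"potential_V": float(node_v[system.return_node]),
                   "net_current_A": i_ret},
        "voltage_between_terminals_V": float(
            node_v[system.source_node] - node_v[system.return_node]
        ),
        "injected_current_A": terminals.injected_current_A,
    }
    rep = dict(rep)
    rep["n_unknowns"] = system.n_interior
    rep["tol"] = tol
    return FieldSolution(grid=system.grid, V=V, E=E, J=J, valid=valid,
                         terminal_report=report, solver_report=rep, node_v=node_v)


def check_current_conservation(solution: FieldSolution,
                               system: AssembledSystem) -> dict:
    """Audit discrete current conservation of a converged solve.

    Sums the assembled face currents over the closed surface around each
    terminal group and the net divergence at every interior voxel.
    """
    v = solution.node_v
    i_src = _group_current(system, v, system.source_node)
    i_ret = _group_current(system, v, system.return_node)
    target = solution.terminal_report["injected_current_A"]
    # per-node divergence: sum of signed face currents
    flow = system.face_g * (v[system.face_i] - v[system.face_j])
    div = np.zeros(system.n_interior + 2)
    np.add.at(div, system.face_i, flow)
    np.add.at(div, system.face_j, -flow)
    max_div = float(np.max(np.abs(div[: system.n_interior]))) if system.n_interior else 0.0
    return {
        "net_source_current_A": i_src,
        "net_return_current_A": i_ret,
        "relative_imbalance_source": abs(i_src - target) / target,
        "relative_imbalance_pair": abs(i_src + i_ret) / target,
        "max_interior_divergence_A": max_div,
        "max_interior_divergence_rel": max_div / target,
    }


# ===================================================================== #
# Phantom convenience layer
# ===================================================================== #
def terminals_from_phantom(labels: LabelVolume,
                           injected_current_A: float = 0.020,
                           contact_conductance_S_per_m2: float = 2.0,
                           ) -> TerminalSet:
    """Build the EMDA terminal set from a labelled volume.

    The helical catheter electrode is the source (active, positive pole);
    the abdominal patches — split into connected components — are tied
    together as the return, each with the thin resistive skin layer.
    """
    helix = labels.mask("electrode_helix")
    if not helix.any():
        raise ValueError("label volume has no electrode_helix voxels")
    patches = _ph.patch_terminal_masks(labels)
    if not patches:
        raise ValueError("label volume has no electrode_patch voxels")
    terms = [Terminal("helix", helix, "source")]
    for i, m in enumerate(patches):
        terms.append(Terminal(f"patch_{i}", m, "return", contact_layer=True))
    return TerminalSet(terminals=terms, injected_current_A=injected_current_A,
                       contact_conductance_S_per_m2=contact_conductance_S_per_m2)


def solve_emda(labels: LabelVolume, current_A: float = 0.020, tol: float = 1e-8,
               contact_conductance_S_per_m2: float = 2.0,
               conductivity_table: dict[str, float] | None = None,
               ) -> tuple[FieldSolution, AssembledSystem]:
    """Full conduction solve on a labelled phantom; returns solution + system."""
    cond = _ph.assign_conductivity(labels, table=conductivity_table)
    terms = terminals_from_phantom(labels, current_A, contact_conductance_S_per_m2)
    system = assemble_system(cond, terms)
    sol = solve_potential(system, cond, terms, tol=tol)
    return sol, system
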