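"""Passive compartmental cable model for validating extracted morphologies.

A reconstruction can be geometrically close yet electrically wrong — missing
thin branches or inflated diameters change input resistance and voltage
spread.  This module builds a passive (linear, no voltage-gated channels)
compartmental model directly from an SWC tree and compares the steady-state
electrical response of a ground-truth morphology with that of its
extraction.

Discretisation: one frustum compartment per SWC edge; potentials are solved
at the SWC nodes.  Each node carries half the membrane area of every
incident frustum, and the axial conductance along an edge is the exact
frustum resistance ``R = Ra * L / (pi * r0 * r1)`` — both quantities are
invariant under splitting an edge into collinear halves, so refining the
morphology refines the solution without changing the physics.

Units follow the field's conventions: membrane resistivity ``Rm`` in
ohm*cm^2, axial resistivity ``Ra`` in ohm*cm, capacitance ``Cm`` in uF/cm^2,
geometry in um, injected current in nA, voltages in mV.  The defaults
(Rm 10000, Ra 100, Cm 1, E_rest -65) are generic passive-membrane
conventions, not measured values.

The headline comparison is steady-state: inject a constant current at the
root and compare tip voltages (a step-response transient mode is available
via :func:`step_response` for time-domain checks; under a passive model it
adds only the membrane time constant).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import splu, spsolve

from .formats import Morphology, StructureError

__all__ = [
    "PassiveParams",
    "CableModel",
    "build_cable",
    "steady_state",
    "input_resistance",
    "step_response",
    "response_error",
    "ResponseErrorReport",
]


@dataclass
class PassiveParams:
    Rm: float = 10_000.0   # membrane resistivity, ohm*cm^2
    Ra: float = 100.0      # axial resistivity, ohm*cm
    Cm: float = 1.0        # specific capacitance, uF/cm^2
    E_rest: float = -65.0  # resting potential, mV

    def __post_init__(self) -> None:
        if min(self.Rm, self.Ra, self.Cm) <= 0:
            raise ValueError("Rm, Ra and Cm must all be positive")

    def space_constant(self, radius_um: float) -> float:
        """Steady-state length constant (um) of a uniform cable of that radius."""
        a_cm = radius_um * 1e-4
        return float(np.sqrt(self.Rm * a_cm / (2.0 * self.Ra)) * 1e4)


_UM2_TO_CM2 = 1e-8
_UM_TO_CM = 1e-4


def _frustum_lateral_area(r0: np.ndarray, r1: np.ndarray, L: np.ndarray
                          ) -> np.ndarray:
    """Lateral (slant) surface of a frustum, um^2."""
    return np.pi * (r0 + r1) * np.sqrt(L ** 2 + (r1 - r0) ** 2)


@dataclass
class CableModel:
    """Compartmentalised passive neuron.

    ``node_ids`` aligns with the solution vector; ``edges`` are (child_row,
    parent_row) with per-edge frustum ``areas`` (um^2) and axial
    conductances ``g_axial`` (S).  ``g_membrane`` (S) and ``capacitance``
    (F) are nodal (half of each incident frustum).
    """

    node_ids: np.ndarray
    xyz: np.ndarray
    radii: np.ndarray
    edges: np.ndarray
    areas: np.ndarray
    g_axial: np.ndarray
    g_membrane: np.ndarray
    capacitance: np.ndarray
    params: PassiveParams
    injection_row: int

    @property
    def n(self) -> int:
        return len(self.node_ids)

    def total_membrane_area(self) -> float:
        """Sum of frustum lateral areas, um^2."""
        return float(self.areas.sum())

    def tips(self) -> np.ndarray:
        """Rows of leaf nodes."""
        has_child = np.zeros(self.n, dtype=bool)
        has_child[self.edges[:, 1]] = True
        is_child = np.zeros(self.n, dtype=bool)
        is_child[self.edges[:, 0]] = True
        return np.nonzero(~has_child & is_child)[0] if len(self.edges) else np.array([0])

    def conductance_matrix(self) -> sparse.csr_matrix:
        """Symmetric positive-definite nodal conductance matrix (S)."""
        n = self.n
        rows, cols, vals = [], [], []
        for (c, p), g in zip(self.edges, self.g_axial):
            rows += [c, p, c, p]
            cols += [c, p, p, c]
            vals += [g, g, -g, -g]
        G = sparse.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
        return G + sparse.diags(self.g_membrane)


def build_cable(m: Morphology, params: PassiveParams | None = None,
                injection_node: int | None = None) -> CableModel:
    """Compartmentalise a single-rooted morphology.

    Zero-length edges (duplicate points from tracing) are merged into their
    parent node with a warning.  Multi-root morphologies are rejected —
    connect the fragments first.
    """
    params = params or PassiveParams()
    m.validate()
    if len(m.roots()) != 1:
        raise StructureError(
            f"cable model needs a single-rooted tree, got {len(m.roots())} roots; "
            "apply connect edits first")
    m = m.toposorted()

    # merge zero-length edges: remap child -> parent
    pidx = m.parent_index()
    keep = np.ones(m.n_nodes, dtype=bool)
    alias = np.arange(m.n_nodes)
    lengths_all = np.zeros(m.n_nodes)
    for row in range(m.n_nodes):
        p = pidx[row]
        if p < 0:
            continue
        L = float(np.linalg.norm(m.xyz[row] - m.xyz[alias[p]]))
        if L < 1e-12:
            keep[row] = False
            alias[row] = alias[p]
        else:
            alias[row] = row
            lengths_all[row] = L
    if not keep.all():
        warnings.warn(f"merged {int((~keep).sum())} zero-length compartment(s)",
                      stacklevel=2)
    rows_kept = np.nonzero(keep)[0]
    new_row = {old: new for new, old in enumerate(rows_kept)}

    edges, areas, g_ax = [], [], []
    for row in rows_kept:
        p = pidx[row]
        if p < 0:
            continue
        p_eff = alias[p]
        c, pr = new_row[row], new_row[p_eff]
        r0, r1 = float(m.radii[p_eff]), float(m.radii[row])
        L = lengths_all[row]
        area = float(_frustum_lateral_area(np.float64(r0), np.float64(r1),
                                           np.float64(L)))
        R = params.Ra * (L * _UM_TO_CM) / (np.pi * r0 * r1 * _UM2_TO_CM2)
        edges.append((c, pr))
        areas.append(area)
        g_ax.append(1.0 / R)

    n = len(rows_kept)
    g_m = np.zeros(n)
    cap = np.zeros(n)
    for (c, pr), area in zip(edges, areas):
        for node in (c, pr):
            g_m[node] += 0.5 * area * _UM2_TO_CM2 / params.Rm
            cap[node] += 0.5 * area * _UM2_TO_CM2 * params.Cm * 1e-6
    if n == 1:  # single isolated node: sphere membrane
        area = 4.0 * np.pi * float(m.radii[rows_kept[0]]) ** 2
        g_m[0] = area * _UM2_TO_CM2 / params.Rm
        cap[0] = area * _UM2_TO_CM2 * params.Cm * 1e-6
        areas = [area]

    node_ids = m.ids[rows_kept]
    inj_row = 0
    if injection_node is not None:
        hits = np.nonzero(node_ids == injection_node)[0]
        if len(hits) == 0:
            raise KeyError(f"injection node {injection_node} not in model")
        inj_row = int(hits[0])
    else:
        root_rows = np.nonzero(m.parent_ids[rows_kept] == -1)[0]
        inj_row = int(root_rows[0])

    return CableModel(node_ids, m.xyz[rows_kept], m.radii[rows_kept],
                      np.asarray(edges, dtype=np.int64).reshape(-1, 2),
                      np.asarray(areas), np.asarray(g_ax), g_m, cap,
                      params, inj_row)


def steady_state(model: CableModel, I_nA: float) -> np.ndarray:
    """Steady-state membrane potential (mV) per node for a constant injection.

    Solves ``G v = i`` for the deflection from rest; with any finite Rm the
    system is strictly positive definite, so a connected tree always has a
    unique solution.  Kirchhoff balance holds at every node by construction.
    """
    rhs = np.zeros(model.n)
    rhs[model.injection_row] = I_nA * 1e-9  # A
    G = model.conductance_matrix()
    if model.n == 1:
        v = rhs / G.toarray()[0]
    else:
        v = spsolve(G.tocsc(), rhs)
    return model.params.E_rest + v * 1e3  # volts -> mV deflection


def input_resistance(model: CableModel, I_nA: float = 0.1) -> float:
    """Input resistance at the injection site, megohms."""
    v = steady_state(model, I_nA)
    deflection_mV = v[model.injection_row] - model.params.E_rest
    return float(deflection_mV / I_nA)  # mV / nA = megohm


def step_response(model: CableModel, I_nA: float, t_end: float,
                  dt: float = 25e-6) -> tuple[np.ndarray, np.ndarray]:
    """Backward-Euler step response: times (s) and node voltages (mV, n_t x n)."""
    G = model.conductance_matrix().tocsc()
    C = sparse.diags(model.capacitance).tocsc()
    A = (C / dt + G).tocsc()
    lu = splu(A)
    rhs_inj = np.zeros(model.n)
    rhs_inj[model.injection_row] = I_nA * 1e-9
    n_steps = max(int(np.ceil(t_end / dt)), 1)
    v = np.zeros(model.n)
    times = np.empty(n_steps)
    out = np.empty((n_steps, model.n))
    for k in range(n_steps):
        v = lu.solve(C @ v / dt + rhs_inj)
        times[k] = (k + 1) * dt
        out[k] = model.params.E_rest + v * 1e3
    return times, out


@dataclass
class ResponseErrorReport:
    """Electrical discrepancy between two morphologies under passive stimulation."""

    tip_error: float            # mean relative tip-voltage deflection error
    rin_relative_error: float   # relative input-resistance error
    n_tips_matched: int


def response_error(gt: Morphology, test: Morphology,
                   params: PassiveParams | None = None,
                   I_nA: float = 0.1) -> ResponseErrorReport:
    """Fig-of-merit for electrical fidelity of an extraction.

    Both trees get the same constant current at their roots; tip voltages
    are compared after pairing each ground-truth tip with the
    nearest-Euclidean test tip.  The error is the mean
    ``|dV_test - dV_gt| / |dV_gt|`` over matched tips (deflections from
    rest), with the input-resistance relative error reported alongside.
    """
    params = params or PassiveParams()
    mg = build_cable(gt, params)
    mt = build_cable(test, params)
    vg = steady_state(mg, I_nA) - params.E_rest
    vt = steady_state(mt, I_nA) - params.E_rest
    tips_g, tips_t = mg.tips(), mt.tips()
    if len(tips_g) == 0 or len(tips_t) == 0:
        raise StructureError("both morphologies need at least one tip")
    errs = []
    for tg in tips_g:
        d = np.linalg.norm(mt.xyz[tips_t] - mg.xyz[tg], axis=1)
        tt = tips_t[int(np.argmin(d))]
        errs.append(abs(vt[tt] - vg[tg]) / abs(vg[tg]))
    rin_g = vg[mg.injection_row] / I_nA
    rin_t = vt[mt.injection_row] / I_nA
    return ResponseErrorReport(float(np.mean(errs)),
                               float(abs(rin_t - rin_g) / abs(rin_g)),
                               len(tips_g))
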