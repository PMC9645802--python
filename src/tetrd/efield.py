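"""Deterministic membrane-potential solver on mesh vertices.

The intracellular volume conducts ohmically with resistivity Ra; linear
finite elements on the tetrahedrons give a symmetric positive-semidefinite
stiffness (volume-conductance) matrix.  Membrane capacitance, leak and
channel conductances live on patch triangles and are lumped to vertices with
1/3-area weights.  One EField window advances the vertex potentials by a
single backward-Euler solve

    (C/dt + K + diag(G)) v' = (C/dt) v + G_leak*E_leak + G_chan*E_chan + I,

with channel conductances frozen at their window-end counts (implicit, hence
unconditionally stable) and GHK currents evaluated explicitly at the pre-step
voltage.  The sparse system is factorized with SuperLU and the factorization
reused while the conductance pattern is unchanged; a Jacobi-preconditioned
conjugate-gradient fallback is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.constants import physical_constants, R as GAS_R

FARADAY = physical_constants["Faraday constant"][0]
DEFAULT_TEMPERATURE = 293.15  # K


@dataclass
class MembraneParams:
    """Passive electrical constants of a membrane patch."""

    capacitance: float          # F/m^2
    leak_g: float = 0.0         # S/m^2
    leak_erev: float = 0.0      # V
    resistivity: float = 1.0    # Ohm*m (intracellular, volume conduction)

    def __post_init__(self):
        if self.capacitance <= 0:
            raise ValueError("membrane capacitance must be positive")
        if self.resistivity <= 0:
            raise ValueError("axial resistivity must be positive")
        if self.leak_g < 0:
            raise ValueError("leak conductance must be >= 0")


@dataclass
class VoltageState:
    """Vertex potentials and the assembled operators."""

    v: np.ndarray                 # (nv,) volts
    stiffness: sp.csr_matrix      # (nv, nv) S, volume conductance
    capacitance: np.ndarray       # (nv,) F, lumped membrane capacitance
    g_leak: np.ndarray            # (nv,) S, lumped leak conductance
    ge_leak: np.ndarray           # (nv,) A, lumped leak conductance * reversal
    _cache: dict = field(default_factory=dict)

    @property
    def num_vertices(self) -> int:
        return len(self.v)

    def triangle_voltage(self, tris: np.ndarray) -> np.ndarray:
        """Mean vertex potential per triangle (volts)."""
        return self.v[tris].mean(axis=1)


def tet_gradients(vertices: np.ndarray, tets: np.ndarray):
    """Constant shape-function gradients and volumes of linear tets."""
    p = vertices[tets]                      # (nt, 4, 3)
    e = p[:, 1:] - p[:, :1]                 # (nt, 3, 3)
    vols = np.abs(np.linalg.det(e)) / 6.0
    inv = np.linalg.inv(e)                  # rows: gradients of phi1..3 in cols
    g123 = np.transpose(inv, (0, 2, 1))     # (nt, 3, 3): grad phi_1..3
    g0 = -g123.sum(axis=1, keepdims=True)
    return np.concatenate([g0, g123], axis=1), vols


def assemble_stiffness(mesh, resistivity: float) -> sp.csr_matrix:
    """FEM volume-conductance matrix with conductivity 1/Ra."""
    grads, vols = tet_gradients(mesh.vertices, mesh.tets)
    sigma = 1.0 / resistivity
    ke = sigma * vols[:, None, None] * np.einsum("nid,njd->nij", grads, grads)
    nt = len(mesh.tets)
    rows = np.repeat(mesh.tets, 4, axis=1).reshape(nt, 4, 4)
    cols = np.tile(mesh.tets[:, None, :], (1, 4, 1))
    K = sp.coo_matrix(
        (ke.ravel(), (rows.ravel(), cols.ravel())),
        shape=(mesh.num_vertices, mesh.num_vertices),
    ).tocsr()
    K.sum_duplicates()
    return K


def assemble_efield_system(mesh, measures, membranes, v_init: float = 0.0) -> VoltageState:
    """Assemble operators for a mesh with one or more membrane patches.

    ``membranes`` is a list of (triangle index array, MembraneParams).  The
    surface-ratio correction recorded by the cable generator is applied to
    all surface densities.  Resistivity is taken from the first membrane
    (one intracellular medium).
    """
    if not membranes:
        raise ValueError("at least one membrane patch is required")
    rho = mesh.meta.get("surface_ratio", 1.0)
    K = assemble_stiffness(mesh, membranes[0][1].resistivity)
    nv = mesh.num_vertices
    C = np.zeros(nv)
    G = np.zeros(nv)
    GE = np.zeros(nv)
    for tris, mp in membranes:
        areas = measures.tri_areas[tris] * rho
        for tri, a in zip(mesh.tris[tris], areas):
            C[tri] += mp.capacitance * a / 3.0
            G[tri] += mp.leak_g * a / 3.0
            GE[tri] += mp.leak_g * mp.leak_erev * a / 3.0
    if not C.any():
        raise ValueError("no membrane capacitance assembled; check patch tags")
    return VoltageState(np.full(nv, float(v_init)), K, C, G, GE)


def ghk_current(P: float, z: int, v: float, c_in: float, c_out: float,
                temperature: float = DEFAULT_TEMPERATURE):
    """Goldman-Hodgkin-Katz current through one open channel (amperes).

    I = P z^2 F^2 V/(RT) * (c_in - c_out e^{-zFV/RT}) / (1 - e^{-zFV/RT});
    the removable singularity at V = 0 is handled by the series limit
    I -> P z F (c_in - c_out).  Concentrations in mol/m^3, P in m^3/s.
    """
    v = np.asarray(v, dtype=float)
    u = z * FARADAY * v / (GAS_R * temperature)

    def phi(x):
        x = np.asarray(x, dtype=float)
        small = np.abs(x) < 1e-9
        safe = np.where(small, 1.0, x)
        return np.where(small, 1.0 + x / 2.0 + x * x / 12.0, safe / -np.expm1(-safe))

    out = P * z * FARADAY * (c_in * phi(u) - c_out * phi(-u))
    return out if out.ndim else float(out)


def efield_step(vs: VoltageState, dt: float,
                g_extra: np.ndarray | None = None,
                ge_extra: np.ndarray | None = None,
                i_ext: np.ndarray | None = None,
                solver: str = "direct") -> np.ndarray:
    """One backward-Euler step of length ``dt``; updates and returns ``vs.v``.

    ``g_extra``/``ge_extra`` are per-vertex channel conductances and
    conductance-times-reversal terms (treated implicitly); ``i_ext`` collects
    injected plus explicit (GHK) currents.
    """
    if dt <= 0:
        raise ValueError("EField step must be positive")
    nv = vs.num_vertices
    G = vs.g_leak if g_extra is None else vs.g_leak + g_extra
    GE = vs.ge_leak if ge_extra is None else vs.ge_leak + ge_extra
    if not vs.capacitance.any() and not G.any():
        raise ValueError(
            "singular EField system: no capacitance and no membrane conductance; "
            "ground a reference vertex or declare a membrane")

    c_over_dt = vs.capacitance / dt
    b = c_over_dt * vs.v + GE
    if i_ext is not None:
        b = b + i_ext

    key = vs._cache.get("key")
    new_key = (dt, None if g_extra is None else g_extra.tobytes())
    if solver == "direct":
        if key != new_key:
            A = (vs.stiffness + sp.diags(c_over_dt + G)).tocsc()
            vs._cache["key"] = new_key
            vs._cache["solve"] = spla.factorized(A)
        vs.v = vs._cache["solve"](b)
    elif solver == "cg":
        A = (vs.stiffness + sp.diags(c_over_dt + G)).tocsr()
        M = sp.diags(1.0 / A.diagonal())
        v, info = spla.cg(A, b, x0=vs.v, M=M, rtol=1e-12, atol=0.0)
        if info != 0:
            raise RuntimeError(f"CG failed to converge (info={info})")
        vs.v = v
    else:
        raise ValueError(f"unknown solver {solver!r}")
    return vs.v


def hh_gating_model(g_single_na: float = 4e-12, g_single_k: float = 4e-12,
                    e_na: float = 0.050, e_k: float = -0.077):
    """Stochastic Hodgkin-Huxley Na and K channels as multi-state models.

    Na has 8 states m{0..3}h{0..1} (conducting: m3h1), K has 5 states n{0..4}
    (conducting: n4).  Transition rates are the squid-axon alpha/beta forms
    with the usual lattice multiplicities (e.g. m0 -> m1 at 3*alpha_m).
    Returns (na_channel, k_channel).
    """
    from .model import Channel, ChannelCurrent, RateSpec

    def b(name):
        return RateSpec(kind="builtin", name=name)

    na_states = [f"m{i}h{j}" for j in (0, 1) for i in range(4)]
    na_tr = []
    for j in (0, 1):
        for i in range(3):
            na_tr.append((f"m{i}h{j}", f"m{i + 1}h{j}", 3 - i, b("hh_alpha_m")))
            na_tr.append((f"m{i + 1}h{j}", f"m{i}h{j}", i + 1, b("hh_beta_m")))
    for i in range(4):
        na_tr.append((f"m{i}h0", f"m{i}h1", 1, b("hh_alpha_h")))
        na_tr.append((f"m{i}h1", f"m{i}h0", 1, b("hh_beta_h")))
    na = Channel(
        name="NaHH", states=na_states, transitions=na_tr,
        currents=[ChannelCurrent(state="m3h1", kind="ohmic",
                                 g_single=g_single_na, erev=e_na)],
    )

    k_states = [f"n{i}" for i in range(5)]
    k_tr = []
    for i in range(4):
        k_tr.append((f"n{i}", f"n{i + 1}", 4 - i, b("hh_alpha_n")))
        k_tr.append((f"n{i + 1}", f"n{i}", i + 1, b("hh_beta_n")))
    kch = Channel(
        name="KHH", states=k_states, transitions=k_tr,
        currents=[ChannelCurrent(state="n4", kind="ohmic",
                                 g_single=g_single_k, erev=e_k)],
    )
    return na, kch
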