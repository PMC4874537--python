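"""Passive compartmental model of a dendritic tree with one attachable spine.

The estimator this module exists for: the spine→soma EPSP attenuation ratio
is, for fixed synaptic kinetics, almost exactly linear in the spine neck
resistance R_neck and almost independent of the synaptic conductance G_syn.
Simulating the attenuation ratio as a function of distance for a grid of
R_neck values therefore lets each experimentally measured (distance,
attenuation) pair be inverted to an R_neck estimate by linear interpolation.

Model structure
---------------
* a tree of cylindrical sections (soma, basal/apical dendrites) with uniform
  passive membrane (Cm, Rm) and axial resistivity Ra; dendritic sections may
  carry a spine-membrane correction factor F (Cm → F·Cm, Rm → Rm/F) standing
  in for spines not modelled explicitly;
* one explicit spine: a single-compartment cylindrical head (default 1 μm ×
  1 μm) joined to the dendrite by a purely resistive neck (R_neck, MΩ);
* a dual-exponential synaptic conductance g(t) ∝ e^(−t/τ_fall) − e^(−t/τ_rise)
  (defaults 4 / 0.5 ms) on the head, reversal −5 mV absolute.

Numerics: spatial compartments ≤ a configurable fraction of the local DC
length constant; time stepping is Crank–Nicolson (A-stable, second order)
with the time-varying synaptic conductance handled by a Sherman–Morrison
rank-1 update so the system matrix is factorised once per simulation.

Units: mV, ms, nA, μS, nF, μm (so MΩ = mV/nA and μS = 1/MΩ).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.linalg import splu

__all__ = [
    "Section",
    "Morphology",
    "PassiveParams",
    "SpineSynapse",
    "CableModel",
    "AttenuationCurve",
    "RneckInference",
    "discretize",
    "input_resistance",
    "simulate_epsp",
    "scan_locations",
    "infer_rneck",
    "neck_diameter_for_rneck",
    "rneck_for_neck_diameter",
    "synthetic_l5_tree",
    "read_swc",
]

OHM_CM_TO_OHM_UM = 1.0e4


# ---------------------------------------------------------------------------
# morphology
# ---------------------------------------------------------------------------

@dataclass
class Section:
    """An unbranched cylindrical piece of the tree.

    ``parent`` is the index of the parent section (−1 for the root, which
    is the soma); children attach to the distal (arc = 1) end of their
    parent.  ``f_factor`` is the spine-membrane correction applied to this
    section's Cm and Rm.
    """

    length_um: float
    diam_um: float
    kind: str = "basal"  # soma | basal | apical | axon
    parent: int = -1
    f_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.length_um <= 0 or self.diam_um <= 0:
            raise ValueError("section length and diameter must be positive")


@dataclass
class Morphology:
    sections: list[Section]

    def __post_init__(self) -> None:
        if not self.sections:
            raise ValueError("empty morphology")
        roots = [i for i, s in enumerate(self.sections) if s.parent < 0]
        if len(roots) != 1 or roots[0] != 0:
            raise ValueError("morphology must have the single root at index 0")
        for i, s in enumerate(self.sections):
            if s.parent >= i:
                raise ValueError("sections must be listed parents-first")


@dataclass(frozen=True)
class PassiveParams:
    """Uniform passive membrane and cytoplasm properties."""

    cm_uf_cm2: float = 0.75
    ra_ohm_cm: float = 150.0
    rm_ohm_cm2: float = 30000.0
    v_rest_mv: float = -70.35

    def __post_init__(self) -> None:
        if min(self.cm_uf_cm2, self.ra_ohm_cm, self.rm_ohm_cm2) <= 0:
            raise ValueError("passive parameters must be positive")

    def lambda_dc_um(self, diam_um: float, f_factor: float = 1.0) -> float:
        """DC length constant sqrt(Rm·d/(4·Ra)) in μm."""
        rm = self.rm_ohm_cm2 / f_factor
        lam_cm = np.sqrt(rm * (diam_um * 1e-4) / (4.0 * self.ra_ohm_cm))
        return float(lam_cm * 1e4)


def neck_diameter_for_rneck(r_neck_mohm: float, neck_len_um: float = 1.0,
                            ra_ohm_cm: float = 150.0) -> float:
    """Neck diameter (μm) giving R_neck = 4·Ra·L/(π·d²)."""
    if r_neck_mohm <= 0:
        raise ValueError("R_neck must be positive")
    ra_ohm_um = ra_ohm_cm * OHM_CM_TO_OHM_UM
    d2 = 4.0 * ra_ohm_um * neck_len_um / (np.pi * r_neck_mohm * 1e6)
    return float(np.sqrt(d2))


def rneck_for_neck_diameter(diam_um: float, neck_len_um: float = 1.0,
                            ra_ohm_cm: float = 150.0) -> float:
    """Inverse of :func:`neck_diameter_for_rneck`, MΩ."""
    ra_ohm_um = ra_ohm_cm * OHM_CM_TO_OHM_UM
    return float(4.0 * ra_ohm_um * neck_len_um / (np.pi * diam_um**2) / 1e6)


@dataclass
class SpineSynapse:
    """Single-compartment spine head + resistive neck + synapse."""

    head_diam_um: float = 1.0
    head_len_um: float = 1.0
    neck_len_um: float = 1.0
    r_neck_mohm: float = 200.0
    g_syn_ns: float = 0.5
    tau_rise_ms: float = 0.5
    tau_fall_ms: float = 4.0
    e_rev_mv: float = -5.0  # absolute
    onset_ms: float = 1.0

    def __post_init__(self) -> None:
        if self.r_neck_mohm < 0:
            raise ValueError("R_neck must be non-negative")
        if not 0 < self.tau_rise_ms < self.tau_fall_ms:
            raise ValueError("require 0 < τ_rise < τ_fall")
        if self.g_syn_ns < 0:
            raise ValueError("G_syn must be non-negative")

    @property
    def neck_diam_um(self) -> float:
        return neck_diameter_for_rneck(self.r_neck_mohm, self.neck_len_um)

    @property
    def head_area_cm2(self) -> float:
        return float(np.pi * self.head_diam_um * self.head_len_um * 1e-8)

    def conductance_us(self, t_ms: np.ndarray) -> np.ndarray:
        """Dual-exponential conductance time course, μS, peak = G_syn."""
        t = np.asarray(t_ms, dtype=float) - self.onset_ms
        tt = np.clip(t, 0.0, None)
        raw = np.exp(-tt / self.tau_fall_ms) - np.exp(-tt / self.tau_rise_ms)
        raw[t < 0] = 0.0
        tr, td = self.tau_rise_ms, self.tau_fall_ms
        t_pk = np.log(td / tr) / (1.0 / tr - 1.0 / td)
        norm = np.exp(-t_pk / td) - np.exp(-t_pk / tr)
        return (self.g_syn_ns * 1e-3) * raw / norm


# ---------------------------------------------------------------------------
# discretisation
# ---------------------------------------------------------------------------

@dataclass
class CableModel:
    """Compartmentalised passive tree ready for simulation.

    Arrays are per compartment: capacitance ``c_nf``, membrane leak
    ``gm_us``, half-axial resistance to each neighbour, tree distance to the
    soma ``dist_um`` and the originating section index.
    """

    morphology: Morphology
    params: PassiveParams
    c_nf: np.ndarray
    gm_us: np.ndarray
    parent: np.ndarray          # parent compartment index (−1 for soma)
    g_parent_us: np.ndarray     # axial conductance to parent
    dist_um: np.ndarray
    kind: np.ndarray            # str per compartment
    section: np.ndarray
    soma_node: int = 0

    @property
    def n(self) -> int:
        return self.c_nf.size

    def conductance_matrix(self) -> sparse.csc_matrix:
        """Symmetric (membrane + axial) conductance matrix, μS."""
        n = self.n
        rows, cols, vals = [], [], []
        diag = self.gm_us.copy()
        for i in range(n):
            p = self.parent[i]
            if p >= 0:
                g = self.g_parent_us[i]
                diag[i] += g
                diag[p] += g
                rows += [i, p]
                cols += [p, i]
                vals += [-g, -g]
        rows += list(range(n))
        cols += list(range(n))
        vals += list(diag)
        return sparse.csc_matrix((vals, (rows, cols)), shape=(n, n))

    def nodes_of_kind(self, kind: str) -> np.ndarray:
        return np.flatnonzero(self.kind == kind)


def discretize(
    morph: Morphology,
    params: PassiveParams | None = None,
    max_fraction_of_lambda: float = 0.1,
    min_nseg: int = 1,
) -> CableModel:
    """Split sections into compartments no longer than a set fraction of the
    local DC length constant and assemble the model arrays.

    Axial conductance between adjacent compartment centres is the series
    combination of the two half-compartment resistances; a spherical soma is
    one isopotential compartment with zero internal axial resistance.
    """
    params = params or PassiveParams()
    c_nf, gm_us, parent, gpar, dist, kind, secidx = [], [], [], [], [], [], []
    sec_last_node: list[int] = []   # distal node index of each section
    sec_last_halfr: list[float] = []  # half-axial resistance at distal end (MΩ)
    sec_end_dist: list[float] = []

    ra_ohm_um = params.ra_ohm_cm * OHM_CM_TO_OHM_UM

    for si, sec in enumerate(morph.sections):
        f = sec.f_factor
        if sec.kind == "soma":
            # isopotential sphere-equivalent: area π·d·L (= π·d² when L=d)
            area_cm2 = np.pi * sec.diam_um * sec.length_um * 1e-8
            node = len(c_nf)
            c_nf.append(params.cm_uf_cm2 * f * area_cm2 * 1e3)
            gm_us.append(area_cm2 / (params.rm_ohm_cm2 / f) * 1e6)
            parent.append(-1 if sec.parent < 0 else sec_last_node[sec.parent])
            gpar.append(0.0)
            dist.append(0.0)
            kind.append(sec.kind)
            secidx.append(si)
            if sec.parent >= 0:
                gpar[-1] = 1.0 / max(sec_last_halfr[sec.parent], 1e-9)
            sec_last_node.append(node)
            sec_last_halfr.append(0.0)
            sec_end_dist.append(0.0)
            continue

        lam = params.lambda_dc_um(sec.diam_um, f)
        nseg = max(min_nseg, int(np.ceil(sec.length_um / (max_fraction_of_lambda * lam))))
        dx = sec.length_um / nseg
        area_cm2 = np.pi * sec.diam_um * dx * 1e-8
        # half-compartment axial resistance in MΩ
        r_half = ra_ohm_um * (dx / 2.0) / (np.pi * sec.diam_um**2 / 4.0) * 1e-6
        if sec.parent < 0:
            raise ValueError("non-soma root section")
        p_node = sec_last_node[sec.parent]
        p_halfr = sec_last_halfr[sec.parent]
        d0 = sec_end_dist[sec.parent]
        for k in range(nseg):
            node = len(c_nf)
            c_nf.append(params.cm_uf_cm2 * f * area_cm2 * 1e3)
            gm_us.append(area_cm2 / (params.rm_ohm_cm2 / f) * 1e6)
            parent.append(p_node)
            gpar.append(1.0 / (r_half + p_halfr))
            dist.append(d0 + (k + 0.5) * dx)
            kind.append(sec.kind)
            secidx.append(si)
            p_node, p_halfr = node, r_half
        sec_last_node.append(p_node)
        sec_last_halfr.append(r_half)
        sec_end_dist.append(d0 + sec.length_um)

    return CableModel(
        morphology=morph,
        params=params,
        c_nf=np.array(c_nf),
        gm_us=np.array(gm_us),
        parent=np.array(parent, dtype=int),
        g_parent_us=np.array(gpar),
        dist_um=np.array(dist),
        kind=np.array(kind, dtype=object),
        section=np.array(secidx, dtype=int),
    )


def input_resistance(model: CableModel, node: int = 0, i_na: float = 0.01) -> float:
    """Steady-state input resistance ΔV/ΔI at a compartment, MΩ."""
    A = model.conductance_matrix()
    b = np.zeros(model.n)
    b[node] = i_na
    v = splu(A).solve(b)
    return float(v[node] / i_na)


# ---------------------------------------------------------------------------
# EPSP simulation
# ---------------------------------------------------------------------------

@dataclass
class EpspResult:
    t_ms: np.ndarray
    v_head: np.ndarray     # deviation from rest, mV
    v_parent: np.ndarray
    v_soma: np.ndarray
    site_node: int
    dist_um: float

    @property
    def peak_head(self) -> float:
        return float(np.max(self.v_head))

    @property
    def peak_parent(self) -> float:
        return float(np.max(self.v_parent))

    @property
    def peak_soma(self) -> float:
        return float(np.max(self.v_soma))

    @property
    def attenuation_ratio(self) -> float:
        return self.peak_head / self.peak_soma


def simulate_epsp(
    model: CableModel,
    spine: SpineSynapse,
    site_node: int,
    t_stop_ms: float = 40.0,
    dt_ms: float = 0.025,
) -> EpspResult:
    """Attach the spine at a compartment, drive the dual-exponential synapse
    and integrate the passive system by Crank–Nicolson.

    The synaptic conductance enters the system matrix as a rank-1 update on
    the head diagonal; the constant part is LU-factorised once and each step
    is completed with the Sherman–Morrison formula, so the cost per step is
    one triangular solve.  R_neck = 0 is handled exactly by merging the head
    compartment into its parent.
    """
    p = model.params
    merged = spine.r_neck_mohm == 0.0
    n = model.n if merged else model.n + 1
    head = site_node if merged else model.n

    c = np.empty(n)
    c[: model.n] = model.c_nf
    gm = np.empty(n)
    gm[: model.n] = model.gm_us
    head_c = p.cm_uf_cm2 * spine.head_area_cm2 * 1e3
    head_gm = spine.head_area_cm2 / p.rm_ohm_cm2 * 1e6
    if merged:
        c[site_node] += head_c
        gm[site_node] += head_gm
    else:
        c[head] = head_c
        gm[head] = head_gm

    A = model.conductance_matrix().tolil()
    if not merged:
        A = sparse.bmat(
            [[A, None], [None, sparse.lil_matrix((1, 1))]], format="lil"
        )
        g_neck = 1.0 / spine.r_neck_mohm  # μS
        A[head, head] = head_gm + g_neck
        A[site_node, site_node] += g_neck
        A[head, site_node] = -g_neck
        A[site_node, head] = -g_neck
    else:
        A[site_node, site_node] += head_gm
    A = A.tocsc()

    nt = int(round(t_stop_ms / dt_ms)) + 1
    t = np.arange(nt) * dt_ms
    g = spine.conductance_us(t)
    e_dev = spine.e_rev_mv - p.v_rest_mv  # driving force at rest, mV

    Cdt = sparse.diags(c / dt_ms, format="csc")
    M0 = (Cdt + 0.5 * A).tocsc()
    lu = splu(M0)
    e_vec = np.zeros(n)
    e_vec[head] = 1.0
    z = lu.solve(e_vec)
    z_h = z[head]

    v = np.zeros(n)
    vh = np.empty(nt)
    vp = np.empty(nt)
    vs = np.empty(nt)
    vh[0] = vp[0] = vs[0] = 0.0
    half_A = 0.5 * A

    for k in range(1, nt):
        g_old, g_new = g[k - 1], g[k]
        b = (c / dt_ms) * v - half_A @ v
        b[head] += -0.5 * g_old * (v[head] - e_dev) + 0.5 * g_new * e_dev
        y = lu.solve(b)
        alpha = 0.5 * g_new
        v = y - (alpha * y[head] / (1.0 + alpha * z_h)) * z
        if not np.all(np.isfinite(v)):
            raise FloatingPointError(
                f"integration failure at t={k * dt_ms:.3f} ms "
                f"(R_neck={spine.r_neck_mohm}, G_syn={spine.g_syn_ns} nS)"
            )
        vh[k] = v[head]
        vp[k] = v[site_node]
        vs[k] = v[model.soma_node]

    return EpspResult(
        t_ms=t, v_head=vh, v_parent=vp, v_soma=vs,
        site_node=site_node, dist_um=float(model.dist_um[site_node]),
    )


# ---------------------------------------------------------------------------
# attenuation sweep and R_neck inference
# ---------------------------------------------------------------------------

@dataclass
class AttenuationCurve:
    """Quadratic summary ratio(d) = c0 + c2·d² of a per-R_neck site sweep."""

    r_neck_mohm: float
    c0: float
    c2: float
    c1: float = 0.0
    distances_um: np.ndarray = field(default_factory=lambda: np.empty(0))
    ratios: np.ndarray = field(default_factory=lambda: np.empty(0))
    residual_sd: float = 0.0

    def __call__(self, d_um):
        d = np.asarray(d_um, dtype=float)
        return self.c0 + self.c1 * d + self.c2 * d**2


def _fit_quadratic(d: np.ndarray, r: np.ndarray, pure: bool = True):
    if pure:
        X = np.column_stack([np.ones_like(d), d**2])
        coef, *_ = np.linalg.lstsq(X, r, rcond=None)
        c0, c2 = coef
        c1 = 0.0
    else:
        X = np.column_stack([np.ones_like(d), d, d**2])
        coef, *_ = np.linalg.lstsq(X, r, rcond=None)
        c0, c1, c2 = coef
    resid = r - (c0 + c1 * d + c2 * d**2)
    return float(c0), float(c1), float(c2), float(np.std(resid))


def eligible_sites(
    model: CableModel,
    n_sites: int = 117,
    min_distance_um: float = 30.0,
    kind: str = "basal",
) -> np.ndarray:
    """Compartments sampled uniformly over eligible basal arc length
    (deterministic: evenly spaced quantiles of the ordered eligible nodes)."""
    nodes = np.flatnonzero((model.kind == kind) & (model.dist_um >= min_distance_um))
    if nodes.size == 0:
        raise ValueError("no eligible sites")
    order = np.lexsort((model.dist_um[nodes], model.section[nodes]))
    nodes = nodes[order]
    if n_sites >= nodes.size:
        return nodes
    idx = np.unique(np.round(np.linspace(0, nodes.size - 1, n_sites)).astype(int))
    return nodes[idx]


def scan_locations(
    model: CableModel,
    spine_template: SpineSynapse,
    r_neck_grid_mohm,
    n_sites: int = 117,
    min_distance_um: float = 30.0,
    t_stop_ms: float = 40.0,
    dt_ms: float = 0.025,
    pure_quadratic: bool = True,
) -> tuple[list[AttenuationCurve], pd.DataFrame]:
    """Move the spine over the basal tree for each R_neck value and fit the
    quadratic attenuation-vs-distance curve.

    Returns the per-R_neck curves (sorted by R_neck) and a tidy table of raw
    (site, distance, spine peak, soma peak, ratio) samples.
    """
    sites = eligible_sites(model, n_sites, min_distance_um)
    rows = []
    curves = []
    for r_neck in sorted(r_neck_grid_mohm):
        spine = replace(spine_template, r_neck_mohm=float(r_neck))
        ds, ratios = [], []
        for node in sites:
            res = simulate_epsp(model, spine, int(node), t_stop_ms, dt_ms)
            ds.append(res.dist_um)
            ratios.append(res.attenuation_ratio)
            rows.append(dict(r_neck_mohm=r_neck, site=int(node), dist_um=res.dist_um,
                             peak_spine_mv=res.peak_head, peak_soma_mv=res.peak_soma,
                             ratio=res.attenuation_ratio))
        d = np.asarray(ds)
        r = np.asarray(ratios)
        c0, c1, c2, sd = _fit_quadratic(d, r, pure=pure_quadratic)
        curves.append(AttenuationCurve(r_neck_mohm=float(r_neck), c0=c0, c1=c1, c2=c2,
                                       distances_um=d, ratios=r, residual_sd=sd))
    return curves, pd.DataFrame(rows)


@dataclass
class RneckInference:
    """Per-spine R_neck estimates from measured (distance, attenuation)."""

    table: pd.DataFrame  # columns: dist_um, ratio, r_neck_mohm, flag

    @property
    def estimates(self) -> np.ndarray:
        ok = self.table["flag"] == ""
        return self.table.loc[ok, "r_neck_mohm"].to_numpy()


def infer_rneck(curves: list[AttenuationCurve], points) -> RneckInference:
    """Invert attenuation curves: for each experimental (d, ratio), evaluate
    every R_neck curve at d and linearly interpolate in R_neck to match the
    measured ratio.

    Points whose ratio falls below the smallest-R_neck curve, or above the
    largest, are flagged and receive no estimate.
    """
    curves = sorted(curves, key=lambda c: c.r_neck_mohm)
    grid = np.array([c.r_neck_mohm for c in curves])
    rows = []
    for d, ratio in points:
        vals = np.array([c(d) for c in curves])
        if not np.all(np.diff(vals) > 0):
            raise ValueError("attenuation not monotone in R_neck at this distance")
        if ratio < vals[0]:
            rows.append(dict(dist_um=d, ratio=ratio, r_neck_mohm=np.nan,
                             flag="below_grid"))
            continue
        if ratio > vals[-1]:
            rows.append(dict(dist_um=d, ratio=ratio, r_neck_mohm=np.nan,
                             flag="above_grid"))
            continue
        est = float(np.interp(ratio, vals, grid))
        rows.append(dict(dist_um=d, ratio=ratio, r_neck_mohm=est, flag=""))
    return RneckInference(table=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# morphologies
# ---------------------------------------------------------------------------

def synthetic_l5_tree(
    n_basal: int = 10,
    basal_stem_um: float = 40.0,
    basal_stem_diam_um: float = 2.5,
    basal_daughter_um: float = 90.0,
    basal_daughter_diam_um: float = 1.4,
    basal_terminal_um: float = 130.0,
    basal_terminal_diam_um: float = 1.0,
    apical_trunk_um: float = 500.0,
    apical_trunk_diam_um: float = 5.0,
    n_oblique: int = 4,
    f_spine: float = 1.5,
) -> Morphology:
    """Parameterised stand-in for a layer-5 pyramidal morphology.

    Soma + ``n_basal`` twice-bifurcating basal dendrites (stem → two
    daughters → two terminals each, with tapering diameters) + an apical
    trunk with oblique branches and a two-branch tuft.  Dendritic sections
    carry the spine-membrane correction factor ``f_spine``.  Defaults give
    a somatic input resistance of ≈52 MΩ with the standard passive
    parameters.
    """
    secs = [Section(20.0, 20.0, "soma", parent=-1)]
    for _ in range(n_basal):
        stem = len(secs)
        secs.append(Section(basal_stem_um, basal_stem_diam_um, "basal", 0, f_spine))
        for _ in range(2):
            daughter = len(secs)
            secs.append(Section(basal_daughter_um, basal_daughter_diam_um, "basal",
                                stem, f_spine))
            for _ in range(2):
                secs.append(Section(basal_terminal_um, basal_terminal_diam_um,
                                    "basal", daughter, f_spine))
    trunk = len(secs)
    secs.append(Section(apical_trunk_um, apical_trunk_diam_um, "apical", 0, f_spine))
    for _ in range(n_oblique):
        secs.append(Section(150.0, 1.0, "apical", trunk, f_spine))
    for _ in range(2):
        secs.append(Section(300.0, 2.0, "apical", trunk, f_spine))
    return Morphology(secs)


_SWC_KINDS = {1: "soma", 2: "axon", 3: "basal", 4: "apical"}


def read_swc(path: str | Path, f_spine: float = 1.0) -> Morphology:
    """Load an SWC morphology as one section per (non-root) sample point.

    Each point becomes a cylinder from its parent sample to itself; the root
    sample becomes a spherical-equivalent soma section.  Unknown type codes
    map to "basal".
    """
    pts: dict[int, tuple[int, float, np.ndarray, float]] = {}
    order: list[int] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        f = line.split()
        idx, code = int(f[0]), int(f[1])
        xyz = np.array([float(f[2]), float(f[3]), float(f[4])])
        radius, par = float(f[5]), int(f[6])
        pts[idx] = (code, radius, xyz, par)
        order.append(idx)

    sec_of_point: dict[int, int] = {}
    secs: list[Section] = []
    for idx in order:
        code, radius, xyz, par = pts[idx]
        kind = _SWC_KINDS.get(code, "basal")
        if par < 0:
            secs.append(Section(2 * radius, 2 * radius, "soma", parent=-1))
            sec_of_point[idx] = 0
            continue
        pxyz = pts[par][2]
        length = float(np.linalg.norm(xyz - pxyz))
        if length <= 0:
            sec_of_point[idx] = sec_of_point[par]
            continue
        f_fac = f_spine if kind in ("basal", "apical") else 1.0
        secs.append(Section(length, 2 * radius, kind, sec_of_point[par], f_fac))
        sec_of_point[idx] = len(secs) - 1
    return Morphology(secs)
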