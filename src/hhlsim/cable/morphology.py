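"""Geometry and electrical discretization of a type I SGN peripheral axon.

A fiber runs from the inner-hair-cell synapse to the first central
myelin segment: an unmyelinated terminal segment (length ``L_u``), a
heminode (length ``L_h``, the spike initiation site), then five myelin
sheaths separated by four nodes of Ranvier.  The geometry and the
region-specific electrical constants follow rodent SGN measurements;
``R_a`` is set so that a normal fiber conducts at 3-5 m/s.

Myelinopathy is modeled purely geometrically, by lengthening ``L_u``
and/or ``L_h``.  How the fixed complement of ion channels redistributes
over a lengthened region is not known experimentally, so two scaling
conventions are supported:

``default``
    lengthening ``L_u`` keeps channel *density* constant (number grows);
    lengthening ``L_h`` keeps channel *number* constant (density drops
    as 1/L_h).
``reversed``
    the opposite assumption for each region.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

REGION_UNMYEL = 0
REGION_HEMINODE = 1
REGION_MYELIN = 2
REGION_NODE = 3

CONVENTIONS = ("default", "reversed")


@dataclass(frozen=True)
class FiberMorphology:
    """Segment layout of one SGN peripheral fiber (lengths in um)."""

    L_u: float = 10.0
    L_h: float = 1.0
    n_myelin: int = 5
    myelin_length: float = 40.0
    node_length: float = 1.0
    diam_unmyel: float = 1.2
    diam_heminode: float = 1.2
    diam_node: float = 1.2
    diam_myelin: float = 2.2

    def __post_init__(self):
        for name in ("L_u", "L_h", "myelin_length", "node_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def total_length(self) -> float:
        n_nodes = self.n_myelin - 1
        return (
            self.L_u
            + self.L_h
            + self.n_myelin * self.myelin_length
            + n_nodes * self.node_length
        )


@dataclass(frozen=True)
class MembraneParams:
    """Electrical constants per fiber region.

    Conductances in S/cm^2, resistances in ohm*cm^2 (membrane) and
    ohm*cm (axial), capacitances in uF/cm^2, potentials in mV.  The
    unmyelinated terminal carries 1/15 of the nodal channel densities,
    which is what confines spike initiation to the heminode.
    """

    g_na_node: float = 0.1812
    g_k_node: float = 0.225
    g_na_unmyel: float = 0.01208  # = g_na_node / 15
    g_k_unmyel: float = 0.015    # = g_k_node / 15
    r_m: float = 1662.0
    c_m: float = 0.05125
    r_m_myelin: float = 1.3e6
    c_m_myelin: float = 0.0012
    r_a: float = 8291.4
    e_na: float = 66.0
    e_k: float = -88.0
    e_rest: float = -78.0


@dataclass
class CableGrid:
    """Discretized fiber: per-compartment arrays in solver units.

    Units: capacitance nF, conductances uS, lengths um.  With voltages
    in mV and time in ms the membrane currents come out in nA.
    """

    x_center: np.ndarray       # um, distance from the synaptic end
    length: np.ndarray         # um
    region: np.ndarray         # int codes, REGION_*
    c_nF: np.ndarray
    g_leak_uS: np.ndarray
    g_na_uS: np.ndarray
    g_k_uS: np.ndarray
    g_axial_uS: np.ndarray     # size n-1, coupling between i and i+1
    params: MembraneParams
    morphology: FiberMorphology
    convention: str
    idx_synapse: int = 0
    idx_heminode: int = field(default=-1)
    idx_nodes: np.ndarray = field(default_factory=lambda: np.zeros(0, int))

    @property
    def n_comp(self) -> int:
        return self.x_center.size


def _split(length: float, max_dx: float) -> np.ndarray:
    n = max(1, int(np.ceil(length / max_dx - 1e-9)))
    return np.full(n, length / n)


def build_cable(
    morph: FiberMorphology,
    params: MembraneParams | None = None,
    convention: str = "default",
    max_dx_unmyel: float = 1.0,
    max_dx_myelin: float = 10.0,
) -> CableGrid:
    """Discretize a fiber into compartments with region-correct densities.

    The unmyelinated segment is split into compartments of at most
    ``max_dx_unmyel`` um (1 um default: the single-release spike
    threshold in L_u is converged to the 0.1 um scan resolution there)
    and each myelin sheath into at most ``max_dx_myelin`` um; heminode
    and nodes are single compartments.
    The channel-scaling ``convention`` (see module docstring) is applied
    exactly once, relative to the control lengths L_u = 10 um and
    L_h = 1 um.
    """
    if params is None:
        params = MembraneParams()
    if convention not in CONVENTIONS:
        raise ValueError(f"unknown channel-scaling convention {convention!r}")

    lengths, regions, diams = [], [], []

    def add(seg_lengths, region, diam):
        for dl in np.atleast_1d(seg_lengths):
            lengths.append(dl)
            regions.append(region)
            diams.append(diam)

    add(_split(morph.L_u, max_dx_unmyel), REGION_UNMYEL, morph.diam_unmyel)
    add(morph.L_h, REGION_HEMINODE, morph.diam_heminode)
    n_nodes = morph.n_myelin - 1
    for i in range(morph.n_myelin):
        add(_split(morph.myelin_length, max_dx_myelin), REGION_MYELIN,
            morph.diam_myelin)
        if i < n_nodes:
            add(morph.node_length, REGION_NODE, morph.diam_node)

    length = np.asarray(lengths)
    region = np.asarray(regions, dtype=np.int8)
    diam = np.asarray(diams)
    x_right = np.cumsum(length)
    x_center = x_right - length / 2.0

    # channel-density scale factors for the lesioned regions
    if convention == "default":
        scale_u = 1.0                      # constant density
        scale_h = 1.0 / morph.L_h          # constant number (ref L_h = 1 um)
    else:  # reversed
        scale_u = 10.0 / morph.L_u         # constant number (ref L_u = 10 um)
        scale_h = 1.0                      # constant density

    g_na_d = np.zeros_like(length)  # S/cm^2
    g_k_d = np.zeros_like(length)
    r_m = np.full_like(length, params.r_m)
    c_m = np.full_like(length, params.c_m)

    un = region == REGION_UNMYEL
    g_na_d[un] = params.g_na_unmyel * scale_u
    g_k_d[un] = params.g_k_unmyel * scale_u
    hemi = region == REGION_HEMINODE
    g_na_d[hemi] = params.g_na_node * scale_h
    g_k_d[hemi] = params.g_k_node * scale_h
    node = region == REGION_NODE
    g_na_d[node] = params.g_na_node
    g_k_d[node] = params.g_k_node
    mye = region == REGION_MYELIN
    r_m[mye] = params.r_m_myelin
    c_m[mye] = params.c_m_myelin

    area_cm2 = np.pi * (diam * 1e-4) * (length * 1e-4)
    c_nF = c_m * area_cm2 * 1e3            # uF -> nF
    g_leak = area_cm2 / r_m * 1e6          # S -> uS
    g_na = g_na_d * area_cm2 * 1e6
    g_k = g_k_d * area_cm2 * 1e6

    # axial coupling: series half-compartment resistances from the local
    # diameter, so diameter steps are handled consistently
    radius_cm = diam * 1e-4 / 2.0
    r_half = params.r_a * (length * 1e-4 / 2.0) / (np.pi * radius_cm**2)  # ohm
    g_axial = 1e6 / (r_half[:-1] + r_half[1:])  # uS

    idx_heminode = int(np.flatnonzero(hemi)[0])
    idx_nodes = np.flatnonzero(node)

    return CableGrid(
        x_center=x_center,
        length=length,
        region=region,
        c_nF=c_nF,
        g_leak_uS=g_leak,
        g_na_uS=g_na,
        g_k_uS=g_k,
        g_axial_uS=g_axial,
        params=params,
        morphology=morph,
        convention=convention,
        idx_synapse=0,
        idx_heminode=idx_heminode,
        idx_nodes=idx_nodes,
    )
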