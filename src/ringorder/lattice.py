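"""Ideal ice crystal generator.

Builds ideal oxygen sublattices for a handful of ice polymorphs and assigns
protons either in a crystallographically ordered pattern (ferroelectric and
antiferroelectric ice XI) or as a uniformly randomized Bernal-Fowler
ice-rules state (ice Ih, Ic, VII).

Geometry conventions
--------------------
* ``oo_distance`` is the nearest-neighbour O-O separation (default 2.75 A,
  the typical experimental value for ice Ih).
* Hydrogens are placed on the O-O axis at the covalent O-H distance
  (0.9572 A), i.e. perfectly straight hydrogen bonds.  Real (and
  GenIce-built) crystals carry slight distortions; these ideal lattices give
  a tetrahedrality of exactly 1 for the 4-coordinated polymorphs.
* Ice Ic is cubic diamond (8 waters per conventional cell); ice Ih is
  hexagonal diamond (lonsdaleite) in its 8-water orthorhombic setting, with
  the crystallographic c axis along z; ice VII is two interpenetrating
  cubic-diamond sublattices forming a bcc oxygen arrangement (16 waters per
  conventional cell).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .frames import WaterFrame

__all__ = [
    "CrystalSpec",
    "build_oxygen_lattice",
    "assign_protons_ordered",
    "assign_protons_disordered",
    "random_ice_orientation",
    "make_ice",
    "POLYMORPHS",
]

log = logging.getLogger(__name__)

POLYMORPHS = ("Ic", "Ih", "XI_ferro", "XI_antiferro", "VII")
ORDERED_ONLY = ("XI_ferro", "XI_antiferro")
DISORDER_CAPABLE = ("Ic", "Ih", "VII")

OH_COVALENT = 0.9572  # Angstrom
DEFAULT_OO = 2.75  # Angstrom
HBOND_CUTOFF = 3.5  # Angstrom; used for the minimum-image box-size guard


@dataclass
class CrystalSpec:
    """Recipe for one ideal ice crystal."""

    polymorph: str
    replication: tuple[int, int, int]
    oo_distance: float = DEFAULT_OO
    proton_state: str = "disordered"
    seed: int = 0
    zero_net_dipole: bool = False

    def __post_init__(self) -> None:
        if self.polymorph not in POLYMORPHS:
            raise ValueError(f"unknown polymorph {self.polymorph!r}; choose from {POLYMORPHS}")
        rep = tuple(int(r) for r in self.replication)
        if len(rep) != 3 or any(r < 1 for r in rep):
            raise ValueError("replication must be three integers >= 1")
        self.replication = rep
        if self.oo_distance <= 0:
            raise ValueError("oo_distance must be positive")
        if self.polymorph in ORDERED_ONLY and self.proton_state != "ordered":
            raise ValueError(f"{self.polymorph} is a proton-ordered polymorph")
        if self.proton_state == "disordered" and self.polymorph not in DISORDER_CAPABLE:
            raise ValueError(f"proton disorder is only defined for {DISORDER_CAPABLE}")
        if self.proton_state not in ("ordered", "disordered"):
            raise ValueError("proton_state must be 'ordered' or 'disordered'")


# ---------------------------------------------------------------------------
# oxygen sublattices
# ---------------------------------------------------------------------------


def _ic_cell(d: float) -> tuple[np.ndarray, np.ndarray]:
    """Conventional cubic-diamond cell: fractional basis and cell vector."""
    a = 4.0 * d / math.sqrt(3.0)
    frac = np.array(
        [
            [0.0, 0.0, 0.0],
            [0.0, 0.5, 0.5],
            [0.5, 0.0, 0.5],
            [0.5, 0.5, 0.0],
            [0.25, 0.25, 0.25],
            [0.25, 0.75, 0.75],
            [0.75, 0.25, 0.75],
            [0.75, 0.75, 0.25],
        ]
    )
    return frac * a, np.array([a, a, a])


def _ih_cell(d: float) -> tuple[np.ndarray, np.ndarray]:
    """Orthorhombic 8-water lonsdaleite cell, c axis along z.

    Built from the ideal wurtzite-type stacking: hexagonal lattice constant
    a = d*sqrt(8/3), c = 8d/3, atoms at (1/3,2/3,0), (2/3,1/3,1/2) and the
    same xy sites displaced by 3/8 c, converted to the (a, a*sqrt(3), c)
    orthorhombic setting with its doubled basis.
    """
    a = d * math.sqrt(8.0 / 3.0)
    c = 8.0 * d / 3.0
    box = np.array([a, a * math.sqrt(3.0), c])
    hex_basis = np.array(
        [
            [0.0, a / math.sqrt(3.0), 0.0],  # lower sublayer, bilayer 0
            [a / 2.0, a / (2.0 * math.sqrt(3.0)), c / 2.0],  # lower, bilayer 1
            [0.0, a / math.sqrt(3.0), 3.0 * c / 8.0],  # upper, bilayer 0
            [a / 2.0, a / (2.0 * math.sqrt(3.0)), 7.0 * c / 8.0],  # upper, bilayer 1
        ]
    )
    shift = np.array([a / 2.0, a * math.sqrt(3.0) / 2.0, 0.0])
    pts = np.vstack([hex_basis, hex_basis + shift])
    pts -= box * np.floor(pts / box)
    return pts, box


def _vii_cell(d: float) -> tuple[np.ndarray, np.ndarray]:
    """16-water bcc cell: cubic diamond plus a (1/2,1/2,1/2)-shifted copy."""
    ic, box = _ic_cell(d)
    return np.vstack([ic, (ic + box / 2.0) % box]), box


_CELL_BUILDERS = {"Ic": _ic_cell, "Ih": _ih_cell, "XI_ferro": _ih_cell, "XI_antiferro": _ih_cell, "VII": _vii_cell}


def build_oxygen_lattice(spec: CrystalSpec) -> WaterFrame:
    """Generate the ideal oxygen sublattice for ``spec`` (hydrogens unset).

    The returned frame's metadata records the basis index, integer cell
    index and (for ice VII) diamond-sublattice label of every oxygen, which
    the proton-assignment routines rely on.
    """
    basis, cell = _CELL_BUILDERS[spec.polymorph](spec.oo_distance)
    nb = len(basis)
    nx, ny, nz = spec.replication
    box = cell * np.array([nx, ny, nz], dtype=float)
    if np.any(box < 2.0 * HBOND_CUTOFF):
        raise ValueError(
            f"box {box.round(2)} A violates the minimum-image convention; every "
            f"edge must be >= {2.0 * HBOND_CUTOFF} A — increase the replication"
        )
    cells = np.stack(
        np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"), axis=-1
    ).reshape(-1, 3)
    pos = (cells[:, None, :] * cell + basis).reshape(-1, 3)
    n = len(pos)
    sub = np.zeros(n, dtype=int)
    if spec.polymorph == "VII":
        sub = np.tile(np.repeat([0, 1], 8), len(cells))
    frame = WaterFrame(
        pos,
        np.full((n, 2, 3), np.nan),
        box,
        metadata={
            "polymorph": spec.polymorph,
            "replication": spec.replication,
            "oo_distance": spec.oo_distance,
            "basis_index": np.tile(np.arange(nb), len(cells)),
            "cell_index": np.repeat(cells, nb, axis=0),
            "sublattice": sub,
            "seed": spec.seed,
        },
    )
    return frame


def lattice_bonds(frame: WaterFrame) -> np.ndarray:
    """Nearest-neighbour O-O links of an ideal lattice as an (m, 2) array.

    For ice VII only links within the same diamond sublattice are returned:
    the two interpenetrating networks do not hydrogen-bond to each other.
    """
    d = frame.metadata.get("oo_distance", DEFAULT_OO)
    wrapped = frame.oxygen_positions % frame.box
    tree = cKDTree(wrapped, boxsize=frame.box)
    pairs = tree.query_pairs(d * 1.001, output_type="ndarray")
    sub = frame.metadata.get("sublattice")
    if sub is not None and np.any(sub != 0):
        pairs = pairs[sub[pairs[:, 0]] == sub[pairs[:, 1]]]
    return pairs


def _check_four_coordinated(n: int, pairs: np.ndarray) -> np.ndarray:
    deg = np.zeros(n, dtype=int)
    np.add.at(deg, pairs.ravel(), 1)
    if not np.all(deg == 4):
        bad = int(np.argmax(deg != 4))
        raise ValueError(
            f"oxygen {bad} has {deg[bad]} lattice neighbours (need exactly 4); "
            "ice-rules proton assignment requires a 4-coordinated lattice"
        )
    return deg


def _place_hydrogens(frame: WaterFrame, donations: dict[int, list[int]]) -> WaterFrame:
    """Place 2 hydrogens per water along the minimum-image O-O donation axes."""
    out = frame.copy()
    pos, box = frame.oxygen_positions, frame.box
    hyd = np.empty((frame.n_waters, 2, 3))
    for i, accs in donations.items():
        if len(accs) != 2:
            raise ValueError(f"water {i} donates {len(accs)} bonds; the ice rules require 2")
        for h, j in enumerate(accs):
            v = pos[j] - pos[i]
            v -= box * np.round(v / box)
            hyd[i, h] = pos[i] + OH_COVALENT * v / np.linalg.norm(v)
    out.hydrogen_positions = hyd
    return out


# ---------------------------------------------------------------------------
# ordered proton assignment (ice XI)
# ---------------------------------------------------------------------------
#
# Donation tables for the 8-water orthorhombic ice XI cells.  Each entry maps
# a basis index to its two hydrogen-bond acceptors, given as
# (acceptor basis index, integer cell offset).  Both patterns satisfy the ice
# rules when tiled periodically and were selected by exhaustive enumeration
# of all ice-rules states of the periodic 8-water cell:
#
# * XI_ferro: every molecular dipole carries the same positive c component
#   (Cmc2_1-like ferroelectric order); every hexagonal ring contains a
#   double-donor and a double-acceptor water ("percolating loops"), so no
#   ring of any size is directional.
# * XI_antiferro: the 8 molecular dipoles sum to zero (Pna2_1-like
#   antiferroelectric order) and exactly half of the hexagonal rings per
#   water pair are directional, with no directional rings of other sizes.
#
# Basis indices follow _ih_cell: 0/1 lower-sublayer, 2/3 upper-sublayer
# atoms of the two bilayers, 4-7 the same roles in the second hexagonal
# column of the orthorhombic cell.

XI_FERRO_DONATIONS: dict[int, list[tuple[int, tuple[int, int, int]]]] = {
    0: [(2, (0, 0, 0)), (7, (0, 0, -1))],
    1: [(3, (0, 0, 0)), (6, (0, -1, 0))],
    2: [(1, (-1, 0, 0)), (1, (0, 0, 0))],
    3: [(0, (0, 0, 1)), (0, (1, 0, 1))],
    4: [(3, (0, 1, -1)), (6, (0, 0, 0))],
    5: [(2, (0, 0, 0)), (7, (0, 0, 0))],
    6: [(5, (0, 0, 0)), (5, (1, 0, 0))],
    7: [(4, (-1, 0, 1)), (4, (0, 0, 1))],
}
XI_ANTIFERRO_DONATIONS: dict[int, list[tuple[int, tuple[int, int, int]]]] = {
    0: [(3, (0, 0, -1)), (7, (0, 0, -1))],
    1: [(2, (0, 0, 0)), (3, (0, 0, 0))],
    2: [(0, (0, 0, 0)), (1, (-1, 0, 0))],
    3: [(0, (1, 0, 1)), (4, (0, -1, 1))],
    4: [(6, (0, 0, 0)), (7, (1, 0, -1))],
    5: [(2, (0, 0, 0)), (6, (-1, 0, 0))],
    6: [(1, (0, 1, 0)), (5, (0, 0, 0))],
    7: [(4, (0, 0, 1)), (5, (0, 0, 0))],
}


def _ordered_donations(frame: WaterFrame, table) -> dict[int, list[int]]:
    basis = frame.metadata.get("basis_index")
    cells = frame.metadata.get("cell_index")
    if basis is None or cells is None:
        raise ValueError(
            "ordered proton assignment needs a lattice built by "
            "build_oxygen_lattice (basis/cell metadata missing)"
        )
    rep = np.array(frame.metadata["replication"], dtype=int)
    nb = int(basis.max()) + 1
    index = {}
    for i in range(frame.n_waters):
        index[(tuple(cells[i]), int(basis[i]))] = i
    donations: dict[int, list[int]] = {}
    for i in range(frame.n_waters):
        accs = []
        for bj, off in table[int(basis[i])]:
            cj = tuple((cells[i] + np.array(off)) % rep)
            accs.append(index[(cj, bj)])
        donations[i] = accs
    return donations


def assign_protons_ordered(frame: WaterFrame, polymorph: str) -> WaterFrame:
    """Place hydrogens in the ordered ice XI pattern (ferro or antiferro)."""
    if polymorph == "XI_ferro":
        table = XI_FERRO_DONATIONS
    elif polymorph == "XI_antiferro":
        table = XI_ANTIFERRO_DONATIONS
    else:
        raise ValueError(
            f"no ordered proton assignment is defined for {polymorph!r}; "
            "native ordered generation covers XI_ferro and XI_antiferro"
        )
    if frame.metadata.get("polymorph") not in ("Ih", "XI_ferro", "XI_antiferro"):
        raise ValueError("ice XI proton ordering requires an Ih-topology oxygen lattice")
    out = _place_hydrogens(frame, _ordered_donations(frame, table))
    out.metadata["polymorph"] = polymorph
    out.metadata["proton_state"] = "ordered"
    return out


# ---------------------------------------------------------------------------
# disordered proton assignment
# ---------------------------------------------------------------------------


def _fix_ice_rule_defects(n, edges, orient, out_edges, rng) -> None:
    """Annihilate Bjerrum-type defects by reversing donor->acceptor paths.

    ``orient[e]`` = 0 means edges[e][0] donates, 1 means edges[e][1] donates.
    A vertex with out-degree > 2 starts a loop-erased random walk along
    donated bonds; reaching a vertex with out-degree < 2 the whole path is
    reversed, moving one unit of "charge" without disturbing the interior.
    """
    deg = np.zeros(n, dtype=int)
    for e, (a, b) in enumerate(edges):
        deg[a if orient[e] == 0 else b] += 1
    excess = [v for v in range(n) if deg[v] > 2]
    while excess:
        v0 = excess[rng.integers(len(excess))]
        path_v = [v0]
        path_e = []
        pos = {v0: 0}
        v = v0
        while True:
            outs = out_edges[v]
            if deg[v] < 2 and v != v0:
                break
            e = outs[rng.integers(len(outs))]
            a, b = edges[e]
            u = b if orient[e] == 0 else a
            if u in pos:  # loop-erase
                k = pos[u]
                for w in path_v[k + 1 :]:
                    del pos[w]
                path_v = path_v[: k + 1]
                path_e = path_e[:k]
                v = u
                continue
            path_v.append(u)
            path_e.append(e)
            pos[u] = len(path_v) - 1
            v = u
        for e in path_e:  # reverse the path
            a, b = edges[e]
            donor = a if orient[e] == 0 else b
            other = b if orient[e] == 0 else a
            out_edges[donor].remove(e)
            out_edges[other].append(e)
            orient[e] ^= 1
        deg[v0] -= 1
        deg[v] += 1
        excess = [w for w in range(n) if deg[w] > 2]


def _loop_reversal_sweeps(n, edges, orient, out_edges, rng, n_moves) -> None:
    """Decorrelate a valid ice state with rejection-free loop reversals.

    Random walks along donated bonds always close into a directed cycle;
    reversing the cycle yields another valid ice state.  This is the
    standard loop Monte Carlo move for ice models.
    """
    for _ in range(n_moves):
        v = int(rng.integers(n))
        path_v = [v]
        path_e = []
        pos = {v: 0}
        while True:
            outs = out_edges[v]
            e = outs[rng.integers(2)]
            a, b = edges[e]
            u = b if orient[e] == 0 else a
            if u in pos:
                k = pos[u]
                loop_e = path_e[k:] + [e]
                for le in loop_e:
                    a2, b2 = edges[le]
                    donor = a2 if orient[le] == 0 else b2
                    other = b2 if orient[le] == 0 else a2
                    out_edges[donor].remove(le)
                    out_edges[other].append(le)
                    orient[le] ^= 1
                break
            path_v.append(u)
            path_e.append(e)
            pos[u] = len(path_v) - 1
            v = u


def random_ice_orientation(
    edges: list[tuple[int, int]],
    n_vertices: int,
    seed: int,
    n_decorrelation_moves: int | None = None,
) -> np.ndarray:
    """Uniformly randomized ice-rules orientation of a 4-regular link graph.

    Returns an array with 0 where ``edges[e][0]`` donates and 1 where
    ``edges[e][1]`` does; every vertex ends with exactly two outgoing links.
    Useful on its own for synthetic (non-geometric) 2-out/2-in networks.
    """
    deg = np.zeros(n_vertices, dtype=int)
    for a, b in edges:
        deg[a] += 1
        deg[b] += 1
    if not np.all(deg == 4):
        bad = int(np.argmax(deg != 4))
        raise ValueError(f"vertex {bad} has {deg[bad]} links (need 4)")
    rng = np.random.default_rng(seed)
    orient = np.array(rng.integers(0, 2, size=len(edges)), dtype=int)
    out_edges: list[list[int]] = [[] for _ in range(n_vertices)]
    for e, (a, b) in enumerate(edges):
        out_edges[a if orient[e] == 0 else b].append(e)
    _fix_ice_rule_defects(n_vertices, edges, orient, out_edges, rng)
    if n_decorrelation_moves is None:
        n_decorrelation_moves = 4 * len(edges)
    _loop_reversal_sweeps(n_vertices, edges, orient, out_edges, rng, n_decorrelation_moves)
    return orient


def assign_protons_disordered(
    frame: WaterFrame, seed: int, zero_net_dipole: bool = False, n_decorrelation_moves: int | None = None
) -> WaterFrame:
    """Assign a randomized ice-rules proton state, reproducible under seed.

    Every water ends up donating exactly two and accepting exactly two
    hydrogen bonds, with exactly one hydrogen per O-O link.  Starting from a
    random per-link hydrogen placement, path reversals annihilate the
    ice-rule defects, after which loop-reversal Monte Carlo moves (four per
    link by default) decorrelate the state towards a uniform sample of the
    ice manifold.

    ``zero_net_dipole`` additionally drives the total dipole of the cell to
    (approximately) zero with dipole-biased loop reversals; off by default.
    """
    pairs = lattice_bonds(frame)
    n = frame.n_waters
    _check_four_coordinated(n, pairs)
    edges = [tuple(p) for p in pairs]
    orient = random_ice_orientation(edges, n, seed, n_decorrelation_moves)
    if zero_net_dipole:
        out_edges: list[list[int]] = [[] for _ in range(n)]
        for e, (a, b) in enumerate(edges):
            out_edges[a if orient[e] == 0 else b].append(e)
        _zero_dipole_moves(frame, edges, orient, out_edges, np.random.default_rng([seed, 1]))
    donations = {i: [] for i in range(n)}
    for e, (a, b) in enumerate(edges):
        donor, acc = (a, b) if orient[e] == 0 else (b, a)
        donations[donor].append(acc)
    out = _place_hydrogens(frame, donations)
    out.metadata["proton_state"] = "disordered"
    out.metadata["seed"] = seed
    return out


def _bond_unit_vectors(frame, edges):
    pos, box = frame.oxygen_positions, frame.box
    v = np.array([pos[b] - pos[a] for a, b in edges])
    v -= box * np.round(v / box)
    return v / np.linalg.norm(v, axis=1)[:, None]


def _total_dipole(units, orient):
    sign = np.where(orient == 0, 1.0, -1.0)
    return (units * sign[:, None]).sum(axis=0)


def _zero_dipole_moves(frame, edges, orient, out_edges, rng, max_moves: int = 20000) -> None:
    """Greedy dipole reduction: keep loop reversals that shrink |net dipole|."""
    units = _bond_unit_vectors(frame, edges)
    best = np.linalg.norm(_total_dipole(units, orient))
    for _ in range(max_moves):
        if best < 1e-9:
            break
        saved = orient.copy()
        saved_out = [list(o) for o in out_edges]
        _loop_reversal_sweeps(len(out_edges), edges, orient, out_edges, rng, 1)
        new = np.linalg.norm(_total_dipole(units, orient))
        if new < best:
            best = new
        else:
            orient[:] = saved
            for i, o in enumerate(saved_out):
                out_edges[i][:] = o


# ---------------------------------------------------------------------------
# one-call convenience
# ---------------------------------------------------------------------------


def make_ice(spec: CrystalSpec) -> WaterFrame:
    """Build the full crystal described by ``spec`` (oxygens + protons)."""
    frame = build_oxygen_lattice(spec)
    if spec.proton_state == "ordered":
        if spec.polymorph not in ORDERED_ONLY:
            raise ValueError(
                f"no native ordered proton assignment for {spec.polymorph}; "
                "supply an ordered structure as a coordinate file instead"
            )
        return assign_protons_ordered(frame, spec.polymorph)
    return assign_protons_disordered(frame, spec.seed, zero_net_dipole=spec.zero_net_dipole)


def molecular_dipoles(frame: WaterFrame) -> np.ndarray:
    """Unit-less molecular dipole directions: sum of the two O-H unit vectors."""
    v = frame.hydrogen_positions - frame.oxygen_positions[:, None, :]
    v -= frame.box * np.round(v / frame.box)
    v /= np.linalg.norm(v, axis=2)[:, :, None]
    return v.sum(axis=1)
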