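"""File-format plumbing: trajectory readers, structure writers, exports.

Supported formats
-----------------
GRO    fixed-column GROMACS coordinates, nm (converted to Angstrom on
       read), orthorhombic box on the final line; concatenated multi-frame
       files are streamed frame by frame.  Velocity columns are ignored.
PDB    ATOM/HETATM records with a CRYST1 box; multi-frame via MODEL
       records (read through MDAnalysis).
XYZ    extended XYZ with a ``Lattice="ax 0 0 0 by 0 0 0 cz"`` comment;
       atoms must appear as O,H,H triplets.

Waters in GRO/PDB are identified by residue name (SOL, HOH, WAT, TIP*,
SPC*, OPC*); virtual sites (M/MW/EP atoms of 4- and 5-site models) are
dropped, other residues are skipped with a warning.  All reported
coordinates are Angstrom.
"""

from __future__ import annotations

import json
import logging
import re
import warnings
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

from . import __version__ as _version
from .frames import WaterFrame

log = logging.getLogger(__name__)

WATER_RESNAMES = ("SOL", "HOH", "WAT", "TIP", "SPC", "OPC")


def _is_water_resname(name: str) -> bool:
    return any(name.upper().startswith(p) for p in WATER_RESNAMES)


def _group_waters(names, resids, resnames, positions, source: str):
    """Collect (O, H, H) triplets per residue; skip non-water residues."""
    oxy, hyd = [], []
    skipped = set()
    order = np.argsort(np.asarray(resids), kind="stable")
    by_res: dict[int, list[int]] = {}
    for i in order:
        by_res.setdefault(int(resids[i]), []).append(int(i))
    for resid, idxs in by_res.items():
        rname = resnames[idxs[0]]
        if not _is_water_resname(rname):
            skipped.add((rname, resid))
            continue
        o = [i for i in idxs if names[i].upper().startswith("O")]
        h = [i for i in idxs if names[i].upper().startswith("H")]
        if len(o) != 1 or len(h) < 2:
            raise ValueError(
                f"{source}: residue {rname} {resid} is not a water "
                f"({len(o)} O atoms, {len(h)} H atoms)"
            )
        oxy.append(positions[o[0]])
        hyd.append([positions[h[0]], positions[h[1]]])
    if skipped:
        log.warning("%s: skipped %d non-water residues", source, len(skipped))
    if not oxy:
        raise ValueError(f"{source}: no water residues found")
    return np.array(oxy), np.array(hyd)


# ---------------------------------------------------------------------------
# GRO (hand-chunked: concatenated multi-frame GRO is not a trajectory format
# MDAnalysis streams, and the fixed-column layout is unambiguous)
# ---------------------------------------------------------------------------


def read_gro(path) -> Iterator[WaterFrame]:
    path = Path(path)
    with open(path) as fh:
        frame_index = 0
        while True:
            title = fh.readline()
            if not title:
                return
            if not title.strip():
                continue
            try:
                natoms = int(fh.readline())
            except ValueError as exc:
                raise ValueError(f"{path}: malformed atom count after frame title") from exc
            names, resids, resnames, pos = [], [], [], []
            for _ in range(natoms):
                line = fh.readline()
                if len(line) < 44:
                    raise ValueError(f"{path}: truncated atom line: {line!r}")
                resids.append(int(line[0:5]))
                resnames.append(line[5:10].strip())
                names.append(line[10:15].strip())
                pos.append([float(line[20:28]), float(line[28:36]), float(line[36:44])])
            boxline = fh.readline().split()
            if len(boxline) < 3:
                raise ValueError(f"{path}: missing box line (frame {frame_index})")
            if len(boxline) > 3 and any(float(x) != 0.0 for x in boxline[3:]):
                raise ValueError(f"{path}: triclinic boxes are not supported")
            box = np.array([float(x) for x in boxline[:3]]) * 10.0  # nm -> A
            positions = np.array(pos) * 10.0
            names_f = [n for n in names if not _is_virtual(n)]
            keep = [i for i, n in enumerate(names) if not _is_virtual(n)]
            oxy, hyd = _group_waters(
                names_f,
                [resids[i] for i in keep],
                [resnames[i] for i in keep],
                positions[keep],
                f"{path}[{frame_index}]",
            )
            yield WaterFrame(oxy, hyd, box, frame_index=frame_index)
            frame_index += 1


def _is_virtual(name: str) -> bool:
    n = name.upper()
    return n.startswith(("M", "EP", "LP", "D")) and not n.startswith("D2")


def write_gro(frame: WaterFrame, path, title: str | None = None) -> None:
    """Write one frame as GRO (nm, 0.001 nm precision, orthorhombic box)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write((title or f"ringorder v{_version}") + "\n")
        fh.write(f"{frame.n_waters * 3:5d}\n")
        atom = 0
        for i in range(frame.n_waters):
            for name, p in (
                ("OW", frame.oxygen_positions[i]),
                ("HW1", frame.hydrogen_positions[i, 0]),
                ("HW2", frame.hydrogen_positions[i, 1]),
            ):
                atom += 1
                resid = (i % 99999) + 1
                fh.write(
                    f"{resid:5d}{'SOL':<5s}{name:>5s}{(atom % 99999):5d}"
                    f"{p[0] / 10:8.3f}{p[1] / 10:8.3f}{p[2] / 10:8.3f}\n"
                )
        fh.write("".join(f"{x / 10:10.5f}" for x in frame.box) + "\n")


# ---------------------------------------------------------------------------
# PDB via MDAnalysis
# ---------------------------------------------------------------------------


def read_pdb(path) -> Iterator[WaterFrame]:
    import MDAnalysis as mda

    path = Path(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
    dims = u.dimensions
    if dims is None:  # MODEL-partitioned files can orphan a header CRYST1
        for line in path.read_text().splitlines():
            if line.startswith("CRYST1"):
                dims = np.array([float(line[6 + 9 * i : 15 + 9 * i]) for i in range(3)] + [
                    float(line[33:40]), float(line[40:47]), float(line[47:54])
                ])
                break
    if dims is None or not np.all(dims[:3] > 0):
        raise ValueError(
            f"{path}: no CRYST1 box; add one (orthorhombic) — the minimum-image "
            "convention needs periodic box dimensions"
        )
    if not np.allclose(dims[3:6], 90.0):
        raise ValueError(f"{path}: only orthorhombic boxes are supported")
    names = [a.name for a in u.atoms]
    resids = [a.resid for a in u.atoms]
    resnames = [a.resname for a in u.atoms]
    keep = [i for i, n in enumerate(names) if not _is_virtual(n)]
    for k, ts in enumerate(u.trajectory):
        box = (
            ts.dimensions[:3].copy().astype(float)
            if ts.dimensions is not None
            else dims[:3].copy().astype(float)
        )
        oxy, hyd = _group_waters(
            [names[i] for i in keep],
            [resids[i] for i in keep],
            [resnames[i] for i in keep],
            ts.positions[keep].astype(float),
            f"{path}[{k}]",
        )
        yield WaterFrame(oxy, hyd, box, frame_index=k)


def write_pdb(frame: WaterFrame, path, bfactors: np.ndarray | None = None) -> None:
    """Write one frame as PDB with a CRYST1 record.

    ``bfactors`` (one value per water, e.g. per-molecule tetrahedrality) is
    stuffed into the B-factor column of all three atoms of each water for
    structure-colouring visualizations.
    """
    import MDAnalysis as mda

    n = frame.n_waters
    u = mda.Universe.empty(n_atoms=3 * n, n_residues=n, atom_resindex=np.repeat(np.arange(n), 3), trajectory=True)
    u.add_TopologyAttr("names", ["OW", "HW1", "HW2"] * n)
    u.add_TopologyAttr("resnames", ["SOL"] * n)
    u.add_TopologyAttr("resids", (np.arange(n) % 9999) + 1)
    u.add_TopologyAttr("elements", ["O", "H", "H"] * n)
    coords = np.empty((3 * n, 3))
    coords[0::3] = frame.oxygen_positions
    coords[1::3] = frame.hydrogen_positions[:, 0]
    coords[2::3] = frame.hydrogen_positions[:, 1]
    u.atoms.positions = coords
    u.dimensions = [*frame.box, 90.0, 90.0, 90.0]
    temp = np.zeros(3 * n) if bfactors is None else np.repeat(np.asarray(bfactors, float), 3)
    u.add_TopologyAttr("tempfactors", temp)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))


# ---------------------------------------------------------------------------
# extended XYZ (Lattice comment; strict O,H,H atom ordering)
# ---------------------------------------------------------------------------

_LATTICE_RE = re.compile(r'Lattice\s*=\s*"([^"]+)"')


def read_xyz(path) -> Iterator[WaterFrame]:
    path = Path(path)
    with open(path) as fh:
        frame_index = 0
        while True:
            head = fh.readline()
            if not head:
                return
            if not head.strip():
                continue
            natoms = int(head)
            comment = fh.readline()
            m = _LATTICE_RE.search(comment)
            if not m:
                raise ValueError(
                    f'{path}: frame {frame_index} comment lacks Lattice="..." box'
                )
            lat = np.array([float(x) for x in m.group(1).split()]).reshape(3, 3)
            if not np.allclose(lat, np.diag(np.diag(lat))):
                raise ValueError(f"{path}: only orthorhombic lattices are supported")
            box = np.diag(lat).copy()
            elems, pos = [], []
            for _ in range(natoms):
                parts = fh.readline().split()
                elems.append(parts[0])
                pos.append([float(x) for x in parts[1:4]])
            if natoms % 3 != 0 or any(
                tuple(elems[i : i + 3]) != ("O", "H", "H") for i in range(0, natoms, 3)
            ):
                raise ValueError(f"{path}: XYZ input must consist of O,H,H triplets")
            pos = np.array(pos)
            yield WaterFrame(pos[0::3], pos.reshape(-1, 3, 3)[:, 1:], box, frame_index=frame_index)
            frame_index += 1


def write_xyz(frame: WaterFrame, path, append: bool = False) -> None:
    path = Path(path)
    lat = " ".join(
        f"{v:.6f}" for v in np.diag(frame.box).astype(float).reshape(3, 3).ravel()
    )
    with open(path, "a" if append else "w") as fh:
        fh.write(f"{frame.n_waters * 3}\n")
        fh.write(f'Lattice="{lat}" Properties=species:S:1:pos:R:3\n')
        for i in range(frame.n_waters):
            o = frame.oxygen_positions[i]
            fh.write(f"O {o[0]:.6f} {o[1]:.6f} {o[2]:.6f}\n")
            for h in range(2):
                p = frame.hydrogen_positions[i, h]
                fh.write(f"H {p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------

_READERS = {"gro": read_gro, "pdb": read_pdb, "xyz": read_xyz}


def read_trajectory(path, format_hint: str | None = None) -> Iterator[WaterFrame]:
    """Stream WaterFrames from a coordinate/trajectory file."""
    fmt = (format_hint or Path(path).suffix.lstrip(".")).lower()
    if fmt not in _READERS:
        raise ValueError(f"unsupported format {fmt!r}; supported: {sorted(_READERS)}")
    return _READERS[fmt](path)


def write_structure(frame: WaterFrame, path, format_hint: str | None = None) -> None:
    fmt = (format_hint or Path(path).suffix.lstrip(".")).lower()
    writers = {"gro": write_gro, "pdb": write_pdb, "xyz": write_xyz}
    if fmt not in writers:
        raise ValueError(f"unsupported format {fmt!r}")
    writers[fmt](frame, path)


# ---------------------------------------------------------------------------
# analysis exports
# ---------------------------------------------------------------------------


def provenance_header(config: dict | None = None) -> str:
    cfg = json.dumps(config or {}, sort_keys=True, default=str)
    return f"# ringorder v{_version}\n# config: {cfg}\n"


def write_edge_csv(graph, path, config: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(provenance_header(config))
        fh.write("donor,hydrogen,acceptor,shift_x,shift_y,shift_z,r_oo,angle\n")
        for hb in graph.edges:
            s = hb.image_shift
            fh.write(
                f"{hb.donor},{hb.hydrogen},{hb.acceptor},{s[0]},{s[1]},{s[2]},"
                f"{hb.oo_distance:.4f},{hb.ooh_angle:.3f}\n"
            )


def write_ring_csv(ring_sets, path, config: dict | None = None) -> None:
    """Rings of one or more frames: frame, size, directional, members."""
    with open(path, "w") as fh:
        fh.write(provenance_header(config))
        fh.write("frame,size,directional,members\n")
        for rs in ring_sets:
            frame_index = getattr(rs, "frame_index", 0)
            for r in rs.rings:
                fh.write(
                    f"{frame_index},{r.n},{int(r.directional)},"
                    f"\"{' '.join(map(str, r.members))}\"\n"
                )


def write_ring_json(ring_set, path, config: dict | None = None) -> None:
    payload = {
        "tool": f"ringorder v{_version}",
        "config": config or {},
        "frame_index": ring_set.frame_index,
        "max_ring": ring_set.max_ring,
        "rings": [
            {"members": list(r.members), "size": r.n, "directional": r.directional}
            for r in ring_set.rings
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def write_distribution_csv(rows: Sequence[dict], path, config: dict | None = None) -> None:
    """Plot-ready long format: frame, criterion, directional, size, count, normalized."""
    import pandas as pd

    with open(path, "w") as fh:
        fh.write(provenance_header(config))
        pd.DataFrame(rows).to_csv(fh, index=False)


def write_metrics_csv(records, path, config: dict | None = None) -> None:
    import pandas as pd

    rows = []
    for r in records:
        row = {
            "frame": r.frame_index,
            "n_waters": r.n_waters,
            "q_mean": r.q_mean,
            "rsf": r.rsf,
            "criterion": r.criterion,
        }
        row.update({f"rings_{n}": c for n, c in sorted(r.ring_counts.items())})
        rows.append(row)
    with open(path, "w") as fh:
        fh.write(provenance_header(config))
        pd.DataFrame(rows).to_csv(fh, index=False, float_format="%.6f")


# ring-center exports (crystal fingerprint images) ---------------------------

_POV_COLORS = {
    3: (1.0, 0.2, 0.2),
    4: (1.0, 0.6, 0.1),
    5: (0.9, 0.9, 0.1),
    6: (0.8, 0.1, 0.1),
    7: (0.2, 0.8, 0.2),
    8: (0.2, 0.6, 1.0),
    9: (0.5, 0.2, 0.9),
    10: (0.6, 1.0, 0.6),
}


def write_centers_csv(ring_set, centers, path, config: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(provenance_header(config))
        fh.write("size,directional,x,y,z\n")
        for r, c in zip(ring_set.rings, centers):
            fh.write(f"{r.n},{int(r.directional)},{c[0]:.4f},{c[1]:.4f},{c[2]:.4f}\n")


def write_centers_pov(ring_set, centers, box, path, config: dict | None = None) -> None:
    """POV-Ray SDL scene: one sphere per ring center, size/colour by ring size."""
    cx, cy, cz = (float(b) / 2 for b in box)
    lines = [
        f"// ringorder v{_version} ring-center fingerprint",
        f"// config: {json.dumps(config or {}, sort_keys=True, default=str)}",
        "#version 3.6;",
        "global_settings { assumed_gamma 1.0 }",
        "background { color rgb <1,1,1> }",
        f"camera {{ location <{cx},{cy},{cz + 3 * max(box)}> look_at <{cx},{cy},{cz}> }}",
        f"light_source {{ <{cx},{cy},{cz + 4 * max(box)}> color rgb <1,1,1> }}",
    ]
    for r, c in zip(ring_set.rings, centers):
        col = _POV_COLORS.get(r.n, (0.5, 0.5, 0.5))
        radius = 0.25 + 0.05 * r.n
        lines.append(
            f"sphere {{ <{c[0]:.3f},{c[1]:.3f},{c[2]:.3f}>, {radius:.2f} "
            f"pigment {{ color rgb <{col[0]},{col[1]},{col[2]}> }} }}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
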