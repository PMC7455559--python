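"""Readers and writers for structures, trajectories, and density maps.

PDB (single- and multi-model) is the canonical text interchange, parsed and
written through :mod:`gemmi`.  Binary trajectory formats (DCD/XTC) are
accepted through MDAnalysis when it is installed.  Density maps use the
MRC/CCP4 mode-2 container via gemmi; only isotropic voxels are supported
and the map origin is carried in ORIGIN header words 50–52 (Å position of
the center of voxel (0, 0, 0)).
"""

from __future__ import annotations

import logging
from pathlib import Path

import gemmi
import numpy as np

from .models import AtomRecord, DensityMap, Structure, Trajectory

log = logging.getLogger(__name__)

__all__ = [
    "read_structure",
    "write_structure",
    "read_trajectory",
    "write_trajectory",
    "read_map",
    "write_map",
]


class PDBParseError(ValueError):
    pass


def _validate_pdb_lines(path: Path) -> None:
    """Pre-scan coordinate records; gemmi is lenient, we are not."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM  ", "HETATM")):
                if len(line.rstrip("\n")) < 54:
                    raise PDBParseError(
                        f"{path}: line {lineno}: coordinate record too short"
                    )
                try:
                    float(line[30:38])
                    float(line[38:46])
                    float(line[46:54])
                except ValueError:
                    raise PDBParseError(
                        f"{path}: line {lineno}: unparsable coordinates"
                    ) from None


def _model_to_atoms(model: gemmi.Model) -> list[AtomRecord]:
    atoms = []
    for chain in model:
        for res in chain:
            het = res.het_flag == "H"
            for at in res:
                atoms.append(
                    AtomRecord(
                        atom_name=at.name,
                        element=at.element.name,
                        residue_name=res.name,
                        residue_id=res.seqid.num,
                        chain_id=chain.name,
                        position=(at.pos.x, at.pos.y, at.pos.z),
                        is_hetero=het,
                    )
                )
    return atoms


def _box_of(st: gemmi.Structure) -> np.ndarray | None:
    c = st.cell
    if c.a > 1.0 or c.b > 1.0 or c.c > 1.0:  # CRYST1 1 1 1 == no box
        return np.array([c.a, c.b, c.c])
    return None


def read_structure(path: str | Path, format: str = "pdb") -> Structure:
    """Read a single-model PDB file.

    Multi-model files are refused: use :func:`read_trajectory` for those.
    """
    if format != "pdb":
        raise ValueError(f"unsupported structure format {format!r}")
    path = Path(path)
    _validate_pdb_lines(path)
    st = gemmi.read_pdb(str(path))
    if len(st) > 1:
        raise ValueError(
            f"{path} contains {len(st)} MODEL blocks; use read_trajectory "
            "for multi-model files"
        )
    if len(st) == 0:
        raise PDBParseError(f"{path}: no coordinate records")
    return Structure(atoms=_model_to_atoms(st[0]), box=_box_of(st))


def _structure_to_gemmi(
    structure: Structure, coord_sets: list[np.ndarray]
) -> gemmi.Structure:
    st = gemmi.Structure()
    if structure.box is not None:
        b = structure.box
        st.cell = gemmi.UnitCell(b[0], b[1], b[2], 90, 90, 90)
    st.spacegroup_hm = "P 1"
    for imodel, coords in enumerate(coord_sets, start=1):
        model = gemmi.Model(str(imodel))
        chain = None
        res = None
        prev_key = None
        for atom, pos in zip(structure.atoms, coords):
            if chain is None or chain.name != atom.chain_id:
                if chain is not None:
                    model.add_chain(chain)
                chain = gemmi.Chain(atom.chain_id)
                prev_key = None
            key = (atom.residue_id, atom.residue_name)
            if key != prev_key:
                if res is not None:
                    chain.add_residue(res)
                res = gemmi.Residue()
                res.name = atom.residue_name
                res.seqid = gemmi.SeqId(atom.residue_id, " ")
                res.het_flag = "H" if atom.is_hetero else "A"
                prev_key = key
            at = gemmi.Atom()
            at.name = atom.atom_name
            at.element = gemmi.Element(atom.element)
            at.pos = gemmi.Position(*pos)
            res.add_atom(at)
        if res is not None:
            chain.add_residue(res)
        if chain is not None:
            model.add_chain(chain)
        st.add_model(model)
    return st


def write_structure(structure: Structure, path: str | Path) -> None:
    st = _structure_to_gemmi(structure, [structure.coords])
    st.write_pdb(str(path))


def read_trajectory(
    path: str | Path,
    format: str = "pdb",
    topology: Structure | None = None,
    dt_ns: float = 0.1,
) -> Trajectory:
    """Read a multi-frame trajectory.

    ``format='pdb'`` reads multi-model PDB; ``'dcd'``/``'xtc'`` require a
    ``topology`` Structure and MDAnalysis.  Each frame must carry the same
    atom count as the topology.
    """
    path = Path(path)
    if format == "pdb":
        _validate_pdb_lines(path)
        st = gemmi.read_pdb(str(path))
        if len(st) == 0:
            raise PDBParseError(f"{path}: no coordinate records")
        topo = Structure(atoms=_model_to_atoms(st[0]), box=_box_of(st))
        frames = []
        for k, model in enumerate(st):
            atoms = _model_to_atoms(model)
            if len(atoms) != len(topo):
                raise ValueError(
                    f"{path}: frame {k} has {len(atoms)} atoms, "
                    f"topology has {len(topo)}"
                )
            frames.append(
                np.array([a.position for a in atoms], dtype=float)
            )
        return Trajectory(topology=topo, frames=frames, dt_ns=dt_ns)
    if format in ("dcd", "xtc"):
        if topology is None:
            raise ValueError(f"{format} trajectories require a topology Structure")
        try:
            import MDAnalysis as mda
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise ImportError(
                "reading DCD/XTC requires MDAnalysis (install extra 'traj')"
            ) from exc
        u = mda.Universe.empty(len(topology), trajectory=True)
        u.load_new(str(path))
        frames = []
        for k, ts in enumerate(u.trajectory):
            if ts.positions.shape[0] != len(topology):
                raise ValueError(
                    f"{path}: frame {k} has {ts.positions.shape[0]} atoms, "
                    f"topology has {len(topology)}"
                )
            frames.append(np.array(ts.positions, dtype=float))
        return Trajectory(topology=topology, frames=frames, dt_ns=dt_ns)
    raise ValueError(f"unsupported trajectory format {format!r}")


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as a multi-model PDB."""
    st = _structure_to_gemmi(traj.topology, list(traj.frames))
    st.write_pdb(str(path))


_ORIGIN_WORDS = (50, 51, 52)


def read_map(path: str | Path) -> DensityMap:
    """Read an MRC/CCP4 map; mean/sd are recomputed from the voxel data."""
    m = gemmi.read_ccp4_map(str(path))
    spacing = m.grid.spacing
    if max(spacing) - min(spacing) > 1e-4 * max(spacing):
        raise ValueError(
            f"{path}: anisotropic voxels {spacing} unsupported "
            "(isotropic maps only)"
        )
    grid = np.array(m.grid, dtype=np.float64)
    origin = np.array([m.header_float(w) for w in _ORIGIN_WORDS], dtype=float)
    dm = DensityMap(grid=grid, voxel_size=float(spacing[0]), origin=origin)
    if dm.sd == 0:
        log.warning("%s: flat map, σ-scaling unavailable", path)
    return dm


def write_map(density_map: DensityMap, path: str | Path) -> None:
    nx, ny, nz = density_map.shape
    v = density_map.voxel_size
    g = gemmi.FloatGrid(nx, ny, nz)
    np.asarray(g)[...] = density_map.grid.astype(np.float32)
    g.unit_cell = gemmi.UnitCell(nx * v, ny * v, nz * v, 90, 90, 90)
    g.spacegroup = gemmi.SpaceGroup("P1")
    m = gemmi.Ccp4Map()
    m.grid = g
    m.update_ccp4_header()
    for w, val in zip(_ORIGIN_WORDS, density_map.origin):
        m.set_header_float(w, float(val))
    m.write_ccp4_map(str(path))
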