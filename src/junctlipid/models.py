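"""Shared domain containers.

Coordinate conventions used throughout the package:

* all lengths are in Å;
* the junction (pore) axis is z, with the junction midplane at z = 0
  between the two bilayers;
* density-map origins refer to the world-space position of the *center*
  of voxel (0, 0, 0); voxel indices are 0-based;
* subunit and rod labels are 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class AtomRecord:
    """One atom of a model: identity plus a position in Å."""

    atom_name: str
    element: str
    residue_name: str
    residue_id: int
    chain_id: str
    position: tuple[float, float, float]
    is_hetero: bool = False

    def __post_init__(self) -> None:
        if not self.element:
            raise ValueError(f"atom {self.atom_name!r}: element must be non-empty")
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.atom_name!r}: non-finite position")


@dataclass
class Structure:
    """An ordered collection of atoms, optionally with an orthorhombic box."""

    atoms: list[AtomRecord]
    box: np.ndarray | None = None  # (3,) Å, orthorhombic

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array in Å."""
        return np.array([a.position for a in self.atoms], dtype=float).reshape(-1, 3)

    def select(self, predicate) -> np.ndarray:
        """Indices of atoms for which ``predicate(atom)`` is true."""
        return np.array(
            [i for i, a in enumerate(self.atoms) if predicate(a)], dtype=int
        )


@dataclass
class Trajectory:
    """Frames of coordinates over a fixed topology.

    ``dt_ns`` defaults to 0.1 ns per frame, the sampling interval used for
    the configurational-state time series.
    """

    topology: Structure
    frames: list[np.ndarray]
    dt_ns: float = 0.1

    def __post_init__(self) -> None:
        if self.dt_ns <= 0:
            raise ValueError("dt_ns must be > 0")
        n = len(self.topology)
        for k, f in enumerate(self.frames):
            f = np.asarray(f, dtype=float)
            if f.shape != (n, 3):
                raise ValueError(
                    f"frame {k}: shape {f.shape} does not match topology "
                    f"({n} atoms)"
                )
            self.frames[k] = f

    @property
    def n_frames(self) -> int:
        return len(self.frames)


class SigmaUndefinedError(ValueError):
    """Raised when σ-scaling is requested on a flat (sd = 0) map."""


@dataclass
class DensityMap:
    """A 3D scalar field on an isotropic grid.

    ``grid`` is indexed ``[ix, iy, iz]``; ``origin`` is the Å position of
    the center of voxel (0, 0, 0).  ``mean``/``sd`` are full-grid statistics
    used for σ-scaling, recomputed whenever the grid changes.
    """

    grid: np.ndarray
    voxel_size: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    mean: float = field(init=False)
    sd: float = field(init=False)

    def __post_init__(self) -> None:
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be > 0")
        self.grid = np.asarray(self.grid, dtype=np.float64)
        if self.grid.ndim != 3:
            raise ValueError("grid must be 3-dimensional")
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.refresh_stats()

    def refresh_stats(self) -> None:
        self.mean = float(self.grid.mean())
        self.sd = float(self.grid.std())

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape

    def world_to_voxel(self, points: np.ndarray) -> np.ndarray:
        """Fractional voxel indices of world-space points (Å)."""
        pts = np.asarray(points, dtype=float)
        return (pts - self.origin) / self.voxel_size

    def voxel_to_world(self, idx: np.ndarray) -> np.ndarray:
        return np.asarray(idx, dtype=float) * self.voxel_size + self.origin

    def sigma_scale(self, values: np.ndarray) -> np.ndarray:
        """Convert raw density values to σ units ((v − mean)/sd)."""
        if self.sd == 0:
            raise SigmaUndefinedError("σ-scaling unavailable: map sd is 0")
        return (np.asarray(values, dtype=float) - self.mean) / self.sd


@dataclass
class LipidTopology:
    """Atom-name map for a two-chain lipid.

    Carbon lists are ordered from the glycerol (ester) end outward, so list
    position 1 is the carbonyl carbon; "carbons 4–11" indexes this list.
    Note the CHARMM atom-name offset: DMPC names C22..C214 / C32..C314 map
    to positions 1..13 here, a known off-by-one pitfall.
    """

    residue_name: str
    sn1_carbons: list[str]
    sn2_carbons: list[str]
    ch_hydrogens: dict[str, list[str]]
    headgroup_phosphorus: str = "P"

    def chain_carbons(self, chain: str) -> list[str]:
        if chain == "SN1":
            return self.sn1_carbons
        if chain == "SN2":
            return self.sn2_carbons
        raise ValueError(f"unknown chain {chain!r} (expected 'SN1' or 'SN2')")
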