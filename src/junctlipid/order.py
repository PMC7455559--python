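"""Acyl-chain order parameters and leaflet geometry for a dual-bilayer junction.

The deuterium order parameter of a C–H bond against the bilayer normal,

    S_CD = -< (3 cos^2(theta_CD) - 1) / 2 >,

is averaged over all C–H vectors of a carbon and over frames.  It is
bounded in [-1, +0.5]: +0.5 when every C–H vector lies perpendicular to
the normal (extended all-trans chains standing along the normal), -1 when
parallel, 0 for an isotropic distribution.  Values above ~0.25 indicate a
gel-like (liquid-ordered) leaflet; fluid bilayers sit near ~0.2.

The junction geometry has two parallel bilayers; within each membrane the
leaflet facing the inter-membrane gap (z = 0) is the extracellular (EC)
leaflet and the outward-facing one is intracellular (IC).  The bilayer
normal is the junction axis z throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .models import LipidTopology, Structure, Trajectory

S_CD_MIN, S_CD_MAX = -1.0, 0.5

LipidKey = tuple[str, int]  # (chain_id, residue_id)


@dataclass(frozen=True)
class LeafletLabel:
    membrane: int  # 1 (z > 0) or 2 (z < 0)
    leaflet: str  # "EC" (faces the gap) or "IC"


@dataclass
class LipidAtoms:
    """Resolved atom indices of one lipid residue within a Structure."""

    key: LipidKey
    atom_index: dict[str, int]
    heavy_indices: np.ndarray

    def index_of(self, name: str) -> int:
        try:
            return self.atom_index[name]
        except KeyError:
            raise KeyError(
                f"lipid {self.key}: atom {name!r} not found in structure"
            ) from None


def find_lipids(structure: Structure, topo: LipidTopology) -> list[LipidAtoms]:
    """Group the structure's atoms of ``topo.residue_name`` into lipids."""
    groups: dict[LipidKey, dict[str, int]] = {}
    heavies: dict[LipidKey, list[int]] = {}
    for i, a in enumerate(structure.atoms):
        if a.residue_name != topo.residue_name:
            continue
        key = (a.chain_id, a.residue_id)
        groups.setdefault(key, {})[a.atom_name] = i
        if a.element != "H":
            heavies.setdefault(key, []).append(i)
    return [
        LipidAtoms(key=k, atom_index=v, heavy_indices=np.array(heavies[k]))
        for k, v in groups.items()
    ]


def assign_leaflets(
    frame: np.ndarray,
    structure: Structure,
    topo: LipidTopology,
    min_gap: float = 5.0,
) -> dict[LipidKey, LeafletLabel]:
    """Assign every lipid to one of four leaflets by phosphorus z.

    The head-group phosphorus z coordinates are split into 4 clusters at
    the 3 largest sorted gaps; each split gap must exceed ``min_gap`` Å or
    the system is rejected as not being a dual bilayer.
    """
    lipids = find_lipids(structure, topo)
    if not lipids:
        raise ValueError("no lipids found")
    pz = np.array(
        [frame[l.index_of(topo.headgroup_phosphorus)][2] for l in lipids]
    )
    order = np.argsort(pz)
    z_sorted = pz[order]
    gaps = np.diff(z_sorted)
    if len(gaps) < 3:
        raise ValueError("too few lipids to resolve four leaflets")
    split_pos = np.sort(np.argsort(gaps)[-3:])
    if np.any(gaps[split_pos] < min_gap):
        raise ValueError(
            "fewer than 4 separated phosphorus z-clusters: "
            "not a dual-bilayer junction"
        )
    bounds = [0, *(split_pos + 1), len(z_sorted)]
    labels_sorted = np.empty(len(z_sorted), dtype=int)
    means = []
    for c in range(4):
        sl = slice(bounds[c], bounds[c + 1])
        labels_sorted[sl] = c
        means.append(z_sorted[sl].mean())
    # clusters ordered bottom→top: IC2, EC2, EC1, IC1
    cluster_label = {
        0: LeafletLabel(membrane=2, leaflet="IC"),
        1: LeafletLabel(membrane=2, leaflet="EC"),
        2: LeafletLabel(membrane=1, leaflet="EC"),
        3: LeafletLabel(membrane=1, leaflet="IC"),
    }
    out: dict[LipidKey, LeafletLabel] = {}
    for rank, lipid_i in enumerate(order):
        out[lipids[lipid_i].key] = cluster_label[labels_sorted[rank]]
    return out


def _chain_ch_pairs(
    lipid: LipidAtoms, topo: LipidTopology, chain: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(carbon_idx, hydrogen_idx, carbon_position[1-based]) flat arrays."""
    c_idx, h_idx, pos = [], [], []
    for k, cname in enumerate(topo.chain_carbons(chain), start=1):
        hydrogens = topo.ch_hydrogens.get(cname, [])
        if not hydrogens:
            continue
        ci = lipid.index_of(cname)
        for hname in hydrogens:
            if hname not in lipid.atom_index:
                raise ValueError(
                    f"lipid {lipid.key}: carbon {cname} is missing hydrogen "
                    f"{hname}; explicit hydrogens are required"
                )
            c_idx.append(ci)
            h_idx.append(lipid.atom_index[hname])
            pos.append(k)
    return np.array(c_idx, int), np.array(h_idx, int), np.array(pos, int)


def _scd_values(frame: np.ndarray, c_idx, h_idx, normal: np.ndarray) -> np.ndarray:
    v = frame[h_idx] - frame[c_idx]
    cos = (v @ normal) / np.linalg.norm(v, axis=1)
    return -(3.0 * cos**2 - 1.0) / 2.0


def _check_range(values: np.ndarray) -> None:
    if np.any(values < S_CD_MIN - 1e-9) or np.any(values > S_CD_MAX + 1e-9):
        bad = values[(values < S_CD_MIN - 1e-9) | (values > S_CD_MAX + 1e-9)]
        raise AssertionError(
            f"S_CD outside [{S_CD_MIN}, {S_CD_MAX}]: {bad[:5]} — "
            "check the normal vector and hydrogen assignments"
        )


def scd_per_carbon(
    traj: Trajectory,
    lipid: LipidAtoms,
    chain: str,
    topo: LipidTopology,
    normal: np.ndarray = (0.0, 0.0, 1.0),
) -> pd.DataFrame:
    """Per-carbon S_CD profile of one chain, averaged over H pairs and frames.

    Returns a DataFrame with columns ``carbon`` (1-based position along the
    chain from the ester end), ``s_cd`` and ``n_samples``.
    """
    normal = np.asarray(normal, dtype=float)
    normal = normal / np.linalg.norm(normal)
    c_idx, h_idx, pos = _chain_ch_pairs(lipid, topo, chain)
    carbons = np.unique(pos)
    sums = np.zeros(len(carbons))
    counts = np.zeros(len(carbons), dtype=int)
    slot = np.searchsorted(carbons, pos)
    for frame in traj.frames:
        vals = _scd_values(frame, c_idx, h_idx, normal)
        np.add.at(sums, slot, vals)
        np.add.at(counts, slot, 1)
    s_cd = sums / counts
    _check_range(s_cd)
    return pd.DataFrame(
        {"chain": chain, "carbon": carbons, "s_cd": s_cd, "n_samples": counts}
    )


def per_lipid_scd(
    traj: Trajectory,
    lipid: LipidAtoms,
    topo: LipidTopology,
    carbons: tuple[int, int] = (4, 11),
    normal: np.ndarray = (0.0, 0.0, 1.0),
) -> float:
    """Time-averaged S_CD of one lipid, both chains combined.

    Restricted to carbon positions ``carbons[0]..carbons[1]`` inclusive
    (default 4–11, the mid-chain window used for per-lipid coloring).
    """
    normal = np.asarray(normal, dtype=float)
    normal = normal / np.linalg.norm(normal)
    lo, hi = carbons
    total, n = 0.0, 0
    for chain in ("SN1", "SN2"):
        c_idx, h_idx, pos = _chain_ch_pairs(lipid, topo, chain)
        keep = (pos >= lo) & (pos <= hi)
        c_idx, h_idx = c_idx[keep], h_idx[keep]
        for frame in traj.frames:
            vals = _scd_values(frame, c_idx, h_idx, normal)
            total += vals.sum()
            n += vals.size
    value = total / n
    _check_range(np.array([value]))
    return value


def lipid_protein_distances(
    frame: np.ndarray,
    lipids: list[LipidAtoms],
    protein_indices: np.ndarray,
    structure: Structure | None = None,
) -> np.ndarray:
    """Min heavy-atom distance from each lipid to the protein, one frame."""
    tree = cKDTree(frame[protein_indices])
    out = np.empty(len(lipids))
    for i, lip in enumerate(lipids):
        d, _ = tree.query(frame[lip.heavy_indices])
        out[i] = d.min()
    return out


def shell_average_scd(
    traj: Trajectory,
    protein_indices: np.ndarray,
    lipids: list[LipidAtoms],
    topo: LipidTopology,
    shell_width: float = 5.0,
    leaflet_filter: str | None = None,
    leaflets: dict[LipidKey, LeafletLabel] | None = None,
    n_shells: int = 8,
    normal: np.ndarray = (0.0, 0.0, 1.0),
) -> pd.DataFrame:
    """Mean S_CD per carbon per chain in concentric shells around the protein.

    A lipid-frame sample is binned by the lipid's minimum heavy-atom
    distance to any protein atom in that frame; shells are contiguous
    ``shell_width``-Å bands starting at distance 0 from the protein
    surface.  Lipids from both membranes are pooled; EC and IC leaflets
    are averaged separately via ``leaflet_filter``.  Empty shells are
    reported with n = 0 rather than dropped.
    """
    if protein_indices is None or len(protein_indices) == 0:
        raise ValueError("empty protein selection")
    normal = np.asarray(normal, dtype=float)
    normal = normal / np.linalg.norm(normal)

    if leaflet_filter is not None:
        if leaflets is None:
            leaflets = assign_leaflets(traj.frames[0], traj.topology, topo)
        lipids = [
            l for l in lipids if leaflets[l.key].leaflet == leaflet_filter
        ]

    chains = ("SN1", "SN2")
    pair_data = {
        ch: [ _chain_ch_pairs(l, topo, ch) for l in lipids ] for ch in chains
    }
    carbons = np.unique(
        np.concatenate([p[2] for ch in chains for p in pair_data[ch]])
    )
    nC = len(carbons)
    sums = np.zeros((n_shells, 2, nC))
    counts = np.zeros((n_shells, 2, nC), dtype=int)
    shell_lipid_frames = np.zeros(n_shells, dtype=int)

    for frame in traj.frames:
        dist = lipid_protein_distances(frame, lipids, protein_indices)
        shell = np.floor(dist / shell_width).astype(int)
        for li, sh in enumerate(shell):
            if sh >= n_shells:
                continue
            shell_lipid_frames[sh] += 1
            for ci, ch in enumerate(chains):
                c_idx, h_idx, pos = pair_data[ch][li]
                vals = _scd_values(frame, c_idx, h_idx, normal)
                slot = np.searchsorted(carbons, pos)
                np.add.at(sums[sh, ci], slot, vals)
                np.add.at(counts[sh, ci], slot, 1)

    rows = []
    for sh in range(n_shells):
        for ci, ch in enumerate(chains):
            for k, carbon in enumerate(carbons):
                n = counts[sh, ci, k]
                rows.append(
                    {
                        "shell": sh + 1,
                        "inner": sh * shell_width,
                        "outer": (sh + 1) * shell_width,
                        "chain": ch,
                        "carbon": int(carbon),
                        "s_cd": sums[sh, ci, k] / n if n else np.nan,
                        "n": int(n),
                    }
                )
    df = pd.DataFrame(rows)
    _check_range(df["s_cd"].dropna().to_numpy())
    return df


def area_per_lipid(
    frame: np.ndarray,
    structure: Structure,
    leaflet_lipids: list[LipidAtoms],
    protein_indices: np.ndarray,
    z_range: tuple[float, float],
    box_xy: tuple[float, float] | None = None,
    raster: float = 1.0,
    dilation: float = 2.0,
) -> float:
    """Mean in-plane area per lipid in one leaflet, Å².

    The protein's cross-section within the leaflet's z-slab is estimated
    by rasterizing protein heavy atoms onto a 2D grid (``raster`` Å) and
    dilating by ``dilation`` Å; the remaining box area is divided by the
    leaflet's lipid count.
    """
    if not leaflet_lipids:
        raise ValueError("no lipids in leaflet")
    if box_xy is None:
        if structure.box is None:
            raise ValueError("box dimensions required")
        box_xy = (structure.box[0], structure.box[1])
    total_area = box_xy[0] * box_xy[1]

    protein_area = 0.0
    if protein_indices is not None and len(protein_indices) > 0:
        pos = frame[protein_indices]
        in_slab = (pos[:, 2] >= z_range[0]) & (pos[:, 2] <= z_range[1])
        pos = pos[in_slab]
        if len(pos):
            from scipy.ndimage import binary_dilation

            nx = max(int(np.ceil(box_xy[0] / raster)), 1)
            ny = max(int(np.ceil(box_xy[1] / raster)), 1)
            x0 = pos[:, 0].min() - dilation - raster
            y0 = pos[:, 1].min() - dilation - raster
            mask = np.zeros((nx + 8, ny + 8), dtype=bool)
            ix = np.clip(((pos[:, 0] - x0) / raster).astype(int), 0, mask.shape[0] - 1)
            iy = np.clip(((pos[:, 1] - y0) / raster).astype(int), 0, mask.shape[1] - 1)
            mask[ix, iy] = True
            r = int(np.ceil(dilation / raster))
            yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
            selem = (xx**2 + yy**2) * raster**2 <= dilation**2
            mask = binary_dilation(mask, structure=selem)
            protein_area = mask.sum() * raster**2

    return (total_area - protein_area) / len(leaflet_lipids)
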