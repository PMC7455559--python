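"""Annular-lipid configurational states from rod densities.

The time-averaged extracellular-leaflet acyl-chain density of the channel
resolves elongated "rod" features — one per acyl-chain position, 19 per
subunit × 12 subunits = 228 positions.  A chain occupies a rod when at
least five of its carbons sit inside the rod's σ ≥ σ_min region; a lipid
is in configurational state "i–j" when its SN1 chain occupies rod i and
SN2 occupies rod j (i ≠ j).  Classifying every lipid within 15 Å of the
protein at every frame (0.1 ns apart) yields per-lipid state time series,
from which dwell times and transition counts follow.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .density import SymmetryGroup, sigma_at
from .models import DensityMap, LipidTopology, Structure, Trajectory
from .order import LipidAtoms, LipidKey

log = logging.getLogger(__name__)

SIGMA_MIN_DEFAULT = 8.0
MIN_CARBONS_OCCUPIED = 5
PROXIMITY_CUTOFF = 15.0
MIN_ROD_VOXELS = 20

NONE_STATE = "none"
DEGENERATE_STATE = "degenerate"


@dataclass
class Rod:
    """One connected σ ≥ σ_min density component, assigned to a subunit."""

    subunit: int  # 1..12
    index: int  # 1..n within subunit, by increasing centroid radius
    voxels: np.ndarray  # (n, 3) integer grid indices
    centroid: np.ndarray  # world-space Å

    @property
    def label(self) -> tuple[int, int]:
        return (self.subunit, self.index)


@dataclass
class RodCatalogue:
    rods: list[Rod]
    sigma_min: float
    source_map: DensityMap
    # voxel → rod id lookup (-1 outside any rod), same shape as the map
    label_grid: np.ndarray = field(repr=False, default=None)

    def __len__(self) -> int:
        return len(self.rods)

    def rods_per_subunit(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for r in self.rods:
            out[r.subunit] = out.get(r.subunit, 0) + 1
        return out


def build_rod_catalogue(
    density_map: DensityMap,
    sigma_min: float = SIGMA_MIN_DEFAULT,
    z_slab: tuple[float, float] | None = None,
    sym: SymmetryGroup | None = None,
    min_voxels: int = MIN_ROD_VOXELS,
    radial_bin: float = 2.0,
) -> RodCatalogue:
    """Segment rod densities above ``sigma_min`` into a catalogue.

    Voxels with σ ≥ sigma_min inside the z-slab are grouped into
    26-connected components; components below ``min_voxels`` voxels are
    discarded as noise.  Components are assigned to subunits by the 30°
    angular sector of their centroid around the symmetry axis (sector s
    spans [(s−1)·30°, s·30°)), and numbered within each subunit by
    increasing centroid radius, ties broken by azimuth — a deterministic
    replacement for an arbitrary numbering.
    """
    sym = sym or SymmetryGroup.d6()
    sigma_grid = density_map.sigma_scale(density_map.grid)
    mask = sigma_grid >= sigma_min
    if z_slab is not None:
        nz = density_map.shape[2]
        zw = density_map.origin[2] + density_map.voxel_size * np.arange(nz)
        z_ok = (zw >= z_slab[0]) & (zw <= z_slab[1])
        mask &= z_ok[None, None, :]

    structure26 = np.ones((3, 3, 3), dtype=bool)
    labels, n_comp = ndimage.label(mask, structure=structure26)
    if n_comp == 0:
        log.warning("no voxels at σ ≥ %.1f: empty rod catalogue", sigma_min)
        return RodCatalogue(
            rods=[],
            sigma_min=sigma_min,
            source_map=density_map,
            label_grid=np.full(density_map.shape, -1, dtype=np.int32),
        )

    center = sym.center
    per_subunit: dict[int, list[tuple[float, float, np.ndarray, np.ndarray]]] = {}
    for comp in range(1, n_comp + 1):
        vox = np.argwhere(labels == comp)
        if len(vox) < min_voxels:
            continue
        centroid = density_map.voxel_to_world(vox.mean(axis=0))
        dx, dy = centroid[0] - center[0], centroid[1] - center[1]
        azimuth = np.arctan2(dy, dx) % (2 * np.pi)
        radius = float(np.hypot(dx, dy))
        sector = int(azimuth // (np.pi / 6)) + 1  # 30° sectors, 1-based
        per_subunit.setdefault(sector, []).append(
            (radius, float(azimuth), centroid, vox)
        )

    rods: list[Rod] = []
    label_grid = np.full(density_map.shape, -1, dtype=np.int32)
    for subunit in sorted(per_subunit):
        # radius is binned before sorting so that rods at (nearly) equal
        # radius — a hexagonal row — are ordered by azimuth, not by
        # sub-voxel centroid noise
        members = sorted(
            per_subunit[subunit],
            key=lambda t: (round(t[0] / radial_bin), t[1]),
        )
        for idx, (_, _, centroid, vox) in enumerate(members, start=1):
            rod_id = len(rods)
            rods.append(
                Rod(subunit=subunit, index=idx, voxels=vox, centroid=centroid)
            )
            label_grid[vox[:, 0], vox[:, 1], vox[:, 2]] = rod_id

    counts = [len(v) for v in per_subunit.values()]
    if counts and max(counts) > 2 * max(min(counts), 1):
        log.warning(
            "rod counts per subunit vary %d–%d: map may not be symmetric",
            min(counts),
            max(counts),
        )
    return RodCatalogue(
        rods=rods,
        sigma_min=sigma_min,
        source_map=density_map,
        label_grid=label_grid,
    )


def chain_occupancy(
    carbon_positions: np.ndarray,
    rod: Rod,
    catalogue: RodCatalogue,
) -> tuple[bool, int]:
    """Does this chain occupy the rod, and with how many carbons?

    A carbon counts when its nearest voxel belongs to the rod's voxel set
    AND the interpolated σ at its position is ≥ σ_min; the chain occupies
    the rod when ≥ 5 carbons count.
    """
    if isinstance(rod, int):
        rod_id = rod
    else:
        rod_id = next(i for i, r in enumerate(catalogue.rods) if r is rod)
    count = _rod_carbon_counts(carbon_positions, catalogue)[1].get(rod_id, 0)
    return count >= MIN_CARBONS_OCCUPIED, count


def _rod_carbon_counts(
    carbon_positions: np.ndarray, catalogue: RodCatalogue
) -> tuple[int, dict[int, int]]:
    """Per-rod qualifying-carbon counts for one chain in one frame."""
    dm = catalogue.source_map
    vox = np.rint(dm.world_to_voxel(carbon_positions)).astype(int)
    shape = np.array(dm.shape)
    inside = np.all((vox >= 0) & (vox < shape), axis=1)
    counts: dict[int, int] = {}
    if not inside.any():
        return 0, counts
    pos_in = carbon_positions[inside]
    vox_in = vox[inside]
    rod_ids = catalogue.label_grid[vox_in[:, 0], vox_in[:, 1], vox_in[:, 2]]
    sig = sigma_at(dm, pos_in)
    sig = np.atleast_1d(sig)
    ok = (rod_ids >= 0) & (sig >= catalogue.sigma_min)
    for rid in rod_ids[ok]:
        counts[int(rid)] = counts.get(int(rid), 0) + 1
    return int(ok.sum()), counts


def _best_rod(counts: dict[int, int], catalogue: RodCatalogue) -> int | None:
    """Occupied rod for a chain: max carbon count, ties to lowest rod label."""
    qualifying = {
        rid: c for rid, c in counts.items() if c >= MIN_CARBONS_OCCUPIED
    }
    if not qualifying:
        return None
    return min(
        qualifying,
        key=lambda rid: (-qualifying[rid], catalogue.rods[rid].label),
    )


def classify_state(
    frame: np.ndarray,
    lipid: LipidAtoms,
    topo: LipidTopology,
    catalogue: RodCatalogue,
    ordered: bool = True,
) -> str:
    """Per-frame configurational state of one lipid.

    Returns "i–j" (SN1 rod i, SN2 rod j; subunit-qualified labels like
    "s4:1–s4:2"), "degenerate" when both chains occupy the same rod, or
    "none" when either chain occupies no rod.  With ``ordered=False``
    the pair is sorted so "i–j" and "j–i" collapse to one label.
    """
    assignments = []
    for chain in ("SN1", "SN2"):
        names = topo.chain_carbons(chain)
        idx = [lipid.index_of(n) for n in names]
        _, counts = _rod_carbon_counts(frame[idx], catalogue)
        assignments.append(_best_rod(counts, catalogue))
    i, j = assignments
    if i is None or j is None:
        return NONE_STATE
    if i == j:
        return DEGENERATE_STATE
    if not ordered:
        i, j = sorted((i, j), key=lambda r: catalogue.rods[r].label)
    return f"{_rod_name(catalogue, i)}–{_rod_name(catalogue, j)}"


def _rod_name(catalogue: RodCatalogue, rod_id: int) -> str:
    rod = catalogue.rods[rod_id]
    return f"s{rod.subunit}:{rod.index}"


@dataclass
class StateSeries:
    lipid: LipidKey
    labels: list[str]
    in_range: np.ndarray  # bool per frame
    dt_ns: float


def state_timeseries(
    traj: Trajectory,
    lipids: list[LipidAtoms],
    topo: LipidTopology,
    catalogue: RodCatalogue,
    protein_indices: np.ndarray,
    cutoff: float = PROXIMITY_CUTOFF,
    fixed_membership: bool = False,
    ordered: bool = True,
) -> list[StateSeries]:
    """Per-frame state label for every lipid near the protein.

    Proximity (min heavy-atom distance ≤ cutoff) is evaluated per frame,
    so membership can toggle; with ``fixed_membership=True`` the
    first-frame decision holds for the whole series.
    Out-of-range frames carry the "none" label with in_range = False.
    """
    series = [
        StateSeries(
            lipid=l.key,
            labels=[],
            in_range=np.zeros(traj.n_frames, dtype=bool),
            dt_ns=traj.dt_ns,
        )
        for l in lipids
    ]
    member0: dict[int, bool] = {}
    for fi, frame in enumerate(traj.frames):
        tree = cKDTree(frame[protein_indices])
        for li, lip in enumerate(lipids):
            d, _ = tree.query(frame[lip.heavy_indices])
            near = bool(d.min() <= cutoff)
            if fixed_membership:
                near = member0.setdefault(li, near)
            if near:
                series[li].in_range[fi] = True
                series[li].labels.append(
                    classify_state(frame, lip, topo, catalogue, ordered=ordered)
                )
            else:
                series[li].labels.append(NONE_STATE)
    return series


@dataclass
class DwellRecord:
    lipid: LipidKey
    state: str
    start_frame: int
    n_frames: int
    duration_ns: float


def dwell_analysis(
    series: StateSeries,
) -> tuple[list[DwellRecord], int, str]:
    """Run-length dwell records, transition count and stability verdict.

    Dwells are maximal runs of identical labels over in-range frames;
    a transition is a label change between adjacent in-range frames.  A
    lipid is "stable" when no transition between pair-states occurs over
    its in-range span (dwells in "none"/"degenerate" do not count as
    pair-state transitions).
    """
    if not series.labels:
        raise ValueError("empty state series")
    frames = [
        (fi, lab)
        for fi, (lab, ir) in enumerate(zip(series.labels, series.in_range))
        if ir
    ]
    records: list[DwellRecord] = []
    transitions = 0
    pair_transitions = 0
    prev_label = None
    for fi, lab in frames:
        if prev_label is not None and lab != prev_label:
            transitions += 1
            if _is_pair(lab) and _is_pair(prev_label):
                pair_transitions += 1
        if prev_label == lab and records:
            records[-1].n_frames += 1
            records[-1].duration_ns += series.dt_ns
        else:
            records.append(
                DwellRecord(
                    lipid=series.lipid,
                    state=lab,
                    start_frame=fi,
                    n_frames=1,
                    duration_ns=series.dt_ns,
                )
            )
        prev_label = lab
    verdict = "stable" if pair_transitions == 0 else "transitioning"
    return records, transitions, verdict


def _is_pair(label: str) -> bool:
    return label not in (NONE_STATE, DEGENERATE_STATE)


def state_census(all_series: list[StateSeries]) -> pd.DataFrame:
    """Aggregate occupancy fractions and mean dwell times per state.

    Fractions are over in-range frames of all lipids and sum to 1
    (including the "none" and "degenerate" bins).
    """
    frame_counts: dict[str, int] = {}
    dwell_sums: dict[str, float] = {}
    dwell_counts: dict[str, int] = {}
    lipid_sets: dict[str, set] = {}
    total = 0
    for s in all_series:
        for lab, ir in zip(s.labels, s.in_range):
            if not ir:
                continue
            total += 1
            frame_counts[lab] = frame_counts.get(lab, 0) + 1
            lipid_sets.setdefault(lab, set()).add(s.lipid)
        if s.in_range.any():
            records, _, _ = dwell_analysis(s)
            for r in records:
                dwell_sums[r.state] = dwell_sums.get(r.state, 0.0) + r.duration_ns
                dwell_counts[r.state] = dwell_counts.get(r.state, 0) + 1
    rows = [
        {
            "state": lab,
            "fraction": frame_counts[lab] / total if total else np.nan,
            "mean_dwell_ns": dwell_sums.get(lab, 0.0)
            / max(dwell_counts.get(lab, 0), 1),
            "n_lipids": len(lipid_sets[lab]),
        }
        for lab in sorted(frame_counts)
    ]
    return pd.DataFrame(rows)
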