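"""Three-criterion validation of modeled water positions.

A modeled water is assessed by:

1. hydrogen-bond coordination — at least two N/O donor/acceptor partners
   within a strict < 4.0 Å donor–acceptor distance (distance-only; no
   angle screening);
2. half-map consistency — density ≥ 2.5σ at the water oxygen in BOTH
   independently reconstructed half-maps;
3. experiment/simulation overlap — density ≥ 5.3σ in the experimental map
   AND ≥ 5.0σ in the time-averaged MD water density map.

Criteria 1–2 are required for acceptance; criterion 3 is advisory and is
reported as an agreement fraction (the share of accepted waters also seen
by simulation at an equivalent position).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import density as dmod
from .density import SymmetryGroup, average_maps, compute_density_map, symmetrize
from .models import DensityMap, Structure, Trajectory

WATER_RESNAMES = {"HOH", "WAT", "TIP3", "SOL"}


@dataclass
class HBondRules:
    elements: frozenset[str] = frozenset({"N", "O"})
    cutoff: float = 4.0  # donor–acceptor distance, Å (strict <)
    min_partners: int = 2

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be > 0")


def find_hbond_partners(
    water_position: np.ndarray,
    water_atom_indices: set[int],
    structure: Structure,
    rules: HBondRules | None = None,
    coords: np.ndarray | None = None,
) -> list[int]:
    """Indices of N/O atoms within the donor–acceptor cutoff of a water O.

    The water's own atoms are excluded; the criterion is distance-only.
    """
    rules = rules or HBondRules()
    if coords is None:
        coords = structure.coords
    cand = [
        i
        for i, a in enumerate(structure.atoms)
        if a.element in rules.elements and i not in water_atom_indices
    ]
    if not cand:
        return []
    cand = np.array(cand)
    d = np.linalg.norm(coords[cand] - np.asarray(water_position), axis=1)
    return [int(i) for i in cand[d < rules.cutoff]]


def halfmap_consistency(
    position: np.ndarray,
    half1: DensityMap,
    half2: DensityMap,
    threshold: float = 2.5,
) -> tuple[bool, float, float]:
    """Pass iff σ ≥ threshold in BOTH half-maps at the position."""
    s1 = dmod.sigma_at(half1, position)
    s2 = dmod.sigma_at(half2, position)
    return (s1 >= threshold and s2 >= threshold), s1, s2


def md_overlap(
    position: np.ndarray,
    cryoem_map: DensityMap,
    md_map: DensityMap,
    threshold_cryoem: float = 5.3,
    threshold_md: float = 5.0,
) -> tuple[bool, float, float]:
    """Pass iff the experimental map ≥ 5.3σ AND the MD water map ≥ 5.0σ."""
    se = dmod.sigma_at(cryoem_map, position)
    sm = dmod.sigma_at(md_map, position)
    return (se >= threshold_cryoem and sm >= threshold_md), se, sm


@dataclass
class WaterValidationSummary:
    n_waters: int
    frac_hbond: float
    frac_halfmaps: float
    frac_md_overlap: float
    frac_accepted: float
    frac_accepted_with_md: float  # of accepted waters, share also seen by MD


def validate_waters(
    model: Structure,
    half1: DensityMap,
    half2: DensityMap,
    cryoem_map: DensityMap,
    md_map: DensityMap,
    rules: HBondRules | None = None,
    halfmap_threshold: float = 2.5,
    cryoem_threshold: float = 5.3,
    md_threshold: float = 5.0,
) -> tuple[pd.DataFrame, WaterValidationSummary]:
    """Assess every water in the model against all three criteria.

    The verdict requires criteria 1 and 2; criterion 3 is recorded and
    summarized as the fraction of accepted waters with an MD counterpart.
    """
    rules = rules or HBondRules()
    coords = model.coords
    waters: dict[tuple[str, int], dict] = {}
    for i, a in enumerate(model.atoms):
        if a.residue_name in WATER_RESNAMES:
            w = waters.setdefault((a.chain_id, a.residue_id), {"idx": set()})
            w["idx"].add(i)
            if a.element == "O":
                w["oxygen"] = i

    rows = []
    for key, w in sorted(waters.items()):
        if "oxygen" not in w:
            continue
        o_pos = coords[w["oxygen"]]
        partners = find_hbond_partners(o_pos, w["idx"], model, rules, coords)
        pass_hb = len(partners) >= rules.min_partners
        pass_half, s1, s2 = halfmap_consistency(
            o_pos, half1, half2, halfmap_threshold
        )
        pass_md, se, sm = md_overlap(
            o_pos, cryoem_map, md_map, cryoem_threshold, md_threshold
        )
        rows.append(
            {
                "water": f"{key[0]}:{key[1]}",
                "n_hbond_partners": len(partners),
                "sigma_half1": s1,
                "sigma_half2": s2,
                "sigma_cryoem": se,
                "sigma_md": sm,
                "pass_hbond": pass_hb,
                "pass_halfmaps": pass_half,
                "pass_md_overlap": pass_md,
                "accepted": pass_hb and pass_half,
            }
        )
    table = pd.DataFrame(rows)
    if table.empty:
        import logging

        logging.getLogger(__name__).warning("model contains no waters")
        summary = WaterValidationSummary(0, *(np.nan,) * 5)
        return table, summary

    accepted = table["accepted"]
    summary = WaterValidationSummary(
        n_waters=len(table),
        frac_hbond=table["pass_hbond"].mean(),
        frac_halfmaps=table["pass_halfmaps"].mean(),
        frac_md_overlap=table["pass_md_overlap"].mean(),
        frac_accepted=accepted.mean(),
        frac_accepted_with_md=(
            table.loc[accepted, "pass_md_overlap"].mean()
            if accepted.any()
            else np.nan
        ),
    )
    return table, summary


def water_density_from_traj(
    runs: list[Trajectory],
    voxel_size: float = 0.649,
    sym: SymmetryGroup | None = None,
    extent=None,
) -> DensityMap:
    """Time-averaged, run-averaged, symmetrized water-oxygen density map."""
    sym = sym or SymmetryGroup.d6()

    def is_water_oxygen(a):
        return a.residue_name in WATER_RESNAMES and a.element == "O"

    if extent is None:
        # one lattice for all runs so they can be averaged voxelwise
        pts = np.concatenate(
            [
                f[t.topology.select(is_water_oxygen)]
                for t in runs
                for f in t.frames
            ]
        )
        pad = 4.0 * 1.8
        extent = (pts.min(axis=0) - pad, pts.max(axis=0) + pad)
    maps = [
        compute_density_map(t, is_water_oxygen, voxel_size, extent=extent)
        for t in runs
    ]
    return symmetrize(average_maps(maps), sym)
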