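"""Seeded generator of toy dual-membrane junction systems with planted truth.

The generator emulates the geometry of a gap-junction-like channel for
testing the analysis stages end to end:

* a 12-subunit pseudo-protein of wedge-arranged pseudo-atoms about the z
  axis, spanning both membranes;
* two parallel bilayers with midplanes at z = ±39.5 Å, giving phosphorus
  planes near ±22 Å (extracellular, facing the gap) and ±57 Å
  (intracellular);
* two-chain lipids with 14 carbons per chain and explicit hydrogens,
  posed geometrically — an ordered (small-tilt, all-trans, gel-like)
  model for the extracellular leaflets versus a disordered (large-tilt,
  trans/gauche) model for the intracellular leaflets;
* a hexagonal lattice of 19 acyl-chain "rod" sites per 30° subunit
  sector, with selected lipids hopping between rod-pair configurations
  under a planted Markov chain;
* waters with scripted hydrogen-bond partners, plus decoys, and density
  maps (full, two independently noised half-maps, and an MD-style water
  map covering a planted fraction of the waters).

Lipids are posed, not physically simulated: every planted quantity
(leaflet labels, per-leaflet S_CD expectation, per-frame configurational
states, water verdicts) is recorded in a truth structure so downstream
modules can be scored without re-deriving geometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .density import SymmetryGroup
from .models import AtomRecord, DensityMap, LipidTopology, Structure, Trajectory

# geometry constants (Å)
CC_RISE = 1.27  # per-carbon rise of an all-trans chain along its axis
CH_LENGTH = 1.09
HEAD_TO_C1 = 1.5
CHAIN_XY_OFFSET = 0.9  # lateral SN1/SN2 separation


def default_lipid_topology() -> LipidTopology:
    """A 14-carbon two-chain PC lipid with CHARMM-style atom names.

    SN2 carbons are named C21..C214 with hydrogens HkR/HkS (HkT on the
    terminal methyl); SN1 carbons C31..C314 with HkX/HkY (HkZ terminal).
    Position 1 is the carbonyl carbon and carries no hydrogen.
    """
    sn2 = [f"C2{k}" for k in range(1, 15)]
    sn1 = [f"C3{k}" for k in range(1, 15)]
    ch: dict[str, list[str]] = {}
    for k in range(2, 15):
        ch[f"C2{k}"] = [f"H{k}R", f"H{k}S"] + (["H14T"] if k == 14 else [])
        ch[f"C3{k}"] = [f"H{k}X", f"H{k}Y"] + (["H14Z"] if k == 14 else [])
    return LipidTopology(
        residue_name="DMP",
        sn1_carbons=sn1,
        sn2_carbons=sn2,
        ch_hydrogens=ch,
        headgroup_phosphorus="P",
    )


@dataclass
class JunctionSpec:
    n_subunits: int = 12
    membrane_midplane: float = 39.5  # |z| of each bilayer midplane, Å
    leaflet_offset: float = 17.5  # midplane → phosphorus-plane distance
    lipids_per_leaflet: int = 50
    protein_radius: float = 40.0
    lipid_ring_start: float = 4.0  # first lipid ring outside protein surface
    lipid_ring_spacing: float = 8.0
    n_waters: int = 40
    n_decoy_waters: int = 40
    md_water_fraction: float = 0.76  # share of waters also present in MD map
    seed: int = 0

    @property
    def ec_plane(self) -> float:
        return self.membrane_midplane - self.leaflet_offset  # ≈ 22

    @property
    def ic_plane(self) -> float:
        return self.membrane_midplane + self.leaflet_offset  # ≈ 57


@dataclass
class OrderSpec:
    """Chain model of one leaflet: tilt distribution and dihedral disorder."""

    tilt_sd_deg: float = 5.0
    gauche_prob: float = 0.0  # probability a C–H sample is isotropic
    xy_jitter: float = 0.3  # per-frame head-group jitter, Å

    @property
    def planted_scd(self) -> float:
        """Closed-form expected S_CD of this chain model.

        C–H vectors are perpendicular to a chain director tilted by
        α ~ N(0, σ) from z, with uniform azimuth, except a ``gauche_prob``
        fraction drawn isotropically (contributing 0).  Then
        ⟨cos²θ⟩ = E[sin²α]/2 with E[sin²α] = (1 − e^{−2σ²})/2.
        """
        s = math.radians(self.tilt_sd_deg)
        e_sin2 = (1.0 - math.exp(-2.0 * s * s)) / 2.0
        s_trans = -(3.0 * e_sin2 / 2.0 - 1.0) / 2.0
        return (1.0 - self.gauche_prob) * s_trans


ORDERED_EC = OrderSpec(tilt_sd_deg=5.0, gauche_prob=0.0)
DISORDERED_IC = OrderSpec(tilt_sd_deg=30.0, gauche_prob=0.45)


@dataclass
class KineticSpec:
    """Markov switching of kinetic lipids between rod-pair configurations."""

    states: list[tuple[int, int]]  # (SN1 rod index, SN2 rod index), 1-based
    transition: np.ndarray  # row-stochastic
    dt_ns: float = 0.1
    n_kinetic_per_subunit: int = 1

    def __post_init__(self) -> None:
        self.transition = np.asarray(self.transition, dtype=float)
        if not np.allclose(self.transition.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition matrix rows must sum to 1")

    @classmethod
    def two_state(
        cls,
        mean_dwell_ns: float = 2.0,
        dt_ns: float = 0.1,
        states=((1, 2), (1, 5)),
    ) -> "KineticSpec":
        p = dt_ns / mean_dwell_ns
        t = np.array([[1 - p, p], [p, 1 - p]])
        return cls(states=list(states), transition=t, dt_ns=dt_ns)

    @property
    def planted_mean_dwell_ns(self) -> np.ndarray:
        stay = np.diag(self.transition)
        return self.dt_ns / (1.0 - stay)


def sample_markov_series(
    kinetics: KineticSpec, n_series: int, n_frames: int, seed: int = 0
):
    """Draw per-lipid state label series directly from the Markov model.

    Produces :class:`junctlipid.states.StateSeries` objects (all frames
    in range), for statistical tests of dwell/transition estimators at
    scales where posing full geometry would be wasteful.
    """
    from .states import StateSeries

    rng = np.random.default_rng(seed)
    n_states = len(kinetics.states)
    out = []
    for s in range(n_series):
        path = np.empty(n_frames, dtype=int)
        path[0] = rng.integers(n_states)
        for f in range(1, n_frames):
            path[f] = rng.choice(n_states, p=kinetics.transition[path[f - 1]])
        labels = ["{}–{}".format(*kinetics.states[k]) for k in path]
        out.append(
            StateSeries(
                lipid=("M", s + 1),
                labels=labels,
                in_range=np.ones(n_frames, dtype=bool),
                dt_ns=kinetics.dt_ns,
            )
        )
    return out


def rod_lattice(spec: JunctionSpec) -> dict[tuple[int, int], np.ndarray]:
    """(subunit, rod index) → xy site of each of the 19 rods per sector.

    Rows of 5/4/4/3/3 sites at increasing radius, placed with angular
    margins so no rod touches a 30° sector boundary.  Rod numbering is by
    increasing radius then azimuth, matching the deterministic catalogue
    numbering.
    """
    rows = [(4.0, 5), (8.0, 4), (12.0, 4), (16.0, 3), (20.0, 3)]
    sites: dict[tuple[int, int], np.ndarray] = {}
    for s in range(1, spec.n_subunits + 1):
        a0 = (s - 1) * (np.pi / 6)
        idx = 1
        for dr, count in rows:
            r = spec.protein_radius + dr
            margin = np.pi / 6 * 0.1
            angles = a0 + np.linspace(
                margin, np.pi / 6 - margin, count
            )
            for a in angles:
                sites[(s, idx)] = np.array([r * np.cos(a), r * np.sin(a)])
                idx += 1
    return sites


ROD_Z_RANGE = (24.0, 36.0)  # acyl rod extent in the upper EC leaflet


@dataclass
class SystemTruth:
    spec: JunctionSpec
    leaflet_of: dict  # lipid key → (membrane, leaflet)
    lipid_sites: dict  # lipid key → fixed head xy
    protein_indices: np.ndarray
    water_truth: list  # dicts: key, position, has_partners, has_density, md_present
    rod_sites: dict


@dataclass
class SystemBundle:
    structure: Structure
    topology: LipidTopology
    truth: SystemTruth


LEAFLET_CHAINS = {  # chain id per leaflet
    (1, "EC"): "A",
    (1, "IC"): "B",
    (2, "EC"): "C",
    (2, "IC"): "D",
}


def generate_system(spec: JunctionSpec | None = None) -> SystemBundle:
    """Build the static junction system: protein, four leaflets, waters."""
    spec = spec or JunctionSpec()
    rng = np.random.default_rng(spec.seed)
    topo = default_lipid_topology()
    atoms: list[AtomRecord] = []

    # pseudo-protein: wedges of atoms on the cylinder surface
    protein_indices = []
    z_levels = np.arange(-60.0, 60.1, 4.0)
    for s in range(spec.n_subunits):
        for da in (0.3, 0.7):
            a = (s + da) * (np.pi / 6)
            for r_frac in (0.6, 1.0):
                r = spec.protein_radius * r_frac
                x, y = r * np.cos(a), r * np.sin(a)
                for z in z_levels:
                    protein_indices.append(len(atoms))
                    atoms.append(
                        AtomRecord(
                            atom_name="CA",
                            element="C",
                            residue_name="GLY",
                            residue_id=len(protein_indices),
                            chain_id="P",
                            position=(x, y, z),
                        )
                    )

    # lipid head sites: rings around the protein, identical in each leaflet
    n = spec.lipids_per_leaflet
    sites = []
    ring_r = spec.protein_radius + spec.lipid_ring_start
    while len(sites) < n:
        count = max(int(2 * np.pi * ring_r / 9.0), 1)  # ~9 Å spacing
        angles = np.linspace(0, 2 * np.pi, count, endpoint=False)
        angles += rng.uniform(0, 2 * np.pi / count)
        for a in angles:
            sites.append((ring_r * np.cos(a), ring_r * np.sin(a)))
        ring_r += spec.lipid_ring_spacing
    sites = sites[:n]

    leaflet_of = {}
    lipid_sites = {}
    leaflets = [
        (1, "EC", spec.ec_plane, +1.0),
        (1, "IC", spec.ic_plane, -1.0),
        (2, "EC", -spec.ec_plane, -1.0),
        (2, "IC", -spec.ic_plane, +1.0),
    ]
    for membrane, leaflet, z_plane, _ in leaflets:
        chain_id = LEAFLET_CHAINS[(membrane, leaflet)]
        for resid, (x, y) in enumerate(sites, start=1):
            key = (chain_id, resid)
            leaflet_of[key] = (membrane, leaflet)
            lipid_sites[key] = np.array([x, y])
            _append_lipid_atoms(atoms, topo, chain_id, resid, x, y, z_plane)

    # waters on a coarse grid in the gap, with planted partners / decoys
    water_truth = _place_waters(spec, rng, atoms)

    structure = Structure(atoms=atoms, box=np.array([220.0, 220.0, 160.0]))
    truth = SystemTruth(
        spec=spec,
        leaflet_of=leaflet_of,
        lipid_sites=lipid_sites,
        protein_indices=np.array(protein_indices),
        water_truth=water_truth,
        rod_sites=rod_lattice(spec),
    )
    return SystemBundle(structure=structure, topology=topo, truth=truth)


def _append_lipid_atoms(
    atoms: list[AtomRecord],
    topo: LipidTopology,
    chain_id: str,
    resid: int,
    x: float,
    y: float,
    z_plane: float,
) -> None:
    """Placeholder (untilted) pose; frames re-pose every lipid atom."""

    def add(name, element, pos):
        atoms.append(
            AtomRecord(
                atom_name=name,
                element=element,
                residue_name=topo.residue_name,
                residue_id=resid,
                chain_id=chain_id,
                position=tuple(pos),
                is_hetero=True,
            )
        )

    interior = 1.0 if abs(z_plane) < 40 else -1.0
    interior *= np.sign(z_plane)
    add("P", "P", (x, y, z_plane))
    for chain, x_off in (("SN1", -CHAIN_XY_OFFSET), ("SN2", CHAIN_XY_OFFSET)):
        for k, cname in enumerate(topo.chain_carbons(chain), start=1):
            z = z_plane + interior * (HEAD_TO_C1 + CC_RISE * (k - 1))
            add(cname, "C", (x + x_off, y, z))
            for hname in topo.ch_hydrogens.get(cname, []):
                add(hname, "H", (x + x_off + CH_LENGTH, y, z))


def _place_waters(
    spec: JunctionSpec, rng: np.random.Generator, atoms: list[AtomRecord]
) -> list[dict]:
    grid = []
    for z in np.arange(-14.0, 14.1, 7.0):
        for x in np.arange(-28.0, 28.1, 7.0):
            for y in np.arange(-28.0, 28.1, 7.0):
                if np.hypot(x, y) < spec.protein_radius - 8.0:
                    grid.append(np.array([x, y, z]))
    rng.shuffle(grid)
    n_total = spec.n_waters + spec.n_decoy_waters
    if n_total > len(grid):
        raise ValueError("too many waters for the placement grid")
    n_md = int(round(spec.md_water_fraction * spec.n_waters))
    truth = []
    partner_serial = 1
    for w in range(n_total):
        pos = grid[w]
        is_decoy = w >= spec.n_waters
        has_partners = not is_decoy
        md_present = (not is_decoy) and (w < n_md)
        resid = w + 1
        atoms.append(
            AtomRecord(
                atom_name="O",
                element="O",
                residue_name="HOH",
                residue_id=resid,
                chain_id="W",
                position=tuple(pos),
                is_hetero=True,
            )
        )
        if has_partners:
            # two O partners at 2.8 and 3.0 Å — passes the < 4 Å, ≥ 2 rule
            for d, direction in ((2.8, (1.0, 0, 0)), (3.0, (0, 1.0, 0))):
                atoms.append(
                    AtomRecord(
                        atom_name="OP",
                        element="O",
                        residue_name="PTN",
                        residue_id=partner_serial,
                        chain_id="Q",
                        position=tuple(pos + d * np.array(direction)),
                        is_hetero=True,
                    )
                )
                partner_serial += 1
        truth.append(
            {
                "key": ("W", resid),
                "position": pos,
                "has_partners": has_partners,
                "has_density": not is_decoy,
                "md_present": md_present,
            }
        )
    return truth


@dataclass
class TrajectoryTruth:
    scd_ec: float  # planted S_CD expectation, EC leaflets
    scd_ic: float
    kinetic_lipids: list  # lipid keys under Markov control
    state_series: dict  # lipid key → list of "i–j" truth labels (lattice indices)
    kinetics: KineticSpec | None


def generate_trajectory(
    bundle: SystemBundle,
    order_ec: OrderSpec = ORDERED_EC,
    order_ic: OrderSpec = DISORDERED_IC,
    kinetics: KineticSpec | None = None,
    n_frames: int = 100,
    seed: int = 0,
) -> tuple[Trajectory, TrajectoryTruth]:
    """Pose every lipid in every frame; optionally drive rod-hopping lipids.

    EC lipids follow ``order_ec`` (gel-like by default), IC lipids
    ``order_ic`` (fluid by default).  If ``kinetics`` is given, the first
    ``n_kinetic_per_subunit`` lipids of the upper EC leaflet are re-posed
    each frame with SN1/SN2 chains standing on the rod sites of their
    subunit's planted configurational state.
    """
    rng = np.random.default_rng(seed)
    spec = bundle.truth.spec
    topo = bundle.topology
    structure = bundle.structure
    base = structure.coords

    # per-lipid atom index blocks
    from .order import find_lipids

    lipids = {l.key: l for l in find_lipids(structure, topo)}

    kinetic_keys = []
    chains_markov: dict = {}
    if kinetics is not None:
        ec_keys = [
            k
            for k, lab in bundle.truth.leaflet_of.items()
            if lab == (1, "EC")
        ]
        # choose lipids spread across subunits; one per subunit by default
        per_sub: dict[int, list] = {}
        for k in ec_keys:
            xy = bundle.truth.lipid_sites[k]
            az = math.atan2(xy[1], xy[0]) % (2 * np.pi)
            per_sub.setdefault(int(az // (np.pi / 6)) + 1, []).append(k)
        for s in sorted(per_sub):
            kinetic_keys.extend(
                sorted(per_sub[s])[: kinetics.n_kinetic_per_subunit]
            )
        n_states = len(kinetics.states)
        for k in kinetic_keys:
            path = np.empty(n_frames, dtype=int)
            path[0] = rng.integers(n_states)
            for f in range(1, n_frames):
                path[f] = rng.choice(n_states, p=kinetics.transition[path[f - 1]])
            chains_markov[k] = path

    frames = []
    for fi in range(n_frames):
        coords = base.copy()
        for key, lipid in lipids.items():
            membrane, leaflet = bundle.truth.leaflet_of[key]
            if key in chains_markov:
                _pose_kinetic(
                    coords,
                    lipid,
                    topo,
                    bundle.truth,
                    kinetics.states[chains_markov[key][fi]],
                    rng,
                )
                continue
            ospec = order_ec if leaflet == "EC" else order_ic
            z_plane = {
                (1, "EC"): spec.ec_plane,
                (1, "IC"): spec.ic_plane,
                (2, "EC"): -spec.ec_plane,
                (2, "IC"): -spec.ic_plane,
            }[(membrane, leaflet)]
            midplane = spec.membrane_midplane * np.sign(z_plane)
            interior = float(np.sign(midplane - z_plane))
            _pose_lipid(
                coords,
                lipid,
                topo,
                bundle.truth.lipid_sites[key],
                z_plane,
                interior,
                ospec,
                rng,
            )
        frames.append(coords)

    # truth state labels in lattice numbering within the lipid's subunit
    state_series = {}
    for k in kinetic_keys:
        xy = bundle.truth.lipid_sites[k]
        labels = [
            "{}–{}".format(*kinetics.states[s]) for s in chains_markov[k]
        ]
        state_series[k] = labels

    truth = TrajectoryTruth(
        scd_ec=order_ec.planted_scd,
        scd_ic=order_ic.planted_scd,
        kinetic_lipids=kinetic_keys,
        state_series=state_series,
        kinetics=kinetics,
    )
    dt = kinetics.dt_ns if kinetics is not None else 0.1
    return Trajectory(topology=structure, frames=frames, dt_ns=dt), truth


def _sample_perp_dirs(
    d: np.ndarray, n: int, gauche_prob: float, rng: np.random.Generator
) -> np.ndarray:
    """n C–H unit vectors: perpendicular to director d, or isotropic."""
    # orthonormal frame around d
    ref = np.array([1.0, 0.0, 0.0])
    if abs(d @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(d, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    phi = rng.uniform(0, 2 * np.pi, size=n)
    dirs = np.outer(np.cos(phi), e1) + np.outer(np.sin(phi), e2)
    if gauche_prob > 0:
        iso_mask = rng.random(n) < gauche_prob
        n_iso = int(iso_mask.sum())
        if n_iso:
            v = rng.normal(size=(n_iso, 3))
            v /= np.linalg.norm(v, axis=1, keepdims=True)
            dirs[iso_mask] = v
    return dirs


def _pose_lipid(
    coords: np.ndarray,
    lipid,
    topo: LipidTopology,
    site_xy: np.ndarray,
    z_plane: float,
    interior: float,
    ospec: OrderSpec,
    rng: np.random.Generator,
) -> None:
    tilt = abs(rng.normal(0.0, math.radians(ospec.tilt_sd_deg)))
    azim = rng.uniform(0, 2 * np.pi)
    d = np.array(
        [
            math.sin(tilt) * math.cos(azim),
            math.sin(tilt) * math.sin(azim),
            interior * math.cos(tilt),
        ]
    )
    head = np.array(
        [
            site_xy[0] + rng.normal(0, ospec.xy_jitter),
            site_xy[1] + rng.normal(0, ospec.xy_jitter),
            z_plane,
        ]
    )
    coords[lipid.index_of(topo.headgroup_phosphorus)] = head
    for chain, x_off in (("SN1", -CHAIN_XY_OFFSET), ("SN2", CHAIN_XY_OFFSET)):
        start = head + np.array([x_off, 0.0, 0.0])
        for k, cname in enumerate(topo.chain_carbons(chain), start=1):
            cpos = start + d * (HEAD_TO_C1 + CC_RISE * (k - 1))
            coords[lipid.index_of(cname)] = cpos
            hnames = topo.ch_hydrogens.get(cname, [])
            if hnames:
                dirs = _sample_perp_dirs(d, len(hnames), ospec.gauche_prob, rng)
                for hname, u in zip(hnames, dirs):
                    coords[lipid.index_of(hname)] = cpos + CH_LENGTH * u

def _pose_kinetic(
    coords: np.ndarray,
    lipid,
    topo: LipidTopology,
    truth: SystemTruth,
    state: tuple[int, int],
    rng: np.random.Generator,
) -> None:
    """Stand SN1/SN2 vertically on the rod sites of the planted state."""
    xy = truth.lipid_sites[lipid.key]
    az = math.atan2(xy[1], xy[0]) % (2 * np.pi)
    subunit = int(az // (np.pi / 6)) + 1
    i, j = state
    z0 = ROD_Z_RANGE[0]
    head_xy = (truth.rod_sites[(subunit, i)] + truth.rod_sites[(subunit, j)]) / 2
    coords[lipid.index_of(topo.headgroup_phosphorus)] = np.array(
        [head_xy[0], head_xy[1], z0 - 2.0]
    )
    for chain, rod_idx in (("SN1", i), ("SN2", j)):
        sxy = truth.rod_sites[(subunit, rod_idx)]
        for k, cname in enumerate(topo.chain_carbons(chain), start=1):
            jit = rng.normal(0, 0.1, size=2)
            cpos = np.array(
                [sxy[0] + jit[0], sxy[1] + jit[1], z0 + 1.0 + CC_RISE * (k - 1)]
            )
            coords[lipid.index_of(cname)] = cpos
            for n_h, hname in enumerate(topo.ch_hydrogens.get(cname, [])):
                ang = rng.uniform(0, 2 * np.pi)
                coords[lipid.index_of(hname)] = cpos + CH_LENGTH * np.array(
                    [math.cos(ang), math.sin(ang), 0.0]
                )


def generate_rod_map(
    spec: JunctionSpec | None = None,
    voxel_size: float = 0.8,
    amplitude: float = 50.0,
    rod_sigma: float = 0.9,
    seed: int = 0,
    noise_sd: float = 0.0,
) -> DensityMap:
    """Synthetic EC-leaflet acyl density: one Gaussian rod per lattice site.

    Each rod is a dense column of Gaussians spanning ROD_Z_RANGE; with the
    default amplitude the rod cores contour well above 8σ of the
    (mostly empty) grid while staying disconnected from their neighbours.
    """
    spec = spec or JunctionSpec()
    sites = rod_lattice(spec)
    # the grid spans the full reconstruction box, not just the rod annulus,
    # so full-grid σ statistics resemble a real map's
    r_max = spec.protein_radius + 50.0
    lower = np.array([-r_max, -r_max, ROD_Z_RANGE[0] - 9.0])
    upper = np.array([r_max, r_max, ROD_Z_RANGE[1] + 9.0])
    shape = np.ceil((upper - lower) / voxel_size).astype(int)
    grid = np.zeros(shape)
    zs = np.arange(ROD_Z_RANGE[0], ROD_Z_RANGE[1] + 1e-9, 0.5)
    xi = lower[0] + voxel_size * np.arange(shape[0])
    yi = lower[1] + voxel_size * np.arange(shape[1])
    zi = lower[2] + voxel_size * np.arange(shape[2])
    for (s, idx), xy in sites.items():
        sel_x = np.abs(xi - xy[0]) < 4 * rod_sigma
        sel_y = np.abs(yi - xy[1]) < 4 * rod_sigma
        if not sel_x.any() or not sel_y.any():
            continue
        gx = np.exp(-((xi[sel_x] - xy[0]) ** 2) / (2 * rod_sigma**2))
        gy = np.exp(-((yi[sel_y] - xy[1]) ** 2) / (2 * rod_sigma**2))
        gz = np.zeros(shape[2])
        for z in zs:
            gz += np.exp(-((zi - z) ** 2) / (2 * rod_sigma**2))
        block = (
            amplitude
            * gx[:, None, None]
            * gy[None, :, None]
            * gz[None, None, :]
        )
        ix = np.where(sel_x)[0]
        iy = np.where(sel_y)[0]
        grid[np.ix_(ix, iy, np.arange(shape[2]))] += block
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        grid += rng.normal(0, noise_sd, size=grid.shape)
    return DensityMap(grid=grid, voxel_size=voxel_size, origin=lower)


def generate_water_maps(
    bundle: SystemBundle,
    voxel_size: float = 1.0,
    peak_sigma: float = 0.8,
    peak_amplitude: float = 10.0,
    noise_ratio: float = 0.125,
    seed: int = 0,
) -> dict[str, DensityMap]:
    """Full map, two noised half-maps, and the MD water map.

    Peaks are planted at every non-decoy water (full/half maps) and at the
    MD-co-present subset (MD map).  Half-map noise sd is ``noise_ratio`` ×
    the peak height, so planted peaks sit far above the 2.5σ contour while
    decoys stay in the noise floor.
    """
    rng = np.random.default_rng(seed)
    spec = bundle.truth.spec
    r = spec.protein_radius
    lower = np.array([-r, -r, -20.0])
    upper = np.array([r, r, 20.0])
    shape = np.ceil((upper - lower) / voxel_size).astype(int)

    def peak_map(positions) -> np.ndarray:
        grid = np.zeros(shape)
        axes = [lower[d] + voxel_size * np.arange(shape[d]) for d in range(3)]
        for p in positions:
            g1 = [
                np.exp(-((axes[d] - p[d]) ** 2) / (2 * peak_sigma**2))
                for d in range(3)
            ]
            grid += (
                peak_amplitude
                * g1[0][:, None, None]
                * g1[1][None, :, None]
                * g1[2][None, None, :]
            )
        return grid

    true_pos = [w["position"] for w in bundle.truth.water_truth if w["has_density"]]
    md_pos = [w["position"] for w in bundle.truth.water_truth if w["md_present"]]
    full = peak_map(true_pos)
    noise_sd = noise_ratio * peak_amplitude
    maps = {
        "full": DensityMap(grid=full, voxel_size=voxel_size, origin=lower),
        "half1": DensityMap(
            grid=full + rng.normal(0, noise_sd, size=shape),
            voxel_size=voxel_size,
            origin=lower,
        ),
        "half2": DensityMap(
            grid=full + rng.normal(0, noise_sd, size=shape),
            voxel_size=voxel_size,
            origin=lower,
        ),
        "md": DensityMap(
            grid=peak_map(md_pos), voxel_size=voxel_size, origin=lower
        ),
    }
    return maps


def ordered_ec_fixture(
    lipids_per_leaflet: int = 50,
    n_frames: int = 100,
    seed: int = 7,
) -> tuple[SystemBundle, Trajectory, TrajectoryTruth]:
    """The gel-phase reference fixture: ordered EC leaflets, fluid IC.

    With the default 50 lipids per leaflet the system carries 200 lipids;
    EC chains are all-trans with a 5° Gaussian tilt.
    """
    spec = JunctionSpec(lipids_per_leaflet=lipids_per_leaflet, seed=seed)
    bundle = generate_system(spec)
    traj, truth = generate_trajectory(
        bundle,
        order_ec=ORDERED_EC,
        order_ic=DISORDERED_IC,
        n_frames=n_frames,
        seed=seed,
    )
    return bundle, traj, truth
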