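#!/usr/bin/env python
"""Generate the reference synthetic junction fixture used by every later stage.

Builds a 12-subunit pseudo-channel spanning two bilayers (phosphorus
planes near z = ±22 and ±57 Å), 48 two-chain lipids, Markov-switching
annular lipids, waters with planted hydrogen-bond partners plus decoys,
and the matching density maps.  Everything is seeded, and the planted
ground truth is serialized next to the coordinates.
"""

from pathlib import Path

import numpy as np
import yaml

from junctlipid import io, synth

OUT = Path("results/fixture")
SEED = 7


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    spec = synth.JunctionSpec(lipids_per_leaflet=12, seed=SEED)
    bundle = synth.generate_system(spec)
    kin = synth.KineticSpec.two_state(mean_dwell_ns=2.0)
    traj, truth = synth.generate_trajectory(
        bundle, kinetics=kin, n_frames=50, seed=SEED
    )

    io.write_structure(bundle.structure, OUT / "system.pdb")
    io.write_trajectory(traj, OUT / "trajectory.pdb")
    io.write_map(synth.generate_rod_map(spec, seed=SEED), OUT / "rods.mrc")
    for name, m in synth.generate_water_maps(bundle, seed=SEED).items():
        io.write_map(m, OUT / f"water_{name}.mrc")

    with open(OUT / "truth.yaml", "w") as fh:
        yaml.safe_dump(
            {
                "seed": SEED,
                "planted_scd_ec": float(truth.scd_ec),
                "planted_scd_ic": float(truth.scd_ic),
                "planted_mean_dwell_ns": [
                    float(x) for x in kin.planted_mean_dwell_ns
                ],
                "kinetic_lipids": [list(k) for k in truth.kinetic_lipids],
                "kinetic_state_series": {
                    f"{k[0]}:{k[1]}": v for k, v in truth.state_series.items()
                },
                "waters": [
                    {
                        "key": f"{w['key'][0]}:{w['key'][1]}",
                        "position": [float(x) for x in w["position"]],
                        "has_partners": bool(w["has_partners"]),
                        "has_density": bool(w["has_density"]),
                        "md_present": bool(w["md_present"]),
                    }
                    for w in bundle.truth.water_truth
                ],
            },
            fh,
        )

    pz = np.array(
        [
            a.position[2]
            for a in bundle.structure.atoms
            if a.atom_name == "P" and a.residue_name == "DMP"
        ]
    )
    print(f"system: {len(bundle.structure)} atoms, {traj.n_frames} frames")
    print(
        "phosphorus planes at z ≈ "
        f"{sorted({float(z) for z in np.round(pz, 0)})}"
    )
    print(
        f"planted S_CD: EC {truth.scd_ec:.3f} (gel-like), "
        f"IC {truth.scd_ic:.3f} (fluid)"
    )
    print(f"{len(truth.kinetic_lipids)} lipids under Markov rod-hopping control")
    print(f"fixture written to {OUT}/")


if __name__ == "__main__":
    main()
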