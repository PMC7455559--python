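#!/usr/bin/env python
"""Structure statistics: superposition RMSD, replicate RMSF with 95% CI,
and point-group expansion of an asymmetric unit.

Compares the fixture model against a rigidly moved, lightly perturbed
copy (the recovered RMSD equals the planted coordinate noise), computes
a per-site RMSF profile across 24 synthetic replicates (12 subunits × 2
runs) with a two-tailed Student-t confidence interval, and expands a
33-water asymmetric unit under D6 (expected 396 copies).
"""

from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from junctlipid import compare, io
from junctlipid.density import SymmetryGroup
from junctlipid.models import AtomRecord, Structure

FIX = Path("results/fixture")
OUT = Path("results")


def main() -> None:
    rng = np.random.default_rng(7)
    model = io.read_structure(FIX / "system.pdb")

    noise_sd = 0.1
    rot = Rotation.from_euler("xyz", [4.0, -7.0, 11.0], degrees=True)
    moved = Structure(
        atoms=[
            AtomRecord(
                a.atom_name, a.element, a.residue_name, a.residue_id,
                a.chain_id,
                tuple(
                    rot.apply(np.array(a.position))
                    + [3.0, -2.0, 5.0]
                    + rng.normal(0, noise_sd, 3)
                ),
                a.is_hetero,
            )
            for a in model.atoms
        ]
    )
    pairing = compare.pair_atoms(model, moved, subset="CA")
    rmsd, _, _ = compare.superpose_rmsd(model, moved, pairing)
    expected = noise_sd * np.sqrt(3)
    print(
        f"Cα r.m.s.d. to the perturbed copy: {rmsd:.3f} Å "
        f"over {len(pairing)} atoms (planted noise ⇒ ≈ {expected:.3f} Å)"
    )

    # 24 replicates: 12 subunits × 2 runs of a 20-site chain
    n_sites = 20
    base = rng.normal(0, 5, (n_sites, 3)).cumsum(axis=0)
    true_rmsf = np.linspace(0.4, 1.6, n_sites)
    reps = []
    for _ in range(24):
        frames = base + rng.normal(
            0, true_rmsf[:, None] / np.sqrt(3), (30, n_sites, 3)
        )
        reps.append(frames)
    profile = compare.rmsf_profile(reps)
    profile.to_csv(OUT / "rmsf_profile.tsv", sep="\t", index=False)
    corr = np.corrcoef(profile["rmsf_mean"], true_rmsf)[0, 1]
    width = (profile["ci_high"] - profile["ci_low"]).mean()
    print(
        f"r.m.s.f. profile over n = 24 replicates: correlation with the "
        f"planted mobility gradient {corr:.3f}, mean 95% CI width "
        f"{width:.3f} Å"
    )

    unit = Structure(
        atoms=[
            AtomRecord("O", "O", "HOH", i + 1, "W", tuple(p), True)
            for i, p in enumerate(rng.uniform(5, 30, (33, 3)))
        ]
    )
    expanded = compare.symmetry_expand(unit, SymmetryGroup.d6())
    print(
        f"D6 expansion: {len(unit)} waters per subunit → "
        f"{len(expanded)} in the full channel"
    )
    print(f"wrote {OUT / 'rmsf_profile.tsv'}")


if __name__ == "__main__":
    main()
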