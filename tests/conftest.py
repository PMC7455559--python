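"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from junctlipid import order, states, synth


@pytest.fixture(scope="session")
def small_bundle():
    """A small junction system: 12 lipids/leaflet, 20 waters + 20 decoys."""
    spec = synth.JunctionSpec(
        lipids_per_leaflet=12, n_waters=20, n_decoy_waters=20, seed=11
    )
    return synth.generate_system(spec)


@pytest.fixture(scope="session")
def small_traj(small_bundle):
    traj, truth = synth.generate_trajectory(
        small_bundle, n_frames=6, seed=11
    )
    return traj, truth


@pytest.fixture(scope="session")
def rod_map():
    """Default-spec synthetic EC rod map (19 rods × 12 subunits)."""
    return synth.generate_rod_map()


@pytest.fixture(scope="session")
def rod_catalogue(rod_map):
    return states.build_rod_catalogue(rod_map, sigma_min=8.0)


@pytest.fixture(scope="session")
def kinetic_setup():
    """System with Markov-switching lipids plus the matching rod map."""
    spec = synth.JunctionSpec(lipids_per_leaflet=30, seed=3)
    bundle = synth.generate_system(spec)
    kin = synth.KineticSpec.two_state(mean_dwell_ns=2.0)
    traj, truth = synth.generate_trajectory(
        bundle, kinetics=kin, n_frames=50, seed=3
    )
    dm = synth.generate_rod_map(spec)
    cat = states.build_rod_catalogue(dm, sigma_min=8.0)
    lipids = {l.key: l for l in order.find_lipids(bundle.structure, bundle.topology)}
    return bundle, traj, truth, dm, cat, lipids


@pytest.fixture(scope="session")
def water_maps(small_bundle):
    return synth.generate_water_maps(small_bundle, seed=11)


def strip_subunit(label: str) -> str:
    """'s4:1–s4:2' → '1–2' for comparison with lattice-numbered truth."""
    if ":" not in label:
        return label
    return "–".join(p.split(":")[-1] for p in label.split("–"))
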