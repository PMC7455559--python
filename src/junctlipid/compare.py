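"""Structure and trajectory statistics: superposition RMSD, RMSF, expansion.

Backbone here means N, CA, C, O (carbonyl); a Cα-only subset is available
for Cα r.m.s.d. comparisons.  Superposition uses the least-squares rigid
fit (Kabsch, via SVD with the proper-rotation correction).  Per-residue
r.m.s.f. values are averaged across replicates (e.g., 12 subunits × 2
production runs = 24) with a two-tailed Student-t 95% confidence interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .density import SymmetryGroup
from .models import AtomRecord, Structure, Trajectory

log = logging.getLogger(__name__)

BACKBONE_ATOMS = ("N", "CA", "C", "O")


@dataclass
class AtomPairing:
    pairs: list[tuple[int, int]]
    policy: str

    def __len__(self) -> int:
        return len(self.pairs)


def _subset_names(subset: str) -> tuple[str, ...]:
    if subset == "backbone":
        return BACKBONE_ATOMS
    if subset == "CA":
        return ("CA",)
    raise ValueError(f"unknown subset {subset!r} (use 'backbone' or 'CA')")


def _residue_key(a: AtomRecord) -> tuple[str, int, str]:
    return (a.chain_id, a.residue_id, a.atom_name)


def pair_atoms(a: Structure, b: Structure, subset: str = "backbone") -> AtomPairing:
    """One-to-one pairing of subset atoms shared by both models.

    Atoms are matched by (chain id, residue number, atom name); residues
    present in only one model (e.g., trimmed flexible domains) are simply
    excluded.  When no chain ids are shared, matching falls back to a
    sequence-position pairing of chains in order of appearance.
    """
    names = _subset_names(subset)
    map_a = {
        _residue_key(at): i
        for i, at in enumerate(a.atoms)
        if at.atom_name in names and not at.is_hetero
    }
    map_b = {
        _residue_key(at): i
        for i, at in enumerate(b.atoms)
        if at.atom_name in names and not at.is_hetero
    }
    shared = sorted(set(map_a) & set(map_b))
    policy = f"key-match subset={subset}"
    if not shared:
        # chain-id mismatch: map chains by order of appearance
        chains_a = list(dict.fromkeys(at.chain_id for at in a.atoms))
        chains_b = list(dict.fromkeys(at.chain_id for at in b.atoms))
        rename = dict(zip(chains_b, chains_a))
        map_b = {
            (rename.get(k[0], k[0]), k[1], k[2]): v for k, v in map_b.items()
        }
        shared = sorted(set(map_a) & set(map_b))
        policy = f"chain-order fallback subset={subset}"
        log.info("pair_atoms: %s", policy)
    if not shared:
        raise ValueError("no atoms could be paired between the two models")
    return AtomPairing(
        pairs=[(map_a[k], map_b[k]) for k in shared], policy=policy
    )


def kabsch(p: np.ndarray, q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal proper rotation R and translation t minimizing |R·p + t − q|²."""
    pc, qc = p.mean(axis=0), q.mean(axis=0)
    h = (p - pc).T @ (q - qc)
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return rot, qc - rot @ pc


def superpose_rmsd(
    a: Structure, b: Structure, pairing: AtomPairing
) -> tuple[float, np.ndarray, np.ndarray]:
    """Least-squares rigid superposition; returns (rmsd Å, rotation, translation)."""
    if len(pairing) < 3:
        raise ValueError("need ≥3 atom pairs for superposition")
    ca, cb = a.coords, b.coords
    p = np.array([ca[i] for i, _ in pairing.pairs])
    q = np.array([cb[j] for _, j in pairing.pairs])
    if np.linalg.matrix_rank(p - p.mean(axis=0), tol=1e-8) < 2:
        raise ValueError("paired atoms are collinear; superposition is degenerate")
    rot, t = kabsch(p, q)
    moved = p @ rot.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - q) ** 2, axis=1))))
    return rmsd, rot, t


def _superpose_frames(frames: np.ndarray) -> np.ndarray:
    """Iteratively superpose frames onto their time-average."""
    out = frames.copy()
    ref = out[0]
    for _ in range(3):
        for k in range(out.shape[0]):
            rot, t = kabsch(out[k], ref)
            out[k] = out[k] @ rot.T + t
        ref = out.mean(axis=0)
    return out


def rmsf_profile(
    replicate_frames: list[np.ndarray],
    confidence: float = 0.95,
) -> pd.DataFrame:
    """Per-site r.m.s.f. with a Student-t confidence interval across replicates.

    Parameters
    ----------
    replicate_frames
        One (n_frames, n_sites, 3) array per replicate (e.g., the Cα atoms
        of one subunit over one production run; 12 subunits × 2 runs give
        n = 24 replicate values per site).

    Each replicate is internally superposed onto its own time-average
    before fluctuations √⟨|x − ⟨x⟩|²⟩ are computed.
    """
    values = []
    for frames in replicate_frames:
        frames = _superpose_frames(np.asarray(frames, dtype=float))
        mean_pos = frames.mean(axis=0)
        rmsf = np.sqrt(np.mean(np.sum((frames - mean_pos) ** 2, axis=2), axis=0))
        values.append(rmsf)
    vals = np.array(values)  # (n_replicates, n_sites)
    n = vals.shape[0]
    mean = vals.mean(axis=0)
    if n >= 2:
        sd = vals.std(axis=0, ddof=1)
        tq = stats.t.ppf(0.5 + confidence / 2.0, df=n - 1)
        half = tq * sd / np.sqrt(n)
    else:
        sd = np.full_like(mean, np.nan)
        half = np.full_like(mean, np.nan)
        log.warning("rmsf_profile: single replicate, CI undefined")
    return pd.DataFrame(
        {
            "site": np.arange(mean.size),
            "rmsf_mean": mean,
            "rmsf_sd": sd,
            "n": n,
            "ci_low": mean - half,
            "ci_high": mean + half,
        }
    )


def symmetry_expand(asym: Structure, group: SymmetryGroup) -> Structure:
    """Replicate an asymmetric unit under every group rotation.

    The output has input × group-order atoms; chain ids are suffixed with
    the 1-based operation number.  No clash checking is performed.
    """
    coords = asym.coords
    atoms: list[AtomRecord] = []
    for k in range(group.order):
        moved = group.apply(coords, k)
        for a, pos in zip(asym.atoms, moved):
            atoms.append(
                AtomRecord(
                    atom_name=a.atom_name,
                    element=a.element,
                    residue_name=a.residue_name,
                    residue_id=a.residue_id,
                    chain_id=f"{a.chain_id}{k + 1}",
                    position=tuple(pos),
                    is_hetero=a.is_hetero,
                )
            )
    return Structure(atoms=atoms, box=None if asym.box is None else asym.box.copy())
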