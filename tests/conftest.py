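"""Shared fixtures and independent brute-force oracles.

The oracles here are deliberately naive (double loops, 27-image searches,
dense distance matrices, boolean transitive closure) and independent of the
implementation paths they validate.
"""

from __future__ import annotations

import numpy as np
import pytest

from memborient.traj_model import Atom, Frame, Topology, Trajectory


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------

def brute_inertia(coords: np.ndarray, masses: np.ndarray) -> np.ndarray:
    """Element-wise double-loop evaluation of the inertia tensor about the COM."""
    com = np.zeros(3)
    for m, r in zip(masses, coords):
        com += m * r
    com /= masses.sum()
    I = np.zeros((3, 3))
    eye = np.eye(3)
    for m, r in zip(masses, coords):
        d = r - com
        for j in range(3):
            for k in range(3):
                I[j, k] += m * ((d @ d) * eye[j, k] - d[j] * d[k])
    return I


_IMAGE_SHIFTS = np.array(
    [[i, j, k] for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)], dtype=float
)


def brute_min_image(r1: np.ndarray, r2: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Minimum displacement r1−r2 over all 27 periodic image translates."""
    cands = r1 - (r2 + _IMAGE_SHIFTS * box)
    return cands[np.argmin(np.einsum("ij,ij->i", cands, cands))]


def brute_pair_distances(a: np.ndarray, b: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    """Dense (len(a), len(b)) minimum-image distance matrix."""
    d = a[:, None, :] - b[None, :, :]
    if box is not None:
        d = d - box * np.round(d / box)
    return np.sqrt(np.einsum("ijk,ijk->ij", d, d))


def brute_components(edges, n: int) -> list[set]:
    """Connected components via boolean transitive closure."""
    adj = np.eye(n, dtype=bool)
    for i, j in edges:
        adj[i, j] = adj[j, i] = True
    prev = np.zeros_like(adj)
    while not np.array_equal(adj, prev):
        prev = adj.copy()
        adj = adj | (adj @ adj)
    comps, seen = [], set()
    for i in range(n):
        if i in seen:
            continue
        comp = set(np.flatnonzero(adj[i]).tolist())
        seen |= comp
        comps.append(comp)
    return comps


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def trimer_topology():
    """Three chains A/B/C with Cα atoms for residues 140–200 each."""
    atoms = []
    for seg in "ABC":
        for resid in range(140, 201):
            atoms.append(
                Atom(
                    index=len(atoms),
                    name="CA",
                    residue_name="ALA",
                    residue_id=resid,
                    segment_id=seg,
                    mass=12.011,
                )
            )
    return Topology(atoms)


def make_point_topology(n: int, resname: str = "PNT", name: str = "X") -> Topology:
    return Topology(
        [
            Atom(index=i, name=name, residue_name=resname, residue_id=i + 1,
                 segment_id="A", mass=1.0)
            for i in range(n)
        ]
    )


def single_frame_traj(coords: np.ndarray, box=None, topology: Topology | None = None) -> Trajectory:
    top = topology or make_point_topology(len(coords))
    return Trajectory(top, [Frame(coordinates=coords, box=None if box is None else np.asarray(box, float))])
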