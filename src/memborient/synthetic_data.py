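"""Ground-truth scene and trajectory generators.

Every analysis in this package is validated end-to-end against scenes whose
truth is known by construction: a rigid body on a programmed Tait-Bryan
schedule, ideal tilted helices, a planar-bilayer surrogate carrying
phosphorus-like and nitrogen-like marker sites, and multi-copy scenes with
planted oligomer clusters. Generators are fully deterministic under a fixed
seed and write standard GRO/XTC files that the readers accept unchanged,
plus ground-truth CSV sidecars.

The noise model is isotropic Gaussian per particle per frame, independent
across frames — a stand-in chosen for analyzable estimator bias, not a
physical model of thermal motion.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .orientation import (
    STANDARD_BASIS,
    compute_inertia_tensor,
    principal_axes,
    rotation_zyx,
)
from .traj_model import (
    Atom,
    Frame,
    Selection,
    Topology,
    Trajectory,
    write_structure,
    write_trajectory,
)

__all__ = [
    "copy_selections",
    "make_rigid_body",
    "make_ideal_helix",
    "make_ideal_alpha_helix_backbone",
    "make_bilayer_surrogate",
    "make_multicopy_scene",
    "make_two_domain_scene",
    "render_scene",
    "PLASMA_MEMBRANE_COMPOSITION",
]

# mammalian plasma-membrane surrogate composition (relative counts per leaflet)
PLASMA_MEMBRANE_COMPOSITION = {
    "upper": {"POPC": 40, "POPE": 10, "Sph": 15, "GM3": 10, "CHOL": 25},
    "lower": {"POPC": 10, "POPE": 40, "POPS": 15, "PIP2": 10, "CHOL": 25},
}

PHOSPHATE_TYPES = {"POPC", "POPE", "POPS", "PIP2", "Sph"}


# ---------------------------------------------------------------------------
# Rigid body on a programmed orientation schedule
# ---------------------------------------------------------------------------

def make_rigid_body(
    schedule: pd.DataFrame | dict,
    n_particles: int = 500,
    half_axes: tuple = (3.0, 1.5, 0.8),
    box: tuple = (20.0, 20.0, 20.0),
    noise_sigma: float = 0.0,
    frame_stride_ps: float = 100.0,
    seed: int = 0,
    center: tuple | None = None,
) -> tuple[Topology, Trajectory, pd.DataFrame]:
    """Anisotropic rigid body rotated per-frame by a Tait-Bryan schedule.

    ``schedule`` holds per-frame ``yaw``/``pitch``/``roll`` columns in
    degrees. The base body is sampled once (Gaussian cloud with distinct
    spreads ``half_axes`` in nm, masses ~U[10, 16] amu) and pre-rotated
    into its own principal frame, so at frame t the body's principal axes
    are exactly Rz(yaw_t)·Ry(pitch_t)·Rx(roll_t) applied to the standard
    basis — the schedule *is* the ground truth the orientation analysis
    must recover. Optional isotropic Gaussian noise (``noise_sigma`` nm)
    is added per particle per frame.

    Returns (topology, trajectory, schedule-with-time sidecar).
    """
    sched = pd.DataFrame(schedule).reset_index(drop=True)
    for col in ("yaw", "pitch", "roll"):
        if col not in sched:
            sched[col] = 0.0
    n_frames = len(sched)
    if n_frames < 1:
        raise ValueError("schedule must contain at least one frame")
    sx, sy, sz = half_axes
    if len({round(s, 9) for s in half_axes}) < 3:
        raise ValueError("half_axes must be pairwise distinct (anisotropic body)")
    rng = np.random.default_rng(seed)
    base = rng.normal(size=(n_particles, 3)) * np.array([sx, sy, sz])
    masses = rng.uniform(10.0, 16.0, size=n_particles)

    # rotate the sampled cloud into its own principal frame: afterwards its
    # principal axes coincide with e_x, e_y, e_z (long axis along e_x)
    tensor = compute_inertia_tensor(base, masses)
    axes = principal_axes(tensor, reference=STANDARD_BASIS)
    base = (base - tensor.center) @ axes.matrix
    moments = axes.moments
    rel_gaps = np.diff(moments) / moments[-1]
    if np.any(rel_gaps < 1e-3) and (sched[["yaw", "pitch", "roll"]].abs().values > 0).any():
        raise ValueError(
            "body is too isotropic for an orientation schedule (angles unobservable)"
        )

    center = (
        np.asarray(box, dtype=float) / 2.0 if center is None else np.asarray(center, float)
    )
    frames = []
    for t in range(n_frames):
        R = rotation_zyx(sched.at[t, "yaw"], sched.at[t, "pitch"], sched.at[t, "roll"])
        coords = base @ R.T + center
        if noise_sigma > 0:
            coords = coords + rng.normal(scale=noise_sigma, size=coords.shape)
        frames.append(
            Frame(coordinates=coords, box=np.asarray(box, float), time=t * frame_stride_ps)
        )
    atoms = [
        Atom(index=i, name="BD", residue_name="BOD", residue_id=1,
             segment_id="A", mass=float(masses[i]), is_bead=True)
        for i in range(n_particles)
    ]
    topology = Topology(atoms)
    sidecar = sched.copy()
    sidecar.insert(0, "time_ps", np.arange(n_frames) * frame_stride_ps)
    return topology, Trajectory(topology, frames, frame_stride_ps), sidecar


# ---------------------------------------------------------------------------
# Ideal helices
# ---------------------------------------------------------------------------

def make_ideal_helix(
    n_residues: int,
    tilt: float = 0.0,
    azimuth: float = 0.0,
    rise: float = 0.15,
    twist: float = 100.0,
    radius: float = 0.23,
    box: tuple = (10.0, 10.0, 10.0),
) -> tuple[Topology, Frame]:
    """Ideal Cα helix trace (0.15 nm rise, 100°/residue) tilted from +z.

    ``tilt`` is the angle between the helix axis and +z, ``azimuth`` the
    direction of the tilt in the xy plane. Tilt outside [0°, 90°] is
    rejected: tilt is an unsigned fold into that range by definition.
    """
    if n_residues < 8:
        raise ValueError("need at least 8 residues (two helical turns)")
    if not 0.0 <= tilt <= 90.0:
        raise ValueError("tilt must lie in [0, 90] degrees (unsigned fold convention)")
    i = np.arange(n_residues)
    ang = np.deg2rad(twist * i)
    coords = np.column_stack([radius * np.cos(ang), radius * np.sin(ang), rise * i])
    R = rotation_zyx(azimuth, tilt, 0.0)  # Rz(azimuth)·Ry(tilt)
    coords = coords @ R.T
    coords += np.asarray(box, float) / 2.0 - coords.mean(axis=0)
    atoms = [
        Atom(index=k, name="CA", residue_name="ALA", residue_id=k + 1,
             segment_id="A", mass=12.011)
        for k in range(n_residues)
    ]
    return Topology(atoms), Frame(coordinates=coords, box=np.asarray(box, float))


# canonical backbone internal coordinates (nm / degrees)
_BB = {
    "b_n_ca": 0.1458, "b_ca_c": 0.1525, "b_c_n": 0.1329,
    "a_n_ca_c": 111.2, "a_ca_c_n": 116.2, "a_c_n_ca": 121.7,
}


def _place_atom(a, b, c, bond, angle_deg, dihedral_deg):
    """NeRF placement of atom d given three predecessors and internal coords."""
    theta = np.deg2rad(angle_deg)
    chi = np.deg2rad(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [-bond * np.cos(theta), bond * np.sin(theta) * np.cos(chi), bond * np.sin(theta) * np.sin(chi)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def make_ideal_alpha_helix_backbone(
    n_residues: int,
    phi: float = -57.0,
    psi: float = -47.0,
    omega: float = 180.0,
    box: tuple = (10.0, 10.0, 10.0),
) -> tuple[Topology, Frame]:
    """Full N/Cα/C backbone of an ideal helix built from (φ, ψ, ω).

    Constructed atom-by-atom from canonical bond lengths and angles, so the
    backbone dihedral analysis must recover exactly the requested φ/ψ on
    interior residues — an independent geometric oracle.
    """
    if n_residues < 3:
        raise ValueError("need at least 3 residues")
    bb = _BB
    coords = [
        np.array([0.0, 0.0, 0.0]),                 # N1
        np.array([bb["b_n_ca"], 0.0, 0.0]),        # CA1
    ]
    theta = np.deg2rad(bb["a_n_ca_c"])
    coords.append(
        coords[1] + bb["b_ca_c"] * np.array([-np.cos(theta), np.sin(theta), 0.0])
    )  # C1
    for _ in range(1, n_residues):
        N, CA, C = coords[-3], coords[-2], coords[-1]
        Nn = _place_atom(N, CA, C, bb["b_c_n"], bb["a_ca_c_n"], psi)
        CAn = _place_atom(CA, C, Nn, bb["b_n_ca"], bb["a_c_n_ca"], omega)
        Cn = _place_atom(C, Nn, CAn, bb["b_ca_c"], bb["a_n_ca_c"], phi)
        coords.extend([Nn, CAn, Cn])
    coords = np.array(coords)
    coords += np.asarray(box, float) / 2.0 - coords.mean(axis=0)
    names = ["N", "CA", "C"] * n_residues
    atoms = [
        Atom(index=k, name=names[k], residue_name="ALA", residue_id=k // 3 + 1,
             segment_id="A", mass=14.007 if names[k] == "N" else 12.011)
        for k in range(3 * n_residues)
    ]
    return Topology(atoms), Frame(coordinates=coords, box=np.asarray(box, float))


# ---------------------------------------------------------------------------
# Bilayer surrogate
# ---------------------------------------------------------------------------

def make_bilayer_surrogate(
    box: tuple = (12.0, 12.0, 9.0),
    upper: dict | None = None,
    lower: dict | None = None,
    leaflet_offset: float = 2.0,
    jitter_sigma: float = 0.03,
    min_spacing: float = 0.5,
    seed: int = 0,
) -> tuple[Topology, Frame]:
    """Two planar leaflets of typed headgroup marker sites.

    Each lipid contributes one headgroup bead at ±``leaflet_offset`` from
    the box mid-plane, typed by residue name. Phosphate-bearing types
    (POPC/POPE/POPS/PIP2/Sph) name the bead ``P``; GM3 and CHOL use ``HG``.
    POPC additionally carries a nitrogen-like ``N`` site 0.1 nm further
    from the mid-plane, supporting glutamate↔choline distance analyses.
    Sites sit on a jittered square lattice; a leaflet whose lipid count
    exceeds the lattice capacity at ``min_spacing`` raises.
    """
    upper = dict(upper if upper is not None else PLASMA_MEMBRANE_COMPOSITION["upper"])
    lower = dict(lower if lower is not None else PLASMA_MEMBRANE_COMPOSITION["lower"])
    box = np.asarray(box, dtype=float)
    rng = np.random.default_rng(seed)
    zmid = box[2] / 2.0

    atoms: list[Atom] = []
    coords: list[np.ndarray] = []
    resid = 0

    for leaflet, comp, zsign in (("upper", upper, +1), ("lower", lower, -1)):
        total = int(sum(comp.values()))
        if total == 0:
            continue
        nx = int(np.floor(box[0] / min_spacing))
        ny = int(np.floor(box[1] / min_spacing))
        if total > nx * ny:
            raise ValueError(
                f"{leaflet} leaflet: {total} lipids exceed lattice capacity {nx * ny}"
            )
        side = int(np.ceil(np.sqrt(total)))
        dx, dy = box[0] / side, box[1] / side
        sites = [
            np.array([(ix + 0.5) * dx, (iy + 0.5) * dy])
            for iy in range(side) for ix in range(side)
        ][:total]
        order = rng.permutation(total)  # mix types over the lattice
        types = [t for t, n in comp.items() for _ in range(int(n))]
        z_head = zmid + zsign * leaflet_offset
        for site_i, type_i in enumerate(order):
            lt = types[type_i]
            resid += 1
            xy = sites[site_i] + rng.normal(scale=jitter_sigma, size=2)
            head_name = "P" if lt in PHOSPHATE_TYPES else "HG"
            atoms.append(
                Atom(index=len(atoms), name=head_name, residue_name=lt,
                     residue_id=resid, segment_id="MEMB", mass=94.97, is_bead=True)
            )
            coords.append(np.array([xy[0], xy[1], z_head + rng.normal(scale=jitter_sigma)]))
            if lt == "POPC":
                atoms.append(
                    Atom(index=len(atoms), name="N", residue_name=lt,
                         residue_id=resid, segment_id="MEMB", mass=14.007, is_bead=True)
                )
                coords.append(
                    np.array([xy[0], xy[1], z_head + zsign * 0.1 + rng.normal(scale=jitter_sigma)])
                )
    if not atoms:
        # an empty membrane is still a valid (atom-free) topology request;
        # return a zero-atom topology with a consistent empty frame
        return Topology([]), Frame(coordinates=np.empty((0, 3)), box=box)
    return Topology(atoms), Frame(coordinates=np.array(coords), box=box)


# ---------------------------------------------------------------------------
# Two-domain membrane protein scene
# ---------------------------------------------------------------------------

def make_two_domain_scene(
    schedule: pd.DataFrame | dict,
    n_body_particles: int = 200,
    helix_tilt: float = 10.0,
    noise_sigma: float = 0.0,
    upper: dict | None = None,
    lower: dict | None = None,
    seed: int = 0,
) -> tuple[Topology, Trajectory, pd.DataFrame]:
    """Membrane-bound two-domain protein: a TM helix spanning a bilayer
    surrogate plus an extracellular rigid body following an orientation
    schedule above the upper leaflet.

    Segments: ``IG`` (the scheduled rigid body, resname BOD), ``A`` (the
    Cα helix, residues 153–189), ``MEMB`` (typed lipid headgroup markers).
    The helix and membrane are static; the body's Tait-Bryan schedule is
    the ground truth, returned as the sidecar.
    """
    box = (18.0, 18.0, 18.0)
    btop, btraj, sidecar = make_rigid_body(
        schedule,
        n_particles=n_body_particles,
        half_axes=(1.5, 0.8, 0.4),
        box=box,
        noise_sigma=noise_sigma,
        seed=seed,
        center=(9.0, 9.0, 14.0),
    )
    _, hframe = make_ideal_helix(37, tilt=helix_tilt, box=box)
    ltop, lframe = make_bilayer_surrogate(
        box=box, upper=upper, lower=lower, leaflet_offset=2.0, seed=seed + 1
    )

    atoms: list[Atom] = []
    for a in btop.atoms:
        atoms.append(Atom(index=len(atoms), name=a.name, residue_name=a.residue_name,
                          residue_id=a.residue_id, segment_id="IG", mass=a.mass,
                          is_bead=True))
    for k in range(37):
        atoms.append(Atom(index=len(atoms), name="CA", residue_name="ALA",
                          residue_id=153 + k, segment_id="A", mass=12.011))
    lipid_resid_base = 200
    for a in ltop.atoms:
        atoms.append(Atom(index=len(atoms), name=a.name, residue_name=a.residue_name,
                          residue_id=lipid_resid_base + a.residue_id,
                          segment_id="MEMB", mass=a.mass, is_bead=True))
    topology = Topology(atoms)

    static = np.vstack([hframe.coordinates, lframe.coordinates])
    frames = [
        Frame(
            coordinates=np.vstack([bf.coordinates, static]),
            box=np.asarray(box, float),
            time=bf.time,
        )
        for bf in btraj.frames
    ]
    return topology, Trajectory(topology, frames, btraj.frame_stride_ps), sidecar


# ---------------------------------------------------------------------------
# Multi-copy scenes with planted clusters
# ---------------------------------------------------------------------------

_COPY_BEADS = ("BAS", "MID", "SC1", "TIP")  # end-on interfaces are tip↔base
_COPY_SPACING = 0.4  # nm between beads along the copy axis


def make_multicopy_scene(
    planted_sizes: list[int],
    n_frames: int = 10,
    box: tuple = (30.0, 30.0, 10.0),
    cutoff: float = 0.65,
    gap_within: float = 0.4,
    diffusion_sigma: float = 0.0,
    mode: str = "static",
    frame_stride_ps: float = 1000.0,
    seed: int = 0,
) -> tuple[Topology, Trajectory, pd.DataFrame]:
    """Scene of rod-like protein copies with a planted cluster partition.

    Copies are 4-bead rods (base→tip). Within a planted cluster, copies
    chain end-on with a tip↔base gap ``gap_within`` < ``cutoff``; distinct
    clusters (and periodic images) are separated by ≥ 2×``cutoff``. In
    ``static`` mode positions are frozen so the planted partition is the
    truth at every frame; in ``drift`` mode each copy performs an
    independent rigid random walk (σ = ``diffusion_sigma`` nm/frame) and
    the truth is guaranteed only at frame 0.

    Returns (topology, trajectory, truth table copy→cluster).
    """
    if mode not in {"static", "drift"}:
        raise ValueError(f"unknown mode {mode!r}")
    if any(s < 1 for s in planted_sizes):
        raise ValueError("cluster sizes must be ≥ 1")
    n_copies = int(sum(planted_sizes))
    if gap_within >= cutoff:
        raise ValueError("gap_within must be smaller than the contact cutoff")
    box = np.asarray(box, dtype=float)
    rng = np.random.default_rng(seed)

    copy_len = _COPY_SPACING * (len(_COPY_BEADS) - 1)
    pitch = copy_len + gap_within           # base-to-base offset within a chain
    margin = max(2.0 * cutoff, 1.5)         # inter-cluster and edge margin
    z = box[2] / 2.0

    # row-major placement of cluster chains
    positions = np.empty((n_copies, 3))     # base-bead position of each copy
    truth = []
    x, y = margin, margin
    row_h = 0.0
    copy_id = 0
    for cid, size in enumerate(planted_sizes):
        extent = size * pitch - gap_within
        if x + extent > box[0] - margin:
            x = margin
            y += row_h + margin
            row_h = 0.0
        if y > box[1] - margin:
            raise ValueError(
                f"cannot pack {n_copies} copies ({planted_sizes}) into box {tuple(box)}"
            )
        for m in range(size):
            positions[copy_id] = (x + m * pitch, y, z)
            truth.append({"copy": copy_id, "cluster": cid, "size": size})
            copy_id += 1
        x += extent + margin
        row_h = max(row_h, 0.0)
    truth_df = pd.DataFrame(truth)

    bead_offsets = np.array([[k * _COPY_SPACING, 0.0, 0.0] for k in range(len(_COPY_BEADS))])
    atoms = []
    for c in range(n_copies):
        for k, nm in enumerate(_COPY_BEADS):
            atoms.append(
                Atom(index=len(atoms), name=nm, residue_name="CPY",
                     residue_id=c + 1, segment_id=f"C{c:02d}", mass=72.0, is_bead=True)
            )
    topology = Topology(atoms)

    frames = []
    drift = np.zeros((n_copies, 3))
    for t in range(n_frames):
        if mode == "drift" and t > 0 and diffusion_sigma > 0:
            drift += rng.normal(scale=diffusion_sigma, size=(n_copies, 3))
        coords = (positions + drift)[:, None, :] + bead_offsets[None, :, :]
        frames.append(
            Frame(coordinates=coords.reshape(-1, 3), box=box, time=t * frame_stride_ps)
        )
    return topology, Trajectory(topology, frames, frame_stride_ps), truth_df


def copy_selections(topology: Topology) -> list[Selection]:
    """One Selection per copy of a multi-copy scene (keyed by residue id)."""
    out = []
    for resid in sorted(set(int(r) for r in topology.resids)):
        idx = np.flatnonzero(topology.resids == resid)
        out.append(Selection(label=f"copy_{resid - 1}", atom_indices=idx))
    return out


# ---------------------------------------------------------------------------
# Rendering to files
# ---------------------------------------------------------------------------

def render_scene(
    prefix: str,
    topology: Topology,
    trajectory: Trajectory | None = None,
    frame: Frame | None = None,
    truth: dict[str, pd.DataFrame] | None = None,
    seed: int | None = None,
) -> dict[str, str]:
    """Write a scene to ``<prefix>.gro`` (+ ``.xtc`` for trajectories) with
    ground-truth CSV sidecars and a JSON provenance record. Returns the
    mapping of artefact name → path."""
    os.makedirs(os.path.dirname(prefix) or ".", exist_ok=True)
    first = trajectory.frames[0] if trajectory is not None else frame
    if first is None:
        raise ValueError("need a trajectory or a frame to render")
    paths = {"structure": prefix + ".gro"}
    write_structure(paths["structure"], topology, first)
    if trajectory is not None and trajectory.n_frames > 1:
        paths["trajectory"] = prefix + ".xtc"
        write_trajectory(paths["trajectory"], trajectory)
    for name, df in (truth or {}).items():
        p = f"{prefix}_truth_{name}.csv"
        df.to_csv(p, index=False)
        paths[f"truth_{name}"] = p
    prov = {
        "generator": "memborient.synthetic_data",
        "n_atoms": topology.n_atoms,
        "n_frames": trajectory.n_frames if trajectory is not None else 1,
        "seed": seed,
    }
    paths["provenance"] = prefix + "_provenance.json"
    with open(paths["provenance"], "w") as fh:
        json.dump(prov, fh, indent=2)
    return paths
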