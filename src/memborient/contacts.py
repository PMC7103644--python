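"""Residue-resolved contact occupancy.

Three criteria from membrane-protein practice:

* atomistic protein–lipid: a residue touches the membrane when the heavy-
  atom COM of its side chain is within 0.5 nm (5 Å) of a lipid headgroup
  phosphorus atom;
* coarse-grained protein–lipid: the first side-chain bead of a residue
  within 0.65 nm (6.5 Å) of a lipid-type headgroup bead, one series per
  lipid type;
* protein–protein: any particle of a residue within a cutoff of any
  particle of a *different* protein copy, reported as a per-residue
  contact probability with a strict > 2.5 % reporting mask.

All distances use the minimum-image convention in x, y and z. Contact is
strict: distance < cutoff. Neighbour searches use a periodic k-d tree; the
brute-force all-pairs evaluation lives in the test suite as the oracle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .traj_model import Selection, Trajectory

__all__ = [
    "ContactCriterion",
    "ContactSeries",
    "OccupancyMap",
    "residue_lipid_contacts",
    "cg_lipid_contacts",
    "protein_protein_contacts",
    "threshold_mask",
    "nearest_partner_distance",
    "DEFAULT_ATOMISTIC_CUTOFF_NM",
    "DEFAULT_CG_CUTOFF_NM",
    "DEFAULT_REPORT_THRESHOLD",
]

DEFAULT_ATOMISTIC_CUTOFF_NM = 0.5   # 5 Å sidechain-COM ↔ headgroup phosphorus
DEFAULT_CG_CUTOFF_NM = 0.65        # 6.5 Å CG headgroup-bead criterion
DEFAULT_REPORT_THRESHOLD = 0.025   # report residues above 2.5 % of total time

BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT", "BB", "H", "HA", "HN"}


@dataclass(frozen=True)
class ContactCriterion:
    probe: str = "sidechain_com"  # sidechain_com | first_sidechain_bead | any_atom
    partner_atom_names: tuple = ("P",)
    cutoff: float = DEFAULT_ATOMISTIC_CUTOFF_NM  # nm, strict <
    periodic: bool = True

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.probe not in {"sidechain_com", "first_sidechain_bead", "any_atom"}:
            raise ValueError(f"unknown probe {self.probe!r}")


@dataclass
class ContactSeries:
    """Boolean residue × frame contact record plus its criterion."""

    residues: pd.DataFrame          # columns: segment, resid, resname
    times: np.ndarray
    hits: np.ndarray                # (n_residues, n_frames) bool
    criterion: ContactCriterion
    partner_label: str = ""

    @property
    def occupancy(self) -> np.ndarray:
        """Fraction of frames in contact, per residue (∈ [0, 1])."""
        return self.hits.mean(axis=1)

    def occupancy_map(self, threshold: float = DEFAULT_REPORT_THRESHOLD) -> "OccupancyMap":
        return OccupancyMap(
            residues=self.residues.copy(),
            occupancy=self.occupancy,
            threshold=threshold,
            aggregation="per_run",
        )


@dataclass
class OccupancyMap:
    residues: pd.DataFrame
    occupancy: np.ndarray
    threshold: float = DEFAULT_REPORT_THRESHOLD
    aggregation: str = "per_run"  # per_run | pooled

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy, dtype=float)
        if np.any((occ < 0) | (occ > 1)):
            raise ValueError("occupancies must lie in [0, 1]")
        self.occupancy = occ

    @property
    def mask(self) -> np.ndarray:
        """Strictly-above-threshold reporting mask."""
        return self.occupancy > self.threshold

    def to_frame(self) -> pd.DataFrame:
        df = self.residues.copy()
        df["occupancy"] = self.occupancy
        df["passes_threshold"] = self.mask
        return df


# ---------------------------------------------------------------------------
# Neighbour search
# ---------------------------------------------------------------------------

def nearest_partner_distance(
    points: np.ndarray, partners: np.ndarray, box: np.ndarray | None
) -> np.ndarray:
    """Distance from each point to its nearest partner (min-image if box)."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    partners = np.atleast_2d(np.asarray(partners, dtype=float))
    if box is not None:
        box = np.asarray(box, dtype=float)
        tree = cKDTree(np.mod(partners, box), boxsize=box)
        d, _ = tree.query(np.mod(points, box))
    else:
        tree = cKDTree(partners)
        d, _ = tree.query(points)
    return np.atleast_1d(d)


def _pairs_within(
    pts_a: np.ndarray, pts_b: np.ndarray, cutoff: float, box: np.ndarray | None
):
    """Index pairs (i into a, j into b) with min-image distance < cutoff (strict)."""
    if box is not None:
        box = np.asarray(box, dtype=float)
        ta = cKDTree(np.mod(pts_a, box), boxsize=box)
        tb = cKDTree(np.mod(pts_b, box), boxsize=box)
    else:
        ta, tb = cKDTree(pts_a), cKDTree(pts_b)
    pairs = ta.query_ball_tree(tb, r=cutoff)
    out = [(i, j) for i, js in enumerate(pairs) for j in js]
    if not out:
        return np.empty((0, 2), dtype=int)
    arr = np.array(out, dtype=int)
    # query_ball_tree is inclusive at r; the contact convention is strict <
    if box is not None:
        d = pts_a[arr[:, 0]] - pts_b[arr[:, 1]]
        d -= box * np.round(d / box)
    else:
        d = pts_a[arr[:, 0]] - pts_b[arr[:, 1]]
    dist = np.linalg.norm(d, axis=1)
    return arr[dist < cutoff]


# ---------------------------------------------------------------------------
# Residue probes
# ---------------------------------------------------------------------------

def _residue_probe_indices(topology, residue_selection: Selection, probe: str):
    """Per residue: atom indices defining its probe, plus a metadata table."""
    meta = []
    probes = []
    for seg, resid, resname, idx in topology.residue_groups(residue_selection.atom_indices):
        names = topology.names[idx]
        if probe == "any_atom":
            chosen = idx
        else:
            side = idx[~np.isin(names, list(BACKBONE_NAMES))]
            # drop hydrogens: heavy-atom COM convention
            is_h = np.array(
                [str(n).startswith(("H", "1H", "2H", "3H")) for n in topology.names[side]],
                dtype=bool,
            )
            side = side[~is_h]
            if side.size == 0:
                # glycine (or bead-less CG residue): fall back to Cα/backbone
                ca = idx[np.isin(names, ["CA", "BB"])]
                chosen = ca if ca.size else idx[:1]
                warnings.warn(
                    f"residue {resname}{resid} ({seg}) has no side-chain heavy "
                    "atoms; probing at backbone position",
                    stacklevel=3,
                )
            elif probe == "first_sidechain_bead":
                chosen = side[:1]
            else:  # sidechain_com
                chosen = side
        if chosen.size == 0:
            raise ValueError(f"residue {resname}{resid} ({seg}) has no probe atoms")
        probes.append(np.asarray(chosen, dtype=int))
        meta.append({"segment": seg, "resid": resid, "resname": resname})
    return probes, pd.DataFrame(meta)


def _probe_positions(frame_coords, masses, probes, probe_mode: str) -> np.ndarray:
    pts = np.empty((len(probes), 3))
    for k, idx in enumerate(probes):
        if probe_mode == "sidechain_com" and idx.size > 1:
            m = masses[idx]
            pts[k] = (m[:, None] * frame_coords[idx]).sum(axis=0) / m.sum()
        else:
            pts[k] = frame_coords[idx[0]] if idx.size == 1 else frame_coords[idx].mean(axis=0)
    return pts


# ---------------------------------------------------------------------------
# Contact operations
# ---------------------------------------------------------------------------

def residue_lipid_contacts(
    traj: Trajectory,
    protein_residues: Selection,
    lipid_partners: Selection,
    criterion: ContactCriterion | None = None,
) -> ContactSeries:
    """Per-residue, per-frame protein–lipid contact booleans.

    Default criterion: side-chain heavy-atom COM within 0.5 nm (strict) of
    any partner atom (headgroup phosphorus), minimum image.
    """
    crit = criterion or ContactCriterion()
    top = traj.topology
    probes, meta = _residue_probe_indices(top, protein_residues, crit.probe)
    partner_idx = lipid_partners.atom_indices
    if crit.partner_atom_names:
        keep = np.isin(top.names[partner_idx], list(crit.partner_atom_names))
        if keep.any():
            partner_idx = partner_idx[keep]
    hits = np.zeros((len(probes), traj.n_frames), dtype=bool)
    for t, frame in enumerate(traj.frames):
        pts = _probe_positions(frame.coordinates, top.masses, probes, crit.probe)
        partners = frame.coordinates[partner_idx]
        box = frame.box if crit.periodic else None
        d = nearest_partner_distance(pts, partners, box)
        hits[:, t] = d < crit.cutoff
    return ContactSeries(
        residues=meta,
        times=traj.times,
        hits=hits,
        criterion=crit,
        partner_label=lipid_partners.label,
    )


def cg_lipid_contacts(
    traj: Trajectory,
    protein_residues: Selection,
    lipid_headgroups: dict[str, Selection],
    cutoff: float = DEFAULT_CG_CUTOFF_NM,
    known_types: tuple = ("POPC", "POPE", "Sph", "GM3", "CHOL", "POPS", "PIP2"),
    periodic: bool = True,
) -> dict[str, ContactSeries]:
    """Coarse-grained contacts per lipid type (first side-chain bead probe)."""
    for lt in lipid_headgroups:
        if known_types and lt not in known_types:
            raise ValueError(f"unknown lipid type {lt!r}; expected one of {known_types}")
    out = {}
    for lt, sel in lipid_headgroups.items():
        crit = ContactCriterion(
            probe="first_sidechain_bead",
            partner_atom_names=(),
            cutoff=cutoff,
            periodic=periodic,
        )
        out[lt] = residue_lipid_contacts(traj, protein_residues, sel, crit)
        out[lt].partner_label = lt
    return out


def protein_protein_contacts(
    traj: Trajectory,
    copies: list[Selection],
    cutoff: float = DEFAULT_CG_CUTOFF_NM,
    threshold: float = DEFAULT_REPORT_THRESHOLD,
) -> tuple[OccupancyMap, pd.DataFrame]:
    """Inter-copy contact probability per residue, plus per-pair records.

    A residue of one copy is in contact in a frame when any of its
    particles is within ``cutoff`` (strict, minimum image) of any particle
    of a different copy. The occupancy map pools residues of all copies;
    the per-pair table records which copy pairs touch in which frame.
    """
    if len(copies) < 2:
        raise ValueError("need at least two protein copies")
    all_idx = np.concatenate([c.atom_indices for c in copies])
    if len(np.unique(all_idx)) != len(all_idx):
        raise ValueError("copy selections overlap")
    top = traj.topology
    copy_of = np.concatenate(
        [np.full(len(c.atom_indices), k, dtype=int) for k, c in enumerate(copies)]
    )
    # residue bookkeeping per copy
    res_meta = []
    res_of_atom = np.empty(len(all_idx), dtype=int)
    pos_in_all = {int(a): i for i, a in enumerate(all_idx)}
    for k, c in enumerate(copies):
        for seg, resid, resname, idx in top.residue_groups(c.atom_indices):
            rid = len(res_meta)
            res_meta.append(
                {"copy": k, "segment": seg, "resid": resid, "resname": resname}
            )
            for a in idx:
                res_of_atom[pos_in_all[int(a)]] = rid
    meta = pd.DataFrame(res_meta)
    n_res = len(meta)
    hits = np.zeros((n_res, traj.n_frames), dtype=bool)
    pair_records = []
    for t, frame in enumerate(traj.frames):
        pts = frame.coordinates[all_idx]
        pairs = _pairs_within(pts, pts, cutoff, frame.box)
        if pairs.size:
            cross = copy_of[pairs[:, 0]] != copy_of[pairs[:, 1]]
            pairs = pairs[cross]
        touched_pairs = set()
        for i, j in pairs:
            hits[res_of_atom[i], t] = True
            hits[res_of_atom[j], t] = True
            a, b = sorted((int(copy_of[i]), int(copy_of[j])))
            touched_pairs.add((a, b))
        for a, b in sorted(touched_pairs):
            pair_records.append({"time_ps": frame.time, "copy_i": a, "copy_j": b})
    occ_map = OccupancyMap(
        residues=meta,
        occupancy=hits.mean(axis=1),
        threshold=threshold,
        aggregation="pooled",
    )
    pair_df = pd.DataFrame(pair_records, columns=["time_ps", "copy_i", "copy_j"])
    return occ_map, pair_df


def threshold_mask(occ_map: OccupancyMap, fraction: float = DEFAULT_REPORT_THRESHOLD) -> pd.DataFrame:
    """Residues with occupancy strictly above ``fraction``, sorted descending."""
    df = occ_map.residues.copy()
    df["occupancy"] = occ_map.occupancy
    df = df[df["occupancy"] > fraction]
    return df.sort_values("occupancy", ascending=False, kind="stable").reset_index(drop=True)


def write_occupancy_bfactors(path: str, topology, frame, occ_map: OccupancyMap) -> None:
    """Write a PDB with per-residue occupancy stamped into the B-factor
    column (×100, as a percentage) for structure-viewer colouring."""
    from .traj_model import _universe_from

    occ_by_res = {
        (row["segment"], int(row["resid"])): occ_map.occupancy[i]
        for i, row in occ_map.residues.iterrows()
    }
    u = _universe_from(topology, frame)
    b = np.zeros(topology.n_atoms)
    for i in range(topology.n_atoms):
        key = (topology.segids[i], int(topology.resids[i]))
        b[i] = 100.0 * occ_by_res.get(key, 0.0)
    u.add_TopologyAttr("tempfactors", b)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(path)


def pool_occupancy(series_list: list[ContactSeries]) -> OccupancyMap:
    """Pool contact series from replicas: occupancy over all frames of all runs."""
    if not series_list:
        raise ValueError("need at least one series")
    first = series_list[0]
    for s in series_list[1:]:
        if not first.residues.equals(s.residues):
            raise ValueError("replica series cover different residue sets")
    hits = np.concatenate([s.hits for s in series_list], axis=1)
    return OccupancyMap(
        residues=first.residues.copy(),
        occupancy=hits.mean(axis=1),
        aggregation="pooled",
    )
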