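"""Rigid-body domain orientation from the mass-weighted moment-of-inertia
tensor.

For a selected domain (typically the secondary-structure core of an
immunoglobulin-like fold, to exclude flexible-loop noise) the per-frame
principal axes are the eigenvectors of

    I = Σ_i m_i [ (r_i · r_i) 𝟙 − r_i ⊗ r_i ],    r_i relative to the COM,

diagonalised as Λ = Uᵀ I U with U = (p1, p2, p3). The direction-cosine
matrix between the principal axes and a reference basis is decomposed as
intrinsic Z-Y'-X'' Tait-Bryan angles (yaw, pitch, roll). Pitch 0° means the
domain long axis lies in the membrane plane; |pitch| → 90° means it points
along the membrane normal.

Eigenvectors are sign-ambiguous, so axes are made continuous frame-to-frame
(flip so p_k(t)·p_k(t−1) ≥ 0); the first frame is signed against the
reference basis. Moments are ordered ascending, making p1 the long axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .traj_model import Selection, Trajectory

__all__ = [
    "ReferenceBasis",
    "InertiaTensor",
    "PrincipalAxes",
    "EulerAngles",
    "OrientationSeries",
    "DegenerateInertiaWarning",
    "compute_inertia_tensor",
    "principal_axes",
    "direction_cosine_matrix",
    "taitbryan_zyx",
    "rotation_zyx",
    "orientation_series",
    "angle_histogram",
    "angle_heatmap_table",
]


class DegenerateInertiaWarning(UserWarning):
    """Two or more principal moments are (nearly) equal; axes ill-conditioned."""


@dataclass(frozen=True)
class ReferenceBasis:
    """Orthonormal right-handed reference frame (rows e_x, e_y, e_z)."""

    e_x: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))
    e_y: np.ndarray = field(default_factory=lambda: np.array([0.0, 1.0, 0.0]))
    e_z: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    def __post_init__(self) -> None:
        m = self.matrix
        if not np.allclose(m @ m.T, np.eye(3), atol=1e-8):
            raise ValueError("reference basis must be orthonormal")
        if np.linalg.det(m) < 0:
            raise ValueError("reference basis must be right-handed (det=+1)")

    @property
    def matrix(self) -> np.ndarray:
        """3×3 matrix with the basis vectors as rows."""
        return np.vstack([self.e_x, self.e_y, self.e_z]).astype(float)


STANDARD_BASIS = ReferenceBasis()


@dataclass(frozen=True)
class InertiaTensor:
    matrix: np.ndarray  # 3×3, amu·nm²
    center: np.ndarray  # COM used, nm


@dataclass(frozen=True)
class PrincipalAxes:
    """Columns of U (ascending moments: p1 = long axis), det(U) = +1."""

    p1: np.ndarray
    p2: np.ndarray
    p3: np.ndarray
    moments: np.ndarray
    degenerate: bool = False

    @property
    def matrix(self) -> np.ndarray:
        """U with p_k as columns."""
        return np.column_stack([self.p1, self.p2, self.p3])


@dataclass(frozen=True)
class EulerAngles:
    """Intrinsic ZYX Tait-Bryan angles in degrees."""

    yaw: float
    pitch: float
    roll: float
    gimbal_lock: bool = False


@dataclass
class OrientationSeries:
    times: np.ndarray
    axes: list[PrincipalAxes]
    angles: list[EulerAngles]
    reference: ReferenceBasis
    selection_label: str = ""

    @property
    def pitch(self) -> np.ndarray:
        return np.array([a.pitch for a in self.angles])

    @property
    def yaw(self) -> np.ndarray:
        return np.array([a.yaw for a in self.angles])

    @property
    def roll(self) -> np.ndarray:
        return np.array([a.roll for a in self.angles])

    def to_frame(self, run: int | str = 0) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_ps": self.times,
                "yaw_deg": self.yaw,
                "pitch_deg": self.pitch,
                "roll_deg": self.roll,
                "gimbal_lock": [a.gimbal_lock for a in self.angles],
                "run": run,
            }
        )


# ---------------------------------------------------------------------------
# Tensor and axes
# ---------------------------------------------------------------------------

def compute_inertia_tensor(coords: np.ndarray, masses: np.ndarray) -> InertiaTensor:
    """Mass-weighted moment-of-inertia tensor about the COM of ``coords``.

    Requires ≥3 non-collinear points and positive total mass; a degenerate
    (collinear) point set leaves one principal axis undefined and raises.
    """
    coords = np.asarray(coords, dtype=float)
    masses = np.asarray(masses, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("coords must be M×3")
    if coords.shape[0] != masses.shape[0]:
        raise ValueError("coords and masses length mismatch")
    total = masses.sum()
    if total <= 0:
        raise ValueError("total mass must be positive")
    if coords.shape[0] < 3:
        raise ValueError("need at least 3 points for a well-defined tensor")
    center = (masses[:, None] * coords).sum(axis=0) / total
    r = coords - center
    # collinearity check: rank of the centered cloud
    if np.linalg.matrix_rank(r, tol=1e-10) < 2:
        raise ValueError("point set is collinear; principal axes ill-defined")
    r2 = np.einsum("ij,ij->i", r, r)
    tensor = np.einsum("i,jk->jk", masses * r2, np.eye(3)) - np.einsum(
        "i,ij,ik->jk", masses, r, r
    )
    tensor = 0.5 * (tensor + tensor.T)  # symmetrize away float noise
    return InertiaTensor(matrix=tensor, center=center)


def _fix_signs_first_frame(vecs: np.ndarray, reference: ReferenceBasis) -> np.ndarray:
    """First-frame sign convention: p_k·e_k ≥ 0, ties toward +e_z; then det=+1."""
    ref = reference.matrix  # rows e_x, e_y, e_z
    for k in range(3):
        d = float(vecs[:, k] @ ref[k])
        if abs(d) < 1e-12:
            d = float(vecs[:, k] @ ref[2])  # tie-break toward +e_z
        if d < 0:
            vecs[:, k] = -vecs[:, k]
    if np.linalg.det(vecs) < 0:
        vecs[:, 2] = -vecs[:, 2]
    return vecs


def principal_axes(
    tensor: InertiaTensor,
    previous: PrincipalAxes | None = None,
    reference: ReferenceBasis = STANDARD_BASIS,
    degeneracy_tol: float = 1e-6,
) -> PrincipalAxes:
    """Diagonalise the inertia tensor: Λ = Uᵀ I U, ascending moments.

    Sign continuity: with ``previous`` given, each p_k is flipped so that
    p_k·previous_p_k ≥ 0; otherwise the first-frame convention applies
    (p_k·e_k ≥ 0, tie toward +e_z). Handedness det(U)=+1 is enforced by
    flipping the axis with the weakest continuity constraint.

    Near-degenerate moment pairs (relative gap < ``degeneracy_tol``) emit a
    :class:`DegenerateInertiaWarning` and set ``degenerate=True``; axes are
    still returned.
    """
    I = np.asarray(tensor.matrix, dtype=float)
    if not np.allclose(I, I.T, atol=1e-8):
        raise ValueError("inertia tensor must be symmetric")
    moments, vecs = np.linalg.eigh(I)  # ascending
    scale = max(abs(moments[-1]), 1e-300)
    gaps = np.diff(moments) / scale
    degenerate = bool(np.any(gaps < degeneracy_tol))
    if degenerate:
        warnings.warn(
            f"near-degenerate principal moments {moments}; axes ill-conditioned",
            DegenerateInertiaWarning,
            stacklevel=2,
        )
    if previous is None:
        vecs = _fix_signs_first_frame(vecs, reference)
    else:
        prev = previous.matrix
        dots = np.einsum("ik,ik->k", vecs, prev)
        for k in range(3):
            if dots[k] < 0:
                vecs[:, k] = -vecs[:, k]
                dots[k] = -dots[k]
        if np.linalg.det(vecs) < 0:
            k = int(np.argmin(np.abs(dots)))
            vecs[:, k] = -vecs[:, k]
    return PrincipalAxes(
        p1=vecs[:, 0].copy(),
        p2=vecs[:, 1].copy(),
        p3=vecs[:, 2].copy(),
        moments=moments,
        degenerate=degenerate,
    )


def direction_cosine_matrix(
    axes: PrincipalAxes, reference: ReferenceBasis = STANDARD_BASIS
) -> np.ndarray:
    """Direction-cosine matrix R_jk = e_j · p_k between axes and reference."""
    U = axes.matrix
    if not np.allclose(U.T @ U, np.eye(3), atol=1e-8):
        raise ValueError("principal axes must be orthonormal")
    R = reference.matrix @ U
    if np.linalg.det(R) < 0:
        raise ValueError("axes/reference handedness mismatch (det < 0)")
    return R


# ---------------------------------------------------------------------------
# Tait-Bryan angles (intrinsic ZYX)
# ---------------------------------------------------------------------------

def rotation_zyx(yaw: float, pitch: float, roll: float) -> np.ndarray:
    """Compose R = Rz(yaw)·Ry(pitch)·Rx(roll), angles in degrees."""
    a, b, c = np.deg2rad([yaw, pitch, roll])
    ca, sa = np.cos(a), np.sin(a)
    cb, sb = np.cos(b), np.sin(b)
    cc, sc = np.cos(c), np.sin(c)
    Rz = np.array([[ca, -sa, 0], [sa, ca, 0], [0, 0, 1]])
    Ry = np.array([[cb, 0, sb], [0, 1, 0], [-sb, 0, cb]])
    Rx = np.array([[1, 0, 0], [0, cc, -sc], [0, sc, cc]])
    return Rz @ Ry @ Rx


_GIMBAL_EPS = 1e-9


def taitbryan_zyx(R: np.ndarray) -> EulerAngles:
    """Decompose a rotation matrix into intrinsic ZYX Tait-Bryan angles.

    Inverse of :func:`rotation_zyx` for pitch in (−90°, 90°). At gimbal
    lock (|pitch| = 90°) yaw and roll are coupled; by convention roll is
    set to 0, yaw absorbs the in-plane rotation, and the result is flagged.
    """
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3):
        raise ValueError("R must be 3×3")
    if not np.allclose(R @ R.T, np.eye(3), atol=1e-6) or np.linalg.det(R) < 0:
        raise ValueError("R must be a proper rotation (orthogonal, det=+1)")
    s = -R[2, 0]  # sin(pitch)
    if abs(s) >= 1.0 - _GIMBAL_EPS:
        pitch = 90.0 if s > 0 else -90.0
        yaw = float(np.rad2deg(np.arctan2(-R[0, 1], R[1, 1])))
        return EulerAngles(yaw=yaw, pitch=pitch, roll=0.0, gimbal_lock=True)
    pitch = float(np.rad2deg(np.arcsin(np.clip(s, -1.0, 1.0))))
    yaw = float(np.rad2deg(np.arctan2(R[1, 0], R[0, 0])))
    roll = float(np.rad2deg(np.arctan2(R[2, 1], R[2, 2])))
    return EulerAngles(yaw=yaw, pitch=pitch, roll=roll, gimbal_lock=False)


# ---------------------------------------------------------------------------
# Per-trajectory series and histograms
# ---------------------------------------------------------------------------

def orientation_series(
    traj: Trajectory,
    selection: Selection,
    reference_mode: str = "standard_basis",
    degeneracy_tol: float = 1e-6,
) -> OrientationSeries:
    """Per-frame principal axes and Tait-Bryan angles for a selected domain.

    ``reference_mode="standard_basis"`` measures angles against the lab
    frame e_x, e_y, e_z; ``"first_frame"`` measures them against the
    domain's own principal axes in frame 0 (so frame 0 is (0, 0, 0) by
    construction). Sign continuity is applied sequentially along the
    trajectory.
    """
    if reference_mode not in {"standard_basis", "first_frame"}:
        raise ValueError(f"unknown reference_mode {reference_mode!r}")
    idx = selection.atom_indices
    masses = traj.topology.masses[idx]
    axes_list: list[PrincipalAxes] = []
    prev: PrincipalAxes | None = None
    with warnings.catch_warnings():
        warnings.simplefilter("once", DegenerateInertiaWarning)
        for frame in traj.frames:
            tensor = compute_inertia_tensor(frame.coordinates[idx], masses)
            ax = principal_axes(tensor, previous=prev, degeneracy_tol=degeneracy_tol)
            axes_list.append(ax)
            prev = ax
    if reference_mode == "first_frame":
        U0 = axes_list[0].matrix
        reference = ReferenceBasis(e_x=U0[:, 0], e_y=U0[:, 1], e_z=U0[:, 2])
    else:
        reference = STANDARD_BASIS
    angles = [taitbryan_zyx(direction_cosine_matrix(ax, reference)) for ax in axes_list]
    return OrientationSeries(
        times=traj.times,
        axes=axes_list,
        angles=angles,
        reference=reference,
        selection_label=selection.label,
    )


def angle_histogram(
    series,
    bin_width: float = 1.0,
    angle_range: tuple[float, float] = (-90.0, 90.0),
    which: str = "pitch",
    fold_absolute: bool = False,
    pooling: str = "frames",
) -> pd.DataFrame:
    """Probability-normalised histogram of an angle over one or more runs.

    ``pooling="frames"`` concatenates all frames (each frame weighted
    equally, the pooled-replica convention); ``pooling="replicas"``
    histograms each run separately and averages the per-run mass tables —
    the two agree exactly when all runs have equal frame counts.
    ``fold_absolute=True`` histograms |angle|.
    """
    if isinstance(series, OrientationSeries):
        series = [series]
    if len(series) == 0:
        raise ValueError("need at least one series")
    lo, hi = angle_range
    if fold_absolute:
        lo = max(lo, 0.0)
    edges = np.arange(lo, hi + bin_width * 0.5, bin_width)
    if edges[-1] < hi:
        edges = np.append(edges, hi)

    def values(s: OrientationSeries) -> np.ndarray:
        v = getattr(s, which)
        if v.size == 0:
            raise ValueError("empty angle series")
        return np.abs(v) if fold_absolute else v

    if pooling == "frames":
        pooled = np.concatenate([values(s) for s in series])
        counts, _ = np.histogram(pooled, bins=edges)
        mass = counts / counts.sum() if counts.sum() else counts.astype(float)
    elif pooling == "replicas":
        per_run = []
        for s in series:
            c, _ = np.histogram(values(s), bins=edges)
            per_run.append(c / c.sum() if c.sum() else c.astype(float))
        mass = np.mean(per_run, axis=0)
    else:
        raise ValueError(f"unknown pooling mode {pooling!r}")
    return pd.DataFrame(
        {
            "bin_left_deg": edges[:-1],
            "bin_right_deg": edges[1:],
            "bin_center_deg": 0.5 * (edges[:-1] + edges[1:]),
            "probability": mass,
        }
    )


def angle_heatmap_table(series_list, which: str = "pitch") -> pd.DataFrame:
    """Run × time grid of angle values (machine-readable per-run heat map).

    Runs sampled on different time grids are resampled to the first run's
    times by nearest-frame lookup.
    """
    if isinstance(series_list, OrientationSeries):
        series_list = [series_list]
    if not series_list:
        raise ValueError("need at least one series")
    ref_times = series_list[0].times
    rows = {}
    for i, s in enumerate(series_list):
        v = getattr(s, which)
        if s.times.shape == ref_times.shape and np.allclose(s.times, ref_times):
            rows[f"run_{i}"] = v
        else:
            nearest = np.argmin(np.abs(s.times[None, :] - ref_times[:, None]), axis=1)
            rows[f"run_{i}"] = v[nearest]
    table = pd.DataFrame(rows, index=pd.Index(ref_times, name="time_ps")).T
    table.columns = ref_times
    return table
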