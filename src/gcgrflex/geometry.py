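"""Pivot-anchored reference frame and inter-domain orientation coordinates.

The extracellular domain (ECD) of a class B GPCR reorients relative to the
seven-transmembrane (7TM) bundle about a hinge at the base of the TM1 stalk.
Its orientation is summarised per frame by three reaction coordinates in a
Cartesian frame anchored at the hinge:

* origin O — the Calpha of the pivot residue,
* z — the outward membrane normal,
* x — the horizontal (z-orthogonal) unit component of the vector from O to
  the 7TM centre of mass, so the xz plane contains the 7TM COM,
* y — completes the right-handed frame.

theta is the polar angle of OC (C = ECD centre of mass) from z; phi is the
unsigned included angle between the xy-projection of OC and x; d is the
distance between the ECD and 7TM centres of mass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from gcgrflex.errors import DegenerateFrameError, GcgrflexError, ValidationError
from gcgrflex.io import DomainSpec, Trajectory, select

#: Horizontal components smaller than this (Å) leave phi undefined.
DEGENERACY_TOL = 1e-9


@dataclass(frozen=True)
class ReferenceFrame:
    """Orthonormal right-handed frame anchored at the pivot Calpha."""

    origin: np.ndarray
    x_axis: np.ndarray
    y_axis: np.ndarray
    z_axis: np.ndarray

    def __post_init__(self) -> None:
        axes = np.stack([self.x_axis, self.y_axis, self.z_axis])
        if not np.allclose(axes @ axes.T, np.eye(3), atol=1e-10):
            raise ValidationError("frame axes are not orthonormal")


@dataclass
class OrientationSeries:
    """Per-frame (theta, phi, d) in degrees/Å; phi may be NaN where the ECD
    COM sits on the z axis (phi_defined False)."""

    times: np.ndarray
    theta: np.ndarray
    phi: np.ndarray
    d: np.ndarray
    phi_defined: np.ndarray

    def __len__(self) -> int:
        return len(self.times)

    @property
    def n_undefined(self) -> int:
        return int((~self.phi_defined).sum())


@dataclass
class DistanceSeries:
    """Per-frame distance between one atom pair, with window statistics."""

    label: str
    times: np.ndarray
    distances: np.ndarray
    window: tuple[float, float]
    mean: float
    sd: float


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise GcgrflexError("zero-length vector has no direction")
    return v / n


def mass_center(coords: np.ndarray, masses: np.ndarray | None = None) -> np.ndarray:
    """Mass-weighted centre (geometric centroid when masses is None)."""
    if masses is None:
        return coords.mean(axis=0)
    m = np.asarray(masses, dtype=float)
    return (coords * m[:, None]).sum(axis=0) / m.sum()


def build_reference_frame(
    pivot_ca: np.ndarray,
    tm7_com: np.ndarray,
    membrane_normal: np.ndarray = (0.0, 0.0, 1.0),
) -> ReferenceFrame:
    """Construct the pivot-anchored frame from one snapshot.

    x is the unit horizontal component of (7TM COM − O); the frame is
    degenerate when the 7TM COM lies on the z axis through O.
    """
    z = _unit(np.asarray(membrane_normal, dtype=float))
    oc = np.asarray(tm7_com, dtype=float) - np.asarray(pivot_ca, dtype=float)
    horiz = oc - np.dot(oc, z) * z
    if np.linalg.norm(horiz) <= DEGENERACY_TOL:
        raise DegenerateFrameError(
            "7TM centre of mass lies on the z axis; azimuth undefined"
        )
    x = _unit(horiz)
    y = np.cross(z, x)
    return ReferenceFrame(
        origin=np.asarray(pivot_ca, dtype=float), x_axis=x, y_axis=y, z_axis=z
    )


def kabsch_superpose(
    mobile: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid fit of ``mobile`` onto ``reference``.

    Returns (rotation matrix R, translation t) such that the fitted points
    are ``mobile @ R.T + t``.
    """
    mob_c = mobile.mean(axis=0)
    ref_c = reference.mean(axis=0)
    rot, _ = Rotation.align_vectors(reference - ref_c, mobile - mob_c)
    R = rot.as_matrix()
    t = ref_c - mob_c @ R.T
    return R, t


def orientation_of_vector(
    oc: np.ndarray, frame: ReferenceFrame
) -> tuple[float, float, bool]:
    """(theta deg, phi deg, phi_defined) of a vector in the given frame."""
    norm = np.linalg.norm(oc)
    if norm == 0:
        raise GcgrflexError("ECD COM coincides with the origin")
    cz = np.clip(np.dot(oc, frame.z_axis) / norm, -1.0, 1.0)
    theta = np.degrees(np.arccos(cz))
    proj = oc - np.dot(oc, frame.z_axis) * frame.z_axis
    pn = np.linalg.norm(proj)
    if pn <= DEGENERACY_TOL:
        return float(theta), float("nan"), False
    cx = np.clip(np.dot(proj, frame.x_axis) / pn, -1.0, 1.0)
    phi = np.degrees(np.arccos(cx))  # unsigned included angle in [0, 180]
    return float(theta), float(phi), True


def compute_orientation(
    traj: Trajectory,
    domains: DomainSpec,
    superpose: bool = True,
    mass_weighted: bool = True,
    membrane_normal: np.ndarray = (0.0, 0.0, 1.0),
) -> OrientationSeries:
    """Per-frame orientation coordinates of the ECD relative to the 7TM.

    The reference frame is built on the first frame (7TM COM and pivot
    Calpha). With ``superpose`` on, each frame's 7TM Calpha set is
    least-squares superposed onto frame 0 (the rigid transform is applied to
    all atoms) before measurement, so the coordinates report internal motion
    only.
    """
    ecd_idx = select(traj, residue_range=domains.ecd)
    tm7_idx = select(traj, residue_range=domains.tm7)
    pivot_idx = select(
        traj, residue_ids=[domains.pivot_residue], atom_names=["CA"]
    )[0]
    tm7_ca = select(traj, residue_range=domains.tm7, atom_names=["CA"])

    masses = traj.masses if mass_weighted else None
    m_ecd = masses[ecd_idx] if masses is not None else None
    m_tm7 = masses[tm7_idx] if masses is not None else None

    ref_ca = traj.coords[0][tm7_ca]
    frame0 = traj.coords[0]
    frame = build_reference_frame(
        frame0[pivot_idx],
        mass_center(frame0[tm7_idx], m_tm7),
        membrane_normal,
    )

    n = traj.n_frames
    theta = np.empty(n)
    phi = np.empty(n)
    dist = np.empty(n)
    defined = np.ones(n, dtype=bool)
    for i in range(n):
        coords = traj.coords[i]
        if superpose and i > 0:
            R, t = kabsch_superpose(coords[tm7_ca], ref_ca)
            coords = coords @ R.T + t
        ecd_com = mass_center(coords[ecd_idx], m_ecd)
        tm7_com = mass_center(coords[tm7_idx], m_tm7)
        oc = ecd_com - frame.origin
        theta[i], phi[i], defined[i] = orientation_of_vector(oc, frame)
        dist[i] = np.linalg.norm(ecd_com - tm7_com)
    return OrientationSeries(
        times=traj.times.copy(), theta=theta, phi=phi, d=dist, phi_defined=defined
    )


def pair_distance_series(
    traj: Trajectory,
    residue_a: int,
    residue_b: int,
    atom_name: str = "CB",
    window: tuple[float, float] | None = None,
) -> DistanceSeries:
    """Per-frame distance between one named atom in each of two residues,
    with mean ± s.d. over the requested time window (defaults to the whole
    trajectory). Used e.g. for Cβ–Cβ crosslink-design screening."""
    ia = select(traj, residue_ids=[residue_a], atom_names=[atom_name])
    ib = select(traj, residue_ids=[residue_b], atom_names=[atom_name])
    if len(ia) != 1 or len(ib) != 1:
        raise GcgrflexError(
            f"atom {atom_name} not unique in residues {residue_a}/{residue_b}"
        )
    dists = np.linalg.norm(
        traj.coords[:, ia[0], :] - traj.coords[:, ib[0], :], axis=1
    )
    if window is None:
        window = (float(traj.times[0]), float(traj.times[-1]))
    lo, hi = window
    if lo > traj.times[-1] or hi < traj.times[0]:
        raise ValidationError(
            f"window {window} outside trajectory times "
            f"[{traj.times[0]}, {traj.times[-1]}]"
        )
    mask = (traj.times >= lo) & (traj.times <= hi)
    sel = dists[mask]
    return DistanceSeries(
        label=f"{atom_name} {residue_a} - {atom_name} {residue_b}",
        times=traj.times.copy(),
        distances=dists,
        window=(lo, hi),
        mean=float(sel.mean()),
        sd=float(sel.std(ddof=0)),
    )
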