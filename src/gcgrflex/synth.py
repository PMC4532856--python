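"""Seed-deterministic synthetic inputs for every analysis stage.

The generators are kinematic, not physical: rigid pseudo-domain blobs moved
along prescribed (theta, phi, d) schedules emulate the hinge motion of a
two-domain receptor; ideal helices/strands provide real backbone geometry
for hydrogen-bond and surface-area fixtures; membrane slabs, percent-
deuterium tables and crosslink spectra complete the pipeline inputs. Every
generator stores its ground truth so downstream stages can be checked by
parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from gcgrflex.errors import GcgrflexError, ValidationError
from gcgrflex.geometry import OrientationSeries
from gcgrflex.io import AtomRecord, DomainSpec, Trajectory
from gcgrflex import constants
from gcgrflex.xlms import CrosslinkedPeptide, SpectrumPeak, fragment_ions

_CA_MASS = constants.ELEMENT_MASS["C"]
_CA_RADIUS = constants.BONDI_RADIUS["C"]


# --- hinge trajectories -------------------------------------------------------


@dataclass
class HingeScenario:
    """Prescription for a two-domain hinge trajectory.

    theta/phi (degrees) and d (Å) are per-frame schedules of the mobile
    (ECD-like) blob's centre of mass in the pivot-anchored frame; the fixed
    (7TM-like) blob sits below and beside the pivot so the reference frame is
    well defined. ``jitter`` adds seeded per-atom noise whose per-domain mean
    is removed each frame, so blob centres of mass stay exactly on schedule.
    """

    theta: np.ndarray
    phi: np.ndarray
    d: np.ndarray
    atoms_per_domain: int = 40
    blob_radius: float = 8.0
    tm7_com: tuple[float, float, float] = (6.0, 0.0, -18.0)
    jitter: float = 0.0
    dt_ns: float = 1.0
    seed: int = 0
    membrane_slab: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.theta = np.atleast_1d(np.asarray(self.theta, dtype=float))
        self.phi = np.atleast_1d(np.asarray(self.phi, dtype=float))
        self.d = np.atleast_1d(np.asarray(self.d, dtype=float))
        if not (len(self.theta) == len(self.phi) == len(self.d)):
            raise ValidationError("theta, phi, d schedules must have equal length")

    @property
    def n_frames(self) -> int:
        return len(self.theta)


def _blob_template(n: int, radius: float, rng: np.random.Generator) -> np.ndarray:
    pts = rng.uniform(-radius, radius, size=(n, 3))
    return pts - pts.mean(axis=0)  # centre of (equal-mass) blob exactly at 0


def _ca_atoms(res_ids, chain: str) -> list[AtomRecord]:
    return [
        AtomRecord(
            atom_name="CA",
            element="C",
            residue_name="ALA",
            residue_id=int(rid),
            chain_id=chain,
            mass=_CA_MASS,
            vdw_radius=_CA_RADIUS,
        )
        for rid in res_ids
    ]


def make_hinge_trajectory(
    scenario: HingeScenario,
) -> tuple[Trajectory, OrientationSeries, DomainSpec]:
    """Build the trajectory and return it with the scripted ground truth and
    the matching domain definition (ECD residues 1..n, pivot 144, 7TM
    residues 150..). Frames with theta = 0 carry an undefined azimuth."""
    rng = np.random.default_rng(scenario.seed)
    n = scenario.atoms_per_domain
    ecd_tpl = _blob_template(n, scenario.blob_radius, rng)
    tm7_tpl = _blob_template(n, scenario.blob_radius, rng)
    tm7_com = np.asarray(scenario.tm7_com, dtype=float)
    if np.hypot(tm7_com[0], tm7_com[1]) == 0:
        raise GcgrflexError("7TM blob on the z axis would degenerate the frame")

    atoms = (
        _ca_atoms(range(1, n + 1), "A")  # ECD blob
        + _ca_atoms([144], "A")  # pivot
        + _ca_atoms(range(150, 150 + n), "A")  # 7TM blob
    )
    nf = scenario.n_frames
    coords = np.empty((nf, len(atoms), 3))
    th = np.radians(scenario.theta)
    ph = np.radians(scenario.phi)
    direction = np.column_stack(
        [np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), np.cos(th)]
    )
    for f in range(nf):
        ecd_com = scenario.d[f] * direction[f] + 0.0  # origin at pivot (0,0,0)
        ecd = ecd_tpl + ecd_com
        tm7 = tm7_tpl + tm7_com
        if scenario.jitter > 0:
            for blob in (ecd, tm7):
                noise = rng.normal(0.0, scenario.jitter, size=blob.shape)
                blob += noise - noise.mean(axis=0)
        coords[f, :n] = ecd
        coords[f, n] = (0.0, 0.0, 0.0)
        coords[f, n + 1:] = tm7
    times = scenario.dt_ns * np.arange(nf)
    traj = Trajectory(atoms=atoms, coords=coords, times=times)
    # ground-truth d is the ECD-COM to 7TM-COM distance, not the schedule's
    # pivot distance, because the 7TM blob is offset from the pivot
    truth = OrientationSeries(
        times=times.copy(),
        theta=scenario.theta.copy(),
        phi=np.where(scenario.theta > 0, scenario.phi, np.nan),
        d=np.linalg.norm(scenario.d[:, None] * direction - tm7_com, axis=1),
        phi_defined=scenario.theta > 0,
    )
    domains = DomainSpec(
        ecd=(1, n),
        tm7=(150, 150 + n - 1),
        pivot_residue=144,
        membrane_slab=scenario.membrane_slab,
    )
    return traj, truth, domains


def _smooth_noise(
    rng: np.random.Generator, n: int, amplitude: float, window: int = 15
) -> np.ndarray:
    """Band-limited fluctuation: boxcar-smoothed white noise rescaled to the
    requested amplitude (s.d.)."""
    raw = rng.normal(0.0, 1.0, n + window)
    kern = np.ones(window) / window
    sm = np.convolve(raw, kern, mode="valid")[:n]
    sd = sm.std()
    return amplitude * sm / sd if sd > 0 else np.zeros(n)


def apo_like_scenario(n_frames: int = 600, seed: int = 0) -> HingeScenario:
    """Unliganded-receptor-like schedule: the polar angle rises from ~20 deg
    to ~50 deg over the first quarter of the run, then settles near 42 deg
    (closed-state window), with a stable azimuth near 20 deg."""
    rng = np.random.default_rng(seed)
    rise = max(1, n_frames // 4)
    theta = np.empty(n_frames)
    theta[:rise] = np.linspace(20.0, 50.0, rise)
    theta[rise:] = 42.5 + _smooth_noise(rng, n_frames - rise, 1.2)
    phi = 20.0 + _smooth_noise(rng, n_frames, 1.5)
    d = np.empty(n_frames)
    d[:rise] = np.linspace(44.0, 38.0, rise)
    d[rise:] = 38.0 + _smooth_noise(rng, n_frames - rise, 0.5)
    return HingeScenario(
        theta=np.clip(theta, 1.0, 179.0),
        phi=np.clip(phi, 0.0, 180.0),
        d=d,
        seed=seed + 1,
    )


def bound_like_scenario(n_frames: int = 600, seed: int = 0) -> HingeScenario:
    """Peptide-bound-like schedule: the ECD vibrates upright (theta ~20 deg,
    open-state window) while the azimuth wanders more broadly (25-35 deg)."""
    rng = np.random.default_rng(seed)
    theta = 20.0 + _smooth_noise(rng, n_frames, 1.5)
    phi = 30.0 + _smooth_noise(rng, n_frames, 3.0)
    d = 45.0 + _smooth_noise(rng, n_frames, 0.5)
    return HingeScenario(
        theta=np.clip(theta, 1.0, 179.0),
        phi=np.clip(phi, 0.0, 180.0),
        d=d,
        seed=seed + 1,
    )


# --- ideal secondary-structure fixtures ---------------------------------------

# Engh-Huber-like backbone internal coordinates
_B_NCA, _B_CAC, _B_CN, _B_CO, _B_NH = 1.458, 1.525, 1.329, 1.231, 1.01
_A_NCAC, _A_CACN, _A_CNCA, _A_CACO = 111.2, 116.2, 121.7, 120.8


def _place(a, b, c, bond, angle, torsion):
    """NeRF atom placement from three predecessors and internal coords."""
    ang = np.deg2rad(angle)
    tor = np.deg2rad(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    nrm = np.cross(b - a, bc)
    nrm /= np.linalg.norm(nrm)
    m = np.cross(nrm, bc)
    d2 = np.array(
        [
            -bond * np.cos(ang),
            bond * np.cos(tor) * np.sin(ang),
            bond * np.sin(tor) * np.sin(ang),
        ]
    )
    return c + d2[0] * bc + d2[1] * m + d2[2] * nrm


def make_backbone(
    n_residues: int, phi: float, psi: float, omega: float = 180.0
) -> Trajectory:
    """Polyalanine backbone (N, H, CA, C, O; no H on residue 1) built from
    ideal internal coordinates at the given dihedrals."""
    if n_residues < 2:
        raise GcgrflexError("need at least 2 residues")
    N = [np.array([0.0, 0.0, 0.0])]
    CA = [np.array([_B_NCA, 0.0, 0.0])]
    C = [_place(np.array([0.0, -1.0, 0.0]), N[0], CA[0], _B_CAC, _A_NCAC, 0.0)]
    for i in range(1, n_residues):
        N.append(_place(N[i - 1], CA[i - 1], C[i - 1], _B_CN, _A_CACN, psi))
        CA.append(_place(CA[i - 1], C[i - 1], N[i], _B_NCA, _A_CNCA, omega))
        C.append(_place(C[i - 1], N[i], CA[i], _B_CAC, _A_NCAC, phi))
    O = [
        _place(N[i], CA[i], C[i], _B_CO, _A_CACO, psi + 180.0)
        for i in range(n_residues)
    ]
    # residue 1 gets its amide proton from a virtual preceding carbonyl so
    # every residue is classifiable in accessibility fixtures
    virtual_prev_c = _place(C[0], CA[0], N[0], _B_CN, _A_CNCA, phi)
    prev_c = [virtual_prev_c] + C[:-1]
    H: list[np.ndarray] = []
    for i in range(n_residues):
        u = prev_c[i] - N[i]
        v = CA[i] - N[i]
        u /= np.linalg.norm(u)
        v /= np.linalg.norm(v)
        w = -(u + v)
        H.append(N[i] + _B_NH * w / np.linalg.norm(w))

    atoms, xyz = [], []
    for i in range(n_residues):
        entries = [
            ("N", "N", N[i]),
            ("H", "H", H[i]),
            ("CA", "C", CA[i]),
            ("C", "C", C[i]),
            ("O", "O", O[i]),
        ]
        for name, elem, pos in entries:
            atoms.append(
                AtomRecord(
                    atom_name=name,
                    element=elem,
                    residue_name="ALA",
                    residue_id=i + 1,
                    chain_id="A",
                    mass=constants.ELEMENT_MASS[elem],
                    vdw_radius=constants.BONDI_RADIUS[elem],
                )
            )
            xyz.append(pos)
    coords = np.asarray(xyz)[None, :, :]
    return Trajectory(atoms=atoms, coords=coords, times=np.array([0.0]))


def make_ideal_helix(n_residues: int) -> Trajectory:
    """Canonical alpha helix (~1.5 Å rise, ~100 deg twist per residue) whose
    i -> i-4 NH...O pairs satisfy the 0.35 nm / 30 deg hydrogen-bond
    criteria; residues 1-4 donate no helical hydrogen bond."""
    if n_residues < 5:
        raise GcgrflexError("an alpha helix fixture needs at least 5 residues")
    return make_backbone(n_residues, phi=-57.0, psi=-47.0)


def make_extended_strand(n_residues: int) -> Trajectory:
    """Fully extended strand: no main-chain hydrogen bonds."""
    return make_backbone(n_residues, phi=-139.0, psi=135.0)


# --- membrane slab ------------------------------------------------------------


def make_membrane_slab(
    z_lo: float,
    z_hi: float,
    n_atoms: int = 64,
    xy_extent: float = 30.0,
    seed: int = 0,
) -> tuple[list[AtomRecord], np.ndarray]:
    """Lipid pseudo-atoms (phosphate-like P records) filling two leaflets at
    the slab boundaries; used for slab estimation and as trajectory dressing."""
    if not z_lo < z_hi:
        raise ValidationError(f"inverted slab bounds ({z_lo}, {z_hi})")
    rng = np.random.default_rng(seed)
    xy = rng.uniform(-xy_extent, xy_extent, size=(n_atoms, 2))
    z = np.where(
        np.arange(n_atoms) % 2 == 0,
        rng.normal(z_lo, 0.5, n_atoms),
        rng.normal(z_hi, 0.5, n_atoms),
    )
    coords = np.column_stack([xy, z])
    atoms = [
        AtomRecord(
            atom_name="P",
            element="P",
            residue_name="POP",
            residue_id=1000 + i,
            chain_id="L",
            mass=constants.ELEMENT_MASS["P"],
            vdw_radius=constants.BONDI_RADIUS["P"],
        )
        for i in range(n_atoms)
    ]
    return atoms, coords


def add_membrane_slab(
    traj: Trajectory, z_lo: float, z_hi: float, n_atoms: int = 64, seed: int = 0
) -> Trajectory:
    """Append lipid pseudo-atoms (static across frames) to a trajectory."""
    atoms, coords = make_membrane_slab(z_lo, z_hi, n_atoms, seed=seed)
    lipid = np.broadcast_to(coords, (traj.n_frames,) + coords.shape)
    return Trajectory(
        atoms=traj.atoms + atoms,
        coords=np.concatenate([traj.coords, lipid], axis=1),
        times=traj.times.copy(),
        missing_amide_h=traj.missing_amide_h,
    )


def estimate_slab_from_lipids(
    traj: Trajectory, lo_pct: float = 10.0, hi_pct: float = 90.0
) -> tuple[float, float]:
    """Slab bounds as percentiles of lipid-atom z over all frames."""
    from gcgrflex.io import AMINO_ACIDS_3

    lipid = np.array([a.residue_name not in AMINO_ACIDS_3 for a in traj.atoms])
    if not lipid.any():
        raise GcgrflexError("no lipid atoms to estimate a slab from")
    z = traj.coords[:, lipid, 2].ravel()
    return float(np.percentile(z, lo_pct)), float(np.percentile(z, hi_pct))


# --- elastic-network hinge fixture --------------------------------------------


def make_hinge_structure(
    half_length: float = 20.0,
    spacing: float = 4.0,
    half_width: float = 2.5,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-segment Calpha pseudo-structure for hinge-mode analysis: a solid
    square-section beam along z with jittered nodes. A solid beam (unlike a
    thin-necked dumbbell, whose neck acts as a zero-energy pin joint in a
    central-force network) has exactly six rigid modes, and its lowest
    internal modes are the two transverse bending motions. Returns (coords,
    labels) with labels 0 (lower segment), 1 (junction) and 2 (upper
    segment)."""
    rng = np.random.default_rng(seed)
    pts = [
        [x, y, z]
        for z in np.arange(-half_length, half_length + 0.1, spacing)
        for x in (-half_width, half_width)
        for y in (-half_width, half_width)
    ]
    coords = np.asarray(pts) + rng.normal(0.0, 0.3, (len(pts), 3))
    labels = np.where(
        coords[:, 2] > spacing / 2, 2, np.where(coords[:, 2] < -spacing / 2, 0, 1)
    ).astype(int)
    return coords, labels


def bend_hinge(
    coords: np.ndarray, labels: np.ndarray, angle_deg: float, axis=(1.0, 0.0, 0.0)
) -> np.ndarray:
    """Rotate the upper blob (label 2) about the origin by the given angle —
    the hinge-bending displacement used to probe mode overlaps."""
    from scipy.spatial.transform import Rotation

    rot = Rotation.from_rotvec(
        np.radians(angle_deg) * np.asarray(axis, dtype=float)
    )
    out = coords.copy()
    mask = labels == 2
    out[mask] = rot.apply(coords[mask])
    return out


# --- tables and spectra -------------------------------------------------------

#: Percent-deuterium fixture content: six receptor regions at a 10-s
#: timepoint under an ECD-free condition and a peptide-bound condition.
_HDX_FIXTURE_ROWS = [
    ("ECD", "FLFEKWKL", 31, 38, "NNC2648", 13.3, 5.9),
    ("ECD", "FLFEKWKL", 31, 38, "peptide", 3.8, 5.4),
    ("Stalk", "IEVQKEVAKM", 128, 137, "NNC2648", 59.6, 14.6),
    ("Stalk", "IEVQKEVAKM", 128, 137, "peptide", 6.5, 6.2),
    ("ECL1", "LRTRYSQKIGDDL", 198, 210, "NNC2648", 45.8, 3.3),
    ("ECL1", "LRTRYSQKIGDDL", 198, 210, "peptide", 27.2, 2.2),
    ("ICL2", "ATLPERSF", 256, 263, "NNC2648", 67.9, 8.9),
    ("ICL2", "ATLPERSF", 256, 263, "peptide", 56.3, 3.3),
    ("TM6", "AKSTLTL", 348, 354, "NNC2648", 2.7, 0.3),
    ("TM6", "AKSTLTL", 348, 354, "peptide", 3.2, 2.9),
    ("ECL3", "FVTDEHAQGTLRSAKL", 367, 382, "NNC2648", 44.6, 4.2),
    ("ECL3", "FVTDEHAQGTLRSAKL", 367, 382, "peptide", 36.3, 2.5),
]


def make_hdx_fixture(rows=None) -> pd.DataFrame:
    """Percent-deuterium table fixture (default: the six-region receptor
    dataset at 10 s)."""
    rows = _HDX_FIXTURE_ROWS if rows is None else rows
    df = pd.DataFrame(
        rows,
        columns=[
            "region", "peptide", "span_start", "span_end", "condition",
            "percent", "sd",
        ],
    )
    if ((df["percent"] < 0) | (df["percent"] > 100)).any():
        raise ValidationError("percent outside [0, 100]")
    return df


def make_xl_spectrum(
    xl: CrosslinkedPeptide,
    charges=(1,),
    include=None,
    n_noise: int = 0,
    seed: int = 0,
    mz_range: tuple[float, float] = (150.0, 2000.0),
) -> list[SpectrumPeak]:
    """Synthetic fragment spectrum: exactly the requested theoretical ions
    (``include`` = iterable of (chain, series family, index); None = all)
    plus seeded uniform noise peaks kept > 50 ppm away from every
    theoretical ion."""
    rng = np.random.default_rng(seed)
    theo = fragment_ions(xl, charges)
    if include is not None:
        wanted = {(c, s.lower(), i) for c, s, i in include}
        selected = [
            ion
            for ion in theo
            if (ion.chain, ion.series.lower(), ion.index) in wanted
        ]
    else:
        selected = list(theo)
    peaks = [
        SpectrumPeak(mz=ion.mz, intensity=float(rng.uniform(0.2, 1.0)))
        for ion in selected
    ]
    all_theo_mz = np.array([ion.mz for ion in theo])
    added = 0
    while added < n_noise:
        cand = float(rng.uniform(*mz_range))
        if np.min(np.abs(all_theo_mz - cand) / all_theo_mz) * 1e6 > 50.0:
            peaks.append(SpectrumPeak(mz=cand, intensity=float(rng.uniform(0.05, 0.3))))
            added += 1
    peaks.sort(key=lambda p: p.mz)
    return peaks
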