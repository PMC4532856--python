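"""Amide-proton accessibility prediction for comparison with HDX-MS.

A backbone amide proton is called *inaccessible* in a snapshot when any of
three criteria holds:

1. its NH group donates a hydrogen bond to another protein atom
   (donor-acceptor distance <= 0.35 nm and acceptor-donor-hydrogen angle
   <= 30 deg, the geometric convention of common trajectory tools);
2. it is buried, i.e. its solvent-accessible surface area (probe 1.4 Å)
   does not exceed a small threshold;
3. it is exposed only to the lipid bilayer interface, operationalised as
   the proton's z coordinate lying inside a configured membrane slab.

Percentages of accessible amide protons, aggregated per sequence region over
trajectory snapshots, are directly comparable to percent-deuterium uptake at
short exchange times.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from gcgrflex.errors import ConfigurationError, GcgrflexError
from gcgrflex.io import AMINO_ACIDS_3, DomainSpec, Trajectory

#: Amide N-H bond length used when reconstructing missing protons, Å.
NH_BOND = 1.01


@dataclass(frozen=True)
class AccessibilityConfig:
    """Tunable thresholds of the classifier (defaults follow the standard
    trajectory-analysis conventions)."""

    hbond_distance_cutoff: float = 3.5  # Å (0.35 nm), donor N to acceptor
    hbond_angle_cutoff: float = 30.0  # deg, acceptor-donor-hydrogen
    angle_convention: str = "ADH"  # or "DHA" (donor-H...acceptor >= 150 deg)
    dha_angle_cutoff: float = 150.0  # deg, used when angle_convention == "DHA"
    probe_radius: float = 1.4  # Å, water probe
    n_sphere_points: int = 960  # Shrake-Rupley quadrature points
    buried_sasa_threshold: float = 0.01  # Å², criterion (2)
    snapshot_interval: float = 0.1  # ns between analysed snapshots (100 ps)
    analysis_window: float = 500.0  # ns, trajectory tail analysed
    heavy_atoms_only: bool = False  # drop input hydrogens from occlusion set

    def __post_init__(self) -> None:
        for name in (
            "hbond_distance_cutoff", "hbond_angle_cutoff", "probe_radius",
            "n_sphere_points", "buried_sasa_threshold", "snapshot_interval",
            "analysis_window",
        ):
            if not getattr(self, name) > 0:
                raise ConfigurationError(f"{name} must be positive")


@dataclass
class AmideRecord:
    """Classification of one backbone amide proton in one snapshot."""

    residue_id: int
    chain_id: str
    time: float
    hbonded: bool
    sasa: float
    lipid_only: bool
    accessible: bool


@dataclass
class RegionAccessibility:
    """Percent accessible amide protons of one region, mean +/- s.d. over
    snapshots."""

    region: str
    span: tuple[int, int]
    mean_percent: float
    sd: float
    n_snapshots: int
    n_residues: int


# --- topology helpers ---------------------------------------------------------


@dataclass
class _Backbone:
    """Per-residue backbone atom indices; ``h`` is None when the proton has
    to be reconstructed, ``prev_c`` indexes the preceding residue's carbonyl
    carbon (needed for that reconstruction)."""

    key: tuple[str, int]
    n: int
    ca: int
    c: int | None
    h: int | None
    prev_c: int | None
    is_proline: bool


def _index_backbone(traj: Trajectory) -> list[_Backbone]:
    by_res: dict[tuple[str, int], dict[str, int]] = {}
    resname: dict[tuple[str, int], str] = {}
    order: list[tuple[str, int]] = []
    for i, a in enumerate(traj.atoms):
        if a.residue_name not in AMINO_ACIDS_3:
            continue
        key = (a.chain_id, a.residue_id)
        if key not in by_res:
            by_res[key] = {}
            order.append(key)
            resname[key] = a.residue_name
        if a.atom_name in ("N", "CA", "C", "H", "HN", "H1"):
            by_res[key].setdefault(
                "H" if a.atom_name in ("HN", "H1") else a.atom_name, i
            )
    out = []
    for pos, key in enumerate(order):
        d = by_res[key]
        if "N" not in d or "CA" not in d:
            continue
        prev_c = None
        if pos > 0:
            chain_prev, rid_prev = order[pos - 1]
            if chain_prev == key[0] and rid_prev == key[1] - 1:
                prev_c = by_res[order[pos - 1]].get("C")
        out.append(
            _Backbone(
                key=key,
                n=d["N"],
                ca=d["CA"],
                c=d.get("C"),
                h=d.get("H"),
                prev_c=prev_c,
                is_proline=resname[key] == "PRO",
            )
        )
    return out


def reconstruct_amide_h(
    coords: np.ndarray, bb: _Backbone
) -> np.ndarray | None:
    """Place the missing amide proton on N along the outward bisector of the
    C(prev)-N and CA-N directions, 1.01 Å from N. Returns None when the
    preceding carbonyl carbon is unavailable (chain start)."""
    if bb.prev_c is None:
        return None
    n = coords[bb.n]
    u = coords[bb.prev_c] - n
    v = coords[bb.ca] - n
    u /= np.linalg.norm(u)
    v /= np.linalg.norm(v)
    w = -(u + v)
    norm = np.linalg.norm(w)
    if norm == 0:
        return None
    return n + NH_BOND * w / norm


def _amide_positions(
    traj: Trajectory, coords: np.ndarray
) -> dict[tuple[str, int], tuple[int, np.ndarray]]:
    """Map residue key -> (N atom index, amide H position); prolines and
    unreconstructable chain starts are omitted."""
    out = {}
    for bb in _index_backbone(traj):
        if bb.is_proline:
            continue
        if bb.h is not None:
            out[bb.key] = (bb.n, coords[bb.h])
        else:
            h = reconstruct_amide_h(coords, bb)
            if h is not None:
                out[bb.key] = (bb.n, h)
    return out


def _protein_mask(traj: Trajectory) -> np.ndarray:
    return np.array([a.residue_name in AMINO_ACIDS_3 for a in traj.atoms])


# --- hydrogen bonds -----------------------------------------------------------


def detect_mainchain_hbonds(
    traj: Trajectory,
    frame_index: int = 0,
    config: AccessibilityConfig = AccessibilityConfig(),
) -> dict[tuple[str, int], bool | None]:
    """Flag every backbone NH donating a hydrogen bond to any other protein
    N/O atom. Prolines (no NH) map to None.

    Acceptors exclude the donor residue's own atoms; covalently adjacent
    atoms such as the preceding carbonyl oxygen are rejected by the angle
    criterion itself.
    """
    coords = traj.coords[frame_index]
    amides = _amide_positions(traj, coords)
    protein = _protein_mask(traj)
    acc_mask = protein & np.array(
        [a.element in ("N", "O") for a in traj.atoms]
    )
    acc_idx = np.flatnonzero(acc_mask)
    acc_res = np.array(
        [(traj.atoms[i].chain_id, traj.atoms[i].residue_id) for i in acc_idx],
        dtype=object,
    )
    tree = cKDTree(coords[acc_idx])
    result: dict[tuple[str, int], bool | None] = {}
    for bb in _index_backbone(traj):
        if bb.is_proline:
            result[bb.key] = None
            continue
        if bb.key not in amides:
            result[bb.key] = None
            continue
        n_idx, h_pos = amides[bb.key]
        n_pos = coords[n_idx]
        nh = h_pos - n_pos
        nh /= np.linalg.norm(nh)
        hbonded = False
        for j in tree.query_ball_point(n_pos, config.hbond_distance_cutoff):
            if tuple(acc_res[j]) == bb.key:
                continue
            na = coords[acc_idx[j]] - n_pos
            dist = np.linalg.norm(na)
            if dist == 0 or dist > config.hbond_distance_cutoff:
                continue
            if config.angle_convention == "ADH":
                cosang = np.clip(np.dot(na / dist, nh), -1.0, 1.0)
                ok = np.degrees(np.arccos(cosang)) <= config.hbond_angle_cutoff
            else:  # DHA: angle at H between H->D and H->A
                hd = n_pos - h_pos
                ha = coords[acc_idx[j]] - h_pos
                cosang = np.clip(
                    np.dot(hd, ha) / (np.linalg.norm(hd) * np.linalg.norm(ha)),
                    -1.0, 1.0,
                )
                ok = np.degrees(np.arccos(cosang)) >= config.dha_angle_cutoff
            if ok:
                hbonded = True
                break
        result[bb.key] = hbonded
    return result


# --- solvent accessible surface area ------------------------------------------


def sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere point set (golden spiral)."""
    i = np.arange(n, dtype=float) + 0.5
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    golden = math.pi * (3.0 - math.sqrt(5.0))
    phi = golden * i
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def sasa_per_atom(
    coords: np.ndarray,
    radii: np.ndarray,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> np.ndarray:
    """Shrake-Rupley numerical SASA, Å² per atom.

    Test points on each atom's expanded sphere (r + probe) count as exposed
    when outside every other atom's expanded sphere. The fixed point set
    makes results bit-for-bit reproducible.
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    n_atoms = len(coords)
    pts = sphere_points(n_points)
    expanded = radii + probe_radius
    tree = cKDTree(coords)
    out = np.zeros(n_atoms)
    max_r = expanded.max()
    for i in range(n_atoms):
        r_i = expanded[i]
        test = coords[i] + r_i * pts
        neighbors = [
            j
            for j in tree.query_ball_point(coords[i], r_i + max_r)
            if j != i
            and np.linalg.norm(coords[j] - coords[i]) < r_i + expanded[j]
        ]
        if neighbors:
            diff = test[:, None, :] - coords[neighbors][None, :, :]
            inside = (
                (diff ** 2).sum(axis=2) < (expanded[neighbors] ** 2)[None, :]
            ).any(axis=1)
            exposed = int((~inside).sum())
        else:
            exposed = n_points
        out[i] = 4.0 * math.pi * r_i * r_i * exposed / n_points
    return out


def amide_sasa(
    traj: Trajectory,
    frame_index: int = 0,
    config: AccessibilityConfig = AccessibilityConfig(),
) -> dict[tuple[str, int], float]:
    """SASA of every backbone amide proton in one snapshot.

    Occluders are all protein atoms (optionally heavy atoms only) plus the
    reconstructed amide protons themselves; non-protein (lipid) atoms do not
    occlude — the bilayer is handled by the slab criterion instead.
    """
    coords = traj.coords[frame_index]
    protein = _protein_mask(traj)
    occlude = protein.copy()
    if config.heavy_atoms_only:
        occlude &= np.array([a.element != "H" for a in traj.atoms])
    amides = _amide_positions(traj, coords)
    base_coords = coords[occlude]
    base_radii = traj.vdw_radii[occlude]
    occluded_atom_idx = np.flatnonzero(occlude)
    pos_in_base = {int(g): k for k, g in enumerate(occluded_atom_idx)}

    topo_h = {
        bb.key: bb.h
        for bb in _index_backbone(traj)
        if bb.h is not None and occlude[bb.h]
    }
    extra_coords, extra_radii, h_rows = [], [], {}
    h_radius = 1.20  # Bondi hydrogen
    for key in amides:
        n_idx, h_pos = amides[key]
        if key in topo_h:  # topology H already occluding: reuse its row
            h_rows[key] = pos_in_base[topo_h[key]]
        else:
            h_rows[key] = len(base_coords) + len(extra_coords)
            extra_coords.append(h_pos)
            extra_radii.append(h_radius)
    all_coords = (
        np.vstack([base_coords, np.array(extra_coords)])
        if extra_coords
        else base_coords
    )
    all_radii = (
        np.concatenate([base_radii, np.array(extra_radii)])
        if extra_radii
        else base_radii
    )
    sasa = sasa_per_atom(
        all_coords, all_radii, config.probe_radius, config.n_sphere_points
    )
    return {key: float(sasa[row]) for key, row in h_rows.items()}


# --- classification and aggregation -------------------------------------------


def _has_lipids(traj: Trajectory) -> bool:
    return bool((~_protein_mask(traj)).any())


def classify_frame(
    traj: Trajectory,
    frame_index: int,
    domains: DomainSpec,
    config: AccessibilityConfig = AccessibilityConfig(),
) -> list[AmideRecord]:
    """Apply all three criteria to every classifiable amide in one frame."""
    if _has_lipids(traj) and domains.membrane_slab is None:
        raise ConfigurationError(
            "lipid atoms present but no membrane slab configured"
        )
    coords = traj.coords[frame_index]
    hbonds = detect_mainchain_hbonds(traj, frame_index, config)
    sasa = amide_sasa(traj, frame_index, config)
    amides = _amide_positions(traj, coords)
    time = float(traj.times[frame_index])
    records = []
    for key, (n_idx, h_pos) in amides.items():
        hb = bool(hbonds.get(key))
        s = sasa[key]
        exposed = s > config.buried_sasa_threshold
        lipid_only = False
        if domains.membrane_slab is not None and exposed and not hb:
            z_lo, z_hi = domains.membrane_slab
            lipid_only = z_lo <= h_pos[2] <= z_hi
        records.append(
            AmideRecord(
                residue_id=key[1],
                chain_id=key[0],
                time=time,
                hbonded=hb,
                sasa=s,
                lipid_only=lipid_only,
                accessible=(not hb) and exposed and (not lipid_only),
            )
        )
    return records


def classify_amide(
    traj: Trajectory,
    residue_id: int,
    domains: DomainSpec,
    config: AccessibilityConfig = AccessibilityConfig(),
    frame_index: int = 0,
    chain_id: str | None = None,
) -> AmideRecord:
    """Classification of a single residue's amide in one frame."""
    for rec in classify_frame(traj, frame_index, domains, config):
        if rec.residue_id == residue_id and (
            chain_id is None or rec.chain_id == chain_id
        ):
            return rec
    raise GcgrflexError(f"residue {residue_id} has no classifiable amide")


def _snapshot_indices(traj: Trajectory, config: AccessibilityConfig) -> list[int]:
    t_end = traj.times[-1]
    tail = traj.times >= t_end - config.analysis_window
    idx = np.flatnonzero(tail)
    if len(idx) > 1:
        dt = float(np.median(np.diff(traj.times[idx])))
        stride = max(1, int(round(config.snapshot_interval / dt)))
        idx = idx[::stride]
    return list(idx)


def aggregate_accessibility(
    traj: Trajectory,
    domains: DomainSpec,
    regions: list[tuple[str, tuple[int, int]]],
    config: AccessibilityConfig = AccessibilityConfig(),
) -> list[RegionAccessibility]:
    """Percent accessible amide protons per region, mean ± s.d. across
    snapshots sampled at ``snapshot_interval`` over the trajectory tail."""
    snaps = _snapshot_indices(traj, config)
    per_region: dict[str, list[float]] = {label: [] for label, _ in regions}
    n_res: dict[str, int] = {}
    for fi in snaps:
        records = classify_frame(traj, fi, domains, config)
        by_res = {(r.chain_id, r.residue_id): r for r in records}
        for label, (lo, hi) in regions:
            in_span = [
                r for (c, rid), r in by_res.items() if lo <= rid <= hi
            ]
            if not in_span:
                raise GcgrflexError(
                    f"region {label!r} ({lo}-{hi}) has no classifiable residues"
                )
            n_res[label] = len(in_span)
            per_region[label].append(
                100.0 * sum(r.accessible for r in in_span) / len(in_span)
            )
    return [
        RegionAccessibility(
            region=label,
            span=span,
            mean_percent=float(np.mean(per_region[label])),
            sd=float(np.std(per_region[label], ddof=0)),
            n_snapshots=len(snaps),
            n_residues=n_res[label],
        )
        for label, span in regions
    ]


def compare_to_hdx(
    predicted_apo: list[RegionAccessibility],
    predicted_bound: list[RegionAccessibility],
    hdx,
    condition_apo_like: str,
    condition_bound_like: str,
):
    """Side-by-side table of predicted accessibility vs measured percent
    deuterium, with a sign-concordance flag.

    ``condition_apo_like`` names the HDX condition expected to track the apo
    simulation (e.g. a small-molecule-bound receptor whose ECD is free) and
    ``condition_bound_like`` the peptide-bound condition. Concordant means
    the predicted apo-bound difference shares the sign of the measured
    difference; regions with a zero predicted difference are flagged None;
    unmatched regions are listed with NaN, never dropped.
    """
    import pandas as pd

    pa = {r.region: r for r in predicted_apo}
    pb = {r.region: r for r in predicted_bound}
    ha = hdx[hdx["condition"] == condition_apo_like].set_index("region")
    hb = hdx[hdx["condition"] == condition_bound_like].set_index("region")
    regions = sorted(
        set(pa) | set(pb) | set(ha.index) | set(hb.index),
        key=lambda r: (r not in pa, r),
    )
    rows = []
    for region in regions:
        pred_a = pa[region].mean_percent if region in pa else float("nan")
        pred_b = pb[region].mean_percent if region in pb else float("nan")
        meas_a = float(ha.loc[region, "percent"]) if region in ha.index else float("nan")
        meas_b = float(hb.loc[region, "percent"]) if region in hb.index else float("nan")
        pred_delta = pred_a - pred_b
        hdx_delta = meas_a - meas_b
        if any(math.isnan(v) for v in (pred_delta, hdx_delta)):
            concordant = None
            matched = False
        else:
            matched = True
            if pred_delta == 0 or hdx_delta == 0:
                concordant = None
            else:
                concordant = (pred_delta > 0) == (hdx_delta > 0)
        rows.append(
            dict(
                region=region,
                predicted_apo=pred_a,
                predicted_bound=pred_b,
                hdx_apo_like=meas_a,
                hdx_bound_like=meas_b,
                predicted_delta=pred_delta,
                hdx_delta=hdx_delta,
                matched=matched,
                concordant=concordant,
            )
        )
    return pd.DataFrame(rows)
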