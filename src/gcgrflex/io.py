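"""Structure, trajectory, table and configuration I/O plus atom selection.

Coordinate files follow the standard PDB multi-model dialect (one MODEL per
trajectory snapshot), coordinates in Angstrom, residue ids 1-based. Parsing
and writing go through :mod:`biotite.structure.io.pdb`; this module wraps them
in the package's domain types and error taxonomy.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from biotite.structure import AtomArrayStack
from biotite.structure.io.pdb import PDBFile

from gcgrflex import constants
from gcgrflex.errors import (
    ConfigurationError,
    EmptySelectionError,
    ParseError,
    StructuralError,
    ValidationError,
)

AMINO_ACIDS_3 = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}
_AMIDE_H_NAMES = {"H", "HN", "H1"}


@dataclass(frozen=True)
class AtomRecord:
    """One topology atom; per-frame coordinates live on the Trajectory."""

    atom_name: str
    element: str
    residue_name: str
    residue_id: int
    chain_id: str
    mass: float
    vdw_radius: float

    def __post_init__(self) -> None:
        if not self.mass > 0:
            raise ValidationError(f"atom {self.atom_name}: mass must be > 0")
        if not self.vdw_radius > 0:
            raise ValidationError(f"atom {self.atom_name}: vdW radius must be > 0")


@dataclass
class Trajectory:
    """Topology plus per-frame coordinates and times (ns).

    ``coords`` has shape (n_frames, n_atoms, 3) in Angstrom. ``times`` is
    strictly increasing. ``missing_amide_h`` lists residues whose backbone N
    has no attached hydrogen in the input (reconstructed downstream).
    """

    atoms: list[AtomRecord]
    coords: np.ndarray
    times: np.ndarray
    missing_amide_h: frozenset[tuple[str, int]] = frozenset()

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise StructuralError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != len(self.atoms):
            raise StructuralError(
                f"{self.coords.shape[1]} coordinates per frame for "
                f"{len(self.atoms)} topology atoms"
            )
        if not np.isfinite(self.coords).all():
            raise ValidationError("non-finite coordinate")
        if len(self.times) != self.coords.shape[0]:
            raise StructuralError("one time per frame required")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValidationError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms])

    @property
    def vdw_radii(self) -> np.ndarray:
        return np.array([a.vdw_radius for a in self.atoms])

    def frame(self, i: int) -> np.ndarray:
        return self.coords[i]

    def residue_ids(self) -> np.ndarray:
        return np.array([a.residue_id for a in self.atoms])


@dataclass
class DomainSpec:
    """Residue ranges (inclusive, 1-based) defining the receptor domains.

    The pivot residue is the hinge about which the extracellular domain (ECD)
    reorients relative to the seven-transmembrane (7TM) bundle; default 144
    (the methionine at the base of the TM1 stalk). ``membrane_slab`` is an
    optional (z_lo, z_hi) interval in Angstrom marking the bilayer interface.
    """

    ecd: tuple[int, int]
    tm7: tuple[int, int]
    stalk: tuple[int, int] | None = None
    ligand: tuple[int, int] | None = None
    pivot_residue: int = 144
    membrane_slab: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        ranges = {"ecd": self.ecd, "tm7": self.tm7}
        if self.stalk is not None:
            ranges["stalk"] = self.stalk
        if self.ligand is not None:
            ranges["ligand"] = self.ligand
        for name, (lo, hi) in ranges.items():
            if lo > hi:
                raise ValidationError(f"range {name} is inverted: {lo} > {hi}")
        items = sorted(ranges.items(), key=lambda kv: kv[1][0])
        for (na, ra), (nb, rb) in zip(items, items[1:]):
            if ra[1] >= rb[0]:
                raise ValidationError(f"ranges {na} and {nb} overlap")
        if self.membrane_slab is not None and not (
            self.membrane_slab[0] < self.membrane_slab[1]
        ):
            raise ValidationError("membrane slab bounds inverted")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}

    @classmethod
    def from_dict(cls, d: dict) -> "DomainSpec":
        kw = dict(d)
        for key in ("ecd", "tm7", "stalk", "ligand", "membrane_slab"):
            if kw.get(key) is not None:
                kw[key] = tuple(kw[key])
        return cls(**kw)


def load_config(path: str | Path) -> dict:
    """Read a YAML analysis config; the ``domains`` key becomes a DomainSpec."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if "domains" in cfg:
        cfg["domains"] = DomainSpec.from_dict(cfg["domains"])
    return cfg


def save_config(cfg: dict, path: str | Path) -> None:
    out = dict(cfg)
    if isinstance(out.get("domains"), DomainSpec):
        out["domains"] = out["domains"].to_dict()
    with open(path, "w") as fh:
        yaml.safe_dump(out, fh, sort_keys=False)


# --- PDB multi-model trajectories --------------------------------------------


def _prevalidate_pdb(path: Path) -> None:
    """Cheap line scan so parse errors can name the offending line."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM", "HETATM")):
                if len(line.rstrip("\n")) < 54:
                    raise ParseError(f"{path}:{lineno}: truncated coordinate record")
                try:
                    for lo, hi in ((30, 38), (38, 46), (46, 54)):
                        float(line[lo:hi])
                except ValueError:
                    raise ParseError(
                        f"{path}:{lineno}: unreadable coordinates in record "
                        f"{line[:26].rstrip()!r}"
                    ) from None


def _atoms_from_array(arr) -> list[AtomRecord]:
    records = []
    for name, elem, res_name, res_id, chain in zip(
        arr.atom_name, arr.element, arr.res_name, arr.res_id, arr.chain_id
    ):
        element = str(elem).upper().strip() or constants.element_of(str(name))
        mass = constants.ELEMENT_MASS.get(element)
        radius = constants.BONDI_RADIUS.get(element)
        if mass is None or radius is None:
            mass = constants.ELEMENT_MASS[constants.DEFAULT_ELEMENT]
            radius = constants.BONDI_RADIUS[constants.DEFAULT_ELEMENT]
        records.append(
            AtomRecord(
                atom_name=str(name),
                element=element,
                residue_name=str(res_name),
                residue_id=int(res_id),
                chain_id=str(chain),
                mass=mass,
                vdw_radius=radius,
            )
        )
    return records


def _find_missing_amide_h(atoms: list[AtomRecord]) -> frozenset[tuple[str, int]]:
    has_n: set[tuple[str, int]] = set()
    has_h: set[tuple[str, int]] = set()
    for a in atoms:
        if a.residue_name not in AMINO_ACIDS_3 or a.residue_name == "PRO":
            continue
        key = (a.chain_id, a.residue_id)
        if a.atom_name == "N":
            has_n.add(key)
        elif a.atom_name in _AMIDE_H_NAMES:
            has_h.add(key)
    return frozenset(has_n - has_h)


def read_trajectory(
    path: str | Path, times_ns: np.ndarray | None = None
) -> Trajectory:
    """Read a multi-model PDB file as a trajectory.

    Every MODEL must contain the same atoms in the same order. When the file
    carries no time annotation, frames default to 0, 1, 2, ... ns.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _prevalidate_pdb(path)
    pdb = PDBFile.read(str(path))
    try:
        stack = pdb.get_structure()  # AtomArrayStack over all models
    except Exception as exc:  # biotite raises InvalidFileError subclasses
        raise StructuralError(
            f"{path}: inconsistent models ({exc})"
        ) from exc
    if not isinstance(stack, AtomArrayStack):
        stack = AtomArrayStack.from_arrays([stack])
    atoms = _atoms_from_array(stack[0])
    coords = np.asarray(stack.coord, dtype=float)
    if times_ns is None:
        times_ns = np.arange(coords.shape[0], dtype=float)
    return Trajectory(
        atoms=atoms,
        coords=coords,
        times=times_ns,
        missing_amide_h=_find_missing_amide_h(atoms),
    )


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as a multi-model PDB file (inverse of read)."""
    import biotite.structure as struc

    n = traj.n_atoms
    arr = struc.AtomArray(n)
    arr.atom_name = np.array([a.atom_name for a in traj.atoms])
    arr.element = np.array([a.element for a in traj.atoms])
    arr.res_name = np.array([a.residue_name for a in traj.atoms])
    arr.res_id = np.array([a.residue_id for a in traj.atoms])
    arr.chain_id = np.array([a.chain_id for a in traj.atoms])
    arr.hetero = np.array(
        [a.residue_name not in AMINO_ACIDS_3 for a in traj.atoms]
    )
    stack = struc.stack([arr] * traj.n_frames)
    stack.coord = np.asarray(traj.coords, dtype=np.float32)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


# --- selection ----------------------------------------------------------------


def select(
    traj: Trajectory,
    residue_ids=None,
    residue_range: tuple[int, int] | None = None,
    atom_names=None,
    chain_id: str | None = None,
    element: str | None = None,
) -> np.ndarray:
    """Return topology-ordered, duplicate-free atom indices matching all
    given criteria. Raises :class:`EmptySelectionError` on an empty match.
    """
    mask = np.ones(traj.n_atoms, dtype=bool)
    if residue_ids is not None:
        wanted = set(int(r) for r in np.atleast_1d(residue_ids))
        mask &= np.array([a.residue_id in wanted for a in traj.atoms])
    if residue_range is not None:
        lo, hi = residue_range
        mask &= np.array([lo <= a.residue_id <= hi for a in traj.atoms])
    if atom_names is not None:
        names = {str(n) for n in np.atleast_1d(atom_names)}
        mask &= np.array([a.atom_name in names for a in traj.atoms])
    if chain_id is not None:
        mask &= np.array([a.chain_id == chain_id for a in traj.atoms])
    if element is not None:
        mask &= np.array([a.element == element.upper() for a in traj.atoms])
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise EmptySelectionError(
            "selection matched no atoms "
            f"(residue_ids={residue_ids}, residue_range={residue_range}, "
            f"atom_names={atom_names}, chain_id={chain_id}, element={element})"
        )
    return idx


# --- HDX tables and reports ---------------------------------------------------

HDX_COLUMNS = ["region", "peptide", "span_start", "span_end", "condition",
               "percent", "sd"]


def read_hdx_table(path: str | Path) -> pd.DataFrame:
    """Read a delimited percent-deuterium table.

    Expected columns: region, peptide, span_start, span_end, condition,
    percent, sd — one row per (region, condition) at a single exchange
    timepoint. Percent values outside [0, 100] raise ValidationError.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    missing = set(HDX_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    df = df[HDX_COLUMNS].copy()
    df["span_start"] = df["span_start"].astype(int)
    df["span_end"] = df["span_end"].astype(int)
    for col in ("percent", "sd"):
        df[col] = df[col].astype(float)
    bad = df[(df["percent"] < 0) | (df["percent"] > 100)]
    if len(bad):
        raise ValidationError(
            f"percent deuterium outside [0, 100] in rows {bad.index.tolist()}"
        )
    spans = df["span_end"] - df["span_start"] + 1
    mism = df[spans != df["peptide"].str.len()]
    if len(mism):
        raise ValidationError(
            f"residue span does not match peptide length in rows {mism.index.tolist()}"
        )
    return df


def write_report(table: pd.DataFrame, path: str | Path) -> None:
    """Write any tabular report as TSV (lossless float round-trip)."""
    table.to_csv(path, sep="\t", index=False)


def write_hdx_table(df: pd.DataFrame, path: str | Path) -> None:
    write_report(df[HDX_COLUMNS], path)
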