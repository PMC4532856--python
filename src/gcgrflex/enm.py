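"""Elastic-network (Tirion) normal-mode analysis on Calpha coordinates.

Nodes are Calpha atoms joined by uniform harmonic springs within a distance
cutoff Rc (default 12 Å). The Hessian of the network potential is block
structured: for a connected pair (i, j) the off-diagonal 3x3 super-block is
-gamma * r_hat r_hat^T along the equilibrium bond direction, and diagonal
blocks are the negative sums of the off-diagonal blocks in their row, which
makes uniform translations exact zero modes. The six lowest eigenvalues of a
connected network are rigid-body modes; low-frequency internal modes that
follow describe collective motions such as inter-domain hinge bending, and
their overlap with a displacement vector between two conformations measures
how much of the transition each mode carries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from gcgrflex.errors import DisconnectedNetworkError, GcgrflexError
from gcgrflex.geometry import kabsch_superpose

#: Default spring cutoff in Å (typical Calpha elastic-network choice).
DEFAULT_CUTOFF = 12.0
#: Eigenvalues below this fraction of the largest count as rigid-body modes.
RIGID_TOL = 1e-8


@dataclass
class ENMModel:
    coords: np.ndarray  # (N, 3) Calpha positions, Å
    cutoff: float
    gamma: float
    hessian: np.ndarray  # (3N, 3N)

    @property
    def n_nodes(self) -> int:
        return len(self.coords)


@dataclass
class ModeSet:
    """Non-rigid modes sorted by eigenvalue; mode 1 is the lowest
    non-rigid mode."""

    eigenvalues: np.ndarray  # ascending, rigid modes removed
    vectors: np.ndarray  # (3N, k), unit columns
    n_zero: int  # rigid-body modes discarded (6 when connected)


@dataclass
class ModeOverlap:
    mode: int  # 1-based, after rigid modes
    overlap: float
    cumulative: float


def build_enm(
    coords: np.ndarray, cutoff: float = DEFAULT_CUTOFF, gamma: float = 1.0
) -> ENMModel:
    """Assemble the elastic-network Hessian; raises when the contact graph is
    disconnected at the cutoff (naming the component sizes)."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if n < 2:
        raise GcgrflexError("need at least 2 nodes")
    tree = cKDTree(coords)
    pairs = sorted(tree.query_pairs(cutoff))
    adj = np.zeros((n, n), dtype=bool)
    hess = np.zeros((3 * n, 3 * n))
    for i, j in pairs:
        rij = coords[j] - coords[i]
        dist = np.linalg.norm(rij)
        if dist == 0:
            raise GcgrflexError(f"coincident nodes {i} and {j}")
        rhat = rij / dist
        block = -gamma * np.outer(rhat, rhat)
        sl_i, sl_j = slice(3 * i, 3 * i + 3), slice(3 * j, 3 * j + 3)
        hess[sl_i, sl_j] += block
        hess[sl_j, sl_i] += block
        hess[sl_i, sl_i] -= block
        hess[sl_j, sl_j] -= block
        adj[i, j] = adj[j, i] = True
    n_comp, labels = connected_components(adj, directed=False)
    if n_comp > 1:
        sizes = np.bincount(labels).tolist()
        raise DisconnectedNetworkError(
            f"network splits into {n_comp} components of sizes {sizes} "
            f"at cutoff {cutoff} Å"
        )
    return ENMModel(coords=coords, cutoff=cutoff, gamma=gamma, hessian=hess)


def compute_modes(model: ENMModel, k: int = 10) -> ModeSet:
    """Lowest ``k`` non-rigid modes after discarding the rigid-body
    eigenvalues (six for a generic connected network; five for the
    degenerate two-node case). More than six near-zero eigenvalues signal a
    floppy or disconnected network."""
    vals, vecs = eigh(model.hessian)
    scale = max(vals[-1], 1.0)
    n_zero = int((vals < RIGID_TOL * scale).sum())
    if n_zero > 6:
        raise DisconnectedNetworkError(
            f"{n_zero} near-zero eigenvalues: network is not rigidly connected"
        )
    k = min(k, len(vals) - n_zero)
    return ModeSet(
        eigenvalues=vals[n_zero : n_zero + k].copy(),
        vectors=vecs[:, n_zero : n_zero + k].copy(),
        n_zero=n_zero,
    )


def rigid_mode_count(model: ENMModel) -> int:
    """Number of eigenvalues below the rigid tolerance (6 when connected)."""
    vals = eigh(model.hessian, eigvals_only=True)
    scale = max(vals[-1], 1.0)
    return int((vals < RIGID_TOL * scale).sum())


def transition_overlap(
    modes: ModeSet,
    coords_a: np.ndarray,
    coords_b: np.ndarray,
    superpose_subset: np.ndarray | None = None,
) -> list[ModeOverlap]:
    """Overlap of each mode with the conformational difference a -> b.

    ``coords_b`` is first least-squares superposed onto ``coords_a`` (on the
    given node subset, default all nodes) so the difference vector carries no
    rigid-body component; overlap_j = |v_j . dr| / |dr| for unit modes, and
    the cumulative overlap sqrt(sum_j overlap_j^2) is non-decreasing and <= 1.
    """
    coords_a = np.asarray(coords_a, dtype=float)
    coords_b = np.asarray(coords_b, dtype=float)
    if coords_a.shape != coords_b.shape:
        raise GcgrflexError("structures have different node counts")
    subset = (
        np.arange(len(coords_a)) if superpose_subset is None else superpose_subset
    )
    R, t = kabsch_superpose(coords_b[subset], coords_a[subset])
    moved = coords_b @ R.T + t
    dr = (moved - coords_a).ravel()
    norm = np.linalg.norm(dr)
    if norm == 0:
        raise GcgrflexError("identical structures: zero transition vector")
    dr = dr / norm
    out = []
    cum2 = 0.0
    for j in range(modes.vectors.shape[1]):
        ov = float(abs(modes.vectors[:, j] @ dr))
        cum2 += ov * ov
        out.append(ModeOverlap(mode=j + 1, overlap=ov, cumulative=float(np.sqrt(cum2))))
    return out
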