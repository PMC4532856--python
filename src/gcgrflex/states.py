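"""(theta, phi) relative-probability maps and open/closed state windows.

The two-dimensional histogram of the orientation angles is normalised so the
most abundant bin equals 1 ("relative probability"). Named rectangular
windows on the map mark the open state (ECD upright, peptide-binding
competent) and the closed state (ECD folded over the 7TM extracellular face).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from gcgrflex.errors import GcgrflexError, ValidationError
from gcgrflex.geometry import OrientationSeries

#: Default histogram bin width in degrees for both axes.
DEFAULT_BIN_DEG = 2.5


@dataclass(frozen=True)
class StateWindow:
    """Closed rectangle in (theta, phi) degrees; boundaries inclusive."""

    name: str
    theta: tuple[float, float]
    phi: tuple[float, float]

    def __post_init__(self) -> None:
        if self.theta[0] > self.theta[1] or self.phi[0] > self.phi[1]:
            raise ValidationError(f"window {self.name}: empty range")

    def contains(self, theta, phi) -> np.ndarray:
        theta = np.asarray(theta, dtype=float)
        phi = np.asarray(phi, dtype=float)
        return (
            (theta >= self.theta[0])
            & (theta <= self.theta[1])
            & (phi >= self.phi[0])
            & (phi <= self.phi[1])
        )

    @property
    def centroid(self) -> tuple[float, float]:
        return (
            0.5 * (self.theta[0] + self.theta[1]),
            0.5 * (self.phi[0] + self.phi[1]),
        )


#: ECD upright; cluster populated mainly with agonist peptide bound.
OPEN_WINDOW = StateWindow("open", theta=(15.0, 25.0), phi=(20.0, 40.0))
#: ECD folded onto the 7TM extracellular face; apo-receptor cluster.
CLOSED_WINDOW = StateWindow("closed", theta=(40.0, 45.0), phi=(15.0, 25.0))


@dataclass
class StateMap2D:
    """Binned relative-probability grid over (theta, phi)."""

    theta_edges: np.ndarray
    phi_edges: np.ndarray
    counts: np.ndarray
    relative_probability: np.ndarray
    n_samples: int
    n_excluded: int  # undefined-phi samples left out of the map


def _valid(series: OrientationSeries) -> tuple[np.ndarray, np.ndarray, int]:
    mask = series.phi_defined & np.isfinite(series.phi)
    return series.theta[mask], series.phi[mask], int((~mask).sum())


def probability_map(
    series: OrientationSeries,
    theta_bin: float = DEFAULT_BIN_DEG,
    phi_bin: float = DEFAULT_BIN_DEG,
) -> StateMap2D:
    """Histogram the series on a regular grid covering [0, 180]° on both
    axes and normalise by the maximum bin count."""
    theta, phi, n_excl = _valid(series)
    if theta.size == 0:
        raise GcgrflexError("no valid (theta, phi) samples: empty map")
    theta_edges = np.arange(0.0, 180.0 + theta_bin, theta_bin)
    phi_edges = np.arange(0.0, 180.0 + phi_bin, phi_bin)
    counts, _, _ = np.histogram2d(theta, phi, bins=(theta_edges, phi_edges))
    counts = counts.astype(int)
    rel = counts / counts.max()
    return StateMap2D(
        theta_edges=theta_edges,
        phi_edges=phi_edges,
        counts=counts,
        relative_probability=rel,
        n_samples=int(counts.sum()),
        n_excluded=n_excl,
    )


def occupancy(series: OrientationSeries, window: StateWindow) -> float:
    """Fraction of valid samples inside the closed rectangle (boundaries
    inclusive)."""
    theta, phi, _ = _valid(series)
    if theta.size == 0:
        raise GcgrflexError("no valid samples")
    return float(window.contains(theta, phi).mean())


def representative_snapshot(series: OrientationSeries, window: StateWindow) -> int:
    """Frame index of the in-window sample closest (Euclidean, degrees) to
    the window centroid; ties break to the earliest frame."""
    theta, phi = series.theta, series.phi
    inside = series.phi_defined & window.contains(theta, phi)
    if not inside.any():
        raise GcgrflexError(f"no sample inside window {window.name!r}")
    ct, cp = window.centroid
    dist2 = np.where(inside, (theta - ct) ** 2 + (phi - cp) ** 2, np.inf)
    return int(np.argmin(dist2))  # argmin returns the first minimum
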