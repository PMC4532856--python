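#!/usr/bin/env python
"""Build the (theta, phi) relative-probability maps, score the open/closed
state windows and pick representative snapshots.

The open window (theta 15-25 deg, phi 20-40 deg) holds the upright,
peptide-binding-competent conformation; the closed window (theta 40-45 deg,
phi 15-25 deg) holds the conformation with the ECD folded over the 7TM
bundle. Writes the normalised grid, an occupancy report and a heatmap per
scenario under results/.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from gcgrflex import geometry, states

OUT = Path("results")
WINDOWS = (states.OPEN_WINDOW, states.CLOSED_WINDOW)


def load_series(path):
    df = pd.read_csv(path, sep="\t")
    return geometry.OrientationSeries(
        times=df.time_ns.to_numpy(),
        theta=df.theta.to_numpy(),
        phi=df.phi.to_numpy(),
        d=df.d.to_numpy(),
        phi_defined=np.isfinite(df.phi.to_numpy()),
    )


def main() -> None:
    rows = []
    for name in ("apo_like", "bound_like"):
        series = load_series(OUT / "synthetic" / name / "orientation.tsv")
        smap = states.probability_map(series)
        grid = pd.DataFrame(
            smap.relative_probability,
            index=smap.theta_edges[:-1],
            columns=smap.phi_edges[:-1],
        )
        grid.to_csv(OUT / f"statemap_{name}.tsv", sep="\t")
        for window in WINDOWS:
            occ = states.occupancy(series, window)
            try:
                rep = states.representative_snapshot(series, window)
            except Exception:
                rep = None
            rows.append(
                dict(scenario=name, window=window.name, occupancy=occ,
                     representative_frame=rep)
            )
            print(f"{name:11s} {window.name:6s} occupancy {occ:.3f} "
                  f"representative frame {rep}")

        fig, ax = plt.subplots(figsize=(5, 4))
        sub = smap.relative_probability[:30, :30]  # 0-75 deg view
        im = ax.imshow(
            sub, origin="lower", aspect="auto", cmap="viridis",
            extent=[0, 75, 0, 75],
        )
        for w, color in zip(WINDOWS, ("w", "r")):
            ax.add_patch(
                plt.Rectangle(
                    (w.phi[0], w.theta[0]), w.phi[1] - w.phi[0],
                    w.theta[1] - w.theta[0], fill=False, edgecolor=color,
                    linestyle="--",
                )
            )
        ax.set_xlabel("phi (deg)")
        ax.set_ylabel("theta (deg)")
        ax.set_title(f"relative probability, {name}")
        fig.colorbar(im, ax=ax)
        fig.tight_layout()
        fig.savefig(OUT / f"statemap_{name}.png", dpi=120)
        plt.close(fig)

    pd.DataFrame(rows).to_csv(OUT / "state_occupancy.tsv", sep="\t", index=False)
    print(f"wrote occupancy report -> {OUT/'state_occupancy.tsv'}")


if __name__ == "__main__":
    main()
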