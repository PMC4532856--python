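#!/usr/bin/env python
"""Recover the inter-domain orientation coordinates from the simulated
trajectories and verify them against the generator's ground truth.

Reads results/synthetic/<scenario>/ written by 01_simulate.py, computes the
per-frame (theta, phi, d) series in the pivot-anchored frame (7TM Calpha
superposition on), and writes orientation.tsv next to each trajectory.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from gcgrflex import geometry, io

OUT = Path("results/synthetic")


def main() -> None:
    for name in ("apo_like", "bound_like"):
        outdir = OUT / name
        traj = io.read_trajectory(outdir / "trajectory.pdb")
        cfg = io.load_config(outdir / "config.yaml")
        series = geometry.compute_orientation(traj, cfg["domains"])
        pd.DataFrame(
            dict(time_ns=series.times, theta=series.theta, phi=series.phi,
                 d=series.d)
        ).to_csv(outdir / "orientation.tsv", sep="\t", index=False)
        truth = pd.read_csv(outdir / "ground_truth.tsv", sep="\t")
        # PDB coordinates are quantised to 0.001 Å, so recovery from the
        # round-tripped file is limited by that precision, not the method
        err = np.nanmax(
            [
                np.abs(series.theta - truth.theta).max(),
                np.abs(series.phi - truth.phi).max(),
                np.abs(series.d - truth.d).max(),
            ]
        )
        print(
            f"{name}: theta {series.theta.min():.1f}->{series.theta.max():.1f} deg, "
            f"mean d {series.d.mean():.1f} Å, "
            f"max |recovered - truth| = {err:.2e} (file round trip)"
        )


if __name__ == "__main__":
    main()
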