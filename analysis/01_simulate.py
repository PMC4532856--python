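#!/usr/bin/env python
"""Generate the synthetic study inputs: an apo-like and a peptide-bound-like
hinge trajectory with scripted orientation schedules, plus the matching
domain configuration and ground truth.

The apo-like schedule sends the extracellular domain from an upright pose
(theta ~20 deg) down onto the transmembrane bundle (rise to ~50 deg, plateau
near 42 deg); the bound-like schedule keeps it upright with a broader
azimuthal wander. Outputs land in results/synthetic/<scenario>/.
"""

from pathlib import Path

import pandas as pd

from gcgrflex import io, synth

OUT = Path("results/synthetic")
N_FRAMES = 400
SEED = 1


def main() -> None:
    for name, maker in (
        ("apo_like", synth.apo_like_scenario),
        ("bound_like", synth.bound_like_scenario),
    ):
        traj, truth, domains = synth.make_hinge_trajectory(
            maker(N_FRAMES, seed=SEED)
        )
        outdir = OUT / name
        outdir.mkdir(parents=True, exist_ok=True)
        io.write_trajectory(traj, outdir / "trajectory.pdb")
        pd.DataFrame(
            dict(time_ns=truth.times, theta=truth.theta, phi=truth.phi, d=truth.d)
        ).to_csv(outdir / "ground_truth.tsv", sep="\t", index=False)
        io.save_config({"domains": domains}, outdir / "config.yaml")
        print(
            f"{name}: {traj.n_frames} frames, {traj.n_atoms} atoms, "
            f"theta {truth.theta.min():.1f}-{truth.theta.max():.1f} deg -> {outdir}"
        )


if __name__ == "__main__":
    main()
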