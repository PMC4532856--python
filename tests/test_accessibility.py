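import dataclasses
import math

import numpy as np
import pytest

from gcgrflex import accessibility as acc
from gcgrflex import synth
from gcgrflex.errors import ConfigurationError
from gcgrflex.io import AtomRecord, DomainSpec, Trajectory

DOM_NO_SLAB = DomainSpec(ecd=(1, 5), tm7=(400, 401))


def _donor_acceptor_traj(no_distance=2.9):
    """One glycine-like donor (N at origin, H along +x) and a remote residue
    contributing a carbonyl O on the N-H axis."""
    atoms = [
        AtomRecord("N", "N", "GLY", 1, "A", 14.007, 1.55),
        AtomRecord("H", "H", "GLY", 1, "A", 1.008, 1.2),
        AtomRecord("CA", "C", "GLY", 1, "A", 12.011, 1.7),
        AtomRecord("O", "O", "GLY", 5, "A", 15.999, 1.52),
    ]
    coords = np.array(
        [[[0, 0, 0], [1.01, 0, 0], [-0.5, -1.35, 0], [no_distance, 0, 0]]],
        dtype=float,
    )
    return Trajectory(atoms=atoms, coords=coords, times=np.array([0.0]))


class TestHydrogenBonds:
    def test_linear_geometry_bonds(self):
        hb = acc.detect_mainchain_hbonds(_donor_acceptor_traj(2.9))
        assert hb[("A", 1)] is True

    def test_beyond_distance_cutoff(self):
        hb = acc.detect_mainchain_hbonds(_donor_acceptor_traj(3.6))
        assert hb[("A", 1)] is False

    def test_ideal_helix_pattern(self, helix20):
        hb = acc.detect_mainchain_hbonds(helix20)
        bonded = sorted(rid for (_, rid), v in hb.items() if v)
        assert bonded == list(range(5, 21))

    def test_extended_strand_has_none(self):
        strand = synth.make_extended_strand(12)
        hb = acc.detect_mainchain_hbonds(strand)
        assert not any(v for v in hb.values() if v)

    def test_proline_flagged_na(self, helix20):
        atoms = [
            dataclasses.replace(a, residue_name="PRO")
            if a.residue_id == 10
            else a
            for a in helix20.atoms
        ]
        traj = Trajectory(atoms=atoms, coords=helix20.coords, times=helix20.times)
        hb = acc.detect_mainchain_hbonds(traj)
        assert hb[("A", 10)] is None
        assert sum(1 for v in hb.values() if v) == 15

    def test_reconstructed_protons_recover_pattern(self, helix20):
        # drop every input amide proton; detection must reconstruct them
        keep = [i for i, a in enumerate(helix20.atoms) if a.atom_name != "H"]
        traj = Trajectory(
            atoms=[helix20.atoms[i] for i in keep],
            coords=helix20.coords[:, keep],
            times=helix20.times,
        )
        hb = acc.detect_mainchain_hbonds(traj)
        bonded = sorted(rid for (_, rid), v in hb.items() if v)
        assert bonded == list(range(5, 21))


class TestSasa:
    def test_isolated_atom_analytic_sphere(self):
        got = acc.sasa_per_atom(np.zeros((1, 3)), np.array([1.7]))
        exact = 4 * math.pi * (1.7 + 1.4) ** 2
        assert got[0] == pytest.approx(exact, rel=0.005)

    def test_fully_enclosed_atom(self):
        cage = 4.0 * acc.sphere_points(80)
        coords = np.vstack([[0.0, 0.0, 0.0], cage])
        radii = np.concatenate([[1.7], np.full(80, 3.0)])
        got = acc.sasa_per_atom(coords, radii)
        assert got[0] == 0.0

    def test_two_spheres_match_cap_formula(self):
        r1, r2, d = 1.7, 1.52, 2.0
        R1, R2 = r1 + 1.4, r2 + 1.4
        got = acc.sasa_per_atom(
            np.array([[0.0, 0.0, 0.0], [d, 0.0, 0.0]]), np.array([r1, r2])
        )
        # closed-form spherical caps cut at the radical plane
        x = (d * d + R1 * R1 - R2 * R2) / (2 * d)
        exact1 = 4 * math.pi * R1 * R1 - 2 * math.pi * R1 * (R1 - x)
        exact2 = 4 * math.pi * R2 * R2 - 2 * math.pi * R2 * (R2 - (d - x))
        assert got[0] == pytest.approx(exact1, rel=0.01)
        assert got[1] == pytest.approx(exact2, rel=0.01)

    def test_deterministic(self, helix20):
        a = acc.amide_sasa(helix20)
        b = acc.amide_sasa(helix20)
        assert a == b

    def test_cross_check_against_mdtraj(self):
        """Independent route: mdtraj's Shrake-Rupley on the same helix with
        the same radii/probe agrees atom-by-atom (point sets differ)."""
        md = pytest.importorskip("mdtraj")
        from mdtraj.core import element as elem

        helix = synth.make_ideal_helix(12)
        top = md.Topology()
        chain = top.add_chain()
        emap = {
            "H": elem.hydrogen, "C": elem.carbon,
            "N": elem.nitrogen, "O": elem.oxygen,
        }
        res, last = None, None
        for a in helix.atoms:
            if a.residue_id != last:
                res = top.add_residue("ALA", chain)
                last = a.residue_id
            top.add_atom(a.atom_name, emap[a.element], res)
        traj = md.Trajectory(xyz=helix.coords / 10.0, topology=top)
        ref = (
            md.shrake_rupley(
                traj, probe_radius=0.14, n_sphere_points=960, mode="atom"
            )[0]
            * 100.0  # nm^2 -> A^2
        )
        mine = acc.sasa_per_atom(helix.coords[0], helix.vdw_radii, 1.4, 960)
        np.testing.assert_allclose(mine, ref, atol=1.0)


class TestClassification:
    def test_exposed_amide_accessible(self):
        strand = synth.make_extended_strand(6)
        rec = acc.classify_amide(strand, 3, DOM_NO_SLAB)
        assert rec.accessible and not rec.hbonded and not rec.lipid_only

    def test_slab_forces_lipid_only(self):
        strand = synth.make_extended_strand(6)
        z = strand.coords[0][:, 2]
        dom = DomainSpec(
            ecd=(1, 5), tm7=(400, 401),
            membrane_slab=(float(z.min()) - 1, float(z.max()) + 1),
        )
        rec = acc.classify_amide(strand, 3, dom)
        assert rec.lipid_only and not rec.accessible

    def test_hbond_dominates_high_sasa(self, helix20):
        rec = acc.classify_amide(helix20, 10, DOM_NO_SLAB)
        assert rec.hbonded and not rec.accessible

    def test_lipids_without_slab_error(self):
        strand = synth.make_extended_strand(6)
        with_lipids = synth.add_membrane_slab(strand, -15.0, 15.0)
        with pytest.raises(ConfigurationError):
            acc.classify_frame(with_lipids, 0, DOM_NO_SLAB)

    def test_record_invariant(self, helix20):
        for rec in acc.classify_frame(helix20, 0, DOM_NO_SLAB):
            assert rec.accessible == (
                not rec.hbonded
                and rec.sasa > acc.AccessibilityConfig().buried_sasa_threshold
                and not rec.lipid_only
            )


class TestAggregation:
    def test_ideal_helix_region_twenty_percent(self, helix20):
        regs = acc.aggregate_accessibility(
            helix20, DOM_NO_SLAB, [("helix", (1, 20))]
        )
        assert regs[0].mean_percent == pytest.approx(20.0)
        assert regs[0].n_residues == 20

    def test_strand_fully_accessible(self):
        strand = synth.make_extended_strand(8)
        regs = acc.aggregate_accessibility(
            strand, DOM_NO_SLAB, [("strand", (1, 8))]
        )
        assert regs[0].mean_percent == pytest.approx(100.0)

    def test_constant_trajectory_sd_zero(self, helix20):
        traj = Trajectory(
            atoms=helix20.atoms,
            coords=np.repeat(helix20.coords, 3, axis=0),
            times=np.arange(3.0),
        )
        regs = acc.aggregate_accessibility(traj, DOM_NO_SLAB, [("h", (1, 20))])
        assert regs[0].sd == 0.0
        assert regs[0].n_snapshots == 3

    def test_threshold_monotonicity(self):
        strand = synth.make_extended_strand(10)
        pcts = []
        for thr in (0.01, 0.5, 2.0, 5.0):
            cfg = acc.AccessibilityConfig(buried_sasa_threshold=thr)
            regs = acc.aggregate_accessibility(
                strand, DOM_NO_SLAB, [("s", (1, 10))], cfg
            )
            pcts.append(regs[0].mean_percent)
        assert all(a >= b for a, b in zip(pcts, pcts[1:]))

    def test_disabling_slab_only_increases_access(self):
        strand = synth.make_extended_strand(10)
        z = strand.coords[0][:, 2]
        dom_slab = DomainSpec(
            ecd=(1, 5), tm7=(400, 401),
            membrane_slab=(float(z.min()), float(np.median(z))),
        )
        with_slab = acc.aggregate_accessibility(
            strand, dom_slab, [("s", (1, 10))]
        )[0].mean_percent
        without = acc.aggregate_accessibility(
            strand, DOM_NO_SLAB, [("s", (1, 10))]
        )[0].mean_percent
        assert without >= with_slab

    def test_empty_region_errors(self, helix20):
        with pytest.raises(Exception):
            acc.aggregate_accessibility(helix20, DOM_NO_SLAB, [("x", (300, 310))])


class TestCompareToHdx:
    @staticmethod
    def _region(name, value):
        return acc.RegionAccessibility(
            region=name, span=(1, 10), mean_percent=value, sd=1.0,
            n_snapshots=10, n_residues=10,
        )

    def test_stalk_concordant(self):
        hdx = synth.make_hdx_fixture()
        df = acc.compare_to_hdx(
            [self._region("Stalk", 12.7)],
            [self._region("Stalk", 0.9)],
            hdx, "NNC2648", "peptide",
        )
        row = df[df.region == "Stalk"].iloc[0]
        assert row.concordant is True
        assert row.hdx_apo_like == 59.6 and row.hdx_bound_like == 6.5

    def test_inverted_prediction_discordant(self):
        hdx = synth.make_hdx_fixture()
        df = acc.compare_to_hdx(
            [self._region("Stalk", 0.9)],
            [self._region("Stalk", 12.7)],
            hdx, "NNC2648", "peptide",
        )
        assert df[df.region == "Stalk"].iloc[0].concordant is False

    def test_equal_predictions_flagged_undefined(self):
        hdx = synth.make_hdx_fixture()
        df = acc.compare_to_hdx(
            [self._region("Stalk", 5.0)],
            [self._region("Stalk", 5.0)],
            hdx, "NNC2648", "peptide",
        )
        assert df[df.region == "Stalk"].iloc[0].concordant is None

    def test_unmatched_region_listed(self):
        hdx = synth.make_hdx_fixture()
        df = acc.compare_to_hdx(
            [self._region("NoSuchRegion", 10.0)],
            [self._region("NoSuchRegion", 5.0)],
            hdx, "NNC2648", "peptide",
        )
        row = df[df.region == "NoSuchRegion"].iloc[0]
        assert not row.matched
        assert "Stalk" in set(df.region)


def test_config_rejects_nonpositive():
    with pytest.raises(ConfigurationError):
        acc.AccessibilityConfig(probe_radius=0.0)
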