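import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gcgrflex import synth, xlms
from gcgrflex.constants import (
    DISULFIDE_DELTA,
    NEM_DELTA,
    PROTON,
    RESIDUE_MASS,
    WATER,
)
from gcgrflex.errors import GcgrflexError, ValidationError


def brute_force_digest(seq, sites="KRFYWL", max_missed=3, min_len=4, max_len=100):
    """Oracle: enumerate every substring whose termini are cleavage sites or
    protein termini and whose internal cleavable residues number <= max_missed."""
    cut_after = {i for i, c in enumerate(seq) if c in sites}
    starts = [0] + [i + 1 for i in sorted(cut_after) if i + 1 < len(seq)]
    ends = sorted(cut_after | {len(seq) - 1})
    out = set()
    for s in starts:
        for e in ends:
            if e < s:
                continue
            internal = sum(1 for i in cut_after if s <= i < e)
            if internal <= max_missed and min_len <= e - s + 1 <= max_len:
                out.add((s, seq[s : e + 1]))
    return out


class TestDigest:
    @pytest.mark.parametrize(
        "seq",
        ["AKYLPWHCKAF", "MGRASKLFYWD", "PPPPKPPPP", "ACDEFGHIKLM", "WWWW"],
    )
    def test_matches_bruteforce_enumeration(self, seq):
        got = {(p.start, p.sequence) for p in xlms.digest(seq)}
        assert got == brute_force_digest(seq)

    @given(
        st.text(alphabet="ACDKGRFLS", min_size=5, max_size=15)
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_bruteforce_property(self, seq):
        got = {(p.start, p.sequence) for p in xlms.digest(seq)}
        assert got == brute_force_digest(seq)

    def test_all_short_products_filtered(self):
        # every product of KKK is shorter than the 4-residue minimum
        assert xlms.digest("KKK") == []
        # KKKK itself survives: length 4 with exactly 3 missed cleavages
        assert [p.sequence for p in xlms.digest("KKKK")] == ["KKKK"]

    def test_reported_peptides_from_context(self):
        # flanking residues are cleavage-compatible (W before each peptide)
        ecd = "GGW" + "YLPWHCK" + "AGG"
        ecl3 = "GGW" + "AFVTDECAQGTLR" + "SGG"
        assert "YLPWHCK" in {p.sequence for p in xlms.digest(ecd)}
        assert "AFVTDECAQGTLR" in {p.sequence for p in xlms.digest(ecl3)}

    def test_nonstandard_residue_names_position(self):
        with pytest.raises(ValidationError, match="position 3"):
            xlms.digest("AKXLM")

    def test_termini_are_cleavage_sites(self):
        seq = "AKYLPWHCKAF"
        sites = {i for i, c in enumerate(seq) if c in "KRFYWL"}
        for p in xlms.digest(seq):
            start, end = p.start, p.start + len(p.sequence) - 1
            assert start == 0 or (start - 1) in sites
            assert end == len(seq) - 1 or end in sites


class TestMasses:
    @pytest.mark.parametrize(
        "seq, expected",
        [
            ("YLPWHCK", 945.4531),
            ("AFVTDECAQGTLR", 1409.6609),
            ("G", 75.0320),
        ],
    )
    def test_peptide_mass(self, seq, expected):
        # oracle: independent sum over the standard monoisotopic table
        oracle = sum(RESIDUE_MASS[c] for c in seq) + WATER
        assert xlms.peptide_mass(seq) == pytest.approx(oracle, abs=1e-9)
        assert xlms.peptide_mass(seq) == pytest.approx(expected, abs=5e-4)

    def test_crosslink_mass_reproduces_reported_value(self, xl_pair):
        assert xl_pair.mass == pytest.approx(2353.0983, abs=0.001)

    def test_crosslink_symmetric(self):
        a = xlms.crosslink_mass("YLPWHCK", "AFVTDECAQGTLR")
        b = xlms.crosslink_mass("AFVTDECAQGTLR", "YLPWHCK")
        assert a.mass == pytest.approx(b.mass, abs=1e-12)

    def test_two_tetrapeptides_hand_summed(self):
        ledger = (
            sum(RESIDUE_MASS[c] for c in "ACDK") + WATER
            + sum(RESIDUE_MASS[c] for c in "GCLR") + WATER
            + DISULFIDE_DELTA
        )
        assert xlms.crosslink_mass("ACDK", "GCLR").mass == pytest.approx(
            ledger, abs=1e-12
        )

    def test_no_cysteine_rejected(self):
        with pytest.raises(GcgrflexError):
            xlms.crosslink_mass("YLPWHK", "AFVTDEAQGTLR")

    def test_self_link_needs_two_cys(self):
        chain = xlms.PeptideChain("ACDK")
        with pytest.raises(GcgrflexError):
            xlms.crosslink_mass(chain, chain)
        two_cys = xlms.PeptideChain("ACDCK")
        xl = xlms.crosslink_mass(two_cys, two_cys, site_a=1, site_b=3)
        assert xl.mass == pytest.approx(
            2 * xlms.peptide_mass(two_cys) + DISULFIDE_DELTA, abs=1e-12
        )

    def test_nem_modifies_free_cys_only(self):
        chain = xlms.PeptideChain("ACDCK")
        modded = xlms.with_nem(chain, exclude_site=1)
        assert modded.modifications == ((3, NEM_DELTA),)
        assert xlms.peptide_mass(modded) == pytest.approx(
            xlms.peptide_mass(chain) + NEM_DELTA, abs=1e-12
        )


class TestMz:
    def test_doubly_charged_within_10ppm_of_observed(self, xl_pair):
        got = xl_pair.mz(2)
        assert abs(got - 1177.5571) / 1177.5571 * 1e6 < 10

    def test_triply_charged_within_10ppm_of_observed(self, xl_pair):
        got = xl_pair.mz(3)
        assert abs(got - 785.3722) / 785.3722 * 1e6 < 10

    def test_zero_mass_gives_proton(self):
        assert xlms.mz(0.0, 1) == pytest.approx(PROTON, abs=1e-12)

    def test_nonpositive_charge_rejected(self):
        with pytest.raises(ValidationError):
            xlms.mz(100.0, 0)

    @given(
        st.floats(100.0, 5000.0), st.integers(1, 6)
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_mass_mz_roundtrip(self, mass, z):
        assert xlms.neutral_mass(xlms.mz(mass, z), z) == pytest.approx(
            mass, abs=1e-9
        )


class TestMatchPrecursor:
    def test_observed_doubly_charged_peak(self, xl_pair):
        matches = xlms.match_precursor(1177.5571, 2, [xl_pair])
        assert matches and matches[0].isotope == 0
        assert abs(matches[0].ppm) < 10

    def test_five_isotopes_away_rejected(self, xl_pair):
        shifted = xlms.mz(xl_pair.mass + 5 * 1.003355, 2)
        assert xlms.match_precursor(shifted, 2, [xl_pair]) == []

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(4)
        cands = list(rng.uniform(800, 3000, 30))
        obs_mass = cands[7] + 2 * 1.003355 + cands[7] * 3e-6  # 3 ppm off k=2
        obs_mz = xlms.mz(obs_mass, 2)
        got = {
            (m.candidate, m.isotope)
            for m in xlms.match_precursor(obs_mz, 2, cands)
        }
        oracle = set()
        for ci, cand in enumerate(cands):
            for k in range(5):
                ppm = (obs_mass - (cand + k * 1.003355)) / cand * 1e6
                if abs(ppm) <= 10:
                    oracle.add((ci, k))
        assert got == oracle
        assert (7, 2) in got


class TestFragmentIons:
    def test_plain_y2_of_ecl3_chain(self, xl_pair):
        ions = {
            (i.series, i.index): i
            for i in xlms.fragment_ions(xl_pair, charges=(1,))
            if i.chain == "beta"
        }
        y2 = ions[("y", 2)]
        oracle = RESIDUE_MASS["L"] + RESIDUE_MASS["R"] + WATER + PROTON
        assert not y2.carries_partner
        assert y2.mz == pytest.approx(oracle, abs=1e-9)

    def test_linked_Y5_carries_partner(self, xl_pair):
        ions = {
            (i.series, i.index): i
            for i in xlms.fragment_ions(xl_pair, charges=(1,))
            if i.chain == "alpha"
        }
        y5 = ions[("Y", 5)]  # PWHCK spans the linked Cys
        assert y5.carries_partner
        oracle = (
            sum(RESIDUE_MASS[c] for c in "PWHCK")
            + WATER
            + xlms.peptide_mass("AFVTDECAQGTLR")
            + DISULFIDE_DELTA
            + PROTON
        )
        assert y5.mz == pytest.approx(oracle, abs=1e-9)

    def test_series_completeness(self, xl_pair):
        ions = xlms.fragment_ions(xl_pair, charges=(1,))
        for chain, length in (("alpha", 7), ("beta", 13)):
            b_like = [
                i for i in ions if i.chain == chain and i.series in "bB"
            ]
            assert len(b_like) == length - 1
            assert sorted(i.index for i in b_like) == list(range(1, length))

    def test_by_pair_mass_conservation(self):
        seq = "SAMPLER"
        chain_mass = xlms.peptide_mass(seq)
        ions = {
            (i.series, i.index): i.mz
            for i in xlms.linear_fragment_ions(seq, charges=(1,))
        }
        n = len(seq)
        for i in range(1, n):
            total = ions[("b", i)] + ions[("y", n - i)]
            assert total == pytest.approx(chain_mass + 2 * PROTON, abs=1e-9)


class TestValidateSpectrum:
    def test_continuous_ladders_pass(self, xl_pair):
        include = [(c, "y", i) for c in ("alpha", "beta") for i in range(1, 6)]
        peaks = synth.make_xl_spectrum(xl_pair, include=include)
        report = xlms.validate_spectrum(peaks, xl_pair)
        assert report.passed
        assert report.longest_run[("alpha", "y")] >= 4

    def test_gapped_ladder_fails(self, xl_pair):
        include = [(c, "y", i) for c in ("alpha", "beta") for i in (1, 3, 5)]
        peaks = synth.make_xl_spectrum(xl_pair, include=include)
        report = xlms.validate_spectrum(peaks, xl_pair)
        assert not report.passed

    def test_one_chain_only_fails(self, xl_pair):
        include = [("alpha", "y", i) for i in range(1, 7)]
        peaks = synth.make_xl_spectrum(xl_pair, include=include)
        assert not xlms.validate_spectrum(peaks, xl_pair).passed

    def test_noisy_spectrum_matches_bruteforce_assignment(self, xl_pair):
        include = [(c, "y", i) for c in ("alpha", "beta") for i in range(1, 6)]
        peaks = synth.make_xl_spectrum(
            xl_pair, include=include, n_noise=40, seed=8
        )
        report = xlms.validate_spectrum(peaks, xl_pair, fragment_tol_ppm=20.0)
        # oracle: exhaustive greedy over all (ion, peak) pairs sorted by |ppm|
        theo = xlms.fragment_ions(xl_pair, charges=(1,))
        pairs = sorted(
            (
                (abs((p.mz - ion.mz) / ion.mz * 1e6), ti, pi)
                for ti, ion in enumerate(theo)
                for pi, p in enumerate(peaks)
                if abs((p.mz - ion.mz) / ion.mz * 1e6) <= 20.0
            ),
        )
        used_i, used_p, oracle = set(), set(), set()
        for _, ti, pi in pairs:
            if ti in used_i or pi in used_p:
                continue
            used_i.add(ti)
            used_p.add(pi)
            oracle.add((ti, pi))
        got = {
            (theo.index(ion), pi) for ion, pi, _ in report.assignments
        }
        assert got == oracle
        assert report.passed

    def test_case_change_does_not_break_ladder(self, xl_pair):
        # alpha chain y2..y5 cross from plain y (none exist below index 2)
        # into linked Y territory; they form one ladder of length >= 4
        include = [("alpha", "y", i) for i in range(2, 6)]
        include += [("beta", "y", i) for i in range(1, 6)]
        peaks = synth.make_xl_spectrum(xl_pair, include=include)
        report = xlms.validate_spectrum(peaks, xl_pair)
        assert report.longest_run[("alpha", "y")] == 4
        assert report.passed


def test_read_peak_list(tmp_path):
    p = tmp_path / "peaks.txt"
    p.write_text("# mz intensity\n200.5 100\n300.25,55\n")
    peaks = xlms.read_peak_list(p)
    assert [pk.mz for pk in peaks] == [200.5, 300.25]
    bad = tmp_path / "bad.txt"
    bad.write_text("# header\nnot-a-number x\n")
    with pytest.raises(ValidationError, match=":2:"):
        xlms.read_peak_list(bad)
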