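"""Disulfide-crosslink mass-spectrometry arithmetic.

Covers the targeted workflow used to confirm an engineered disulfide between
two receptor domains: combined trypsin/chymotrypsin in-silico digestion,
monoisotopic masses of the two linked chains, the crosslinked precursor mass
(two peptides minus 2 H), charge-state m/z, b/y fragment ladders where
fragments spanning the linked cysteine carry the intact partner chain
(uppercase B/Y series), precursor matching within a ppm window over the first
few isotopes, and the continuity filter on fragment assignments.

All masses are monoisotopic Da. Digestion itself is delegated to
:func:`pyteomics.parser.icleave`; everything downstream is implemented here.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from pyteomics import parser as _pparser

from gcgrflex.constants import (
    DISULFIDE_DELTA,
    ISOTOPE_SPACING,
    NEM_DELTA,
    PROTON,
    RESIDUE_MASS,
    WATER,
)
from gcgrflex.errors import GcgrflexError, ValidationError

#: Cleavage specificity: residues after which each enzyme cuts.
ENZYME_SITES = {
    "trypsin": "KR",
    "chymotrypsin": "FYWL",
}


@dataclass(frozen=True)
class PeptideChain:
    """A digested peptide: sequence, 0-based start in the parent protein and
    per-site modification deltas (0-based site index within the peptide)."""

    sequence: str
    start: int = 0
    modifications: tuple[tuple[int, float], ...] = ()

    def __post_init__(self) -> None:
        bad = [
            (i, c) for i, c in enumerate(self.sequence) if c not in RESIDUE_MASS
        ]
        if bad:
            i, c = bad[0]
            raise ValidationError(
                f"non-standard residue {c!r} at position {self.start + i + 1}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def cys_sites(self, unmodified_only: bool = True) -> list[int]:
        modded = {i for i, _ in self.modifications}
        return [
            i
            for i, c in enumerate(self.sequence)
            if c == "C" and not (unmodified_only and i in modded)
        ]


@dataclass(frozen=True)
class CrosslinkedPeptide:
    """Two digested chains joined by a disulfide bond (net -2.01565 Da)."""

    alpha: PeptideChain
    beta: PeptideChain
    site_alpha: int  # 0-based Cys index within alpha
    site_beta: int
    mass: float  # monoisotopic, Da

    def mz(self, charge: int) -> float:
        return mz(self.mass, charge)


@dataclass(frozen=True)
class FragmentIon:
    chain: str  # "alpha" or "beta"
    series: str  # b, y (plain) or B, Y (carries the partner chain)
    index: int
    carries_partner: bool
    charge: int
    neutral_mass: float
    mz: float


@dataclass(frozen=True)
class SpectrumPeak:
    mz: float
    intensity: float = 1.0
    charge: int | None = None

    def __post_init__(self) -> None:
        if not self.mz > 0:
            raise ValidationError("peak m/z must be positive")
        if self.intensity < 0:
            raise ValidationError("peak intensity must be non-negative")


@dataclass
class PrecursorMatch:
    candidate: int  # index into the candidate list
    ppm: float
    isotope: int  # 0 = monoisotopic peak


@dataclass
class SpectrumReport:
    """Fragment assignment table plus the 4-consecutive-ions filter verdict."""

    assignments: list[tuple[FragmentIon, int, float]]  # (ion, peak idx, ppm)
    longest_run: dict[tuple[str, str], int]  # (chain, series family) -> run
    passed: bool


# --- digestion ----------------------------------------------------------------


def cleavage_rule(enzymes) -> str:
    sites = "".join(ENZYME_SITES[e] for e in enzymes)
    if not sites:
        raise GcgrflexError(f"no known enzymes in {enzymes!r}")
    return f"[{sites}]"


def digest(
    sequence: str,
    enzymes=("trypsin", "chymotrypsin"),
    max_missed: int = 3,
    min_length: int = 4,
    max_length: int = 100,
) -> list[PeptideChain]:
    """All peptides from combined cleavage after K/R (trypsin) and F/Y/W/L
    (chymotrypsin) with at most ``max_missed`` missed sites from the combined
    site set, filtered to the given length range.

    Missed cleavages are counted over the union of both enzymes' sites, i.e.
    a fully specific peptide has enzyme-compatible termini and at most three
    internal cleavable residues.
    """
    bad = [(i, c) for i, c in enumerate(sequence) if c not in RESIDUE_MASS]
    if bad:
        i, c = bad[0]
        raise ValidationError(f"non-standard residue {c!r} at position {i + 1}")
    rule = cleavage_rule(enzymes)
    seen = set()
    out = []
    for start, pep in _pparser.icleave(
        sequence, rule, missed_cleavages=max_missed,
        min_length=min_length, max_length=max_length,
    ):
        key = (start, pep)
        if key not in seen:
            seen.add(key)
            out.append(PeptideChain(sequence=pep, start=start))
    out.sort(key=lambda p: (p.start, len(p.sequence)))
    return out


# --- masses -------------------------------------------------------------------


def peptide_mass(chain: PeptideChain | str) -> float:
    """Monoisotopic peptide mass: residue masses + water + modifications."""
    if isinstance(chain, str):
        chain = PeptideChain(sequence=chain)
    if not chain.sequence:
        raise ValidationError("empty peptide")
    total = sum(RESIDUE_MASS[c] for c in chain.sequence) + WATER
    total += sum(delta for _, delta in chain.modifications)
    return total


def with_nem(chain: PeptideChain, exclude_site: int | None = None) -> PeptideChain:
    """Apply the N-ethylmaleimide adduct to every free cysteine except the
    (crosslinked) one at ``exclude_site``."""
    mods = list(chain.modifications)
    modded = {i for i, _ in mods}
    for i in chain.cys_sites(unmodified_only=False):
        if i != exclude_site and i not in modded:
            mods.append((i, NEM_DELTA))
    return PeptideChain(chain.sequence, chain.start, tuple(sorted(mods)))


def crosslink_mass(
    a: PeptideChain | str,
    b: PeptideChain | str,
    site_a: int | None = None,
    site_b: int | None = None,
) -> CrosslinkedPeptide:
    """Join two cysteine-containing chains by a disulfide: the precursor
    mass is mass(a) + mass(b) - 2.01565 Da. Each chain needs an unmodified
    Cys; linking a chain to itself needs two."""
    if isinstance(a, str):
        a = PeptideChain(sequence=a)
    if isinstance(b, str):
        b = PeptideChain(sequence=b)
    cys_a = a.cys_sites()
    cys_b = b.cys_sites()
    if not cys_a or not cys_b:
        raise GcgrflexError("both chains need an unmodified cysteine")
    if a == b and site_a == site_b and len(cys_a) < 2:
        raise GcgrflexError(
            "linking a chain to itself needs two cysteines"
        )
    sa = cys_a[0] if site_a is None else site_a
    sb = cys_b[0] if site_b is None else site_b
    if a.sequence[sa] != "C" or b.sequence[sb] != "C":
        raise GcgrflexError("link sites must be cysteines")
    mass = peptide_mass(a) + peptide_mass(b) + DISULFIDE_DELTA
    return CrosslinkedPeptide(alpha=a, beta=b, site_alpha=sa, site_beta=sb, mass=mass)


def mz(mass: float, charge: int) -> float:
    """m/z of a neutral mass at the given positive charge state."""
    if charge <= 0:
        raise ValidationError("charge must be a positive integer")
    return (mass + charge * PROTON) / charge


def neutral_mass(mz_value: float, charge: int) -> float:
    if charge <= 0:
        raise ValidationError("charge must be a positive integer")
    return mz_value * charge - charge * PROTON


# --- precursor matching -------------------------------------------------------


def match_precursor(
    observed_mz: float,
    charge: int,
    candidates,
    ppm_tol: float = 10.0,
    max_isotope: int = 4,
) -> list[PrecursorMatch]:
    """Match an observed precursor against candidate masses within the ppm
    tolerance, allowing the observation to be the monoisotopic peak or any of
    the first ``max_isotope`` isotopes. Matches are ranked by |ppm| then by
    the lower isotope index."""
    obs = neutral_mass(observed_mz, charge)
    matches = []
    for ci, cand in enumerate(candidates):
        cand_mass = cand.mass if isinstance(cand, CrosslinkedPeptide) else float(cand)
        for k in range(max_isotope + 1):
            ppm = (obs - (cand_mass + k * ISOTOPE_SPACING)) / cand_mass * 1e6
            if abs(ppm) <= ppm_tol:
                matches.append(PrecursorMatch(candidate=ci, ppm=ppm, isotope=k))
    matches.sort(key=lambda m: (abs(m.ppm), m.isotope))
    return matches


# --- fragment ions ------------------------------------------------------------


def _chain_fragments(
    chain: PeptideChain,
    site: int,
    partner_mass: float,
    designation: str,
    charges,
) -> list[FragmentIon]:
    n = len(chain)
    mods = dict(chain.modifications)
    res = [RESIDUE_MASS[c] + mods.get(i, 0.0) for i, c in enumerate(chain.sequence)]
    link_payload = partner_mass + DISULFIDE_DELTA
    out = []
    for i in range(1, n):  # b_i / y_i for i = 1..n-1
        b_neutral = sum(res[:i])
        b_linked = site is not None and site <= i - 1
        if b_linked:
            b_neutral += link_payload
        y_neutral = sum(res[n - i:]) + WATER
        y_linked = site is not None and site >= n - i
        if y_linked:
            y_neutral += link_payload
        for z in charges:
            out.append(
                FragmentIon(
                    chain=designation,
                    series="B" if b_linked else "b",
                    index=i,
                    carries_partner=b_linked,
                    charge=z,
                    neutral_mass=b_neutral,
                    mz=(b_neutral + z * PROTON) / z,
                )
            )
            out.append(
                FragmentIon(
                    chain=designation,
                    series="Y" if y_linked else "y",
                    index=i,
                    carries_partner=y_linked,
                    charge=z,
                    neutral_mass=y_neutral,
                    mz=(y_neutral + z * PROTON) / z,
                )
            )
    return out


def linear_fragment_ions(
    chain: PeptideChain | str, charges=(1,)
) -> list[FragmentIon]:
    """Plain b/y ladders of an uncrosslinked peptide."""
    if isinstance(chain, str):
        chain = PeptideChain(sequence=chain)
    return _chain_fragments(
        chain, None, 0.0, "alpha", sorted(set(int(z) for z in charges))
    )


def fragment_ions(xl: CrosslinkedPeptide, charges=(1,)) -> list[FragmentIon]:
    """Theoretical b/y ladders of both chains of a crosslinked pair.

    A fragment whose residue span contains the linked cysteine keeps the
    disulfide and therefore carries the entire partner chain plus the
    disulfide delta; those ions are rendered as the uppercase B/Y series.
    """
    charges = sorted(set(int(z) for z in charges))
    if any(z <= 0 for z in charges):
        raise ValidationError("fragment charges must be positive")
    alpha_full = peptide_mass(xl.alpha)
    beta_full = peptide_mass(xl.beta)
    ions = _chain_fragments(xl.alpha, xl.site_alpha, beta_full, "alpha", charges)
    ions += _chain_fragments(xl.beta, xl.site_beta, alpha_full, "beta", charges)
    return ions


# --- spectrum validation ------------------------------------------------------


def _ladder_family(series: str) -> str:
    return series.lower()  # b/B are one ladder, y/Y the other


def validate_spectrum(
    peaks: list[SpectrumPeak],
    xl: CrosslinkedPeptide,
    fragment_tol_ppm: float = 20.0,
    charges=(1,),
) -> SpectrumReport:
    """Greedy nearest-ppm assignment of theoretical fragments to peaks and
    the continuity filter: the identification passes only when each chain
    has at least four consecutive fragment indices matched within a single
    ladder (b-type or y-type; the case change at the linked cysteine does
    not break the ladder)."""
    theo = fragment_ions(xl, charges)
    pairs = []
    for ti, ion in enumerate(theo):
        for pi, peak in enumerate(peaks):
            ppm = (peak.mz - ion.mz) / ion.mz * 1e6
            if abs(ppm) <= fragment_tol_ppm:
                pairs.append((abs(ppm), ti, pi, ppm))
    pairs.sort(key=lambda t: (t[0], t[1], t[2]))
    used_ion: set[int] = set()
    used_peak: set[int] = set()
    assignments = []
    for _, ti, pi, ppm in pairs:
        # one peak explains one ion; the same index at another charge is a
        # separate theoretical ion and may claim a different peak
        if ti in used_ion or pi in used_peak:
            continue
        used_ion.add(ti)
        used_peak.add(pi)
        assignments.append((theo[ti], pi, ppm))

    matched_idx: dict[tuple[str, str], set[int]] = {}
    for ion, _, _ in assignments:
        matched_idx.setdefault(
            (ion.chain, _ladder_family(ion.series)), set()
        ).add(ion.index)
    longest: dict[tuple[str, str], int] = {}
    for key, idxs in matched_idx.items():
        run = best = 0
        prev = None
        for i in sorted(idxs):
            run = run + 1 if prev is not None and i == prev + 1 else 1
            best = max(best, run)
            prev = i
        longest[key] = best
    passed = all(
        max(
            (longest.get((chain, fam), 0) for fam in ("b", "y")),
            default=0,
        )
        >= 4
        for chain in ("alpha", "beta")
    )
    return SpectrumReport(
        assignments=assignments, longest_run=longest, passed=passed
    )


def read_peak_list(path) -> list[SpectrumPeak]:
    """Two-column (m/z, intensity) whitespace/comma-delimited text reader."""
    peaks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = re.split(r"[,\s]+", line)
            try:
                mz_val = float(fields[0])
                inten = float(fields[1]) if len(fields) > 1 else 1.0
            except (ValueError, IndexError):
                raise ValidationError(
                    f"{path}:{lineno}: unreadable peak line {line!r}"
                ) from None
            peaks.append(SpectrumPeak(mz=mz_val, intensity=inten))
    return peaks
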