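"""Physical constants: element masses, Bondi van der Waals radii, and
monoisotopic mass constants used by the crosslink mass-spectrometry stage.

Residue monoisotopic masses come from :mod:`pyteomics.mass` (standard
unmodified residues). Element masses are average atomic masses, adequate for
centre-of-mass geometry; MS arithmetic uses monoisotopic values throughout.
"""

from __future__ import annotations

from pyteomics import mass as _pmass

# --- geometry / COM constants -------------------------------------------------

#: Average atomic masses in Da, used for mass-weighted centres of mass.
ELEMENT_MASS: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
    "SE": 78.971,
}

#: Bondi van der Waals radii in Angstrom.
BONDI_RADIUS: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "SE": 1.90,
}

DEFAULT_ELEMENT = "C"

# --- mass spectrometry constants ---------------------------------------------

#: Monoisotopic mass of water, Da.
WATER = 18.010565
#: Mass of a proton, Da (charge carrier).
PROTON = 1.007276
#: Averagine isotope spacing, Da (C13 - C12).
ISOTOPE_SPACING = 1.003355
#: Net mass change of joining two cysteines by a disulfide bond (loss of 2 H).
DISULFIDE_DELTA = -2.01565
#: N-ethylmaleimide adduct on a free cysteine (variable modification).
NEM_DELTA = +125.047679

#: Monoisotopic residue masses, Da (standard 20 amino acids).
RESIDUE_MASS: dict[str, float] = {
    aa: _pmass.std_aa_mass[aa] for aa in "ACDEFGHIKLMNPQRSTVWY"
}


def element_of(atom_name: str) -> str:
    """Infer the element from a PDB-style atom name (fallback path only)."""
    stripped = atom_name.strip()
    if stripped[:2].upper() in ("SE",):
        return "SE"
    for ch in stripped:
        if ch.isalpha():
            return ch.upper()
    raise ValueError(f"cannot infer element from atom name {atom_name!r}")
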