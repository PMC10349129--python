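"""Monoisotopic mass arithmetic for peptides and their fragment ions.

Everything mass-related in the package flows through the tables defined
here: elemental isotope masses and abundances, residue elemental
compositions, and the modification table.  The methyl-histidine
modification is defined as a net CH2 addition whose mass is *computed*
from the atomic table, which reproduces both the +14.0157 Da mass shift
used to search for methylated peptides and the m/z 124.0869 diagnostic
immonium ion of methylated histidine.

Conventions
-----------
* All residue and modification positions are 1-based and inclusive,
  so "His1" is position 1 of the mature (signal-peptide-trimmed) chain.
* tau- and pi-methylation of the imidazole nitrogens are isobaric;
  ``methyl_his`` models a single mass delta and makes no isomer claim.
* Only b and y fragment series are generated (CID/HCD of tryptic
  peptides); no neutral losses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PROTON_MASS",
    "MONOISOTOPIC_MASS",
    "ISOTOPES",
    "RESIDUE_COMPOSITIONS",
    "ModifiedPeptide",
    "ModificationTable",
    "FragmentIon",
    "DigestPeptide",
    "default_modification_table",
    "composition_mass",
    "peptide_composition",
    "peptide_neutral_mass",
    "mz_of",
    "immonium_mz",
    "fragment_ions",
    "digest",
    "trim_signal_peptide",
    "isotope_envelope",
]

PROTON_MASS = 1.007276466879

# (monoisotopic-first) isotope masses in Da and natural abundances,
# indexed by neutron-count offset from the lightest isotope.
ISOTOPES: dict[str, list[tuple[float, float]]] = {
    "H": [(1.0078250319, 0.999885), (2.0141017780, 0.000115)],
    "C": [(12.0, 0.9893), (13.0033548378, 0.0107)],
    "N": [(14.0030740052, 0.99636), (15.0001088984, 0.00364)],
    "O": [(15.9949146221, 0.99757), (16.9991315, 0.00038), (17.9991604, 0.00205)],
    "S": [
        (31.97207069, 0.9499),
        (32.97145850, 0.0075),
        (33.96786683, 0.0425),
        (0.0, 0.0),  # A+3 of sulfur does not exist
        (35.96708088, 0.0001),
    ],
}

MONOISOTOPIC_MASS: dict[str, float] = {el: iso[0][0] for el, iso in ISOTOPES.items()}

# Elemental composition of amino acid *residues* (i.e. minus water).
RESIDUE_COMPOSITIONS: dict[str, dict[str, int]] = {
    "G": {"C": 2, "H": 3, "N": 1, "O": 1},
    "A": {"C": 3, "H": 5, "N": 1, "O": 1},
    "S": {"C": 3, "H": 5, "N": 1, "O": 2},
    "P": {"C": 5, "H": 7, "N": 1, "O": 1},
    "V": {"C": 5, "H": 9, "N": 1, "O": 1},
    "T": {"C": 4, "H": 7, "N": 1, "O": 2},
    "C": {"C": 3, "H": 5, "N": 1, "O": 1, "S": 1},
    "L": {"C": 6, "H": 11, "N": 1, "O": 1},
    "I": {"C": 6, "H": 11, "N": 1, "O": 1},
    "N": {"C": 4, "H": 6, "N": 2, "O": 2},
    "D": {"C": 4, "H": 5, "N": 1, "O": 3},
    "Q": {"C": 5, "H": 8, "N": 2, "O": 2},
    "K": {"C": 6, "H": 12, "N": 2, "O": 1},
    "E": {"C": 5, "H": 7, "N": 1, "O": 3},
    "M": {"C": 5, "H": 9, "N": 1, "O": 1, "S": 1},
    "H": {"C": 6, "H": 7, "N": 3, "O": 1},
    "F": {"C": 9, "H": 9, "N": 1, "O": 1},
    "R": {"C": 6, "H": 12, "N": 4, "O": 1},
    "Y": {"C": 9, "H": 9, "N": 1, "O": 2},
    "W": {"C": 11, "H": 10, "N": 2, "O": 1},
}

WATER = {"H": 2, "O": 1}
CO = {"C": 1, "O": 1}


def composition_mass(composition: dict[str, int]) -> float:
    """Monoisotopic mass of an elemental composition in Da."""
    try:
        return sum(MONOISOTOPIC_MASS[el] * n for el, n in composition.items())
    except KeyError as exc:  # pragma: no cover - defensive
        raise ValueError(f"unknown element {exc.args[0]!r}") from None


def _add_composition(a: dict[str, int], b: dict[str, int], factor: int = 1) -> None:
    for el, n in b.items():
        a[el] = a.get(el, 0) + factor * n


@dataclass(frozen=True)
class ModificationTable:
    """Named monoisotopic mass deltas and the residues they may sit on.

    ``compositions`` is optional per modification; it is required only
    for modifications that participate in isotope-envelope calculations
    (methyl_his does, and its delta is derived from the composition so
    the two can never disagree).
    """

    deltas: dict[str, float]
    allowed_residues: dict[str, frozenset[str]]
    compositions: dict[str, dict[str, int]] = field(default_factory=dict)

    def delta(self, mod_name: str) -> float:
        if mod_name not in self.deltas:
            raise KeyError(f"unknown modification {mod_name!r}")
        return self.deltas[mod_name]

    def check_allowed(self, mod_name: str, residue: str) -> None:
        self.delta(mod_name)
        if residue not in self.allowed_residues.get(mod_name, frozenset()):
            raise ValueError(
                f"modification {mod_name!r} is not allowed on residue {residue!r}"
            )


def default_modification_table() -> ModificationTable:
    """Modification table with methyl_his computed from atomic masses.

    The methyl group replaces an imidazole N-H hydrogen, so the net
    elemental change is +CH2.
    """
    methyl = {"C": 1, "H": 2}
    phospho = {"H": 1, "P": 1, "O": 3}  # composition informational only
    return ModificationTable(
        deltas={
            "methyl_his": composition_mass(methyl),
            # included so that illegal-placement errors are exercised;
            # delta from standard HPO3 monoisotopic mass
            "phospho": 79.96633,
        },
        allowed_residues={
            "methyl_his": frozenset("H"),
            "phospho": frozenset("STY"),
        },
        compositions={"methyl_his": methyl, "phospho": phospho},
    )


@dataclass(frozen=True)
class ModifiedPeptide:
    """A peptide sequence with positioned modifications.

    Parameters
    ----------
    sequence : str
        Upper-case one-letter amino acid sequence.
    mods : tuple of (int, str)
        1-based residue position and modification name.  At most one
        modification per position; a ``methyl_his`` may only sit on H.
    n_term_free : bool
        Position 1 carries a free alpha-amine (no N-terminal acetylation).
    """

    sequence: str
    mods: tuple[tuple[int, str], ...] = ()
    n_term_free: bool = True

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty peptide sequence")
        for ch in self.sequence:
            if ch not in RESIDUE_COMPOSITIONS:
                raise ValueError(f"unknown residue letter {ch!r}")
        positions = [pos for pos, _ in self.mods]
        if len(positions) != len(set(positions)):
            raise ValueError("at most one modification per position")
        for pos, name in self.mods:
            if not 1 <= pos <= len(self.sequence):
                raise ValueError(
                    f"modification position {pos} outside 1..{len(self.sequence)}"
                )
            if name == "methyl_his" and self.sequence[pos - 1] != "H":
                raise ValueError(
                    f"methyl_his at position {pos} requires H, "
                    f"found {self.sequence[pos - 1]!r}"
                )

    def mod_at(self, pos: int) -> str | None:
        for p, name in self.mods:
            if p == pos:
                return name
        return None


@dataclass(frozen=True)
class FragmentIon:
    """A b- or y-series fragment ion."""

    series: str  # "b" or "y"
    index: int  # ordinal >= 1
    charge: int
    mz: float
    composition_peptide: str  # the sub-sequence the ion covers
    carries_mod: bool


@dataclass(frozen=True)
class DigestPeptide:
    """A proteolytic peptide with 1-based inclusive protein coordinates."""

    sequence: str
    start: int
    end: int
    missed_cleavages: int


def peptide_composition(
    p: ModifiedPeptide, mods: ModificationTable | None = None
) -> dict[str, int]:
    """Elemental composition of the neutral peptide, including water and mods."""
    mods = mods or default_modification_table()
    comp: dict[str, int] = {}
    for ch in p.sequence:
        _add_composition(comp, RESIDUE_COMPOSITIONS[ch])
    _add_composition(comp, WATER)
    for pos, name in p.mods:
        mods.check_allowed(name, p.sequence[pos - 1])
        if name not in mods.compositions:
            raise ValueError(
                f"modification {name!r} has no elemental composition defined"
            )
        _add_composition(comp, mods.compositions[name])
    return comp


def peptide_neutral_mass(
    p: ModifiedPeptide, mods: ModificationTable | None = None
) -> float:
    """Monoisotopic neutral mass: residue masses + water + modification deltas."""
    mods = mods or default_modification_table()
    mass = composition_mass(WATER)
    for ch in p.sequence:
        mass += composition_mass(RESIDUE_COMPOSITIONS[ch])
    for pos, name in p.mods:
        mods.check_allowed(name, p.sequence[pos - 1])
        mass += mods.delta(name)
    return mass


def mz_of(neutral_mass: float, charge: int) -> float:
    """m/z of a neutral mass at a positive charge state (proton adducts)."""
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return (neutral_mass + charge * PROTON_MASS) / charge


def immonium_mz(
    residue: str, mod_name: str | None = None, mods: ModificationTable | None = None
) -> float:
    """m/z of the (singly charged) immonium ion of a residue.

    Standard a1-type immonium: residue mass - CO + proton.  For
    methylated histidine this evaluates to m/z 124.0869, the diagnostic
    ion used to corroborate methyl-His localization.
    """
    mods = mods or default_modification_table()
    if residue not in RESIDUE_COMPOSITIONS:
        raise ValueError(f"unknown residue letter {residue!r}")
    mz = (
        composition_mass(RESIDUE_COMPOSITIONS[residue])
        - composition_mass(CO)
        + PROTON_MASS
    )
    if mod_name is not None:
        mods.check_allowed(mod_name, residue)
        mz += mods.delta(mod_name)
    return mz


def methyl_his_immonium_mz(mods: ModificationTable | None = None) -> float:
    """Diagnostic immonium m/z of methylated histidine."""
    return immonium_mz("H", "methyl_his", mods)


def fragment_ions(
    p: ModifiedPeptide,
    charges: set[int] | frozenset[int] = frozenset({1}),
    mods: ModificationTable | None = None,
) -> list[FragmentIon]:
    """All b1..b(n-1) and y1..y(n-1) ions at each requested charge.

    Modification deltas are assigned to the fragments whose residue span
    covers the modified position, so an N-terminal methyl shifts every
    b ion and no y ion.  Result is sorted by m/z.
    """
    mods = mods or default_modification_table()
    if len(p.sequence) < 2:
        raise ValueError("fragmentation requires a peptide of length >= 2")
    if not charges:
        raise ValueError("empty charge set")
    if any(z < 1 for z in charges):
        raise ValueError("charges must be positive")

    n = len(p.sequence)
    residue_masses = [
        composition_mass(RESIDUE_COMPOSITIONS[ch]) for ch in p.sequence
    ]
    mod_deltas = [0.0] * n
    for pos, name in p.mods:
        mods.check_allowed(name, p.sequence[pos - 1])
        mod_deltas[pos - 1] = mods.delta(name)

    water = composition_mass(WATER)
    ions: list[FragmentIon] = []
    for i in range(1, n):
        b_neutral = sum(residue_masses[:i]) + sum(mod_deltas[:i])
        y_neutral = sum(residue_masses[i:]) + sum(mod_deltas[i:]) + water
        b_mod = any(d != 0.0 for d in mod_deltas[:i])
        y_mod = any(d != 0.0 for d in mod_deltas[i:])
        for z in sorted(charges):
            ions.append(
                FragmentIon("b", i, z, mz_of(b_neutral, z), p.sequence[:i], b_mod)
            )
            ions.append(
                FragmentIon(
                    "y", n - i, z, mz_of(y_neutral, z), p.sequence[i:], y_mod
                )
            )
    ions.sort(key=lambda ion: ion.mz)
    return ions


_PROTEASE_CLEAVES_AFTER = {"trypsin_p": "KR", "lysc": "K"}


def digest(
    protein: str, protease: str = "trypsin_p", max_missed: int = 2
) -> list[DigestPeptide]:
    """In-silico digestion with 0..max_missed missed cleavages.

    ``trypsin_p`` cleaves C-terminal to K and R including before
    proline (the /P convention); ``lysc`` cleaves after K only.
    Coordinates are 1-based inclusive.
    """
    if not protein:
        raise ValueError("empty protein sequence")
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    try:
        cleave_after = _PROTEASE_CLEAVES_AFTER[protease]
    except KeyError:
        raise ValueError(f"unknown protease {protease!r}") from None

    # cut points: index after which the chain is cut (0 and len are termini)
    cuts = [0]
    cuts += [i + 1 for i, ch in enumerate(protein) if ch in cleave_after and i + 1 < len(protein)]
    cuts.append(len(protein))

    peptides: list[DigestPeptide] = []
    for a, start_cut in enumerate(cuts[:-1]):
        for missed in range(max_missed + 1):
            b = a + 1 + missed
            if b >= len(cuts):
                break
            end_cut = cuts[b]
            peptides.append(
                DigestPeptide(
                    sequence=protein[start_cut:end_cut],
                    start=start_cut + 1,
                    end=end_cut,
                    missed_cleavages=missed,
                )
            )
    return peptides


def trim_signal_peptide(protein: str, cleavage_after: int) -> str:
    """Remove a signal peptide; the residue after the cleavage site becomes
    position 1 of the mature protein (His1 for LPMOs)."""
    if not 0 <= cleavage_after < len(protein):
        raise ValueError(
            f"cleavage_after={cleavage_after} outside 0..{len(protein) - 1}"
        )
    return protein[cleavage_after:]


def _power_spectrum(dist: np.ndarray, count: int, n_peaks: int) -> np.ndarray:
    """dist convolved with itself `count` times, truncated to n_peaks."""
    result = np.zeros(n_peaks)
    result[0] = 1.0
    base = dist[:n_peaks].copy()
    while count:
        if count & 1:
            result = np.convolve(result, base)[:n_peaks]
        count >>= 1
        if count:
            base = np.convolve(base, base)[:n_peaks]
    return result


def isotope_envelope(
    p: ModifiedPeptide, n_peaks: int = 3, mods: ModificationTable | None = None
) -> list[tuple[int, float]]:
    """First ``n_peaks`` isotopologue abundances of the neutral peptide.

    Computed by polynomial expansion (convolution) of the per-element
    isotope distributions over the peptide's elemental composition.
    Returns (neutron-offset index, probability) pairs starting at the
    monoisotopic peak; probabilities are exact, so they sum to <= 1.
    """
    if n_peaks < 1:
        raise ValueError("n_peaks must be >= 1")
    comp = peptide_composition(p, mods)
    dist = np.zeros(n_peaks)
    dist[0] = 1.0
    for el, count in comp.items():
        if count == 0:
            continue
        abund = np.array([a for _, a in ISOTOPES[el]])
        dist = np.convolve(dist, _power_spectrum(abund, count, n_peaks))[:n_peaks]
    return [(i, float(dist[i])) for i in range(n_peaks)]
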