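"""Peptide mass and m/z arithmetic for targeted-MS assay design.

Monoisotopic masses drive candidate filtering; heavy-label deltas, precursor
m/z and b/y fragment m/z define the transitions monitored in a parallel
reaction monitoring (PRM) assay.  Residue masses come from pyteomics'
standard tables; everything here is plain sum-of-residues arithmetic on top.

Isobaric peptides are a real hazard in near-identical protein families: two
peptides may share amino-acid composition (hence mass) while differing as
strings.  Nothing in this module — and nothing downstream — may therefore
identify a peptide by mass alone; identity is always (sequence, subtype).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Iterable, Mapping

from pyteomics import mass as _pmass

__all__ = [
    "WATER_MONO",
    "PROTON",
    "ResidueMassTable",
    "LabelScheme",
    "ModificationSpec",
    "MET_OXIDATION",
    "CARBAMIDOMETHYL_CYS",
    "monoisotopic_mass",
    "average_mass",
    "heavy_mass",
    "precursor_mz",
    "fragment_mz",
]

#: Monoisotopic mass of water (Da), released on peptide-bond hydrolysis.
WATER_MONO = 18.0105646863
#: Mass of a proton (Da); charge carrier for positive-mode m/z.
PROTON = 1.00727646688

# Single-isotope substitution deltas used to build heavy-label schemes.
_C13_DELTA = 1.003355
_N15_DELTA = 0.997035

_STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")


def _validate_peptide(peptide: str) -> None:
    if not peptide:
        raise ValueError("peptide must be a non-empty sequence")
    for i, ch in enumerate(peptide, start=1):
        if ch not in _STANDARD_RESIDUES:
            raise ValueError(
                f"invalid residue {ch!r} at position {i}: only the 20 "
                "standard one-letter amino-acid codes are supported"
            )


@dataclass(frozen=True)
class ResidueMassTable:
    """Immutable residue -> monoisotopic mass table (Da).

    Defaults are pyteomics' standard monoisotopic residue masses.
    """

    residues: Mapping[str, float] = field(
        default_factory=lambda: MappingProxyType(
            {aa: _pmass.std_aa_mass[aa] for aa in _STANDARD_RESIDUES}
        )
    )
    water: float = WATER_MONO
    proton: float = PROTON

    def __post_init__(self) -> None:
        if any(m <= 0 for m in self.residues.values()):
            raise ValueError("residue masses must be positive")
        object.__setattr__(self, "residues", MappingProxyType(dict(self.residues)))


_DEFAULT_TABLE = ResidueMassTable()

# Average residue masses, used only for protein molar mass (g/mol) when
# converting femtomoles of peptide to nanograms of parent protein.
_AVERAGE_AA_MASS = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594, "N": 114.1038,
    "D": 115.0886, "Q": 128.1307, "K": 128.1741, "E": 129.1155, "M": 131.1926,
    "H": 137.1411, "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}
_WATER_AVG = 18.01528


@dataclass(frozen=True)
class LabelScheme:
    """Residue -> mass delta (Da) for stable-isotope heavy labels.

    The default is the common SIS chemistry: fully substituted
    Lys(+8) = 6x13C + 2x15N, Leu/Ile(+7) = 6x13C + 1x15N and
    Ala(+4) = 3x13C + 1x15N.
    """

    deltas: Mapping[str, float] = field(
        default_factory=lambda: MappingProxyType(
            {
                "K": 6 * _C13_DELTA + 2 * _N15_DELTA,
                "L": 6 * _C13_DELTA + 1 * _N15_DELTA,
                "I": 6 * _C13_DELTA + 1 * _N15_DELTA,
                "A": 3 * _C13_DELTA + 1 * _N15_DELTA,
            }
        )
    )
    name: str = "13C/15N full substitution (K+8, L+7, I+7, A+4)"

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.deltas.values()):
            raise ValueError("label deltas must be positive")
        object.__setattr__(self, "deltas", MappingProxyType(dict(self.deltas)))


@dataclass(frozen=True)
class ModificationSpec:
    """A named mass modification on a residue (or terminus).

    ``target`` is the one-letter residue code the modification applies to
    ("*" for any).  At most one variable modification per residue position.
    """

    name: str
    target: str
    delta: float

    def __post_init__(self) -> None:
        if not (self.delta == self.delta and abs(self.delta) != float("inf")):
            raise ValueError("modification delta must be finite")


MET_OXIDATION = ModificationSpec("oxidation", "M", 15.9949146221)
CARBAMIDOMETHYL_CYS = ModificationSpec("carbamidomethyl", "C", 57.0214637236)


ModMap = Mapping[int, ModificationSpec]


def _check_mods(peptide: str, mods: ModMap | None) -> ModMap:
    if not mods:
        return {}
    for pos, spec in mods.items():
        if not 1 <= pos <= len(peptide):
            raise ValueError(f"modification position {pos} outside peptide")
        if spec.target != "*" and peptide[pos - 1] != spec.target:
            raise ValueError(
                f"modification {spec.name!r} targets {spec.target!r} but "
                f"position {pos} holds {peptide[pos - 1]!r}"
            )
    return mods


def monoisotopic_mass(
    peptide: str,
    mods: ModMap | None = None,
    table: ResidueMassTable = _DEFAULT_TABLE,
) -> float:
    """Neutral monoisotopic mass (Da) of a peptide.

    ``mods`` maps 1-based positions to :class:`ModificationSpec`.  The result
    is a pure sum, so it is independent of residue order: permutations — and
    in particular compositionally identical peptides from homologous
    proteins — are isobaric.
    """
    _validate_peptide(peptide)
    mods = _check_mods(peptide, mods)
    total = table.water + sum(table.residues[aa] for aa in peptide)
    total += sum(spec.delta for spec in mods.values())
    return total


def average_mass(sequence: str) -> float:
    """Average (chemical) mass in Da == molar mass in g/mol of a protein."""
    _validate_peptide(sequence)
    return _WATER_AVG + sum(_AVERAGE_AA_MASS[aa] for aa in sequence)


def heavy_mass(
    peptide: str,
    scheme: LabelScheme | None = None,
    labeled_positions: Iterable[int] = (),
    mods: ModMap | None = None,
    table: ResidueMassTable = _DEFAULT_TABLE,
) -> float:
    """Mass of the stable-isotope-labeled (heavy) form of a peptide.

    ``labeled_positions`` are 1-based positions carrying a heavy residue;
    each position's residue must be present in the label scheme.
    """
    scheme = scheme or LabelScheme()
    positions = sorted(set(labeled_positions))
    if not positions:
        raise ValueError("at least one labeled position is required")
    light = monoisotopic_mass(peptide, mods=mods, table=table)
    delta = 0.0
    for pos in positions:
        if not 1 <= pos <= len(peptide):
            raise ValueError(f"labeled position {pos} outside peptide")
        residue = peptide[pos - 1]
        if residue not in scheme.deltas:
            raise ValueError(
                f"residue {residue!r} at position {pos} has no heavy label "
                f"in scheme {scheme.name!r}"
            )
        delta += scheme.deltas[residue]
    return light + delta


def precursor_mz(mass: float, charge: int, table: ResidueMassTable = _DEFAULT_TABLE) -> float:
    """m/z of a [M + zH]z+ precursor ion."""
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return (mass + charge * table.proton) / charge


def fragment_mz(
    peptide: str,
    series: str,
    index: int,
    charge: int = 1,
    mods: ModMap | None = None,
    table: ResidueMassTable = _DEFAULT_TABLE,
) -> float:
    """m/z of a b- or y-series fragment ion.

    b_i covers the N-terminal i residues (neutral mass = residue sum);
    y_i covers the C-terminal i residues (residue sum + water).  Positional
    modifications contribute only when the modified residue is covered by
    the fragment.
    """
    _validate_peptide(peptide)
    mods = _check_mods(peptide, mods)
    n = len(peptide)
    if series not in ("b", "y"):
        raise ValueError(f"series must be 'b' or 'y', got {series!r}")
    if not 1 <= index <= n:
        raise ValueError(f"fragment index {index} out of range for length {n}")
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    if series == "b":
        covered = range(1, index + 1)
        neutral = sum(table.residues[peptide[i - 1]] for i in covered)
    else:
        covered = range(n - index + 1, n + 1)
        neutral = table.water + sum(table.residues[peptide[i - 1]] for i in covered)
    neutral += sum(spec.delta for pos, spec in mods.items() if pos in covered)
    return (neutral + charge * table.proton) / charge
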