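"""Assay definitions: the machine-readable form of a PRM peptide panel.

An assay declares, per quantification peptide: the target subtype, the
producing enzyme, sequence coordinates in the parent protein, which
residue positions carry the heavy label (the synthesis chemistry decides
this, so it is configuration, not inference), the precursor charge, the
monitored transitions, whether a Met-oxidation correction applies, and any
miscleaved sibling forms quantified on their own external curves.

A panel for the seven human somatic H1 subtypes ships with the package
(``load_builtin_h1_assay``).
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

from .masses import LabelScheme, heavy_mass, monoisotopic_mass
from .proteolysis import Enzyme, ProteinRecord

__all__ = [
    "Transition",
    "AssayPeptide",
    "AssayDefinition",
    "load_assay",
    "load_builtin_h1_assay",
    "verify_assay_positions",
]


@dataclass(frozen=True)
class Transition:
    """One monitored fragment ion: series ('b'/'y'), index, charge."""

    series: str
    index: int
    charge: int = 1

    def __post_init__(self) -> None:
        if self.series not in ("b", "y"):
            raise ValueError(f"series must be 'b' or 'y', got {self.series!r}")
        if self.index < 1 or self.charge < 1:
            raise ValueError("index and charge must be >= 1")

    @property
    def key(self) -> str:
        return f"{self.series}{self.index}+{self.charge}"

    @classmethod
    def parse(cls, text: str) -> "Transition":
        """Parse 'y4+1' / 'b7+2' style keys."""
        body, _, z = text.partition("+")
        return cls(series=body[0], index=int(body[1:]), charge=int(z or "1"))


@dataclass(frozen=True)
class AssayPeptide:
    sequence: str
    subtype: str
    enzyme: Enzyme
    start: int
    end: int
    missed_cleavages: int = 0
    label_positions: tuple[int, ...] = ()
    precursor_charge: int = 2
    transitions: tuple[Transition, ...] = ()
    oxidation_correction: bool = False
    miscleaved_forms: tuple[str, ...] = ()

    def light_mass(self) -> float:
        return monoisotopic_mass(self.sequence)

    def heavy_mass(self, scheme: LabelScheme | None = None) -> float:
        return heavy_mass(self.sequence, scheme=scheme, labeled_positions=self.label_positions)


@dataclass(frozen=True)
class AssayDefinition:
    name: str
    peptides: tuple[AssayPeptide, ...]
    accession_to_subtype: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        subtypes = [p.subtype for p in self.peptides]
        if len(set(subtypes)) != len(subtypes):
            raise ValueError("one quantification peptide per subtype expected")

    def peptide_for(self, subtype: str) -> AssayPeptide:
        for p in self.peptides:
            if p.subtype == subtype:
                return p
        raise KeyError(subtype)

    def by_sequence(self) -> dict[str, AssayPeptide]:
        return {p.sequence: p for p in self.peptides}

    @property
    def subtypes(self) -> tuple[str, ...]:
        return tuple(p.subtype for p in self.peptides)


def _peptide_from_dict(d: dict) -> AssayPeptide:
    return AssayPeptide(
        sequence=d["sequence"],
        subtype=d["subtype"],
        enzyme=Enzyme(d["enzyme"]),
        start=int(d["start"]),
        end=int(d["end"]),
        missed_cleavages=int(d.get("missed_cleavages", 0)),
        label_positions=tuple(d.get("label_positions", ())),
        precursor_charge=int(d.get("precursor_charge", 2)),
        transitions=tuple(Transition.parse(t) for t in d.get("transitions", ())),
        oxidation_correction=bool(d.get("oxidation_correction", False)),
        miscleaved_forms=tuple(d.get("miscleaved_forms", ())),
    )


def load_assay(path: str | Path) -> AssayDefinition:
    """Load an assay definition from a TOML file."""
    with open(path, "rb") as fh:
        doc = tomllib.load(fh)
    return _assay_from_doc(doc)


def _assay_from_doc(doc: dict) -> AssayDefinition:
    return AssayDefinition(
        name=doc.get("name", "unnamed"),
        peptides=tuple(_peptide_from_dict(d) for d in doc["peptide"]),
        accession_to_subtype=dict(doc.get("accessions", {})),
    )


def load_builtin_h1_assay() -> AssayDefinition:
    """The packaged PRM panel for the seven human somatic H1 subtypes."""
    data = resources.files("prmkit.data").joinpath("h1_assay.toml").read_bytes()
    return _assay_from_doc(tomllib.loads(data.decode()))


def verify_assay_positions(
    assay: AssayDefinition, family: Sequence[ProteinRecord]
) -> dict[str, bool]:
    """Check that each assay peptide's [start, end] slice of its parent
    reproduces its sequence (initiator Met counted as residue 1).

    Returns subtype -> ok; missing parents raise KeyError.
    """
    by_id = {rec.id: rec for rec in family}
    result = {}
    for pep in assay.peptides:
        parent = by_id[pep.subtype]
        result[pep.subtype] = (
            parent.sequence[pep.start - 1 : pep.end] == pep.sequence
        )
    return result
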