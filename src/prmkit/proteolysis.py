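"""In-silico proteolysis and proteotypic-peptide selection.

For a family of near-identical proteins (the motivating case: the seven
human somatic linker-histone H1 subtypes, 65-86% pairwise identity among
the replication-dependent members) absolute quantification by targeted MS
requires peptides that occur in exactly one family member.  This module
digests each protein with trypsin and/or Glu-C, applies the standard
candidate filters (length, monoisotopic mass) and flags uniqueness by exact
substring search against every full-length family sequence.

Positions are 1-based inclusive, counting the initiator methionine of the
canonical sequence as residue 1.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .masses import ResidueMassTable, monoisotopic_mass

__all__ = [
    "Enzyme",
    "GluCMode",
    "ProteinRecord",
    "DigestionParams",
    "PeptideCandidate",
    "digest",
    "enumerate_candidates",
    "annotate_ess",
    "rank_by_ess",
]

_STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")


class Enzyme(str, Enum):
    TRYPSIN = "trypsin"
    GLU_C = "glu_c"


class GluCMode(str, Enum):
    """Glu-C specificity depends on buffer: E only (ammonium bicarbonate)
    or E and D (phosphate)."""

    E_ONLY = "E_only"
    E_AND_D = "E_and_D"


@dataclass(frozen=True)
class ProteinRecord:
    """One family member: subtype label, database accession, sequence."""

    id: str
    accession: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        for i, ch in enumerate(self.sequence, start=1):
            if ch not in _STANDARD_RESIDUES:
                raise ValueError(
                    f"protein {self.id!r}: invalid residue {ch!r} at position {i}"
                )


@dataclass(frozen=True)
class DigestionParams:
    """Cleavage specificity and candidate filters for one enzyme.

    ``proline_rule`` suppresses cleavage when the residue following the
    site is proline (the classical trypsin exception; off by default for
    Glu-C).  Filters: candidates are kept when length <= ``max_length``
    ("less than 25 residues" reads as <= 24) and neutral unmodified
    monoisotopic mass >= ``min_mass_da``.
    """

    enzyme: Enzyme
    glu_c_mode: GluCMode = GluCMode.E_ONLY
    max_missed_cleavages: int = 0
    min_mass_da: float = 600.0
    max_length: int = 24
    proline_rule: bool = True

    def __post_init__(self) -> None:
        if self.max_length < 1:
            raise ValueError("max_length must be >= 1")
        if self.min_mass_da < 0:
            raise ValueError("min_mass_da must be >= 0")
        if self.max_missed_cleavages < 0:
            raise ValueError("max_missed_cleavages must be >= 0")

    @classmethod
    def trypsin(cls, **kw) -> "DigestionParams":
        return cls(enzyme=Enzyme.TRYPSIN, **kw)

    @classmethod
    def glu_c(cls, mode: GluCMode = GluCMode.E_ONLY, **kw) -> "DigestionParams":
        kw.setdefault("proline_rule", False)
        return cls(enzyme=Enzyme.GLU_C, glu_c_mode=mode, **kw)

    @property
    def cleavage_residues(self) -> frozenset[str]:
        if self.enzyme is Enzyme.TRYPSIN:
            return frozenset("KR")
        if self.glu_c_mode is GluCMode.E_AND_D:
            return frozenset("ED")
        return frozenset("E")


@dataclass(frozen=True)
class PeptideCandidate:
    """One digestion product, with provenance and selection metadata."""

    sequence: str
    subtype: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    enzyme: Enzyme
    missed_cleavages: int
    mono_mass: float
    unique: bool | None = None
    ess: float | None = None
    n_observations: int | None = None
    accession: str = ""

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError(
                f"positions {self.start}-{self.end} inconsistent with "
                f"length {len(self.sequence)}"
            )
        if self.mono_mass <= 0:
            raise ValueError("mono_mass must be positive")
        if self.ess is not None and not 0.0 <= self.ess <= 1.0:
            raise ValueError(f"ess must be in [0, 1], got {self.ess}")


def cleavage_sites(sequence: str, params: DigestionParams) -> list[int]:
    """0-based indices i such that the bond after sequence[i] is cleaved."""
    residues = params.cleavage_residues
    sites = []
    for i, aa in enumerate(sequence[:-1]):
        if aa in residues:
            if params.proline_rule and sequence[i + 1] == "P":
                continue
            sites.append(i)
    return sites


def digest(
    sequence: str,
    params: DigestionParams,
    subtype: str = "",
    accession: str = "",
    table: ResidueMassTable | None = None,
) -> list[PeptideCandidate]:
    """Digest one protein sequence; no length/mass filtering at this stage.

    With ``max_missed_cleavages = k`` the output contains every
    concatenation of 1..k+1 adjacent fully-cleaved fragments, with its
    missed-cleavage count recorded.
    """
    if not sequence:
        raise ValueError("cannot digest an empty sequence")
    for i, ch in enumerate(sequence, start=1):
        if ch not in _STANDARD_RESIDUES:
            raise ValueError(f"invalid residue {ch!r} at position {i}")
    kwargs = {"table": table} if table is not None else {}

    sites = cleavage_sites(sequence, params)
    # fragment boundaries as 0-based [start, end) pairs
    starts = [0] + [s + 1 for s in sites]
    ends = [s + 1 for s in sites] + [len(sequence)]
    n_frag = len(starts)
    out: list[PeptideCandidate] = []
    for i in range(n_frag):
        for k in range(params.max_missed_cleavages + 1):
            j = i + k
            if j >= n_frag:
                break
            s, e = starts[i], ends[j]
            pep = sequence[s:e]
            out.append(
                PeptideCandidate(
                    sequence=pep,
                    subtype=subtype,
                    start=s + 1,
                    end=e,
                    enzyme=params.enzyme,
                    missed_cleavages=k,
                    mono_mass=monoisotopic_mass(pep, **kwargs),
                    accession=accession,
                )
            )
    out.sort(key=lambda c: (c.start, c.end))
    return out


def _occurrence_count(peptide: str, family: Sequence[ProteinRecord]) -> int:
    """Number of family members whose full sequence contains the peptide."""
    return sum(1 for rec in family if peptide in rec.sequence)


def enumerate_candidates(
    family: Sequence[ProteinRecord],
    params_trypsin: DigestionParams | None = None,
    params_gluc: DigestionParams | None = None,
    keep_shared: bool = False,
    background: Sequence[ProteinRecord] = (),
) -> list[PeptideCandidate]:
    """Enumerate filtered, family-unique candidate peptides.

    Each protein is digested with both enzymes (pass ``None`` to skip one);
    peptides pass the filters when length <= max_length and monoisotopic
    mass >= min_mass_da; a peptide is *unique* when its sequence occurs, as
    an exact substring, in exactly one family member's full sequence (I/L
    are distinct characters).  ``background`` sequences, when given, must
    also not contain the peptide.  By default only unique candidates are
    returned, sorted by (subtype, start).
    """
    if not family:
        raise ValueError("family must be non-empty")
    ids = [rec.id for rec in family]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate subtype ids in family: {dupes}")

    param_sets = [p for p in (params_trypsin, params_gluc) if p is not None]
    if not param_sets:
        raise ValueError("at least one enzyme's DigestionParams is required")

    out: list[PeptideCandidate] = []
    for rec in family:
        seen: dict[tuple[str, int], PeptideCandidate] = {}
        for params in param_sets:
            for cand in digest(rec.sequence, params, subtype=rec.id, accession=rec.accession):
                if len(cand.sequence) > params.max_length:
                    continue
                if cand.mono_mass < params.min_mass_da:
                    continue
                key = (cand.sequence, cand.start)
                if key in seen:
                    continue  # same peptide from the other enzyme
                seen[key] = cand
        for cand in seen.values():
            n_occ = _occurrence_count(cand.sequence, family)
            is_unique = n_occ == 1 and _occurrence_count(cand.sequence, background) == 0
            if is_unique or keep_shared:
                out.append(replace(cand, unique=is_unique))
    out.sort(key=lambda c: (c.subtype, c.start, c.end))
    return out


def annotate_ess(
    candidates: Iterable[PeptideCandidate],
    ess_table: Mapping[str, tuple[float, int]],
) -> list[PeptideCandidate]:
    """Attach empirical suitability scores (ESS, from a spectral-evidence
    database such as PeptideAtlas) to candidates by peptide sequence.

    Missing entries are left unset; ESS outside [0, 1] is rejected.
    """
    for pep, (ess, _n) in ess_table.items():
        if not 0.0 <= ess <= 1.0:
            raise ValueError(f"ESS for {pep!r} outside [0, 1]: {ess}")
    out = []
    for cand in candidates:
        entry = ess_table.get(cand.sequence)
        if entry is None:
            out.append(cand)
        else:
            ess, n_obs = entry
            out.append(replace(cand, ess=ess, n_observations=int(n_obs)))
    return out


def rank_by_ess(
    candidates: Iterable[PeptideCandidate],
) -> dict[str, list[PeptideCandidate]]:
    """Per-subtype candidates sorted by ESS descending (unset ESS last)."""
    by_subtype: dict[str, list[PeptideCandidate]] = {}
    for cand in candidates:
        by_subtype.setdefault(cand.subtype, []).append(cand)
    for subtype, cands in by_subtype.items():
        cands.sort(key=lambda c: (-(c.ess if c.ess is not None else -1.0), c.start))
    return by_subtype
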