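"""From transition-level peak areas to absolute subtype amounts and
complement profiles.

The quantification signal for one peptide in one replicate is the ratio of
summed light to summed heavy fragment-ion areas over the *matched* set of
transitions (intersection of the fragments observed in both labels — a
ratio must compare like with like).  For Met-containing peptides the
oxidized and unmodified forms are summed at the area level per label before
ratioing, so partial oxidation does not lose signal.  Amounts are expressed
per microgram of protein extract or per milliliter of blood; the
"complement" view renormalizes quantifiable subtypes to percent-of-total.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Iterable, Literal, Mapping, Sequence

__all__ = [
    "PeakAreaRecord",
    "SubtypeQuant",
    "ComplementProfile",
    "BandModel",
    "DEFAULT_BAND_MODEL",
    "lh_ratio",
    "combine_oxidized",
    "to_absolute",
    "complement_profile",
    "expected_band_percentages",
    "replicate_cv",
]

CANONICAL = "canonical"
OXIDIZED = "oxidized"


@dataclass(frozen=True)
class PeakAreaRecord:
    """One transition's integrated XIC area for one replicate and label."""

    sample: str
    replicate: str
    peptide: str
    form: str  # "canonical", "oxidized", or "miscleaved:<sequence>"
    label: Literal["light", "heavy"]
    fragment: str  # e.g. "y4+1"
    area: float
    retention_time: float | None = None

    def __post_init__(self) -> None:
        if self.area < 0:
            raise ValueError(f"negative area {self.area} for {self.peptide} {self.fragment}")
        if self.label not in ("light", "heavy"):
            raise ValueError(f"label must be 'light' or 'heavy', got {self.label!r}")

    @property
    def key(self) -> tuple:
        return (self.sample, self.replicate, self.peptide, self.form, self.label, self.fragment)


@dataclass(frozen=True)
class SubtypeQuant:
    """Absolute amount of one subtype in one sample (replicate-averaged)."""

    subtype: str
    amount: float
    unit: str  # "ng/ug" or "ng/mL"
    cv: float | None = None
    below_loq: bool = False
    n_replicates: int = 1

    def __post_init__(self) -> None:
        if self.amount < 0:
            raise ValueError("amount must be >= 0")
        if self.cv is not None and self.cv < 0:
            raise ValueError("cv must be >= 0")


@dataclass(frozen=True)
class ComplementProfile:
    """Percent-of-total representation of the subtype family in a sample."""

    sample: str
    percents: Mapping[str, float]
    total: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "percents", MappingProxyType(dict(self.percents)))
        if any(p < 0 for p in self.percents.values()):
            raise ValueError("percentages must be >= 0")
        if self.percents and abs(sum(self.percents.values()) - 100.0) > 1e-9:
            raise ValueError("percentages must sum to 100")


@dataclass(frozen=True)
class BandModel:
    """Electrophoretic band -> set of co-migrating subtypes.

    The default reflects SDS-PAGE of linker-histone acid extracts: one
    high-MW band with H1.3/H1.4/H1.5, an intermediate band with H1.1/H1.2,
    and a low-MW band with H1.0.  Subtypes outside every band (H1X) are
    excluded and the remainder renormalized before band summation.
    """

    bands: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        if not self.bands:
            raise ValueError("band model must define at least one band")
        bands = {k: frozenset(v) for k, v in self.bands.items()}
        seen: set[str] = set()
        for name, members in bands.items():
            if seen & members:
                raise ValueError(f"band {name!r} overlaps another band")
            seen |= members
        object.__setattr__(self, "bands", MappingProxyType(bands))

    @property
    def covered(self) -> frozenset[str]:
        out: frozenset[str] = frozenset()
        for members in self.bands.values():
            out |= members
        return out


DEFAULT_BAND_MODEL = BandModel(
    bands={
        "high": frozenset({"H1.3", "H1.4", "H1.5"}),
        "intermediate": frozenset({"H1.1", "H1.2"}),
        "low": frozenset({"H1.0"}),
    }
)


def _sum_by_label(
    records: Iterable[PeakAreaRecord], forms: set[str] | None = None
) -> tuple[dict[str, float], dict[str, float]]:
    """(light, heavy) fragment -> summed area, optionally restricted to forms."""
    light: dict[str, float] = {}
    heavy: dict[str, float] = {}
    for rec in records:
        if forms is not None and rec.form not in forms:
            continue
        bucket = light if rec.label == "light" else heavy
        bucket[rec.fragment] = bucket.get(rec.fragment, 0.0) + rec.area
    return light, heavy


def _ratio_from_sums(light: dict[str, float], heavy: dict[str, float]) -> float:
    matched = sorted(set(light) & set(heavy))
    if not matched:
        raise ValueError("no fragment observed in both light and heavy labels")
    h = sum(heavy[f] for f in matched)
    if h == 0:
        raise ValueError("heavy area sum is zero over matched fragments")
    return float(sum(light[f] for f in matched) / h)


def lh_ratio(records: Sequence[PeakAreaRecord], form: str = CANONICAL) -> float:
    """Light/heavy ratio for one peptide form in one replicate.

    Summed light areas over summed heavy areas, restricted to the
    intersection of fragments present in both labels.
    """
    light, heavy = _sum_by_label(records, forms={form})
    return _ratio_from_sums(light, heavy)


def combine_oxidized(records: Sequence[PeakAreaRecord]) -> float:
    """L/H ratio with Met-oxidation correction.

    Oxidized and unmodified areas are summed per label and fragment before
    ratioing: (L_unox + L_ox) / (H_unox + H_ox).  With no oxidized form
    present this reduces to :func:`lh_ratio`.
    """
    light, heavy = _sum_by_label(records, forms={CANONICAL, OXIDIZED})
    return _ratio_from_sums(light, heavy)


def to_absolute(
    amount: float,
    molar_mass: float | None = None,
    normalizer: Literal["ug_extract", "mL_blood"] = "ug_extract",
    normalizer_value: float = 1.0,
    subtype: str = "",
    amount_unit: Literal["fmol", "ng"] = "ng",
    cv: float | None = None,
    below_loq: bool = False,
    n_replicates: int = 1,
) -> SubtypeQuant:
    """Convert a peptide amount to a normalized absolute subtype amount.

    Assumes 1:1 peptide:protein stoichiometry.  ``fmol`` input is converted
    to ng of protein via the subtype molar mass (g/mol); the result is then
    divided by the normalizer (micrograms of total protein, or milliliters
    of blood processed).
    """
    if normalizer_value <= 0:
        raise ValueError("normalizer value must be positive")
    if amount < 0:
        raise ValueError("amount must be >= 0")
    if amount_unit == "fmol":
        if molar_mass is None or molar_mass <= 0:
            raise ValueError("fmol -> ng conversion requires a positive molar mass")
        ng = amount * 1e-15 * molar_mass * 1e9  # fmol * g/mol -> g -> ng
    else:
        ng = amount
    unit = "ng/ug" if normalizer == "ug_extract" else "ng/mL"
    return SubtypeQuant(
        subtype=subtype,
        amount=ng / normalizer_value,
        unit=unit,
        cv=cv,
        below_loq=below_loq,
        n_replicates=n_replicates,
    )


def complement_profile(
    quants: Sequence[SubtypeQuant],
    sample: str = "",
    include_below_loq: bool = False,
) -> ComplementProfile:
    """Percent-of-total profile over quantifiable subtypes.

    Subtypes flagged below the quantification limit are excluded (and the
    rest renormalized) unless ``include_below_loq`` is set.
    """
    usable = [q for q in quants if include_below_loq or not q.below_loq]
    total = sum(q.amount for q in usable)
    if not usable or total <= 0:
        raise ValueError("no quantifiable subtype above the LOQ")
    percents = {q.subtype: 100.0 * q.amount / total for q in usable}
    return ComplementProfile(sample=sample, percents=percents, total=total)


def expected_band_percentages(
    profile: ComplementProfile, model: BandModel = DEFAULT_BAND_MODEL
) -> dict[str, float]:
    """Expected electrophoretic band percentages from a complement profile.

    Subtypes not assigned to any band are dropped and the remaining
    percentages renormalized to 100 before summation per band.
    """
    covered = model.covered
    kept = {s: p for s, p in profile.percents.items() if s in covered}
    denom = sum(kept.values())
    if denom <= 0:
        raise ValueError("no profiled subtype is covered by the band model")
    return {
        band: sum(100.0 * kept.get(s, 0.0) / denom for s in members)
        for band, members in model.bands.items()
    }


def replicate_cv(amounts: Sequence[float]) -> float:
    """Percent coefficient of variation across replicates (n-1 sd / mean)."""
    if len(amounts) < 2:
        raise ValueError("replicate CV needs at least 2 replicates")
    mean = sum(amounts) / len(amounts)
    if mean == 0:
        raise ValueError("replicate CV undefined: mean is zero")
    var = sum((a - mean) ** 2 for a in amounts) / (len(amounts) - 1)
    return 100.0 * math.sqrt(var) / mean
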