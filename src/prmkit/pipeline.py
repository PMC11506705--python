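"""End-to-end quantification: peak-area report -> subtype amounts -> profile.

Orchestrates the per-peptide rules: Met-oxidation area summation, the
light/heavy ratio over matched transitions, single-point (or curve-based)
quantification, external-curve correction for miscleaved sibling forms,
replicate averaging with CV, LOQ censoring, and the complement profile.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

from .assay import AssayDefinition, AssayPeptide
from .calibration import (
    CalibrationCurve,
    CalibrationPoint,
    single_point_quantify,
)
from .quantification import (
    CANONICAL,
    OXIDIZED,
    ComplementProfile,
    PeakAreaRecord,
    SubtypeQuant,
    combine_oxidized,
    complement_profile,
    lh_ratio,
    replicate_cv,
)

__all__ = [
    "SampleResult",
    "quantify_report",
    "calibration_points_from_report",
    "fit_curves_from_report",
]


def calibration_points_from_report(
    records: Sequence[PeakAreaRecord],
    peptide: AssayPeptide,
    design: Mapping[str, float],
) -> list[CalibrationPoint]:
    """L/H calibration points for one peptide from a calibration-series
    report; ``design`` maps sample (level) ids to spiked light amounts."""
    points: list[CalibrationPoint] = []
    groups: dict[tuple[str, str], list[PeakAreaRecord]] = {}
    for rec in records:
        if rec.peptide != peptide.sequence or rec.sample not in design:
            continue
        groups.setdefault((rec.sample, rec.replicate), []).append(rec)
    for (sample, replicate), recs in sorted(groups.items()):
        ratio = (
            combine_oxidized(recs) if peptide.oxidation_correction else lh_ratio(recs)
        )
        points.append(
            CalibrationPoint(amount=design[sample], lh=ratio, replicate=replicate)
        )
    return points


def fit_curves_from_report(
    records: Sequence[PeakAreaRecord],
    assay: AssayDefinition,
    design: Mapping[str, float],
) -> dict[str, CalibrationCurve]:
    """Fit one calibration curve per assay peptide from a series report."""
    from .calibration import fit_calibration

    curves: dict[str, CalibrationCurve] = {}
    for pep in assay.peptides:
        points = calibration_points_from_report(records, pep, design)
        if len(points) >= 2:
            curves[pep.sequence] = fit_calibration(points, peptide=pep.sequence)
    return curves


@dataclass(frozen=True)
class SampleResult:
    """Quantification output for one sample."""

    sample: str
    quants: tuple[SubtypeQuant, ...]
    profile: ComplementProfile | None
    per_replicate: Mapping[str, Mapping[str, float]]  # subtype -> replicate -> ng


def _miscleaved_form_value(
    records: Sequence[PeakAreaRecord], form: str
) -> float:
    """L/H ratio for a miscleaved form, or summed light area when no heavy
    standard exists for it (external light-peptide curves are then fitted
    on area rather than ratio)."""
    try:
        return lh_ratio(records, form=form)
    except ValueError:
        return sum(r.area for r in records if r.form == form and r.label == "light")


def _quantify_peptide_replicate(
    records: Sequence[PeakAreaRecord],
    pep: AssayPeptide,
    reference: CalibrationPoint | None,
    curve: CalibrationCurve | None,
    miscleavage_curves: Mapping[str, CalibrationCurve],
    mode: Literal["proportional", "curve"],
) -> float:
    """Amount (ng) of one subtype in one replicate, all forms summed."""
    ratio = combine_oxidized(records) if pep.oxidation_correction else lh_ratio(records)
    amount = single_point_quantify(ratio, reference=reference, mode=mode, curve=curve)
    for form_seq in pep.miscleaved_forms:
        form = f"miscleaved:{form_seq}"
        if not any(r.form == form for r in records):
            continue
        mc_curve = miscleavage_curves.get(form_seq)
        if mc_curve is None:
            raise ValueError(
                f"miscleaved form {form_seq!r} detected but no external curve supplied"
            )
        value = _miscleaved_form_value(records, form)
        contribution = single_point_quantify(value, mode="curve", curve=mc_curve)
        if mc_curve.lod is not None and contribution < mc_curve.lod:
            contribution = 0.0
        amount += contribution
    return amount


def quantify_report(
    records: Sequence[PeakAreaRecord],
    assay: AssayDefinition,
    references: Mapping[str, CalibrationPoint] | None = None,
    curves: Mapping[str, CalibrationCurve] | None = None,
    miscleavage_curves: Mapping[str, CalibrationCurve] | None = None,
    mode: Literal["proportional", "curve"] = "proportional",
    normalizer: Literal["ug_extract", "mL_blood"] = "ug_extract",
    normalizer_value: float = 1.0,
    loq: Mapping[str, float] | None = None,
) -> dict[str, SampleResult]:
    """Quantify every sample in a transition-level peak-area report.

    ``references``/``curves`` map peptide sequence to the single
    calibration point (proportional mode) or fitted curve (curve mode);
    ``miscleavage_curves`` maps miscleaved-form sequences to their external
    curves; ``loq`` maps peptide sequence to a quantification limit in ng —
    subtype amounts below it are censored from the complement profile.
    Amount units are ng throughout; the normalizer converts to ng/ug
    extract or ng/mL blood.
    """
    references = references or {}
    curves = curves or {}
    miscleavage_curves = miscleavage_curves or {}
    loq = loq or {}
    unit = "ng/ug" if normalizer == "ug_extract" else "ng/mL"

    by_sample: dict[str, dict[tuple[str, str], list[PeakAreaRecord]]] = {}
    known = assay.by_sequence()
    for rec in records:
        if rec.peptide not in known:
            continue
        by_sample.setdefault(rec.sample, {}).setdefault(
            (rec.peptide, rec.replicate), []
        ).append(rec)

    results: dict[str, SampleResult] = {}
    for sample, groups in sorted(by_sample.items()):
        quants: list[SubtypeQuant] = []
        per_replicate: dict[str, dict[str, float]] = {}
        for pep in assay.peptides:
            rep_amounts: dict[str, float] = {}
            for (pep_seq, replicate), recs in sorted(groups.items()):
                if pep_seq != pep.sequence:
                    continue
                rep_amounts[replicate] = _quantify_peptide_replicate(
                    recs,
                    pep,
                    references.get(pep.sequence),
                    curves.get(pep.sequence),
                    miscleavage_curves,
                    mode,
                )
            if not rep_amounts:
                continue
            amounts = list(rep_amounts.values())
            mean_amount = sum(amounts) / len(amounts)
            cv = replicate_cv(amounts) if len(amounts) >= 2 and mean_amount > 0 else None
            pep_loq = loq.get(pep.sequence)
            quants.append(
                SubtypeQuant(
                    subtype=pep.subtype,
                    amount=float(mean_amount / normalizer_value),
                    unit=unit,
                    cv=cv,
                    below_loq=bool(pep_loq is not None and mean_amount < pep_loq),
                    n_replicates=len(amounts),
                )
            )
            per_replicate[pep.subtype] = rep_amounts
        try:
            profile = complement_profile(quants, sample=sample)
        except ValueError:
            profile = None
        results[sample] = SampleResult(
            sample=sample,
            quants=tuple(quants),
            profile=profile,
            per_replicate=per_replicate,
        )
    return results
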