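"""Ground-truth-known synthetic inputs for every pipeline stage.

Emulates the artifacts a targeted-MS experiment produces after peak
integration: calibration-series and sample transition-level peak-area
reports (with configurable multiplicative log-normal noise, miscleavage
and Met-oxidation signal splitting), and small patient cohorts with a
group effect on total analyte and Dirichlet-distributed subtype
percentages.

What it emulates / does not: areas are generated directly per transition
(no chromatograms, no retention-time drift, no interference), light and
heavy forms co-elute perfectly, and the instrument response is linear
through the origin per transition.  Noise is log-normal with a stated CV
— the multiplicative error structure typical of integrated peak areas.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .assay import AssayDefinition, AssayPeptide
from .quantification import CANONICAL, OXIDIZED, PeakAreaRecord

__all__ = [
    "SimulationConfig",
    "simulate_calibration",
    "simulate_sample_report",
    "simulate_cohort",
]

#: Calibration levels (ng of light peptide at fixed heavy spike).  Chosen to
#: bracket sub-ng quantification limits with a decade of headroom, the way a
#: dilution series for a low-abundance nuclear protein is laid out.
DEFAULT_LEVELS = (0.05, 0.1, 0.25, 0.5, 1.0, 2.5, 5.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the generators.

    ``true_amounts`` are ng of each subtype's light analyte in the sample;
    ``heavy_spike`` is the ng of every heavy standard; ``noise_cv`` is the
    percent coefficient of variation of the multiplicative per-transition
    area noise; ``miscleavage_fraction`` / ``oxidation_fraction`` divert
    that share of the light signal into the miscleaved / oxidized form.
    Identical (seed, config) pairs yield identical outputs.
    """

    seed: int
    assay: AssayDefinition
    true_amounts: Mapping[str, float] = field(default_factory=dict)
    heavy_spike: float = 1.0
    noise_cv: float = 10.0
    miscleavage_fraction: float = 0.0
    oxidation_fraction: float = 0.0
    n_replicates: int = 3
    calibration_levels: Sequence[float] = DEFAULT_LEVELS

    def __post_init__(self) -> None:
        if not 0.0 <= self.miscleavage_fraction < 1.0:
            raise ValueError("miscleavage_fraction must be in [0, 1)")
        if not 0.0 <= self.oxidation_fraction < 1.0:
            raise ValueError("oxidation_fraction must be in [0, 1)")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.heavy_spike <= 0:
            raise ValueError("heavy_spike must be positive")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if any(a < 0 for a in self.true_amounts.values()):
            raise ValueError("true amounts must be >= 0")


def _lognormal_factor(rng: np.random.Generator, cv_percent: float, size: int) -> np.ndarray:
    """Multiplicative noise with unit mean and the stated CV."""
    if cv_percent == 0:
        return np.ones(size)
    cv = cv_percent / 100.0
    sigma2 = np.log(1.0 + cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=size)


def _base_intensities(form_key: str, n_transitions: int) -> np.ndarray:
    """Per-transition relative response factors (area units per ng).

    A fixed property of the (peptide form, transition) pair — derived from a
    hash of the form's sequence — so light and heavy share the same
    fragmentation pattern (as co-eluting isotopologues do) and external
    calibration runs of the same species respond identically to samples.
    """
    rng = np.random.default_rng(zlib.crc32(form_key.encode()))
    return 10_000.0 * rng.uniform(0.2, 1.0, size=n_transitions)


def _emit(
    rows: list[dict],
    pep: AssayPeptide,
    sample: str,
    replicate: str,
    form: str,
    label: str,
    amounts_ng: float,
    base: np.ndarray,
    noise: np.ndarray,
) -> None:
    for t, b, f in zip(pep.transitions, base, noise):
        rows.append(
            {
                "sample": sample,
                "replicate": replicate,
                "peptide": pep.sequence,
                "form": form,
                "label": label,
                "fragment": t.key,
                "area": amounts_ng * b * f,
            }
        )


def _records_from_rows(rows: list[dict]) -> list[PeakAreaRecord]:
    return [PeakAreaRecord(**row) for row in rows]


def simulate_calibration(
    config: SimulationConfig,
) -> tuple[list[PeakAreaRecord], dict]:
    """Calibration-series peak-area report plus a ground-truth record.

    Per level, replicate and transition, light areas are proportional to
    the level amount and heavy areas to the fixed spike, both with
    log-normal noise.  The generating L/H-vs-amount slope per peptide is
    1 / heavy_spike (intercept 0); the truth record stores it.
    """
    if len(set(config.calibration_levels)) < 2:
        raise ValueError("at least 2 distinct calibration levels are required")
    if any(a < 0 for a in config.calibration_levels):
        raise ValueError("calibration levels must be >= 0")
    rng = np.random.default_rng(config.seed)
    rows: list[dict] = []
    truth = {
        "generating_slope": {},
        "heavy_spike": config.heavy_spike,
        "levels": list(config.calibration_levels),
        "noise_cv": config.noise_cv,
    }
    for pep in config.assay.peptides:
        base = _base_intensities(pep.sequence, len(pep.transitions))
        truth["generating_slope"][pep.sequence] = 1.0 / config.heavy_spike
        for level in config.calibration_levels:
            for rep in range(1, config.n_replicates + 1):
                sample = f"cal_{level:g}"
                n = len(pep.transitions)
                _emit(
                    rows, pep, sample, str(rep), CANONICAL, "light",
                    level, base, _lognormal_factor(rng, config.noise_cv, n),
                )
                _emit(
                    rows, pep, sample, str(rep), CANONICAL, "heavy",
                    config.heavy_spike, base, _lognormal_factor(rng, config.noise_cv, n),
                )
    return _records_from_rows(rows), truth


def simulate_sample_report(
    config: SimulationConfig,
    sample: str = "S1",
) -> tuple[list[PeakAreaRecord], dict]:
    """Sample peak-area report with known true subtype amounts.

    The light signal of each peptide is split between the canonical form
    and, when configured, a miscleaved sibling (first entry of the assay
    peptide's ``miscleaved_forms``) and/or an oxidized form (peptides with
    ``oxidation_correction``).  Heavy standards are spiked only for the
    canonical (and oxidized) assay peptide.
    """
    rng = np.random.default_rng(config.seed)
    rows: list[dict] = []
    truth = {
        "true_amounts": dict(config.true_amounts),
        "heavy_spike": config.heavy_spike,
        "miscleavage_fraction": config.miscleavage_fraction,
        "oxidation_fraction": config.oxidation_fraction,
    }
    for pep in config.assay.peptides:
        if pep.subtype not in config.true_amounts:
            continue
        amount = config.true_amounts[pep.subtype]
        base = _base_intensities(pep.sequence, len(pep.transitions))
        n = len(pep.transitions)
        light_total = amount
        mc_amount = 0.0
        if config.miscleavage_fraction > 0 and pep.miscleaved_forms:
            mc_amount = light_total * config.miscleavage_fraction
            light_total -= mc_amount
        ox_amount = 0.0
        if config.oxidation_fraction > 0 and pep.oxidation_correction:
            ox_amount = light_total * config.oxidation_fraction
            light_total -= ox_amount
        for rep in range(1, config.n_replicates + 1):
            rep_id = str(rep)
            _emit(rows, pep, sample, rep_id, CANONICAL, "light",
                  light_total, base, _lognormal_factor(rng, config.noise_cv, n))
            _emit(rows, pep, sample, rep_id, CANONICAL, "heavy",
                  config.heavy_spike, base, _lognormal_factor(rng, config.noise_cv, n))
            if ox_amount > 0:
                _emit(rows, pep, sample, rep_id, OXIDIZED, "light",
                      ox_amount, base, _lognormal_factor(rng, config.noise_cv, n))
            if mc_amount > 0:
                mc_seq = pep.miscleaved_forms[0]
                form = f"miscleaved:{mc_seq}"
                mc_base = _base_intensities(mc_seq, n)
                _emit(rows, pep, sample, rep_id, form, "light",
                      mc_amount, mc_base, _lognormal_factor(rng, config.noise_cv, n))
    return _records_from_rows(rows), truth


def simulate_external_curve(
    form_sequence: str,
    n_transitions: int,
    levels: Sequence[float] = DEFAULT_LEVELS,
    noise_cv: float = 10.0,
    n_replicates: int = 3,
    seed: int = 0,
) -> list[tuple[float, float]]:
    """External light-peptide dilution series for one (miscleaved) form.

    Returns (amount, summed light area over the form's transitions) pairs —
    the response on which an external calibration curve is fitted when no
    heavy standard exists for the form.  The response factors are the same
    fixed per-form intensities the sample generator uses, emulating an
    external run of the identical synthetic species (acquired on a
    different day, hence its own noise draws).
    """
    rng = np.random.default_rng(seed)
    base = _base_intensities(form_sequence, n_transitions)
    points = []
    for level in levels:
        for _ in range(n_replicates):
            noise = _lognormal_factor(rng, noise_cv, n_transitions)
            points.append((float(level), float(np.sum(level * base * noise))))
    return points


def simulate_cohort(
    n_responders: int,
    n_nonresponders: int,
    effect: float = 0.0,
    sd: float = 1.0,
    seed: int = 0,
    baseline: float = 10.0,
    subtypes: Sequence[str] = ("H1.0", "H1.1", "H1.2", "H1.3", "H1.4", "H1.5", "H1X"),
    responder_alpha: Sequence[float] | None = None,
    nonresponder_alpha: Sequence[float] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Synthetic patient cohort: group label, total analyte, subtype percents.

    Total amounts (e.g. total H1 in ng/mL blood) are normal with mean
    ``baseline`` for responders and ``baseline + effect`` for
    non-responders, sd ``sd``, truncated at 0.  Subtype percentages are
    Dirichlet draws (respecting the sum-to-100 constraint), with separate
    concentration vectors per group when supplied.
    """
    if n_responders < 1 or n_nonresponders < 1:
        raise ValueError("both group sizes must be >= 1")
    rng = np.random.default_rng(seed)
    k = len(subtypes)
    resp_alpha = np.asarray(responder_alpha if responder_alpha is not None else [5.0] * k, float)
    nonresp_alpha = np.asarray(
        nonresponder_alpha if nonresponder_alpha is not None else [5.0] * k, float
    )
    if resp_alpha.size != k or nonresp_alpha.size != k:
        raise ValueError("alpha vectors must match the number of subtypes")

    rows = []
    for group, n, mu, alpha in (
        ("responder", n_responders, baseline, resp_alpha),
        ("non-responder", n_nonresponders, baseline + effect, nonresp_alpha),
    ):
        totals = np.clip(rng.normal(mu, sd, size=n), a_min=0.0, a_max=None)
        percents = 100.0 * rng.dirichlet(alpha, size=n)
        for i in range(n):
            prefix = "R" if group == "responder" else "NR"
            row = {
                "subject": f"{prefix}{i + 1}",
                "group": group,
                "total": float(totals[i]),
            }
            row.update({s: float(p) for s, p in zip(subtypes, percents[i])})
            rows.append(row)
    truth = {
        "baseline": baseline,
        "effect": effect,
        "sd": sd,
        "responder_alpha": resp_alpha.tolist(),
        "nonresponder_alpha": nonresp_alpha.tolist(),
        "seed": seed,
    }
    return pd.DataFrame(rows), truth


def truth_to_json(truth: dict, path) -> None:
    """Write a ground-truth side record as JSON."""
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
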