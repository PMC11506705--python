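"""Readers, writers and the result bundle.

One dialect per artifact class: comma-separated CSV with "." decimals for
transition-level peak-area reports (the shape of a Skyline-style export),
TSV for candidate tables and percentage exports, JSON for result bundles.
All readers validate loudly; nothing is silently coerced or dropped.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .proteolysis import PeptideCandidate, ProteinRecord
from .quantification import PeakAreaRecord

__all__ = [
    "PEAK_REPORT_COLUMNS",
    "read_fasta",
    "read_peak_report",
    "write_peak_report",
    "read_ess_table",
    "read_calibration_design",
    "write_candidates",
    "ResultBundle",
    "write_results",
    "read_results",
]

PEAK_REPORT_COLUMNS = ("sample", "replicate", "peptide", "form", "label", "fragment", "area")

_STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")


def read_fasta(
    path: str | Path,
    accession_to_subtype: Mapping[str, str] | None = None,
) -> list[ProteinRecord]:
    """Read a protein family from FASTA, order preserved.

    Headers are parsed for the accession (UniProt ``db|ACC|NAME`` style or
    plain first token); sequences are uppercased and whitespace-stripped.
    ``accession_to_subtype`` maps accessions to short subtype labels; with
    no mapping the accession doubles as the label.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    out: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in records:
        parts = rec.id.split("|")
        accession = parts[1] if len(parts) >= 2 else parts[0]
        if accession in seen:
            raise ValueError(f"duplicate accession {accession!r} in {path}")
        seen.add(accession)
        seq = "".join(str(rec.seq).split()).upper()
        for i, ch in enumerate(seq, start=1):
            if ch not in _STANDARD_RESIDUES:
                raise ValueError(
                    f"record {accession!r}: illegal residue {ch!r} at position {i}"
                )
        label = (accession_to_subtype or {}).get(accession, accession)
        out.append(ProteinRecord(id=label, accession=accession, sequence=seq))
    return out


def read_peak_report(path: str | Path) -> list[PeakAreaRecord]:
    """Read a transition-level peak-area CSV into typed records.

    Required columns: sample, replicate, peptide, form, label, fragment,
    area (optional retention_time).  Missing columns, negative areas and
    duplicate (sample, replicate, peptide, form, label, fragment) keys are
    rejected by name.
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in PEAK_REPORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"peak report {path} missing column(s): {missing}")
    records: list[PeakAreaRecord] = []
    seen: set[tuple] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        area = float(getattr(row, "area"))
        if area < 0:
            raise ValueError(f"{path} line {i}: negative area {area}")
        rt = getattr(row, "retention_time", None)
        rec = PeakAreaRecord(
            sample=str(row.sample),
            replicate=str(row.replicate),
            peptide=str(row.peptide),
            form=str(row.form),
            label=str(row.label),
            fragment=str(row.fragment),
            area=area,
            retention_time=float(rt) if rt not in (None, "", "nan") and rt == rt else None,
        )
        if rec.key in seen:
            raise ValueError(f"{path} line {i}: duplicate record key {rec.key}")
        seen.add(rec.key)
        records.append(rec)
    return records


def write_peak_report(records: Iterable[PeakAreaRecord], path: str | Path) -> None:
    rows = [dataclasses.asdict(r) for r in records]
    df = pd.DataFrame(rows, columns=list(PEAK_REPORT_COLUMNS) + ["retention_time"])
    df.to_csv(path, index=False)


def read_ess_table(path: str | Path) -> dict[str, tuple[float, int]]:
    """Read a peptide -> (ESS, n_observations) annotation TSV."""
    df = pd.read_csv(path, sep="\t")
    for col in ("peptide", "ess"):
        if col not in df.columns:
            raise ValueError(f"ESS table {path} missing column {col!r}")
    out = {}
    for row in df.itertuples(index=False):
        n_obs = int(getattr(row, "n_observations", 0) or 0)
        out[str(row.peptide)] = (float(row.ess), n_obs)
    return out


def read_calibration_design(path: str | Path) -> dict[str, float]:
    """Read a calibration design CSV: sample (level id) -> amount."""
    df = pd.read_csv(path)
    for col in ("sample", "amount"):
        if col not in df.columns:
            raise ValueError(f"calibration design {path} missing column {col!r}")
    design = {}
    for row in df.itertuples(index=False):
        amount = float(row.amount)
        if amount < 0:
            raise ValueError(f"negative calibration amount {amount}")
        design[str(row.sample)] = amount
    return design


_CANDIDATE_COLUMNS = (
    "subtype", "accession", "enzyme", "sequence", "start", "end",
    "missed_cleavages", "mono_mass", "unique", "ess", "n_observations",
)


def write_candidates(candidates: Sequence[PeptideCandidate], path: str | Path) -> None:
    """Write a candidate table as TSV."""
    rows = []
    for c in candidates:
        rows.append(
            {
                "subtype": c.subtype,
                "accession": c.accession,
                "enzyme": c.enzyme.value,
                "sequence": c.sequence,
                "start": c.start,
                "end": c.end,
                "missed_cleavages": c.missed_cleavages,
                "mono_mass": round(c.mono_mass, 4),
                "unique": c.unique,
                "ess": c.ess,
                "n_observations": c.n_observations,
            }
        )
    pd.DataFrame(rows, columns=_CANDIDATE_COLUMNS).to_csv(path, sep="\t", index=False)


def _jsonify(obj):
    """Recursively convert dataclasses / numpy / mappings to JSON-safe types."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonify(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, Mapping):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        return [_jsonify(v) for v in obj]
    return obj


def config_hash(config: Mapping) -> str:
    """Stable short hash of a configuration mapping."""
    canonical = json.dumps(_jsonify(config), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


@dataclass
class ResultBundle:
    """Run metadata plus per-stage outputs, serializable to JSON.

    Empty stages are serialized as explicit nulls, never omitted, so a
    reader can distinguish "not run" from "missing file".
    """

    config: dict = field(default_factory=dict)
    seed: int | None = None
    version: str = "0"
    candidates: list | None = None
    curves: dict | None = None
    quants: dict | None = None
    profiles: dict | None = None
    stats: dict | None = None

    def to_dict(self) -> dict:
        return {
            "meta": {
                "config_hash": config_hash(self.config),
                "config": _jsonify(self.config),
                "seed": self.seed,
                "version": self.version,
            },
            "candidates": _jsonify(self.candidates),
            "curves": _jsonify(self.curves),
            "quants": _jsonify(self.quants),
            "profiles": _jsonify(self.profiles),
            "stats": _jsonify(self.stats),
        }


def write_results(bundle: ResultBundle, path: str | Path) -> None:
    """Write a result bundle as JSON (stable key order)."""
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(bundle.to_dict(), fh, indent=2, sort_keys=True)


def read_results(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
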