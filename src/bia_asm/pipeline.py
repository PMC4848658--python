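"""Validation pipeline: equations x strata -> agreement report.

Applies the requested prediction equations to a cohort with reference ASM,
stratifies by total, sex, and the four BMI bands, computes an
:class:`~bia_asm.agreement.AgreementResult` per (equation, stratum) cell and
serialises the grid as TSV, JSON or Markdown.  Strata with fewer than 2
pairs carry an explicit insufficient-n marker; strata below 20 subjects are
flagged as too small for reliable agreement estimates (agreement statistics
on a handful of subjects have very wide intervals).
"""
from __future__ import annotations

import hashlib
import io
import json
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from . import __version__ as _pkg_version
from .agreement import AgreementResult, PairedSeries, compare
from .equations import REGISTRY_VERSION, EquationSpec, predict_records, resolve_equations
from .errors import ValidationError
from .records import BMIBand, Sex, SubjectRecord

SMALL_STRATUM_N = 20
SMALL_STRATUM_NOTE = (
    "stratum n < 20: agreement estimates on very small strata are unstable "
    "and should not be generalised"
)

SCHEMES = ("total", "sex", "bmi")
_SCHEME_LABELS = {
    "total": ("total",),
    "sex": ("men", "women"),
    "bmi": ("underweight", "normal", "overweight", "obese"),
}


def stratify(records: Sequence[SubjectRecord], scheme: str) -> Dict[str, List[SubjectRecord]]:
    """Partition records by scheme; labels and their order are fixed.

    ``total`` -> one stratum; ``sex`` -> men, women; ``bmi`` -> underweight,
    normal, overweight, obese.  The partition is exhaustive and disjoint
    within a scheme; empty strata are kept (and flagged downstream).
    """
    if scheme not in _SCHEME_LABELS:
        raise ValidationError(f"unknown stratification scheme {scheme!r}; valid: {', '.join(SCHEMES)}")
    out: Dict[str, List[SubjectRecord]] = {label: [] for label in _SCHEME_LABELS[scheme]}
    for rec in records:
        if scheme == "total":
            out["total"].append(rec)
        elif scheme == "sex":
            out["men" if rec.sex is Sex.MALE else "women"].append(rec)
        else:
            out[rec.bmi_band.value].append(rec)
    return out


@dataclass(frozen=True)
class StratumCell:
    """One (equation, stratum) cell of the validation grid."""

    equation: str
    stratum: str
    n: int
    predicted_mean: Optional[float] = None
    predicted_sd: Optional[float] = None
    reference_mean: Optional[float] = None
    reference_sd: Optional[float] = None
    agreement: Optional[AgreementResult] = None
    insufficient: bool = False
    flags: Tuple[str, ...] = ()


@dataclass
class StratifiedReport:
    """Full validation grid plus provenance."""

    strata: List[Tuple[str, str, int]]  # (scheme, label, n)
    cells: Dict[Tuple[str, str], StratumCell]
    provenance: Dict[str, object] = field(default_factory=dict)

    def cell(self, equation: str, stratum: str) -> StratumCell:
        return self.cells[(equation, stratum)]


def run_validation(
    records: Sequence[SubjectRecord],
    equations="all",
    schemes: Sequence[str] = SCHEMES,
    yoshida_index: str = "z",
    extra_provenance: Optional[Mapping[str, object]] = None,
) -> StratifiedReport:
    """Validate the requested equations against the reference ASM.

    Every record must carry ``reference_asm``; records without one are an
    error (listing the offending ids) rather than silently dropped.
    """
    specs: Tuple[EquationSpec, ...] = resolve_equations(equations)
    if not specs:
        raise ValidationError("at least one equation must be requested")
    missing = [r.id for r in records if r.reference_asm is None]
    if missing:
        raise ValidationError(
            f"{len(missing)} record(s) lack reference_asm: {', '.join(map(str, missing[:10]))}"
            + ("..." if len(missing) > 10 else "")
        )

    strata: List[Tuple[str, str, int]] = []
    cells: Dict[Tuple[str, str], StratumCell] = {}
    for scheme in schemes:
        partition = stratify(records, scheme)
        for label, subset in partition.items():
            strata.append((scheme, label, len(subset)))
            reference = np.array([r.reference_asm for r in subset], dtype=float)
            for spec in specs:
                flags = []
                if spec.warning:
                    flags.append(spec.warning)
                if len(subset) < 2:
                    cells[(spec.name, label)] = StratumCell(
                        equation=spec.name, stratum=label, n=len(subset),
                        insufficient=True, flags=tuple(flags + ["insufficient n (< 2)"]),
                    )
                    continue
                if len(subset) < SMALL_STRATUM_N:
                    flags.append(SMALL_STRATUM_NOTE)
                predicted = predict_records(subset, spec, yoshida_index)
                result = compare(PairedSeries(predicted, reference, stratum_label=label))
                cells[(spec.name, label)] = StratumCell(
                    equation=spec.name,
                    stratum=label,
                    n=len(subset),
                    predicted_mean=float(predicted.mean()),
                    predicted_sd=float(predicted.std(ddof=1)),
                    reference_mean=float(reference.mean()),
                    reference_sd=float(reference.std(ddof=1)),
                    agreement=result,
                    flags=tuple(flags),
                )

    provenance: Dict[str, object] = {
        "package_version": _pkg_version,
        "registry_version": REGISTRY_VERSION,
        "yoshida_index": f"ht2_over_{yoshida_index.upper()}",
        "equations": [s.name for s in specs],
        "schemes": list(schemes),
        "n_records": len(records),
    }
    if extra_provenance:
        provenance.update(extra_provenance)
    provenance["config_hash"] = hashlib.sha256(
        json.dumps(provenance, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]
    return StratifiedReport(strata=strata, cells=cells, provenance=provenance)


# ---------------------------------------------------------------- rendering

_TSV_COLUMNS = (
    "scheme", "stratum", "equation", "n",
    "predicted_mean_sd", "reference_mean_sd",
    "mean_error_ci", "p", "pearson_r", "loa", "rmse_ci", "flags",
)


def _fmt(x: Optional[float], nd: int = 2) -> str:
    return "NA" if x is None else f"{x:.{nd}f}"


def _fmt_ci(ci: Optional[Tuple[float, float]]) -> str:
    return "NA" if ci is None else f"({ci[0]:.2f}, {ci[1]:.2f})"


def _rows(report: StratifiedReport):
    for scheme, label, n in report.strata:
        for eq in report.provenance.get("equations", []):
            cell = report.cells.get((eq, label))
            if cell is None:
                continue
            a = cell.agreement
            yield {
                "scheme": scheme,
                "stratum": label,
                "equation": eq,
                "n": str(cell.n),
                "predicted_mean_sd": "NA" if a is None else f"{_fmt(cell.predicted_mean)} ({_fmt(cell.predicted_sd)})",
                "reference_mean_sd": "NA" if a is None else f"{_fmt(cell.reference_mean)} ({_fmt(cell.reference_sd)})",
                "mean_error_ci": "NA" if a is None else f"{a.mean_error:.2f} {_fmt_ci(a.me_ci)}",
                "p": "NA" if a is None else f"{a.paired_t_p:.3g}",
                "pearson_r": "NA" if a is None else _fmt(a.pearson_r),
                "loa": "NA" if a is None else _fmt_ci(a.loa),
                "rmse_ci": "NA" if a is None else f"{a.rmse:.2f} {_fmt_ci(a.rmse_ci)}",
                "flags": "; ".join(cell.flags),
            }


def _provenance_lines(report: StratifiedReport, prefix: str) -> List[str]:
    return [
        f"{prefix} {key}: {value}"
        for key, value in sorted(report.provenance.items(), key=lambda kv: kv[0])
    ]


def render_report(report: StratifiedReport, format: str = "tsv") -> str:
    """Serialise the grid; values rounded to 2 decimals here and only here."""
    if format == "tsv":
        buf = io.StringIO()
        for line in _provenance_lines(report, "#"):
            buf.write(line + "\n")
        buf.write("\t".join(_TSV_COLUMNS) + "\n")
        for row in _rows(report):
            buf.write("\t".join(row[c] for c in _TSV_COLUMNS) + "\n")
        return buf.getvalue()
    if format == "markdown":
        lines = [f"> {line[2:]}" for line in _provenance_lines(report, "#")]
        lines.append("")
        lines.append("| " + " | ".join(_TSV_COLUMNS) + " |")
        lines.append("|" + "---|" * len(_TSV_COLUMNS))
        for row in _rows(report):
            lines.append("| " + " | ".join(row[c] for c in _TSV_COLUMNS) + " |")
        return "\n".join(lines) + "\n"
    if format == "json":
        payload = {
            "provenance": report.provenance,
            "strata": [
                {"scheme": s, "stratum": label, "n": n} for s, label, n in report.strata
            ],
            "cells": [dict(row) for row in _rows(report)],
        }
        return json.dumps(payload, indent=2, sort_keys=True, default=str) + "\n"
    raise ValidationError(f"unknown report format {format!r}; valid: tsv, json, markdown")
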