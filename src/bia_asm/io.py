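"""CSV subject tables, YAML configuration and atomic report writing.

CSV dialect: comma-separated, UTF-8, mandatory header with columns
``id, sex, age, height_m, weight_kg, resistance_ohm, reactance_ohm`` and
optional ``asm_dxa_kg``.  Sex accepts male/female/M/F/1/0; height is metres
by default with a cm option converted at parse time.  Decimal separator is
"." only — no locale-dependent parsing.
"""
from __future__ import annotations

import os
import tempfile
from pathlib import Path
from typing import List, Optional, Sequence

import pandas as pd
import yaml

from .errors import SchemaError, ValidationError
from .pipeline import StratifiedReport, render_report
from .records import SubjectRecord, parse_sex

REQUIRED_COLUMNS = ("id", "sex", "age", "height_m", "weight_kg", "resistance_ohm", "reactance_ohm")
OPTIONAL_COLUMNS = ("asm_dxa_kg",)


def read_subjects(path, height_unit: str = "m") -> List[SubjectRecord]:
    """Read and validate a subject CSV; aggregate row errors with line numbers."""
    if height_unit not in ("m", "cm"):
        raise ValidationError(f"height_unit must be 'm' or 'cm', got {height_unit!r}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")

    records: List[SubjectRecord] = []
    errors: List[str] = []
    for i, row in enumerate(df.itertuples(index=False)):
        line_no = i + 2  # header is line 1
        try:
            height = _num(row.height_m, "height_m")
            if height_unit == "cm":
                height = height / 100.0
            ref_raw = getattr(row, "asm_dxa_kg", "")
            reference = None if str(ref_raw).strip() == "" else _num(ref_raw, "asm_dxa_kg")
            records.append(
                SubjectRecord(
                    id=str(row.id),
                    sex=parse_sex(row.sex),
                    age=_num(row.age, "age"),
                    height=height,
                    weight=_num(row.weight_kg, "weight_kg"),
                    resistance=_num(row.resistance_ohm, "resistance_ohm"),
                    reactance=_num(row.reactance_ohm, "reactance_ohm"),
                    reference_asm=reference,
                )
            )
        except ValidationError as exc:
            errors.append(f"line {line_no}: {exc}")
    if errors:
        raise ValidationError(
            f"{path}: {len(errors)} invalid row(s):\n" + "\n".join(errors)
        )
    return records


def _num(value, column: str) -> float:
    try:
        return float(value)
    except (TypeError, ValueError):
        raise ValidationError(f"column {column!r}: unparseable numeric {value!r}") from None


def write_subjects(records: Sequence[SubjectRecord], path) -> None:
    """Write subjects in the same CSV dialect ``read_subjects`` consumes."""
    df = pd.DataFrame(
        {
            "id": [r.id for r in records],
            "sex": [r.sex.value for r in records],
            "age": [f"{r.age:.10g}" for r in records],
            "height_m": [f"{r.height:.10g}" for r in records],
            "weight_kg": [f"{r.weight:.10g}" for r in records],
            "resistance_ohm": [f"{r.resistance:.10g}" for r in records],
            "reactance_ohm": [f"{r.reactance:.10g}" for r in records],
            "asm_dxa_kg": ["" if r.reference_asm is None else f"{r.reference_asm:.10g}" for r in records],
        }
    )
    _atomic_write_text(path, df.to_csv(index=False))


def write_report(report: StratifiedReport, path, format: str = "tsv") -> None:
    """Render and atomically write a validation report (temp file + rename)."""
    _atomic_write_text(path, render_report(report, format))


def _atomic_write_text(path, text: str) -> None:
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent or Path("."), suffix=".tmp")
    try:
        with os.fdopen(fd, "w", encoding="utf-8", newline="") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def load_yaml_config(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        loaded = yaml.safe_load(fh) or {}
    if not isinstance(loaded, dict):
        raise ValidationError(f"{path}: YAML config must be a mapping")
    return loaded
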