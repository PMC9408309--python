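"""Reading and writing report tables, analysis configs, and fiber/series CSVs.

Report cohorts are stored as two long-format tables — one drug row and one
reaction row per (report, item) pair — in one of three delimited dialects:

========  =========  ==========================
dialect   delimiter  files written
========  =========  ==========================
csv       ``,``      drugs.csv, reactions.csv
tsv       tab        drugs.tsv, reactions.tsv
faers     ``$``      drugs.txt, reactions.txt
========  =========  ==========================

The drug table has header ``report_id,drug_name,role``; the reaction table
``report_id,pt``.  Rows sharing a report_id are merged into one report
(FAERS-style long format).  Writing then reading is the identity on the
report set, up to order.
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict
from pathlib import Path
from typing import Iterable, Sequence

import yaml

from .cohort import CohortConfig
from .errors import ParseError
from .reports import Role, SpontaneousReport, normalize_drug_name

__all__ = [
    "DIALECTS",
    "write_reports",
    "read_reports",
    "read_report_tables",
    "write_cohort_sidecar",
    "load_analysis_config",
]

#: dialect name -> (delimiter, file extension)
DIALECTS = {"csv": (",", "csv"), "tsv": ("\t", "tsv"), "faers": ("$", "txt")}


def _dialect(dialect: str) -> tuple[str, str]:
    try:
        return DIALECTS[dialect]
    except KeyError:
        raise ParseError(f"unknown dialect {dialect!r}; choose from {sorted(DIALECTS)}") from None


def write_reports(
    reports: Iterable[SpontaneousReport], path: str | Path, dialect: str = "csv"
) -> tuple[Path, Path]:
    """Write a cohort as a drug table and a reaction table under directory ``path``.

    Returns the two file paths.  Rows are sorted (by report_id, then item) so
    identical cohorts serialize identically.
    """
    delim, ext = _dialect(dialect)
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    drugs_path = path / f"drugs.{ext}"
    reacs_path = path / f"reactions.{ext}"
    reports = sorted(reports, key=lambda r: r.report_id)
    with open(drugs_path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter=delim)
        w.writerow(["report_id", "drug_name", "role"])
        for rep in reports:
            for name, role in sorted(rep.drugs):
                w.writerow([rep.report_id, name, role.value])
    with open(reacs_path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter=delim)
        w.writerow(["report_id", "pt"])
        for rep in reports:
            for pt in sorted(rep.reactions):
                w.writerow([rep.report_id, pt])
    return drugs_path, reacs_path


def _read_rows(path: Path, delim: str, expected_header: Sequence[str]) -> list[tuple[int, list[str]]]:
    rows: list[tuple[int, list[str]]] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter=delim)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: file is empty (missing header)") from None
        if [h.strip() for h in header] != list(expected_header):
            raise ParseError(f"{path}: expected header {list(expected_header)}, got {header}", line=1)
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not cell.strip() for cell in row):
                continue
            if len(row) != len(expected_header):
                raise ParseError(f"{path}: expected {len(expected_header)} fields, got {len(row)}", line=lineno)
            rows.append((lineno, row))
    return rows


def read_report_tables(
    drugs_path: str | Path, reactions_path: str | Path, dialect: str = "csv"
) -> list[SpontaneousReport]:
    """Read a cohort from explicit drug/reaction table paths."""
    delim, _ = _dialect(dialect)
    drugs: dict[str, set[tuple[str, Role]]] = {}
    reactions: dict[str, set[str]] = {}
    for lineno, (rid, name, role) in _read_rows(Path(drugs_path), delim, ["report_id", "drug_name", "role"]):
        rid = rid.strip()
        if not rid:
            raise ParseError(f"{drugs_path}: empty report_id", line=lineno)
        if not name.strip():
            raise ParseError(f"{drugs_path}: empty drug name", line=lineno)
        try:
            role_val = Role(role.strip().upper())
        except ValueError:
            raise ParseError(f"{drugs_path}: unknown role {role!r}", line=lineno) from None
        drugs.setdefault(rid, set()).add((normalize_drug_name(name), role_val))
    for lineno, (rid, pt) in _read_rows(Path(reactions_path), delim, ["report_id", "pt"]):
        rid = rid.strip()
        if not rid:
            raise ParseError(f"{reactions_path}: empty report_id", line=lineno)
        if not pt.strip():
            raise ParseError(f"{reactions_path}: empty reaction term", line=lineno)
        reactions.setdefault(rid, set()).add(pt.strip())
    ids = sorted(set(drugs) | set(reactions))
    return [
        SpontaneousReport(
            report_id=rid,
            drugs=frozenset(drugs.get(rid, ())),
            reactions=frozenset(reactions.get(rid, ())),
        )
        for rid in ids
    ]


def read_reports(path: str | Path, dialect: str = "csv") -> list[SpontaneousReport]:
    """Read a cohort previously written with :func:`write_reports` to ``path``."""
    _, ext = _dialect(dialect)
    path = Path(path)
    return read_report_tables(path / f"drugs.{ext}", path / f"reactions.{ext}", dialect)


def write_cohort_sidecar(config: CohortConfig, path: str | Path) -> Path:
    """Record the full generative config next to the emitted tables (provenance)."""
    path = Path(path)
    payload = asdict(config)
    payload["exposures"] = dict(config.exposures)
    payload["odds_multipliers"] = dict(config.odds_multipliers)
    out = path / "cohort_config.json" if path.is_dir() else path
    out.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    return out


def load_analysis_config(path: str | Path):
    """Load a case/exposure analysis config (YAML or JSON).

    Expected structure::

        case:
          name: OIPN            # optional
          terms: [ ... ]
        exposures:
          - name: omeprazole
            members: [OMEPRAZOLE]
            roles: [SUSPECT, CONCOMITANT]   # optional, default both

    Returns ``(CaseDefinition, list[ExposureDefinition])``.
    """
    from .disprop import CaseDefinition, ExposureDefinition  # local import, avoids a cycle

    text = Path(path).read_text(encoding="utf-8")
    data = yaml.safe_load(text)
    if not isinstance(data, dict) or "case" not in data or "exposures" not in data:
        raise ParseError(f"{path}: config must contain 'case' and 'exposures' keys")
    case = data["case"]
    case_def = CaseDefinition(name=case.get("name", "case"), terms=tuple(case["terms"]))
    exposures = []
    for entry in data["exposures"]:
        roles = tuple(Role(r.upper()) for r in entry.get("roles", [r.value for r in Role]))
        exposures.append(
            ExposureDefinition(
                name=entry["name"], members=tuple(entry["members"]), roles_counted=frozenset(roles)
            )
        )
    return case_def, exposures
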