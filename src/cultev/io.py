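"""TSV readers/writers and report formatting.

Fixed dialect for every file the toolkit reads or writes: UTF-8, tab
separator, required header row, ``#``-prefixed comment/metadata lines, no
quoting.  Currency fields are plain numbers (no symbols or thousands
separators).  Reports are written atomically (temp file, then rename) so a
failure never leaves a partial output behind.
"""

from __future__ import annotations

import os
import tempfile
from typing import Iterable

import pandas as pd

from .cpestimate import CultivationRecord, TaxonProfile
from .errors import ParseError, ValidationError
from .evmodel import CultivationProbability, IsolateCategory

__all__ = [
    "read_community_profile",
    "read_taxon_catalog",
    "read_scenario",
    "read_records",
    "write_report",
    "read_report",
]


def _read_rows(path: str, required: tuple[str, ...]) -> tuple[list[str], list[tuple[int, list[str]]]]:
    """Parse a TSV into (header, [(line_number, fields), ...]), skipping comments."""
    header: list[str] | None = None
    rows: list[tuple[int, list[str]]] = []
    try:
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line.strip() or line.lstrip().startswith("#"):
                    continue
                fields = line.split("\t")
                if header is None:
                    header = [f.strip() for f in fields]
                    missing = [c for c in required if c not in header]
                    if missing:
                        raise ParseError(
                            f"{path}:{lineno}: missing required column(s) {', '.join(missing)}"
                        )
                    continue
                if len(fields) != len(header):
                    raise ParseError(
                        f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}"
                    )
                rows.append((lineno, fields))
    except OSError as exc:
        raise ParseError(f"cannot read {path}: {exc}") from exc
    if header is None:
        raise ParseError(f"{path}: no header row found")
    return header, rows


def _number(value: str, path: str, lineno: int, column: str) -> float:
    try:
        return float(value)
    except ValueError:
        raise ParseError(f"{path}:{lineno}: non-numeric {column} {value!r}") from None


def read_community_profile(path: str) -> list[TaxonProfile]:
    """Read a community profile TSV (columns: taxon_id, relative_abundance)."""
    header, rows = _read_rows(path, ("taxon_id", "relative_abundance"))
    i_id = header.index("taxon_id")
    i_ab = header.index("relative_abundance")
    seen: dict[str, int] = {}
    profiles: list[TaxonProfile] = []
    for lineno, fields in rows:
        tid = fields[i_id].strip()
        if tid in seen:
            raise ParseError(f"{path}:{lineno}: duplicate taxon_id {tid!r} (first at line {seen[tid]})")
        seen[tid] = lineno
        ab = _number(fields[i_ab], path, lineno, "relative_abundance")
        try:
            profiles.append(TaxonProfile(taxon_id=tid, relative_abundance=ab))
        except ValidationError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
    total = sum(p.relative_abundance for p in profiles)
    if total > 1.0 + 1e-6:
        raise ParseError(f"{path}: relative abundances sum to {total:.6f} > 1")
    return profiles


def read_taxon_catalog(path: str) -> dict[str, tuple[float, CultivationProbability]]:
    """Read a taxon catalog TSV (columns: taxon_id, i_value, cp)."""
    header, rows = _read_rows(path, ("taxon_id", "i_value", "cp"))
    i_id, i_val, i_cp = (header.index(c) for c in ("taxon_id", "i_value", "cp"))
    catalog: dict[str, tuple[float, CultivationProbability]] = {}
    for lineno, fields in rows:
        tid = fields[i_id].strip()
        if tid in catalog:
            raise ParseError(f"{path}:{lineno}: duplicate taxon_id {tid!r}")
        value = _number(fields[i_val], path, lineno, "i_value")
        cp = _number(fields[i_cp], path, lineno, "cp")
        try:
            catalog[tid] = (value, CultivationProbability(cp))
        except ValidationError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return catalog


def read_scenario(path: str) -> list[IsolateCategory]:
    """Read a scenario TSV (columns: label, i_value, cp, count)."""
    header, rows = _read_rows(path, ("label", "i_value", "cp", "count"))
    idx = {c: header.index(c) for c in ("label", "i_value", "cp", "count")}
    cats: list[IsolateCategory] = []
    for lineno, fields in rows:
        try:
            cats.append(
                IsolateCategory(
                    label=fields[idx["label"]].strip(),
                    value=_number(fields[idx["i_value"]], path, lineno, "i_value"),
                    cp=_number(fields[idx["cp"]], path, lineno, "cp"),
                    count=int(_number(fields[idx["count"]], path, lineno, "count")),
                )
            )
        except ValidationError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return cats


def read_records(path: str) -> list[CultivationRecord]:
    """Read experiment records for cP estimation.

    Accepts either (taxon_id, n_isolates, expected_occurrences) directly or
    (taxon_id, n_isolates, n_wells, abundance, cells_per_well), in which case
    expected occurrences are computed with the nominal occupancy model.
    """
    header, rows = _read_rows(path, ("taxon_id", "n_isolates"))
    direct = "expected_occurrences" in header
    if not direct:
        for col in ("n_wells", "abundance", "cells_per_well"):
            if col not in header:
                raise ParseError(
                    f"{path}: need either expected_occurrences or "
                    "(n_wells, abundance, cells_per_well) columns"
                )
    idx = {c: header.index(c) for c in header}
    records: list[CultivationRecord] = []
    for lineno, fields in rows:
        tid = fields[idx["taxon_id"]].strip()
        n = int(_number(fields[idx["n_isolates"]], path, lineno, "n_isolates"))
        if direct:
            occ = _number(fields[idx["expected_occurrences"]], path, lineno, "expected_occurrences")
        else:
            occ = (
                _number(fields[idx["n_wells"]], path, lineno, "n_wells")
                * _number(fields[idx["abundance"]], path, lineno, "abundance")
                * _number(fields[idx["cells_per_well"]], path, lineno, "cells_per_well")
            )
        try:
            records.append(CultivationRecord(taxon_id=tid, n_isolates=n, expected_occurrences=occ))
        except ValidationError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return records


def _format_value(v) -> str:
    if isinstance(v, bool):
        return str(v).lower()
    if isinstance(v, float):
        return f"{v:.6g}"
    return str(v)


def write_report(
    table: pd.DataFrame,
    path: str | None,
    metadata: dict | None = None,
    fmt: str = "tsv",
) -> str:
    """Write a report table as TSV with ``#`` metadata header lines.

    Floats are rendered with 6 significant digits; column order is the
    DataFrame's (deterministic).  ``path=None`` returns the rendered text
    without writing.  Writes go to a temp file first, then an atomic rename.
    """
    if fmt != "tsv":
        raise ValidationError(f"unsupported report format {fmt!r}")
    lines = [f"# {k}: {v}" for k, v in (metadata or {}).items()]
    lines.append("\t".join(str(c) for c in table.columns))
    for _, row in table.iterrows():
        lines.append("\t".join(_format_value(v) for v in row))
    text = "\n".join(lines) + "\n"
    if path is not None:
        directory = os.path.dirname(os.path.abspath(path))
        fd, tmp = tempfile.mkstemp(dir=directory, suffix=".tmp")
        try:
            with os.fdopen(fd, "w", encoding="utf-8") as fh:
                fh.write(text)
            os.replace(tmp, path)
        except OSError:
            if os.path.exists(tmp):
                os.unlink(tmp)
            raise
    return text


def read_report(path: str) -> tuple[dict[str, str], pd.DataFrame]:
    """Read back a report written by :func:`write_report`."""
    metadata: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        data_lines: list[str] = []
        for line in fh:
            if line.startswith("#"):
                body = line[1:].strip()
                if ":" in body:
                    k, v = body.split(":", 1)
                    metadata[k.strip()] = v.strip()
            else:
                data_lines.append(line)
    from io import StringIO

    if data_lines:
        df = pd.read_csv(StringIO("".join(data_lines)), sep="\t")
    else:
        df = pd.DataFrame()
    return metadata, df
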