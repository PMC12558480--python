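"""Reading and writing FAERS-style quarterly ASCII tables.

FAERS quarterly extracts are ``'$'``-delimited text files with one header
line, one table per entity: DEMO (demographics/administrative), DRUG, REAC
(reactions as MedDRA PTs), THER (therapy dates) and OUTC (outcomes). This
module parses them into pandas DataFrames with a fixed canonical schema per
table kind, tolerating the realities of spontaneous-report data: empty
fields are missing, dates may be partial, enum codes drift, and malformed
lines are skipped and counted rather than aborting the run.

Column layouts changed across FAERS history, so the mapping from file
columns to the canonical schema is configuration (``column_map``), with the
modern layout as default.
"""

from __future__ import annotations

import gzip
import io as _io
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .dates import parse_partial_date

DELIM = "$"

#: canonical columns per table kind (stable output order)
SCHEMAS: dict[str, list[str]] = {
    "demo": ["report_id", "case_id", "receipt_date", "event_date", "sex",
             "age_value", "age_unit", "reporter", "country"],
    "drug": ["report_id", "drug_seq", "role", "drugname", "active_ingredient"],
    "reac": ["report_id", "pt"],
    "ther": ["report_id", "drug_seq", "start_date", "end_date"],
    "outc": ["report_id", "outcome"],
}

#: default mapping from modern FAERS ASCII headers to canonical names
DEFAULT_COLUMN_MAPS: dict[str, dict[str, str]] = {
    "demo": {"primaryid": "report_id", "caseid": "case_id", "fda_dt": "receipt_date",
             "event_dt": "event_date", "sex": "sex", "age": "age_value",
             "age_cod": "age_unit", "occp_cod": "reporter", "occr_country": "country"},
    "drug": {"primaryid": "report_id", "drug_seq": "drug_seq", "role_cod": "role",
             "drugname": "drugname", "prod_ai": "active_ingredient"},
    "reac": {"primaryid": "report_id", "pt": "pt"},
    "ther": {"primaryid": "report_id", "dsg_drug_seq": "drug_seq",
             "start_dt": "start_date", "end_dt": "end_date"},
    "outc": {"primaryid": "report_id", "outc_cod": "outcome"},
}

SEX_CODES = {"F", "M"}
AGE_UNITS = {"YR", "DEC", "MON", "WK", "DY", "HR"}
ROLE_CODES = {"PS", "SS", "C", "I"}
OUTCOME_CODES = {"DE", "LT", "HO", "DS", "CA", "RI", "OT"}
REPORTER_LEVELS = {"physician", "pharmacist", "other health-professional",
                   "consumer", "unknown"}
#: FAERS occupation codes → reporter levels
REPORTER_CODES = {"MD": "physician", "PH": "pharmacist", "CN": "consumer",
                  "OT": "other health-professional", "HP": "other health-professional"}

#: factors converting an age value in the given unit to years
AGE_UNIT_TO_YEARS = {"YR": 1.0, "DEC": 10.0, "MON": 1 / 12.0,
                     "WK": 1 / 52.18, "DY": 1 / 365.25, "HR": 1 / 8766.0}


def age_in_years(value: float, unit: str) -> float:
    """Normalize an (age value, unit code) pair to years; NaN if unusable."""
    if pd.isna(value):
        return float("nan")
    factor = AGE_UNIT_TO_YEARS.get(str(unit).upper())
    return float(value) * factor if factor is not None else float("nan")


@dataclass
class ParseLog:
    """Counters accumulated while reading/writing; never raises on data."""

    skipped_lines: list = field(default_factory=list)   # (path, line_no, reason)
    unknown_codes: Counter = field(default_factory=Counter)
    replaced_delimiters: int = 0

    def merge(self, other: "ParseLog") -> None:
        self.skipped_lines.extend(other.skipped_lines)
        self.unknown_codes.update(other.unknown_codes)
        self.replaced_delimiters += other.replaced_delimiters


@dataclass
class ReportBundle:
    """The five typed tables of one extract, keyed by report_id."""

    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    ther: pd.DataFrame
    outc: pd.DataFrame

    def table(self, kind: str) -> pd.DataFrame:
        return getattr(self, kind)

    @property
    def kinds(self) -> tuple[str, ...]:
        return ("demo", "drug", "reac", "ther", "outc")


def _open_text(path: Path):
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if path.suffix == ".gz" or magic == b"\x1f\x8b":
        return _io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8-sig")
    return open(path, "r", encoding="utf-8-sig")


def _normalize_enum(series: pd.Series, valid: set, log: ParseLog, colname: str,
                    mapping: Mapping[str, str] | None = None) -> pd.Series:
    s = series.fillna("").astype(str).str.strip().str.upper()
    if mapping:
        lowered = {k.upper(): v for k, v in mapping.items()}
        mapped = s.map(lowered)
        # values already at canonical level pass through
        canon = series.fillna("").astype(str).str.strip()
        mapped = mapped.where(mapped.notna(), canon.where(canon.isin(valid)))
        unknown = mapped.isna() & (s != "")
        for code in s[unknown].unique():
            log.unknown_codes[f"{colname}:{code}"] += int((s[unknown] == code).sum())
        return mapped.fillna("unknown") if "unknown" in valid else mapped.fillna("UNK")
    known = s.isin(valid) | (s == "UNK")   # UNK is the canonical missing code
    unknown = ~known & (s != "")
    for code in s[unknown].unique():
        log.unknown_codes[f"{colname}:{code}"] += int((s[unknown] == code).sum())
    return s.where(known, "UNK")


def read_table(
    path: str | Path,
    kind: str,
    column_map: Mapping[str, str] | None = None,
    log: ParseLog | None = None,
) -> pd.DataFrame:
    """Read one '$'-delimited table into the canonical schema.

    Lines whose field count disagrees with the header are skipped and logged
    with their line number; empty fields become missing; unknown enum codes
    are preserved as UNK (or reporter "unknown") and counted. The file may
    be gzip-compressed and may start with a UTF-8 BOM.
    """
    if kind not in SCHEMAS:
        raise ValueError(f"unknown table kind {kind!r}")
    path = Path(path)
    log = log if log is not None else ParseLog()
    cmap = dict(column_map or DEFAULT_COLUMN_MAPS[kind])

    with _open_text(path) as fh:
        header = fh.readline().rstrip("\r\n")
        if not header:
            raise IOError(f"{path}: empty file, expected a header line")
        cols = header.split(DELIM)
        ncol = len(cols)
        rows, idxs = [], []
        for line_no, line in enumerate(fh, start=2):
            line = line.rstrip("\r\n")
            if not line:
                continue
            fields = line.split(DELIM)
            if len(fields) != ncol:
                log.skipped_lines.append((str(path), line_no,
                                          f"expected {ncol} fields, got {len(fields)}"))
                continue
            rows.append(fields)
            idxs.append(line_no)

    raw = pd.DataFrame(rows, columns=cols, dtype=str) if rows else pd.DataFrame(columns=cols, dtype=str)
    raw = raw.replace("", pd.NA)
    # map file columns (case-insensitive) to canonical names
    lower_map = {k.lower(): v for k, v in cmap.items()}
    renamed = {}
    for col in raw.columns:
        tgt = lower_map.get(col.lower(), col.lower() if col.lower() in SCHEMAS[kind] else None)
        if tgt is not None and tgt not in renamed:
            renamed[tgt] = raw[col]
    df = pd.DataFrame({c: renamed.get(c, pd.Series([pd.NA] * len(raw), dtype="object"))
                       for c in SCHEMAS[kind]})

    if "report_id" in df.columns:
        df["report_id"] = df["report_id"].astype("string").str.strip()
    if kind == "demo":
        df["case_id"] = df["case_id"].astype("string").str.strip()
        df["sex"] = _normalize_enum(df["sex"], SEX_CODES, log, "sex")
        df["age_unit"] = _normalize_enum(df["age_unit"], AGE_UNITS, log, "age_unit")
        df["reporter"] = _normalize_enum(df["reporter"], REPORTER_LEVELS, log,
                                         "reporter", REPORTER_CODES)
        df["age_value"] = pd.to_numeric(df["age_value"], errors="coerce")
        df["country"] = df["country"].astype("string")
    elif kind == "drug":
        df["role"] = _normalize_enum(df["role"], ROLE_CODES, log, "role")
        df["drug_seq"] = pd.to_numeric(df["drug_seq"], errors="coerce").astype("Int64")
        for c in ("drugname", "active_ingredient"):
            df[c] = df[c].astype("string")
    elif kind == "reac":
        df["pt"] = df["pt"].astype("string")
        df = df[df["pt"].notna() & (df["pt"].str.strip() != "")].reset_index(drop=True)
    elif kind == "ther":
        df["drug_seq"] = pd.to_numeric(df["drug_seq"], errors="coerce").astype("Int64")
    elif kind == "outc":
        df["outcome"] = _normalize_enum(df["outcome"], OUTCOME_CODES, log, "outcome")
    for c in df.columns:
        if c.endswith("_date"):
            df[c] = df[c].astype("string")
    return df


def write_table(
    records: pd.DataFrame,
    path: str | Path,
    kind: str | None = None,
    log: ParseLog | None = None,
    delim_substitute: str = " ",
) -> None:
    """Write records as a '$'-delimited file with header, missing → empty.

    Free-text fields containing the delimiter have it replaced by
    ``delim_substitute``; each replacement is counted in the log.
    """
    log = log if log is not None else ParseLog()
    path = Path(path)
    cols = SCHEMAS[kind] if kind else list(records.columns)
    lines = [DELIM.join(cols)]
    if len(records):
        df = records.reindex(columns=cols)
        str_df = df.astype("object")
        for c in cols:
            col = str_df[c]
            col = col.map(lambda v: "" if pd.isna(v) else _fmt_field(v))
            n_bad = int(col.str.contains(DELIM, regex=False).sum())
            if n_bad:
                log.replaced_delimiters += int(
                    col.str.count(DELIM.replace("$", r"\$")).sum())
                col = col.str.replace(DELIM, delim_substitute, regex=False)
            str_df[c] = col
        lines.extend(DELIM.join(row) for row in str_df.itertuples(index=False))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def _fmt_field(v) -> str:
    if isinstance(v, float) and v == int(v):
        return str(int(v))
    return str(v)


def read_bundle(directory: str | Path,
                column_maps: Mapping[str, Mapping[str, str]] | None = None,
                log: ParseLog | None = None) -> ReportBundle:
    """Read demo/drug/reac/ther/outc tables from a directory.

    Accepts ``<kind>.txt`` or ``<kind>.txt.gz`` (case-insensitive stem).
    """
    directory = Path(directory)
    tables = {}
    for kind in SCHEMAS:
        candidates = [p for p in directory.iterdir()
                      if p.name.lower() in {f"{kind}.txt", f"{kind}.txt.gz"}]
        if not candidates:
            raise IOError(f"missing {kind} table in {directory}")
        cmap = (column_maps or {}).get(kind)
        tables[kind] = read_table(sorted(candidates)[0], kind, cmap, log)
    return ReportBundle(**tables)


def write_bundle(bundle: ReportBundle, directory: str | Path,
                 log: ParseLog | None = None) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for kind in bundle.kinds:
        write_table(bundle.table(kind), directory / f"{kind}.txt", kind, log)


@dataclass
class ValidationReport:
    """Read-only consistency summary of a bundle."""

    orphans: dict                # table kind -> count of report_ids not in demo
    partial_dates: dict          # column -> count at month/year precision
    missing_dates: dict          # column -> count missing
    negative_durations: int      # THER rows with full dates and end < start
    n_reports: int

    @property
    def total_orphans(self) -> int:
        return sum(self.orphans.values())


def validate_bundle(bundle: ReportBundle) -> ValidationReport:
    """Count orphan report ids, partial/missing dates and negative therapy
    durations. Never mutates the bundle."""
    known = set(bundle.demo["report_id"].dropna())
    orphans = {}
    for kind in ("drug", "reac", "ther", "outc"):
        ids = bundle.table(kind)["report_id"].dropna()
        orphans[kind] = int((~ids.isin(known)).sum())

    partial, missing = {}, {}
    for kind, col in (("demo", "receipt_date"), ("demo", "event_date"),
                      ("ther", "start_date"), ("ther", "end_date")):
        series = bundle.table(kind)[col]
        parsed = series.map(parse_partial_date)
        missing[f"{kind}.{col}"] = int(parsed.isna().sum())
        partial[f"{kind}.{col}"] = int(sum(
            1 for p in parsed if p is not None and p.precision.value != "day"))

    neg = 0
    for start, end in zip(bundle.ther["start_date"], bundle.ther["end_date"]):
        ps, pe = parse_partial_date(start), parse_partial_date(end)
        if ps is not None and pe is not None \
                and ps.precision.value == "day" and pe.precision.value == "day" \
                and pe.to_date() < ps.to_date():
            neg += 1
    return ValidationReport(orphans=orphans, partial_dates=partial,
                            missing_dates=missing, negative_durations=neg,
                            n_reports=int(bundle.demo["report_id"].nunique()))
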