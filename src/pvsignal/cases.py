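"""Case-level processing: deduplication, target-drug identification and
construction of the (report, term) pair sets that feed the fourfold tables.

FAERS cases are resubmitted as updated versions sharing a case id; only the
most recent version (by receipt date) enters the analysis. Reports are then
partitioned into *target* reports — those with at least one drug row whose
name matches the target synonym list in a qualifying role (primary suspect
by default) — and *background* reports (everything else, the comparator).
The counting unit throughout is the unique (deduplicated report, PT) pair;
SOC-level tables use unique (report, SOC) pairs after PT→SOC mapping.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .dates import date_sort_key, parse_partial_date
from .io import ReportBundle, age_in_years

#: search terms for the default target drug: generic and US brand name
DEFAULT_SYNONYMS = frozenset({"CINACALCET", "SENSIPAR"})


def normalize_term(term: str) -> str:
    """Trim, collapse internal whitespace and casefold for matching."""
    return " ".join(str(term).split()).casefold()


@dataclass(frozen=True)
class SynonymList:
    """Uppercase drug-name search terms, matched as substrings."""

    names: frozenset = DEFAULT_SYNONYMS

    def __post_init__(self) -> None:
        if not self.names:
            raise ValueError("synonym list must be nonempty")
        object.__setattr__(self, "names", frozenset(s.upper() for s in self.names))

    @classmethod
    def from_file(cls, path: str | Path) -> "SynonymList":
        """One synonym per line (first column if delimited); '#' comments."""
        names = set()
        for line in Path(path).read_text(encoding="utf-8-sig").splitlines():
            line = line.strip()
            if line and not line.startswith("#"):
                names.add(line.split("\t")[0].split("$")[0].strip().upper())
        return cls(frozenset(names))


class MeddraMap:
    """PT → SOC mapping (user supplied; MedDRA itself is licensed).

    Keys are matched after term normalization; queries for unmapped PTs
    return None and are reported by the mapping operation.
    """

    def __init__(self, mapping: Mapping[str, str]):
        self._map = {normalize_term(pt): str(soc).strip() for pt, soc in mapping.items()}

    def __len__(self) -> int:
        return len(self._map)

    def get(self, pt: str) -> Optional[str]:
        return self._map.get(normalize_term(pt))

    @classmethod
    def from_file(cls, path: str | Path, delimiter: str = "\t") -> "MeddraMap":
        """Two-column delimited text: PT, SOC. '#' comments and blanks skipped."""
        mapping = {}
        for line in Path(path).read_text(encoding="utf-8-sig").splitlines():
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split(delimiter)
            if len(parts) >= 2:
                mapping[parts[0].strip()] = parts[1].strip()
        return cls(mapping)


def deduplicate(demo: pd.DataFrame) -> set[str]:
    """Report ids to keep: per case id, the version with the latest receipt
    date; ties broken by the larger report id on its zero-padded form.

    Missing/unparseable receipt dates sort minimal, so such a version is
    kept only if it is the sole version of its case. Deterministic and
    idempotent.
    """
    if demo.empty:
        return set()
    df = demo[["report_id", "case_id"]].copy()
    df["_date_key"] = demo["receipt_date"].map(date_sort_key)
    width = int(df["report_id"].str.len().max())
    df["_id_key"] = df["report_id"].str.zfill(width)
    df = df.sort_values(["case_id", "_date_key", "_id_key"], kind="mergesort")
    kept = df.groupby("case_id", sort=False).tail(1)
    return set(kept["report_id"])


def match_drug(drugname: object, active_ingredient: object = None,
               synonyms: SynonymList | None = None) -> bool:
    """True iff any synonym occurs as a substring of the uppercased drug
    name or active ingredient."""
    synonyms = synonyms or SynonymList()
    for value in (drugname, active_ingredient):
        if value is None or (isinstance(value, float) and np.isnan(value)) or value is pd.NA:
            continue
        hay = str(value).upper()
        if any(s in hay for s in synonyms.names):
            return True
    return False


@dataclass
class DrugEventSet:
    """Deduplicated (report, PT) pairs partitioned into target vs background.

    ``target_pairs``/``background_pairs`` have columns ``report_id``,
    ``term`` (display casing), ``term_norm``; after :meth:`annotate_soc`
    the SOC-level pair frames are available too. ``report_meta`` holds one
    row per deduplicated report (sex, age_years, reporter, country,
    receipt_year, event_date, is_target).
    """

    target_pairs: pd.DataFrame
    background_pairs: pd.DataFrame
    target_report_ids: set
    report_meta: pd.DataFrame
    soc_target_pairs: Optional[pd.DataFrame] = None
    soc_background_pairs: Optional[pd.DataFrame] = None
    unmapped_pts: list = field(default_factory=list)

    def pairs_at_level(self, level: str) -> tuple[pd.DataFrame, pd.DataFrame]:
        if level == "pt":
            return self.target_pairs, self.background_pairs
        if level == "soc":
            if self.soc_target_pairs is None:
                raise ValueError("SOC pairs not built; call annotate_soc first")
            return self.soc_target_pairs, self.soc_background_pairs
        raise ValueError(f"unknown level {level!r}")

    def annotate_soc(self, meddra_map: MeddraMap, mode: str = "unique") -> None:
        """Attach SOC labels and build SOC-level pair sets.

        ``mode='unique'`` (default): a report contributes at most one pair
        per SOC; ``mode='sum'``: every PT pair contributes, so a SOC pair
        count is the sum of its PT pair counts.
        """
        unmapped: set[str] = set()
        frames = []
        for pairs in (self.target_pairs, self.background_pairs):
            soc = pairs["term_norm"].map(lambda t: meddra_map.get(t))
            miss = pairs.loc[soc.isna(), "term"]
            unmapped.update(miss.unique().tolist())
            mapped = pairs.loc[soc.notna()].copy()
            mapped["term"] = soc[soc.notna()].to_numpy()
            mapped["term_norm"] = mapped["term"].map(normalize_term)
            if mode == "unique":
                mapped = mapped.drop_duplicates(["report_id", "term_norm"])
            mapped = mapped.reset_index(drop=True)
            frames.append(mapped[["report_id", "term", "term_norm"]])
        self.soc_target_pairs, self.soc_background_pairs = frames
        self.unmapped_pts = sorted(unmapped)


def map_pt_to_soc(pairs: pd.DataFrame, meddra_map: MeddraMap,
                  mode: str = "unique") -> tuple[pd.DataFrame, list[str]]:
    """SOC-annotated pair set plus the list of unmapped PTs.

    Unmapped PTs are excluded from the SOC-level pairs only (they remain in
    PT-level analyses untouched).
    """
    soc = pairs["term_norm"].map(lambda t: meddra_map.get(t))
    unmapped = sorted(pairs.loc[soc.isna(), "term"].unique().tolist())
    out = pairs.loc[soc.notna()].copy()
    out["soc"] = soc[soc.notna()].to_numpy()
    if mode == "unique":
        out = out.drop_duplicates(["report_id", "soc"])
    return out.reset_index(drop=True), unmapped


def extract_event_sets(
    bundle: ReportBundle,
    synonyms: SynonymList | None = None,
    role_filter: Iterable[str] = ("PS",),
    kept_report_ids: set | None = None,
) -> DrugEventSet:
    """Build the deduplicated target/background (report, PT) pair sets.

    A report is a target report iff it has at least one drug row matching
    the synonyms with role in ``role_filter``. Reports whose only matching
    rows fail the role filter stay in the background (the comparator is
    "all other reports", not "reports without the drug"). Within-report
    duplicate PTs collapse to one pair.
    """
    synonyms = synonyms or SynonymList()
    roles = {r.upper() for r in role_filter}
    if kept_report_ids is None:
        kept_report_ids = deduplicate(bundle.demo)

    demo = bundle.demo[bundle.demo["report_id"].isin(kept_report_ids)].copy()
    demo = demo.drop_duplicates("report_id")

    drug = bundle.drug[bundle.drug["report_id"].isin(kept_report_ids)]
    if len(drug):
        pattern = "|".join(sorted(map(re.escape, synonyms.names)))
        name_hit = drug["drugname"].fillna("").str.upper().str.contains(pattern, regex=True)
        ai_hit = drug["active_ingredient"].fillna("").str.upper().str.contains(pattern, regex=True)
        hit = (name_hit | ai_hit) & drug["role"].isin(roles)
        target_ids = set(drug.loc[hit, "report_id"])
    else:
        target_ids = set()

    reac = bundle.reac[bundle.reac["report_id"].isin(kept_report_ids)].copy()
    reac["term_norm"] = reac["pt"].map(normalize_term)
    reac = reac.rename(columns={"pt": "term"})
    reac = reac.drop_duplicates(["report_id", "term_norm"])
    is_target = reac["report_id"].isin(target_ids)
    cols = ["report_id", "term", "term_norm"]
    target_pairs = reac.loc[is_target, cols].reset_index(drop=True)
    background_pairs = reac.loc[~is_target, cols].reset_index(drop=True)

    meta = pd.DataFrame({
        "report_id": demo["report_id"],
        "sex": demo["sex"],
        "age_years": [age_in_years(v, u) for v, u in
                      zip(demo["age_value"], demo["age_unit"])],
        "reporter": demo["reporter"],
        "country": demo["country"],
        "receipt_year": [
            (p.year if (p := parse_partial_date(d)) is not None else None)
            for d in demo["receipt_date"]],
        "event_date": demo["event_date"],
        "is_target": demo["report_id"].isin(target_ids),
    }).reset_index(drop=True)

    return DrugEventSet(
        target_pairs=target_pairs,
        background_pairs=background_pairs,
        target_report_ids=target_ids,
        report_meta=meta,
    )
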