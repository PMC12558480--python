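"""Descriptive epidemiology of target-drug reports.

Summaries are per deduplicated target report (not per event pair): sex,
age bins (on age normalized to years), reporter type, country, outcome
distribution, annual report counts, and time-to-onset (TTO) — days from
the start of target-drug therapy to the event — with median/IQR and the
conventional bins <7, 7–28, 28–60, ≥60 days.

Each summary records its denominator policy because spontaneous-report
tables are heavily incomplete: outcome percentages use counted outcome
codes (one code at most once per report) rather than reports, and TTO
percentages use all target reports with unknowns shown.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .cases import DrugEventSet, SynonymList, match_drug
from .dates import days_between, parse_partial_date
from .io import ReportBundle

AGE_BIN_EDGES = [0, 18, 45, 60, 75, 90, float("inf")]
AGE_BIN_LABELS = ["<18", "18-44", "45-59", "60-74", "75-89", ">=90"]
TTO_BIN_EDGES = [0, 7, 28, 60, float("inf")]
TTO_BIN_LABELS = ["<7", "7-28", "28-60", ">=60"]

#: worst-outcome severity order, most severe first
OUTCOME_SEVERITY = ["DE", "LT", "DS", "HO", "CA", "RI", "OT"]
OUTCOME_LABELS = {"DE": "death", "LT": "life threatening", "HO": "hospitalization",
                  "DS": "disability", "CA": "congenital anomaly",
                  "RI": "required intervention", "OT": "other serious",
                  "UNK": "other serious"}


def _table(category: str, counts: pd.Series, denominator: int | None = None,
           policy: str = "target reports") -> pd.DataFrame:
    denom = int(counts.sum()) if denominator is None else denominator
    pct = 100.0 * counts / denom if denom else counts * 0.0
    return pd.DataFrame({
        "category": category,
        "level": counts.index.astype(str),
        "count": counts.to_numpy(dtype=np.int64),
        "percent": np.round(pct.to_numpy(dtype=float), 2),
        "denominator_policy": policy,
    })


def _bin(values: Iterable[float], edges, labels) -> pd.Series:
    """Left-closed bins: [e0,e1) -> labels[0], ...; NaN -> 'unknown'."""
    arr = pd.Series(list(values), dtype=float)
    cut = pd.cut(arr, bins=edges, labels=labels, right=False, include_lowest=True)
    out = cut.astype(object)
    out[arr.isna()] = "unknown"
    return out.fillna("unknown")


def summarize_demographics(events: DrugEventSet, top_k_countries: int = 1) -> pd.DataFrame:
    """Sex, age-bin, reporter and country tables over target reports.

    Countries outside the ``top_k_countries`` most frequent collapse to
    "other"; missing country is "unknown".
    """
    meta = events.report_meta[events.report_meta["is_target"].astype(bool)]
    n = len(meta)
    sex = meta["sex"].fillna("UNK").replace({"F": "female", "M": "male", "UNK": "unknown"})
    sex_tab = _table("sex", sex.value_counts().reindex(
        ["female", "male", "unknown"], fill_value=0), n)

    age_bins = _bin(meta["age_years"], AGE_BIN_EDGES, AGE_BIN_LABELS)
    age_tab = _table("age_years", age_bins.value_counts().reindex(
        AGE_BIN_LABELS + ["unknown"], fill_value=0), n)

    rep_tab = _table("reporter", meta["reporter"].fillna("unknown").value_counts(), n)

    country = meta["country"].fillna("unknown").astype(str)
    top = country[country != "unknown"].value_counts().head(top_k_countries).index
    collapsed = country.where(country.isin(top) | (country == "unknown"), "other")
    ctry_tab = _table("country", collapsed.value_counts(), n)

    return pd.concat([sex_tab, age_tab, rep_tab, ctry_tab], ignore_index=True)


def summarize_outcomes(events: DrugEventSet, outc: pd.DataFrame,
                       policy: str = "per_code") -> pd.DataFrame:
    """Outcome distribution for target reports.

    ``policy="per_code"`` (default): each outcome code counts at most once
    per report and the percent denominator is the number of counted codes.
    ``policy="worst"``: one outcome per report, the most severe present
    (death > life threatening > disability > hospitalization > congenital
    anomaly > required intervention > other serious), denominator = reports
    with any outcome. Unknown codes fall under "other serious".
    """
    target_ids = {rid for rid, t in
                  zip(events.report_meta["report_id"], events.report_meta["is_target"]) if t}
    sub = outc[outc["report_id"].isin(target_ids)].copy()
    sub["outcome"] = sub["outcome"].where(sub["outcome"].isin(OUTCOME_SEVERITY), "UNK")
    sub = sub.drop_duplicates(["report_id", "outcome"])
    if policy == "per_code":
        counts = sub["outcome"].map(OUTCOME_LABELS).value_counts()
        return _table("outcome", counts, policy="counted outcome codes")
    if policy == "worst":
        rank = {c: i for i, c in enumerate(OUTCOME_SEVERITY + ["UNK"])}
        worst = (sub.assign(rank=sub["outcome"].map(rank))
                 .sort_values(["report_id", "rank"], kind="mergesort")
                 .groupby("report_id", sort=False).head(1))
        counts = worst["outcome"].map(OUTCOME_LABELS).value_counts()
        return _table("outcome", counts, policy="worst outcome per report")
    raise ValueError(f"unknown outcome policy {policy!r}")


@dataclass
class TtoSummary:
    records: pd.DataFrame        # report_id, days (nullable), bin
    median: float
    q1: float
    q3: float
    n_known: int
    n_negative: int              # negative differences, treated as unknown

    def bin_table(self) -> pd.DataFrame:
        counts = self.records["bin"].value_counts().reindex(
            TTO_BIN_LABELS + ["unknown"], fill_value=0)
        return _table("tto_days", counts, len(self.records))


def compute_tto(events: DrugEventSet, ther: pd.DataFrame, drug: pd.DataFrame,
                synonyms: SynonymList | None = None,
                anchor: str = "event_date") -> TtoSummary:
    """Time to onset per target report.

    Days from the earliest day-precision therapy start date of a
    synonym-matched PS drug row to the report's event date (the anchor is
    configurable but defaults to the event date, not the receipt date).
    Both dates must have day precision; otherwise — and for negative
    differences, which are tracked separately — the report's TTO is
    unknown. Median and quartiles use linear interpolation over the known
    values.
    """
    synonyms = synonyms or SynonymList()
    meta = events.report_meta[events.report_meta["is_target"].astype(bool)]
    target_ids = set(meta["report_id"])

    dsub = drug[(drug["report_id"].isin(target_ids)) & (drug["role"] == "PS")]
    mask = np.array([match_drug(dn, ai, synonyms) for dn, ai in
                     zip(dsub["drugname"], dsub["active_ingredient"])], dtype=bool)
    matched = dsub.loc[mask] if len(dsub) else dsub
    seqs = set(zip(matched["report_id"], matched["drug_seq"].astype("Int64")))

    tsub = ther[ther["report_id"].isin(target_ids)]
    starts: dict[str, object] = {}
    for rid, seq, start in zip(tsub["report_id"], tsub["drug_seq"], tsub["start_date"]):
        if (rid, seq) not in seqs:
            continue
        p = parse_partial_date(start)
        if p is None or p.precision.value != "day":
            continue
        if rid not in starts or p.to_date() < starts[rid].to_date():
            starts[rid] = p

    anchor_dates = dict(zip(meta["report_id"], meta[anchor]))
    rows, n_neg = [], 0
    for rid in meta["report_id"]:
        days: Optional[int] = None
        start = starts.get(rid)
        event = parse_partial_date(anchor_dates.get(rid))
        if start is not None and event is not None:
            delta = days_between(start, event)
            if delta is not None:
                if delta < 0:
                    n_neg += 1
                else:
                    days = delta
        rows.append((rid, days))
    records = pd.DataFrame(rows, columns=["report_id", "days"])
    records["days"] = records["days"].astype("Float64")
    records["bin"] = _bin(records["days"].astype(float), TTO_BIN_EDGES, TTO_BIN_LABELS)

    known = records["days"].dropna().astype(float).to_numpy()
    if known.size:
        q1, med, q3 = np.percentile(known, [25, 50, 75])
    else:
        q1 = med = q3 = float("nan")
    return TtoSummary(records=records, median=float(med), q1=float(q1),
                      q3=float(q3), n_known=int(known.size), n_negative=n_neg)


def annual_counts(events: DrugEventSet) -> pd.DataFrame:
    """Target reports per receipt year (year precision suffices)."""
    meta = events.report_meta[events.report_meta["is_target"].astype(bool)]
    years = meta["receipt_year"].map(lambda y: "unknown" if pd.isna(y) else str(int(y)))
    counts = years.value_counts().sort_index()
    return _table("receipt_year", counts, len(meta))
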