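"""Synthetic FAERS-like data with known ground truth.

The generator emulates the structure of spontaneous-report extracts —
multi-event and multi-drug reports, duplicate case versions, role codes,
partial and missing dates, demographics and outcomes — with drug–event
associations planted at configurable relative risk, so that every pipeline
stage can be tested against exact bookkeeping and analytic expectations.

Generative model
----------------
Each of ``n_reports`` cases gets one primary-suspect (PS) drug drawn from
``baseline_drug_weights`` and an event count K from a Poisson truncated at 1
(every report has at least one event). Event PTs are drawn i.i.d. from the
baseline PT weights, multiplied by the planted relative risk for the
report's PS drug and renormalized, then de-duplicated within the report.

Under this renormalization the target-vs-background reporting odds ratio
for a planted PT equals the planted relative risk exactly in the
single-draw case: with baseline weight w, risk R and renormalizer
Z = 1 + w(R−1), the planted PT's renormalized weight is w' = wR/Z and
1 − w' = (Z − wR)/Z = (1 − w)/Z, so the target odds w'/(1−w') = wR/(1−w)
are exactly R times the background odds w/(1−w). The planted RR is
therefore the estimand of the downstream ROR (up to the small
within-report de-duplication effect), which is what makes signal-recovery
tests meaningful.

A configurable fraction of cases receive a superseded earlier version
(same case id, strictly earlier receipt date, own report id), so correct
deduplication output is known exactly.
"""

from __future__ import annotations

import datetime as _dt
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cases import MeddraMap, SynonymList
from .io import ReportBundle, write_bundle
from .stats import FourfoldTable

_EPOCH_START = _dt.date(2004, 1, 1).toordinal()
_EPOCH_END = _dt.date(2025, 3, 31).toordinal()

_TARGET_NAMES = ("CINACALCET", "SENSIPAR", "CINACALCET HCL",
                 "SENSIPAR 30MG TABLET", "CINACALCET 60 MG")
_COUNTRIES = ("JP", "FR", "DE", "GB", "CA", "BR", "IT")


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic extract.

    Defaults emulate the reporting profile of a moderately reported drug:
    ~1.6 events per report (the target drug in the motivating dataset shows
    47,755 events over 30,540 reports ≈ 1.56), heavy missingness in event
    dates (about half, matching ~52% unknown time-to-onset), one third
    missing age, and a log-normal onset-time distribution whose median and
    quartile spread match an 82-day median with (8, 315) IQR.
    """

    n_reports: int = 5000
    n_drugs: int = 20
    n_pts: int = 200
    baseline_pt_weights: Optional[Sequence[float]] = None
    baseline_drug_weights: Optional[Sequence[float]] = None
    planted_signals: Sequence[tuple] = ()          # (drug id, pt id, RR >= 0)
    events_per_report_mean: float = 1.6
    drugs_per_report_mean: float = 2.0
    duplicate_rate: float = 0.05
    missing_sex_rate: float = 0.13
    missing_age_rate: float = 0.33
    missing_date_rate: float = 0.50
    partial_date_rate: float = 0.05
    tto_lognormal_params: tuple = (4.4, 2.7)       # (mu, sigma) of ln(days)
    n_socs: int = 12
    target_drug: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reports < 1 or self.n_drugs < 1 or self.n_pts < 1:
            raise ConfigurationError("n_reports, n_drugs, n_pts must be positive")
        if self.events_per_report_mean <= 0 or self.drugs_per_report_mean <= 0:
            raise ConfigurationError("per-report means must be positive")
        for name in ("duplicate_rate", "missing_sex_rate", "missing_age_rate",
                     "missing_date_rate", "partial_date_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0 or (name == "duplicate_rate" and v >= 1.0):
                raise ConfigurationError(f"{name}={v} out of range")
        object.__setattr__(self, "baseline_pt_weights",
                           self._check_weights(self.baseline_pt_weights, self.n_pts,
                                               "baseline_pt_weights", zipf=True))
        object.__setattr__(self, "baseline_drug_weights",
                           self._check_weights(self.baseline_drug_weights, self.n_drugs,
                                               "baseline_drug_weights"))
        planted_pts = set()
        for drug, pt, rr in self.planted_signals:
            if not (0 <= drug < self.n_drugs) or not (0 <= pt < self.n_pts):
                raise ConfigurationError(f"planted signal ({drug},{pt}) out of range")
            if rr < 0:
                raise ConfigurationError("planted relative risks must be >= 0")
            planted_pts.add(pt)
        if self.n_pts < len(planted_pts):
            raise ConfigurationError("n_pts smaller than number of planted PTs")

    @staticmethod
    def _check_weights(w, n: int, name: str, zipf: bool = False) -> np.ndarray:
        if w is None:
            if zipf:
                raw = 1.0 / (np.arange(n) + 10.0)   # mildly skewed baseline
            else:
                raw = np.ones(n)
                raw[0] = max(1.0, 0.25 * n)          # target drug reported often
            w = raw / raw.sum()
        w = np.asarray(w, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ConfigurationError(f"{name} must be a length-{n} probability vector")
        return w

    # -- naming -------------------------------------------------------------
    def pt_name(self, j: int) -> str:
        return f"PT_{j:04d}"

    def soc_name(self, s: int) -> str:
        return f"SOC_{s:02d}"

    def drug_name(self, d: int) -> str:
        return "CINACALCET" if d == self.target_drug else f"DRUG{d:03d}"

    def meddra_map(self) -> MeddraMap:
        return MeddraMap({self.pt_name(j): self.soc_name(j % self.n_socs)
                          for j in range(self.n_pts)})

    def synonyms(self) -> SynonymList:
        return SynonymList(frozenset({"CINACALCET", "SENSIPAR"}))

    def renormalized_pt_weights(self, drug: int) -> np.ndarray:
        """Baseline PT weights with this drug's planted risks applied."""
        w = np.array(self.baseline_pt_weights, dtype=float)
        for d, pt, rr in self.planted_signals:
            if d == drug:
                w[pt] *= rr
        total = w.sum()
        if total <= 0:
            raise ConfigurationError("all PT weights zero after planting")
        return w / total


@dataclass
class GroundTruth:
    """Exact bookkeeping and model expectations for one generated bundle."""

    config: SimConfig
    pair_counts: pd.DataFrame          # ps_drug, pt_id, count (deduplicated reports)
    planted: dict                      # (drug, pt) -> rr
    superseded_report_ids: list
    n_cases: int
    events_total: int                  # unique (report, PT) pairs, current versions
    target_pair_count: int             # pairs with PS = target drug
    reports_per_year: dict

    @property
    def n_duplicate_versions(self) -> int:
        return len(self.superseded_report_ids)

    def realized_fourfold(self, pt: int) -> FourfoldTable:
        """Integer cells for the target drug vs this PT from the tallies."""
        tgt = self.pair_counts["ps_drug"] == self.config.target_drug
        hit = self.pair_counts["pt_id"] == pt
        a = int(self.pair_counts.loc[tgt & hit, "count"].sum())
        c = int(self.pair_counts.loc[~tgt & hit, "count"].sum())
        b = self.target_pair_count - a
        d = int(self.pair_counts["count"].sum()) - self.target_pair_count - c
        return FourfoldTable(a=a, b=b, c=c, d=d)


def _truncated_poisson(rng: np.random.Generator, lam: float, size: int) -> np.ndarray:
    """Poisson(lam) conditioned on >= 1, by resampling zeros."""
    out = rng.poisson(lam, size)
    zero = out == 0
    while zero.any():
        out[zero] = rng.poisson(lam, int(zero.sum()))
        zero = out == 0
    return out


def _pt_inclusion_prob(w: np.ndarray, lam: float) -> np.ndarray:
    """P(PT j appears in a report) = 1 − E[(1−w_j)^K], K ~ TruncPoisson(lam)."""
    x = 1.0 - w
    return 1.0 - (np.expm1(lam * x)) / np.expm1(lam)


def expected_fourfold(config: SimConfig, drug: int, pt: int) -> FourfoldTable:
    """Analytic expected fourfold cells for (drug, pt) under the model.

    Cells count expected unique (deduplicated report, PT) pairs with the
    row partition "PS drug == drug" vs all other PS drugs.
    """
    if not (0 <= drug < config.n_drugs) or not (0 <= pt < config.n_pts):
        raise ConfigurationError("drug or pt id out of range")
    lam = config.events_per_report_mean
    n = config.n_reports
    dw = np.asarray(config.baseline_drug_weights)
    a = b = c = d = 0.0
    for g in range(config.n_drugs):
        p_incl = _pt_inclusion_prob(config.renormalized_pt_weights(g), lam)
        pairs = n * dw[g] * p_incl.sum()
        with_pt = n * dw[g] * p_incl[pt]
        if g == drug:
            a += with_pt
            b += pairs - with_pt
        else:
            c += with_pt
            d += pairs - with_pt
    return FourfoldTable(a=a, b=b, c=c, d=d)


def _dates_to_str(ordinals: np.ndarray) -> list[str]:
    return [_dt.date.fromordinal(int(o)).strftime("%Y%m%d") for o in ordinals]


def _degrade_dates(rng: np.random.Generator, dates: list[str],
                   missing_rate: float, partial_rate: float) -> list[str]:
    """Blank a fraction of dates and truncate another fraction to month/year."""
    u = rng.random(len(dates))
    v = rng.random(len(dates))
    out = []
    for s, ui, vi in zip(dates, u, v):
        if ui < missing_rate:
            out.append("")
        elif ui < missing_rate + partial_rate:
            out.append(s[:6] if vi < 0.5 else s[:4])
        else:
            out.append(s)
    return out


def generate_bundle(config: SimConfig) -> tuple[ReportBundle, GroundTruth]:
    """Generate one synthetic extract plus its ground truth.

    Pure function of the configuration (including its seed): identical
    configs yield identical bundles.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_reports
    report_ids = np.array([f"R{i:08d}" for i in range(n)])
    case_ids = np.array([f"C{i:07d}" for i in range(n)])

    # --- PS drug and events --------------------------------------------------
    ps_drug = rng.choice(config.n_drugs, size=n, p=config.baseline_drug_weights)
    k_events = _truncated_poisson(rng, config.events_per_report_mean, n)

    rep_idx_parts, pt_parts = [], []
    for g in np.unique(ps_drug):
        mask = ps_drug == g
        total = int(k_events[mask].sum())
        draws = rng.choice(config.n_pts, size=total,
                           p=config.renormalized_pt_weights(int(g)))
        rep_idx_parts.append(np.repeat(np.nonzero(mask)[0], k_events[mask]))
        pt_parts.append(draws)
    pair_df = pd.DataFrame({
        "rep": np.concatenate(rep_idx_parts),
        "pt_id": np.concatenate(pt_parts),
    }).drop_duplicates().sort_values(["rep", "pt_id"]).reset_index(drop=True)

    # --- dates ---------------------------------------------------------------
    receipt_ord = rng.integers(_EPOCH_START + 400, _EPOCH_END + 1, size=n)
    event_ord = receipt_ord - rng.integers(0, 60, size=n)
    tto_mu, tto_sigma = config.tto_lognormal_params
    tto_days = np.maximum(0, np.round(rng.lognormal(tto_mu, tto_sigma, size=n))).astype(int)
    start_ord = event_ord - tto_days
    start_ord = np.maximum(start_ord, _dt.date(1990, 1, 1).toordinal())

    receipt_str = _dates_to_str(receipt_ord)
    event_str = _degrade_dates(rng, _dates_to_str(event_ord),
                               config.missing_date_rate, config.partial_date_rate)
    start_str = _degrade_dates(rng, _dates_to_str(start_ord),
                               config.missing_date_rate, config.partial_date_rate)

    # --- demographics --------------------------------------------------------
    sex = rng.choice(["F", "M"], size=n, p=[0.54, 0.46])
    sex = np.where(rng.random(n) < config.missing_sex_rate, "UNK", sex)
    age_years = np.clip(np.round(rng.normal(60, 15, size=n)), 1, 100)
    unit_pick = rng.random(n)
    age_unit = np.where(unit_pick < 0.90, "YR", np.where(unit_pick < 0.95, "DEC", "MON"))
    age_value = np.where(age_unit == "YR", age_years,
                         np.where(age_unit == "DEC", age_years / 10.0, age_years * 12.0))
    age_missing = rng.random(n) < config.missing_age_rate
    reporter = rng.choice(["other health-professional", "consumer", "pharmacist",
                           "physician", "unknown"], size=n,
                          p=[0.325, 0.30, 0.25, 0.115, 0.01])
    is_us = rng.random(n) < 0.895
    country = np.where(is_us, "US", rng.choice(_COUNTRIES, size=n))

    demo = pd.DataFrame({
        "report_id": report_ids, "case_id": case_ids,
        "receipt_date": receipt_str, "event_date": event_str,
        "sex": sex,
        "age_value": [None if m else float(v) for v, m in zip(age_value, age_missing)],
        "age_unit": ["UNK" if m else u for u, m in zip(age_unit, age_missing)],
        "reporter": reporter, "country": country,
    })

    # --- drugs ---------------------------------------------------------------
    n_drug_rows = _truncated_poisson(rng, config.drugs_per_report_mean, n)
    extra_counts = n_drug_rows - 1
    total_extra = int(extra_counts.sum())
    extra_drug = rng.choice(config.n_drugs, size=total_extra,
                            p=config.baseline_drug_weights)
    extra_role = rng.choice(["SS", "C", "I"], size=total_extra, p=[0.3, 0.6, 0.1])
    name_noise = rng.random(n + total_extra)

    def _name(d: int, noise: float) -> str:
        if d == config.target_drug:
            return _TARGET_NAMES[int(noise * len(_TARGET_NAMES))]
        base = config.drug_name(d)
        return f"{base} 10MG" if noise < 0.3 else base

    drug_rows = {
        "report_id": list(report_ids), "drug_seq": [1] * n,
        "role": ["PS"] * n,
        "drugname": [_name(int(d), name_noise[i]) for i, d in enumerate(ps_drug)],
        "active_ingredient": [
            "CINACALCET HYDROCHLORIDE" if d == config.target_drug else None
            for d in ps_drug],
    }
    extra_rep = np.repeat(np.arange(n), extra_counts)
    seq_within = np.concatenate([np.arange(2, 2 + c) for c in extra_counts if c > 0]) \
        if total_extra else np.array([], dtype=int)
    drug_rows["report_id"].extend(report_ids[extra_rep])
    drug_rows["drug_seq"].extend(seq_within.tolist())
    drug_rows["role"].extend(extra_role.tolist())
    drug_rows["drugname"].extend(
        _name(int(d), name_noise[n + i]) for i, d in enumerate(extra_drug))
    drug_rows["active_ingredient"].extend(
        "CINACALCET HYDROCHLORIDE" if d == config.target_drug else None
        for d in extra_drug)
    drug = pd.DataFrame(drug_rows)

    # --- reactions, therapy, outcomes ---------------------------------------
    reac = pd.DataFrame({
        "report_id": report_ids[pair_df["rep"].to_numpy()],
        "pt": [config.pt_name(j) for j in pair_df["pt_id"]],
    })
    ther_end = np.where(rng.random(n) < 0.5, "",
                        _dates_to_str(start_ord + rng.integers(1, 400, size=n)))
    ther = pd.DataFrame({
        "report_id": report_ids, "drug_seq": [1] * n,
        "start_date": start_str, "end_date": list(ther_end),
    })
    has_outc = rng.random(n) < 0.55
    n_codes = np.where(rng.random(n) < 0.2, 2, 1) * has_outc
    outc_rep = np.repeat(np.arange(n), n_codes)
    outc_codes = rng.choice(["OT", "HO", "DE", "DS", "LT"],
                            size=int(n_codes.sum()), p=[0.43, 0.32, 0.18, 0.04, 0.03])
    outc = pd.DataFrame({"report_id": report_ids[outc_rep], "outcome": outc_codes})

    # --- duplicate case versions --------------------------------------------
    dup_mask = rng.random(n) < config.duplicate_rate
    dup_idx = np.nonzero(dup_mask)[0]
    superseded_ids = [f"R{n + j:08d}" for j in range(len(dup_idx))]
    if len(dup_idx):
        back = rng.integers(30, 400, size=len(dup_idx))
        dup_demo = demo.iloc[dup_idx].copy()
        dup_demo["report_id"] = superseded_ids
        dup_demo["receipt_date"] = _dates_to_str(receipt_ord[dup_idx] - back)
        demo = pd.concat([demo, dup_demo], ignore_index=True)
        id_map = dict(zip(report_ids[dup_idx], superseded_ids))

        def _with_dups(tbl: pd.DataFrame) -> pd.DataFrame:
            dup_tbl = tbl[tbl["report_id"].isin(id_map)].copy()
            dup_tbl["report_id"] = dup_tbl["report_id"].map(id_map)
            return pd.concat([tbl, dup_tbl], ignore_index=True)

        drug, reac, ther, outc = map(_with_dups, (drug, reac, ther, outc))

    bundle = ReportBundle(demo=demo, drug=drug, reac=reac, ther=ther, outc=outc)

    # --- ground truth --------------------------------------------------------
    tallies = (pair_df.assign(ps_drug=ps_drug[pair_df["rep"].to_numpy()])
               .groupby(["ps_drug", "pt_id"]).size()
               .rename("count").reset_index())
    years = pd.Series([int(s[:4]) for s in receipt_str])
    is_target_rep = ps_drug[pair_df["rep"].to_numpy()] == config.target_drug
    truth = GroundTruth(
        config=config,
        pair_counts=tallies,
        planted={(d, p): r for d, p, r in config.planted_signals},
        superseded_report_ids=superseded_ids,
        n_cases=n,
        events_total=len(pair_df),
        target_pair_count=int(is_target_rep.sum()),
        reports_per_year=years[ps_drug == config.target_drug]
        .value_counts().sort_index().to_dict(),
    )
    return bundle, truth


def simulate_to_dir(config: SimConfig, directory: str | Path) -> GroundTruth:
    """Generate a bundle and write it (plus synonym list, PT→SOC map and a
    ground-truth summary) as text files under ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    bundle, truth = generate_bundle(config)
    write_bundle(bundle, directory)
    (directory / "synonyms.txt").write_text(
        "\n".join(sorted(config.synonyms().names)) + "\n")
    map_lines = [f"{config.pt_name(j)}\t{config.soc_name(j % config.n_socs)}"
                 for j in range(config.n_pts)]
    (directory / "pt_soc_map.tsv").write_text("\n".join(map_lines) + "\n")
    summary = {
        "n_cases": truth.n_cases,
        "n_duplicate_versions": truth.n_duplicate_versions,
        "events_total": truth.events_total,
        "target_pair_count": truth.target_pair_count,
        "planted": [[d, p, r] for (d, p), r in truth.planted.items()],
    }
    (directory / "ground_truth.json").write_text(json.dumps(summary, indent=2) + "\n")
    return truth
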