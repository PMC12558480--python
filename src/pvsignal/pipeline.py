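"""End-to-end pipeline: ingest → dedup → event sets → signal tables →
descriptives, with a machine-readable run manifest.

The pipeline is deterministic given its inputs and configuration; outputs
are delimited text files (PT and SOC signal tables, forest-plot-ready
estimates, one descriptive table per category) plus ``manifest.json``
recording the configuration hash, input checksums, stage record counts and
accumulated warnings. Re-running an identical configuration reproduces
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cases import (DrugEventSet, MeddraMap, SynonymList, deduplicate,
                    extract_event_sets)
from .descriptives import (annual_counts, compute_tto, summarize_demographics,
                           summarize_outcomes)
from .io import ParseLog, ReportBundle, read_bundle, validate_bundle
from .stats import SignalCriteria, signal_frame

#: organ classes excluded from PT-level results by default because their
#: events are commonly attributable to progression of the underlying disease
DEFAULT_SOC_EXCLUSIONS = (
    "musculoskeletal and connective tissue disorders",
    "neoplasms benign, malignant and unspecified (incl. cysts and polyps)",
    "renal and urinary disorders",
    "vascular disorders",
    "pregnancy, puerperium and perinatal conditions",
    "nervous system disorders",
)


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run (loadable from YAML)."""

    input_dir: str
    output_dir: str
    synonym_file: Optional[str] = None
    meddra_map_file: Optional[str] = None
    role_filter: Sequence[str] = ("PS",)
    min_a: int = 3
    p_adj_threshold: float = 0.05
    composite_policy: str = "ror_primary"
    soc_exclusions: Sequence[str] = DEFAULT_SOC_EXCLUSIONS
    exclude_socs_at_pt_level: bool = True
    sort_key: str = "count"
    outcome_policy: str = "per_code"
    rounding_decimals: int = 2
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def criteria(self) -> SignalCriteria:
        return SignalCriteria(min_a=self.min_a,
                              p_adj_threshold=self.p_adj_threshold,
                              composite_policy=self.composite_policy)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    version: str
    config_hash: str
    input_checksums: dict
    stage_counts: dict
    warnings: list
    output_files: list

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True) + "\n"


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def apply_soc_exclusions(signal_table: pd.DataFrame,
                         exclusions: Sequence[str] = DEFAULT_SOC_EXCLUSIONS,
                         known_socs: Sequence[str] | None = None,
                         warnings: list | None = None) -> pd.DataFrame:
    """Drop rows whose ``soc`` is in the exclusion list (case-insensitive).

    Exclusion names that match no known SOC produce a warning and are
    ignored. Requires a ``soc`` column (PTs mapped to SOCs).
    """
    if "soc" not in signal_table.columns:
        raise PipelineError("exclusions", "signal table lacks a 'soc' column")
    excl = {e.strip().casefold() for e in exclusions}
    if known_socs is not None and warnings is not None:
        known = {s.strip().casefold() for s in known_socs}
        for name in sorted(excl - known):
            warnings.append(f"exclusion name not a known SOC, ignored: {name}")
    soc_norm = signal_table["soc"].fillna("").str.strip().str.casefold()
    kept = signal_table[~soc_norm.isin(excl)].copy()
    return kept


def rank_and_format(signal_table: pd.DataFrame, sort_key: str = "count",
                    decimals: int = 2) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stable descending sort plus report-ready rounding.

    ``sort_key="count"`` sorts by report count a (ties by ROR, then term);
    ``sort_key="ror"`` sorts by ROR (ties by count, then term). Returns the
    formatted table and a forest-plot-ready frame (term, estimate, lo, hi).
    """
    if sort_key not in {"count", "ror"}:
        raise ValueError(f"unknown sort key {sort_key!r}")
    df = signal_table.reset_index()
    primary, secondary = (("a", "ror") if sort_key == "count" else ("ror", "a"))
    df = df.sort_values([primary, secondary, "term"],
                        ascending=[False, False, True], kind="mergesort")
    out = df.copy()
    ratio_cols = [c for c in ("ror", "ror_lo95", "ror_hi95", "prr", "prr_lo95",
                              "prr_hi95", "chi2", "ic", "ic025", "ebgm", "ebgm05")
                  if c in out.columns]
    out[ratio_cols] = out[ratio_cols].round(decimals)
    forest = df[["term", "ror", "ror_lo95", "ror_hi95"]].rename(
        columns={"ror": "estimate", "ror_lo95": "lo", "ror_hi95": "hi"})
    return out.reset_index(drop=True), forest.reset_index(drop=True)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _write_tsv(df: pd.DataFrame, path: Path, header_note: str | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if header_note:
            fh.write(f"# {header_note}\n")
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the full analysis and write all outputs.

    Stages: read → validate → dedup → extract event sets → PT/SOC signal
    tables (statistics, FDR, flags) → SOC exclusions at PT level →
    descriptives. Any fatal stage error raises :class:`PipelineError` after
    removing partial outputs.
    """
    in_dir, out_dir = Path(config.input_dir), Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    warnings: list[str] = []
    written: list[Path] = []
    try:
        log = ParseLog()
        try:
            bundle = read_bundle(in_dir, log=log)
        except IOError as exc:
            raise PipelineError("read", str(exc))
        checksums = {p.name: _checksum(p) for p in sorted(in_dir.iterdir())
                     if p.is_file()}
        for path, line_no, reason in log.skipped_lines:
            warnings.append(f"skipped {path}:{line_no}: {reason}")
        for code, count in sorted(log.unknown_codes.items()):
            warnings.append(f"unknown code {code} x{count}")

        report = validate_bundle(bundle)
        if report.total_orphans:
            warnings.append(f"orphan report ids: {report.orphans}")

        kept = deduplicate(bundle.demo)
        synonyms = (SynonymList.from_file(config.synonym_file)
                    if config.synonym_file else SynonymList())
        events = extract_event_sets(bundle, synonyms,
                                    role_filter=config.role_filter,
                                    kept_report_ids=kept)
        if not events.target_report_ids:
            warnings.append("no reports matched the target-drug synonyms")

        criteria = config.criteria()
        pt_table = signal_frame(events, "pt", criteria)

        meddra = (MeddraMap.from_file(config.meddra_map_file)
                  if config.meddra_map_file else None)
        soc_table = None
        if meddra is not None:
            events.annotate_soc(meddra)
            if events.unmapped_pts:
                warnings.append(
                    f"{len(events.unmapped_pts)} PTs unmapped to SOC "
                    f"(excluded from SOC level only)")
            soc_table = signal_frame(events, "soc", criteria)
            pt_soc = pt_table.index.to_series().map(lambda t: meddra.get(t))
            pt_table = pt_table.assign(soc=pt_soc.to_numpy())
            if config.exclude_socs_at_pt_level:
                before = len(pt_table)
                known = soc_table.index.tolist()
                pt_table = apply_soc_exclusions(pt_table, config.soc_exclusions,
                                                known_socs=known, warnings=warnings)
                warnings.append(
                    f"SOC exclusions removed {before - len(pt_table)} PT rows")
        else:
            pt_table = pt_table.assign(soc=pd.NA)

        note = (f"criteria: min_a={criteria.min_a}, policy={criteria.composite_policy}, "
                f"p_adj<{criteria.p_adj_threshold}; FDR family = terms with "
                f"a>=min_a at this level")
        pt_fmt, pt_forest = rank_and_format(pt_table, config.sort_key,
                                            config.rounding_decimals)
        _write(out_dir, "pt_signals.tsv", pt_fmt, note, written)
        _write(out_dir, "pt_forest.tsv", pt_forest, None, written)
        if soc_table is not None:
            soc_fmt, soc_forest = rank_and_format(soc_table, config.sort_key,
                                                  config.rounding_decimals)
            _write(out_dir, "soc_signals.tsv", soc_fmt, note, written)
            _write(out_dir, "soc_forest.tsv", soc_forest, None, written)

        demo_tab = summarize_demographics(events)
        outc_tab = summarize_outcomes(events, bundle.outc, config.outcome_policy)
        tto = compute_tto(events, bundle.ther, bundle.drug, synonyms)
        year_tab = annual_counts(events)
        _write(out_dir, "demographics.tsv", demo_tab,
               "denominator: target reports", written)
        _write(out_dir, "outcomes.tsv", outc_tab,
               f"policy: {config.outcome_policy}", written)
        _write(out_dir, "tto.tsv", tto.bin_table(),
               f"median={tto.median:.2f} q1={tto.q1:.2f} q3={tto.q3:.2f} "
               f"n_known={tto.n_known} negative_excluded={tto.n_negative}", written)
        _write(out_dir, "annual_counts.tsv", year_tab,
               "denominator: target reports", written)

        n_pairs = len(events.target_pairs) + len(events.background_pairs)
        manifest = RunManifest(
            version=__version__,
            config_hash=config.config_hash(),
            input_checksums=checksums,
            stage_counts={
                "demo_rows": int(len(bundle.demo)),
                "reports_after_dedup": len(kept),
                "target_reports": len(events.target_report_ids),
                "target_pairs": int(len(events.target_pairs)),
                "background_pairs": int(len(events.background_pairs)),
                "total_pairs": int(n_pairs),
                "pt_terms": int(len(pt_table)),
                "soc_terms": int(len(soc_table)) if soc_table is not None else 0,
            },
            warnings=warnings,
            output_files=sorted(p.name for p in written),
        )
        (out_dir / "manifest.json").write_text(manifest.to_json())
        return manifest
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        (out_dir / "manifest.json").unlink(missing_ok=True)
        raise


def _write(out_dir: Path, name: str, df: pd.DataFrame, note: str | None,
           written: list) -> None:
    path = out_dir / name
    _write_tsv(df, path, note)
    written.append(path)
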