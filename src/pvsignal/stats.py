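"""Disproportionality statistics on fourfold (2x2) report tables.

Each adverse-event term is summarised against a target drug by the table

    =============  ==========  ===============
    reports        with term    with other terms
    =============  ==========  ===============
    target drug        a             b
    all others         c             d
    =============  ==========  ===============

with N = a+b+c+d, counted in unique (deduplicated report, term) pairs.
Four classical signal statistics are computed per term:

* ROR, the reporting odds ratio ad/(bc), with a Wald 95% CI on the log
  scale using SE = sqrt(1/a+1/b+1/c+1/d);
* PRR, the proportional reporting ratio (a/(a+b))/(c/(c+d)), with
  SE = sqrt(1/a − 1/(a+b) + 1/c − 1/(c+d));
* IC, the information component log2(aN/((a+b)(a+c))), i.e. the base-2 log
  of the observed-to-expected co-reporting count, with lower credibility
  bound IC025 = IC − 2·SE/ln2 (SE as for the ROR);
* EBGM, the observed-to-expected relative reporting ratio aN/((a+b)(a+c))
  (the unshrunk form; no gamma-mixture empirical-Bayes prior fitting), with
  EBGM05 = exp(ln EBGM − 1.645·SE), its one-sided 5th percentile.

Association is tested with Pearson's chi-square (df=1, no continuity
correction) and p-values are adjusted across terms with the
Benjamini–Hochberg false-discovery-rate step-up.

IC and EBGM share the same point estimate on different scales
(IC = log2 EBGM); both are reported because their conventional thresholds
(IC025 > 0, EBGM05 > 1) differ in how the uncertainty is folded in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps
from statsmodels.stats.multitest import multipletests

Z95 = 1.96          # two-sided 95% normal quantile
Z05 = 1.645         # one-sided 5th-percentile quantile (EBGM05)
LN2 = math.log(2.0)


@dataclass(frozen=True)
class FourfoldTable:
    """Cells of the 2x2 report table; real-valued cells are allowed so the
    same container serves the reconstruction oracle."""

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if v < 0 or not np.isfinite(v):
                raise ValueError(f"cell {name}={v} must be finite and >= 0")

    @property
    def n(self) -> float:
        return self.a + self.b + self.c + self.d

    def as_tuple(self) -> tuple:
        return (self.a, self.b, self.c, self.d)


@dataclass(frozen=True)
class SignalStats:
    """Per-term disproportionality statistics.

    ``defined`` is False (and the estimate fields NaN) when a zero cell makes
    the statistics undefined; ``reason`` then says which cell. No continuity
    correction is applied unless requested explicitly.
    """

    term: str
    a: float
    b: float
    c: float
    d: float
    ror: float = math.nan
    ror_lo95: float = math.nan
    ror_hi95: float = math.nan
    prr: float = math.nan
    prr_lo95: float = math.nan
    prr_hi95: float = math.nan
    chi2: float = math.nan
    p: float = math.nan
    p_adj: float = math.nan
    ic: float = math.nan
    ic025: float = math.nan
    ebgm: float = math.nan
    ebgm05: float = math.nan
    se_ln: float = math.nan
    se_ln_prr: float = math.nan
    defined: bool = True
    reason: Optional[str] = None


@dataclass(frozen=True)
class SignalCriteria:
    """Signal thresholds and the composite flag policy.

    Defaults follow common pharmacovigilance practice: at least 3 reports,
    ROR/PRR 95% CI lower bound > 1, IC025 > 0, EBGM05 > 1, adjusted p < 0.05.
    All comparisons are strict. ``composite_policy``:

    * ``ror_primary`` (default): ROR rule and the adjusted-p rule;
    * ``all_four``: all four method rules and the adjusted-p rule;
    * ``any``: any method rule and the adjusted-p rule.

    a < min_a forces every flag False regardless of the estimates.
    """

    min_a: int = 3
    p_adj_threshold: float = 0.05
    composite_policy: str = "ror_primary"

    def __post_init__(self) -> None:
        if self.min_a < 1:
            raise ValueError("min_a must be >= 1")
        if self.composite_policy not in {"ror_primary", "all_four", "any"}:
            raise ValueError(f"unknown composite_policy {self.composite_policy!r}")


# ---------------------------------------------------------------------------
# vectorized kernel — the scalar API delegates here so that per-table and
# whole-frame computations are bit-for-bit identical
# ---------------------------------------------------------------------------

_STAT_COLS = [
    "ror", "ror_lo95", "ror_hi95", "prr", "prr_lo95", "prr_hi95",
    "chi2", "p", "ic", "ic025", "ebgm", "ebgm05", "se_ln", "se_ln_prr",
]


def _kernel(a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray) -> dict:
    """All statistics on float64 arrays; zero cells yield NaN rows."""
    a, b, c, d = (np.asarray(x, dtype=np.float64) for x in (a, b, c, d))
    n = a + b + c + d
    ok = (a > 0) & (b > 0) & (c > 0) & (d > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        se_ln = np.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
        se_ln_prr = np.sqrt(1.0 / a - 1.0 / (a + b) + 1.0 / c - 1.0 / (c + d))
        ror = (a * d) / (b * c)
        prr = (a / (a + b)) / (c / (c + d))
        ebgm = a * n / ((a + b) * (a + c))
        ic = np.log2(ebgm)
        ror_lo = np.exp(np.log(ror) - Z95 * se_ln)
        ror_hi = np.exp(np.log(ror) + Z95 * se_ln)
        prr_lo = np.exp(np.log(prr) - Z95 * se_ln_prr)
        prr_hi = np.exp(np.log(prr) + Z95 * se_ln_prr)
        ebgm05 = np.exp(np.log(ebgm) - Z05 * se_ln)
        ic025 = ic - 2.0 * se_ln / LN2
        chi2 = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
    p = _sps.chi2.sf(chi2, 1)
    out = dict(
        ror=ror, ror_lo95=ror_lo, ror_hi95=ror_hi,
        prr=prr, prr_lo95=prr_lo, prr_hi95=prr_hi,
        chi2=chi2, p=p, ic=ic, ic025=ic025,
        ebgm=ebgm, ebgm05=ebgm05, se_ln=se_ln, se_ln_prr=se_ln_prr,
    )
    nan = np.where(ok, 0.0, np.nan)
    for k in out:
        out[k] = out[k] + nan  # NaN-out undefined rows without branching
    out["defined"] = ok
    return out


def compute_signal_stats(
    table: FourfoldTable,
    term: str = "",
    *,
    haldane: bool = False,
) -> SignalStats:
    """Statistics for a single fourfold table.

    Zero cells make the estimates undefined and are reported as such;
    ``haldane=True`` opts in to the Haldane–Anscombe +0.5 correction on all
    four cells instead (never applied silently).
    """
    a, b, c, d = table.as_tuple()
    if haldane and min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    res = _kernel(np.array([a]), np.array([b]), np.array([c]), np.array([d]))
    defined = bool(res["defined"][0])
    reason = None
    if not defined:
        zero = [nm for nm, v in zip("abcd", (a, b, c, d)) if v == 0]
        reason = f"zero cell(s): {', '.join(zero)}"
    return SignalStats(
        term=term, a=table.a, b=table.b, c=table.c, d=table.d,
        defined=defined, reason=reason,
        **{k: float(res[k][0]) for k in _STAT_COLS},
    )


def build_fourfold(events, term: str, level: str = "pt") -> FourfoldTable:
    """Fourfold table for one term from a :class:`~pvsignal.cases.DrugEventSet`.

    ``level`` selects the pair partition: ``"pt"`` uses (report, PT) pairs,
    ``"soc"`` uses (report, SOC) pairs (requires SOC-annotated pairs on the
    event set). A term absent from both partitions yields a=c=0.
    """
    tgt, bkg = events.pairs_at_level(level)
    norm = _norm_term(term)
    a = int((tgt["term_norm"] == norm).sum())
    c = int((bkg["term_norm"] == norm).sum())
    return FourfoldTable(a=a, b=len(tgt) - a, c=c, d=len(bkg) - c)


def _norm_term(term: str) -> str:
    return " ".join(str(term).split()).casefold()


def signal_frame(
    events,
    level: str = "pt",
    criteria: SignalCriteria | None = None,
    *,
    haldane: bool = False,
) -> pd.DataFrame:
    """Per-term statistics for every term at the given level, vectorized.

    Returns a DataFrame indexed by term with the count cells, all statistics,
    BH-adjusted p (family = terms with a >= criteria.min_a), per-method flags
    and the composite flag. Terms with a < min_a get p_adj = NaN and all
    flags False.
    """
    criteria = criteria or SignalCriteria()
    tgt, bkg = events.pairs_at_level(level)
    terms = (
        pd.concat([tgt[["term_norm", "term"]], bkg[["term_norm", "term"]]])
        .drop_duplicates("term_norm")
        .set_index("term_norm")["term"]
        .sort_index()
    )
    a = tgt["term_norm"].value_counts().reindex(terms.index, fill_value=0)
    c = bkg["term_norm"].value_counts().reindex(terms.index, fill_value=0)
    a_arr = a.to_numpy(dtype=np.float64)
    c_arr = c.to_numpy(dtype=np.float64)
    b_arr = float(len(tgt)) - a_arr
    d_arr = float(len(bkg)) - c_arr
    if haldane:
        zero = (a_arr == 0) | (b_arr == 0) | (c_arr == 0) | (d_arr == 0)
        shift = np.where(zero, 0.5, 0.0)
        res = _kernel(a_arr + shift, b_arr + shift, c_arr + shift, d_arr + shift)
    else:
        res = _kernel(a_arr, b_arr, c_arr, d_arr)
    df = pd.DataFrame({"term": terms.to_numpy(), "a": a_arr.astype(np.int64),
                       "b": b_arr.astype(np.int64), "c": c_arr.astype(np.int64),
                       "d": d_arr.astype(np.int64)}, index=terms.index)
    for k in _STAT_COLS:
        df[k] = res[k]
    df["defined"] = res["defined"]

    in_family = (df["a"] >= criteria.min_a) & df["defined"]
    df["p_adj"] = np.nan
    if in_family.any():
        df.loc[in_family, "p_adj"] = adjust_fdr(df.loc[in_family, "p"].tolist())
    _add_flags(df, criteria)
    return df.set_index("term")


def _add_flags(df: pd.DataFrame, criteria: SignalCriteria) -> None:
    eligible = (df["a"] >= criteria.min_a) & df["defined"].astype(bool)
    df["flag_ror"] = eligible & (df["ror_lo95"] > 1.0)
    df["flag_prr"] = eligible & (df["prr_lo95"] > 1.0)
    df["flag_ic"] = eligible & (df["ic025"] > 0.0)
    df["flag_ebgm"] = eligible & (df["ebgm05"] > 1.0)
    p_ok = eligible & (df["p_adj"] < criteria.p_adj_threshold)
    if criteria.composite_policy == "ror_primary":
        method = df["flag_ror"]
    elif criteria.composite_policy == "all_four":
        method = df["flag_ror"] & df["flag_prr"] & df["flag_ic"] & df["flag_ebgm"]
    else:  # any
        method = df["flag_ror"] | df["flag_prr"] | df["flag_ic"] | df["flag_ebgm"]
    df["flag_composite"] = method & p_ok


def flag_signals(stats: SignalStats, criteria: SignalCriteria | None = None) -> dict:
    """Per-method signal flags plus the composite flag for one term."""
    criteria = criteria or SignalCriteria()
    df = pd.DataFrame([{
        "a": stats.a, "defined": stats.defined, "ror_lo95": stats.ror_lo95,
        "prr_lo95": stats.prr_lo95, "ic025": stats.ic025,
        "ebgm05": stats.ebgm05, "p_adj": stats.p_adj,
    }])
    _add_flags(df, criteria)
    row = df.iloc[0]
    return {k: bool(row[k]) for k in
            ("flag_ror", "flag_prr", "flag_ic", "flag_ebgm", "flag_composite")}


def adjust_fdr(p_values: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1].tolist()


def reconstruct_fourfold(a: float, a_plus_b: float, prr: float, ebgm: float) -> FourfoldTable:
    """Invert (a, a+b, PRR, EBGM) back to a real-valued fourfold table.

    Solves r1 = c/(c+d) = (a/(a+b))/PRR and s = (a+c)/N = a/((a+b)·EBGM)
    for c and N: N = (r1(a+b) − a)/(r1 − s), c = r1(N − a − b). This is the
    validation oracle used to cross-check a published results table whose
    background cells are not printed: the held-out statistics (ROR, CIs,
    chi-square, IC bounds) computed on the reconstructed table must agree
    with the printed ones.
    """
    if a < 1 or a_plus_b <= a:
        raise ValueError("need a >= 1 and a+b > a")
    if prr <= 0 or ebgm <= 0:
        raise ValueError("PRR and EBGM must be positive")
    r1 = (a / a_plus_b) / prr
    s = a / (a_plus_b * ebgm)
    if math.isclose(r1, s, rel_tol=1e-12):
        raise ValueError("degenerate reconstruction: c/(c+d) equals (a+c)/N")
    n = (r1 * a_plus_b - a) / (r1 - s)
    c = r1 * (n - a_plus_b)
    b = a_plus_b - a
    d = n - a_plus_b - c
    if c <= 0 or d <= 0 or n <= 0:
        raise ValueError("inconsistent inputs: reconstruction yields non-positive cells")
    return FourfoldTable(a=float(a), b=float(b), c=c, d=d)


# ---------------------------------------------------------------------------
# optional full-Bayes information component
# ---------------------------------------------------------------------------

def bcpnn_ic_bayes(table: FourfoldTable) -> tuple[float, float]:
    """Bayesian BCPNN information component E(IC) and IC025.

    Uses the standard independent-prior closed form (Dirichlet/beta priors
    with all hyperparameters 1 for the margins and a joint prior calibrated
    so that E(IC)=0 under independence): with N the table total,

        E(IC)  = log2[ (a+g11)(N+alpha)(N+beta) / ((N+gamma)(a+b+1)(a+c+1)) ]

    with alpha = beta = 2, g11 = 1 and gamma = g11·(N+alpha)(N+beta) /
    ((a+b+1)(a+c+1)), and the delta-method variance of Bate et al.'s
    formulation. Offered as an optional mode; the package default is the
    simplified IC = log2(EBGM), whose printed values standard analyses use.
    """
    a, b, c, d = table.as_tuple()
    n = a + b + c + d
    alpha = beta = 2.0
    a1 = b1 = g11 = 1.0
    gamma = g11 * (n + alpha) * (n + beta) / ((a + b + a1) * (a + c + b1))
    e_ic = math.log2(
        (a + g11) * (n + alpha) * (n + beta)
        / ((n + gamma) * (a + b + a1) * (a + c + b1))
    )
    v_ic = (1.0 / LN2**2) * (
        (n - a + gamma - g11) / ((a + g11) * (1 + n + gamma))
        + (n - (a + b) + alpha - a1) / ((a + b + a1) * (1 + n + alpha))
        + (n - (a + c) + beta - b1) / ((a + c + b1) * (1 + n + beta))
    )
    return e_ic, e_ic - 2.0 * math.sqrt(v_ic)
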