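import math

import numpy as np
import pandas as pd
import pytest

from pvsignal.cases import extract_event_sets
from pvsignal.simulate import SimConfig, generate_bundle
from pvsignal.stats import (FourfoldTable, SignalCriteria, SignalStats,
                            adjust_fdr, bcpnn_ic_bayes, build_fourfold,
                            compute_signal_stats, flag_signals,
                            reconstruct_fourfold, signal_frame)


def random_tables(n, seed, low=1, high=2000):
    rng = np.random.default_rng(seed)
    cells = rng.integers(low, high, size=(n, 4))
    return [FourfoldTable(*map(float, row)) for row in cells]


class TestComputeSignalStats:
    def test_hand_worked_table(self):
        """a=3, b=7, c=30, d=960 worked by hand from the defining formulas."""
        s = compute_signal_stats(FourfoldTable(3, 7, 30, 960))
        assert s.ror == pytest.approx(2880 / 210, rel=1e-12)
        assert s.prr == pytest.approx(0.3 / (30 / 990), rel=1e-12)
        assert s.ebgm == pytest.approx(3 * 1000 / (33 * 10), rel=1e-12)
        assert s.ic == pytest.approx(math.log2(3 * 1000 / (33 * 10)), rel=1e-12)
        assert s.chi2 == pytest.approx(22.57, abs=0.01)

    def test_symmetric_table_is_null(self):
        s = compute_signal_stats(FourfoldTable(5, 5, 5, 5))
        assert s.ror == s.prr == s.ebgm == 1.0
        assert s.ic == 0.0 and s.chi2 == 0.0 and s.p == pytest.approx(1.0)

    def test_ci_ordering_and_se_definitions(self):
        s = compute_signal_stats(FourfoldTable(12, 40, 99, 1400))
        assert s.ror_lo95 < s.ror < s.ror_hi95
        assert s.prr_lo95 < s.prr < s.prr_hi95
        assert s.ebgm05 < s.ebgm and s.ic025 < s.ic
        assert s.se_ln == pytest.approx(math.sqrt(1/12 + 1/40 + 1/99 + 1/1400))
        assert s.se_ln_prr == pytest.approx(
            math.sqrt(1/12 - 1/52 + 1/99 - 1/1499))

    def test_zero_cell_undefined_unless_haldane(self):
        s = compute_signal_stats(FourfoldTable(0, 10, 5, 100))
        assert not s.defined and "a" in s.reason
        assert math.isnan(s.ror)
        h = compute_signal_stats(FourfoldTable(0, 10, 5, 100), haldane=True)
        assert h.defined and h.ror > 0

    def test_monotone_in_a_at_fixed_margins(self):
        """More target cases for the term, same margins, stronger signal."""
        def table(a):
            a_b, a_c, n = 100, 80, 10000
            return FourfoldTable(a, a_b - a, a_c - a, n - a_b - a_c + a)
        lo, hi = compute_signal_stats(table(20)), compute_signal_stats(table(40))
        for attr in ("ror", "prr", "ic", "ebgm", "chi2"):
            assert getattr(hi, attr) > getattr(lo, attr)

    def test_identities_on_random_tables(self):
        """ic == log2(ebgm) exactly; ror == prr*((a+b)/b)*(d/(c+d))."""
        for t in random_tables(1000, seed=5):
            s = compute_signal_stats(t)
            assert s.ic == np.log2(s.ebgm)
            a, b, c, d = t.as_tuple()
            assert s.ror == pytest.approx(s.prr * ((a + b) / b) * (d / (c + d)),
                                          rel=1e-12)

    def test_vectorized_equals_scalar_bitwise(self):
        cfg = SimConfig(n_reports=800, seed=3, planted_signals=((0, 1, 6.0),))
        bundle, _ = generate_bundle(cfg)
        events = extract_event_sets(bundle)
        frame = signal_frame(events)
        for term, row in frame[frame["defined"]].head(40).iterrows():
            s = compute_signal_stats(FourfoldTable(row["a"], row["b"],
                                                   row["c"], row["d"]))
            for col in ("ror", "prr", "chi2", "ic", "ic025", "ebgm", "ebgm05",
                        "se_ln", "se_ln_prr", "p"):
                assert getattr(s, col) == row[col], (term, col)


class TestBuildFourfold:
    def test_toy_counting(self, toy_bundle):
        events = extract_event_sets(toy_bundle)
        t = build_fourfold(events, "nausea")
        # target pairs: r2 x {nausea, vomiting}; background: r3 x {hypocalcaemia,
        # nausea}, r4 x {tetany}
        assert t.as_tuple() == (1, 1, 1, 2)

    def test_absent_term_gives_zero_a_and_c(self, toy_bundle):
        events = extract_event_sets(toy_bundle)
        t = build_fourfold(events, "no such term")
        assert t.a == 0 and t.c == 0

    def test_a_sums_to_target_pairs(self, toy_bundle):
        events = extract_event_sets(toy_bundle)
        frame = signal_frame(events)
        assert frame["a"].sum() == len(events.target_pairs)
        assert (frame[["a", "b"]].sum(axis=1) == len(events.target_pairs)).all()


class TestAdjustFdr:
    def test_hand_worked_step_up(self):
        got = adjust_fdr([0.001, 0.012, 0.03, 0.04, 0.2])
        assert got == pytest.approx([0.005, 0.03, 0.05, 0.05, 0.2])

    def test_single_p_unchanged(self):
        assert adjust_fdr([0.42]) == pytest.approx([0.42])

    def test_all_equal_stay_equal(self):
        assert adjust_fdr([0.03] * 6) == pytest.approx([0.03] * 6)

    def test_bounds_order_and_validation(self):
        rng = np.random.default_rng(0)
        p = rng.random(200)
        q = np.array(adjust_fdr(p))
        assert (q >= p - 1e-15).all() and (q <= 1.0).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()
        with pytest.raises(ValueError):
            adjust_fdr([0.5, 1.5])


class TestFlags:
    def _stats(self, **kw):
        base = dict(term="x", a=10, b=5, c=5, d=100, ror_lo95=2.0, prr_lo95=2.0,
                    ic025=1.0, ebgm05=2.0, p_adj=0.001)
        base.update(kw)
        return SignalStats(**base)

    def test_min_a_forces_all_false(self):
        flags = flag_signals(self._stats(a=2, ror_lo95=50.0))
        assert not any(flags.values())

    def test_boundary_strict_inequalities(self):
        flags = flag_signals(self._stats(a=3, ror_lo95=1.01, p_adj=0.04))
        assert flags["flag_composite"]
        assert not flag_signals(self._stats(ic025=0.0))["flag_ic"]
        assert not flag_signals(self._stats(ebgm05=1.0))["flag_ebgm"]
        assert not flag_signals(self._stats(p_adj=0.05))["flag_composite"]

    def test_composite_policies(self):
        s = self._stats(ic025=-0.5)   # IC fails, ROR passes
        assert flag_signals(s, SignalCriteria(composite_policy="ror_primary"))["flag_composite"]
        assert not flag_signals(s, SignalCriteria(composite_policy="all_four"))["flag_composite"]
        assert flag_signals(s, SignalCriteria(composite_policy="any"))["flag_composite"]

    def test_criteria_validation(self):
        with pytest.raises(ValueError):
            SignalCriteria(min_a=0)
        with pytest.raises(ValueError):
            SignalCriteria(composite_policy="bogus")


class TestReconstruction:
    def test_round_trip_exact_on_integer_tables(self):
        for t in random_tables(200, seed=9, low=2, high=5000):
            s = compute_signal_stats(t)
            r = reconstruct_fourfold(t.a, t.a + t.b, s.prr, s.ebgm)
            assert r.c == pytest.approx(t.c, rel=1e-10)
            assert r.n == pytest.approx(t.n, rel=1e-10)

    def test_round_trip_reproduces_inputs(self):
        r = reconstruct_fourfold(610, 47755, 40.79, 39.4)
        s = compute_signal_stats(r)
        assert s.prr == pytest.approx(40.79, rel=1e-4)
        assert s.ebgm == pytest.approx(39.4, rel=1e-4)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            reconstruct_fourfold(0, 100, 2.0, 2.0)
        with pytest.raises(ValueError):
            reconstruct_fourfold(10, 5, 2.0, 2.0)
        with pytest.raises(ValueError):
            reconstruct_fourfold(10, 100, -1.0, 2.0)
        # PRR == EBGM makes the two constraints collinear -> degenerate
        with pytest.raises(ValueError):
            reconstruct_fourfold(10, 100, 5.0, 5.0)


class TestBayesianIc:
    def test_shrinks_toward_zero_and_bounds_below(self):
        t = FourfoldTable(8, 92, 1000, 99000)
        s = compute_signal_stats(t)
        e_ic, ic025 = bcpnn_ic_bayes(t)
        assert ic025 < e_ic
        assert 0 < e_ic < s.ic   # shrunk toward zero, same direction

    def test_null_table_centred_near_zero(self):
        e_ic, _ = bcpnn_ic_bayes(FourfoldTable(50, 450, 500, 4500))
        assert e_ic == pytest.approx(0.0, abs=0.05)
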