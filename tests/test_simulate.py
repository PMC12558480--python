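import numpy as np
import pytest

from pvsignal.cases import deduplicate, extract_event_sets
from pvsignal.io import write_bundle
from pvsignal.simulate import (ConfigurationError, SimConfig, expected_fourfold,
                               generate_bundle)
from pvsignal.stats import compute_signal_stats


def uniform_config(**kw):
    n_pts = kw.pop("n_pts", 50)
    n_drugs = kw.pop("n_drugs", 4)
    base = dict(
        n_reports=kw.pop("n_reports", 800),
        n_drugs=n_drugs, n_pts=n_pts,
        baseline_pt_weights=np.full(n_pts, 1.0 / n_pts),
        baseline_drug_weights=np.full(n_drugs, 1.0 / n_drugs),
    )
    base.update(kw)
    return SimConfig(**base)


class TestConfigValidation:
    def test_bad_probability_vector(self):
        with pytest.raises(ConfigurationError):
            SimConfig(n_pts=3, baseline_pt_weights=[0.5, 0.2, 0.2])

    def test_planted_pt_out_of_range(self):
        with pytest.raises(ConfigurationError):
            SimConfig(n_pts=5, planted_signals=((0, 7, 2.0),))

    def test_negative_relative_risk(self):
        with pytest.raises(ConfigurationError):
            SimConfig(planted_signals=((0, 1, -2.0),))

    def test_rates_bounded(self):
        with pytest.raises(ConfigurationError):
            SimConfig(duplicate_rate=1.0)
        with pytest.raises(ConfigurationError):
            SimConfig(missing_date_rate=1.5)


class TestDeterminism:
    def test_same_seed_byte_identical(self, tmp_path):
        cfg = uniform_config(seed=21, planted_signals=((0, 1, 5.0),))
        for sub in ("x", "y"):
            bundle, _ = generate_bundle(cfg)
            write_bundle(bundle, tmp_path / sub)
        for name in ("demo.txt", "drug.txt", "reac.txt", "ther.txt", "outc.txt"):
            assert (tmp_path / "x" / name).read_bytes() == \
                   (tmp_path / "y" / name).read_bytes()

    def test_different_seeds_differ(self):
        b1, _ = generate_bundle(uniform_config(seed=1))
        b2, _ = generate_bundle(uniform_config(seed=2))
        assert not b1.reac.equals(b2.reac)


class TestBookkeeping:
    def test_duplicate_versions_exactly_recoverable(self):
        cfg = uniform_config(n_reports=1000, duplicate_rate=0.1, seed=4)
        bundle, truth = generate_bundle(cfg)
        assert len(bundle.demo) == truth.n_cases + truth.n_duplicate_versions
        kept = deduplicate(bundle.demo)
        assert len(kept) == truth.n_cases
        assert kept.isdisjoint(truth.superseded_report_ids)

    def test_reac_conservation(self):
        cfg = uniform_config(seed=6, duplicate_rate=0.0)
        bundle, truth = generate_bundle(cfg)
        # REAC rows = unique (report, PT) pairs = sum of per-report event counts
        assert len(bundle.reac) == truth.events_total
        assert truth.events_total == int(truth.pair_counts["count"].sum())

    def test_one_ps_drug_per_report(self):
        bundle, _ = generate_bundle(uniform_config(seed=8))
        ps = bundle.drug[bundle.drug["role"] == "PS"]
        counts = ps.groupby("report_id").size()
        assert (counts == 1).all()
        assert set(counts.index) == set(bundle.demo["report_id"])

    def test_pipeline_counts_match_ground_truth(self):
        cfg = uniform_config(n_reports=1200, seed=10,
                             planted_signals=((0, 3, 6.0),))
        bundle, truth = generate_bundle(cfg)
        events = extract_event_sets(bundle)
        assert len(events.target_pairs) == truth.target_pair_count
        t = truth.realized_fourfold(3)
        from pvsignal.stats import build_fourfold
        got = build_fourfold(events, cfg.pt_name(3))
        assert got.as_tuple() == t.as_tuple()


class TestExpectedFourfold:
    def test_uniform_no_signal_expected_ror_is_one(self):
        cfg = uniform_config()
        t = expected_fourfold(cfg, 0, 5)
        assert t.a * t.d / (t.b * t.c) == pytest.approx(1.0, rel=1e-9)

    def test_planted_rr_orders_ror_above_prr_above_one(self):
        cfg = uniform_config(planted_signals=((0, 5, 5.0),))
        t = expected_fourfold(cfg, 0, 5)
        ror = t.a * t.d / (t.b * t.c)
        prr = (t.a / (t.a + t.b)) / (t.c / (t.c + t.d))
        assert ror > prr > 1.0

    def test_cells_conserve_expected_pair_total(self):
        cfg = uniform_config(planted_signals=((0, 5, 5.0),))
        totals = [expected_fourfold(cfg, 0, pt) for pt in range(cfg.n_pts)]
        # every table shares the same N = expected total pair count
        ns = {round(t.n, 6) for t in totals}
        assert len(ns) == 1
        # and the a-cells partition the expected target pairs (= a+b margin)
        a_sum = sum(t.a for t in totals)
        assert a_sum == pytest.approx(totals[0].a + totals[0].b, rel=1e-9)

    def test_ids_out_of_range(self):
        with pytest.raises(ConfigurationError):
            expected_fourfold(uniform_config(), 99, 0)

    def test_expectation_close_to_realized_at_scale(self):
        cfg = uniform_config(n_reports=4000, seed=13, duplicate_rate=0.0,
                             planted_signals=((0, 2, 8.0),))
        _, truth = generate_bundle(cfg)
        exp = expected_fourfold(cfg, 0, 2)
        got = truth.realized_fourfold(2)
        assert got.a == pytest.approx(exp.a, rel=0.25)
        assert got.n == pytest.approx(exp.n, rel=0.05)


def test_null_generator_ror_centred_on_one():
    """With planted RR = 1 the downstream ROR estimates centre on 1
    (Monte-Carlo check of the null generative model)."""
    rors = []
    for seed in range(50):
        cfg = uniform_config(n_reports=2500, n_pts=50, seed=seed,
                             duplicate_rate=0.0,
                             planted_signals=((0, 7, 1.0),))
        bundle, truth = generate_bundle(cfg)
        t = truth.realized_fourfold(7)
        s = compute_signal_stats(t)
        if s.defined:
            rors.append(s.ror)
    assert 0.9 <= float(np.median(rors)) <= 1.1
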