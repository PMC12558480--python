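"""Descriptive profile of target-drug reports on a synthetic extract.

Sex/age/reporter/country distributions, the outcome distribution under the
per-code counting policy, time-to-onset with median/IQR, and annual report
counts — the descriptive layer that accompanies a signal analysis.
"""

from pvsignal import (SimConfig, annual_counts, compute_tto, extract_event_sets,
                      generate_bundle, summarize_demographics,
                      summarize_outcomes)

bundle, truth = generate_bundle(SimConfig(n_reports=3000, seed=7))
events = extract_event_sets(bundle)
print(f"target reports: {events.report_meta['is_target'].sum()} "
      f"of {len(events.report_meta)}")

demo = summarize_demographics(events)
print("\nsex and age distribution (percent of target reports):")
print(demo[demo["category"].isin(["sex", "age_years"])]
      [["category", "level", "count", "percent"]].to_string(index=False))

outc = summarize_outcomes(events, bundle.outc)
print("\noutcomes (percent of counted outcome codes):")
print(outc[["level", "count", "percent"]].to_string(index=False))

tto = compute_tto(events, bundle.ther, bundle.drug)
print(f"\ntime to onset: median {tto.median:.0f} days "
      f"(IQR {tto.q1:.0f}-{tto.q3:.0f}), known for {tto.n_known} reports")
print(tto.bin_table()[["level", "count", "percent"]].to_string(index=False))
print("\nabout half the reports have unknown onset because event or therapy")
print("start dates are missing or below day precision - as in real")
print("spontaneous-report data.")

years = annual_counts(events)
print(f"\nreports span {years['level'].iloc[0]}-{years['level'].iloc[-1]} "
      f"({len(years)} calendar years)")
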