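"""Recovery of a planted relative risk by the ROR estimator.

The generator renormalizes PT weights within each report's primary-suspect
drug, which makes the planted relative risk the exact estimand of the
reporting odds ratio. This script plants RR = 5 on one PT, replicates the
study 20 times, and reports how often the estimator's own 95% CI covers
the planted value.
"""

import numpy as np

from pvsignal import (SimConfig, build_fourfold, compute_signal_stats,
                      expected_fourfold, extract_event_sets, generate_bundle)

RR, PT = 5.0, 10
n_pts = 200

def config(seed: int) -> SimConfig:
    return SimConfig(
        n_reports=6000, n_drugs=5, n_pts=n_pts,
        baseline_pt_weights=np.full(n_pts, 1.0 / n_pts),
        baseline_drug_weights=[0.5, 0.125, 0.125, 0.125, 0.125],
        duplicate_rate=0.0, planted_signals=((0, PT, RR),), seed=seed)

exp = expected_fourfold(config(0), 0, PT)
print(f"planted RR = {RR} on PT_{PT:04d}; expected a = {exp.a:.1f}, "
      f"expected ROR = {exp.a * exp.d / (exp.b * exp.c):.2f}")

rors, covered = [], 0
for seed in range(20):
    bundle, _ = generate_bundle(config(seed))
    events = extract_event_sets(bundle)
    s = compute_signal_stats(build_fourfold(events, f"PT_{PT:04d}"))
    rors.append(s.ror)
    covered += s.ror_lo95 <= RR <= s.ror_hi95

print(f"median ROR over 20 replicates: {np.median(rors):.2f}")
print(f"95% CI covered the planted RR in {covered}/20 replicates")
print("(coverage near 95% indicates the estimator and its standard error")
print(" are both calibrated under the generative model)")
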