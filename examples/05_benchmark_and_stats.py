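"""A small end-to-end benchmark with the Friedman strategy comparison.

Nine synthetic targets (3 per difficulty), five strategies; ML-Select is
retrained over repeated seeded runs with leave-one-out training pools and
averaged. The Friedman test ranks the strategies per target (rank 1 = best
purity) and the step-down post-hoc compares each against the best-ranked.
"""

import numpy as np

from basinselect import generate_benchmark, run_benchmark

targets = generate_benchmark(3, 3, 3, base_seed=5)
report = run_benchmark(targets, runs=5, base_seed=5)

print("mean B1 purity per strategy:")
for s in report.strategies:
    vals = [report.metrics[t][s]["B1"]["p"] for t in report.target_ids]
    print(f"  {s:6s} {np.mean(vals):.3f}")

stats = report.stats["B1"]
print(f"\nFriedman chi2 = {stats['friedman_statistic']:.2f}, "
      f"p = {stats['friedman_p']:.2e}")
print(f"best (control) method: {stats['control']}")
print("method            avg rank   p (vs control)  critical  significant")
for c in stats["comparisons"]:
    print(f"{c['method']:14s} {stats['average_rank'][c['method']]:9.2f} "
          f"{c['p']:15.2e} {c['critical']:9.4f}  {c['significant']}")
# A significant Friedman p plus per-method p below the step-down critical
# level means the control's purity advantage is unlikely to be rank noise.
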