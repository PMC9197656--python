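"""End-to-end run on a paper-scale synthetic dataset.

Generates 89 studies x 284 indicators with a long-tailed coverage
distribution (most indicators reported by fewer than 10% of studies, one
severity index by ~75%), screens them into threshold profiles, pools every
retained indicator within every profile, and prints the significance
summary: in how many profiles each indicator significantly decreased or
increased.
"""

import sys

from metaprofile import (
    bin_coverage,
    compute_icr,
    gen_paper_like,
    heatmap_matrix,
    run_all,
    summarize_significance,
)

seed = int(sys.argv[1]) if len(sys.argv) > 1 else 1
ds, truth = gen_paper_like(seed=seed)
print(f"dataset: {ds.T_s} studies, {len(ds.indicators)} indicators")

hist = bin_coverage(compute_icr(ds))
print("coverage deciles:", hist.counts)

rs = run_all(ds)
print(f"profiles analyzed: {len(rs.profiles)} "
      f"({', '.join(p.name for p in rs.profiles)})")

summ = summarize_significance(rs)
head = summ.head(10)
print("\nper-indicator significance across profiles (top coverage first):")
print(head.to_string(index=False))
print("\nA large decrease count for the severity index (true SMD -0.9) and "
      "an increase count for the REM share (true SMD +0.45) recover the "
      "generator's ground truth; null indicators stay near zero counts.")

mat = heatmap_matrix(rs)
print(f"\nheatmap matrix: {mat.shape[0]} indicators x {mat.shape[1]} profiles "
      "(pooled SMD where significant, 0 where tested nonsignificant, "
      "NaN where absent/unestimable)")
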