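"""Recompute the arithmetic around the published summary tables.

Every check is deterministic fixture arithmetic: grand depth means
(averaging the three ecosystem means per depth row), within-ecosystem
depth-ratio percentages, depth-weighted 0-75 cm profile means using the
midpoint-partition weights, 0-30 cm carbon sums, and the
sqrt-sum-of-squares total SEs.  Each row shows the recomputed value,
the printed value and the rounding rule used for the comparison.
"""

from rootflux import reproduce_published_values

report = reproduce_published_values()
print(report)
print(f"\nall checks pass: {report.all_pass}")
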