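"""Assign sensory ending types to clusters by exhaustive search.

Anatomical fold changes (AF) describe how each ending type distributes
over stomach regions; barcode-derived fold changes (SF) describe how each
candidate cluster group's dual-labelled cells distribute.  All 4^7 = 16,384
assignments of 7 free clusters to 4 ending types are scored by the total
squared SF-AF discrepancy; the minimum-variance trial wins.
"""

import time

from vagalseq import (
    anatomical_fold_change,
    best_assignment,
    generate_ending_tables,
    innervation_intensity,
)
from vagalseq.synthetic import DEFAULT_FIXED_MAP

truth = {"J2": "cIMA", "J4": "cIMA", "I7": "cIMA",
         "I2": "IGLE", "I4": "IGLE", "I5": "IGLE", "I6": "IGLE"}

endings_df, labels, _ = generate_ending_tables(truth, seed=1, noise_sd=0.05)
af = anatomical_fold_change(innervation_intensity(endings_df))

t0 = time.perf_counter()
best, variance = best_assignment(af, labels, sorted(truth), DEFAULT_FIXED_MAP)
dt = time.perf_counter() - t0

print(f"searched 4^7 = 16,384 assignments in {dt:.2f} s")
print(f"best-fit variance: {variance:.4g}")
print("recovered assignment of free clusters:")
for cluster in sorted(truth):
    mark = "ok" if best[cluster] == truth[cluster] else "MISS"
    print(f"  {cluster} -> {best[cluster]:5s} (truth {truth[cluster]:5s}) {mark}")
# At small noise the generator's hidden assignment is recovered exactly;
# the variance quantifies the residual anatomical/barcode mismatch.
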