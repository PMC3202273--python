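"""Normalize expression dialects, collapse redundant probes, call significance.

Whatever the input form (treatment/control values, ratios, log2- or
log10-ratios), differential expression is re-calculated to log2-ratios.
Redundant probes for a member are averaged by arithmetic mean on the log2
scale, and a strict fold-change threshold (default ratio > 4/3 or < 3/4)
gives the three-state call displayed as red/black/green.
"""

import math

from famexmatrix import call_significance, classify_codirection, collapse_redundant, to_log2
from famexmatrix.expression import CoDirectionSpec

# one underlying two-fold induction in all four dialects
print("values (8, 4)      ->", to_log2((8.0, 4.0), "values_pair"))
print("ratio 2.0          ->", to_log2(2.0, "ratio"))
print("log2-ratio 1.0     ->", to_log2(1.0, "log2_ratio"))
print("log10-ratio log10 2 ->", to_log2(math.log10(2.0), "log10_ratio"))

# two redundant probes at ratios 2 and 8: mean on the log2 scale is 2.0
# (i.e. a 4-fold summary), not log2 of the mean ratio (log2 5 = 2.32)
avg = collapse_redundant([1.0, 3.0])
print("collapsed probes [1.0, 3.0] ->", avg, "->", call_significance(avg))

# boundary behaviour is strict: a ratio of exactly 4/3 is not significant
print("ratio exactly 4/3 ->", call_significance(math.log2(4.0 / 3.0)))
print("ratio 0.5         ->", call_significance(math.log2(0.5)))

# co-direction across the two objects drives the pre-selection of pairs
spec = CoDirectionSpec("co_both")
print("(up, up) under co_both  ->", classify_codirection("up", "up", spec))
print("(up, down) under co_both ->", classify_codirection("up", "down", spec))
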