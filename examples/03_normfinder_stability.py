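"""NormFinder-style stability of candidate controls in a case/control cohort.

Decomposes candidate log2 expression into inter-group bias and
intra-group variance, reports per-gene stability values (lower = more
stable), the best single control, and the best two-control combination.
"""

from ecselect.normfinder import best_pair, normfinder_stability, pair_table
from ecselect.simulate import default_validation_spec, generate_cohort

cohort = generate_cohort(default_validation_spec(), seed=11)
res = normfinder_stability(cohort.matrix, cohort.sheet, ["miR-16", "miR-425", "U6"])

print("stability values (|shrunken group bias| + SE, log2 units):")
print(res.stability.sort_values().round(3))
print("\ninter-group differences d (log2; cancer column; sums to 0 across groups):")
print(res.d.round(3))
print("\nintra-group variance estimates (finite-gene corrected):")
print(res.sigma2.round(3))

pair, value = best_pair(res)
print(f"\nbest single control: {res.best_single}")
print(f"best pair: {pair} with combined stability {value:.3f}")
print("(a pair can beat both members when their group biases cancel)")
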