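"""Rank candidate controls with geNorm on a simulated validation cohort.

Converts Cq to relative quantities, runs stepwise exclusion on the
gene-stability measure M, and reads the V(n/n+1) series to decide how
many controls to combine.
"""

from ecselect.genorm import optimal_ec_count, stepwise_ranking, to_relative_quantity
from ecselect.simulate import default_validation_spec, generate_cohort

cohort = generate_cohort(default_validation_spec(), seed=11)
q = to_relative_quantity(cohort.matrix, candidates=["miR-16", "miR-425", "U6"])

ranking = stepwise_ranking(q)
print("M by elimination round (lower = more stable):")
print(ranking.m_by_round.round(3))
print(f"\nfinal pair: {ranking.final_pair} with shared M = {ranking.final_m:.3f}")

series = optimal_ec_count(q, ranking, v_cutoff=0.15)
print(f"\nV(n/n+1) series:\n{series.v.round(3)}")
print(
    f"recommended number of controls: {series.recommended_n} ({series.rule}; "
    "when no V drops below 0.15 the minimizing n is used)"
)
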