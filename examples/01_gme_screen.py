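"""Screen a simulated 384-well miRNA profiling panel for candidate controls.

Generates the 10 cancer / 10 control array screen, ranks every assay by
the SD of its deviation from the per-sample global mean expression, and
nominates candidates after a literature-style exclusion.
"""

from ecselect.gme import nominate_candidates, rank_by_gme
from ecselect.cq import collapse_assay_wells
from ecselect.simulate import (
    NEGATIVE_CONTROL,
    SNORNA_ASSAYS,
    U6_WELLS,
    generate_array_screen,
)

cohort = generate_array_screen(seed=7)
matrix = collapse_assay_wells(cohort.matrix, {w: "U6" for w in U6_WELLS})
controls = ["U6", *SNORNA_ASSAYS, NEGATIVE_CONTROL]

ranking = rank_by_gme(matrix, expressed_cutoff=35.0, control_assays=controls)
top10 = ranking.top(10)
print("top 10 by GME deviation SD (cycles; smaller = closer to the global mean):")
print(ranking.table.loc[top10, ["score", "rank"]].round(3))

# assays with a known disease association are disqualified as controls
nominees = nominate_candidates(ranking, k=10, exclusion_list=top10[:9])
print(f"\nnominee after excluding 9 disease-associated assays: {nominees[0]}")
print("(a near-global-mean assay with no exclusion is the candidate to validate)")
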