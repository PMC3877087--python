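"""Standard-curve efficiency and EC-dependent relative quantification.

Estimates amplification efficiency from a dilution series, then shows
how the choice of normalizer changes the apparent differential
expression of target miRNAs (the reason control validation matters).
"""

from ecselect.quantify import ec_sensitivity_experiment, estimate_efficiency
from ecselect.simulate import (
    default_validation_spec,
    generate_cohort,
    generate_dilution_series,
)

# amplification efficiency from a noiseless 10-fold, 5-point series
series = generate_dilution_series(true_efficiency=95.0, anchor_cq=20.0, noise_sd=0.05, seed=3)
model = estimate_efficiency(series, assay_id="miR-93")
print(
    f"standard curve: slope {model.slope:.3f} cycles/log10, "
    f"E = {model.efficiency:.1f}% (accepted 90-110%: {model.accepted})"
)

cohort = generate_cohort(default_validation_spec(), seed=11)
strategies = {
    "U6": ["U6"],
    "miR-16": ["miR-16"],
    "miR-425": ["miR-425"],
    "miR-16+miR-425": ["miR-16", "miR-425"],
}
pvals, rq, _ = ec_sensitivity_experiment(
    cohort.matrix, cohort.sheet,
    targets=["miR-93", "miR-181a", "miR-652"],
    strategies=strategies,
    control_group="control",
)
print("\np-values for cancer-vs-control differential expression of each target")
print("under each normalization strategy (log10 RQ, gated t / Mann-Whitney):")
print(pvals.round(4))
print(
    "\nreading: miR-93 is a true null in the generator - significance under "
    "the biased U6-like control alone is a normalization artifact; miR-652 "
    "(a designed 4-fold shift) stays significant under every strategy."
)
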