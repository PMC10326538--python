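"""Desk-scale glimpse of the study's main effect: recombination biases theta3-hat.

Runs two tiny scenario cells (no recombination vs rho = 1) with 100 loci and
a few replicates, then compares the ancestral-size estimates.  The full-scale
study uses 1,000 loci and many more replicates; even this small run usually
shows the inflation of theta3-hat under recombination.
"""

from imcoal import IMParams, ScenarioConfig, run_experiment, summarize

truth = IMParams(theta1=10, theta2=10, theta3=10, m1=0.0, m2=0.0, tau=2.5)

for rho in (0.0, 1.0):
    config = ScenarioConfig(
        truth=truth, rho=rho, loci_counts=(100,), replicates=3, seed=30 + int(rho)
    )
    results = run_experiment(config)
    stats = summarize(results, truth)
    row = stats[stats.parameter == "theta3"].iloc[0]
    print(
        f"rho = {rho:3.1f}: mean theta3-hat {row['mean']:6.3f}  "
        f"bias {row['bias']:+.3f}  SE {row['se']:.3f}"
    )
print()
print("theta3-hat is inflated when a randomly chosen block tree is treated")
print("as the locus' single genealogy under recombination; at 1,000 loci the")
print("bias stabilizes near the values the full study reports.")
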