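"""Monte-Carlo comparison of assembly methods by classification accuracy.

Runs a small paired experiment (DINA, 3 attributes, 100-item banks,
10-item tests, 10 replications of 1000 examinees per group): each
replication draws a fresh bank and two examinee groups, assembles a test
with each method, simulates responses, MAP-classifies with the first
group's empirical prior, and scores attribute (ACR) and pattern (PCR)
recovery against the generating truth.
"""

from cdta import ExperimentConfig, outperform_proportions, run_experiment, summarize

config = ExperimentConfig(
    model="DINA", K=3, M=100, N=1000, J=10, rho=0.0,
    methods=("mmd", "cdi", "random"), replications=10, seed=42,
    milp_time_limit=2.0,
)
table = run_experiment(config)

print("mean accuracy over 10 paired replications:")
print(summarize(table).to_string(index=False, float_format="%.4f"))

props = outperform_proportions(table, "pcr")
wins = props[(props.better == "mmd") & (props.worse == "cdi")]
print(f"\nmaximin beats cdi-greedy on PCR in "
      f"{wins.proportion.iloc[0]:.0%} of replications")
print("ACR counts correct attribute calls; PCR requires the whole "
      "3-attribute pattern to be exactly recovered, so PCR <= ACR.")
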