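"""Generate synthetic cohorts and check that cut-off derivation recovers
the generating activity zones.

The generator draws phenotypes, genotypes from severe/attenuated allele
pools, log-normal per-phenotype activities, Bernoulli clinical findings
and per-field missingness. Here the activity distributions leave a clean
gap between Hurler and non-Hurler mass, so the derived boundaries should
land inside it in every replicate.
"""

from mpsi_predict import SimulationConfig, recovery_experiment, simulate

config = SimulationConfig(
    n_patients=120,
    seed=42,
    missingness={},
    activity_distributions={"H": (-1.8, 0.15), "HS": (-0.05, 0.08), "S": (0.6, 0.15)},
)

cohort = simulate(config)
print(f"simulated {len(cohort)} patients "
      f"({sum(r.phenotype == 'H' for r in cohort)} Hurler), seed {config.seed}")

result = recovery_experiment(config, n_reps=10)
print("\nper-replicate derived cut-offs and full-algorithm performance:")
print(result.replicates[["seed", "lower", "upper", "sensitivity", "specificity"]]
      .to_string(index=False))
print("\nmean/sd summary:")
print(result.summary.to_string())
print("\nWith fully separated classes the gray zone collapses: both boundaries sit")
print("at the top of the Hurler activity mass, below every non-Hurler value, and")
print("the algorithm scored with its own derived cut-offs is perfect.")
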