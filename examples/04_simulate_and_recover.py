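"""Generate synthetic study data and check parameter recovery.

Draws participant-level data from the population implied by the study's
estimates (latent variances .0120/.0121, standardized criterion paths
.45/.48), refits the structural model across replications, and reports
bias, coverage, and how often the true inverted-u course wins the model
comparison.  Uses a reduced number of replications to stay quick.
"""

from fixedlinks import PopulationModel, generate, parameter_recovery_study

pop = PopulationModel()
print("population residual SDs:", [round(float(s), 3) for s in pop.wmc_residual_sds])

data = generate(pop, n=200, seed=1)
print("\nfirst generated participants:")
print(data.head(3).round(3).to_string())

summary = parameter_recovery_study(pop, n=200, replications=60, seed=1)
print(f"\nconverged {summary.converged}/{summary.replications} replications")
for key in ("std:Reasoning~Constant", "std:Reasoning~Dynamic"):
    print(f"{key:28s} bias {summary.bias[key]:+.3f}  SD {summary.empirical_sd[key]:.3f}")
print("variance z-test power:", {k: round(v, 2) for k, v in summary.z_significant_rate.items()})
print("course selected:", summary.course_selection)
# Bias near zero and a clear plurality for the inverted-u course show
# the pipeline recovers the generating structure at the study's n.
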