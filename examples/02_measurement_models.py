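"""Fit the five measurement models to the bundled correlation matrix.

Fits the congeneric one-factor model and the four two-latent
fixed-links models (constant + linear / quadratic / logarithmic /
inverted-u) to the published correlations among the five working-memory
task conditions (n = 200), prints the fit table, the latent-variance
z-tests, and the model-comparison verdict.
"""

import warnings

from fixedlinks import load_study_correlations, run_measurement_models
from fixedlinks.pipeline import format_p

warnings.filterwarnings("ignore", message="fitting a correlation matrix")

wmc = load_study_correlations(wmc_only=True)
report = run_measurement_models(wmc)

print(report.fit_table())
print()
for name, tests in report.variance_tests.items():
    for latent, (z, p) in tests.items():
        var = report.fits[name].theta_hat[f"{latent}~~{latent}"]
        print(f"{name}: {latent:9s} variance {var:.4f}  z = {z:5.2f}  p {format_p(p)}")
print()
print("rejected (dynamic variance n.s.):", report.comparison["rejected"])
print("preferred by AIC among the rest: ", report.comparison["preferred"])
# The inverted-u fixed-links model attains the best information
# criterion and CFI of the five candidates.  Note that refitting the
# *printed two-decimal correlation* matrix attenuates the
# dynamic-variance z-tests relative to an analysis of the original
# covariance matrix: latent variances are metric-dependent in
# fixed-links models, so on this input the z-based rejection rule fires
# where the original covariance-metric analysis found significance.
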