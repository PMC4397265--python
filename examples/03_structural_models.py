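"""Relate the working-memory latents to the reasoning factor.

Fits two structural models to the bundled 8-variable correlation matrix
(n = 200): the traditional model (reasoning on one common WMC factor)
and the fixed-links model (reasoning on the constant and the dynamic
latent separately), then Wald-tests the dynamic path against the
traditional coefficient.
"""

import warnings

from fixedlinks import load_study_correlations, run_structural_models

warnings.filterwarnings("ignore", message="fitting a correlation matrix")

moments = load_study_correlations()
report = run_structural_models(moments, wald_constraint=0.68)

for model, paths in report.structural.items():
    print(model)
    for key, info in paths.items():
        print(
            f"  {key:20s} beta = {info['beta_std']:.2f}"
            f"  ({info['shared_variance_pct']:.2f}% shared variance, p {info['p_printed']})"
        )
w = report.wald
print(
    f"\nWald test of {w['path']} = {w['constraint']}: "
    f"chi2(1) = {w['W']:.2f}, p {w['p_printed']}"
)
# The single-factor model attributes ~42% of reasoning variance to
# "WMC"; the decomposition shows roughly half of that association is
# carried by condition-independent (constant) processes.
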