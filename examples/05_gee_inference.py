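"""Factorial GEE on pixel observations clustered by animal.

Fits the Gaussian-identity marginal model with exchangeable working
correlation to one simulated study, reports the omnibus effect tests
and the pairwise contrasts behind the emulated findings.
"""

import qmristats as q
from qmristats.power import run_reduced_study

observations = run_reduced_study(seed=8)

result = q.fit_gee(observations, parameter="T1")
print(f"clusters (animals): {result.n_clusters}, observations: {result.n_obs}")
print(f"working correlation alpha = {result.alpha:.3f}, dispersion = {result.scale:.1f}")
print("\nomnibus Wald tests (T1):")
print(result.wald_tests.to_string(index=False, float_format=lambda v: f"{v:.4g}"))

c = q.pairwise_contrast(result, "state", "control", "tumor", condition="fed", region="cortex")
print(f"\nfed cortex, tumor - control T1: {c.estimate:+.1f} ms (robust SE {c.se:.1f}), p = {c.p:.4g}")
# A clearly negative estimate with p < 0.05 reproduces the direction of
# the emulated finding: higher activity-dependent Mn uptake (lower T1)
# in the fed tumor-bearing cortex.

md = q.fit_gee(observations, parameter="MD")
c = q.pairwise_contrast(md, "condition", "fed", "fasted", state="control", region="cortex")
print(f"control cortex, fasted - fed MD: {c.estimate:+.3e} mm²/s, p = {c.p:.4g}")
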