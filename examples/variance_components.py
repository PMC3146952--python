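"""Estimate data-generating parameters from a training dataset.

Power simulation needs the per-level outcome SDs.  Here we generate a
synthetic two-level child-growth survey (160 villages, 2,090 children,
village SD 0.482, child SD 1.297), then recover those SDs with an
intercept-only random-intercept mixed model, exactly the workflow one
would apply to a real baseline survey.
"""

import numpy as np

import powersim as ps

table = ps.generate_training_fixture(
    ps.PROFILES["east-java"], np.random.default_rng(7)
)
print(f"training data: {len(table)} children in "
      f"{table['cluster_id'].nunique()} villages, "
      f"mean HAZ {table['y'].mean():.3f}, SD {table['y'].std():.3f}")

vc = ps.estimate_variance_components(table, levels="two_level")
rho = ps.icc(vc.sigma_g, vc.sigma_e)

print(f"village-level SD (sigma_g): {vc.sigma_g:.3f}  (generating value 0.482)")
print(f"child-level SD  (sigma_e): {vc.sigma_e:.3f}  (generating value 1.297)")
print(f"implied ICC               : {rho:.2f}   (generating value 0.12)")
print("The ICC is the share of outcome variance sitting between villages;")
print("it drives the design effect 1+(n-1)*rho that penalizes adding")
print("children to a village instead of adding villages.")
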