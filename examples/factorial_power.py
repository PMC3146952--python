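"""Power for a two-treatment factorial design with multi-level randomization.

Sanitation mobilization is randomized across villages; nutrient
supplementation (LNS) goes to half the households within every
village.  Children are measured at baseline and after two years, with
10% dropout.  No closed-form power formula covers this design, which
is exactly where the simulation engine earns its keep.
"""

import powersim as ps
from powersim.config import default_analysis

params = ps.FactorialParams(
    mu=-1.98, beta1=0.15, beta2=0.15, beta3=0.15,
    sigma_v=0.297, sigma_c=1.259, sigma_e=1.079,
)

for c in (60, 110, 160):
    design = ps.DesignSpec(
        clusters_per_arm=c, units_per_cluster=20, timepoints=2,
        cluster_level_treatments=("A",), unit_level_treatments=("X",),
        unit_allocation_fraction=0.5, dropout_rate=0.10,
    )
    scenario = ps.Scenario(
        design=design, params=params,
        analysis=default_analysis(design, params),
        n_reps=500, seed=100 + c,
    )
    p = ps.empirical_power(scenario).power
    print(f"c={c:>3} villages/arm  power: sanitation {p['A']:.2f}  "
          f"LNS {p['X']:.2f}  interaction {p['A:X']:.2f}")

print("Main effects pool information across all households, so their")
print("power is far higher than the interaction's at the same effect")
print("size: only a quarter of children receive both treatments.")
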