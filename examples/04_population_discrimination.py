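"""Which basal feature predicts the firing pattern?

Generates a two-class synthetic population (RS-like: longer, bushier;
IB-like: shorter, sparser), runs the basal x apical simulation grid,
derives majority-vote RS/IB profiles, and compares total length against
median diameter as single-feature Bayes classifiers of the profile.

Runtime is about a minute (40 compartmental simulations).
"""

import numpy as np

import dendrofire as df

trees, _ = df.generate_population(df.PopulationRecipe(n_per_class=10,
                                                      seed=1))
fx = df.fixture_suite()
grid = df.run_grid(
    trees, [fx["simple_apical"], fx["mid_apical"]], fx["mini_basal"],
    control=df.control_cell(),
)
profiles = np.array(grid.basal_profiles())
print("cell counts:", grid.counts())
print("basal profiles:", dict(zip(*np.unique(profiles,
                                             return_counts=True))))

lengths = np.array([df.total_length(t, structure=df.BASAL) for t in trees])
diams = np.array([df.median_diameter(t, structure=df.BASAL)
                  for t in trees])
_, p = df.mann_whitney(lengths[profiles == "RS"],
                       lengths[profiles == "IB"])
print(f"total length, RS vs IB profiles: Mann-Whitney p = {p:.2e}")

for name, values in (("total_length", lengths),
                     ("median_diameter", diams)):
    rep = df.bayes_evaluate(values, profiles, seed=1, feature=name,
                            min_per_class=3)
    print(f"Bayes accuracy by {name:16s}: {rep.accuracy:.3f}")

# Total length separates the firing groups strongly and out-classifies
# median diameter — the feature ranking the analysis is built to expose.
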