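"""Within-site beta diversity and its direction of change.

Uses the synthetic generator to build one paired survey, then asks for
each site whether its plots grew more similar (homogenization, negative
delta-beta) or more dissimilar (heterogenization, positive delta-beta)
between the surveys.
"""

from resurvey import SimulationTruth, beta_change, gen_paired_survey

ps, traits, manifest = gen_paired_survey(SimulationTruth(seed=42))
table = beta_change(ps, bootstrap_reps=500, seed=0)
print(table.round(3).to_string(index=False))
print()
print("beta_old/beta_new: multiple-assemblage turnover (order-2 Hill")
print("decomposition) of each site's plots per period, 0 = identical")
print("plots, 1 = pairwise disjoint; se_* are plot-bootstrap standard")
print("errors. delta_beta > 0 means the site heterogenized over time.")
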