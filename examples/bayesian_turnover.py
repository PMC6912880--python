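"""Bayesian turnover modeling with PSIS-LOO model comparison.

Fits normal linear models of plot-level turnover on site fertility and
sampling time, ranks them by leave-one-out predictive density, and
reports the fertility effect and Bayesian R^2 of the fertility model.
"""

import warnings

import numpy as np

from resurvey import SimulationTruth, gen_paired_survey, pairwise_turnover
from resurvey import bayes

warnings.filterwarnings("ignore")

ps, traits, _ = gen_paired_survey(SimulationTruth(seed=1))
turnover = pairwise_turnover(ps)

y = turnover["d"].to_numpy()
infert = (turnover["fertility"] == "infertile").to_numpy(float)
st = turnover["sampling_time"].to_numpy(float)

designs = {
    "turnover ~ 1": (np.ones((len(y), 1)), ["Intercept"]),
    "turnover ~ fertility": (
        np.column_stack([np.ones(len(y)), infert]), ["Intercept", "infertile"]),
    "turnover ~ fertility + time": (
        np.column_stack([np.ones(len(y)), infert, bayes.ortho_poly(st, 1)]),
        ["Intercept", "infertile", "stime"]),
}
loos = []
fits = {}
for label, (X, names) in designs.items():
    fit = bayes.fit_normal_lm(y, X, coef_names=names, chains=2, draws=800,
                              warmup=800, seed=3)
    fits[label] = (X, fit)
    loos.append((label, bayes.psis_loo(fit.pointwise_loglik)))

print(bayes.compare_models(loos).round(2).to_string(index=False))
print()

X, fit = fits["turnover ~ fertility"]
eff = fit.get("infertile")
r2 = bayes.bayes_r2(fit, X)
print(f"fertility effect on turnover: {eff.mean():+.3f} "
      f"[{np.percentile(eff, 2.5):+.3f}, {np.percentile(eff, 97.5):+.3f}] (95% CI)")
print(f"Bayesian R^2 (median): {np.median(r2):.2f}")
print()
print("The negative coefficient says infertile plots turned over less")
print("than fertile ones; elpd_loo ranks models by out-of-sample fit.")
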