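"""Maximum-likelihood parameter recovery on synthetic data.

Generates a noisy euthyroid dose-response time course (single 400 ug oral
LT4 dose at hour 24) from known parameters, perturbs the starting point and
refits the T4 secretion gain S4 and T3 clearance k05 by Nelder-Mead, then
reports inverse-Hessian percent coefficients of variation.
"""

import numpy as np

from hptsim import ModelParameters, fit_parameters, parameter_cvs
from hptsim.synth import euthyroid_dose_response_designs, synth_timecourses

truth = ModelParameters()
design = euthyroid_dose_response_designs((400.0,))[0]
times = np.arange(6.0, 120.0, 6.0)
sigmas = {"T4": 2.0, "T3": 0.05, "TSH": 0.08}
obs = synth_timecourses(truth, design, times, sigmas, seed=1)

init = truth.replace(S4=truth.S4 * 1.10, k05=truth.k05 * 0.90)
fit = fit_parameters([(design, obs)], init=init, free_params=("S4", "k05"),
                     n_restarts=1, maxiter=250)

print(f"{'parameter':10s} {'truth':>10s} {'start':>10s} {'fitted':>10s}")
for name in ("S4", "k05"):
    print(f"{name:10s} {getattr(truth, name):10.5f} {getattr(init, name):10.5f} "
          f"{fit.estimates[name]:10.5f}")
print(f"profiled noise SDs: " +
      ", ".join(f"{k}={v:.3f}" for k, v in fit.sigmas.items()))

cvs = parameter_cvs(fit, [(design, obs)], base=init)
print("percent CVs (inverse Hessian): " +
      ", ".join(f"{k}={v:.1f}%" for k, v in cvs.items()))
print("both parameters are recovered close to truth; the CVs quantify how "
      "sharply this protocol identifies them")
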