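"""Recover a perturbed synaptic gain from a noisy evoked-response pair.

Generates data from a circuit whose granular->superficial AMPA gain is
raised by 0.3 log-units, inverts the model by variational Laplace, and
prints the recovered value with its posterior uncertainty and the free
energy (the evidence bound the scheme maximizes).
"""

import numpy as np

from pedcm import (
    ErfForwardModel, GaussianBelief, InversionSettings, NoiseModel,
    invert, simulate_erf_pair, stack_erf_pair,
)
from pedcm.synthetic import default_base_params

base = default_base_params()
names = [f"gamma:{e.name}" for e in base.edges]        # the 22 connection gains
target = "gamma:AMPA:ss->sp"

truth = np.zeros(len(names))
truth[names.index(target)] = 0.3
std, dev = simulate_erf_pair(base.apply_log_factors(names, truth))
y = stack_erf_pair(std, dev)
y += np.random.default_rng(1).normal(0, 0.05, y.size)   # low measurement noise

priors = GaussianBelief.diagonal(names, 0.0, 1 / 16)    # log-scale shrinkage priors
result = invert(y, ErfForwardModel(base, names), priors, NoiseModel(), InversionSettings())

i = names.index(target)
sd = float(np.sqrt(result.posterior.cov[i, i]))
print(f"free energy:     {result.free_energy:.1f} nats "
      f"({result.iterations} iterations, converged={result.converged})")
print(f"true log-gain:   +0.300 on {target}")
print(f"recovered:       {result.posterior.mean[i]:+.3f} +/- {sd:.3f}")
# A recovered value within ~0.1 of the truth shows the gain is identifiable
# from a single subject's ERF pair at this noise level.
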