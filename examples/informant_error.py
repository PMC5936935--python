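"""How informant inaccuracy distorts the reciprocity correlations.

Roster interviews hinge on informants' thresholds for calling an alter
"helpful"; heterogeneous thresholds inflate the informant-side
individual variance.  This demo injects extra noise into the
informant-side receiving effect before simulating nominations, refits,
and tabulates the bias of each recovered correlation.
"""

import numpy as np

from gssrm import McmcConfig, balanced_design, informant_error_experiment
from gssrm.inference import default_experiment_parameters

design = balanced_design(20, 5)
params = default_experiment_parameters()
frame = informant_error_experiment(
    params,
    error_sd_grid=[0.0, 1.5],
    design=design,
    mcmc_config=McmcConfig(chains=2, warmup=800, draws=800, seed=2),
    rng=np.random.default_rng(7),
)
print(frame.pivot_table(index="parameter", columns="error_sd", values="bias").round(3))

# Reading: with noise sd 1.5 the actor-level generalized reciprocity
# rho_a1b1 attenuates toward zero, while the dyadic reciprocities
# rho_hh and rho_uu remain close to their generating values -
# dyad-level conclusions are robust to informant inaccuracy even when
# node-level ones are not.  (rho_a2b2 is estimated from only 20
# households and is noisy in any single replicate; the test suite
# averages replicates.)
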