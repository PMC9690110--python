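"""End-to-end TIP clustering of a simulated Gaussian mixture.

Generates the four-cluster well-separated benchmark scenario (n = 110,
p = 2), runs the TIP Gibbs sampler with the NIW likelihood, and reports
the PEAR consensus partition.  Uses shortened chains so the example
runs in a few seconds; the benchmark itself uses 1000 + 1000.
"""

import numpy as np

from tipclust import (
    SamplerConfig,
    adjusted_rand,
    generate_separated,
    posterior_similarity_from_draws,
    run_sampler,
    select_consensus,
    sim1,
)

data = generate_separated(sim1(seed=42))
print(f"dataset: n = {data.X.shape[0]}, p = {data.X.shape[1]}, "
      f"true K = {data.spec.K_star} (sizes {data.spec.sizes})")

config = SamplerConfig(burn_in=200, samples=200, seed=7)
record = run_sampler(X=data.X, config=config)

Bbar = posterior_similarity_from_draws(record.draws)
consensus = select_consensus(record.draws, Bbar)
K = int(consensus.assignment.max())
ari = adjusted_rand(consensus.assignment, data.labels)

print(f"cluster-count trace (last 10): {record.K_trace[-10:]}")
print(f"consensus K = {K}, PEAR = {consensus.pear_value:.3f}, "
      f"ARI vs truth = {ari:.3f}")
print(
    "\nThe K trace wanders above the true 4 because every iteration opens"
    " a transient invited table; the PEAR consensus collapses the chain"
    " back to the stable partition (K = 4, ARI = 1 when recovery is"
    " perfect)."
)
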