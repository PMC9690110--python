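"""The Ewens-Pitman Attraction baseline and its CRP special case.

Shows the EPA seating conditional, its exact reduction to the CRP under
zero discount and constant similarity, West's posterior draws for the
mass parameter alpha, and a short baseline run on the benchmark data.
"""

import numpy as np

from tipclust import (
    EPAParams,
    SamplerConfig,
    SimilarityMatrix,
    adjusted_rand,
    epa_conditional,
    generate_separated,
    posterior_similarity_from_draws,
    run_epa_sampler,
    sample_alpha_west,
    select_consensus,
    sim1,
)

# seating conditional: third subject, two prior subjects in one cluster
v = np.array([[1.0, 0.8, 0.2], [0.8, 1.0, 0.5], [0.2, 0.5, 1.0]])
labels, probs = epa_conditional(
    3, np.array([1, 1]), np.arange(3), SimilarityMatrix(v), EPAParams(alpha=1.0)
)
print(f"EPA conditional (alpha=1, one seated cluster): join = {probs[0]:.3f}, "
      f"new = {probs[1]:.3f}")

# CRP reduction: constant similarity makes seating size-proportional
vc = np.full((3, 3), 0.5); np.fill_diagonal(vc, 1.0)
_, probs_crp = epa_conditional(
    3, np.array([1, 1]), np.arange(3), SimilarityMatrix(vc), EPAParams(alpha=1.0)
)
print(f"CRP case (constant similarity): join = {probs_crp[0]:.3f} = |S|/(alpha+i-1)")

# West's posterior for alpha given K clusters
rng = np.random.default_rng(0)
draws = [sample_alpha_west(3, 110, EPAParams(), rng) for _ in range(5000)]
rate = 1 + np.euler_gamma + np.log(110)
print(f"alpha | K=3, n=110: sample mean {np.mean(draws):.3f} "
      f"(theory: 3/rate = {3 / rate:.3f})")

# short baseline run (collapsed scheme mixes like a DP-mixture sampler)
data = generate_separated(sim1(seed=42))
rec = run_epa_sampler(
    X=data.X, config=SamplerConfig(burn_in=100, samples=100, seed=1),
    scheme="collapsed",
)
cons = select_consensus(rec.draws, posterior_similarity_from_draws(rec.draws))
print(f"EPA (collapsed) consensus K = {int(cons.assignment.max())}, "
      f"ARI = {adjusted_rand(cons.assignment, data.labels):.3f}")
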