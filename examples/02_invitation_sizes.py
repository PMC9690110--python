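"""How a host decides how many subjects to invite.

For a host subject, the sorted distances to everyone else are segmented
by binary segmentation; the position of the first change point (the
count of near neighbours before the first break) becomes the Poisson
mean of the invitation size.
"""

import numpy as np

from tipclust import (
    binary_segmentation,
    compute_distance_matrix,
    estimate_invitation_size,
    sorted_row_distances,
)

# one tight group of 6 around 0, another far group of 4 around 50
rng = np.random.default_rng(3)
X = np.concatenate([rng.normal(0, 0.3, 6), rng.normal(50, 0.3, 4)])[:, None]
D = compute_distance_matrix(X)

host = 0
y = sorted_row_distances(D, host)
cps = binary_segmentation(y, n_subjects=D.n)
print("host's sorted distances:", np.round(y, 2))
print("change points (1-based positions):", cps.locations)

rng2 = np.random.default_rng(7)
draws = [estimate_invitation_size(D, host, rng2).n_tau for _ in range(8)]
size = estimate_invitation_size(D, host, np.random.default_rng(0))
print(f"Poisson mean used: {size.mean_used} (host has that many near neighbours)")
print("eight invitation-size draws:", draws)
print(
    "\nThe first change point sits where the host's distance profile jumps"
    " from the 5 within-group neighbours to the far group, so invitations"
    " concentrate around the host's natural cluster size."
)
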