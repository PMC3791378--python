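"""Independent continuous-time Markov chain oracle for mean first-passage.

For a single molecule on an empty circular genome with a flat landscape,
the simulator's dynamics form a finite CTMC over states
{bound at 0, ..., bound at L-1, free}.  The mean first-passage time to
the target-bound state solves the linear system

    t(s) = h(s) + sum_{s'} P(s, s') t(s'),   t(target) = 0,

with h the mean holding time of each state.  This module builds that
system directly from the kinetic parameters and solves it with a dense
linear solve — fully independent of the event-driven implementation.
"""

import numpy as np


def ctmc_mean_first_passage(
    L: int,
    target: int,
    tau0: float,
    k_assoc: float,
    move_probs,
    hop_range: int,
) -> float:
    """Mean first-passage time from the free state to binding the target."""
    psl, psr, ph, pu = move_probs
    n = L + 1  # states: bound 0..L-1, free = L
    free = L
    P = np.zeros((n, n))
    h = np.empty(n)
    h[:L] = tau0
    h[free] = 1.0 / k_assoc
    for i in range(L):
        P[i, (i - 1) % L] += psl
        P[i, (i + 1) % L] += psr
        per_hop = ph / (2 * hop_range)
        for d in range(1, hop_range + 1):
            P[i, (i + d) % L] += per_hop
            P[i, (i - d) % L] += per_hop
        P[i, free] += pu
    P[free, :L] = 1.0 / L
    keep = [s for s in range(n) if s != target]
    Q = P[np.ix_(keep, keep)]
    t = np.linalg.solve(np.eye(len(keep)) - Q, h[keep])
    return float(t[keep.index(free)])
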