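"""Independent brute-force oracles used by the test suite.

Kept free of any petctdose import so the checks stay a genuinely separate
route from the implementation under test.
"""

import itertools


def brute_force_mann_whitney(sample_a, sample_b):
    """Exact two-sided Mann–Whitney by enumerating every labelling.

    U counts (a > b) pairs with half credit for ties; the two-sided p-value
    is min(1, 2·min(P(U <= u_obs), P(U >= u_obs))) over all C(n, n_a)
    assignments of the pooled values to group A.
    """
    pooled = list(sample_a) + list(sample_b)
    n, k = len(pooled), len(sample_a)

    def u_stat(indices):
        idx = set(indices)
        aa = [pooled[i] for i in indices]
        bb = [pooled[i] for i in range(n) if i not in idx]
        return sum(
            1.0 if x > y else (0.5 if x == y else 0.0) for x in aa for y in bb
        )

    u_obs = u_stat(tuple(range(k)))
    us = [u_stat(c) for c in itertools.combinations(range(n), k)]
    m = len(us)
    cdf = sum(u <= u_obs + 1e-12 for u in us) / m
    sf = sum(u >= u_obs - 1e-12 for u in us) / m
    return u_obs, min(1.0, 2.0 * min(cdf, sf))
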