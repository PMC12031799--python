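"""Independent reference computations used by the test suite."""

import numpy as np

from vurscore.association import chi_square_test


def permutation_pvalues(table, n_shuffles, seed):
    """Fixed-margin Monte-Carlo permutation oracle for the Pearson statistic.

    Shuffles the exposure labels over subjects (outcome margin fixed by
    construction) and returns ``(tail p, mid-p)``: P(chi2* >= chi2_obs) with
    ties at the observed statistic counted fully or by half.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n = a + b + c + d
    exposure = np.zeros(n, dtype=bool)
    exposure[: a + c] = True
    outcome = np.zeros(n, dtype=bool)
    outcome[:a] = True
    outcome[a + c : a + c + b] = True
    obs, _ = chi_square_test(table)
    rng = np.random.default_rng(seed)
    ge = ties = 0
    for _ in range(n_shuffles):
        perm = rng.permutation(exposure)
        aa = int((perm & outcome).sum())
        bb = int(outcome.sum()) - aa
        cc = int(perm.sum()) - aa
        dd = n - aa - bb - cc
        # Pearson statistic for a 2x2 in closed form
        stat = n * (aa * dd - bb * cc) ** 2 / (
            (aa + bb) * (cc + dd) * (aa + cc) * (bb + dd)
        )
        if stat >= obs - 1e-9:
            ge += 1
            if abs(stat - obs) <= 1e-9:
                ties += 1
    return ge / n_shuffles, (ge - 0.5 * ties) / n_shuffles
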