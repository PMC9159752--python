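"""Independent oracles shared by the test suite (kept free of any code path
they are used to check)."""

import numpy as np


def brute_force_tau_a(x, y):
    """O(m^2) Kendall tau-a: direct concordance count over all entry pairs."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    m = len(x)
    s = 0
    for i in range(m):
        for j in range(i + 1, m):
            s += np.sign(x[j] - x[i]) * np.sign(y[j] - y[i])
    return s / (m * (m - 1) / 2)


def restrict_rdm(rdm, items):
    """Sub-RDM over an item subset via the square-matrix form."""
    import scipy.spatial.distance as ssd

    from actionrsa import RDM

    sq = rdm.square()[np.ix_(items, items)]
    return RDM(ssd.squareform(sq, checks=False), len(items))
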