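"""Numba kernels for the neutral-model core.

Two hot loops live here: log-space polynomial multiplication (the
convolution that assembles the Etienne K(D, A) coefficients from
per-species Stirling polynomials) and the sequential urn simulator of
dispersal-limited neutral communities.
"""

import numpy as np
from numba import njit

NEG_INF = -np.inf


@njit(cache=True)
def log_poly_mul(a, b):
    """Convolution of two coefficient vectors stored as logs.

    out[k] = logsumexp_{i+j=k} (a[i] + b[j]).  All inputs finite or -inf.
    """
    out = np.full(a.size + b.size - 1, NEG_INF)
    for i in range(a.size):
        ai = a[i]
        if ai == NEG_INF:
            continue
        for j in range(b.size):
            bj = b[j]
            if bj == NEG_INF:
                continue
            out[i + j] = np.logaddexp(out[i + j], ai + bj)
    return out


@njit(cache=True)
def urn_simulate(n_communities, J, theta, I_vec, seed, shared):
    """Sequential two-level urn construction of neutral local communities.

    Individual k (0-based; k individuals already present) of community c is
    a new immigrant ancestor with probability I/(I+k) where ``I =
    I_vec[c]`` (a negative entry means unlimited immigration, the Ewens
    limit), otherwise it copies the species of a uniformly chosen earlier
    individual in the same community.  Each new ancestor draws its species
    from a Hoppe urn with mass theta: a brand-new species with probability
    theta/(theta+a) given a earlier ancestors in the urn, else the species
    of a uniform earlier ancestor.  With ``shared`` the ancestor urn
    persists across communities, so all communities sample one common
    metacommunity.

    Returns (labels, n_species): labels is (n_communities, J) int64 species
    indices in 0..n_species-1.
    """
    np.random.seed(seed)
    labels = np.empty((n_communities, J), dtype=np.int64)
    anc_species = np.empty(n_communities * J, dtype=np.int64)
    n_anc = 0
    n_species = 0
    anc_start = 0
    for c in range(n_communities):
        if not shared:
            anc_start = n_anc
        I = I_vec[c]
        for k in range(J):
            new_ancestor = True
            if I >= 0.0 and k > 0:
                new_ancestor = np.random.random() * (I + k) < I
            if new_ancestor:
                n_urn = n_anc - anc_start
                if np.random.random() * (theta + n_urn) < theta:
                    sp = n_species
                    n_species += 1
                else:
                    sp = anc_species[anc_start + int(np.random.random() * n_urn)]
                anc_species[n_anc] = sp
                n_anc += 1
                labels[c, k] = sp
            else:
                labels[c, k] = labels[c, int(np.random.random() * k)]
    return labels, n_species
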