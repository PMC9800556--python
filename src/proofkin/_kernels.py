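"""Numba kernels for generic mass-action rate laws.

One pair of compiled functions serves every mechanism: directed reaction j
has rate k[j] * x[r1[j]] (* x[r2[j]] when r2[j] >= 0) and stoichiometry
column S[:, j].
"""
import numpy as np
from numba import njit


@njit(cache=True)
def mass_action_rhs(x, k, r1, r2, S):
    m = k.shape[0]
    v = np.empty(m)
    for j in range(m):
        vj = k[j] * x[r1[j]]
        if r2[j] >= 0:
            vj *= x[r2[j]]
        v[j] = vj
    return S @ v


@njit(cache=True)
def mass_action_jac(x, k, r1, r2, S):
    n = S.shape[0]
    m = k.shape[0]
    J = np.zeros((n, n))
    for j in range(m):
        a = r1[j]
        b = r2[j]
        if b < 0:
            g = k[j]
            for i in range(n):
                if S[i, j] != 0.0:
                    J[i, a] += S[i, j] * g
        else:
            ga = k[j] * x[b]
            gb = k[j] * x[a]
            for i in range(n):
                if S[i, j] != 0.0:
                    J[i, a] += S[i, j] * ga
                    J[i, b] += S[i, j] * gb
    return J
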