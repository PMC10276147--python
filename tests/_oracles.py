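"""Independent oracles for solver tests.

The convex oracle builds the full quadratic form of the summary-statistics
objective and minimizes it by splitting each coefficient into positive and
negative parts, which turns the L1 term into a linear one over a smooth
bound-constrained QP solved with L-BFGS-B.  It shares no code with the
coordinate-descent path it checks.
"""

import numpy as np
from scipy.optimize import minimize


def dense_quadratic(blocks, model, n, s, cross):
    """Q and v with f(b) = b'Qb - 2 v'b + penalty, b stacked SNP-major (p*q,)."""
    p = blocks.n_snps
    q = model.n_traits
    se2inv = 1.0 / model.residual
    R = np.zeros((p, p))
    for (a, b), Rl in zip(blocks.blocks, blocks.ld):
        R[a:b, a:b] = Rl
    M = (1.0 - s) * R + s * np.eye(p)
    Q = np.zeros((p * q, p * q))
    for k in range(q):
        idx = np.arange(p) * q + k
        Q[np.ix_(idx, idx)] += n[k] * se2inv[k] * M
    om = model.precision
    for j in range(p):
        blk = om[j]
        off = blk - np.diag(np.diag(blk))
        Q[j * q : (j + 1) * q, j * q : (j + 1) * q] += np.diag(np.diag(blk)) + cross * off
    return Q


def convex_oracle(Q, v, lam, w):
    """argmin b'Qb - 2 v'b + 2 lam sum(w |b|) via positive/negative-part splitting."""
    d = len(v)

    def fg(x):
        u, t = x[:d], x[d:]
        b = u - t
        g = Q @ b
        val = b @ g - 2.0 * v @ b + 2.0 * lam * np.sum(w * (u + t))
        grad = np.concatenate([2 * g - 2 * v + 2 * lam * w, -2 * g + 2 * v + 2 * lam * w])
        return val, grad

    res = minimize(
        fg,
        np.zeros(2 * d),
        jac=True,
        method="L-BFGS-B",
        bounds=[(0.0, None)] * (2 * d),
        options={"maxiter": 50000, "ftol": 1e-18, "gtol": 1e-14},
    )
    return res.x[:d] - res.x[d:]
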