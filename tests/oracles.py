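"""Independent reference implementations used only to check the package.

Everything here works on the full 4-index MO ERI tensor with elementary
operations (pairwise Jacobi rotations, Taylor series), sharing no code path
with the Cholesky/trust-region implementation it validates.
"""

import numpy as np
from scipy.optimize import minimize_scalar


def rotate_mo_eri(g, U):
    for sub in ("ap,abcd->pbcd", "bq,pbcd->pqcd", "cr,pqcd->pqrd", "ds,pqrd->pqrs"):
        g = np.einsum(sub, U, g, optimize=True)
    return g


def pair_self_energy(g, p, q, t):
    """Self-repulsion of the (p,q) pair after a 2x2 rotation by angle t."""
    G1 = g[p, p, p, p]
    G2 = g[p, p, p, q]
    G3a = g[p, q, p, q]
    G3b = g[p, p, q, q]
    G4 = g[p, q, q, q]
    G5 = g[q, q, q, q]
    c, s = np.cos(t), np.sin(t)
    e_p = (c ** 4 * G1 - 4 * c ** 3 * s * G2 + (4 * G3a + 2 * G3b) * c * c * s * s
           - 4 * c * s ** 3 * G4 + s ** 4 * G5)
    e_q = (s ** 4 * G1 + 4 * s ** 3 * c * G2 + (4 * G3a + 2 * G3b) * c * c * s * s
           + 4 * s * c ** 3 * G4 + c ** 4 * G5)
    return e_p + e_q


def jacobi_er_maximize(g0, tol=1e-10, max_sweeps=500):
    """Greedy 2x2 Jacobi-sweep maximizer of sum_p (pp|pp).

    For each pair the optimal angle is located by a fine scan over a full
    period followed by bounded scalar refinement; sweeps repeat until the
    total energy gain of a sweep drops below ``tol``.  Returns the maximized
    self-repulsion energy.
    """
    g = g0.copy()
    n = g.shape[0]

    def energy():
        return float(np.einsum("pppp->", g))

    ts = np.linspace(-np.pi / 4, np.pi / 4, 181)
    for _ in range(max_sweeps):
        e_before = energy()
        for p in range(n):
            for q in range(p + 1, n):
                vals = [pair_self_energy(g, p, q, t) for t in ts]
                i0 = int(np.argmax(vals))
                res = minimize_scalar(
                    lambda t: -pair_self_energy(g, p, q, t),
                    bounds=(ts[max(i0 - 1, 0)], ts[min(i0 + 1, len(ts) - 1)]),
                    method="bounded", options={"xatol": 1e-14},
                )
                t = float(res.x)
                if pair_self_energy(g, p, q, t) - pair_self_energy(g, p, q, 0.0) > 1e-14:
                    R = np.eye(n)
                    R[p, p] = R[q, q] = np.cos(t)
                    R[p, q] = np.sin(t)
                    R[q, p] = -np.sin(t)
                    g = rotate_mo_eri(g, R)
        if energy() - e_before < tol:
            break
    return energy()


def expm_taylor(K, terms=30):
    """Matrix exponential by plain Taylor summation (series oracle)."""
    out = np.eye(K.shape[0])
    term = np.eye(K.shape[0])
    for k in range(1, terms + 1):
        term = term @ K / k
        out = out + term
    return out
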