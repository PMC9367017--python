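"""Minimal restricted Hartree-Fock with DIIS.

Coulomb/exchange builds go through an internal tight-threshold Cholesky
factorization of the ERI matrix, so only O(N_J n^2) memory is touched.
"""

from __future__ import annotations

import numpy as np

_LINDEP_TOL = 1e-8


class SCFError(RuntimeError):
    def __init__(self, message, residual=None):
        super().__init__(message)
        self.residual = residual


def _orthogonalizer(S: np.ndarray) -> np.ndarray:
    w, V = np.linalg.eigh(S)
    keep = w > _LINDEP_TOL * w.max()
    return V[:, keep] / np.sqrt(w[keep])


def _cholesky_vectors(ints, tau=1e-8):
    # local import: mol_integrals imports this module
    from .cholesky import decompose_eri

    L = decompose_eri(ints, tau=tau)
    n = ints.n_ao
    out = np.zeros((L.N_J, n, n))
    iu = np.tril_indices(n)
    out[:, iu[0], iu[1]] = L.L
    out[:, iu[1], iu[0]] = L.L
    return out


def restricted_hartree_fock(ints, conv=1e-7, max_iter=200, diis_depth=8):
    """Returns (C, orbital_energies, total_energy) for a closed-shell system."""
    S = ints.overlap
    H = ints.core_hamiltonian
    X = _orthogonalizer(S)
    nocc = ints.molecule.n_electrons // 2
    Lchol = _cholesky_vectors(ints)
    e_nuc = ints.molecule.nuclear_repulsion()

    nao = S.shape[0]
    nj = Lchol.shape[0]

    def fock(D):
        j_w = np.einsum("jab,ab->j", Lchol, D)
        J = np.einsum("j,jab->ab", j_w, Lchol)
        half = (Lchol.reshape(nj * nao, nao) @ D).reshape(nj, nao, nao)
        K = np.tensordot(Lchol, half, axes=([0, 2], [0, 2]))
        return H + 2.0 * J - K

    # core-Hamiltonian guess
    e, Cp = np.linalg.eigh(X.T @ H @ X)
    C = X @ Cp
    D = C[:, :nocc] @ C[:, :nocc].T
    errs, focks = [], []
    last_res = np.inf
    for _ in range(max_iter):
        F = fock(D)
        # DIIS error in the orthonormal basis
        err = X.T @ (F @ D @ S - S @ D @ F) @ X
        last_res = np.abs(err).max()
        if last_res < conv:
            e, Cp = np.linalg.eigh(X.T @ F @ X)
            C = X @ Cp
            energy = float(np.einsum("ab,ab->", D, H + F)) + e_nuc
            return C, e, energy
        errs.append(err.ravel())
        focks.append(F)
        if len(errs) > diis_depth:
            errs.pop(0)
            focks.pop(0)
        if len(errs) > 1:
            m = len(errs)
            B = -np.ones((m + 1, m + 1))
            B[-1, -1] = 0.0
            B[:m, :m] = np.array([[ei @ ej for ej in errs] for ei in errs])
            rhs = np.zeros(m + 1)
            rhs[-1] = -1.0
            try:
                c = np.linalg.solve(B, rhs)[:m]
                F = sum(ci * Fi for ci, Fi in zip(c, focks))
            except np.linalg.LinAlgError:
                pass
        e, Cp = np.linalg.eigh(X.T @ F @ X)
        C = X @ Cp
        D = C[:, :nocc] @ C[:, :nocc].T
    raise SCFError(f"SCF not converged in {max_iter} iterations", residual=last_res)
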