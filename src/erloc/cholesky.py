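"""Pivoted incomplete Cholesky decomposition of the two-electron integrals.

The ERI matrix over packed symmetric AO pairs, M[(ab),(cd)] = (ab|cd), is
positive semidefinite, so a greedy pivoted Cholesky factorization
M ~= L^T L truncated when the largest residual diagonal drops below tau
bounds every elementwise reconstruction error by tau (Cauchy-Schwarz on the
residual Gram matrix).  The number of vectors N_J grows linearly with system
size and shrinks as tau is loosened.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class CholeskyBreakdownError(RuntimeError):
    """Residual diagonal went significantly negative: inconsistent integrals."""


@dataclass
class CholeskyVectors:
    """Cholesky factor of the AO ERI matrix over packed pairs (a >= b)."""

    L: np.ndarray            # (N_J, n_pair)
    tau: float
    pivot_order: list
    n_ao: int
    residual_diagonal: np.ndarray  # diagnostics: diagonal at termination

    @property
    def N_J(self) -> int:
        return self.L.shape[0]

    @property
    def n_pair(self) -> int:
        return self.L.shape[1]


@dataclass
class MOCholesky:
    """Cholesky vectors in an MO space: (N_J, n, n), symmetric per vector."""

    L_mo: np.ndarray
    space: str = "custom"

    @property
    def N_J(self) -> int:
        return self.L_mo.shape[0]

    @property
    def n(self) -> int:
        return self.L_mo.shape[1]


def decompose_eri(ints, tau: float) -> CholeskyVectors:
    """Greedy pivoted incomplete Cholesky decomposition at threshold ``tau``.

    Repeatedly selects the largest residual diagonal (ties broken toward the
    lowest pair index), forms the corresponding residual column scaled by
    1/sqrt(D_max) and subtracts its outer-product contribution from the
    residual diagonal; stops once the largest residual diagonal is <= tau.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    D = np.array(ints.eri_diagonal, dtype=float, copy=True)
    n_pair = D.size
    buf = np.empty((min(256, n_pair), n_pair))
    k = 0
    pivots = []
    while True:
        if D.min() < -10.0 * tau:
            raise CholeskyBreakdownError(
                f"residual diagonal {D.min():.3e} below -10*tau"
            )
        p = int(np.argmax(D))  # argmax returns the lowest index on ties
        d_max = D[p]
        if d_max <= tau:
            break
        col = np.asarray(ints.eri_column_provider(p), dtype=float)
        if k:
            col -= buf[:k, p] @ buf[:k]
        if k == buf.shape[0]:
            buf = np.vstack([buf, np.empty_like(buf)])
        buf[k] = col / np.sqrt(d_max)
        pivots.append(p)
        D -= buf[k] * buf[k]
        D[p] = 0.0  # exact by construction; guards roundoff
        k += 1
    L = buf[:k].copy() if k else np.zeros((0, n_pair))
    return CholeskyVectors(
        L=L, tau=float(tau), pivot_order=pivots, n_ao=ints.n_ao,
        residual_diagonal=D,
    )


def unpack_vector(v: np.ndarray, n: int) -> np.ndarray:
    out = np.zeros((n, n))
    iu = np.tril_indices(n)
    out[iu] = v
    out.T[iu] = v
    return out


def transform_to_mo(L_ao: CholeskyVectors, C) -> MOCholesky:
    """MO-basis Cholesky vectors L[J]_pq = sum_ab C_ap L[J]_ab C_bq.

    Performed as two successive half transformations (never through a
    4-index intermediate); the packed AO pair index is unpacked to a full
    symmetric matrix first, which accounts for the off-diagonal factor.
    """
    Cm = C.C if hasattr(C, "C") else np.asarray(C)
    n_ao = L_ao.n_ao
    if Cm.shape[0] != n_ao:
        raise ValueError(f"C has {Cm.shape[0]} AO rows, expected {n_ao}")
    nj = L_ao.N_J
    ncol = Cm.shape[1]
    iu = np.tril_indices(n_ao)
    M = np.zeros((nj, n_ao, n_ao))
    M[:, iu[0], iu[1]] = L_ao.L
    M[:, iu[1], iu[0]] = L_ao.L
    half = (M.reshape(nj * n_ao, n_ao) @ Cm).reshape(nj, n_ao, ncol)
    out = np.matmul(Cm.T[None, :, :], half)
    out = 0.5 * (out + out.transpose(0, 2, 1))  # enforce exact symmetry
    space = getattr(C, "space", "custom")
    return MOCholesky(L_mo=out, space=space)


def recompression_check(L: CholeskyVectors, ints, sample: int, seed: int) -> float:
    """Max |(ab|cd) - sum_J L_ab L_cd| over ``sample`` random pair columns."""
    if sample < 1:
        raise ValueError("sample must be >= 1")
    rng = np.random.default_rng(seed)
    cols = rng.integers(0, L.n_pair, size=sample)
    err = 0.0
    for p in cols:
        exact = np.asarray(ints.eri_column_provider(int(p)))
        approx = L.L[:, int(p)] @ L.L if L.N_J else np.zeros_like(exact)
        err = max(err, float(np.abs(exact - approx).max()))
    return err


def save_vectors(path, L: CholeskyVectors) -> None:
    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset("L", data=L.L)
        fh.create_dataset("pivot_order", data=np.asarray(L.pivot_order, dtype=np.int64))
        fh.attrs["tau"] = L.tau
        fh.attrs["n_ao"] = L.n_ao
        fh.create_dataset("residual_diagonal", data=L.residual_diagonal)


def load_vectors(path) -> CholeskyVectors:
    import h5py

    with h5py.File(path, "r") as fh:
        return CholeskyVectors(
            L=fh["L"][...],
            tau=float(fh.attrs["tau"]),
            pivot_order=[int(i) for i in fh["pivot_order"][...]],
            n_ao=int(fh.attrs["n_ao"]),
            residual_diagonal=fh["residual_diagonal"][...],
        )
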