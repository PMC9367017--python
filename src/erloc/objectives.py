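"""Localization objectives: Edmiston-Ruedenberg and Foster-Boys.

Both objectives are "diagonal dominance" functionals over a stack of
symmetric MO-basis matrices M[J]:

    f = offset - sum_J sum_p (M[J]_pp)^2

For Edmiston-Ruedenberg the M[J] are the MO Cholesky vectors of the electron
repulsion integrals, so sum_Jp (M[J]_pp)^2 = sum_p (pp|pp) is the orbital
self-repulsion energy E and f = -E (offset 0).  For Foster-Boys the M[J] are
the three MO dipole matrices and the offset is the rotation-invariant trace
of the second moment, so f equals the summed orbital variances
sum_p (<p|r^2|p> - |<p|r|p>|^2).  Both therefore share one gradient/Hessian
engine.

Orbital rotations are parametrized as C -> C exp(kappa) with kappa real
antisymmetric; unique parameters are kappa_pq with p > q (row-major
lower-triangle order).  Derivatives at kappa = 0:

    dE/dkappa_pq          = 4[(pq|qq) - (pq|pp)]
    (H_E kappa)           = 4(dR - dR^T) + (1/2)[kappa, A_E]
    dR = kappa^T R + Y . kappa + 2 Z . kappa
    H_E diag(p,q)         = 16 (pq|pq) - 4[(pp|pp) + (qq|qq) - 2(pp|qq)]

with intermediates d[J]_p = M[J]_pp, R_ab = sum_J M[J]_ab d[J]_b,
Y_atb = sum_J M[J]_at d[J]_b, Z_atb = sum_J M[J]_ab M[J]_tb,
W_pq = sum_J (M[J]_pq)^2, all built once per macroiteration; the Hessian
commutator term makes the bilinear form exactly symmetric away from
stationary points (the chart-curvature correction of the exponential
parametrization).  Every formula here is locked to central-finite-difference
oracles in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cholesky import CholeskyVectors, MOCholesky, transform_to_mo


class StaleStateError(RuntimeError):
    """A state object was used after its objective was refreshed elsewhere."""


def pair_indices(n: int):
    """Row-major lower-triangle (p > q) index pair arrays."""
    return np.tril_indices(n, -1)


@dataclass
class Kappa:
    """Unique antisymmetric rotation parameters kappa_pq, p > q."""

    values: np.ndarray
    n: int

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        m = self.n * (self.n - 1) // 2
        if self.values.shape != (m,):
            raise ValueError(f"expected {m} unique parameters, got {self.values.shape}")

    @classmethod
    def zeros(cls, n: int) -> "Kappa":
        return cls(np.zeros(n * (n - 1) // 2), n)

    @classmethod
    def from_matrix(cls, K: np.ndarray, atol: float = 1e-12) -> "Kappa":
        K = np.asarray(K, dtype=float)
        if np.abs(K + K.T).max() > atol:
            raise ValueError("matrix is not antisymmetric")
        n = K.shape[0]
        return cls(K[pair_indices(n)], n)

    def to_matrix(self) -> np.ndarray:
        K = np.zeros((self.n, self.n))
        K[pair_indices(self.n)] = self.values
        return K - K.T

    @property
    def norm(self) -> float:
        return float(np.linalg.norm(self.values))


@dataclass
class ERState:
    """Per-macroiteration intermediates of a diagonal-dominance objective.

    ``M`` are the symmetric MO matrices (Cholesky vectors for ER, dipole
    matrices for FB); d/R/Y/Z/W are the contraction intermediates built once
    per macroiteration, from which energy, gradient and Hessian products are
    formed without touching M again.
    """

    M: np.ndarray                # (N_J, n, n)
    offset: float = 0.0
    space: str = "custom"
    d: np.ndarray = field(init=False, repr=False)
    R: np.ndarray = field(init=False, repr=False)
    Y: np.ndarray = field(init=False, repr=False)
    Z: np.ndarray = field(init=False, repr=False)
    W: np.ndarray = field(init=False, repr=False)
    _stale: bool = field(default=False, init=False, repr=False)

    def __post_init__(self):
        M = self.M
        self.d = np.einsum("jpp->jp", M)
        self.R = np.einsum("jab,jb->ab", M, self.d)
        self.Y = np.einsum("jat,jb->atb", M, self.d)
        self.Z = np.einsum("jab,jtb->atb", M, M)
        self.W = np.einsum("jpq,jpq->pq", M, M)

    @property
    def n(self) -> int:
        return self.M.shape[1]

    @property
    def diagonal_sum(self) -> float:
        """sum_J sum_p (M[J]_pp)^2; the ER self-repulsion energy."""
        return float(np.einsum("jp,jp->", self.d, self.d))

    @property
    def f_value(self) -> float:
        return self.offset - self.diagonal_sum

    def _check(self):
        if self._stale:
            raise StaleStateError("state predates the latest refresh")

    def gradient_full(self) -> np.ndarray:
        """Gradient of f as a full antisymmetric matrix."""
        self._check()
        return -4.0 * (self.R - self.R.T)

    def gradient(self) -> Kappa:
        g = self.gradient_full()
        return Kappa(g[pair_indices(self.n)], self.n)

    def hessian_apply(self, kappa: Kappa) -> np.ndarray:
        """(H_f kappa) as a full antisymmetric matrix (symmetric bilinear form)."""
        self._check()
        K = kappa.to_matrix() if isinstance(kappa, Kappa) else np.asarray(kappa)
        if K.shape != (self.n, self.n):
            raise ValueError("kappa dimension mismatch")
        dR = K.T @ self.R
        dR += np.einsum("tb,atb->ab", K, self.Y)
        dR += 2.0 * np.einsum("tb,atb->ab", K, self.Z)
        A_E = 4.0 * (self.R - self.R.T)
        H_E = 4.0 * (dR - dR.T) + 0.5 * (K @ A_E - A_E @ K)
        return -H_E

    def hessian_diagonal_full(self) -> np.ndarray:
        """H_pq,pq of f for every pair, as a symmetric matrix."""
        self._check()
        e = np.einsum("jp,jp->p", self.d, self.d)
        Vc = self.d.T @ self.d
        return 4.0 * (e[:, None] + e[None, :] - 2.0 * Vc) - 16.0 * self.W

    def hessian_diagonal(self) -> Kappa:
        return Kappa(self.hessian_diagonal_full()[pair_indices(self.n)], self.n)


# ---------------------------------------------------------------------------
# spec-level operations (Edmiston-Ruedenberg flavor)
# ---------------------------------------------------------------------------

def refresh_er_state(L_ao: CholeskyVectors | MOCholesky, C) -> ERState:
    """Transform Cholesky vectors to the orbital basis and build intermediates."""
    if isinstance(L_ao, MOCholesky):
        mo = L_ao
    else:
        mo = transform_to_mo(L_ao, C)
    return ERState(M=mo.L_mo, offset=0.0, space=mo.space)


def er_energy(state: ERState) -> float:
    """Self-repulsion energy E = sum_p (pp|pp); the solver minimizes f = -E."""
    state._check()
    return state.diagonal_sum


def er_energy_decomposition(state: ERState):
    """(self-repulsion, interorbital Coulomb, interorbital exchange).

    self + interorbital exchange equals sum_J ||L[J]||_F^2 and
    self + interorbital Coulomb equals sum_J (Tr L[J])^2; both are invariant
    under orthogonal rotations of the space.
    """
    state._check()
    self_rep = state.diagonal_sum
    trace_sq = float(np.sum(state.d.sum(axis=1) ** 2))
    frob_sq = float(np.einsum("jpq,jpq->", state.M, state.M))
    return self_rep, trace_sq - self_rep, frob_sq - self_rep


def er_gradient(state: ERState) -> np.ndarray:
    return state.gradient_full()


def er_hessian_apply(state: ERState, kappa: Kappa) -> np.ndarray:
    return state.hessian_apply(kappa)


def er_hessian_diagonal(state: ERState) -> np.ndarray:
    return state.hessian_diagonal_full()


# ---------------------------------------------------------------------------
# objective contracts for the trust-region solver
# ---------------------------------------------------------------------------

class Objective:
    """Contract the restricted-step solver optimizes against.

    ``refresh(C)`` builds the per-macroiteration state; value/gradient/
    Hessian products are read off the state.  Refreshing invalidates states
    handed out earlier (their intermediates no longer describe the current
    orbitals).
    """

    space: str = "custom"

    def __init__(self):
        self._last_state: ERState | None = None

    def _build(self, C) -> ERState:  # pragma: no cover - abstract
        raise NotImplementedError

    def refresh(self, C) -> ERState:
        state = self._build(C)
        if self._last_state is not None:
            self._last_state._stale = True
        self._last_state = state
        return state

    def value(self, C) -> float:
        return self._build(C).f_value


class CholeskyERObjective(Objective):
    """f = -sum_p (pp|pp) over MO Cholesky vectors (Edmiston-Ruedenberg)."""

    def __init__(self, L_ao: CholeskyVectors):
        super().__init__()
        self.L_ao = L_ao

    def _build(self, C) -> ERState:
        mo = transform_to_mo(self.L_ao, C)
        return ERState(M=mo.L_mo, offset=0.0, space=mo.space)


class FosterBoysObjective(Objective):
    """f = sum_p (<p|r^2|p> - |<p|r|p>|^2), the summed orbital variances."""

    def __init__(self, ints):
        super().__init__()
        pm = ints.position_moments
        self._dip = np.stack([pm["x"], pm["y"], pm["z"]])
        self._r2 = pm["xx"] + pm["yy"] + pm["zz"]

    def _build(self, C) -> ERState:
        Cm = C.C if hasattr(C, "C") else np.asarray(C)
        U = np.einsum("ap,uab,bq->upq", Cm, self._dip, Cm, optimize=True)
        offset = float(np.trace(Cm.T @ self._r2 @ Cm))
        return ERState(M=U, offset=offset, space=getattr(C, "space", "custom"))


def fb_objective(ints, C=None) -> FosterBoysObjective:
    """Foster-Boys variance-sum objective in the same contract as ER."""
    return FosterBoysObjective(ints)


# ---------------------------------------------------------------------------
# exact-ERI oracle (naive quartic-scaling path; testing reference)
# ---------------------------------------------------------------------------

def exact_er_oracle(ints, C):
    """(E, gradient of f) from the full 4-index MO ERI tensor.

    Quartic AO->MO transformation with no factorization; the reference that
    every Cholesky-based quantity is tested against.  Refuses systems whose
    in-core ERI tensor is unavailable.
    """
    Cm = C.C if hasattr(C, "C") else np.asarray(C)
    try:
        g_ao = ints.full_eri()
    except MemoryError as exc:
        raise MemoryError("system too large for the exact-ERI oracle") from exc
    g = np.einsum("ap,abcd->pbcd", Cm, g_ao, optimize=True)
    g = np.einsum("bq,pbcd->pqcd", Cm, g, optimize=True)
    g = np.einsum("cr,pqcd->pqrd", Cm, g, optimize=True)
    g = np.einsum("ds,pqrd->pqrs", Cm, g, optimize=True)
    n = Cm.shape[1]
    E = float(np.einsum("pppp->", g))
    G = np.zeros((n, n))
    for p in range(n):
        for q in range(n):
            # d f / d kappa_pq = 4[(pq|pp) - (pq|qq)] for f = -E
            G[p, q] = 4.0 * (g[p, q, p, p] - g[p, q, q, q])
    return E, G


__all__ = [
    "CholeskyERObjective", "ERState", "FosterBoysObjective", "Kappa",
    "Objective", "StaleStateError", "er_energy", "er_energy_decomposition",
    "er_gradient", "er_hessian_apply", "er_hessian_diagonal",
    "exact_er_oracle", "fb_objective", "pair_indices", "refresh_er_state",
]
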