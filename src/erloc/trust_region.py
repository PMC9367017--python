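"""Restricted-step (trust-region) second-order minimizer for orbital rotations.

Macroiterations rebuild the objective state, test the max-abs gradient
element against the convergence threshold, and take a step obtained either
as an unshifted Newton step (positive-definite model, step inside the trust
radius h) or from the lowest eigenpair of the alpha-scaled augmented Hessian

        [[0,        alpha g^T],
         [alpha g,  H       ]]

whose lowest eigenvalue mu lies below the lowest eigenvalue of H
(Hylleraas-Undheim-MacDonald), so (H - mu) is positive definite and
kappa = x_tail / (alpha x_0) solves the level-shifted Newton equation.
alpha is adjusted by bracketing/bisection until |kappa| lands in
[0.9 h, 1.1 h].  The eigenproblem is solved in a growing reduced space with
Davidson preconditioning by (diag H - mu).  An integer line search applies
exp(n kappa) while the objective keeps decreasing, and h is updated from the
ratio of actual to model reduction.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

from .objectives import Kappa, Objective, pair_indices

H_MIN, H_MAX = 1e-4, 10.0


@dataclass
class TrustConfig:
    conv_tol: float = 1e-6        # max-abs gradient element (au)
    h0: float = 0.5               # initial trust radius
    max_macro: int = 200
    max_micro: int = 100
    micro_rel_tol: float = 1e-3   # Davidson residual, relative to |g|
    ratio_lo: float = 0.25
    ratio_hi: float = 0.75
    shrink: float = 0.7
    grow: float = 1.2
    line_search_max_n: int = 16
    max_subspace: int = 30        # Davidson restart dimension

    def __post_init__(self):
        if not (0.0 < self.ratio_lo < self.ratio_hi < 1.0):
            raise ValueError("need 0 < ratio_lo < ratio_hi < 1")
        if not (self.shrink < 1.0 < self.grow):
            raise ValueError("need shrink < 1 < grow")
        for name in ("conv_tol", "h0", "micro_rel_tol"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class AugHessSolution:
    mu: float
    alpha: float | None
    x: np.ndarray
    kappa: object            # Kappa when solving an orbital problem
    micro_iters: int


@dataclass
class IterationRecord:
    macro_index: int
    f_value: float
    max_grad: float
    h: float
    mu: float
    n_micro: int
    line_search_n: int


@dataclass
class LocalizationResult:
    U_total: np.ndarray
    C_localized: object
    trace: list
    converged: bool
    final_spreads: object = None

    @property
    def n_macro(self) -> int:
        return len(self.trace)


class StepFailure(RuntimeError):
    """Microiteration budget exhausted; caller shrinks h and retries."""


def orthogonal_exponential(kappa) -> np.ndarray:
    """U = exp(K) for antisymmetric K; exactly orthogonal with det +1."""
    K = kappa.to_matrix() if isinstance(kappa, Kappa) else np.asarray(kappa)
    return expm(K)


def update_trust_radius(h: float, predicted_change: float, actual_change: float,
                        cfg: TrustConfig, hit_boundary: bool = True) -> float:
    """Fletcher-style radius update from the model/actual reduction ratio."""
    if predicted_change >= 0:
        raise ValueError("descent model must predict a negative change")
    r = actual_change / predicted_change
    if r < cfg.ratio_lo:
        h = cfg.shrink * h
    elif r > cfg.ratio_hi and hit_boundary:
        h = cfg.grow * h
    return float(min(max(h, H_MIN), H_MAX))


# ---------------------------------------------------------------------------
# step equation
# ---------------------------------------------------------------------------

def _newton_cg(g, hop, diag, h, cfg):
    """Preconditioned CG on H x = -g with negative-curvature detection.

    Returns (x, iters) or None if the model is not positive definite along
    the Krylov path or the step leaves the trust region.
    """
    m = g.size
    prec = np.maximum(np.abs(diag), 1e-8 * max(np.abs(diag).max(), 1.0))
    x = np.zeros(m)
    r = -g.copy()
    z = r / prec
    p = z.copy()
    rz = float(r @ z)
    tol = cfg.micro_rel_tol * np.linalg.norm(g)
    for it in range(1, cfg.max_micro + 1):
        Hp = hop(p)
        curv = float(p @ Hp)
        if curv <= 1e-14 * float(p @ p):
            return None
        a = rz / curv
        x = x + a * p
        if np.linalg.norm(x) > h:
            return None
        r = r - a * Hp
        if np.linalg.norm(r) <= tol:
            return x, it
        z = r / prec
        rz_new = float(r @ z)
        p = z + (rz_new / rz) * p
        rz = rz_new
    return None


class _AugmentedDavidson:
    """Reduced-space lowest-eigenpair solver for the bordered system.

    The basis is shared across alpha values: for basis vector (b0, bv) the
    operator action only needs H bv, which is cached, so re-solving after an
    alpha change costs one small dense diagonalization.
    """

    def __init__(self, g, hop, diag, cfg):
        self.g = g
        self.hop = hop
        self.diag = diag
        self.cfg = cfg
        self.gnorm = np.linalg.norm(g)
        m = g.size
        self.b0 = []          # head components
        self.BV = []          # tail components
        self.HBV = []         # cached H @ tail
        self.n_applies = 0
        self._append(1.0, np.zeros(m))
        self._append(0.0, g / self.gnorm)

    def _append(self, b0, bv):
        # orthonormalize against current basis (twice, for stability)
        for _ in range(2):
            for c0, cv in zip(self.b0, self.BV):
                ov = b0 * c0 + bv @ cv
                b0 -= ov * c0
                bv = bv - ov * cv
        nrm = math.sqrt(b0 * b0 + bv @ bv)
        if nrm < 1e-10:
            return False
        b0 /= nrm
        bv = bv / nrm
        self.b0.append(b0)
        self.BV.append(bv)
        self.HBV.append(self.hop(bv))
        self.n_applies += 1
        return True

    def _reduced(self, alpha):
        k = len(self.b0)
        b0 = np.array(self.b0)
        BV = np.array(self.BV)
        HBV = np.array(self.HBV)
        gb = BV @ self.g
        T = BV @ HBV.T
        T = 0.5 * (T + T.T)
        T += alpha * (np.outer(b0, gb) + np.outer(gb, b0))
        return T, b0, BV, HBV, gb

    def solve(self, alpha):
        """Converge the lowest eigenpair at this alpha; returns (mu, x0, xv)."""
        cfg = self.cfg
        tol = cfg.micro_rel_tol * self.gnorm
        while True:
            T, b0, BV, HBV, gb = self._reduced(alpha)
            w, Y = np.linalg.eigh(T)
            y = Y[:, 0]
            mu = float(w[0])
            x0 = float(b0 @ y)
            xv = BV.T @ y
            # residual of the augmented eigenproblem
            r0 = alpha * (self.g @ xv) - mu * x0
            rv = alpha * x0 * self.g + HBV.T @ y - mu * xv
            rnorm = math.sqrt(r0 * r0 + rv @ rv)
            if rnorm <= tol:
                return mu, x0, xv
            if self.n_applies >= cfg.max_micro:
                raise StepFailure(f"micro budget exhausted (residual {rnorm:.2e})")
            if len(self.b0) >= cfg.max_subspace:
                # collapse to the current best vector and restart
                self.b0, self.BV, self.HBV = [], [], []
                self._append(1.0, np.zeros_like(self.g))
                self._append(x0, xv)
                continue
            denom = self.diag - mu
            denom = np.where(np.abs(denom) < 1e-8, np.copysign(1e-8, denom), denom)
            if not self._append(0.0, rv / denom):
                # preconditioned residual linearly dependent; use raw residual
                if not self._append(0.0, rv):
                    raise StepFailure("Davidson subspace stagnated")


def lowest_hessian_eigenpair(hop, diag, cfg: TrustConfig | None = None,
                             tol: float = 1e-6):
    """Davidson lowest eigenpair of the (unaugmented) Hessian operator.

    Used to verify that a gradient-converged point is a minimum: at a
    stationary point the augmented-Hessian eigenvector loses its head
    component and degenerates into exactly this eigenproblem.
    """
    cfg = cfg or TrustConfig()
    m = diag.size
    if m == 1:
        v = np.ones(1)
        return float(hop(v)[0]), v
    start = np.zeros(m)
    start[int(np.argmin(diag))] = 1.0
    basis = [start]
    applies = [hop(start)]
    for _ in range(min(cfg.max_micro, 4 * m)):
        B = np.array(basis)
        HB = np.array(applies)
        T = B @ HB.T
        T = 0.5 * (T + T.T)
        w, Y = np.linalg.eigh(T)
        lam = float(w[0])
        x = B.T @ Y[:, 0]
        r = HB.T @ Y[:, 0] - lam * x
        if np.linalg.norm(r) <= tol * max(1.0, abs(lam)):
            return lam, x
        if len(basis) >= cfg.max_subspace:
            basis, applies = [x], [hop(x)]
            continue
        denom = diag - lam
        denom = np.where(np.abs(denom) < 1e-8, np.copysign(1e-8, denom), denom)
        z = r / denom
        for b in basis:
            z = z - (z @ b) * b
        nrm = np.linalg.norm(z)
        if nrm < 1e-10:
            return lam, x
        z /= nrm
        basis.append(z)
        applies.append(hop(z))
    return lam, x


def solve_step(gradient, hessian_apply, hessian_diagonal, h: float,
               cfg: TrustConfig | None = None) -> AugHessSolution:
    """Solve the restricted-step equations for one macroiteration.

    ``gradient`` may be a Kappa or a plain vector; ``hessian_apply`` must map
    the same representation to itself; ``hessian_diagonal`` matches the
    gradient representation.  If the (reduced) model is positive definite
    and the Newton step lies inside the trust radius it is returned with
    mu = 0; otherwise the augmented-Hessian branch finds the level-shifted
    step with |kappa| in [0.9 h, 1.1 h].
    """
    cfg = cfg or TrustConfig()
    as_kappa = isinstance(gradient, Kappa)
    if as_kappa:
        n = gradient.n
        iu = pair_indices(n)
        g = gradient.values.copy()

        def hop(v):
            out = hessian_apply(Kappa(v, n))
            return out[iu] if isinstance(out, np.ndarray) and out.ndim == 2 else np.asarray(out)

        diag = hessian_diagonal.values if isinstance(hessian_diagonal, Kappa) \
            else np.asarray(hessian_diagonal)[iu] if np.asarray(hessian_diagonal).ndim == 2 \
            else np.asarray(hessian_diagonal)
    else:
        g = np.asarray(gradient, dtype=float).copy()
        hop = hessian_apply
        diag = np.asarray(hessian_diagonal, dtype=float)
    if np.abs(g).max() == 0.0:
        raise ValueError("solve_step requires a nonzero gradient")

    newton = _newton_cg(g, hop, diag, h, cfg)
    if newton is not None:
        x, its = newton
        kap = Kappa(x, n) if as_kappa else x
        return AugHessSolution(mu=0.0, alpha=None, x=x, kappa=kap, micro_iters=its)

    dav = _AugmentedDavidson(g, hop, diag, cfg)

    def step_at(alpha):
        mu, x0, xv = dav.solve(alpha)
        if abs(x0) < 1e-12:
            # gradient nearly orthogonal to the lowest eigenvector; nudge alpha
            raise StepFailure("vanishing head component in augmented eigenvector")
        k = xv / (alpha * x0)
        return mu, k

    alpha = 1.0
    mu, k = step_at(alpha)
    lo, hi = None, None      # |k| decreasing in alpha: lo = too-short alpha side
    for _ in range(60):
        ln = np.linalg.norm(k)
        if 0.9 * h <= ln <= 1.1 * h:
            break
        if ln > 1.1 * h:
            hi = alpha       # too long -> need larger alpha
            alpha = alpha * 4.0 if lo is None else 0.5 * (alpha + lo)
        else:
            lo = alpha       # too short -> need smaller alpha
            if hi is None:
                if alpha < 1e-10:
                    break    # step is intrinsically short (quasi-Newton regime)
                alpha = alpha / 4.0
            else:
                alpha = 0.5 * (alpha + hi)
        mu, k = step_at(alpha)
    kap = Kappa(k, n) if as_kappa else k
    return AugHessSolution(mu=mu, alpha=alpha, x=k, kappa=kap,
                           micro_iters=dav.n_applies)


# ---------------------------------------------------------------------------
# line search and the macroiteration loop
# ---------------------------------------------------------------------------

def line_search(C, kappa: Kappa, objective: Objective, f0: float | None = None,
                max_n: int = 16):
    """Apply U = exp(kappa) repeatedly while the objective strictly decreases.

    Returns (n, C_new, f_new); n = 0 means even a single application
    increased the objective (the caller rejects the step and shrinks h).
    """
    U = orthogonal_exponential(kappa)
    if f0 is None:
        f0 = objective.value(C)
    best_C, best_f, n = C, f0, 0
    cur = C
    for k in range(1, max_n + 1):
        cur = cur.rotated(U) if hasattr(cur, "rotated") else cur @ U
        f = objective.value(cur)
        if f < best_f:
            best_C, best_f, n = cur, f, k
        else:
            break
    return n, best_C, best_f


def localize(C0, objective: Objective, cfg: TrustConfig | None = None,
             callback=None) -> LocalizationResult:
    """Trust-region localization of the orbital set ``C0``.

    Never raises on non-convergence; the result carries the full trace and
    ``converged=False``.
    """
    cfg = cfg or TrustConfig()
    C = C0
    n = C0.C.shape[1] if hasattr(C0, "C") else C0.shape[1]
    U_total = np.eye(n)
    h = cfg.h0
    trace = []
    converged = False
    iu = pair_indices(n)
    escapes_left = 12
    for it in range(cfg.max_macro):
        state = objective.refresh(C)
        f = state.f_value
        gfull = state.gradient_full()
        gmax = float(np.abs(gfull).max()) if n > 1 else 0.0
        if gmax <= cfg.conv_tol:
            # gradient-stationary; verify it is a minimum, not a saddle
            diag_full = state.hessian_diagonal_full()[iu] if n > 1 else None
            esc = None
            if n > 1 and escapes_left > 0:
                lam, vec = lowest_hessian_eigenpair(
                    lambda v: state.hessian_apply(Kappa(v, n))[iu],
                    diag_full, cfg)
                if lam < -1e-7 * max(1.0, float(np.abs(diag_full).max())):
                    esc = (lam, vec)
            if esc is None:
                trace.append(IterationRecord(it, f, gmax, h, 0.0, 0, 0))
                converged = True
                if callback:
                    callback(trace[-1])
                break
            # kick along the negative-curvature direction (either sign
            # descends to second order; the line search arbitrates)
            lam, vec = esc
            escapes_left -= 1
            moved = False
            for scale in (min(h, 0.5), 0.1 * min(h, 0.5), 0.01 * min(h, 0.5)):
                for sgn in (1.0, -1.0):
                    kappa = Kappa(sgn * scale * vec / np.linalg.norm(vec), n)
                    ls_n, C_new, f_new = line_search(
                        C, kappa, objective, f0=f,
                        max_n=cfg.line_search_max_n)
                    if ls_n > 0:
                        U_step = orthogonal_exponential(kappa)
                        for _ in range(ls_n):
                            U_total = U_total @ U_step
                        C = C_new
                        moved = True
                        break
                if moved:
                    break
            trace.append(IterationRecord(it, f, gmax, h, lam, 0, ls_n if moved else 0))
            if callback:
                callback(trace[-1])
            if not moved:
                converged = True   # numerically flat in every tested direction
                break
            continue
        grad = Kappa(gfull[iu], n)
        diag = Kappa(state.hessian_diagonal_full()[iu], n)

        accepted = False
        mu, n_micro, ls_n = 0.0, 0, 0
        for _reject in range(25):
            try:
                sol = solve_step(grad, state.hessian_apply, diag, h, cfg)
            except StepFailure:
                if h <= H_MIN * 1.0001:
                    break
                h = max(cfg.shrink * h, H_MIN)
                continue
            kappa = sol.kappa
            ls_n, C_new, f_new = line_search(C, kappa, objective, f0=f,
                                             max_n=cfg.line_search_max_n)
            if ls_n == 0:
                if h <= H_MIN * 1.0001:
                    break
                h = max(0.5 * h, H_MIN)
                continue
            mu, n_micro = sol.mu, sol.micro_iters
            Hk = state.hessian_apply(kappa)[iu]
            predicted = float(grad.values @ kappa.values
                              + 0.5 * kappa.values @ Hk)
            if predicted < 0:
                hit = kappa.norm >= 0.9 * h
                h = update_trust_radius(h, predicted, f_new - f, cfg,
                                        hit_boundary=hit)
            U_step = orthogonal_exponential(kappa)
            for _ in range(ls_n):
                U_total = U_total @ U_step
            C = C_new
            accepted = True
            break
        trace.append(IterationRecord(it, f, gmax, h, mu, n_micro, ls_n))
        if callback:
            callback(trace[-1])
        if not accepted:
            break
    return LocalizationResult(U_total=U_total, C_localized=C, trace=trace,
                              converged=converged)


# ---------------------------------------------------------------------------
# trace export
# ---------------------------------------------------------------------------

_TRACE_FIELDS = ("macro_index", "f_value", "max_grad", "h", "mu",
                 "n_micro", "line_search_n")


def trace_to_jsonl(trace, path) -> None:
    with open(path, "w") as fh:
        for rec in trace:
            fh.write(json.dumps({k: getattr(rec, k) for k in _TRACE_FIELDS}) + "\n")


def trace_to_csv(trace, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_TRACE_FIELDS)
        for rec in trace:
            w.writerow([getattr(rec, k) for k in _TRACE_FIELDS])


__all__ = [
    "AugHessSolution", "IterationRecord", "LocalizationResult", "StepFailure",
    "TrustConfig", "line_search", "localize", "orthogonal_exponential",
    "solve_step", "trace_to_csv", "trace_to_jsonl", "update_trust_radius",
]
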