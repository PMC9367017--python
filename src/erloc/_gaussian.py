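"""Compact McMurchie-Davidson Gaussian integral engine.

Evaluates overlap, kinetic, nuclear-attraction, Cartesian multipole moment
(x, y, z, x^2, y^2, z^2) and electron-repulsion integrals over contracted
spherical-harmonic Gaussian shells with angular momentum up to d.

All integrals are computed over unnormalized Cartesian primitives via 1-D
Hermite expansion coefficients E_t^{ij} and the Hermite Coulomb tensor
R_{tuv}; primitive normalization (in the (l,0,0) convention), contraction
normalization and the Cartesian->real-spherical transformation are folded in
afterwards.  Lengths in bohr, energies in hartree throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gamma, gammainc

_DFACT = [1.0, 1.0, 3.0, 15.0, 105.0]  # (2l-1)!!

# Cartesian component exponent triples, alphabetical within each l
CART_COMPONENTS = {
    0: [(0, 0, 0)],
    1: [(1, 0, 0), (0, 1, 0), (0, 0, 1)],
    2: [(2, 0, 0), (1, 1, 0), (1, 0, 1), (0, 2, 0), (0, 1, 1), (0, 0, 2)],
}

_SQ3 = math.sqrt(3.0)
# rows: real spherical functions, columns: Cartesian components above.
# d ordering follows the Molden convention: d0, d+1, d-1, d+2, d-2.
SPH_COEF = {
    0: np.array([[1.0]]),
    1: np.eye(3),
    2: np.array(
        [
            #  xx     xy    xz     yy    yz    zz
            [-0.5, 0.0, 0.0, -0.5, 0.0, 1.0],       # d0  ~ (2z^2-x^2-y^2)/2
            [0.0, 0.0, _SQ3, 0.0, 0.0, 0.0],        # d+1 ~ sqrt(3) xz
            [0.0, 0.0, 0.0, 0.0, _SQ3, 0.0],        # d-1 ~ sqrt(3) yz
            [_SQ3 / 2, 0.0, 0.0, -_SQ3 / 2, 0.0, 0.0],  # d+2
            [0.0, _SQ3, 0.0, 0.0, 0.0, 0.0],        # d-2 ~ sqrt(3) xy
        ]
    ),
}


def primitive_norm(alpha: float, l: int) -> float:
    """Norm of the unnormalized Cartesian primitive x^l exp(-alpha r^2)."""
    return (2.0 * alpha / math.pi) ** 0.75 * (4.0 * alpha) ** (l / 2.0) / math.sqrt(_DFACT[l])


@dataclass
class Shell:
    """One contracted spherical shell on a center.

    ``coeffs`` are effective primitive coefficients: published contraction
    coefficients times the primitive (l,0,0) norm, rescaled so the contracted
    (l,0,0) Cartesian function has unit self-overlap.
    """

    l: int
    center: np.ndarray
    exps: np.ndarray
    coeffs: np.ndarray
    sph_off: int = 0
    cart_off: int = 0

    @property
    def n_sph(self) -> int:
        return 2 * self.l + 1

    @property
    def n_cart(self) -> int:
        return len(CART_COMPONENTS[self.l])


def make_shell(l: int, center, exps, coeffs) -> Shell:
    exps = np.asarray(exps, dtype=float)
    raw = np.asarray(coeffs, dtype=float)
    eff = raw * np.array([primitive_norm(a, l) for a in exps])
    # contracted self-overlap of the (l,0,0) Cartesian function
    pa, pb = np.meshgrid(exps, exps, indexing="ij")
    p = pa + pb
    o = (math.pi / p) ** 1.5 * _DFACT[l] / (2.0 * p) ** l
    s = eff @ o @ eff
    return Shell(l=l, center=np.asarray(center, dtype=float), exps=exps, coeffs=eff / math.sqrt(s))


# ---------------------------------------------------------------------------
# Hermite expansion coefficients
# ---------------------------------------------------------------------------

def _e_tables(la: int, lb: int, a, b, ax: float, bx: float):
    """E_t^{ij} for one Cartesian direction, vectorized over primitive pairs.

    a, b: flattened exponent arrays (K,); returns array (K, la+1, lb+1, la+lb+1).
    The Gaussian product prefactor exp(-mu Xab^2) is folded into E_0^{00}.
    """
    K = a.shape[0]
    p = a + b
    mu = a * b / p
    xab = ax - bx
    xpa = -(b / p) * xab
    xpb = (a / p) * xab
    inv2p = 0.5 / p
    nt = la + lb + 1
    E = np.zeros((K, la + 1, lb + 1, nt))
    E[:, 0, 0, 0] = np.exp(-mu * xab * xab)
    for i in range(la + 1):
        for j in range(lb + 1):
            if i == 0 and j == 0:
                continue
            if j == 0:
                src = E[:, i - 1, 0]
                x = xpa
            else:
                src = E[:, i, j - 1]
                x = xpb
            dst = E[:, i, j]
            for t in range(i + j + 1):
                v = x * src[:, t]
                if t > 0:
                    v = v + inv2p * src[:, t - 1]
                if t + 1 <= i + j - 1:
                    v = v + (t + 1) * src[:, t + 1]
                dst[:, t] = v
    return E


@dataclass
class ShellPair:
    sa: Shell
    sb: Shell
    p: np.ndarray          # (K,) combined exponents
    P: np.ndarray          # (K,3) product centers
    cc: np.ndarray         # (K,) products of effective coefficients
    E: list = field(default_factory=list)        # per-direction E tables
    herm: np.ndarray | None = None  # (K, nca*ncb, (Lab+1)^3) bra Hermite tensor
    herm_support: list = field(default_factory=list)  # nonzero (t,u,v) grid points
    q_max: float = 0.0     # Cauchy-Schwarz bound sqrt(max (ab|ab))

    @property
    def lab(self) -> int:
        return self.sa.l + self.sb.l


def make_shell_pair(sa: Shell, sb: Shell, with_hermite: bool = True) -> ShellPair:
    a = np.repeat(sa.exps, len(sb.exps))
    b = np.tile(sb.exps, len(sa.exps))
    cc = np.repeat(sa.coeffs, len(sb.coeffs)) * np.tile(sb.coeffs, len(sa.coeffs))
    p = a + b
    P = (a[:, None] * sa.center[None, :] + b[:, None] * sb.center[None, :]) / p[:, None]
    E = [_e_tables(sa.l, sb.l, a, b, sa.center[d], sb.center[d]) for d in range(3)]
    sp = ShellPair(sa=sa, sb=sb, p=p, P=P, cc=cc, E=E)
    if with_hermite:
        sp.herm = _bra_hermite(sp)
        g = sa.l + sb.l + 1
        cube = np.abs(sp.herm).sum(axis=(0, 1)).reshape(g, g, g)
        sp.herm_support = [tuple(int(x) for x in idx)
                           for idx in np.argwhere(cube != 0.0)]
    return sp


def _bra_hermite(sp: ShellPair) -> np.ndarray:
    """Combined 3-D Hermite tensor over Cartesian pairs, grid (Lab+1)^3."""
    la, lb = sp.sa.l, sp.sb.l
    L = la + lb
    K = sp.p.shape[0]
    ca = CART_COMPONENTS[la]
    cb = CART_COMPONENTS[lb]
    out = np.zeros((K, len(ca) * len(cb), (L + 1) ** 3))
    g = L + 1
    for ia, (ax, ay, az) in enumerate(ca):
        for ib, (bx, by, bz) in enumerate(cb):
            ex = sp.E[0][:, ax, bx, : ax + bx + 1]
            ey = sp.E[1][:, ay, by, : ay + by + 1]
            ez = sp.E[2][:, az, bz, : az + bz + 1]
            blk = ex[:, :, None, None] * ey[:, None, :, None] * ez[:, None, None, :]
            cube = np.zeros((K, g, g, g))
            cube[:, : ax + bx + 1, : ay + by + 1, : az + bz + 1] = blk
            out[:, ia * len(cb) + ib] = cube.reshape(K, -1)
    return out


# ---------------------------------------------------------------------------
# Boys function and Hermite Coulomb tensor
# ---------------------------------------------------------------------------

def boys(nmax: int, T: np.ndarray) -> np.ndarray:
    """F_n(T) for n = 0..nmax; returns (nmax+1,) + T.shape.

    F_nmax is evaluated through the regularized lower incomplete gamma
    function (small-T arguments by series), lower orders by stable downward
    recursion.
    """
    T = np.asarray(T, dtype=float)
    out = np.empty((nmax + 1,) + T.shape)
    a = nmax + 0.5
    small = T < 1e-12
    Ts = np.where(small, 1.0, T)
    top = gamma(a) * gammainc(a, Ts) / (2.0 * Ts ** a)
    series = 1.0 / (2 * nmax + 1) - T / (2 * nmax + 3)
    out[nmax] = np.where(small, series, top)
    if nmax > 0:
        eT = np.exp(-T)
        for n in range(nmax, 0, -1):
            out[n - 1] = (2.0 * T * out[n] + eT) / (2 * n - 1)
    return out


def hermite_r(L: int, alpha: np.ndarray, PQ: np.ndarray) -> np.ndarray:
    """Hermite Coulomb tensor R^0_{tuv} on the full (L+1)^3 grid.

    alpha: (K,), PQ: (K,3).  Returns (K, L+1, L+1, L+1); entries with
    t+u+v > L are left zero (they are never referenced).
    """
    K = alpha.shape[0]
    T = alpha * np.einsum("kd,kd->k", PQ, PQ)
    F = boys(L, T)
    g = L + 1
    # Rn[n, t, u, v, k]
    Rn = np.zeros((g, g, g, g, K))
    fac = np.ones(K)
    for n in range(g):
        Rn[n, 0, 0, 0] = fac * F[n]
        fac = fac * (-2.0 * alpha)
    X, Y, Z = PQ[:, 0], PQ[:, 1], PQ[:, 2]
    for t in range(1, g):
        for n in range(g - t):
            v = X * Rn[n + 1, t - 1, 0, 0]
            if t >= 2:
                v = v + (t - 1) * Rn[n + 1, t - 2, 0, 0]
            Rn[n, t, 0, 0] = v
    for u in range(1, g):
        for t in range(g - u):
            for n in range(g - t - u):
                v = Y * Rn[n + 1, t, u - 1, 0]
                if u >= 2:
                    v = v + (u - 1) * Rn[n + 1, t, u - 2, 0]
                Rn[n, t, u, 0] = v
    for w in range(1, g):
        for t in range(g - w):
            for u in range(g - t - w):
                for n in range(g - t - u - w):
                    v = Z * Rn[n + 1, t, u, w - 1]
                    if w >= 2:
                        v = v + (w - 1) * Rn[n + 1, t, u, w - 2]
                    Rn[n, t, u, w] = v
    return np.moveaxis(Rn[0], -1, 0)


# ---------------------------------------------------------------------------
# One-electron integrals
# ---------------------------------------------------------------------------

def _sph_block(sa: Shell, sb: Shell, cart_block: np.ndarray) -> np.ndarray:
    return SPH_COEF[sa.l] @ cart_block @ SPH_COEF[sb.l].T


def _overlap_1d(E, i, j, p):
    return E[:, i, j, 0] * np.sqrt(np.pi / p)


def _one_electron_blocks(sa: Shell, sb: Shell):
    """Per-pair data for overlap/kinetic/moment assembly (extended E tables)."""
    a = np.repeat(sa.exps, len(sb.exps))
    b = np.tile(sb.exps, len(sa.exps))
    cc = np.repeat(sa.coeffs, len(sb.coeffs)) * np.tile(sb.coeffs, len(sa.coeffs))
    p = a + b
    # raise ket angular momentum by 2 to reach kinetic and second moments
    E = [_e_tables(sa.l, sb.l + 2, a, b, sa.center[d], sb.center[d]) for d in range(3)]
    return a, b, cc, p, E


def one_electron_matrices(shells, charges=None, centers=None, want=("S", "T", "V", "M")):
    """Overlap S, kinetic T, nuclear attraction V and moment matrices.

    Moments are x, y, z, xx, yy, zz about the coordinate origin.
    Returns dict of (n_sph, n_sph) arrays.
    """
    n = sum(sh.n_sph for sh in shells)
    res = {}
    if "S" in want:
        res["S"] = np.zeros((n, n))
    if "T" in want:
        res["T"] = np.zeros((n, n))
    if "V" in want:
        res["V"] = np.zeros((n, n))
    if "M" in want:
        for key in ("x", "y", "z", "xx", "yy", "zz"):
            res[key] = np.zeros((n, n))
    for isa, sa in enumerate(shells):
        for sb in shells[: isa + 1]:
            a, b, cc, p, E = _one_electron_blocks(sa, sb)
            ca = CART_COMPONENTS[sa.l]
            cb = CART_COMPONENTS[sb.l]
            Bc = sb.center
            s1 = {}

            def ov(d, i, j):
                if (d, i, j) not in s1:
                    s1[(d, i, j)] = _overlap_1d(E[d], i, j, p)
                return s1[(d, i, j)]

            blocks = {k: np.zeros((len(ca), len(cb))) for k in res if k not in ("S", "T", "V")}
            Sb = np.zeros((len(ca), len(cb)))
            Tb = np.zeros((len(ca), len(cb)))
            Vb = np.zeros((len(ca), len(cb)))
            if "V" in want:
                Rv = {}
                PQ = {}
            for ia, A in enumerate(ca):
                for ib, B in enumerate(cb):
                    sx = ov(0, A[0], B[0])
                    sy = ov(1, A[1], B[1])
                    sz = ov(2, A[2], B[2])
                    if "S" in want:
                        Sb[ia, ib] = cc @ (sx * sy * sz)
                    if "T" in want:
                        tt = 0.0
                        for d, (ai, bi) in enumerate(zip(A, B)):
                            td = (
                                -2.0 * b * b * ov(d, ai, bi + 2)
                                + b * (2 * bi + 1) * ov(d, ai, bi)
                            )
                            if bi >= 2:
                                td = td - 0.5 * bi * (bi - 1) * ov(d, ai, bi - 2)
                            o = [sx, sy, sz]
                            o[d] = td
                            tt = tt + cc @ (o[0] * o[1] * o[2])
                        Tb[ia, ib] = tt
                    if "M" in want:
                        for d, key1, key2 in ((0, "x", "xx"), (1, "y", "yy"), (2, "z", "zz")):
                            o1 = ov(d, A[d], B[d] + 1) + Bc[d] * ov(d, A[d], B[d])
                            o2 = (
                                ov(d, A[d], B[d] + 2)
                                + 2.0 * Bc[d] * ov(d, A[d], B[d] + 1)
                                + Bc[d] ** 2 * ov(d, A[d], B[d])
                            )
                            o = [sx, sy, sz]
                            oo = list(o)
                            o[d] = o1
                            oo[d] = o2
                            blocks[key1][ia, ib] = cc @ (o[0] * o[1] * o[2])
                            blocks[key2][ia, ib] = cc @ (oo[0] * oo[1] * oo[2])
            if "V" in want:
                L = sa.l + sb.l
                P = (a[:, None] * sa.center[None, :] + b[:, None] * Bc[None, :]) / p[:, None]
                for Zc, C in zip(charges, centers):
                    R = hermite_r(L, p, P - C[None, :])
                    pref = -Zc * 2.0 * np.pi / p
                    for ia, A in enumerate(ca):
                        for ib, B in enumerate(cb):
                            acc = np.zeros(len(p))
                            for t in range(A[0] + B[0] + 1):
                                ex = E[0][:, A[0], B[0], t]
                                for u in range(A[1] + B[1] + 1):
                                    ey = E[1][:, A[1], B[1], u]
                                    for w in range(A[2] + B[2] + 1):
                                        ez = E[2][:, A[2], B[2], w]
                                        acc += ex * ey * ez * R[:, t, u, w]
                            Vb[ia, ib] += cc @ (pref * acc)

            def put(mat, blk):
                sb_blk = _sph_block(sa, sb, blk)
                mat[sa.sph_off: sa.sph_off + sa.n_sph, sb.sph_off: sb.sph_off + sb.n_sph] = sb_blk
                if sa is not sb:
                    mat[sb.sph_off: sb.sph_off + sb.n_sph, sa.sph_off: sa.sph_off + sa.n_sph] = sb_blk.T

            if "S" in want:
                put(res["S"], Sb)
            if "T" in want:
                put(res["T"], Tb)
            if "V" in want:
                put(res["V"], Vb)
            if "M" in want:
                for key in ("x", "y", "z", "xx", "yy", "zz"):
                    put(res[key], blocks[key])
    return res


# ---------------------------------------------------------------------------
# Electron repulsion integrals
# ---------------------------------------------------------------------------

def _eri_quartet(sp1: ShellPair, sp2: ShellPair) -> np.ndarray:
    """Spherical ERI block ((ab|cd)) of shape (na*nb, nc*nd)."""
    L1, L2 = sp1.lab, sp2.lab
    L = L1 + L2
    K1 = sp1.p.shape[0]
    K2 = sp2.p.shape[0]
    p = sp1.p[:, None]
    q = sp2.p[None, :]
    alpha = (p * q / (p + q)).ravel()
    PQ = (sp1.P[:, None, :] - sp2.P[None, :, :]).reshape(-1, 3)
    R = hermite_r(L, alpha, PQ)  # (K1*K2, L+1, L+1, L+1)
    pref = (
        2.0 * np.pi ** 2.5 / (p * q * np.sqrt(p + q))
        * sp1.cc[:, None] * sp2.cc[None, :]
    ).ravel()
    g1 = L1 + 1
    npair2 = sp2.herm.shape[1]
    # contract ket Hermite indices against shifted R slices
    I = np.zeros((K1, K2, npair2, g1, g1, g1))
    Rr = R.reshape(K1, K2, L + 1, L + 1, L + 1)
    ket = sp2.herm.reshape(K2, npair2, L2 + 1, L2 + 1, L2 + 1)
    for tk in range(L2 + 1):
        for uk in range(L2 + 1):
            for wk in range(L2 + 1):
                e = ket[:, :, tk, uk, wk]
                if not np.any(e):
                    continue
                sgn = -1.0 if (tk + uk + wk) % 2 else 1.0
                Rsl = Rr[:, :, tk: tk + g1, uk: uk + g1, wk: wk + g1]
                I += (sgn * e)[None, :, :, None, None, None] * Rsl[:, :, None]
    I = I.reshape(K1, K2, npair2 * g1 ** 3)
    # J[k1, q, h] = sum_k2 pref[k1,k2] I[k1,k2,q,h]; then contract the bra
    J = np.matmul(pref.reshape(K1, 1, K2), I).reshape(K1, npair2, g1 ** 3)
    out = np.matmul(sp1.herm, J.transpose(0, 2, 1)).sum(axis=0)
    na, nb = sp1.sa.n_cart, sp1.sb.n_cart
    nc, nd = sp2.sa.n_cart, sp2.sb.n_cart
    if max(sp1.sa.l, sp1.sb.l, sp2.sa.l, sp2.sb.l) <= 1:
        return out  # s/p spherical transform is the identity
    ca = SPH_COEF[sp1.sa.l]
    cb = SPH_COEF[sp1.sb.l]
    cc_ = SPH_COEF[sp2.sa.l]
    cd = SPH_COEF[sp2.sb.l]
    blk = out.reshape(na, nb, nc, nd)
    blk = np.tensordot(ca, blk, axes=(1, 0))
    blk = np.tensordot(cb, blk, axes=(1, 1)).transpose(1, 0, 2, 3)
    blk = np.tensordot(blk, cc_, axes=(2, 1)).transpose(0, 1, 3, 2)
    blk = np.tensordot(blk, cd, axes=(3, 1))
    return blk.reshape(ca.shape[0] * cb.shape[0], cc_.shape[0] * cd.shape[0])


def _eri_sig_batch(bra_pairs: list, ket_pairs: list,
                   bi: np.ndarray, qi: np.ndarray) -> np.ndarray:
    """Spherical ERI blocks for many (bra, ket) combinations at once.

    All bra pairs share one (l_a, l_b, K1) signature and all ket pairs one
    (l_c, l_d, K2) signature; ``bi``/``qi`` index the combinations to
    evaluate.  Returns (NC, n_sph_ab, n_sph_cd).
    """
    sp1 = bra_pairs[0]
    sp2 = ket_pairs[0]
    L1, L2 = sp1.lab, sp2.lab
    L = L1 + L2
    g1 = L1 + 1
    K1 = sp1.p.shape[0]
    K2 = sp2.p.shape[0]
    NC = bi.size
    p1 = np.stack([b.p for b in bra_pairs])[bi]        # (NC, K1)
    P1 = np.stack([b.P for b in bra_pairs])[bi]        # (NC, K1, 3)
    cc1 = np.stack([b.cc for b in bra_pairs])[bi]
    p2 = np.stack([k.p for k in ket_pairs])[qi]
    P2 = np.stack([k.P for k in ket_pairs])[qi]
    cc2 = np.stack([k.cc for k in ket_pairs])[qi]
    psum = p1[:, :, None] + p2[:, None, :]             # (NC, K1, K2)
    alpha = p1[:, :, None] * p2[:, None, :] / psum
    PQ = P1[:, :, None, :] - P2[:, None, :, :]
    R = hermite_r(L, alpha.ravel(), PQ.reshape(-1, 3))
    Rr = R.reshape(NC, K1, K2, L + 1, L + 1, L + 1)
    pref = (2.0 * np.pi ** 2.5 / (p1[:, :, None] * p2[:, None, :] * np.sqrt(psum))
            * cc1[:, :, None] * cc2[:, None, :])
    npair1 = sp1.herm.shape[1]
    npair2 = sp2.herm.shape[1]
    herm2 = np.stack([k.herm for k in ket_pairs])      # (nk, K2, npair2, g2^3)
    kh = herm2.reshape(len(ket_pairs), K2, npair2, L2 + 1, L2 + 1, L2 + 1)[qi]
    grid = sorted({pt for k in ket_pairs for pt in k.herm_support})
    I = np.zeros((NC, K1, K2, npair2, g1, g1, g1))
    for tk, uk, wk in grid:
        e = kh[:, :, :, tk, uk, wk]                    # (NC, K2, npair2)
        sgn = -1.0 if (tk + uk + wk) % 2 else 1.0
        Rsl = Rr[:, :, :, tk: tk + g1, uk: uk + g1, wk: wk + g1]
        I += (sgn * e)[:, None, :, :, None, None, None] * Rsl[:, :, :, None]
    I = I.reshape(NC * K1, K2, npair2 * g1 ** 3)
    J = np.matmul(pref.reshape(NC * K1, 1, K2), I)
    J = J.reshape(NC, K1, npair2, g1 ** 3)
    herm1 = np.stack([b.herm for b in bra_pairs])[bi]  # (NC, K1, npair1, g1^3)
    A1 = herm1.transpose(0, 2, 1, 3).reshape(NC, npair1, K1 * g1 ** 3)
    A2 = J.transpose(0, 2, 1, 3).reshape(NC, npair2, K1 * g1 ** 3)
    out = np.matmul(A1, A2.transpose(0, 2, 1))         # (NC, npair1, npair2)
    if max(sp1.sa.l, sp1.sb.l, sp2.sa.l, sp2.sb.l) <= 1:
        return out
    ca = SPH_COEF[sp1.sa.l]
    cb = SPH_COEF[sp1.sb.l]
    cc_ = SPH_COEF[sp2.sa.l]
    cd = SPH_COEF[sp2.sb.l]
    na, nb = sp1.sa.n_cart, sp1.sb.n_cart
    nc, nd = sp2.sa.n_cart, sp2.sb.n_cart
    blk = out.reshape(NC, na, nb, nc, nd)
    blk = np.tensordot(blk, ca, axes=(1, 1))
    blk = np.tensordot(blk, cb, axes=(1, 1))
    blk = np.tensordot(blk, cc_, axes=(1, 1))
    blk = np.tensordot(blk, cd, axes=(1, 1))
    return blk.reshape(NC, ca.shape[0] * cb.shape[0], cc_.shape[0] * cd.shape[0])


def _pack_index(i: np.ndarray, j: np.ndarray) -> np.ndarray:
    return i * (i + 1) // 2 + j


class ERIEngine:
    """Shell-pair driven ERI evaluator over packed symmetric AO pair indices.

    Pairs are packed as (i, j) with i >= j, index i(i+1)/2 + j.  Supports a
    full in-core packed matrix for modest systems and on-demand row blocks
    (for pivoted Cholesky) for larger ones.
    """

    def __init__(self, shells, screen: float = 1e-12):
        self.shells = list(shells)
        self.n_sph = sum(sh.n_sph for sh in self.shells)
        self.n_pair = self.n_sph * (self.n_sph + 1) // 2
        self.screen = screen
        self.pairs = []
        for ia in range(len(self.shells)):
            for ib in range(ia + 1):
                self.pairs.append(make_shell_pair(self.shells[ia], self.shells[ib]))
        # packed-index bookkeeping per shell pair
        self._rows = []
        self._sel = []
        for sp in self.pairs:
            ia = np.arange(sp.sa.sph_off, sp.sa.sph_off + sp.sa.n_sph)
            ib = np.arange(sp.sb.sph_off, sp.sb.sph_off + sp.sb.n_sph)
            I = np.repeat(ia, len(ib))
            Jj = np.tile(ib, len(ia))
            keep = I >= Jj
            self._sel.append(keep)
            self._rows.append(_pack_index(I[keep], Jj[keep]))
        self._pair_of_packed = np.empty(self.n_pair, dtype=int)
        self._pos_in_pair = np.empty(self.n_pair, dtype=int)
        for isp, rows in enumerate(self._rows):
            self._pair_of_packed[rows] = isp
            self._pos_in_pair[rows] = np.arange(len(rows))
        self._diag = None
        self._screen_bounds()

    def _screen_bounds(self):
        for sp in self.pairs:
            blk = _eri_quartet(sp, sp)
            d = np.abs(np.diag(blk))
            sp.q_max = float(np.sqrt(d.max())) if d.size else 0.0

    def diagonal(self) -> np.ndarray:
        """(alpha beta|alpha beta) over packed pairs."""
        if self._diag is None:
            d = np.empty(self.n_pair)
            for isp, sp in enumerate(self.pairs):
                blk = _eri_quartet(sp, sp)
                d[self._rows[isp]] = np.diag(blk)[self._sel[isp]]
            self._diag = d
        return self._diag.copy()

    def _signature(self, isp: int):
        sp = self.pairs[isp]
        return (sp.sa.l, sp.sb.l, sp.p.shape[0], sp.sa is sp.sb)

    def _sig_groups(self):
        if not hasattr(self, "_sig_cache"):
            groups = {}
            for isp in range(len(self.pairs)):
                groups.setdefault(self._signature(isp), []).append(isp)
            self._sig_cache = groups
        return self._sig_cache

    def _scatter_targets(self, group):
        """Packed-row index matrix (len(group), r) for a signature group."""
        return np.array([self._rows[i] for i in group])

    def _combos(self, group1, group2, same):
        """Surviving (local bra, local ket) combination index arrays."""
        q1 = np.array([self.pairs[i].q_max for i in group1])
        q2 = np.array([self.pairs[i].q_max for i in group2])
        if same:
            bi, qi = np.tril_indices(len(group1))
        else:
            bi, qi = np.meshgrid(np.arange(len(group1)), np.arange(len(group2)),
                                 indexing="ij")
            bi, qi = bi.ravel(), qi.ravel()
        keep = q1[bi] * q2[qi] >= self.screen
        return bi[keep], qi[keep]

    def full_packed(self) -> np.ndarray:
        """Dense packed ERI pair matrix (n_pair, n_pair)."""
        V = np.zeros((self.n_pair, self.n_pair))
        sigs = list(self._sig_groups().items())
        for a in range(len(sigs)):
            sig1, group1 = sigs[a]
            bra_pairs = [self.pairs[i] for i in group1]
            rows1 = self._scatter_targets(group1)
            sel1 = self._sel[group1[0]]
            for b in range(a + 1):
                sig2, group2 = sigs[b]
                ket_pairs = [self.pairs[i] for i in group2]
                rows2 = self._scatter_targets(group2)
                sel2 = self._sel[group2[0]]
                bi, qi = self._combos(group1, group2, same=(a == b))
                if bi.size == 0:
                    continue
                K1 = bra_pairs[0].p.shape[0]
                K2 = ket_pairs[0].p.shape[0]
                npair2 = ket_pairs[0].herm.shape[1]
                g1c = (bra_pairs[0].lab + 1) ** 3
                chunk = max(1, int(8e6 // max(K1 * K2 * npair2 * g1c, 1)))
                for i0 in range(0, bi.size, chunk):
                    bs, qs = bi[i0: i0 + chunk], qi[i0: i0 + chunk]
                    blocks = _eri_sig_batch(bra_pairs, ket_pairs, bs, qs)
                    blocks = blocks[:, sel1][:, :, sel2]
                    RI = rows1[bs]
                    CI = rows2[qs]
                    V[RI[:, :, None], CI[:, None, :]] = blocks
                    V[CI[:, :, None], RI[:, None, :]] = blocks.transpose(0, 2, 1)
        return V

    def row_block(self, isp: int) -> np.ndarray:
        """All ERI columns for the packed pairs belonging to shell pair isp."""
        sp1 = self.pairs[isp]
        sel1 = self._sel[isp]
        out = np.zeros((len(self._rows[isp]), self.n_pair))
        for sig2, group2 in self._sig_groups().items():
            ket_pairs = [self.pairs[i] for i in group2]
            rows2 = self._scatter_targets(group2)
            sel2 = self._sel[group2[0]]
            q2 = np.array([self.pairs[i].q_max for i in group2])
            keep = np.where(sp1.q_max * q2 >= self.screen)[0]
            if keep.size == 0:
                continue
            K1 = sp1.p.shape[0]
            K2 = ket_pairs[0].p.shape[0]
            npair2 = ket_pairs[0].herm.shape[1]
            g1c = (sp1.lab + 1) ** 3
            chunk = max(1, int(8e6 // max(K1 * K2 * npair2 * g1c, 1)))
            for i0 in range(0, keep.size, chunk):
                qs = keep[i0: i0 + chunk]
                bs = np.zeros(qs.size, dtype=int)
                blocks = _eri_sig_batch([sp1], ket_pairs, bs, qs)
                blocks = blocks[:, sel1][:, :, sel2]
                CI = rows2[qs]
                for q in range(qs.size):
                    out[:, CI[q]] = blocks[q]
        return out

    def column(self, packed_index: int) -> np.ndarray:
        isp = int(self._pair_of_packed[packed_index])
        return self.row_block(isp)[self._pos_in_pair[packed_index]]


def packed_to_square(V: np.ndarray, n: int) -> np.ndarray:
    """Packed pair matrix -> full 4-index tensor (n,n,n,n). Oracle use only."""
    npair = n * (n + 1) // 2
    assert V.shape == (npair, npair)
    full = np.empty((n, n, n, n))
    idx = np.zeros((n, n), dtype=int)
    k = 0
    for i in range(n):
        for j in range(i + 1):
            idx[i, j] = idx[j, i] = _pack_index(np.array(i), np.array(j))
    full = V[idx.reshape(-1)][:, idx.reshape(-1)].reshape(n, n, n, n)
    return full
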