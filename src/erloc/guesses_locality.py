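"""Initial-guess generators and orbital-locality diagnostics.

Guesses never change the space that is spanned: the metric-weighted
projector C C^T is preserved to tight tolerance.  Locality is measured by
the second-moment orbital spread

    sigma2_p = sqrt( sum_u (<p|u^2|p> - <p|u|p>^2) ),  u in {x, y, z},

in bohr, summarized by its maximum (the least local orbital, a conservative
measure) and its mean over the set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mol_integrals import MOCoefficients
from .objectives import fb_objective
from .trust_region import TrustConfig, localize


class RankDeficiencyError(RuntimeError):
    pass


class IntegralConsistencyError(RuntimeError):
    pass


@dataclass
class SpreadReport:
    sigma2: np.ndarray       # per-orbital spread (au)
    centroids: np.ndarray    # per-orbital <r> (au), shape (n, 3)

    @property
    def sigma2_max(self) -> float:
        return float(self.sigma2.max())

    @property
    def sigma2_avg(self) -> float:
        return float(self.sigma2.mean())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "orbital": np.arange(len(self.sigma2)),
            "centroid_x": self.centroids[:, 0],
            "centroid_y": self.centroids[:, 1],
            "centroid_z": self.centroids[:, 2],
            "sigma2": self.sigma2,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def cholesky_orbital_guess(C_space: MOCoefficients, S: np.ndarray) -> MOCoefficients:
    """Cholesky orbitals: pivoted factorization of the density C C^T.

    The pivoted Cholesky vectors of the one-particle density are local by
    construction (each is anchored on the dominant remaining AO diagonal);
    symmetric (Loewdin) S-orthonormalization then minimally perturbs them.
    The spanned space is unchanged.
    """
    C = C_space.C
    n_ao, n = C.shape
    D = C @ C.T
    diag = np.diag(D).copy()
    V = np.zeros((n_ao, n))
    piv = []
    for k in range(n):
        p = int(np.argmax(diag))
        if diag[p] <= 1e-10:
            raise RankDeficiencyError(
                f"density residual exhausted after {k} of {n} vectors"
            )
        col = D[:, p] - V[:, :k] @ V[p, :k]
        V[:, k] = col / np.sqrt(diag[p])
        diag -= V[:, k] ** 2
        diag[p] = 0.0
        piv.append(p)
    M = V.T @ S @ V
    w, Q = np.linalg.eigh(M)
    if w.min() <= 1e-12:
        raise RankDeficiencyError("Cholesky vectors metrically rank deficient")
    C_out = V @ (Q / np.sqrt(w)) @ Q.T
    return MOCoefficients(C_out, space=C_space.space, source="guess")


def foster_boys_guess(ints, C_space: MOCoefficients,
                      cfg: TrustConfig | None = None) -> MOCoefficients:
    """Foster-Boys orbitals (variance-sum minimized) from a Cholesky start."""
    if C_space.n == 1:
        return C_space
    start = cholesky_orbital_guess(C_space, ints.overlap)
    res = localize(start, fb_objective(ints), cfg or TrustConfig())
    out = res.C_localized
    return MOCoefficients(out.C, space=C_space.space, source="guess")


def orbital_spreads(ints, C: MOCoefficients) -> SpreadReport:
    """Second-moment spreads and centroids of the orbital set."""
    Cm = C.C if hasattr(C, "C") else np.asarray(C)
    pm = ints.position_moments
    cents = np.stack([np.einsum("ap,ab,bp->p", Cm, pm[u], Cm) for u in "xyz"], axis=1)
    second = np.stack(
        [np.einsum("ap,ab,bp->p", Cm, pm[u], Cm) for u in ("xx", "yy", "zz")], axis=1
    )
    var = (second - cents ** 2).sum(axis=1)
    if var.min() < -1e-10:
        raise IntegralConsistencyError(f"negative orbital variance {var.min():.3e}")
    sigma2 = np.sqrt(np.clip(var, 0.0, None))
    return SpreadReport(sigma2=sigma2, centroids=cents)


def canonicalize_output(C: MOCoefficients, report: SpreadReport,
                        tol: float = 1e-6) -> MOCoefficients:
    """Deterministic orbital ordering and sign convention.

    Orbitals are sorted by centroid lexicographically (x, then y, then z, on
    a ``tol`` grid; exactly degenerate centroids keep input order), and each
    column's largest-magnitude coefficient is made positive.  Idempotent.
    """
    cents = np.round(report.centroids / tol).astype(np.int64)
    order = np.lexsort((cents[:, 2], cents[:, 1], cents[:, 0]))
    Cm = C.C[:, order]
    for j in range(Cm.shape[1]):
        i = int(np.argmax(np.abs(Cm[:, j])))
        if Cm[i, j] < 0:
            Cm[:, j] = -Cm[:, j]
    return MOCoefficients(Cm, space=C.space, source=C.source)


__all__ = [
    "IntegralConsistencyError", "RankDeficiencyError", "SpreadReport",
    "canonicalize_output", "cholesky_orbital_guess", "foster_boys_guess",
    "orbital_spreads",
]
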