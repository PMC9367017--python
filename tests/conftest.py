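import numpy as np
import pytest

from erloc.cholesky import decompose_eri
from erloc.mol_integrals import BasisSpec, compute_ao_integrals, make_fixture, run_scf


class SystemCache:
    """Session-wide cache of fixture molecules, integrals, SCF and CD results.

    The heavy objects (in-core ERIs, converged SCF orbitals) are computed at
    most once per test session.
    """

    def __init__(self):
        self._mol = {}
        self._ints = {}
        self._scf = {}
        self._chol = {}

    def molecule(self, name, **params):
        key = (name, tuple(sorted(params.items())))
        if key not in self._mol:
            self._mol[key] = make_fixture(name, params)
        return self._mol[key]

    def ints(self, name, basis):
        key = (name, basis)
        if key not in self._ints:
            mol = self.molecule(name)
            spec = BasisSpec.for_molecule(mol, basis)
            self._ints[key] = compute_ao_integrals(mol, spec)
        return self._ints[key]

    def scf(self, name, basis):
        """Returns (ints, occupied, virtual, scf_energy)."""
        key = (name, basis)
        if key not in self._scf:
            ints = self.ints(name, basis)
            occ, vir, e = run_scf(ints.molecule, ints.basis, ints=ints)
            self._scf[key] = (occ, vir, e)
        occ, vir, e = self._scf[key]
        return self.ints(name, basis), occ, vir, e

    def chol(self, name, basis, tau=1e-8):
        key = (name, basis, tau)
        if key not in self._chol:
            self._chol[key] = decompose_eri(self.ints(name, basis), tau=tau)
        return self._chol[key]


@pytest.fixture(scope="session")
def cache():
    return SystemCache()


def mo_eri(ints, C):
    """Quartic-scaling AO->MO transformation of the full ERI tensor."""
    Cm = C.C if hasattr(C, "C") else np.asarray(C)
    g = ints.full_eri()
    for sub in ("ap,abcd->pbcd", "bq,pbcd->pqcd", "cr,pqcd->pqrd", "ds,pqrd->pqrs"):
        g = np.einsum(sub, Cm, g, optimize=True)
    return g
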