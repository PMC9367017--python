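"""Molecules, basis sets, AO integrals and the SCF boundary.

Coordinates are stored in bohr; XYZ input (angstrom) is converted with the
CODATA factor 1.8897261254578281.  All AO integrals are over real
spherical-harmonic Gaussians.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import cached_property

import numpy as np

from . import _basis_data
from ._gaussian import ERIEngine, make_shell, one_electron_matrices, packed_to_square
from ._scf import SCFError, restricted_hartree_fock

BOHR_PER_ANGSTROM = 1.8897261254578281

#: largest AO count for which a dense in-core ERI pair matrix is built
INCORE_AO_LIMIT = 200

_Z = {"H": 1, "He": 2, "Li": 3, "Be": 4, "B": 5, "C": 6, "N": 7, "O": 8, "F": 9, "Ne": 10}


class UnsupportedBasisError(KeyError):
    """Element/basis combination without tabulated shell data."""


class FixtureError(ValueError):
    pass


@dataclass(frozen=True)
class Molecule:
    elements: tuple
    coords: np.ndarray  # (n_atoms, 3), bohr
    charge: int = 0
    spin_multiplicity: int = 1

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "elements", tuple(self.elements))
        if len(self.elements) == 0:
            raise ValueError("empty molecule")
        if coords.shape[0] != len(self.elements):
            raise ValueError("element/coordinate count mismatch")
        if not np.all(np.isfinite(coords)):
            raise ValueError("non-finite coordinates")
        if coords.shape[0] > 1:
            d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
            np.fill_diagonal(d, np.inf)
            if d.min() <= 0.5:
                raise ValueError(f"atoms closer than 0.5 bohr (min {d.min():.3f})")

    @property
    def charges(self):
        return np.array([_Z[e] for e in self.elements], dtype=float)

    @property
    def n_electrons(self) -> int:
        return int(self.charges.sum()) - self.charge

    def nuclear_repulsion(self) -> float:
        z = self.charges
        e = 0.0
        for i in range(len(z)):
            for j in range(i):
                e += z[i] * z[j] / np.linalg.norm(self.coords[i] - self.coords[j])
        return e

    def translated(self, shift) -> "Molecule":
        return Molecule(self.elements, self.coords + np.asarray(shift, dtype=float),
                        self.charge, self.spin_multiplicity)

    def rotated(self, R) -> "Molecule":
        return Molecule(self.elements, self.coords @ np.asarray(R, dtype=float).T,
                        self.charge, self.spin_multiplicity)


@dataclass(frozen=True)
class BasisSpec:
    name: str
    shells_per_element: dict
    spherical: bool = True

    @classmethod
    def for_molecule(cls, molecule: Molecule, name: str) -> "BasisSpec":
        table = {}
        for el in dict.fromkeys(molecule.elements):
            try:
                table[el] = _basis_data.shell_structure(el, name)
            except KeyError as exc:
                raise UnsupportedBasisError(f"no data for {el} in basis {name!r}") from exc
        return cls(name=name, shells_per_element=table)


@dataclass
class MOCoefficients:
    """MO coefficient block; columns are metric-orthonormal orbitals."""

    C: np.ndarray
    space: str = "custom"   # occupied | virtual | custom
    source: str = "guess"   # scf | file | guess

    @property
    def n(self) -> int:
        return self.C.shape[1]

    def rotated(self, U: np.ndarray, source=None) -> "MOCoefficients":
        return MOCoefficients(self.C @ U, space=self.space, source=source or self.source)


@dataclass
class AOIntegrals:
    """AO-basis integrals for one molecule/basis pair."""

    molecule: Molecule
    basis: BasisSpec
    shells: list
    overlap: np.ndarray
    kinetic: np.ndarray
    nuclear: np.ndarray
    position_moments: dict          # keys x,y,z,xx,yy,zz
    _engine: ERIEngine = field(repr=False, default=None)

    @property
    def n_ao(self) -> int:
        return self.overlap.shape[0]

    @property
    def core_hamiltonian(self) -> np.ndarray:
        return self.kinetic + self.nuclear

    @cached_property
    def eri_diagonal(self) -> np.ndarray:
        return self._engine.diagonal()

    def eri_column_provider(self, packed_index: int) -> np.ndarray:
        """Column (alpha beta | . ) of the packed ERI pair matrix."""
        if self.n_ao <= INCORE_AO_LIMIT:
            return self.full_packed_eri()[packed_index].copy()
        return self._engine.column(packed_index)

    @cached_property
    def _packed(self) -> np.ndarray:
        if self.n_ao > INCORE_AO_LIMIT:
            raise MemoryError(
                f"in-core ERI refused for n_ao={self.n_ao} > {INCORE_AO_LIMIT}"
            )
        return self._engine.full_packed()

    def full_packed_eri(self) -> np.ndarray:
        return self._packed

    def full_eri(self) -> np.ndarray:
        """Dense (n,n,n,n) ERI tensor; oracle-scale systems only."""
        return packed_to_square(self._packed, self.n_ao)


def count_basis_functions(molecule: Molecule, basis: BasisSpec) -> int:
    """Number of spherical-harmonic AO basis functions.

    Additive over atoms and independent of the geometry.
    """
    n = 0
    for el in molecule.elements:
        if el not in basis.shells_per_element:
            raise UnsupportedBasisError(f"no shells for element {el}")
        n += sum((2 * l + 1) * cnt for l, cnt in basis.shells_per_element[el])
    return n


def compute_ao_integrals(molecule: Molecule, basis: BasisSpec) -> AOIntegrals:
    """Evaluate all AO integrals the localization pipeline needs."""
    name = basis.name
    if not _basis_data.has_primitives(name):
        raise UnsupportedBasisError(
            f"basis {name!r} has shell metadata only (counting); no primitive data"
        )
    shells = []
    off = 0
    for el, xyz in zip(molecule.elements, molecule.coords):
        for l, exps, coeffs in _basis_data.primitive_shells(el, name):
            sh = make_shell(l, xyz, exps, coeffs)
            sh.sph_off = off
            off += sh.n_sph
            shells.append(sh)
    mats = one_electron_matrices(
        shells, charges=molecule.charges, centers=molecule.coords
    )
    moments = {k: mats[k] for k in ("x", "y", "z", "xx", "yy", "zz")}
    engine = ERIEngine(shells)
    return AOIntegrals(
        molecule=molecule,
        basis=basis,
        shells=shells,
        overlap=mats["S"],
        kinetic=mats["T"],
        nuclear=mats["V"],
        position_moments=moments,
        _engine=engine,
    )


def run_scf(molecule: Molecule, basis: BasisSpec, conv: float = 1e-7,
            ints: AOIntegrals | None = None):
    """Restricted Hartree-Fock; returns (occupied, virtual, scf_energy).

    Convergence is on the max-abs element of the orbital-gradient (DIIS
    error) matrix.  Near-linearly-dependent AO combinations are projected
    out in the orthogonalizer.
    """
    if molecule.spin_multiplicity != 1 or molecule.n_electrons % 2:
        raise ValueError("closed-shell molecules only")
    if ints is None:
        ints = compute_ao_integrals(molecule, basis)
    C, eps, energy = restricted_hartree_fock(ints, conv=conv)
    nocc = molecule.n_electrons // 2
    occ = MOCoefficients(C[:, :nocc], space="occupied", source="scf")
    vir = MOCoefficients(C[:, nocc:], space="virtual", source="scf")
    return occ, vir, energy


# ---------------------------------------------------------------------------
# Fixture molecules
# ---------------------------------------------------------------------------

_TET = math.degrees(math.acos(-1.0 / 3.0))  # 109.4712...


def _deg(a):
    return math.radians(a)


def _water() -> Molecule:
    r = 0.9572 * BOHR_PER_ANGSTROM
    th = _deg(104.52)
    coords = np.array([
        [0.0, 0.0, 0.0],
        [r * math.sin(th / 2), 0.0, r * math.cos(th / 2)],
        [-r * math.sin(th / 2), 0.0, r * math.cos(th / 2)],
    ])
    return Molecule(("O", "H", "H"), coords)

def _ammonia() -> Molecule:
    r = 1.012 * BOHR_PER_ANGSTROM
    hnh = _deg(106.8)
    # N at apex; three H on a cone about z
    s = math.sin(hnh / 2) / math.sin(_deg(60))  # sin(polar angle from axis)
    s = min(s, 1.0)
    pol = math.asin(s)
    hs = []
    for k in range(3):
        az = 2 * math.pi * k / 3
        hs.append([r * math.sin(pol) * math.cos(az),
                   r * math.sin(pol) * math.sin(az),
                   r * math.cos(pol)])
    return Molecule(("N", "H", "H", "H"), np.vstack([[0.0, 0.0, 0.0], hs]))

def _ethene() -> Molecule:
    rcc = 1.339 * BOHR_PER_ANGSTROM
    rch = 1.087 * BOHR_PER_ANGSTROM
    th = _deg(180.0 - 121.3)
    x = rcc / 2
    coords = [[-x, 0, 0], [x, 0, 0]]
    for sx in (-1, 1):
        for sy in (-1, 1):
            coords.append([sx * (x + rch * math.cos(th)), sy * rch * math.sin(th), 0.0])
    return Molecule(("C", "C", "H", "H", "H", "H"), np.array(coords))


def _frame(axis, ref):
    """Right-handed orthonormal frame (a, e1, e2) with e1 ~ ref - (ref.a)a."""
    a = axis / np.linalg.norm(axis)
    e1 = ref - np.dot(ref, a) * a
    e1 = e1 / np.linalg.norm(e1)
    e2 = np.cross(a, e1)
    return a, e1, e2


def _methyl_hydrogens(c, neighbor, r_ch, plane_ref):
    """Three staggered H's on carbon ``c`` bonded to ``neighbor``."""
    a, e1, e2 = _frame(c - neighbor, plane_ref)
    th = _deg(180.0 - _TET)  # polar angle of H from the C->a axis
    hs = []
    for k in range(3):
        az = _deg(60.0) + 2 * math.pi * k / 3
        d = a * math.cos(th) + (e1 * math.cos(az) + e2 * math.sin(az)) * math.sin(th)
        hs.append(c + r_ch * d)
    return hs


def _alkane_backbone(n_c: int, rcc: float):
    half = _deg(_TET) / 2
    dx = rcc * math.sin(half)
    dz = rcc * math.cos(half)
    return np.array([[i * dx, 0.0, (i % 2) * dz] for i in range(n_c)])


def _chain_hydrogens(carbons, rch):
    """Two H's (+-y) on each interior carbon of an all-trans backbone."""
    hs = []
    half = _deg(_TET) / 2
    for i in range(1, len(carbons) - 1):
        c = carbons[i]
        u = (carbons[i - 1] - c) / np.linalg.norm(carbons[i - 1] - c)
        v = (carbons[i + 1] - c) / np.linalg.norm(carbons[i + 1] - c)
        bis = -(u + v)
        bis /= np.linalg.norm(bis)
        y = np.array([0.0, 1.0, 0.0])
        for s in (1.0, -1.0):
            d = bis * math.cos(half) + s * y * math.sin(half)
            hs.append(c + rch * d)
    return hs


def _alkane(n_c: int) -> Molecule:
    if n_c < 2:
        raise FixtureError("alkane_chain needs n_C >= 2")
    rcc = 1.536 * BOHR_PER_ANGSTROM
    rch = 1.091 * BOHR_PER_ANGSTROM
    C = _alkane_backbone(n_c, rcc)
    plane = np.array([0.0, 0.0, 1.0])
    hs = _methyl_hydrogens(C[0], C[1], rch, plane)
    hs += _chain_hydrogens(C, rch)
    hs += _methyl_hydrogens(C[-1], C[-2], rch, plane)
    elements = ("C",) * n_c + ("H",) * (2 * n_c + 2)
    return Molecule(elements, np.vstack([C, hs]))


def _fatty_acid(n_c: int) -> Molecule:
    """All-trans n-alkanoic acid CH3-(CH2)_{n-2}-COOH, formula CnH2nO2."""
    if n_c < 2:
        raise FixtureError("fatty_acid_chain needs n_C >= 2")
    rcc = 1.536 * BOHR_PER_ANGSTROM
    rch = 1.091 * BOHR_PER_ANGSTROM
    rco_d = 1.214 * BOHR_PER_ANGSTROM
    rco_s = 1.360 * BOHR_PER_ANGSTROM
    roh = 0.970 * BOHR_PER_ANGSTROM
    C = _alkane_backbone(n_c, rcc)
    # carboxyl carbon is C[0]; sp2, substituents in the xz backbone plane
    u = (C[1] - C[0]) / np.linalg.norm(C[1] - C[0])
    a, e1, _ = _frame(u, np.array([0.0, 0.0, 1.0]))
    d1 = -a * math.cos(_deg(60)) + e1 * math.sin(_deg(60))   # 120 deg from C-C
    d2 = -a * math.cos(_deg(60)) - e1 * math.sin(_deg(60))
    o_dbl = C[0] + rco_d * d1
    o_h = C[0] + rco_s * d2
    # hydroxyl H: in-plane, anti to the carbonyl
    w = (o_h - C[0]) / np.linalg.norm(o_h - C[0])
    _, f1, _ = _frame(w, o_dbl - C[0])
    h_o = o_h + roh * (w * math.cos(_deg(180 - 105)) + f1 * math.sin(_deg(180 - 105)))
    hs = _chain_hydrogens(C, rch)
    hs += _methyl_hydrogens(C[-1], C[-2], rch, np.array([0.0, 0.0, 1.0]))
    elements = ("C",) * n_c + ("O", "O") + ("H",) * (2 * n_c)
    coords = np.vstack([C, o_dbl, o_h, np.vstack([h_o] + [np.asarray(h) for h in hs])])
    return Molecule(elements, coords)


def make_fixture(name: str, params: dict | None = None) -> Molecule:
    """Deterministic idealized fixture geometries (same inputs, same bits)."""
    params = dict(params or {})
    n_c = params.pop("n_C", None)
    if params:
        raise FixtureError(f"unknown fixture parameters {sorted(params)}")
    if name == "water":
        return _water()
    if name == "ammonia":
        return _ammonia()
    if name == "ethane":
        return _alkane(2)
    if name == "ethene":
        return _ethene()
    if name == "alkane_chain":
        return _alkane(int(n_c if n_c is not None else 4))
    if name == "fatty_acid_chain":
        return _fatty_acid(int(n_c if n_c is not None else 20))
    raise FixtureError(f"unknown fixture {name!r}")


def read_xyz(path) -> Molecule:
    """Standard 2-header-line XYZ file, element symbols, angstrom."""
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    try:
        n = int(lines[0].split()[0])
    except (IndexError, ValueError) as exc:
        raise ValueError(f"{path}: first line must be the atom count") from exc
    elements, coords = [], []
    for ln in lines[2: 2 + n]:
        parts = ln.split()
        elements.append(parts[0].capitalize())
        coords.append([float(x) for x in parts[1:4]])
    if len(elements) != n:
        raise ValueError(f"{path}: expected {n} atoms, found {len(elements)}")
    return Molecule(tuple(elements), np.array(coords) * BOHR_PER_ANGSTROM)


__all__ = [
    "AOIntegrals", "BasisSpec", "FixtureError", "MOCoefficients", "Molecule",
    "SCFError", "UnsupportedBasisError", "BOHR_PER_ANGSTROM",
    "compute_ao_integrals", "count_basis_functions", "make_fixture",
    "read_xyz", "run_scf",
]
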