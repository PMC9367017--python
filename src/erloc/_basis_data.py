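"""Embedded Gaussian basis-set data.

Two layers of data live here:

* ``SHELL_STRUCTURE``: per-element contracted shell counts for the Dunning
  correlation-consistent families (cc-pVXZ, aug-cc-pVXZ, X = D,T,Q) and for
  STO-3G.  This is all that spherical basis-function counting needs and it is
  tabulated for H/He and the first-row p-block (B-Ne).
* ``PRIMITIVES``: full exponent/coefficient tables for the basis sets the
  in-package integral engine can actually evaluate (STO-3G and cc-pVDZ for
  H, C, N, O).  Primitive data are the published literature constants
  (Hehre/Stewart/Pople STO-3G; Dunning cc-pVDZ), given for normalized
  primitives in the (l,0,0) convention.

Angular momenta are encoded 0=s, 1=p, 2=d, 3=f, 4=g; all shells are
spherical-harmonic (2l+1 functions per contracted shell).
"""

from __future__ import annotations

FIRST_ROW = ("B", "C", "N", "O", "F", "Ne")

# shells as a list of (l, number of contracted functions of that l)
_CC_STRUCTURE_H = {
    "cc-pvdz": [(0, 2), (1, 1)],
    "cc-pvtz": [(0, 3), (1, 2), (2, 1)],
    "cc-pvqz": [(0, 4), (1, 3), (2, 2), (3, 1)],
}
_CC_STRUCTURE_ROW1 = {
    "cc-pvdz": [(0, 3), (1, 2), (2, 1)],
    "cc-pvtz": [(0, 4), (1, 3), (2, 2), (3, 1)],
    "cc-pvqz": [(0, 5), (1, 4), (2, 3), (3, 2), (4, 1)],
}


def _augment(shells):
    # 'aug-' adds one diffuse function for every angular momentum present
    return shells + [(l, 1) for l, _ in shells]


def _sto3g_structure(element: str):
    if element in ("H", "He"):
        return [(0, 1)]
    if element in ("Li", "Be"):
        return [(0, 2), (1, 1)]  # Li/Be STO-3G carry a 2sp shell
    if element in FIRST_ROW:
        return [(0, 2), (1, 1)]
    raise KeyError(element)


def shell_structure(element: str, basis_name: str):
    """Contracted shell list [(l, count), ...] for ``element`` in ``basis_name``.

    Raises ``KeyError`` for unsupported element/basis combinations.
    """
    name = basis_name.strip().lower()
    if name == "sto-3g":
        return list(_sto3g_structure(element))
    aug = name.startswith("aug-")
    core = name[4:] if aug else name
    if element in ("H", "He"):
        shells = _CC_STRUCTURE_H[core]
    elif element in FIRST_ROW:
        shells = _CC_STRUCTURE_ROW1[core]
    else:
        raise KeyError(f"{element}/{basis_name}")
    shells = list(shells)
    return _augment(shells) if aug else shells


# ---------------------------------------------------------------------------
# Primitive data for the evaluatable basis sets.
# Each shell: (l, [exponents], [contraction coefficients]).
# ---------------------------------------------------------------------------

_STO3G = {
    "H": [
        (0, [3.42525091, 0.62391373, 0.16885540],
            [0.15432897, 0.53532814, 0.44463454]),
    ],
    "C": [
        (0, [71.6168370, 13.0450960, 3.5305122],
            [0.15432897, 0.53532814, 0.44463454]),
        (0, [2.9412494, 0.6834831, 0.2222899],
            [-0.09996723, 0.39951283, 0.70011547]),
        (1, [2.9412494, 0.6834831, 0.2222899],
            [0.15591627, 0.60768372, 0.39195739]),
    ],
    "N": [
        (0, [99.1061690, 18.0523120, 4.8856602],
            [0.15432897, 0.53532814, 0.44463454]),
        (0, [3.7804559, 0.8784966, 0.2857144],
            [-0.09996723, 0.39951283, 0.70011547]),
        (1, [3.7804559, 0.8784966, 0.2857144],
            [0.15591627, 0.60768372, 0.39195739]),
    ],
    "O": [
        (0, [130.7093200, 23.8088610, 6.4436083],
            [0.15432897, 0.53532814, 0.44463454]),
        (0, [5.0331513, 1.1695961, 0.3803890],
            [-0.09996723, 0.39951283, 0.70011547]),
        (1, [5.0331513, 1.1695961, 0.3803890],
            [0.15591627, 0.60768372, 0.39195739]),
    ],
}

_CCPVDZ_S_C = [6665.0, 1000.0, 228.0, 64.71, 21.06, 6.459, 2.343, 0.7048, 0.1596]
_CCPVDZ_S_N = [9046.0, 1357.0, 309.3, 87.73, 28.56, 10.21, 3.838, 1.466, 0.4402]
_CCPVDZ_S_O = [11720.0, 1759.0, 400.8, 113.7, 37.03, 13.27, 5.025, 1.013, 0.3023]

_CCPVDZ = {
    "H": [
        (0, [13.0100, 1.9620, 0.4446], [0.0196850, 0.1379770, 0.4781480]),
        (0, [0.1220], [1.0]),
        (1, [0.7270], [1.0]),
    ],
    "C": [
        # 1s/2s contractions: atomic-HF orbitals in the primitive set
        # (the defining construction for correlation-consistent s spaces)
        (0, _CCPVDZ_S_C,
            [0.00070315, 0.00519757, 0.02805731, 0.09635341, 0.30265211,
             0.51542363, 0.19572770, 0.01205803, -0.00121466]),
        (0, _CCPVDZ_S_C,
            [-0.00015484, -0.00110817, -0.00635646, -0.02099921, -0.07875068,
             -0.16007053, -0.17110767, 0.53286869, 0.66696865]),
        (0, [0.1596], [1.0]),
        (1, [9.439, 2.002, 0.5456, 0.1517],
            [0.02945831, 0.16651419, 0.36821415, 0.53052533]),
        (1, [0.1517], [1.0]),
        (2, [0.5500], [1.0]),
    ],
    "N": [
        (0, _CCPVDZ_S_N,
            [0.00069939, 0.00539879, 0.02736409, 0.10352581, 0.27767444,
             0.45281976, 0.26906797, 0.01609705, 0.00215536]),
        (0, _CCPVDZ_S_N,
            [-0.00016155, -0.00128017, -0.00633306, -0.02603241, -0.07131555,
             -0.16782527, -0.13836644, 0.12731363, 0.97354251]),
        (0, [0.4402], [1.0]),
        (1, [13.55, 2.917, 0.7973, 0.2185],
            [0.01755728, 0.09701445, 0.21290500, 0.27395517]),
        (1, [0.2185], [1.0]),
        (2, [0.8170], [1.0]),
    ],
    "O": [
        (0, _CCPVDZ_S_O,
            [0.000710, 0.005470, 0.027837, 0.104800, 0.283062,
             0.448719, 0.270952, 0.015458, -0.002585]),
        (0, _CCPVDZ_S_O,
            [-0.000160, -0.001263, -0.006267, -0.025716, -0.070924,
             -0.165411, -0.116955, 0.557368, 0.572759]),
        (0, [0.3023], [1.0]),
        (1, [17.70, 3.854, 1.046], [0.043018, 0.228913, 0.508728]),
        (1, [0.2753], [1.0]),
        (2, [1.1850], [1.0]),
    ],
}

PRIMITIVES = {"sto-3g": _STO3G, "cc-pvdz": _CCPVDZ}


def primitive_shells(element: str, basis_name: str):
    """Primitive data [(l, exps, coeffs), ...]; KeyError if not evaluatable."""
    name = basis_name.strip().lower()
    return [
        (l, list(e), list(c)) for l, e, c in PRIMITIVES[name][element]
    ]


def has_primitives(basis_name: str) -> bool:
    return basis_name.strip().lower() in PRIMITIVES
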