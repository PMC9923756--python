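"""Geometry/basis ingestion and restricted-kinetic-balance (RKB) integrals.

The large-component scalar basis is a set of uncontracted Cartesian Gaussian
shells.  The small-component space is generated from it by the RKB map
sigma.p: every derivative d_u chi_mu of a large function is expanded in an
auxiliary scalar basis Phi (shells of angular momentum l-1 and l+1 with the
same exponent and center), so that all small-component matrix elements reduce
to ordinary scalar integrals over Phi contracted with sparse derivative maps
D_u (d_u chi_mu = sum_g D_u[g, mu] phi_g).

Atomic units are used throughout; geometries are converted to bohr on input.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla

from . import _mcmurchie as md

SPEED_OF_LIGHT = 137.0359991  # au (CODATA value used throughout)
ANGSTROM = 1.0 / 0.529177210903

ELEMENTS = [
    "X", "H", "He", "Li", "Be", "B", "C", "N", "O", "F", "Ne",
    "Na", "Mg", "Al", "Si", "P", "S", "Cl", "Ar", "K", "Ca",
    "Sc", "Ti", "V", "Cr", "Mn", "Fe", "Co", "Ni", "Cu", "Zn",
    "Ga", "Ge", "As", "Se", "Br", "Kr", "Rb", "Sr", "Y", "Zr",
    "Nb", "Mo", "Tc", "Ru", "Rh", "Pd", "Ag", "Cd", "In", "Sn",
    "Sb", "Te", "I", "Xe", "Cs", "Ba", "La", "Ce", "Pr", "Nd",
    "Pm", "Sm", "Eu", "Gd", "Tb", "Dy", "Ho", "Er", "Tm", "Yb",
    "Lu", "Hf", "Ta", "W", "Re", "Os", "Ir", "Pt", "Au", "Hg",
    "Tl", "Pb", "Bi", "Po", "At", "Rn", "Fr", "Ra", "Ac", "Th",
    "Pa", "U",
]
Z_OF = {s: z for z, s in enumerate(ELEMENTS) if z}

# Mass numbers of the most abundant isotope, used by the Gaussian
# finite-nucleus model (r_rms = 0.836 A^(1/3) + 0.570 fm).
ISOTOPE_A = [
    0, 1, 4, 7, 9, 11, 12, 14, 16, 19, 20,
    23, 24, 27, 28, 31, 32, 35, 40, 39, 40,
    45, 48, 51, 52, 55, 56, 59, 58, 63, 64,
    69, 74, 75, 80, 79, 84, 85, 88, 89, 90,
    93, 98, 98, 102, 103, 106, 107, 114, 115, 120,
    121, 130, 127, 132, 133, 138, 139, 140, 141, 142,
    145, 152, 153, 158, 159, 162, 165, 166, 169, 174,
    175, 180, 181, 184, 187, 192, 193, 195, 197, 202,
    205, 208, 209, 209, 210, 222, 223, 226, 227, 232,
    231, 238,
]

L_SYMBOLS = {"s": 0, "p": 1, "d": 2, "f": 3, "g": 4}
BOHR_FM = 52917.7210903  # 1 bohr in fm


def gaussian_nucleus_exponent(Z: int) -> float:
    """Exponent of the Gaussian nuclear charge model for element Z."""
    A = ISOTOPE_A[Z]
    r_rms_fm = 0.836 * A ** (1.0 / 3.0) + 0.570
    r_rms = r_rms_fm / BOHR_FM
    return 1.5 / r_rms ** 2


class InputError(ValueError):
    """Malformed geometry/basis input."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class Molecule:
    """Nuclear framework: (symbol, Z, position/bohr) per atom plus net charge."""

    atoms: list  # list of (symbol, Z, np.ndarray(3))
    charge: int = 0
    finite_nucleus: bool = True

    def __post_init__(self):
        for sym, z, pos in self.atoms:
            if not np.all(np.isfinite(pos)):
                raise InputError(f"non-finite position for atom {sym}")
            if int(z) < 1:
                raise InputError(f"nuclear charge must be >= 1 (got {z} for {sym})")

    @property
    def natoms(self) -> int:
        return len(self.atoms)

    @property
    def n_electrons(self) -> int:
        return sum(z for _, z, _ in self.atoms) - self.charge

    @property
    def coords(self) -> np.ndarray:
        return np.array([pos for _, _, pos in self.atoms])

    @property
    def charges(self) -> np.ndarray:
        return np.array([float(z) for _, z, _ in self.atoms])

    def nuclear_repulsion(self) -> float:
        e = 0.0
        for i in range(self.natoms):
            for j in range(i):
                r = np.linalg.norm(self.coords[i] - self.coords[j])
                e += self.charges[i] * self.charges[j] / r
        return e

    def center_of_nuclear_charge(self) -> np.ndarray:
        q = self.charges
        return (q[:, None] * self.coords).sum(axis=0) / q.sum()


@dataclass
class GaussianBasis:
    """Uncontracted per-element shell lists: element -> [(l, [exponents])]."""

    shells: dict  # element symbol -> list of (l, exponent) pairs, uncontracted

    def __post_init__(self):
        norm = {}
        for el, lst in self.shells.items():
            seen = set()
            out = []
            for l, a in lst:
                a = float(a)
                if a <= 0.0:
                    raise InputError(f"non-positive exponent {a} for {el}")
                key = (int(l), a)
                if key in seen:  # duplicates after de-contraction collapse
                    continue
                seen.add(key)
                out.append((int(l), a))
            # strictly decreasing exponents within each angular momentum
            out.sort(key=lambda t: (t[0], -t[1]))
            norm[el] = out
        self.shells = norm

    def for_element(self, el: str):
        if el not in self.shells:
            raise InputError(f"no basis for element {el}")
        return self.shells[el]


@dataclass
class ShellList:
    """Flat shell arrays consumable by the numba integral kernels."""

    centers: np.ndarray  # (nsh, 3)
    exps: np.ndarray  # (nsh,)
    ls: np.ndarray  # (nsh,) int64
    offs: np.ndarray  # (nsh,) function offsets
    atom_of: np.ndarray  # (nsh,) atom index
    nbf: int
    norms: np.ndarray  # (nbf,) per-function normalization

    @classmethod
    def build(cls, shell_tuples):
        """shell_tuples: iterable of (atom_index, center, l, exponent)."""
        centers, exps, ls, offs, atom_of, norms = [], [], [], [], [], []
        nbf = 0
        for ia, ctr, l, a in shell_tuples:
            centers.append(np.asarray(ctr, float))
            exps.append(float(a))
            ls.append(int(l))
            offs.append(nbf)
            atom_of.append(ia)
            norms.append(md.cart_norms(int(l), float(a)))
            nbf += md.ncart(int(l))
        return cls(
            centers=np.array(centers).reshape(-1, 3),
            exps=np.array(exps),
            ls=np.array(ls, dtype=np.int64),
            offs=np.array(offs, dtype=np.int64),
            atom_of=np.array(atom_of, dtype=np.int64),
            nbf=nbf,
            norms=np.concatenate(norms) if norms else np.zeros(0),
        )

    def function_atom(self) -> np.ndarray:
        out = np.empty(self.nbf, dtype=np.int64)
        for ish in range(len(self.exps)):
            n = md.ncart(int(self.ls[ish]))
            out[self.offs[ish]: self.offs[ish] + n] = self.atom_of[ish]
        return out


def molecular_shells(mol: Molecule, basis: GaussianBasis) -> ShellList:
    tuples = []
    for ia, (sym, _z, pos) in enumerate(mol.atoms):
        for l, a in basis.for_element(sym):
            tuples.append((ia, pos, l, a))
    return ShellList.build(tuples)


# ---------------------------------------------------------------------------
# Input parsing
# ---------------------------------------------------------------------------


def parse_xyz(text: str, charge: int = 0) -> Molecule:
    """Parse XYZ-format geometry text (coordinates in Angstrom by default).

    A token ``bohr`` or ``au`` in the comment line switches units to bohr.
    """
    lines = text.splitlines()
    if not lines:
        raise InputError("empty geometry file")
    try:
        natoms = int(lines[0].split()[0])
    except (IndexError, ValueError) as exc:
        raise InputError(f"line 1: expected atom count, got {lines[0]!r}") from exc
    comment = lines[1] if len(lines) > 1 else ""
    unit = 1.0 if re.search(r"\b(bohr|au)\b", comment, re.I) else ANGSTROM
    atoms = []
    for ln in range(2, 2 + natoms):
        if ln >= len(lines):
            raise InputError(f"line {ln + 1}: geometry truncated")
        parts = lines[ln].split()
        if len(parts) < 4:
            raise InputError(f"line {ln + 1}: expected 'El x y z'")
        sym = parts[0].capitalize()
        if sym not in Z_OF:
            raise InputError(f"line {ln + 1}: unknown element token {parts[0]!r}")
        try:
            xyz = np.array([float(x) for x in parts[1:4]]) * unit
        except ValueError as exc:
            raise InputError(f"line {ln + 1}: malformed coordinates") from exc
        atoms.append((sym, Z_OF[sym], xyz))
    return Molecule(atoms=atoms, charge=charge)


def parse_nwchem_basis(text: str) -> GaussianBasis:
    """Parse an NWChem-style ASCII basis block into an uncontracted basis.

    Contracted sets are exploded to their primitives (contraction coefficients
    are discarded; duplicate exponents collapse).
    """
    shells: dict = {}
    cur_el = None
    cur_l = None
    for raw in text.splitlines():
        line = raw.split("#")[0].strip()
        if not line or line.lower().startswith(("basis", "end")):
            continue
        parts = line.split()
        if parts[0].capitalize() in Z_OF and len(parts) >= 2 and parts[1].lower() in L_SYMBOLS:
            cur_el = parts[0].capitalize()
            cur_l = L_SYMBOLS[parts[1].lower()]
            shells.setdefault(cur_el, [])
            continue
        if cur_el is None:
            raise InputError(f"basis line outside element block: {raw!r}")
        try:
            a = float(parts[0].replace("D", "E").replace("d", "e"))
        except ValueError as exc:
            raise InputError(f"malformed basis line: {raw!r}") from exc
        shells[cur_el].append((cur_l, a))
    return GaussianBasis(shells=shells)


def basis_from_dict(spec: dict) -> GaussianBasis:
    """Build a basis from a mapping (YAML-friendly).

    Two per-element forms are supported::

        O: {s: [9000.0, 1300.0, ...], p: [34.0, ...]}
        O: {even_tempered: {s: [n, alpha0, beta], p: [...]}}
    """
    shells: dict = {}
    for el, entry in spec.items():
        el = str(el).capitalize()
        if el not in Z_OF:
            raise InputError(f"unknown element token {el!r} in basis spec")
        lst = []
        if "even_tempered" in entry:
            for lsym, (n, a0, beta) in entry["even_tempered"].items():
                l = L_SYMBOLS[lsym.lower()]
                for k in range(int(n)):
                    lst.append((l, float(a0) * float(beta) ** k))
        else:
            for lsym, exps in entry.items():
                l = L_SYMBOLS[lsym.lower()]
                for a in exps:
                    lst.append((l, float(a)))
        shells[el] = lst
    return GaussianBasis(shells=shells)


def load_system(geometry, basis_spec, config=None):
    """Load (Molecule, GaussianBasis) from file paths, text, or objects.

    ``config`` may carry ``charge`` and ``finite_nucleus`` overrides.  Every
    element appearing in the geometry must have a basis entry.
    """
    config = config or {}
    if isinstance(geometry, Molecule):
        mol = geometry
    else:
        text = geometry
        if "\n" not in str(geometry):
            with open(geometry) as fh:
                text = fh.read()
        mol = parse_xyz(text, charge=int(config.get("charge", 0)))
    if "finite_nucleus" in config:
        mol.finite_nucleus = bool(config["finite_nucleus"])

    if isinstance(basis_spec, GaussianBasis):
        basis = basis_spec
    elif isinstance(basis_spec, dict):
        basis = basis_from_dict(basis_spec)
    else:
        text = basis_spec
        if "\n" not in str(basis_spec):
            with open(basis_spec) as fh:
                text = fh.read()
        if text.lstrip().lower().startswith("basis") or re.search(
            r"^\s*[A-Za-z]{1,2}\s+[spdfg]\s*$", text, re.M
        ):
            basis = parse_nwchem_basis(text)
        else:
            import yaml

            basis = basis_from_dict(yaml.safe_load(text))
    for sym, _z, _pos in mol.atoms:
        basis.for_element(sym)  # raises naming the element
    return mol, basis


# ---------------------------------------------------------------------------
# RKB space and integral set
# ---------------------------------------------------------------------------


def _canonical_orthogonalization(metric: np.ndarray, cutoff: float) -> np.ndarray:
    """Eigenvalue-filtered X with X^T metric X = 1 (deterministic ordering).

    The metric is diagonally normalized first so that the cutoff measures
    genuine linear dependence rather than the (physical) scale spread of
    steep-vs-diffuse exponents; this matters for the RKB small-component
    metric T/(2c^2) whose diagonal spans many decades.
    """
    d = np.sqrt(np.diag(metric))
    if np.any(d <= 0.0):
        raise InputError("metric has a non-positive diagonal entry")
    mn = metric / np.outer(d, d)
    w, v = np.linalg.eigh(mn)
    keep = w > cutoff * w.max()
    if not np.any(keep):
        raise InputError("no basis functions survive the linear-dependence cutoff")
    # ascending eigenvalue order from eigh is deterministic; keep it
    return (v[:, keep] / np.sqrt(w[keep])) / d[:, None]


@dataclass
class RKBSpace:
    """RKB bookkeeping: derivative maps, Phi shells, orthonormalization maps."""

    shells_L: ShellList
    shells_P: ShellList
    Du: np.ndarray  # (3, nP, nL) derivative maps over normalized functions
    X_L: np.ndarray  # raw L -> orthonormal L
    X_S: np.ndarray  # raw RKB small -> orthonormal small (metric T/2c^2)
    c: float
    lindep_cutoff: float

    @property
    def nL(self) -> int:
        return self.shells_L.nbf

    @property
    def nP(self) -> int:
        return self.shells_P.nbf

    @property
    def n2L(self) -> int:
        """Orthonormal large-component spinor dimension."""
        return 2 * self.X_L.shape[1]

    @property
    def n2S(self) -> int:
        return 2 * self.X_S.shape[1]

    def small_map(self) -> np.ndarray:
        """M: raw RKB small 2-spinor coefficients -> Phi (x) spin expansion.

        sigma.p chi_mu = -i sum_u sigma_u d_u chi_mu; the physical small
        component carries a 1/(2c) kinetic-balance factor.
        """
        nP, nL = self.nP, self.nL
        M = np.zeros((2 * nP, 2 * nL), dtype=complex)
        sig = pauli_matrices()
        fac = -1j / (2.0 * self.c)
        for u in range(3):
            M += fac * np.kron(sig[u + 1], self.Du[u])
        return M


def pauli_matrices() -> np.ndarray:
    """sigma_0..sigma_3 as a (4, 2, 2) complex array."""
    s = np.zeros((4, 2, 2), dtype=complex)
    s[0] = np.eye(2)
    s[1] = [[0, 1], [1, 0]]
    s[2] = [[0, -1j], [1j, 0]]
    s[3] = [[1, 0], [0, -1]]
    return s


def _phi_shells(shells_L: ShellList):
    """Auxiliary scalar shells spanning all Cartesian derivatives of L."""
    keys = {}
    tuples = []
    for ish in range(len(shells_L.exps)):
        ia = int(shells_L.atom_of[ish])
        a = float(shells_L.exps[ish])
        l = int(shells_L.ls[ish])
        for lp in ([l - 1] if l > 0 else []) + [l + 1]:
            key = (ia, lp, a)
            if key not in keys:
                keys[key] = len(tuples)
                tuples.append((ia, shells_L.centers[ish], lp, a))
    shells_P = ShellList.build(tuples)
    index = {}
    for jsh in range(len(shells_P.exps)):
        key = (int(shells_P.atom_of[jsh]), int(shells_P.ls[jsh]), float(shells_P.exps[jsh]))
        index[key] = jsh
    return shells_P, index


def _derivative_maps(shells_L: ShellList, shells_P: ShellList, index) -> np.ndarray:
    """D_u with d_u chi_mu = sum_g D_u[g, mu] phi_g over *normalized* functions."""
    Du = np.zeros((3, shells_P.nbf, shells_L.nbf))
    for ish in range(len(shells_L.exps)):
        l = int(shells_L.ls[ish])
        a = float(shells_L.exps[ish])
        ia = int(shells_L.atom_of[ish])
        comps = np.asarray(md._cart_comps(l))
        norms_src = md.cart_norms(l, a)
        for ic, comp in enumerate(comps):
            mu = shells_L.offs[ish] + ic
            for u in range(3):
                # d/dx x^n e^{-a r^2} = n x^{n-1} - 2a x^{n+1} (per component)
                if comp[u] > 0:
                    tgt = comp.copy()
                    tgt[u] -= 1
                    _add_phi(Du, u, mu, ia, l - 1, a, tgt, comp[u] * norms_src[ic],
                             shells_P, index)
                tgt = comp.copy()
                tgt[u] += 1
                _add_phi(Du, u, mu, ia, l + 1, a, tgt, -2.0 * a * norms_src[ic],
                         shells_P, index)
    return Du


def _add_phi(Du, u, mu, ia, lp, a, tgt, coef, shells_P, index):
    jsh = index[(ia, lp, a)]
    comps = np.asarray(md._cart_comps(lp))
    norms_dst = md.cart_norms(lp, a)
    pos = int(np.where((comps == tgt).all(axis=1))[0][0])
    Du[u, shells_P.offs[jsh] + pos, mu] += coef / norms_dst[pos]


class IntegralSet:
    """Scalar integrals over the large (L) and auxiliary (Phi) bases.

    ERI class tensors are computed lazily and cached; an audit counter per
    class records how often each was *assembled* (used by tests asserting that
    the 2c SCF path never touches the small-component classes).
    """

    def __init__(self, mol: Molecule, shells_L: ShellList, shells_P: ShellList,
                 gauge_origin: np.ndarray, c: float = SPEED_OF_LIGHT):
        self.mol = mol
        self.shells_L = shells_L
        self.shells_P = shells_P
        self.gauge_origin = np.asarray(gauge_origin, float)
        self.c = c
        self.audit = {"LL": 0, "LP": 0, "PP": 0}
        self._eri = {}
        self._kmat = {}
        self._compute_one_electron()

    def _compute_one_electron(self):
        mol = self.mol
        nucexp = np.array(
            [gaussian_nucleus_exponent(z) if mol.finite_nucleus else -1.0
             for _s, z, _p in mol.atoms]
        )
        for tag, sh in (("L", self.shells_L), ("P", self.shells_P)):
            S, T, V, D = md.one_electron(
                sh.centers, sh.exps, sh.ls, sh.offs, sh.nbf,
                mol.charges, mol.coords, nucexp, self.gauge_origin,
            )
            N = np.outer(sh.norms, sh.norms)
            setattr(self, f"S_{tag}", S * N)
            setattr(self, f"T_{tag}", T * N)
            setattr(self, f"V_{tag}", V * N)
            setattr(self, f"dip_{tag}", D * N[None, :, :])

    def _eri_tensor(self, cls: str) -> np.ndarray:
        if cls in self._eri:
            return self._eri[cls]
        L, P = self.shells_L, self.shells_P
        if cls == "LL":
            G = md.eri_class(L.centers, L.exps, L.ls, L.offs, L.nbf,
                             L.centers, L.exps, L.ls, L.offs, L.nbf, True)
            G *= np.einsum("m,n,k,l->mnkl", L.norms, L.norms, L.norms, L.norms)
        elif cls == "LP":
            G = md.eri_class(L.centers, L.exps, L.ls, L.offs, L.nbf,
                             P.centers, P.exps, P.ls, P.offs, P.nbf, False)
            G *= np.einsum("m,n,k,l->mnkl", L.norms, L.norms, P.norms, P.norms)
        elif cls == "PP":
            G = md.eri_class(P.centers, P.exps, P.ls, P.offs, P.nbf,
                             P.centers, P.exps, P.ls, P.offs, P.nbf, True)
            G *= np.einsum("m,n,k,l->mnkl", P.norms, P.norms, P.norms, P.norms)
        else:  # pragma: no cover
            raise KeyError(cls)
        self.audit[cls] += 1
        self._eri[cls] = G
        return G

    @property
    def eri_LLLL(self):
        return self._eri_tensor("LL")

    @property
    def eri_LLPP(self):
        return self._eri_tensor("LP")

    @property
    def eri_PPPP(self):
        return self._eri_tensor("PP")

    def k_matrix(self, cls: str) -> np.ndarray:
        """Exchange-ordered ERI matrix K[(m v), (k l)] = (mk|lv), cached.

        Contracting it with a density block D[k, l] (raveled) yields the
        exchange matrix K[m, v] as a single BLAS GEMV.
        """
        if cls not in self._kmat:
            G = self._eri_tensor(cls)
            n1, n2 = G.shape[0], G.shape[2]
            # G[m,k,l,v] = (mk|lv); want [(m,v),(k,l)]
            self._kmat[cls] = np.ascontiguousarray(
                G.transpose(0, 3, 1, 2).reshape(n1 * n2, n1 * n2)
            )
        return self._kmat[cls]

    def release_small_component(self):
        """Drop cached small-component ERI tensors (memory hygiene)."""
        self._eri.pop("LP", None)
        self._eri.pop("PP", None)
        self._kmat.pop("LP", None)
        self._kmat.pop("PP", None)

    def save(self, path: str):
        """Persist matrices in the HDF5 checkpoint layout /integrals/{...}."""
        import h5py

        with h5py.File(path, "w") as fh:
            g = fh.create_group("integrals")
            g["S"] = self.S_L
            g["T"] = self.T_L
            g["V"] = self.V_L
            for i, u in enumerate("xyz"):
                g[f"dipole_{u}"] = self.dip_L[i]
            g["S_phi"] = self.S_P
            g["V_phi"] = self.V_P
            g.attrs["c"] = self.c
            g.attrs["gauge_origin"] = self.gauge_origin


def build_rkb_integrals(mol: Molecule, basis: GaussianBasis,
                        gauge_origin=None, c: float = SPEED_OF_LIGHT,
                        lindep_cutoff: float = 1e-9):
    """Construct (RKBSpace, IntegralSet) for a molecule.

    Linear dependencies are removed by canonical orthogonalization of the
    large-component metric S and of the RKB small-component metric T/(2c^2),
    both with the same eigenvalue cutoff.
    """
    shells_L = molecular_shells(mol, basis)
    if shells_L.nbf == 0:
        raise InputError("empty basis")
    shells_P, index = _phi_shells(shells_L)
    if gauge_origin is None:
        gauge_origin = mol.center_of_nuclear_charge()
    ints = IntegralSet(mol, shells_L, shells_P, gauge_origin, c=c)
    Du = _derivative_maps(shells_L, shells_P, index)
    X_L = _canonical_orthogonalization(ints.S_L, lindep_cutoff)
    X_S = _canonical_orthogonalization(ints.T_L / (2.0 * c * c), lindep_cutoff)
    rkb = RKBSpace(shells_L=shells_L, shells_P=shells_P, Du=Du,
                   X_L=X_L, X_S=X_S, c=c, lindep_cutoff=lindep_cutoff)
    return rkb, ints


def dirac_point_nucleus_energy(Z: float, c: float = SPEED_OF_LIGHT) -> float:
    """Closed-form 1s Dirac eigenvalue (point nucleus), rest mass removed."""
    return c * c * (np.sqrt(1.0 - (Z / c) ** 2) - 1.0)
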