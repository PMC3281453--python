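"""Molecular structures: types, file formats, topology and parameter assignment.

The in-memory :class:`Structure` is deliberately small: an ordered atom list
(element, mass, Cartesian coordinates in A, partial charge in units of e) and
an explicit bond list.  File formats keep their native 1-based indexing; all
internal indices are 0-based.

Supported file formats: XYZ (plain), SDF / MOL V2000, and a minimal PDB reader
(ATOM/HETATM records only).  Parameter sets are YAML files with sections
``vdw``, ``stretch``, ``bend``, ``torsion``, ``charges``, ``hbond``,
``nonbonded``; a builtin minimal set with UFF-like magnitudes ships with the
package and can be replaced by a user file.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .constants import (
    COVALENT_RADII,
    ELEMENT_MASSES,
    HBOND_ELECTRONEGATIVE,
)
from .errors import (
    ClashError,
    ParseError,
    UnparameterizedPatternError,
    UnsupportedDialectError,
    UnsupportedElementError,
)

CLASH_DISTANCE = 0.4  # A; closer than this is treated as a hard clash
BOND_PERCEPTION_FACTOR = 1.2  # bond if r < factor * (r_cov_i + r_cov_j)


# ---------------------------------------------------------------------------
# core types
# ---------------------------------------------------------------------------

@dataclass
class Atom:
    """One atom: element symbol, mass (amu), coords (A), partial charge (e)."""

    element: str
    coords: tuple[float, float, float]
    mass: float | None = None
    partial_charge: float = 0.0

    def __post_init__(self):
        if self.element not in ELEMENT_MASSES:
            raise UnsupportedElementError(
                f"unsupported element {self.element!r}"
            )
        if self.mass is None:
            self.mass = ELEMENT_MASSES[self.element]
        if self.mass <= 0:
            raise ValueError(f"non-positive mass for {self.element}")
        self.coords = tuple(float(c) for c in self.coords)


@dataclass
class Structure:
    """An ordered list of atoms plus an explicit bond list.

    ``bonds`` are ``(i, j, order)`` with 0-based indices, ``i < j`` after
    normalization.  ``angles`` and ``torsions`` are populated by
    :func:`perceive_topology`.
    """

    atoms: list[Atom]
    bonds: list[tuple[int, int, int]] = field(default_factory=list)
    name: str = ""
    angles: list[tuple[int, int, int]] | None = None
    torsions: list[tuple[int, int, int, int]] | None = None

    def __post_init__(self):
        if len(self.atoms) < 1:
            raise ValueError("a Structure needs at least one atom")
        n = len(self.atoms)
        seen = set()
        norm = []
        for i, j, order in self.bonds:
            if i == j:
                raise ValueError(f"self-bond on atom {i}")
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond ({i},{j}) out of range for {n} atoms")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ValueError(f"duplicate bond {key}")
            seen.add(key)
            norm.append((key[0], key[1], int(order)))
        self.bonds = norm

    # -- convenience accessors ------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms], dtype=float)

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.partial_charge for a in self.atoms], dtype=float)

    def with_coords(self, coords: np.ndarray) -> "Structure":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise ValueError("coordinate array shape mismatch")
        atoms = [
            Atom(a.element, tuple(xyz), a.mass, a.partial_charge)
            for a, xyz in zip(self.atoms, coords)
        ]
        return Structure(atoms, list(self.bonds), self.name,
                         self.angles, self.torsions)

    def copy(self) -> "Structure":
        return self.with_coords(self.coords)


def merge_structures(a: Structure, b: Structure, name: str = "") -> Structure:
    """Concatenate two structures (a's atoms first); bond indices of *b* shift."""
    off = a.n_atoms
    atoms = [Atom(x.element, x.coords, x.mass, x.partial_charge)
             for x in a.atoms + b.atoms]
    bonds = list(a.bonds) + [(i + off, j + off, o) for i, j, o in b.bonds]
    return Structure(atoms, bonds, name or f"{a.name}+{b.name}")


# ---------------------------------------------------------------------------
# XYZ
# ---------------------------------------------------------------------------

def read_xyz(path: str | Path) -> Structure:
    """Read a plain XYZ file (count line, comment line, ``El x y z`` lines)."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise ParseError(f"{path}: line 1: malformed atom count "
                         f"{lines[0]!r}") from None
    comment = lines[1] if len(lines) > 1 else ""
    atom_lines = [ln for ln in lines[2:] if ln.strip()]
    if len(atom_lines) < n:
        raise ParseError(
            f"{path}: expected {n} atom lines, found {len(atom_lines)}"
        )
    atoms = []
    for k, ln in enumerate(atom_lines[:n]):
        parts = ln.split()
        if len(parts) < 4:
            raise ParseError(f"{path}: line {k + 3}: malformed atom line {ln!r}")
        el = parts[0].capitalize() if len(parts[0]) > 1 else parts[0].upper()
        if el not in ELEMENT_MASSES:
            raise UnsupportedElementError(
                f"{path}: line {k + 3}: unknown element {parts[0]!r}"
            )
        try:
            xyz = tuple(float(v) for v in parts[1:4])
        except ValueError:
            raise ParseError(
                f"{path}: line {k + 3}: bad coordinates {ln!r}"
            ) from None
        atoms.append(Atom(el, xyz))
    return Structure(atoms, [], name=comment.strip())


def write_xyz(structure: Structure, path: str | Path) -> None:
    lines = [str(structure.n_atoms), structure.name or ""]
    for a in structure.atoms:
        x, y, z = a.coords
        lines.append(f"{a.element:2s} {x:15.8f} {y:15.8f} {z:15.8f}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# SDF / MOL V2000
# ---------------------------------------------------------------------------

def read_sdf(path: str | Path) -> Structure:
    """Read the first molecule of an SDF / MOL V2000 file."""
    lines = Path(path).read_text().splitlines()
    if len(lines) < 4:
        raise ParseError(f"{path}: truncated MOL header")
    counts = lines[3]
    if "V3000" in counts:
        raise UnsupportedDialectError(f"{path}: V3000 MOL files not supported")
    try:
        n_atoms = int(counts[0:3])
        n_bonds = int(counts[3:6])
    except ValueError:
        raise ParseError(
            f"{path}: line 4: malformed counts line {counts!r}"
        ) from None
    if len(lines) < 4 + n_atoms + n_bonds:
        raise ParseError(
            f"{path}: counts line declares {n_atoms} atoms and {n_bonds} "
            f"bonds but the file is shorter"
        )
    atoms = []
    for k in range(n_atoms):
        ln = lines[4 + k]
        try:
            x, y, z = float(ln[0:10]), float(ln[10:20]), float(ln[20:30])
            el = ln[31:34].strip()
        except (ValueError, IndexError):
            raise ParseError(
                f"{path}: line {5 + k}: malformed atom line {ln!r}"
            ) from None
        if el not in ELEMENT_MASSES:
            raise UnsupportedElementError(
                f"{path}: line {5 + k}: unknown element {el!r}"
            )
        atoms.append(Atom(el, (x, y, z)))
    # optional data field with per-atom partial charges (one float per atom)
    charges = None
    for k, ln in enumerate(lines[4 + n_atoms:]):
        if ln.strip().lower().startswith(">") and "partial_charges" in ln:
            values = []
            for data_ln in lines[4 + n_atoms + k + 1:]:
                if not data_ln.strip() or data_ln.startswith("$$$$"):
                    break
                values.extend(float(v) for v in data_ln.split())
            if len(values) != n_atoms:
                raise ParseError(
                    f"{path}: partial_charges field has {len(values)} "
                    f"values for {n_atoms} atoms")
            charges = values
            break
    if charges is not None:
        for atom, q in zip(atoms, charges):
            atom.partial_charge = q
    bonds = []
    for k in range(n_bonds):
        ln = lines[4 + n_atoms + k]
        try:
            i, j = int(ln[0:3]), int(ln[3:6])
            order = int(ln[6:9])
        except (ValueError, IndexError):
            raise ParseError(
                f"{path}: line {5 + n_atoms + k}: malformed bond line {ln!r}"
            ) from None
        if not (1 <= i <= n_atoms and 1 <= j <= n_atoms):
            raise ParseError(
                f"{path}: bond {k + 1} references atom outside 1..{n_atoms}"
            )
        bonds.append((i - 1, j - 1, order))  # file is 1-based
    name = lines[0].strip()
    return Structure(atoms, bonds, name=name)


def write_sdf(structure: Structure, path: str | Path) -> None:
    """Write a single-molecule SDF (MOL V2000 + ``$$$$``)."""
    out = [structure.name or "molecule", "  stericds", ""]
    out.append(f"{structure.n_atoms:3d}{len(structure.bonds):3d}"
               "  0  0  0  0  0  0  0  0999 V2000")
    for a in structure.atoms:
        x, y, z = a.coords
        out.append(f"{x:10.4f}{y:10.4f}{z:10.4f} {a.element:<3s}"
                   " 0  0  0  0  0  0  0  0  0  0  0  0")
    for i, j, order in structure.bonds:
        out.append(f"{i + 1:3d}{j + 1:3d}{order:3d}  0  0  0  0")
    out.append("M  END")
    if np.abs(structure.charges).max() > 0:
        out.append(">  <partial_charges>")
        out.extend(f"{a.partial_charge:.6f}" for a in structure.atoms)
        out.append("")
    out.append("$$$$")
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# minimal PDB
# ---------------------------------------------------------------------------

def read_pdb(path: str | Path) -> Structure:
    """Minimal PDB reader: ATOM/HETATM coordinates and elements only."""
    atoms = []
    for lineno, ln in enumerate(Path(path).read_text().splitlines(), 1):
        if not ln.startswith(("ATOM", "HETATM")):
            continue
        try:
            x = float(ln[30:38])
            y = float(ln[38:46])
            z = float(ln[46:54])
        except (ValueError, IndexError):
            raise ParseError(
                f"{path}: line {lineno}: malformed coordinates"
            ) from None
        el = ln[76:78].strip().capitalize() if len(ln) >= 78 else ""
        if not el:
            # fall back on the first alphabetic character of the atom name
            name = ln[12:16].strip()
            el = next((c for c in name if c.isalpha()), "").upper()
        if el not in ELEMENT_MASSES:
            raise UnsupportedElementError(
                f"{path}: line {lineno}: unknown element {el!r}"
            )
        atoms.append(Atom(el, (x, y, z)))
    if not atoms:
        raise ParseError(f"{path}: no ATOM/HETATM records found")
    return Structure(atoms, [], name=Path(path).stem)


# ---------------------------------------------------------------------------
# topology perception
# ---------------------------------------------------------------------------

def derive_angles(n_atoms: int, bonds) -> list[tuple[int, int, int]]:
    """Unique angle triples (i, j, k), j the vertex, i < k, sorted."""
    nbrs = [[] for _ in range(n_atoms)]
    for i, j, _ in bonds:
        nbrs[i].append(j)
        nbrs[j].append(i)
    angles = []
    for j in range(n_atoms):
        ns = sorted(nbrs[j])
        for a in range(len(ns)):
            for b in range(a + 1, len(ns)):
                angles.append((ns[a], j, ns[b]))
    return sorted(angles)


def derive_torsions(n_atoms: int, bonds) -> list[tuple[int, int, int, int]]:
    """Unique proper torsions (i, j, k, l) around each bond j-k, sorted."""
    nbrs = [[] for _ in range(n_atoms)]
    bond_set = set()
    for i, j, _ in bonds:
        nbrs[i].append(j)
        nbrs[j].append(i)
        bond_set.add((i, j))
    torsions = set()
    for j, k in bond_set:
        for i in nbrs[j]:
            if i == k:
                continue
            for l in nbrs[k]:
                if l == j or l == i:
                    continue
                quad = (i, j, k, l)
                rev = (l, k, j, i)
                torsions.add(min(quad, rev))
    return sorted(torsions)


def perceive_topology(structure: Structure) -> Structure:
    """Infer bonds (if absent) from covalent radii, then angles and torsions.

    A pair is bonded when its distance is below ``1.2 x`` the sum of the two
    covalent radii.  Any pair closer than 0.4 A raises :class:`ClashError`.
    Ordering of all derived terms is deterministic (lexicographic).
    """
    coords = structure.coords
    n = structure.n_atoms
    if n > 1:
        diff = coords[:, None, :] - coords[None, :, :]
        dist = np.sqrt((diff ** 2).sum(-1))
        iu = np.triu_indices(n, 1)
        dmin = dist[iu].min()
        if dmin < CLASH_DISTANCE:
            i, j = min(zip(*iu), key=lambda ij: dist[ij])
            raise ClashError(
                f"atoms {i} and {j} are {dmin:.3f} A apart (< {CLASH_DISTANCE} A)"
            )
    bonds = list(structure.bonds)
    if not bonds and n > 1:
        radii = np.array([COVALENT_RADII[e] for e in structure.elements])
        cutoff = BOND_PERCEPTION_FACTOR * (radii[:, None] + radii[None, :])
        for i in range(n):
            for j in range(i + 1, n):
                if dist[i, j] < cutoff[i, j]:
                    bonds.append((i, j, 1))
    out = Structure(structure.atoms, bonds, structure.name)
    out.angles = derive_angles(n, out.bonds)
    out.torsions = derive_torsions(n, out.bonds)
    return out


# ---------------------------------------------------------------------------
# parameter sets
# ---------------------------------------------------------------------------

@dataclass
class ParameterizedSystem:
    """A Structure with every force-field term resolved to numbers.

    Bonded terms are stored as index arrays plus parameter arrays; nonbonded
    pairs are enumerated once with 1-2/1-3 exclusions and 1-4 scaling baked
    into ``nb_scale``.  ``molecule_of`` labels connected components so
    inter-molecular analyses (H-bond monitoring between host and guest) can
    partition atoms.
    """

    structure: Structure
    stretch_idx: np.ndarray        # (m, 2) int
    stretch_k: np.ndarray          # kcal/mol/A^2
    stretch_r0: np.ndarray         # A
    bend_idx: np.ndarray           # (m, 3) int
    bend_k: np.ndarray             # kcal/mol/rad^2
    bend_theta0: np.ndarray        # rad
    torsion_idx: np.ndarray        # (m, 4) int
    torsion_v: np.ndarray          # kcal/mol
    torsion_n: np.ndarray          # int periodicity
    torsion_gamma: np.ndarray      # rad
    nb_pairs: np.ndarray           # (p, 2) int
    nb_scale: np.ndarray           # 1.0 or the 1-4 factor
    nb_eps: np.ndarray             # kcal/mol (Lorentz-Berthelot combined)
    nb_sigma: np.ndarray           # A
    nb_qq: np.ndarray              # q_i*q_j, e^2
    hbond_pairs: np.ndarray        # (h, 2) int: (hydrogen, acceptor)
    donors: list[tuple[int, int]]  # (heavy donor, hydrogen)
    acceptors: list[int]
    molecule_of: np.ndarray        # (n,) int connected-component label
    options: dict                  # cutoff, dielectric, scale14, hbond params
    frozen: np.ndarray | None = None  # (n,) bool; frozen atoms never move

    @property
    def masses(self) -> np.ndarray:
        return self.structure.masses

    @property
    def n_atoms(self) -> int:
        return self.structure.n_atoms


def _load_paramset(paramset: str | Path | dict) -> dict:
    if isinstance(paramset, dict):
        return paramset
    if isinstance(paramset, (str, Path)) and Path(str(paramset)).exists():
        return yaml.safe_load(Path(paramset).read_text())
    # builtin named set shipped with the package
    fname = f"params_{paramset}.yaml"
    try:
        text = resources.files("stericds.data").joinpath(fname).read_text()
    except FileNotFoundError:
        raise UnparameterizedPatternError(
            str(paramset), f"unknown parameter set {paramset!r}"
        ) from None
    return yaml.safe_load(text)


def _pair_key(e1: str, e2: str) -> str:
    return "-".join(sorted((e1, e2)))


def _lookup(table: dict, keys: list[str], kind: str):
    for key in keys:
        if key in table:
            return table[key]
    raise UnparameterizedPatternError(keys[0], f"no {kind} parameters for "
                                               f"pattern {keys[0]!r}")


def _connected_components(n: int, bonds) -> np.ndarray:
    label = np.full(n, -1, dtype=int)
    nbrs = [[] for _ in range(n)]
    for i, j, _ in bonds:
        nbrs[i].append(j)
        nbrs[j].append(i)
    comp = 0
    for start in range(n):
        if label[start] >= 0:
            continue
        stack = [start]
        label[start] = comp
        while stack:
            v = stack.pop()
            for w in nbrs[v]:
                if label[w] < 0:
                    label[w] = comp
                    stack.append(w)
        comp += 1
    return label


def assign_parameters(structure: Structure,
                      paramset: str | Path | dict = "minimal"
                      ) -> ParameterizedSystem:
    """Resolve all force-field terms for *structure* from a parameter set.

    Missing patterns raise :class:`UnparameterizedPatternError` naming the
    pattern; parameters are never silently zeroed.  Van der Waals pair
    parameters use Lorentz-Berthelot combination (arithmetic sigma, geometric
    epsilon); hydrogen-bond donors are H atoms bonded to N/O/F and acceptors
    are N/O/F atoms.
    """
    params = _load_paramset(paramset)
    if structure.angles is None or (not structure.bonds and structure.n_atoms > 1):
        structure = perceive_topology(structure)
    elements = structure.elements
    n = structure.n_atoms

    # per-element vdW (also the "is this element parameterized" gate)
    vdw = params.get("vdw", {})
    eps = np.empty(n)
    sig = np.empty(n)
    for i, el in enumerate(elements):
        if el not in vdw:
            raise UnparameterizedPatternError(el, f"element {el!r} has no vdW "
                                                  "parameters")
        eps[i] = float(vdw[el]["epsilon"])
        sig[i] = float(vdw[el]["sigma"])

    radii = {el: COVALENT_RADII[el] for el in set(elements)}

    # stretches: one per bond
    s_idx, s_k, s_r0 = [], [], []
    for i, j, _ in structure.bonds:
        key = _pair_key(elements[i], elements[j])
        entry = _lookup(params.get("stretch", {}), [key, "*-*"], "stretch")
        r0 = entry.get("r0")
        if r0 is None:  # wildcard entries may defer to covalent radii
            r0 = radii[elements[i]] + radii[elements[j]]
        s_idx.append((i, j))
        s_k.append(float(entry["k"]))
        s_r0.append(float(r0))

    # bends: one per angle triple
    b_idx, b_k, b_t0 = [], [], []
    for i, j, k in structure.angles:
        e1, ec, e2 = elements[i], elements[j], elements[k]
        lo, hi = sorted((e1, e2))
        keys = [f"{lo}-{ec}-{hi}", f"*-{ec}-*", "*-*-*"]
        entry = _lookup(params.get("bend", {}), keys, "bend")
        b_idx.append((i, j, k))
        b_k.append(float(entry["k"]))
        b_t0.append(math.radians(float(entry["theta0"])))

    # torsions
    t_idx, t_v, t_n, t_g = [], [], [], []
    for i, j, k, l in structure.torsions:
        ej, ek = sorted((elements[j], elements[k]))
        keys = [f"*-{ej}-{ek}-*", "*-*-*-*"]
        entry = _lookup(params.get("torsion", {}), keys, "torsion")
        t_idx.append((i, j, k, l))
        t_v.append(float(entry["v"]))
        t_n.append(int(entry["n"]))
        t_g.append(math.radians(float(entry.get("gamma", 0.0))))

    # nonbonded pair list with exclusions
    opts = dict(params.get("nonbonded", {}))
    scale14 = float(opts.get("scale14", 0.5))
    bonded = {(min(i, j), max(i, j)) for i, j, _ in structure.bonds}
    excl13 = {(min(i, k), max(i, k)) for i, _, k in structure.angles}
    pairs14 = {(min(i, l), max(i, l)) for i, _, _, l in structure.torsions}
    pairs14 -= bonded | excl13
    p_idx, p_scale = [], []
    for i in range(n):
        for j in range(i + 1, n):
            key = (i, j)
            if key in bonded or key in excl13:
                continue
            p_idx.append(key)
            p_scale.append(scale14 if key in pairs14 else 1.0)
    p_idx = np.array(p_idx, dtype=int).reshape(-1, 2)
    charges = structure.charges
    if p_idx.size:
        pi, pj = p_idx[:, 0], p_idx[:, 1]
        nb_eps = np.sqrt(eps[pi] * eps[pj])
        nb_sig = 0.5 * (sig[pi] + sig[pj])
        nb_qq = charges[pi] * charges[pj]
    else:
        nb_eps = nb_sig = nb_qq = np.empty(0)

    # hydrogen-bond donors/acceptors and candidate (H, acceptor) pairs
    nbrs = [[] for _ in range(n)]
    for i, j, _ in structure.bonds:
        nbrs[i].append(j)
        nbrs[j].append(i)
    donors = []
    for h in range(n):
        if elements[h] != "H":
            continue
        for d in nbrs[h]:
            if elements[d] in HBOND_ELECTRONEGATIVE:
                donors.append((d, h))
    acceptors = [i for i in range(n) if elements[i] in HBOND_ELECTRONEGATIVE]
    hb_pairs = []
    for d, h in donors:
        for a in acceptors:
            if a == d or a in nbrs[d]:  # exclude the donor and 1-3 neighbours
                continue
            hb_pairs.append((h, a))
    hb_pairs = np.array(sorted(hb_pairs), dtype=int).reshape(-1, 2)

    options = {
        "cutoff": float(opts.get("cutoff", 12.0)),
        "dielectric": float(opts.get("dielectric", 1.5)),
        "scale14": scale14,
        "hbond": dict(params.get("hbond",
                                 {"epsilon": 2.0, "r0": 1.9, "cutoff": 5.0})),
    }

    return ParameterizedSystem(
        structure=structure,
        stretch_idx=np.array(s_idx, dtype=int).reshape(-1, 2),
        stretch_k=np.array(s_k), stretch_r0=np.array(s_r0),
        bend_idx=np.array(b_idx, dtype=int).reshape(-1, 3),
        bend_k=np.array(b_k), bend_theta0=np.array(b_t0),
        torsion_idx=np.array(t_idx, dtype=int).reshape(-1, 4),
        torsion_v=np.array(t_v), torsion_n=np.array(t_n, dtype=int),
        torsion_gamma=np.array(t_g),
        nb_pairs=p_idx, nb_scale=np.array(p_scale),
        nb_eps=nb_eps, nb_sigma=nb_sig, nb_qq=nb_qq,
        hbond_pairs=hb_pairs, donors=donors, acceptors=acceptors,
        molecule_of=_connected_components(n, structure.bonds),
        options=options,
    )


# ---------------------------------------------------------------------------
# chitin-model host
# ---------------------------------------------------------------------------

def _load_monomer_template() -> dict:
    text = resources.files("stericds.data").joinpath(
        "chitin_monomer.yaml").read_text()
    return yaml.safe_load(text)


def build_chitin_host(n_units: int) -> Structure:
    """Assemble an N-acetylglucosamine-oligomer-like host from the shipped
    monomer template.

    Units are joined with a beta(1->4)-style glycosidic link: the anomeric
    hydroxyl (O + H) of unit *i* and the C4-hydroxyl hydrogen of unit *i+1*
    are eliminated (3 atoms per linkage) and a C1-O4 bond is formed, each
    successive unit being flipped 180 degrees about the chain axis as in the
    two-fold screw of natural chitin.  The output is deterministic.
    """
    if not (1 <= n_units <= 8):
        raise ValueError(f"n_units must be in 1..8, got {n_units}")
    tpl = _load_monomer_template()
    elements = [a[0] for a in tpl["atoms"]]
    coords0 = np.array([a[1:4] for a in tpl["atoms"]], dtype=float)
    charges0 = np.array([a[4] for a in tpl["atoms"]], dtype=float)
    bonds0 = [tuple(b) for b in tpl["bonds"]]
    link = tpl["linkage"]
    c1, o4 = link["c1"], link["o4"]
    drop_head = sorted(link["drop_from_reducing"], reverse=True)  # O1, HO1
    drop_tail = link["drop_from_nonreducing"]                     # HO4
    o1 = link["o1"]

    # flip alternate units 180 deg about the x axis (chain direction)
    flip = np.diag([1.0, -1.0, -1.0])

    atoms: list[Atom] = []
    bonds: list[tuple[int, int, int]] = []
    prev_map: dict[int, int] = {}
    for u in range(n_units):
        coords = coords0 @ (flip.T if u % 2 else np.eye(3))
        drop = set()
        if u < n_units - 1:
            drop.update(drop_head)       # lose anomeric O-H (head of link)
        if u > 0:
            drop.add(drop_tail)          # lose H on O4 (tail of link)
        if u > 0:
            # place this unit so its O4 lands where the previous unit's
            # (removed) anomeric oxygen sat
            target = prev_o1_pos
            coords = coords + (target - coords[o4])
        idx_map = {}
        for k in range(len(elements)):
            if k in drop:
                continue
            idx_map[k] = len(atoms)
            atoms.append(Atom(elements[k], tuple(coords[k]),
                              partial_charge=float(charges0[k])))
        for i, j, order in bonds0:
            if i in drop or j in drop:
                continue
            bonds.append((idx_map[i], idx_map[j], order))
        if u > 0:
            bonds.append((prev_map[c1], idx_map[o4], 1))
        prev_map = idx_map
        prev_o1_pos = coords[o1] if u < n_units - 1 else None

    # neutralize the charge remainder left by the eliminated atoms,
    # spread over all atoms so the host stays exactly neutral
    total = sum(a.partial_charge for a in atoms)
    if abs(total) > 1e-12:
        shift = total / len(atoms)
        for a in atoms:
            a.partial_charge -= shift

    host = Structure(atoms, bonds, name=f"chitin_host_{n_units}")
    host.angles = derive_angles(host.n_atoms, host.bonds)
    host.torsions = derive_torsions(host.n_atoms, host.bonds)
    return host
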