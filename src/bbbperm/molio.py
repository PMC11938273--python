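"""Molecular structure I/O, 3D embedding, force-field optimization and atom annotation.

This module owns the :class:`Molecule3D` container that all geometry and
surface operations act on.  RDKit does the heavy lifting (SMILES/SDF
parsing, ETKDG embedding, MMFF94 minimization, Gasteiger charges); the
container itself is a plain, immutable-by-convention dataclass so that
downstream numerical code never depends on RDKit objects.

All operations are pure: they return a new :class:`Molecule3D` and never
mutate their input.
"""

from __future__ import annotations

import copy
import importlib.resources
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem, rdDetermineBonds

from .exceptions import (
    ConfigurationError,
    ElementError,
    EmbeddingError,
    NumericalError,
    ParameterizationError,
    ParseError,
    RadiusTableError,
    StateError,
)

__all__ = [
    "Atom",
    "Molecule3D",
    "GeometrySettings",
    "OptimizationResult",
    "parse_structure",
    "write_structure",
    "embed_3d",
    "optimize_geometry",
    "assign_partial_charges",
    "assign_vdw_radii",
    "load_radius_table",
    "bondi_radii",
]

_PERIODIC_TABLE = Chem.GetPeriodicTable()


def _atomic_number(symbol: str) -> int:
    """0 for unknown symbols (RDKit raises on some malformed ones)."""
    try:
        return _PERIODIC_TABLE.GetAtomicNumber(symbol)
    except RuntimeError:
        return 0


@dataclass
class Atom:
    """A single atom: element, Cartesian position (Å) and annotations.

    ``partial_charge`` (electron units) and ``vdw_radius`` (Å) start unset
    and are filled in by :func:`assign_partial_charges` /
    :func:`assign_vdw_radii`.
    """

    element: str
    position: np.ndarray | None = None
    formal_charge: int = 0
    partial_charge: float | None = None
    vdw_radius: float | None = None

    def __post_init__(self) -> None:
        if _atomic_number(self.element) == 0 and self.element != "*":
            raise ElementError(f"unknown element symbol {self.element!r}")
        if self.position is not None:
            self.position = np.asarray(self.position, dtype=float)
            if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
                raise ValueError(f"position must be a finite 3-vector, got {self.position!r}")
        if self.vdw_radius is not None and self.vdw_radius <= 0:
            raise ValueError("vdw_radius must be positive")

    @property
    def is_hydrogen(self) -> bool:
        return self.element == "H"


@dataclass
class Molecule3D:
    """An explicit-hydrogen molecule with optional 3D coordinates.

    ``bonds`` is a list of ``(i, j, order)`` with ``i < j``; ``provenance``
    tracks how the geometry was obtained (``raw`` = no coordinates,
    ``embedded`` = distance-geometry guess, ``optimized`` = force-field
    minimized or externally supplied optimized structure).
    """

    id: str
    atoms: list[Atom]
    bonds: list[tuple[int, int, float]]
    provenance: str = "raw"

    def __post_init__(self) -> None:
        n = len(self.atoms)
        for i, j, _order in self.bonds:
            if i == j:
                raise ValueError(f"self-bond on atom {i}")
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond ({i},{j}) out of range for {n} atoms")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def has_coordinates(self) -> bool:
        return all(a.position is not None for a in self.atoms)

    def coordinates(self) -> np.ndarray:
        if not self.has_coordinates():
            raise StateError(f"molecule {self.id!r} has atoms without coordinates")
        return np.array([a.position for a in self.atoms], dtype=float)

    def neighbors(self, index: int) -> list[int]:
        out = []
        for i, j, _ in self.bonds:
            if i == index:
                out.append(j)
            elif j == index:
                out.append(i)
        return out

    def copy(self) -> "Molecule3D":
        return copy.deepcopy(self)


@dataclass
class GeometrySettings:
    """Force-field minimization protocol (defaults follow the 3D PSA workflow:
    up to 9999 steps, energy tolerance 1e-7 kcal/mol, whole run repeated 3x)."""

    max_steps: int = 9999
    convergence_threshold: float = 1e-7
    repeats: int = 3
    method: str = "MMFF94"

    def __post_init__(self) -> None:
        if self.max_steps < 1:
            raise ConfigurationError("max_steps must be >= 1")
        if self.convergence_threshold <= 0:
            raise ConfigurationError("convergence_threshold must be positive")
        if self.repeats < 1:
            raise ConfigurationError("repeats must be >= 1")


@dataclass
class OptimizationResult:
    """Minimized molecule plus the energy trajectory across repeats."""

    molecule: Molecule3D
    initial_energy: float
    final_energy: float
    energies_per_repeat: list[float]
    converged: bool


# ---------------------------------------------------------------------------
# RDKit conversion


_BOND_ORDERS = {
    Chem.BondType.SINGLE: 1.0,
    Chem.BondType.DOUBLE: 2.0,
    Chem.BondType.TRIPLE: 3.0,
    Chem.BondType.AROMATIC: 1.5,
}
_ORDER_TO_BOND = {v: k for k, v in _BOND_ORDERS.items()}


def to_rdkit(molecule: Molecule3D, sanitize: bool = True) -> Chem.Mol:
    """Build an RDKit molecule (with a conformer when coordinates exist)."""
    em = Chem.RWMol()
    for atom in molecule.atoms:
        a = Chem.Atom(atom.element)
        a.SetFormalCharge(atom.formal_charge)
        a.SetNoImplicit(True)
        em.AddAtom(a)
    for i, j, order in molecule.bonds:
        em.AddBond(i, j, _ORDER_TO_BOND.get(order, Chem.BondType.SINGLE))
    mol = em.GetMol()
    if sanitize:
        Chem.SanitizeMol(mol)
    if molecule.has_coordinates():
        conf = Chem.Conformer(molecule.n_atoms)
        for idx, atom in enumerate(molecule.atoms):
            x, y, z = atom.position
            conf.SetAtomPosition(idx, (float(x), float(y), float(z)))
        mol.AddConformer(conf, assignId=True)
    return mol


def from_rdkit(mol: Chem.Mol, mol_id: str = "mol", provenance: str = "raw") -> Molecule3D:
    conf = mol.GetConformer() if mol.GetNumConformers() else None
    atoms = []
    for a in mol.GetAtoms():
        pos = None
        if conf is not None:
            p = conf.GetAtomPosition(a.GetIdx())
            pos = np.array([p.x, p.y, p.z])
        atoms.append(Atom(element=a.GetSymbol(), position=pos, formal_charge=a.GetFormalCharge()))
    bonds = []
    for b in mol.GetBonds():
        i, j = sorted((b.GetBeginAtomIdx(), b.GetEndAtomIdx()))
        bonds.append((i, j, _BOND_ORDERS.get(b.GetBondType(), 1.0)))
    return Molecule3D(id=mol_id, atoms=atoms, bonds=sorted(bonds), provenance=provenance)


# ---------------------------------------------------------------------------
# Parsing and writing


def parse_structure(text: str, format: str, mol_id: str = "mol") -> Molecule3D:
    """Parse a SMILES string, an SDF/MOL block, or an XYZ block into a
    :class:`Molecule3D`.

    SMILES input gets explicit hydrogens added and carries no coordinates
    (``provenance='raw'``); SDF and XYZ keep the coordinates as given
    (``provenance='optimized'`` is *not* assumed — they are tagged
    ``embedded`` so the caller decides whether to re-minimize).
    """
    if not text or not text.strip():
        raise ParseError("empty structure text")
    fmt = format.lower()
    if fmt == "smiles":
        line = text.strip().splitlines()[0]
        parts = line.split("\t")
        smiles = parts[0].strip()
        if len(parts) > 1 and parts[1].strip():
            mol_id = parts[1].strip()
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise ParseError(f"unparsable SMILES: {smiles!r}")
        mol = Chem.AddHs(mol)
        return from_rdkit(mol, mol_id=mol_id, provenance="raw")
    if fmt in ("sdf", "mol"):
        mol = Chem.MolFromMolBlock(text, removeHs=False)
        if mol is None:
            raise ParseError("unparsable SDF/MOL block")
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
        return from_rdkit(mol, mol_id=name.strip() or mol_id, provenance="embedded")
    if fmt == "xyz":
        return _parse_xyz(text, mol_id)
    raise ConfigurationError(f"unsupported structure format {format!r}")


def _parse_xyz(text: str, mol_id: str) -> Molecule3D:
    lines = text.strip().splitlines()
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError) as exc:
        raise ParseError(f"XYZ line 1: expected an atom count, got {lines[0]!r}") from exc
    if len(lines) < n + 2:
        raise ParseError(f"XYZ: expected {n} atom lines, found {len(lines) - 2}")
    comment = lines[1].strip()
    atoms = []
    for ln, line in enumerate(lines[2 : 2 + n], start=3):
        fields = line.split()
        if len(fields) < 4:
            raise ParseError(f"XYZ line {ln}: expected 'element x y z', got {line!r}")
        element = fields[0].capitalize() if len(fields[0]) > 1 else fields[0].upper()
        if _atomic_number(element) == 0:
            raise ElementError(f"XYZ line {ln}: unknown element {fields[0]!r}")
        try:
            xyz = [float(v) for v in fields[1:4]]
        except ValueError as exc:
            raise ParseError(f"XYZ line {ln}: non-numeric coordinate in {line!r}") from exc
        atoms.append(Atom(element=element, position=np.array(xyz)))
    bonds = _perceive_bonds(atoms)
    return Molecule3D(id=comment or mol_id, atoms=atoms, bonds=bonds, provenance="embedded")


def _perceive_bonds(atoms: Sequence[Atom]) -> list[tuple[int, int, float]]:
    """Connectivity from interatomic distances (RDKit's perception, with a
    covalent-radius fallback for fragments RDKit rejects)."""
    block = f"{len(atoms)}\n\n" + "\n".join(
        f"{a.element} {a.position[0]:.6f} {a.position[1]:.6f} {a.position[2]:.6f}" for a in atoms
    )
    raw = Chem.MolFromXYZBlock(block)
    if raw is not None:
        try:
            rdDetermineBonds.DetermineConnectivity(raw)
            return sorted(
                (*sorted((b.GetBeginAtomIdx(), b.GetEndAtomIdx())), 1.0) for b in raw.GetBonds()
            )
        except (ValueError, RuntimeError):
            pass
    bonds = []
    for i in range(len(atoms)):
        for j in range(i + 1, len(atoms)):
            ri = _PERIODIC_TABLE.GetRcovalent(atoms[i].element)
            rj = _PERIODIC_TABLE.GetRcovalent(atoms[j].element)
            d = float(np.linalg.norm(atoms[i].position - atoms[j].position))
            if d < 1.3 * (ri + rj):
                bonds.append((i, j, 1.0))
    return bonds


def write_structure(molecule: Molecule3D, format: str) -> str:
    """Serialize to an SDF (MOL V2000) or XYZ block."""
    fmt = format.lower()
    if fmt in ("sdf", "mol"):
        mol = to_rdkit(molecule, sanitize=False)
        Chem.SanitizeMol(mol, Chem.SanitizeFlags.SANITIZE_FINDRADICALS)
        mol.SetProp("_Name", molecule.id)
        return Chem.MolToMolBlock(mol, includeStereo=False)
    if fmt == "xyz":
        coords = molecule.coordinates()
        lines = [str(molecule.n_atoms), molecule.id]
        for atom, (x, y, z) in zip(molecule.atoms, coords):
            lines.append(f"{atom.element} {x:.8f} {y:.8f} {z:.8f}")
        return "\n".join(lines) + "\n"
    raise ConfigurationError(f"unsupported output format {format!r}")


# ---------------------------------------------------------------------------
# Embedding and optimization


def embed_3d(molecule: Molecule3D, seed: int, max_attempts: int = 5) -> Molecule3D:
    """Generate 3D coordinates with the ETKDG distance-geometry method.

    The same ``seed`` always yields bitwise-identical coordinates; different
    seeds yield different conformers.
    """
    if molecule.n_atoms == 0:
        raise EmbeddingError("cannot embed an empty molecule")
    mol = to_rdkit(molecule)
    for attempt in range(max_attempts):
        params = AllChem.ETKDGv3()
        params.randomSeed = int(seed) + 7919 * attempt
        params.useRandomCoords = attempt > 1
        if AllChem.EmbedMolecule(mol, params) == 0:
            out = from_rdkit(mol, mol_id=molecule.id, provenance="embedded")
            for new, old in zip(out.atoms, molecule.atoms):
                new.partial_charge = old.partial_charge
                new.vdw_radius = old.vdw_radius
            return out
    raise EmbeddingError(f"embedding failed for {molecule.id!r} after {max_attempts} attempts")


def optimize_geometry(
    molecule: Molecule3D, settings: GeometrySettings | None = None
) -> OptimizationResult:
    """Minimize the geometry with the Merck molecular force field (MMFF94).

    The full minimization is repeated ``settings.repeats`` times on the
    running geometry; the energy is non-increasing across repeats.  The
    ``converged`` flag reports whether the last repeat terminated below the
    energy-change threshold (i.e. the minimizer stopped before exhausting
    ``max_steps``).
    """
    settings = settings or GeometrySettings()
    if settings.method.upper() not in ("MMFF94", "MMFF94S", "MMFF"):
        raise ConfigurationError(f"unsupported force field {settings.method!r}")
    if not molecule.has_coordinates():
        raise StateError("optimize_geometry requires coordinates; call embed_3d first")
    mol = to_rdkit(molecule)
    variant = "MMFF94s" if settings.method.upper() == "MMFF94S" else "MMFF94"
    props = AllChem.MMFFGetMoleculeProperties(mol, mmffVariant=variant)
    if props is None:
        raise ParameterizationError(f"MMFF cannot parameterize molecule {molecule.id!r}")
    ff = AllChem.MMFFGetMoleculeForceField(mol, props)
    if ff is None:
        raise ParameterizationError(f"MMFF force field setup failed for {molecule.id!r}")
    initial = ff.CalcEnergy()
    if not math.isfinite(initial):
        raise NumericalError(f"non-finite initial MMFF energy for {molecule.id!r}")
    conf = mol.GetConformer()
    energies = []
    converged = False
    best = initial
    for _ in range(settings.repeats):
        snapshot = [conf.GetAtomPosition(i) for i in range(mol.GetNumAtoms())]
        status = ff.Minimize(
            maxIts=settings.max_steps, energyTol=settings.convergence_threshold
        )
        e = ff.CalcEnergy()
        if not math.isfinite(e):
            raise NumericalError(f"non-finite MMFF energy for {molecule.id!r}")
        if e > best:
            # a re-minimization from a converged state can wiggle upward by
            # numerical noise; keep the better geometry
            for i, p in enumerate(snapshot):
                conf.SetAtomPosition(i, p)
            e = best
        best = e
        energies.append(e)
        converged = status == 0
    out = from_rdkit(mol, mol_id=molecule.id, provenance="optimized")
    for new, old in zip(out.atoms, molecule.atoms):
        new.partial_charge = old.partial_charge
        new.vdw_radius = old.vdw_radius
    return OptimizationResult(
        molecule=out,
        initial_energy=initial,
        final_energy=energies[-1],
        energies_per_repeat=energies,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# Atom annotation


def assign_partial_charges(molecule: Molecule3D, model: str = "gasteiger") -> Molecule3D:
    """Attach per-atom partial charges (electron units).

    ``model='gasteiger'`` computes Gasteiger–Marsili charges; ``'mmff94'``
    uses MMFF94 bond-charge-increment charges.  Both conserve the molecular
    formal charge.  Pre-existing charges (e.g. read from an input column)
    can be kept with ``model='input'``.
    """
    model = model.lower()
    out = molecule.copy()
    if model == "input":
        if any(a.partial_charge is None for a in out.atoms):
            raise StateError("model='input' but some atoms have no partial charge")
        return out
    mol = to_rdkit(molecule)
    if model == "gasteiger":
        AllChem.ComputeGasteigerCharges(mol)
        charges = [float(a.GetDoubleProp("_GasteigerCharge")) for a in mol.GetAtoms()]
    elif model in ("mmff94", "mmff"):
        props = AllChem.MMFFGetMoleculeProperties(mol)
        if props is None:
            raise ParameterizationError(f"MMFF charges unavailable for {molecule.id!r}")
        charges = [props.GetMMFFPartialCharge(i) for i in range(mol.GetNumAtoms())]
    else:
        raise ConfigurationError(f"unsupported charge model {model!r}")
    if not all(math.isfinite(c) for c in charges):
        raise NumericalError(f"non-finite partial charge for {molecule.id!r}")
    for atom, q in zip(out.atoms, charges):
        atom.partial_charge = q
    return out


def load_radius_table(path) -> dict[str, float]:
    """Read an element<TAB>radius table (Å); '#' lines are comments."""
    table = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            element, value = line.split("\t")
            table[element] = float(value)
    return table


def bondi_radii() -> dict[str, float]:
    """The packaged Bondi (1964) van der Waals radius table."""
    ref = importlib.resources.files("bbbperm.data") / "bondi_radii.tsv"
    with importlib.resources.as_file(ref) as path:
        return load_radius_table(path)


def assign_vdw_radii(
    molecule: Molecule3D, table: Mapping[str, float] | None = None
) -> Molecule3D:
    """Attach van der Waals radii from ``table`` (default: Bondi 1964)."""
    table = dict(table) if table is not None else bondi_radii()
    missing = sorted({a.element for a in molecule.atoms} - set(table))
    if missing:
        raise RadiusTableError(f"radius table lacks element(s): {', '.join(missing)}")
    out = molecule.copy()
    for atom in out.atoms:
        atom.vdw_radius = table[atom.element]
    return out
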