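"""Dot-surface solvent-accessible areas and the geometric 3D polar surface area.

The surface is the classic Shrake–Rupley construction: quasi-uniform test
points ("dots") are placed on each atom's solvent-accessible sphere of
radius ``r_vdw + probe`` (probe 1.4 Å = water), and a dot counts toward the
atom's exposed area unless it lies inside some other atom's accessible
sphere.  The dots come from recursive icosahedron subdivision, so the
construction is deterministic and symmetric; the "dot density" level ``L``
yields ``10·4^L + 2`` dots per atom (level 4 → 2562).

The 3D PSA is the polar share of that surface: the summed exposed area of
nitrogen and oxygen atoms plus their attached hydrogens, optionally further
restricted to atoms whose partial charge exceeds ±0.6 e.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .exceptions import ConfigurationError, StateError
from .molio import Molecule3D

__all__ = [
    "DotSurfaceSettings",
    "PolarRule",
    "SurfaceResult",
    "generate_dot_sphere",
    "compute_sasa",
    "select_polar_atoms",
    "compute_3d_psa",
]

MAX_DENSITY_LEVEL = 5


@dataclass(frozen=True)
class DotSurfaceSettings:
    """Dot-surface parameters: water probe 1.4 Å, density level 4 (2562
    dots/atom), dots on the solvent-accessible sphere (``dot_solvent``)."""

    probe_radius: float = 1.4
    density_level: int = 4
    dot_solvent: bool = True

    def __post_init__(self) -> None:
        if self.probe_radius < 0:
            raise ConfigurationError("probe_radius must be >= 0")
        if not 1 <= self.density_level <= MAX_DENSITY_LEVEL:
            raise ConfigurationError(
                f"density_level must be in [1, {MAX_DENSITY_LEVEL}], got {self.density_level}"
            )


@dataclass(frozen=True)
class PolarRule:
    """Which atoms count as polar.

    Default: N and O plus their attached hydrogens.  With
    ``use_charge_filter`` the set is additionally intersected with atoms of
    |partial charge| ≥ ``charge_threshold`` (default 0.6 e) and their
    attached hydrogens.
    """

    elements: frozenset[str] = frozenset({"N", "O"})
    include_attached_h: bool = True
    charge_threshold: float = 0.6
    use_charge_filter: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "elements", frozenset(self.elements))
        if self.charge_threshold < 0:
            raise ConfigurationError("charge_threshold must be >= 0")


@dataclass
class SurfaceResult:
    """Per-atom exposed areas (Å²), their total, and the polar share."""

    per_atom_area: np.ndarray
    total_sasa: float
    polar_area: float
    polar_atom_indices: frozenset[int]
    settings_used: DotSurfaceSettings


# ---------------------------------------------------------------------------
# Icosphere dots


def _icosahedron() -> tuple[np.ndarray, list[tuple[int, int, int]]]:
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array(
        [
            (-1, phi, 0), (1, phi, 0), (-1, -phi, 0), (1, -phi, 0),
            (0, -1, phi), (0, 1, phi), (0, -1, -phi), (0, 1, -phi),
            (phi, 0, -1), (phi, 0, 1), (-phi, 0, -1), (-phi, 0, 1),
        ],
        dtype=float,
    )
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    faces = [
        (0, 11, 5), (0, 5, 1), (0, 1, 7), (0, 7, 10), (0, 10, 11),
        (1, 5, 9), (5, 11, 4), (11, 10, 2), (10, 7, 6), (7, 1, 8),
        (3, 9, 4), (3, 4, 2), (3, 2, 6), (3, 6, 8), (3, 8, 9),
        (4, 9, 5), (2, 4, 11), (6, 2, 10), (8, 6, 7), (9, 8, 1),
    ]
    return verts, faces


@lru_cache(maxsize=MAX_DENSITY_LEVEL + 1)
def generate_dot_sphere(density_level: int) -> np.ndarray:
    """Unit-sphere dots by icosahedron subdivision: ``10·4^level + 2`` points.

    Level 0 is the bare icosahedron (12 vertices).  Each subdivision splits
    every triangle in four and re-projects new vertices onto the sphere.
    The result is deterministic and centro-symmetric.
    """
    if not 0 <= density_level <= MAX_DENSITY_LEVEL:
        raise ConfigurationError(
            f"density_level must be in [0, {MAX_DENSITY_LEVEL}], got {density_level}"
        )
    verts, faces = _icosahedron()
    verts = [tuple(v) for v in verts]
    for _ in range(density_level):
        midpoint_cache: dict[tuple[int, int], int] = {}

        def midpoint(i: int, j: int) -> int:
            key = (min(i, j), max(i, j))
            if key not in midpoint_cache:
                m = np.add(verts[i], verts[j]) / 2.0
                m /= np.linalg.norm(m)
                verts.append(tuple(m))
                midpoint_cache[key] = len(verts) - 1
            return midpoint_cache[key]

        new_faces = []
        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [(a, ab, ca), (b, bc, ab), (c, ca, bc), (ab, bc, ca)]
        faces = new_faces
    dots = np.array(verts, dtype=float)
    dots.setflags(write=False)
    return dots


# ---------------------------------------------------------------------------
# SASA


def _require_surface_ready(molecule: Molecule3D) -> None:
    for idx, atom in enumerate(molecule.atoms):
        if atom.position is None:
            raise StateError(f"atom {idx} of {molecule.id!r} has no coordinates")
        if atom.vdw_radius is None:
            raise StateError(
                f"atom {idx} of {molecule.id!r} has no vdW radius; call assign_vdw_radii"
            )


def compute_sasa(
    molecule: Molecule3D, settings: DotSurfaceSettings | None = None
) -> SurfaceResult:
    """Shrake–Rupley solvent-accessible surface area.

    For atom *i*, dots sit at ``x_i + (r_i + probe)·u`` for each unit dot
    ``u``; a dot is exposed iff its distance to every other atom *j* is at
    least ``r_j + probe`` (a dot exactly on a neighbor's sphere counts as
    exposed).  The atom's area is the exposed-dot fraction of
    ``4π(r_i + probe)²``.  With ``dot_solvent=False`` the same test runs on
    the bare van der Waals spheres.
    """
    settings = settings or DotSurfaceSettings()
    _require_surface_ready(molecule)
    coords = molecule.coordinates()
    radii = np.array([a.vdw_radius for a in molecule.atoms], dtype=float)
    probe = settings.probe_radius if settings.dot_solvent else 0.0
    sphere_radii = radii + probe
    dots = generate_dot_sphere(settings.density_level)
    n_dots = len(dots)

    per_atom = np.zeros(molecule.n_atoms)
    for i in range(molecule.n_atoms):
        dot_pos = coords[i] + sphere_radii[i] * dots  # (D, 3)
        # only neighbors whose accessible sphere can reach atom i's sphere
        sep = np.linalg.norm(coords - coords[i], axis=1)
        near = np.where((sep < sphere_radii + sphere_radii[i]) & (np.arange(len(sep)) != i))[0]
        exposed = np.ones(n_dots, dtype=bool)
        for j in near:
            d2 = np.einsum("ij,ij->i", dot_pos - coords[j], dot_pos - coords[j])
            exposed &= d2 >= sphere_radii[j] ** 2
        per_atom[i] = 4.0 * np.pi * sphere_radii[i] ** 2 * exposed.sum() / n_dots

    total = float(per_atom.sum())
    return SurfaceResult(
        per_atom_area=per_atom,
        total_sasa=total,
        polar_area=0.0,
        polar_atom_indices=frozenset(),
        settings_used=settings,
    )


def select_polar_atoms(molecule: Molecule3D, rule: PolarRule | None = None) -> frozenset[int]:
    """Atom indices counted as polar under ``rule``.

    Element rule: atoms whose element is in ``rule.elements`` plus (when
    ``include_attached_h``) hydrogens bonded to one of them.  The optional
    charge filter intersects with {|q| ≥ threshold} ∪ {their attached H}.
    """
    rule = rule or PolarRule()

    def with_attached_h(core: set[int]) -> set[int]:
        out = set(core)
        if rule.include_attached_h:
            for idx in core:
                for nb in molecule.neighbors(idx):
                    if molecule.atoms[nb].is_hydrogen:
                        out.add(nb)
        return out

    by_element = with_attached_h(
        {i for i, a in enumerate(molecule.atoms) if a.element in rule.elements}
    )
    if not rule.use_charge_filter:
        return frozenset(by_element)
    if any(a.partial_charge is None for a in molecule.atoms):
        raise StateError("charge filter requested but partial charges are missing")
    by_charge = with_attached_h(
        {
            i
            for i, a in enumerate(molecule.atoms)
            if abs(a.partial_charge) >= rule.charge_threshold
        }
    )
    return frozenset(by_element & by_charge)


def compute_3d_psa(
    molecule: Molecule3D,
    settings: DotSurfaceSettings | None = None,
    rule: PolarRule | None = None,
) -> SurfaceResult:
    """SASA plus its polar share (the 3D PSA) in one pass."""
    result = compute_sasa(molecule, settings)
    polar = select_polar_atoms(molecule, rule)
    result.polar_atom_indices = polar
    result.polar_area = float(result.per_atom_area[sorted(polar)].sum()) if polar else 0.0
    return result
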