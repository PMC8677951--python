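"""Topology descriptors of porphyrinoid macrocycles from XYZ geometries.

Two geometric descriptors summarize the conformation of an expanded
porphyrin:

* **Φ_p** (torsional ring strain, degrees) — the average dihedral angle
  between neighboring heterocycle ring planes, taken over the six cyclic
  neighbor pairs; planar macrocycles have Φ_p near 0°, strongly twisted ones
  tens of degrees.
* **Π** (π-conjugation index, signed, |Π| ≤ 1) — the product over cyclic
  neighbor pairs of the cosines between consecutively orientation-propagated
  ring-plane normals.  It measures how effectively neighboring p-orbitals
  overlap; an untwisted (Hückel) loop gives a positive product, while a
  singly-twisted (Möbius) loop forces exactly one orientation reversal and a
  negative product.  Values above ~0.30 indicate conformations able to
  sustain macrocyclic aromaticity.

Ring planes are total-least-squares fits (smallest singular vector of the
centered ring coordinates).  An inversion-center test classifies
centrosymmetric (C_i) structures, whose first hyperpolarizability — and
hence β_HRS — vanishes identically.

A fixture generator builds hexaphyrin-like frames (six regular pentagon
rings on a circle with prescribed inter-ring plane angles and an optional
Möbius reversal) so every operation is testable against constructed truth
without quantum-chemistry coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "MacrocycleGeometry",
    "TopologyDescriptors",
    "read_xyz",
    "write_xyz",
    "ring_plane_normal",
    "phi_p",
    "pi_index",
    "classify_topology",
    "detect_inversion_center",
    "describe",
    "ring_normals_for_angles",
    "build_macrocycle",
    "GeometryError",
]

PI_AROMATIC_THRESHOLD = 0.30


class GeometryError(ValueError):
    """Invalid geometry, sidecar, or degenerate ring."""


@dataclass(frozen=True)
class MacrocycleGeometry:
    """Atoms plus the ordered heterocycle rings of the macrocycle.

    ``rings`` holds 0-based atom indices, ordered around the macrocycle with
    wraparound neighbor relation; the optional ``path`` lists the annulene
    conjugation pathway.
    """

    elements: tuple[str, ...]
    coordinates: np.ndarray  # (n_atoms, 3), Angstrom
    rings: tuple[tuple[int, ...], ...]
    path: tuple[int, ...] = ()

    def __post_init__(self):
        coords = np.asarray(self.coordinates, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise GeometryError(f"coordinates must be (n, 3), got {coords.shape}")
        if len(self.elements) != coords.shape[0]:
            raise GeometryError("elements and coordinates length mismatch")
        n = coords.shape[0]
        for ring in self.rings:
            if len(ring) < 4:
                raise GeometryError(f"ring {ring} has fewer than 4 atoms")
            for i in ring:
                if not 0 <= i < n:
                    raise GeometryError(f"ring atom index {i} out of range (n={n})")
        for i in self.path:
            if not 0 <= i < n:
                raise GeometryError(f"path atom index {i} out of range (n={n})")
        object.__setattr__(self, "coordinates", coords)


@dataclass(frozen=True)
class TopologyDescriptors:
    phi_p: float
    pi_index: float
    topology: str  # Hueckel | Moebius
    aromatic_by_pi: bool
    centrosymmetric: bool


def read_xyz(xyz_path, rings_path) -> MacrocycleGeometry:
    """Read a standard XYZ file plus a YAML/JSON sidecar naming the rings.

    Sidecar schema (1-based atom indices)::

        rings:
          - [1, 2, 3, 4, 5]
          ...
        path: [1, 2, ...]   # optional
    """
    lines = Path(xyz_path).read_text().splitlines()
    if len(lines) < 2:
        raise GeometryError(f"{xyz_path}: truncated XYZ file")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise GeometryError(f"{xyz_path}: first line must be the atom count") from None
    if len(lines) < 2 + n:
        raise GeometryError(f"{xyz_path}: expected {n} atom lines")
    elements, coords = [], []
    for ln in lines[2 : 2 + n]:
        parts = ln.split()
        if len(parts) < 4:
            raise GeometryError(f"{xyz_path}: malformed atom line {ln!r}")
        elements.append(parts[0])
        try:
            coords.append([float(p) for p in parts[1:4]])
        except ValueError:
            raise GeometryError(f"{xyz_path}: non-numeric coordinate in {ln!r}") from None

    side = yaml.safe_load(Path(rings_path).read_text())
    if not isinstance(side, dict) or "rings" not in side:
        raise GeometryError(f"{rings_path}: sidecar must define 'rings'")

    def _to0(indices, what):
        out = []
        for i in indices:
            if not isinstance(i, int) or i < 1:
                raise GeometryError(
                    f"{rings_path}: {what} indices are 1-based positive, got {i!r}"
                )
            out.append(i - 1)
        return tuple(out)

    rings = tuple(_to0(r, "ring") for r in side["rings"])
    path = _to0(side.get("path", []), "path")
    return MacrocycleGeometry(tuple(elements), np.array(coords), rings, path)


def write_xyz(g: MacrocycleGeometry, xyz_path, rings_path=None, comment="") -> None:
    lines = [str(len(g.elements)), comment]
    for el, (x, y, z) in zip(g.elements, g.coordinates):
        lines.append(f"{el} {x:.10f} {y:.10f} {z:.10f}")
    Path(xyz_path).write_text("\n".join(lines) + "\n")
    if rings_path is not None:
        doc = {"rings": [[i + 1 for i in r] for r in g.rings]}
        if g.path:
            doc["path"] = [i + 1 for i in g.path]
        Path(rings_path).write_text(yaml.safe_dump(doc))


def ring_plane_normal(coords: np.ndarray) -> np.ndarray:
    """Unit normal of the total-least-squares plane through the ring atoms."""
    pts = np.asarray(coords, dtype=float)
    centered = pts - pts.mean(axis=0)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < 1e-10 * max(s[0], 1e-30):
        raise GeometryError("degenerate (collinear) ring: plane fit undefined")
    return vt[2]


def _ring_normals(g: MacrocycleGeometry) -> np.ndarray:
    if len(g.rings) < 2:
        raise GeometryError("need at least 2 rings")
    return np.array([ring_plane_normal(g.coordinates[list(r)]) for r in g.rings])


def phi_p(g: MacrocycleGeometry) -> float:
    """Average inter-ring plane dihedral over the cyclic neighbor pairs, degrees.

    Each pair contributes the unsigned angle between ring planes, folded into
    [0°, 90°] (plane orientation carries no sign).
    """
    normals = _ring_normals(g)
    n = len(normals)
    angles = []
    for m in range(n):
        c = abs(float(np.dot(normals[m], normals[(m + 1) % n])))
        angles.append(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))
    return float(np.mean(angles))


def pi_index(g: MacrocycleGeometry) -> float:
    """Signed p-orbital overlap product Π.

    Ring normals from plane fits are sign-ambiguous, so orientation is
    propagated around the loop: each normal is flipped, if needed, to point
    along its predecessor.  The product of the neighbor cosines then closes
    the loop against the *original* first normal; an untwisted loop closes
    consistently (Π > 0) while a Möbius loop accumulates one reversal
    (Π < 0), whatever ring is chosen as the start.
    """
    normals = _ring_normals(g)
    n = len(normals)
    oriented = [normals[0]]
    for m in range(1, n):
        nm = normals[m]
        if np.dot(oriented[-1], nm) < 0:
            nm = -nm
        oriented.append(nm)
    product = 1.0
    for m in range(n):
        if m < n - 1:
            product *= float(np.dot(oriented[m], oriented[m + 1]))
        else:
            product *= float(np.dot(oriented[-1], oriented[0]))  # closure, unflipped
    return product


def classify_topology(pi: float) -> str:
    """Hueckel for Π > 0, Moebius for Π < 0; Π = 0 is indeterminate."""
    if pi > 0:
        return "Hueckel"
    if pi < 0:
        return "Moebius"
    raise GeometryError("pi_index is zero: topology indeterminate")


def detect_inversion_center(g: MacrocycleGeometry, tol: float = 0.1):
    """Test whether inversion through the centroid maps the structure onto itself.

    Every atom must map onto an atom of the same element within ``tol`` Å
    under x → 2·centroid − x, with a one-to-one matching (greedy nearest
    neighbor with verification — adequate for exact or near-exact C_i).
    Returns ``(is_centrosymmetric, centroid)``.
    """
    coords = g.coordinates
    if len(coords) < 2:
        raise GeometryError("need at least 2 atoms")
    center = coords.mean(axis=0)
    inverted = 2 * center - coords
    unused: dict[str, list[int]] = {}
    for i, el in enumerate(g.elements):
        unused.setdefault(el, []).append(i)
    for i, el in enumerate(g.elements):
        candidates = unused.get(el, [])
        if not candidates:
            return False, center
        dists = np.linalg.norm(coords[candidates] - inverted[i], axis=1)
        j = int(np.argmin(dists))
        if dists[j] > tol:
            return False, center
        candidates.pop(j)
    return True, center


def describe(g: MacrocycleGeometry, inversion_tol: float = 0.1) -> TopologyDescriptors:
    """All topology descriptors of a geometry in one pass."""
    pi = pi_index(g)
    return TopologyDescriptors(
        phi_p=phi_p(g),
        pi_index=pi,
        topology=classify_topology(pi),
        aromatic_by_pi=pi >= PI_AROMATIC_THRESHOLD,
        centrosymmetric=detect_inversion_center(g, inversion_tol)[0],
    )


# --- synthetic fixture generator --------------------------------------------

def ring_normals_for_angles(angles, moebius: bool = False) -> np.ndarray:
    """Six unit normals whose cyclic neighbor plane angles equal ``angles``.

    ``angles`` are the six inter-ring plane angles in degrees, each in
    [0°, 90°]; with ``moebius=True`` the loop closes with one orientation
    reversal (oriented normals sweep past 90°), which flips the sign of Π
    while keeping the same unsigned plane angles.

    Construction: normals are placed on the unit sphere at colatitudes
    interpolating from ``angles[0]`` to the closure colatitude (``angles[5]``
    or 180° − ``angles[5]``), with azimuth increments solved from the
    spherical law of cosines so consecutive arc distances match exactly.
    Raises if no such closed loop exists (spherical triangle inequalities).
    """
    a = np.asarray(angles, dtype=float)
    if a.shape != (6,):
        raise GeometryError("need exactly 6 neighbor angles")
    if np.any(a < 0) or np.any(a > 90):
        raise GeometryError("plane angles must lie in [0, 90] degrees")
    a_rad = np.radians(a)
    theta = np.empty(6)
    theta[0] = 0.0
    theta[1] = a_rad[0]
    closure = np.pi - a_rad[5] if moebius else a_rad[5]
    # colatitude path theta[1] -> theta[5] in 4 arcs of lengths a[1..4]
    theta[5] = closure
    for m in (2, 3, 4):
        remaining = theta[5] - theta[m - 1]
        steps_left = 5 - (m - 1)
        theta[m] = theta[m - 1] + remaining / steps_left
        lo = abs(theta[m - 1] - a_rad[m - 1])
        hi = theta[m - 1] + a_rad[m - 1]
        theta[m] = float(np.clip(theta[m], lo, hi))
    phi = np.zeros(6)
    for m in range(1, 5):
        t0, t1, arc = theta[m], theta[m + 1], a_rad[m]
        s0, s1 = np.sin(t0), np.sin(t1)
        if s0 < 1e-12 or s1 < 1e-12:
            if abs(abs(t1 - t0) - arc) > 1e-9:
                raise GeometryError(
                    f"cannot realize angle sequence {list(a)}: polar step {m}"
                )
            dphi = 0.0
        else:
            cosd = (np.cos(arc) - np.cos(t0) * np.cos(t1)) / (s0 * s1)
            if not -1 - 1e-9 <= cosd <= 1 + 1e-9:
                raise GeometryError(
                    f"angle sequence {list(a)} violates the spherical "
                    f"triangle inequality at step {m}"
                )
            dphi = float(np.arccos(np.clip(cosd, -1.0, 1.0)))
        phi[m + 1] = phi[m] + dphi
    normals = np.column_stack(
        [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)]
    )
    return normals


def build_macrocycle(
    normals: np.ndarray,
    macro_radius: float = 6.0,
    ring_radius: float = 1.2,
    atoms_per_ring: int = 5,
    element: str = "C",
) -> MacrocycleGeometry:
    """Place one regular polygon ring per normal on a circle.

    Ring m sits at azimuth 2πm/n on a circle of ``macro_radius`` Å in the xy
    plane, its atoms forming a regular ``atoms_per_ring``-gon of radius
    ``ring_radius`` Å in the plane perpendicular to ``normals[m]``.  The
    inter-ring plane angles of the result equal those of the supplied
    normals exactly (up to floating point), making Φ_p and Π known by
    construction.
    """
    normals = np.asarray(normals, dtype=float)
    n_rings = len(normals)
    elements: list[str] = []
    coords: list[np.ndarray] = []
    rings: list[tuple[int, ...]] = []
    for m, nm in enumerate(normals):
        nm = nm / np.linalg.norm(nm)
        ref = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(ref, nm)) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        e1 = ref - np.dot(ref, nm) * nm
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(nm, e1)
        az = 2 * np.pi * m / n_rings
        center = macro_radius * np.array([np.cos(az), np.sin(az), 0.0])
        start = len(elements)
        for k in range(atoms_per_ring):
            ang = 2 * np.pi * k / atoms_per_ring
            coords.append(center + ring_radius * (np.cos(ang) * e1 + np.sin(ang) * e2))
            elements.append(element)
        rings.append(tuple(range(start, start + atoms_per_ring)))
    return MacrocycleGeometry(tuple(elements), np.array(coords), tuple(rings))
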