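"""Molecular geometry containers and multi-frame XYZ input/output.

The package works with labelled 12-atom 2-thiouracil structures.  Ring sites
follow the standard pyrimidine numbering N1-C2-N3-C4-C5-C6 with the thione
sulfur on C2, the carbonyl oxygen on C4, and protons H9 (N1), H10 (N3),
H11 (C5), H12 (C6).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np

from .constants import ALLOWED_ELEMENTS, ISOTOPE_MASS_AMU

CANONICAL_SITE_LABELS = (
    "N1", "C2", "N3", "C4", "C5", "C6", "S", "O", "H9", "H10", "H11", "H12",
)
CANONICAL_ELEMENTS = ("N", "C", "N", "C", "C", "C", "S", "O", "H", "H", "H", "H")
RING_SITES = ("N1", "C2", "N3", "C4", "C5", "C6")

#: formula of 2-thiouracil as element -> count
COMPOSITION_2TURA = {"C": 4, "H": 4, "N": 2, "O": 1, "S": 1}

MIN_PAIR_DISTANCE = 0.5  # Angstrom; anything closer is an atom clash


class GeometryError(ValueError):
    """Raised for invalid geometries or malformed geometry files."""


@dataclass(frozen=True)
class Atom:
    """A labelled atom: chemical element, isotope mass (amu), site label."""

    element: str
    site_label: str
    mass: float = 0.0

    def __post_init__(self):
        if self.element not in ALLOWED_ELEMENTS:
            raise GeometryError(f"unsupported element {self.element!r}")
        if self.mass == 0.0:
            object.__setattr__(self, "mass", ISOTOPE_MASS_AMU[self.element])
        if self.mass <= 0:
            raise GeometryError(f"non-positive mass for {self.site_label}")


@dataclass
class Geometry:
    """An ordered set of atoms with Cartesian positions in Angstrom."""

    atoms: list[Atom]
    positions: np.ndarray          # (n_atoms, 3), Angstrom
    time: float | None = None      # fs
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.shape != (len(self.atoms), 3):
            raise GeometryError(
                f"positions shape {self.positions.shape} does not match "
                f"{len(self.atoms)} atoms")
        if not np.all(np.isfinite(self.positions)):
            raise GeometryError("non-finite coordinates")
        labels = [a.site_label for a in self.atoms]
        if len(set(labels)) != len(labels):
            raise GeometryError("duplicate site labels")
        self._index = {a.site_label: i for i, a in enumerate(self.atoms)}

    # -- accessors ---------------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    @property
    def site_labels(self) -> list[str]:
        return [a.site_label for a in self.atoms]

    @property
    def masses_amu(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms])

    def index(self, site_label: str) -> int:
        try:
            return self._index[site_label]
        except KeyError:
            raise GeometryError(f"no atom with site label {site_label!r}") from None

    def r(self, site_label: str) -> np.ndarray:
        """Position of a labelled atom."""
        return self.positions[self.index(site_label)]

    def bond_vector(self, a: str, b: str) -> np.ndarray:
        """Vector from site ``a`` to site ``b``."""
        return self.r(b) - self.r(a)

    def distance(self, a: str, b: str) -> float:
        return float(np.linalg.norm(self.bond_vector(a, b)))

    def copy(self, **overrides) -> "Geometry":
        g = replace(self, positions=self.positions.copy(), **overrides)
        g.meta = dict(self.meta)
        return g

    # -- validation --------------------------------------------------------
    def composition(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for e in self.elements:
            out[e] = out.get(e, 0) + 1
        return out

    def min_pair_distance(self) -> float:
        d = np.linalg.norm(self.positions[:, None] - self.positions[None, :], axis=-1)
        iu = np.triu_indices(self.n_atoms, 1)
        return float(d[iu].min())

    def validate_2tura(self) -> None:
        """Enforce the 2-thiouracil contract: 12 atoms, C4H4N2OS, no clash."""
        if self.n_atoms != 12:
            raise GeometryError(f"expected 12 atoms, got {self.n_atoms}")
        if self.composition() != COMPOSITION_2TURA:
            raise GeometryError(f"composition {self.composition()} is not C4H4N2OS")
        dmin = self.min_pair_distance()
        if dmin <= MIN_PAIR_DISTANCE:
            raise GeometryError(
                f"atom clash: minimum pairwise distance {dmin:.3f} A "
                f"<= {MIN_PAIR_DISTANCE} A")

    # -- planarity helpers -------------------------------------------------
    def ring_plane(self) -> tuple[np.ndarray, np.ndarray]:
        """Best-fit plane through the six ring atoms: (centroid, unit normal)."""
        pts = np.array([self.r(s) for s in RING_SITES])
        return best_fit_plane(pts)

    def out_of_plane(self) -> np.ndarray:
        """Signed distance of every atom from the ring best-fit plane (A)."""
        c, n = self.ring_plane()
        return (self.positions - c) @ n

    def rms_out_of_plane(self) -> float:
        return float(np.sqrt(np.mean(self.out_of_plane() ** 2)))


def best_fit_plane(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares plane through points: returns (centroid, unit normal).

    The normal sign is fixed to have a non-negative z component (ties broken
    on y then x) so repeated calls agree.
    """
    pts = np.asarray(points, dtype=float)
    c = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - c)
    n = vt[2]
    for comp in (2, 1, 0):
        if abs(n[comp]) > 1e-12:
            if n[comp] < 0:
                n = -n
            break
    return c, n


def angle_between(u: np.ndarray, v: np.ndarray) -> float:
    """Angle between two vectors, degrees in [0, 180]."""
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise GeometryError("angle of zero-length vector")
    c = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, IUPAC sign convention."""
    b0 = np.asarray(p1) - np.asarray(p0)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    return float(np.degrees(np.arctan2(y, x)))


@dataclass
class Trajectory:
    """Time-ordered geometry frames with a constant generator step."""

    frames: list[Geometry]
    dt: float | None = None        # fs, when produced by the generator
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        times = self.times
        if any(t is None for t in times):
            raise GeometryError("every trajectory frame needs a timestamp")
        if not all(b > a for a, b in zip(times, times[1:])):
            raise GeometryError("trajectory timestamps must strictly increase")

    @property
    def times(self) -> list[float]:
        return [f.time for f in self.frames]

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def frame_at(self, t: float, atol: float = 1e-6) -> Geometry:
        """Frame with timestamp ``t`` (fs), exact within ``atol``."""
        for f in self.frames:
            if abs(f.time - t) <= atol:
                return f
        raise GeometryError(f"no frame at t={t} fs "
                            f"(range {self.times[0]}..{self.times[-1]})")


# ---------------------------------------------------------------------------
# multi-frame XYZ


def _parse_comment(comment: str) -> dict:
    meta = {}
    for key, val in re.findall(r"(\w+)=(\S+)", comment):
        meta[key] = val
    return meta


def _atoms_for(elements: list[str], labels: list[str] | None) -> list[Atom]:
    if labels is None:
        if tuple(elements) == CANONICAL_ELEMENTS:
            labels = list(CANONICAL_SITE_LABELS)
        else:
            labels = [f"{e}{i}" for i, e in enumerate(elements)]
    return [Atom(e, l) for e, l in zip(elements, labels)]


def read_xyz(path) -> Trajectory:
    """Read a multi-frame XYZ file into a :class:`Trajectory`.

    The comment line may carry ``key=value`` metadata; ``t=<fs>`` provides
    the timestamp and ``labels=<comma list>`` the site labels.  Files whose
    element sequence matches the canonical 2-thiouracil order get canonical
    labels automatically.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not any(line.strip() for line in lines):
        raise GeometryError(f"{path}: empty XYZ file")
    frames: list[Geometry] = []
    i = 0
    n_atoms_first = None
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError:
            raise GeometryError(
                f"{path}: line {i + 1}: malformed atom-count line "
                f"{lines[i]!r}") from None
        if n_atoms_first is None:
            n_atoms_first = n
        elif n != n_atoms_first:
            raise GeometryError(
                f"{path}: line {i + 1}: inconsistent atom count "
                f"{n} (first frame had {n_atoms_first})")
        if i + 1 + n >= len(lines) + 1:
            raise GeometryError(f"{path}: line {i + 1}: truncated frame")
        meta = _parse_comment(lines[i + 1])
        elements, coords = [], []
        for j in range(n):
            ln = i + 2 + j
            parts = lines[ln].split()
            if len(parts) < 4:
                raise GeometryError(f"{path}: line {ln + 1}: expected "
                                    f"'element x y z', got {lines[ln]!r}")
            elements.append(parts[0])
            try:
                coords.append([float(x) for x in parts[1:4]])
            except ValueError:
                raise GeometryError(
                    f"{path}: line {ln + 1}: non-numeric coordinate "
                    f"in {lines[ln]!r}") from None
        labels = meta.pop("labels", None)
        labels = labels.split(",") if labels else None
        t = float(meta.pop("t")) if "t" in meta else None
        frames.append(Geometry(_atoms_for(elements, labels),
                               np.array(coords), time=t, meta=meta))
        i += 2 + n
    if len(frames) > 1:
        times = [f.time for f in frames]
        if any(t is None for t in times):
            raise GeometryError(f"{path}: multi-frame file without t= stamps")
        if not all(b > a for a, b in zip(times, times[1:])):
            raise GeometryError(f"{path}: frame timestamps must strictly increase")
        return Trajectory(frames)
    if frames[0].time is None:
        frames[0].time = 0.0
    return Trajectory(frames)


def write_xyz(traj: Trajectory | Geometry, path, precision: int = 6) -> None:
    """Write a geometry or trajectory as multi-frame XYZ.

    The comment line records ``t=<fs>`` plus any string-valued metadata of
    the frame and, when labels are non-canonical, a ``labels=`` list.
    """
    frames = [traj] if isinstance(traj, Geometry) else list(traj.frames)
    with open(path, "w") as fh:
        for g in frames:
            t = 0.0 if g.time is None else g.time
            fields = [f"t={t:g}"]
            fields += [f"{k}={v}" for k, v in g.meta.items()
                       if isinstance(v, (str, int, float)) and k != "t"]
            fields.append("labels=" + ",".join(g.site_labels))
            fh.write(f"{g.n_atoms}\n{' '.join(fields)}\n")
            for e, r in zip(g.elements, g.positions):
                fh.write(f"{e} {r[0]:.{precision}f} {r[1]:.{precision}f} "
                         f"{r[2]:.{precision}f}\n")
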