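"""Molecular-frame momentum representations of coincidence events.

Two symmetry-adapted frames are used to inspect S+/O+/H+ threefold
coincidences from the Coulomb explosion:

* **Recoil frame** (frame A): the S+ momentum defines the z axis and spans
  the y-z plane with the O+ momentum (O y-component >= 0); all momenta are
  rotated into this frame and normalized by |p_S|, so the sulfur always
  maps to (0, 0, 1).  Newton plots are projections of these normalized
  momenta.

* **Sum/difference frame** (frame B): built from p_S + p_O and p_S - p_O.
  The polar axis z' lies along the *sum* (the assignment validated against
  the simulated planar layout: it puts H10/H12 at the poles, H9 at
  azimuth Phi = 0 and H11 at Phi = +-180); the Phi = 0 half-plane contains
  the difference vector.  Proton emission is described by the spherical
  angles (Theta, Phi).

Both representations are invariant under global lab-frame rotations and
under uniform rescaling of all momenta.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .explosion import ExplosionResult


class DegenerateFrameError(ValueError):
    """The event's S/O momenta cannot define the requested frame."""


@dataclass
class CoincidenceEvent:
    """One S+/O+/H+ coincidence: lab-frame momentum vectors in a.u.

    ``protons`` maps a site label (or a generic label in measured mode,
    where proton identity is unknown) to a momentum vector.  ``weight`` is
    a count weight, ``delay`` an optional pump-probe delay tag in fs.
    """

    p_s: np.ndarray
    p_o: np.ndarray
    protons: dict[str, np.ndarray]
    weight: float = 1.0
    delay: float | None = None
    pumped: bool | None = None

    def __post_init__(self):
        self.p_s = np.asarray(self.p_s, dtype=float)
        self.p_o = np.asarray(self.p_o, dtype=float)
        self.protons = {k: np.asarray(v, dtype=float)
                        for k, v in self.protons.items()}
        if float(self.p_s @ self.p_s) == 0.0 or \
                float(self.p_o @ self.p_o) == 0.0:
            raise DegenerateFrameError("zero S or O momentum")
        if self.weight <= 0:
            raise ValueError("event weight must be > 0")

    @classmethod
    def from_result(cls, res: ExplosionResult,
                    proton_sites=("H9", "H10", "H11", "H12"),
                    delay: float | None = None,
                    pumped: bool | None = None) -> "CoincidenceEvent":
        """Build an event from an exploded geometry, keeping all protons."""
        return cls(
            p_s=res.momentum("S"),
            p_o=res.momentum("O"),
            protons={h: res.momentum(h) for h in proton_sites},
            delay=delay if delay is not None else res.time,
            pumped=pumped,
        )


@dataclass
class RecoilFrameEvent:
    """Event in frame A: momenta rotated and scaled by 1/|p_S|."""

    p_s: np.ndarray                 # (0, 0, 1) by construction
    p_o: np.ndarray                 # x = 0, y >= 0
    protons: dict[str, np.ndarray]
    weight: float = 1.0
    delay: float | None = None


@dataclass
class AngularEvent:
    """Per-proton spherical angles in frame B, degrees.

    ``angles`` maps proton label -> (theta, phi) with theta in [0, 180] and
    phi in (-180, 180] (+-180 identified).
    """

    angles: dict[str, tuple[float, float]]
    weight: float = 1.0
    delay: float | None = None

    def cos_theta(self, label: str) -> float:
        return float(np.cos(np.radians(self.angles[label][0])))


def cos_alpha(event: CoincidenceEvent) -> float:
    """Cosine of the relative emission angle between the S+ and O+ ions."""
    ns, no = np.linalg.norm(event.p_s), np.linalg.norm(event.p_o)
    return float(np.clip(event.p_s @ event.p_o / (ns * no), -1.0, 1.0))


def _recoil_basis(p_s: np.ndarray, p_o: np.ndarray,
                  parallel_tol: float = 1e-9) -> np.ndarray:
    z = p_s / np.linalg.norm(p_s)
    o_perp = p_o - (p_o @ z) * z
    n = np.linalg.norm(o_perp)
    if n <= parallel_tol * np.linalg.norm(p_o):
        raise DegenerateFrameError("S and O momenta parallel: y-z plane undefined")
    y = o_perp / n
    x = np.cross(y, z)              # right-handed: x cross y = z
    return np.stack([x, y, z])


def to_recoil_frame(event: CoincidenceEvent) -> RecoilFrameEvent:
    """Transform an event into frame A (rotation + 1/|p_S| scaling)."""
    basis = _recoil_basis(event.p_s, event.p_o)
    scale = 1.0 / np.linalg.norm(event.p_s)

    def tf(p):
        return basis @ p * scale

    out = RecoilFrameEvent(
        p_s=np.array([0.0, 0.0, 1.0]),   # exact by construction
        p_o=tf(event.p_o),
        protons={k: tf(v) for k, v in event.protons.items()},
        weight=event.weight,
        delay=event.delay,
    )
    out.p_o[0] = 0.0                     # exact by construction
    return out


def _sumdiff_basis(p_s: np.ndarray, p_o: np.ndarray,
                   polar_axis: str = "sum",
                   parallel_tol: float = 1e-9) -> np.ndarray:
    """Orthonormal frame-B basis rows (x', y', z').

    ``polar_axis`` selects whether z' follows the sum or the difference of
    the S/O momenta; ``"sum"`` is the assignment that reproduces the
    planar-molecule proton layout and is the default everywhere.
    """
    s = p_s + p_o
    d = p_s - p_o
    z_src, ref = (s, d) if polar_axis == "sum" else (d, s)
    nz = np.linalg.norm(z_src)
    scale = max(np.linalg.norm(p_s), np.linalg.norm(p_o))
    if nz <= parallel_tol * scale:
        raise DegenerateFrameError(f"degenerate {polar_axis} momentum: "
                                   "frame-B polar axis undefined")
    z = z_src / nz
    x_perp = ref - (ref @ z) * z
    nx = np.linalg.norm(x_perp)
    if nx <= parallel_tol * scale:
        raise DegenerateFrameError("sum and difference momenta parallel: "
                                   "frame-B azimuth undefined")
    x = x_perp / nx
    y = np.cross(z, x)
    return np.stack([x, y, z])


def to_sumdiff_frame(event: CoincidenceEvent,
                     polar_axis: str = "sum") -> AngularEvent:
    """Proton (Theta, Phi) angles in frame B."""
    basis = _sumdiff_basis(event.p_s, event.p_o, polar_axis=polar_axis)
    angles = {}
    for lab, p in event.protons.items():
        q = basis @ p
        r = np.linalg.norm(q)
        if r == 0:
            raise DegenerateFrameError(f"zero proton momentum for {lab}")
        theta = float(np.degrees(np.arccos(np.clip(q[2] / r, -1.0, 1.0))))
        phi = float(np.degrees(np.arctan2(q[1], q[0])))
        if phi <= -180.0:           # identify -180 with +180
            phi = 180.0
        angles[lab] = (theta, phi)
    return AngularEvent(angles=angles, weight=event.weight, delay=event.delay)


def wrap_phi_difference(a: float, b: float) -> float:
    """Smallest absolute difference of two azimuths under 360-degree wrap."""
    return float(abs((a - b + 180.0) % 360.0 - 180.0))


def _stack_events(events):
    """Flatten events into arrays: (p_S, p_O, weights, proton owner index,
    proton labels, proton momenta)."""
    ps = np.array([e.p_s for e in events])
    po = np.array([e.p_o for e in events])
    w = np.array([e.weight for e in events])
    idx, labs, ph = [], [], []
    for i, e in enumerate(events):
        for lab, p in e.protons.items():
            idx.append(i)
            labs.append(lab)
            ph.append(p)
    return (ps, po, w, np.array(idx, dtype=int), labs,
            np.array(ph).reshape(-1, 3))


def _sumdiff_angles_batch(events, polar_axis: str = "sum",
                          parallel_tol: float = 1e-9):
    """Vectorized frame-B angles for all protons of all events.

    Returns (cos_theta, phi_deg, weights, n_skipped_events); numerically
    identical to mapping :func:`to_sumdiff_frame` over the events, but in
    one pass.  Events with a degenerate frame are dropped and counted.
    """
    ps, po, w, idx, _labs, ph = _stack_events(events)
    s, d = ps + po, ps - po
    z_src, ref = (s, d) if polar_axis == "sum" else (d, s)
    nz = np.linalg.norm(z_src, axis=1)
    scale = np.maximum(np.linalg.norm(ps, axis=1),
                       np.linalg.norm(po, axis=1))
    ok = nz > parallel_tol * scale
    nz_safe = np.where(nz == 0, 1.0, nz)
    z = z_src / nz_safe[:, None]
    x_perp = ref - np.einsum("ik,ik->i", ref, z)[:, None] * z
    nx = np.linalg.norm(x_perp, axis=1)
    ok &= nx > parallel_tol * scale
    nx_safe = np.where(nx == 0, 1.0, nx)
    x = x_perp / nx_safe[:, None]
    y = np.cross(z, x)

    zi, xi, yi = z[idx], x[idx], y[idx]
    r = np.linalg.norm(ph, axis=1)
    r_safe = np.where(r == 0, 1.0, r)
    ct = np.clip(np.einsum("ik,ik->i", ph, zi) / r_safe, -1.0, 1.0)
    phi = np.degrees(np.arctan2(np.einsum("ik,ik->i", ph, yi),
                                np.einsum("ik,ik->i", ph, xi)))
    keep = ok[idx] & (r > 0)
    return ct[keep], phi[keep], w[idx][keep], int((~ok).sum())


# ---------------------------------------------------------------------------
# histograms


@dataclass
class Histogram2D:
    """2D histogram with Poisson errors and a normalization record."""

    xedges: np.ndarray
    yedges: np.ndarray
    counts: np.ndarray               # (nx, ny)
    errors: np.ndarray
    xlabel: str = "x"
    ylabel: str = "y"
    norm: dict = field(default_factory=dict)

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        self.errors = np.asarray(self.errors, dtype=float)
        if self.errors.shape != self.counts.shape:
            raise ValueError("error array shape must match counts")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def normalized(self) -> "Histogram2D":
        """Scale so the map integrates (sums) to 1; errors scale alike."""
        tot = self.total
        if tot == 0:
            raise ValueError("cannot normalize an empty histogram")
        return Histogram2D(self.xedges, self.yedges,
                           self.counts / tot, self.errors / tot,
                           self.xlabel, self.ylabel,
                           norm={**self.norm, "per_total_ions": tot})

    def bin_centers(self):
        return (0.5 * (self.xedges[:-1] + self.xedges[1:]),
                0.5 * (self.yedges[:-1] + self.yedges[1:]))

    def peak_position(self) -> tuple[float, float]:
        i, j = np.unravel_index(np.argmax(self.counts), self.counts.shape)
        cx, cy = self.bin_centers()
        return float(cx[i]), float(cy[j])

    def rebin(self, fx: int = 1, fy: int = 1) -> "Histogram2D":
        """Merge bins by integer factors; counts are conserved exactly."""
        nx, ny = self.counts.shape
        if nx % fx or ny % fy:
            raise ValueError(f"bin counts {nx}x{ny} not divisible by {fx}x{fy}")
        c = self.counts.reshape(nx // fx, fx, ny // fy, fy).sum(axis=(1, 3))
        e = np.sqrt((self.errors ** 2)
                    .reshape(nx // fx, fx, ny // fy, fy).sum(axis=(1, 3)))
        return Histogram2D(self.xedges[::fx], self.yedges[::fy], c, e,
                           self.xlabel, self.ylabel, dict(self.norm))


@dataclass
class Histogram1D:
    """1D histogram with Poisson errors and a normalization record."""

    edges: np.ndarray
    counts: np.ndarray
    errors: np.ndarray
    label: str = "x"
    norm: dict = field(default_factory=dict)

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    def normalized(self) -> "Histogram1D":
        tot = self.total
        if tot == 0:
            raise ValueError("cannot normalize an empty histogram")
        return Histogram1D(self.edges, self.counts / tot, self.errors / tot,
                           self.label, {**self.norm, "per_total_ions": tot})

    def peak_center(self) -> float:
        return float(self.centers[np.argmax(self.counts)])


def cos_alpha_histogram(events, bin_width: float = 0.05) -> Histogram1D:
    """Histogram of cos(alpha) over events, bins of ``bin_width`` on [-1, 1]."""
    ps = np.array([e.p_s for e in events])
    po = np.array([e.p_o for e in events])
    weights = np.array([e.weight for e in events])
    values = np.clip(
        np.einsum("ik,ik->i", ps, po)
        / (np.linalg.norm(ps, axis=1) * np.linalg.norm(po, axis=1)),
        -1.0, 1.0)
    edges = np.arange(-1.0, 1.0 + bin_width / 2, bin_width)
    counts, _ = np.histogram(values, bins=edges, weights=weights)
    return Histogram1D(edges, counts.astype(float), np.sqrt(counts),
                       label="cos(alpha)")


def newton_plot(events, plane: str = "y-z", species: str = "H",
                bins: int = 100, extent: float = 1.5,
                warn=None) -> Histogram2D:
    """Newton plot: 2D histogram of normalized recoil-frame momenta.

    ``plane`` selects the projection ("y-z" top view or "x-z" side view);
    ``species`` selects which ions enter ("H" for all protons, "O" for
    oxygen, "OH" for both).  Events whose frame is degenerate are skipped
    and counted in the histogram's ``norm["skipped"]``.
    """
    if plane not in ("y-z", "x-z"):
        raise ValueError(f"unknown plane {plane!r}")
    ax_a, ax_b = (1, 2) if plane == "y-z" else (0, 2)
    pts, wts = [], []
    skipped = 0
    for e in events:
        try:
            fe = to_recoil_frame(e)
        except DegenerateFrameError:
            skipped += 1
            continue
        if "O" in species:
            pts.append((fe.p_o[ax_a], fe.p_o[ax_b]))
            wts.append(fe.weight)
        if "H" in species:
            for p in fe.protons.values():
                pts.append((p[ax_a], p[ax_b]))
                wts.append(fe.weight)
    edges = np.linspace(-extent, extent, bins + 1)
    if not pts:
        if warn is not None:
            warn("empty selection: Newton plot has no entries")
        z = np.zeros((bins, bins))
        return Histogram2D(edges, edges, z, z.copy(),
                           xlabel=f"p_{plane[0]}/|p_S|", ylabel="p_z/|p_S|",
                           norm={"skipped": skipped})
    pts = np.array(pts)
    counts, _, _ = np.histogram2d(pts[:, 0], pts[:, 1], bins=[edges, edges],
                                  weights=np.array(wts))
    return Histogram2D(edges, edges, counts, np.sqrt(counts),
                       xlabel=f"p_{plane[0]}/|p_S|", ylabel="p_z/|p_S|",
                       norm={"skipped": skipped, "n_ions": float(len(pts))})


def angular_map(events, phi_bins: int = 72, costheta_bins: int = 40,
                polar_axis: str = "sum", normalize: bool = False,
                warn=None) -> Histogram2D:
    """Proton occupancy map over (Phi, cos Theta) in frame B.

    With ``normalize=True`` the map is scaled by its integrated number of
    ions so different delay steps can be compared.
    """
    phi_edges = np.linspace(-180.0, 180.0, phi_bins + 1)
    ct_edges = np.linspace(-1.0, 1.0, costheta_bins + 1)
    events = list(events)
    if not events:
        if warn is not None:
            warn("empty selection: angular map has no entries")
        z = np.zeros((phi_bins, costheta_bins))
        return Histogram2D(phi_edges, ct_edges, z, z.copy(),
                           xlabel="Phi (deg)", ylabel="cos(Theta)",
                           norm={"skipped": 0})
    cts, phis, wts, skipped = _sumdiff_angles_batch(events,
                                                    polar_axis=polar_axis)
    if cts.size == 0:
        if warn is not None:
            warn("empty selection: angular map has no entries")
        z = np.zeros((phi_bins, costheta_bins))
        return Histogram2D(phi_edges, ct_edges, z, z.copy(),
                           xlabel="Phi (deg)", ylabel="cos(Theta)",
                           norm={"skipped": skipped})
    # put the +180 representative in the last bin
    phis = np.where(phis >= 180.0, np.nextafter(180.0, -1), phis)
    counts, _, _ = np.histogram2d(phis, cts, bins=[phi_edges, ct_edges],
                                  weights=wts)
    h = Histogram2D(phi_edges, ct_edges, counts, np.sqrt(counts),
                    xlabel="Phi (deg)", ylabel="cos(Theta)",
                    norm={"skipped": skipped, "n_ions": float(len(phis))})
    return h.normalized() if normalize else h


def count_features(hist: Histogram2D, threshold_frac: float = 0.2) -> int:
    """Number of 4-connected components above a fraction of the maximum.

    This is the deterministic contract behind "cleanly separated features":
    threshold at ``threshold_frac`` of the histogram maximum and count
    connected components with 4-connectivity.
    """
    if hist.counts.max() <= 0:
        return 0
    mask = hist.counts >= threshold_frac * hist.counts.max()
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    _, n = ndimage.label(mask, structure=structure)
    return int(n)
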