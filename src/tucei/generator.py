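"""Synthetic 2-thiouracil geometries and excited-state trajectory ensembles.

The generator emulates the geometric signatures of the first picosecond of
UV-excited 2-thiouracil that the rest of the pipeline probes:

* a planar ground state (S0) whose C2->S / C4->O bond-vector angle is 116 deg,
* an early local pyramidalization at C2 that carries the N1-C2-N3 triangle
  and its protons out of the ring plane (geometry "G2"),
* a later sulfur out-of-plane bend with C-S elongation that drives the
  bond-vector angle towards 104 deg (geometry "G3"),
* thermal out-of-plane smearing of the vibrational ground state, and
* smooth staged onsets of the two deformations along a trajectory.

No electronic structure is computed anywhere: these are purely kinematic
deformation presets applied to a fixed reference frame geometry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy.spatial.transform import Rotation

from .geometry import (
    Geometry,
    GeometryError,
    RING_SITES,
    Trajectory,
    angle_between,
    read_xyz,
)

S0_FIXTURE = "s0_2thiouracil.xyz"
S0_CO_CS_ANGLE = 116.0   # deg, ground-state C2->S vs C4->O bond-vector angle
G3_CO_CS_ANGLE = 104.0   # deg, late-time value the G3 preset approaches

#: default RMS out-of-plane thermal displacement per atom, Angstrom
DEFAULT_SIGMA_OOP = 0.05


def ring_normal(g: Geometry) -> np.ndarray:
    """Unit normal of the ring, oriented by the N1->C2->...->C6 circulation.

    Unlike a raw SVD normal this sign convention co-rotates with the
    molecule, which makes every deformation operator equivariant under
    global rotations.
    """
    pts = np.array([g.r(s) for s in RING_SITES])
    c = pts.mean(axis=0)
    rel = pts - c
    n = np.sum(np.cross(rel, np.roll(rel, -1, axis=0)), axis=0)
    norm = np.linalg.norm(n)
    if norm < 1e-12:
        raise GeometryError("degenerate ring: cannot orient plane normal")
    return n / norm


def co_cs_angle(g: Geometry) -> float:
    """Angle between the C2->S and C4->O bond vectors, degrees."""
    return angle_between(g.bond_vector("C2", "S"), g.bond_vector("C4", "O"))


# ---------------------------------------------------------------------------
# S0 builder


def _load_fixture() -> Geometry:
    with resources.as_file(
            resources.files("tucei.data").joinpath(S0_FIXTURE)) as p:
        traj = read_xyz(p)
    g = traj.frames[0]
    g.meta["preset"] = "S0"
    return g


def build_s0(overrides: dict[str, float] | None = None) -> Geometry:
    """Planar ground-state 2-thiouracil.

    Parameters
    ----------
    overrides:
        Optional internal-coordinate overrides applied to the packaged
        fixture: ``cs_bond`` / ``co_bond`` / ``nh_bond`` / ``ch_bond``
        (Angstrom) rescale the exocyclic and X-H bonds along their bond
        vectors; ``co_cs_angle`` (degrees) sets the C2->S vs C4->O
        bond-vector angle by an in-plane rotation of S about C2
        (default 116.0).

    The result is planar by construction and validated against the
    12-atom / C4H4N2OS / no-clash contract.
    """
    ov = dict(overrides or {})
    g = _load_fixture()

    def stretch_bond(anchor: str, atom: str, length: float):
        v = g.bond_vector(anchor, atom)
        g.positions[g.index(atom)] = g.r(anchor) + v / np.linalg.norm(v) * length

    if "cs_bond" in ov:
        stretch_bond("C2", "S", ov.pop("cs_bond"))
    if "co_bond" in ov:
        stretch_bond("C4", "O", ov.pop("co_bond"))
    if "nh_bond" in ov:
        length = ov.pop("nh_bond")
        stretch_bond("N1", "H9", length)
        stretch_bond("N3", "H10", length)
    if "ch_bond" in ov:
        length = ov.pop("ch_bond")
        stretch_bond("C5", "H11", length)
        stretch_bond("C6", "H12", length)
    target = ov.pop("co_cs_angle", S0_CO_CS_ANGLE)
    if ov:
        raise GeometryError(f"unknown internal-coordinate overrides: {sorted(ov)}")

    _set_co_cs_angle_inplane(g, target)
    try:
        g.validate_2tura()
    except GeometryError as exc:
        raise GeometryError(f"override produced an invalid geometry: {exc}") from exc
    return g


def _set_co_cs_angle_inplane(g: Geometry, target: float) -> None:
    """Rotate S in-plane about C2 until angle(C2->S, C4->O) == target."""
    n = ring_normal(g)
    cs = g.bond_vector("C2", "S")
    co = g.bond_vector("C4", "O")
    current = angle_between(cs, co)
    delta = target - current
    if abs(delta) < 1e-10:
        return
    for sign in (1.0, -1.0):
        rot = Rotation.from_rotvec(np.radians(sign * delta) * n)
        cand = rot.apply(cs)
        if abs(angle_between(cand, co) - target) < 1e-8:
            g.positions[g.index("S")] = g.r("C2") + cand
            return
    raise GeometryError(f"cannot reach co_cs_angle={target} deg by in-plane rotation")


# ---------------------------------------------------------------------------
# deformation operators


def apply_c2_pyramidalization(g: Geometry, angle: float,
                              move_nh_hydrogens: bool = True) -> Geometry:
    """Pyramidalize the ring at C2 by rotating it about the N1-N3 axis.

    A positive angle lifts C2 towards the ring-circulation normal.  With
    ``move_nh_hydrogens`` (the G2 preset) the protons attached to N1 and N3
    follow the same rotation, emulating the N1-C2-N3 triangle folding out of
    the plane.  C4, C5, C6 (and S, whose motion is a separate operator) are
    untouched.
    """
    if not np.isfinite(angle):
        raise GeometryError("pyramidalization angle must be finite")
    if abs(angle) > 90.0:
        raise GeometryError(f"|pyramidalization angle| {abs(angle):.1f} deg "
                            "> 90 deg is outside the preset's validity")
    out = g.copy()
    if angle == 0.0:
        return out
    axis = out.bond_vector("N1", "N3")
    axis = axis / np.linalg.norm(axis)
    origin = out.r("N1")
    rot = Rotation.from_rotvec(np.radians(angle) * axis)
    movers = ["C2"] + (["H9", "H10"] if move_nh_hydrogens else [])
    for s in movers:
        i = out.index(s)
        out.positions[i] = origin + rot.apply(out.positions[i] - origin)
    out.meta["pucker_angle"] = angle
    return out


def apply_sulfur_oop(g: Geometry, angle: float, stretch: float = 0.0,
                     target_co_cs_angle: float | None = None) -> Geometry:
    """Bend the sulfur out of the ring plane about C2 and stretch C2-S.

    The C2->S bond vector is tilted by ``angle`` degrees towards the
    ring-circulation normal and lengthened by ``stretch`` Angstrom.  When
    ``target_co_cs_angle`` is given, the in-plane component of the bond is
    additionally rotated so that the total C2->S / C4->O bond-vector angle
    equals the target (the G3 preset pairs the out-of-plane bend with an
    in-plane closing towards 104 deg).  Ring atoms are untouched.
    """
    out = g.copy()
    if angle == 0.0 and stretch == 0.0 and target_co_cs_angle is None:
        return out
    n = ring_normal(out)
    cs = out.bond_vector("C2", "S")
    length = np.linalg.norm(cs) + stretch
    if length <= 0:
        raise GeometryError(f"C2-S stretch {stretch} A collapses the bond")
    # split into in-plane and out-of-plane parts
    cs_ip = cs - (cs @ n) * n
    nip = np.linalg.norm(cs_ip)
    if nip < 1e-12:
        raise GeometryError("C2-S bond parallel to ring normal; bend undefined")
    u_ip = cs_ip / nip

    beta = np.radians(angle)
    if target_co_cs_angle is not None:
        co = out.bond_vector("C4", "O")
        norm_co = np.linalg.norm(co)
        co_oop = float(co @ n)
        co_ip = co - co_oop * n
        nco_ip = np.linalg.norm(co_ip)
        co_ip /= nco_ip
        # direction u(phi) = cos(beta) R(phi, n) co_ip + sin(beta) n gives
        # cos(total) |co| = cos(beta) cos(phi) |co_ip| + sin(beta) (co.n)
        c_target = np.cos(np.radians(target_co_cs_angle))
        c_phi = (c_target * norm_co - np.sin(beta) * co_oop) / \
            (np.cos(beta) * nco_ip)
        if abs(c_phi) > 1.0 + 1e-9:
            raise GeometryError(
                f"target co_cs_angle {target_co_cs_angle} deg unreachable "
                f"with out-of-plane bend {angle} deg")
        phi = np.arccos(np.clip(c_phi, -1.0, 1.0))
        # rotate co_ip by +-phi about n; keep the side the bond already lies on
        cands = [Rotation.from_rotvec(s * phi * n).apply(co_ip)
                 for s in (1.0, -1.0)]
        u_ip = max(cands, key=lambda u: float(u @ (cs_ip / nip)))
    direction = np.cos(beta) * u_ip + np.sin(beta) * n
    out.positions[out.index("S")] = out.r("C2") + length * direction
    out.meta["s_oop_angle"] = angle
    out.meta["cs_stretch"] = stretch
    return out


# ---------------------------------------------------------------------------
# thermal ensembles


def thermal_ensemble(g: Geometry, sigma_oop: float = DEFAULT_SIGMA_OOP,
                     n: int = 1, seed: int | None = 0,
                     mass_weighted: bool = False,
                     isotropic: bool = False,
                     rng: np.random.Generator | None = None) -> list[Geometry]:
    """Thermally smeared copies of a geometry.

    Each copy receives independent zero-mean Gaussian displacements of
    standard deviation ``sigma_oop`` (Angstrom) per atom along the ring
    normal (``isotropic=True`` displaces all three Cartesian components
    instead).  With ``mass_weighted=True`` the per-atom amplitude scales as
    ``sqrt(m_H / m_i)`` so heavy atoms move less, as equipartition of a
    vibrational mode would give.  Seed-reproducible.
    """
    if n < 1:
        raise GeometryError(f"ensemble size {n} < 1")
    if sigma_oop < 0:
        raise GeometryError("sigma_oop must be >= 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    normal = ring_normal(g)
    scale = np.ones(g.n_atoms)
    if mass_weighted:
        masses = g.masses_amu
        scale = np.sqrt(masses.min() / masses)
    out = []
    for k in range(n):
        c = g.copy()
        if sigma_oop > 0:
            if isotropic:
                disp = rng.normal(0.0, sigma_oop, size=(g.n_atoms, 3))
                disp *= scale[:, None]
            else:
                z = rng.normal(0.0, sigma_oop, size=g.n_atoms) * scale
                disp = z[:, None] * normal[None, :]
            c.positions = c.positions + disp
        c.meta["thermal_index"] = k
        out.append(c)
    return out


# ---------------------------------------------------------------------------
# staged-onset excited-state trajectories


@dataclass
class DeformationParams:
    """Amplitudes and onset times of the two symmetry-breaking motions.

    ``tau_pucker`` / ``tau_s`` are the fs onset times of the C2
    pyramidalization and of the sulfur out-of-plane bend plus C-S stretch:
    each motion rises smoothly over the ``ramp_width`` fs *preceding* its
    onset time and is fully developed at it, so a measurement at the onset
    delay already sees the complete deformation (and none of it one ramp
    width earlier).  The late-time C2->S / C4->O bond-vector angle
    approaches ``target_co_cs_angle``.  In the default staged scenario
    ``tau_s >= tau_pucker``; the reverse is permitted (e.g. for symmetry
    checks) but warned about.
    """

    pucker_angle: float = 30.0        # deg, G2 preset
    s_oop_angle: float = 40.0         # deg, G3 preset
    cs_stretch: float = 0.1           # Angstrom, G3 preset
    tau_pucker: float = 65.0          # fs
    tau_s: float = 130.0              # fs
    ramp_width: float = 30.0          # fs
    target_co_cs_angle: float = G3_CO_CS_ANGLE

    def __post_init__(self):
        if self.tau_pucker < 0:
            raise GeometryError("tau_pucker must be >= 0")
        if self.tau_s < self.tau_pucker:
            warnings.warn("tau_s < tau_pucker: sulfur motion precedes the "
                          "pucker, which reverses the default staging",
                          stacklevel=2)
        if self.ramp_width <= 0:
            raise GeometryError("ramp_width must be > 0")


def onset_ramp(t: np.ndarray | float, tau: float, width: float):
    """Causal smoothstep onset: 0 up to tau - width, 1 from tau onwards.

    The rise is the cubic smoothstep 3 s^2 - 2 s^3 over [tau - width, tau]
    (clipped at t = 0, so the rise shortens when tau < width and the t = 0
    frame is always undeformed).
    """
    t = np.asarray(t, dtype=float)
    start = max(tau - width, 0.0)
    denom = tau - start
    if denom <= 0:
        return (t >= tau).astype(float)
    s = np.clip((t - start) / denom, 0.0, 1.0)
    return s * s * (3.0 - 2.0 * s)


def deform_frame(base: Geometry, p: DeformationParams, t: float) -> Geometry:
    """Geometry at time ``t`` fs of the staged deformation applied to ``base``.

    The sulfur bend is applied on the opposite side of the ring plane from
    the C2 pucker (sp3-like pyramidalization at C2 puts the substituent
    anti to the displaced ring atom), so the two motions reinforce rather
    than cancel in the fragment-momentum observables.
    """
    amp_p = float(onset_ramp(t, p.tau_pucker, p.ramp_width))
    amp_s = float(onset_ramp(t, p.tau_s, p.ramp_width))
    g = base
    if amp_p > 0:
        g = apply_c2_pyramidalization(g, p.pucker_angle * amp_p)
    if amp_s > 0:
        # interpolate the bond-vector angle from its current (thermal) value
        # towards the G3 target as the sulfur motion switches on
        start = co_cs_angle(g)
        target = (1.0 - amp_s) * start + amp_s * p.target_co_cs_angle
        g = apply_sulfur_oop(g, -np.sign(p.pucker_angle) * p.s_oop_angle * amp_s,
                             stretch=p.cs_stretch * amp_s,
                             target_co_cs_angle=target)
    out = g if g is not base else base.copy()
    out.time = t
    return out


def synth_excited_trajectory(p: DeformationParams | None = None,
                             t_end: float = 1000.0, dt: float = 5.0,
                             seed: int | None = 0,
                             sigma_oop: float = DEFAULT_SIGMA_OOP,
                             base: Geometry | None = None) -> Trajectory:
    """One synthetic excited-state trajectory with staged deformation onsets.

    Frames are emitted at t = 0, dt, ..., t_end fs.  The t = 0 frame is a
    thermally sampled S0 geometry (exactly; the onset ramps vanish at 0) and
    late frames approach the G3 preset including its target bond-vector
    angle.
    """
    if p is None:
        p = DeformationParams()
    if not (0 < dt <= t_end):
        raise GeometryError(f"need 0 < dt <= t_end, got dt={dt}, t_end={t_end}")
    if base is None:
        base = thermal_ensemble(build_s0(), sigma_oop=sigma_oop, n=1,
                                seed=seed)[0]
    times = np.arange(0.0, t_end + dt / 2, dt)
    frames = [deform_frame(base, p, float(t)) for t in times]
    meta = {"seed": seed, "sigma_oop": sigma_oop, "params": p}
    return Trajectory(frames, dt=dt, metadata=meta)


def synth_trajectory_ensemble(p: DeformationParams | None = None,
                              n: int = 100, t_end: float = 1000.0,
                              dt: float = 5.0, seed: int = 0,
                              sigma_oop: float = DEFAULT_SIGMA_OOP
                              ) -> list[Trajectory]:
    """Ensemble of trajectories with independent thermal initial conditions."""
    seeds = np.random.SeedSequence(seed).spawn(n)
    out = []
    for k, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        base = thermal_ensemble(build_s0(), sigma_oop=sigma_oop, n=1,
                                rng=rng)[0]
        traj = synth_excited_trajectory(p, t_end=t_end, dt=dt,
                                        seed=seed, sigma_oop=sigma_oop,
                                        base=base)
        traj.metadata["member"] = k
        out.append(traj)
    return out
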